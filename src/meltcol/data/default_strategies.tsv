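rank	taxon	strategy	citation
class	Betaproteobacteria	copiotroph	commonly r-selected in resource pulses
class	Gammaproteobacteria	copiotroph	fast-growing opportunists
class	Clostridia	copiotroph	fermentative r-strategists
class	Bacilli	copiotroph	spore-forming fast growers
phylum	Bacteroidetes	oligotroph	reclassified K-strategists in recent soil surveys
phylum	Acidobacteria	oligotroph	canonical soil oligotrophs
phylum	Verrucomicrobia	oligotroph	slow-growing soil clades
phylum	Chloroflexi	oligotroph	stress-tolerant K-strategists
phylum	Planctomycetes	oligotroph	slow-growing aquatic/soil clades
phylum	Gemmatimonadetes	oligotroph	dry-soil K-strategists
phylum	Actinobacteria	oligotroph	most-recent classification; contested in the literature
phylum	Proteobacteria	unclear	heterogeneous; classify at class level
genus	Massilia	copiotroph	fast growth rates on labile substrates
genus	Pseudomonas	copiotroph	classic r-strategist
genus	Polaromonas	oligotroph	cold-adapted slow grower
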