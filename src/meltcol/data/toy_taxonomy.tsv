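feature_id	domain	phylum	class	order	family	genus
A01	Bacteria	Proteobacteria	Gammaproteobacteria	Pseudomonadales	Moraxellaceae	Psychrobacter
A02	Bacteria	Cyanobacteria	Oxyphotobacteria	Nostocales	Nostocaceae	Nostoc
A03	Bacteria	Acidobacteria	Acidobacteriia	Acidobacteriales	Acidobacteriaceae	Granulicella
A04	Bacteria	Verrucomicrobia	Verrucomicrobiae	Chthoniobacterales	Chthoniobacteraceae	Chthoniobacter
A05	Bacteria	Chloroflexi	Chloroflexia	Ktedonobacterales	Ktedonobacteraceae	Ktedonobacter
A06	Bacteria	Gemmatimonadetes	Gemmatimonadetes_c	Gemmatimonadales	Gemmatimonadaceae	Gemmatimonas
A07	Bacteria	Actinobacteria	Actinobacteria_c	Micrococcales	Micrococcaceae	Arthrobacter
A08	Bacteria	Planctomycetes	Planctomycetia	Planctomycetales	Planctomycetaceae	Planctomyces
A09	Bacteria	Proteobacteria	Betaproteobacteria	Burkholderiales	Oxalobacteraceae	Janthinobacterium
A10	Bacteria	Firmicutes	Bacilli	Bacillales	Bacillaceae	Bacillus
A11	Bacteria	Proteobacteria	Betaproteobacteria	Burkholderiales	Oxalobacteraceae	Massilia
A12	Bacteria	Bacteroidetes	Sphingobacteriia	Sphingobacteriales	Sphingobacteriaceae	Pedobacter
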