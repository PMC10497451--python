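# Methods

## Study design assumed by the pipeline

The pipeline targets a melt-season time series: three compartments — surface
snow (the layer in contact with the atmosphere), bulk snow (the underlying
layers), and soil — sampled on a set of ordered days (default D1, D4, D8, D11,
D15, D19; 18 samples), plus pooled negative controls (extraction-kit and
sequencing blanks). Counts are ASV × sample integers. Days are calendar-offset
integers, never indices. Surface and bulk snow are merged by OR into a single
"snow" habitat for the coloniser rules, because the question is whether a
feature was anywhere in the snowpack; per-layer provenance is retained in the
detection history for reporting.

## Contaminant identification (prevalence method)

Snow is low-biomass, so reagent contamination can dominate amplicon libraries.
For each feature we form the 2×2 contingency table of presence/absence ×
control/sample, where presence means count ≥ 1 (configurable). The score is the
one-sided significance probability of *control enrichment*: when every
expected cell count is ≥ 5 we use the chi-square statistic and halve the
two-sided p-value in the signed direction (score = p/2 if the feature is more
prevalent in controls, 1 − p/2 otherwise); otherwise we use the exact
hypergeometric (one-sided Fisher) tail probability. Small scores mean
control-enriched; a feature is flagged when score < threshold (default 0.5,
"more prevalent in controls than in samples"). The flagged set is monotone in
the threshold by construction.

Degenerate features: present only in controls → score forced to 0 (contaminant
by definition); absent everywhere → score undefined, retained by convention
and logged in the report. Extraction and sequencing controls are pooled into
one control class. The chi-square/exact-fallback semantics are this package's
documented definition of the prevalence test; agreement with any particular
external implementation's internals is not a contract.

## Coloniser classification

Each feature's history is a boolean detection matrix over
{snow, soil} × days, with detection = count ≥ `detection_threshold`
(default 1, applied after contaminant removal). A (habitat, day) cell with no
underlying sample is *missing* — "no evidence", never treated as absence.
Classes are evaluated in precedence order:

1. `snow_only` — never detected in soil;
2. `soil_only` — never detected in snow;
3. `resident_day1` — detected in soil on the first sampling day (the rule only
   fires if a day-1 soil sample exists); takes precedence over `soil_first`;
4. `soil_first` — earliest soil detection strictly precedes earliest snow
   detection; a same-day tie is resolved by `tie_policy` (default
   `soil_first`, the conservative exclusion — a same-day first appearance
   cannot show snow origin);
5. `potential_coloniser` — the remainder: absent from day-1 soil, snow-first,
   later in soil — subject to the snow-persistence policy; a feature failing
   the policy is demoted to `soil_first`.

"Consistently identified in the snow" is genuinely ambiguous for occupancy
rules, so the policy is configurable and recorded in the report:

* `any` (default): ≥ 1 snow detection — the operative reading of
  "first identified in snow, subsequently observed in soil";
* `all_days`: detected in snow on every sampling day with snow data;
* `before_soil`: detected in snow on every sampling day strictly before the
  first soil detection.

**Successful colonisers** are potential colonisers with
≥ `min_soil_detections` soil detections (default 2) including, by default, the
final sampling day. The study design has exactly one soil sample per day, so
"soil samples" and "soil detection days" coincide; the implementation counts
days. The classes partition the features and successful ⊆ potential on every
input; both properties, and exhaustive agreement with a brute-force
set-operation classifier over all boolean histories for 5- and 6-day designs,
are asserted in the test suite.

## Life strategies

Successful colonisers are annotated copiotroph / oligotroph / unclear through
an ordered (rank, taxon) → strategy lookup; the most specific matching rank
wins (genus > family > … > domain), no match → unclear. Literature
classifications at this granularity are coarse and contested (several phyla
have been classified both ways), so the mapping is shipped as editable data
(`data/default_strategies.tsv`) with a provenance note per rule. The bundled
table is a small partial reconstruction covering common Arctic soil/snow taxa,
not a literature survey; analyses that depend on the tally should supply a
curated table.

## Community statistics

* **Alpha diversity**: Shannon H = −Σ pᵢ ln pᵢ (natural log), with observed
  richness reported alongside; output headers name the index. H ≤ ln(richness)
  with equality iff uniform.
* **Bray–Curtis**: d(j,k) = Σ|xᵢⱼ−xᵢₖ| / Σ(xᵢⱼ+xᵢₖ) on TSS fractions or raw
  counts; a semimetric (no triangle inequality asserted). Two all-zero samples
  get distance 0 with a warning.
* **PCoA**: classical metric scaling (double-centre −½D², eigendecompose, via
  scikit-bio). Negative eigenvalues are reported, not corrected (no
  Lingoes/Cailliez); their axes are excluded, and axis signs are arbitrary. If
  fewer positive eigenvalues exist than requested axes, the result is
  truncated with a warning.
* **Phylum composition**: per-sample phylum fractions; a phylum is lumped into
  "Other (<1%)" when its *mean* fraction within its grouping (default: one
  global group; per-compartment grouping available) is below `min_fraction`
  (default 0.01). Features without a phylum go to "Unassigned".
* **Time trends**: simple OLS of a per-sample value on day; R² and the
  two-sided p from the F(1, n−2) test (equivalently the slope t-test).
  A constant response returns slope 0, R² 0, p 1. No multiple-testing
  correction is applied to trend p-values; callers screening many trends must
  correct downstream.
* **Total sum scaling** divides each sample by its library size; all-zero
  samples stay zero with a warning rather than an error, since a sample can
  legitimately be emptied by contaminant removal.

## Synthetic data generator

The simulator emulates the assumed study design: 6 days × 3 compartments plus
6 negative controls, ~10²–10³ features by default, uneven depth, planted
colonisers, planted contaminants.

* **Profiles.** The snow community is a log-normal relative-abundance profile
  (σ = 1.5 by default — snow communities are uneven) over snow-only features,
  shared background, and colonisers; the soil community an independent
  log-normal profile (σ = 1.0, more even and richer by default: 600 residents
  vs 300 snow features) over residents and shared background.
* **Drift.** Day-to-day compositional change is multiplicative log-normal
  jitter on the previous day's profile (σ = 0.3/day), renormalised — a random
  walk in log-abundance. A Dirichlet resampling scheme was considered and
  rejected: at realistic concentrations it absorbs rare features at zero
  within a step or two, which would silently delete planted colonisers from
  the snow mid-series and break the generator's own ground-truth contract
  (colonisers are in the snow from day 1 onward).
* **Transfer.** From `transfer_day` (default D8, after the melt peak) each
  coloniser establishes in soil with probability
  `coloniser_establishment_prob` per day, contributing relative abundance
  `transfer_fraction × (snow abundance) × (snow:soil biomass ratio)` before
  renormalisation. The biomass ratio defaults to 10⁻²: snow carries orders of
  magnitude fewer cells than soil, so arriving cells are rare in the soil
  pool. Ground truth records the days each coloniser was actually present in
  the soil community (pre-sampling), which is what recovery is scored against.
* **Contaminants and controls.** Contaminant features appear in negative
  controls at `contaminant_control_prevalence` (default 0.9) and in real
  samples at a low background prevalence (default 0.05); controls also pick up
  sparse cross-talk from real features (rate 0.01).
* **Depth.** Per-sample read depth is log-normal around `depth_mean`
  (default 27,000 reads — a typical per-sample MiSeq amplicon yield)
  with log-σ `depth_dispersion` (0.3); reads are assigned multinomially, so
  column sums equal the drawn depths exactly. All randomness comes from one
  seeded generator: same config + seed → bit-identical output.

**What the defaults do and do not show.** At the default depth and biomass
ratio, a planted coloniser's soil relative abundance is
~10⁻³ × its snow abundance, mostly *below* the detection limit — the honest
consequence of low snow biomass: occupancy detection of colonisers at survey
depth is hard, and default-regime runs recover only the most abundant planted
colonisers. Method validity is therefore established in an idealised
noise-free regime (`recovery_benchmark_config`): 200 features, 20 colonisers,
depth 10⁵, establishment probability 1, transfer fraction 1, biomass ratio 1,
no control cross-talk. There the potential-coloniser set recovers every
planted coloniser (sensitivity 1.0) with precision ≥ 0.95 across 20 seeds, and
recovery sensitivity is non-increasing in the detection threshold. The
simulator does not model snow physics (percolation, refreeze), growth
dynamics after establishment, chimeras/index-hopping, or eukaryotes; passing
tests show the *rules* behave as specified under the generative model, not
that any particular field dataset will yield a given coloniser count.

## Numerical and degenerate-input choices

* Count tables validate non-negativity, integer values, and ID uniqueness at
  construction; a zero-feature table (after filtering) is valid downstream.
* `filter_min_abundance` thresholds on feature totals and is idempotent.
* The exact contaminant test matches an independent hypergeometric
  enumeration to < 10⁻¹⁰ on all 2×2 tables with margins ≤ 12 (asserted in the
  tests at machine precision).
* PCoA round-trips Euclidean configurations to 10⁻⁹; Bray–Curtis, Shannon and
  OLS trends match closed forms to 10⁻¹⁰.
* Ties at the same rank in a strategy table are a validation error at load.

## Known limitations

* The contaminant test's chi-square branch is an asymptotic approximation; its
  decisions near the threshold can differ from the exact test at matched
  margins (only the exact branch carries the enumeration guarantee).
* Life-strategy assignment inherits the weaknesses of taxonomy-based trait
  inference; the default table is deliberately small and flagged as such.
* One soil sample per day means soil-sample and soil-day counts coincide;
  designs with replicate soil samples per day would need a per-sample
  successful-coloniser rule.
* BIOM support covers plain count tables (no observation metadata round-trip).
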