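# Methods

This note documents the models, numerical conventions, and design choices
behind `peatnet`, and what the synthetic tests do and do not establish
about real data.

## Soil-carbon chemistry

A closed-flask incubation (fresh peat in a sealed flask at a controlled
temperature) yields CO2 concentrations c0 and c1 (volume ppm) at the start
and end of the incubation. The SOC-normalised mineralization rate is

    CMR = Δc · V · M / (m · Δt · 22.4) · α / SOC,   α = 273/(273 + T),

with Δc = c1 − c0, V the headspace void volume (L), M = 12 g/mol (mass of
carbon — the output is mg *C*, not mg CO2; "molar mass of CO2's carbon" is
stated explicitly because the phrase is ambiguous), m soil mass (kg), Δt
days, 22.4 L/mol the standard molar gas volume, and T in °C. The formula
is applied exactly as stated; whether gas-chromatograph readings were
already temperature-corrected upstream is the caller's responsibility.
Unit bookkeeping lives in one place (`chem.py`) so alternative dialects
(e.g. mg CO2 output) can be derived without touching callers. Void volume
is a direct input; a typical setup is a 250 ml flask with 30 g of soil,
but headspace is measured, not assumed. Division guards name the offending
field; a zero concentration change legitimately returns 0.

The FTIR recalcitrance index is the corrected 1630/1030 peak-area ratio
(aromatic/carboxylate bands over the polysaccharide band). The DOC
carbohydrate share uses the linear calibration
`percent = 49204 · carb − 1.7606` on the area-normalised ~1030 cm⁻¹ peak
height; a negative result means the sample is below the calibration range
and is *flagged*, never clamped, to preserve auditability. Raw spectral
processing (baseline correction, peak integration over 4000–400 cm⁻¹) is
out of scope; inputs are pre-extracted peak summaries.

## OTU-table processing

Counts are taxa × samples with semicolon-delimited lineages. Conventions:

* **Rarefaction** draws from the multivariate hypergeometric distribution
  (subsampling *without* replacement), the community standard; the default
  depth is 39 575 reads/sample. Samples below depth cannot be rarefied and
  are dropped with a loud provenance entry (the alternative — keeping them
  unrarefied — silently breaks downstream comparability).
* **Archaea removal** matches the domain rank case-insensitively with or
  without `d__`/`k__`/`D_0__` prefixes, covering both Greengenes-style and
  bare SILVA lineages, and logs the read fraction removed.
* **Top-N selection** (default 2000) keeps the highest total counts; ties
  at the cutoff break by taxon ID ascending, making selection reproducible.
* Every filter appends to the table's provenance log, so a finished run
  can narrate counts in/out per stage.

## SparCC correlation inference

Fractions are compositional, so naive correlations are biased negative.
SparCC works with log-ratio variances t(i,j) = Var log(xᵢ/xⱼ) =
ωᵢ + ωⱼ − 2ρᵢⱼ√(ωᵢωⱼ), where ω are basis (absolute-abundance) log
variances. Under approximate sparsity of true correlations, row sums of t
give the linear system M ω = t·1 with M = diag(p−1) + (1 − I), after which
ρᵢⱼ = (ωᵢ + ωⱼ − t(i,j)) / (2√(ωᵢωⱼ)).

Numerical conventions, all configurable, following the original method's
defaults since only the two downstream thresholds are study-level choices:

* 20 Dirichlet resamples per estimate (fractions drawn per sample from
  Dirichlet(counts + 1)), aggregated by the element-wise median;
* iterative exclusion: per round, the strongest not-yet-excluded pair with
  |ρ| > 0.1 is removed from the sums and the system re-solved, up to 10
  rounds; a pair is never excluded if either taxon would drop below three
  remaining partners (the system becomes singular otherwise);
* a non-positive solved basis variance means the sparsity approximation
  failed for that taxon; its off-diagonal correlations are reported as 0
  (no evidence of association) with a warning — the clamping alternative
  fabricates |ρ| = 1 edges, which poisons the permutation null;
* the log-ratio variance matrix is computed from the covariance of
  log-fractions (one BLAS call) and is verified against a literal per-pair
  loop in the test suite; fewer than 4 taxa is rejected (the basis system
  is under-determined).

Significance: each of 100 permutations shuffles every taxon's counts
across samples independently (destroying association, preserving
marginals) and re-runs the full estimator; p = (1 + #{|ρ_perm| ≥ |ρ_obs|})
/ (1 + B), two-sided on |ρ|, so the smallest attainable p is 1/(B+1).
No multiple-testing correction is applied by default — the network filter
is a raw significance level of 0.05 combined with |ρ| ≥ 0.6 (AND
semantics) — matching the study-level convention for these networks;
measured type-I error at the pair level is ≈ 0.05 (asserted ≤ 0.07).

## Modules and node roles

Module detection runs on the unweighted, unsigned adjacency (signs are
kept for reporting; ignoring them for topology is standard Zi–Pi
practice). The default algorithm is Clauset–Newman–Moore greedy modularity
maximization — chosen because it is deterministic; Louvain is available
behind a flag with seed control. Nodes and edges are inserted in sorted
order so ties break identically across runs; isolated nodes are excluded
and reported. On the two-clique oracle graph the greedy partition attains
the exhaustive-search modularity maximum (verified over all 115 975
partitions of 10 nodes in the test suite).

Zi = (k_is − mean_s)/sd_s over the node's own module s; sd_s = 0 (uniform
within-degree, or a singleton module) yields Zi = 0 rather than NaN so
small modules never crash classification. Pi = 1 − Σ_t (k_it/k_i)².
Role cut-offs are Zi > 2.5 and Pi > 0.625 with *strict* inequalities;
boundary values fall in the lower category. Module hubs, connectors, and
network hubs are collectively "critical nodes".

## Eigengenes, GS/MM, and the keystone rule

Member relative abundances are standardized per taxon (mean 0, sd 1 across
samples; relative abundances chosen as the input scale), and the eigengene
is the first left singular vector of the samples × members matrix
(unit norm; variance explained = s₁²/Σs²). Principal components are
sign-ambiguous, so the eigengene is oriented to correlate positively with
the mean standardized member profile — module–trait correlation signs are
then meaningful. Constant members are dropped with a warning; a module
reduced below two members is skipped and reported.

GS is the Pearson correlation of a taxon's abundance with an external
trait; the trait defaults to CMR and is configurable (the screening trait
is a choice, not hard-coded). MM is the correlation with the own-module
eigengene. Both use one shared Pearson implementation (exact t transform
with n − 2 df; constant vectors give a not-computable result instead of an
exception; missing values drop pairwise and are logged). Hub genes require
GS and MM p < 0.05 (raw), and

    keystone = (hub gene OR critical node) AND function_flag,

where the carbon-metabolism function flag is user-supplied annotation —
literature-based functional assignment is deliberately outside
computational scope. Taxa without an annotation pass the gate flagged as
un-annotated, so structural candidates are never silently lost.

## Synthetic data generator

The generator emulates the study conditions at the count-table level:

* **Design**: 3 sites × 2 land uses × 4 plots × 2 depths = 48 composite
  samples (24 per land use). Site-specific detail (peat thickness,
  cultivation age) is metadata only; no site effect sizes are planted
  because none are stated at that granularity.
* **Counts**: logistic-normal-multinomial. Per-taxon baselines are
  Normal(0, 1); latent deviations follow an exchangeable block correlation
  (z = √c·f_block + √(1−c)·e, which realises the block matrix exactly and
  rejects c ≥ 1 as non-positive-definite); softmax per sample; multinomial
  at the sequencing depth, so columns sum to the depth exactly. This is
  the generative family whose log-ratio structure SparCC assumes.
* **Traits**: a linked trait is the standardized mean latent signal of its
  module plus Gaussian noise with variance solved in closed form,
  var_noise = var_signal·(1/r² − 1), so the population correlation with
  the module signal is exactly the target; negative targets flip the
  signal sign. Unlinked traits are independent noise. Per-trait
  location/scale decoration is affine and leaves correlations untouched.
* **Scenarios**: `natural` plants carbohydrates–CMR = 0.60 (phenolics
  unlinked); `cultivated` plants phenolics–CMR = −0.58 and
  carbohydrates–CMR = −0.66. Both traits share the CMR module, so a
  trait–trait correlation is the product of the two trait–module links;
  the CMR anchor is √0.60 ≈ 0.7746 in the natural scenario (symmetric
  split) and 0.85 in the cultivated one (keeps both derived links
  below 1). The planted values live in the scenario files, not in
  operation logic. Scenario communities use 100 taxa at depth 2000 with
  three planted blocks and 5% archaeal labels on non-block taxa (so the
  domain filter never disturbs planted structure) — a desk-scale stand-in
  chosen once for fast, well-conditioned inference.

Empirically, the mean recovered trait–trait correlation over 200
replicates at n = 24 sits within ~0.02 of the planted value; forcing the
realised module signal to unit sample variance inflates the magnitude
slightly, well inside the ±0.05 recovery band the tests assert.

All randomness flows from one integer seed through spawned child streams
(latents, multinomials, trait noise, taxonomy), so identical configuration
reproduces identical bytes.

**What passing synthetic tests do not show**: real communities have
overdispersion beyond the multinomial, phylogenetically structured rather
than block-exchangeable correlation, depth variation across samples, and
trait measurement error that is not Gaussian or independent. Recovery of
planted effects here validates the estimators' correctness, not their
power on field data.

## Pipeline

One analysis per land-use level (never pooled; the two depths within a
group are pooled by default, giving 24 samples per network, configurable
via the grouping variable). Stage order: archaea removal → rarefaction →
top-N → SparCC → permutation p → network → modules → Zi–Pi → eigengenes →
module–trait → GS/MM → hub genes → keystone report. Every threshold is
echoed to the log; outputs include a manifest with SHA-256 hashes of all
tables, and a rerun with the same seed is byte-identical.

## Known limitations

* SparCC variance floors and pair-exclusion caps are heuristics; with very
  few taxa (< ~10) estimates are noisy and the zero-reporting rule is
  conservative by construction.
* Greedy modularity can merge small planted blocks connected by chance
  edges; the Louvain option with multiple seeds is the usual remedy.
* The permutation null re-estimates the full SparCC matrix per
  permutation, which is the dominant cost; for thousands of taxa, lower
  `n_resamples` for the null or fewer permutations are the practical
  knobs.
* BIOM-format ingestion is not provided; inputs are tab-separated tables.
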