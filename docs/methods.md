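# Methods

## Overview

`nichecomm` decides, for every curated ligand–receptor interaction and every
ordered pair of cell clusters that co-occur in a declared microenvironment,
whether the interaction is *relevant*: expressed on both sides and supported
by differential expression of at least one member gene. The package has five
computational stages — expression summary, depth-stratified differential
expression, microenvironment pair enumeration, relevance calling, and an
optional permutation null — plus a negative-binomial simulator that generates
every input the stages consume.

## Expression summary

Counts are library-normalized per cell to a fixed total (default 10,000;
counts-per-10k), with no log transform. For each cluster and gene we keep

* `mean_expr` — arithmetic mean of normalized expression over the cluster's
  cells, and
* `frac_expr` — fraction of cells with raw count > 0.

"Expressed at the cell level" means raw count > 0; this is the simplest
reproducible definition and makes `frac_expr` independent of normalization.
A heteromeric complex is reduced to its limiting subunit: both statistics are
the minimum over subunits. The biological rationale is that a functional
multimer is bounded by its scarcest component; the practical consequence is
monotonicity (a complex never scores above any of its subunits), which the
test suite checks as a property. Partner means are computed on normalized,
non-log values: log bases would be an extra free parameter, and the min rule
is scale-consistent only on a common linear scale. This is a config-level
choice (`scale` in `RunConfig`), not a claim that other conventions are wrong.

## Depth-stratified Wilcoxon differential expression

Sequencing depth confounds rank tests on sparse counts: per-cell
normalization equalizes totals but cannot restore dropped-out zeros, so a
cluster sequenced deeper looks globally "up". The test therefore:

1. partitions the analyzed cells into `n_strata = 4` blocks by total-count
   rank (stable ties; block sizes differ by ≤ 1, remainder to the lowest-depth
   blocks), independent of donor;
2. within each stratum computes a Wilcoxon rank-sum Z for the target cluster
   against all other cells in the same stratum, using the midrank identity
   `Var(W) = n1·n2/(n(n−1)) · (Σ r² − n(n+1)²/4)`, which equals the classical
   tie-corrected variance without per-gene tie counting; a gene with zero rank
   variance in a stratum gets Z = 0, a stratum with an empty in- or out-group
   contributes nothing;
3. combines contributing strata with weighted Stouffer
   `z = Σ wᵢzᵢ / √(Σ wᵢ²)`, default `wᵢ = √nᵢ` (stratum size). Because
   quartile blocks are near-equal by construction, the weighted and unweighted
   modes differ only when strata drop out of a comparison; both are exposed
   (`weighting="sqrt_n" | "unweighted"`).

Two-sided p-values come from the standard normal; BH adjustment runs across
genes within each one-vs-rest comparison. The direction requirement (positive
fold change) is deliberately *not* part of the test — it is applied at
relevance calling, so the DE table remains a symmetric, reusable statistic.
`log2_fc = log2((mean_in + ε)/(mean_out + ε))` with ε = 1e−9 on normalized
means; ε only guards the zero-mean edge and is far below any mean the 10%
detection criterion admits.

The out-group is every cell supplied to the call (the analysis universe). To
analyze a lineage subset, pass the subset; quartiles are then recomputed over
that universe.

On a two-cluster null with a 2× depth ratio (2,000 genes, 300 cells per
cluster), the stratified test's empirical false-positive rate at α = 0.05 is
0.04–0.065 across seeds while the naive single-stratum test reaches ≈ 0.7 —
this contrast is recomputed by `scripts/acceptance.py`, not quoted from
anywhere. Residual within-stratum depth variation keeps the stratified rate
slightly above nominal at quartile resolution; finer strata would trade this
against per-stratum sample size.

## Microenvironments and eligible pairs

A microenvironment is a named set of cluster labels declared to co-occur in
space and time; phase tags are annotation only. Eligibility is the full set of
ordered pairs (self-pairs included — autocrine signaling is real) within each
environment; a pair shared by two environments is reported once per
environment rather than merged, so downstream tables stay per-niche. Members
absent from the annotation are dropped with a warning instead of failing the
run. Nothing is inferred from data: memberships are an explicit modeling input
(e.g. derived upstream from spatial deconvolution), which keeps the
restriction auditable.

## Relevance calling

For each interaction and eligible ordered pair (A, B): partner_a is assigned
to A and partner_b to B (the converse assignment is exactly the reversed
ordered pair); the call is

relevant ⇔ `frac(partner_a, A) ≥ min_frac` ∧ `frac(partner_b, B) ≥ min_frac`
∧ ∃ member gene g, cluster c ∈ {A, B}: `q(c, g) < max_fdr` ∧
`log2_fc(c, g) > min_log2_fc`.

The 10% detection threshold is inclusive (≥). Defaults are
`min_frac = 0.10`, `min_log2_fc = 0.02`, `max_fdr = 0.005`; the named
`"supplementary"` preset (positive lfc, `max_fdr = 0.001`) reflects the
stricter variant used for tabulated outputs in this method family — both are
exposed and neither is silently preferred. "log fold change" is implemented as
log₂; at thresholds this small the base matters little, and the choice is a
config switch rather than a hidden constant. Interactions with member genes
missing from the matrix are skipped and logged (`.attrs["skipped"]` and the
run manifest), not failed: real matrices rarely cover a full database.

The long-form output keeps ordered pairs; the binary matrix collapses to
unordered pair columns `env|clusterA|clusterB` with an entry of 1 iff any
orientation is relevant.

## Permutation null (optional)

The interaction score is the mean of the two partner means (min rule first).
Cluster labels are shuffled uniformly across all analyzed cells —
`n_permutations = 1000` by default — and
`p = (1 + #{null ≥ observed}) / (n + 1)`, the add-one estimator, so
p ∈ [1/(n+1), 1] and is never zero. Shuffling spans the whole analysis set
rather than within environments: the null asks "any cluster structure at
all?", and a within-environment mode would condition on the restriction being
tested. Only eligible pairs are scored when the restriction is on (default).
The relevance caller does not consume these p-values; the two analyses are
complementary, and no FDR is applied across interaction p-values.

## Synthetic data generator

The simulator defines the package's study conditions. Counts for cell c
(cluster k), gene g are negative binomial with mean
`baseline_mean · fold[k, g] · lib_c` and variance `m + α·m²`, drawn
gamma–Poisson. Defaults, chosen once as a realistic droplet-scRNA-seq regime:

* `baseline_mean = 0.5` counts/gene — detection fraction ≈ 0.3 at baseline,
  so unplanted genes clear the 10% criterion and specificity is genuinely
  tested through the DE criterion, not trivially through detection;
* `dispersion α = 0.5` — substantial overdispersion, typical of unnormalized
  droplet counts;
* `libsize_sigma = 0.6` — unit-mean log-normal library factors
  (`exp(N(−σ²/2, σ²))`), CV ≈ 0.66, the within-sample depth spread that makes
  stratification matter; per-cluster `depth_multipliers` superimpose the
  systematic confound (`depth_confounded_null` uses ratio 2);
* 200 cells per cluster and 4-fold planted effects for recovery experiments;
  3 donors assigned round-robin (donor labels are carried, not modeled —
  donor effects are out of the generator's scope);
* 5 decoy interactions per planted one, drawn from unplanted genes, enabling
  decoy-call-rate measurement.

What passing tests on these data do **not** show: robustness to ambient RNA,
doublets, batch/donor structure, zero-inflation beyond NB, or misannotated
clusters — none of which the generator emulates.

## Numerical and interface choices

* Ties everywhere are resolved by stable input order; one integer seed drives
  every stochastic stage, so identical config + seed reproduces outputs
  byte-for-byte (asserted in the suite).
* Tabular outputs are TSV with floats at 6 significant digits; the JSON run
  manifest records package and database versions, thresholds, seed and SHA-256
  input digests.
* Gene identity is exact string match between database and matrix; no symbol
  aliasing (aliasing would need an external resource and make calls
  non-auditable).
* Problem sizes in the test and acceptance runs (≤ 2,000 genes, ≤ 800 cells,
  ≤ 1,000 permutations, 10–20 replicates) were chosen as the smallest scales
  at which the measured rates are stable to well within the asserted margins.

## Known limitations

* The Stouffer combination assumes per-stratum Z-scores are approximately
  standard normal under the null; very small strata (< ~10 cells) weaken the
  normal approximation.
* The relevance decision is binary by design; it carries no interaction-level
  effect size or p-value (the permutation module exists for score-level
  significance).
* Complexes are scored by the minimum rule only; no stoichiometry or
  subunit-weighting is modeled.
* The one-vs-rest DE shares cells across comparisons, so q-values are not
  independent across clusters.
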