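# Methods

This note records the models, statistics, and design choices behind
`spongemod`, in the order the pipeline runs them, together with the
rationale for choices that were genuinely open.

## Synthetic data: the generative model

All validation runs on synthetic bundles with planted ground truth. Per
sample `s`, each planted module `m` draws a latent activity `f_m(s) ~ N(0,1)`
and, for each of its `q_m` shared miRNAs, `u_k(s) ~ N(0,1)`. Member genes are

```
x_i(s) = b_i + w_i [ α_m f_m(s) − β_m Σ_k u_k(s) ] + ε,   ε ~ N(0, σ²)
```

for lncRNAs and mRNAs alike; the shared miRNAs' own expression rows are the
`u_k` plus a baseline. The negative miRNA term encodes repression: ceRNA
partners correlate positively with each other and negatively with their
shared miRNAs. A **decoy** module sets `β_m = 0` — equally co-expressed, but
its lncRNA–mRNA correlation owes nothing to miRNAs, so its population SCC is
zero. Background genes are baseline plus unit Gaussian noise.

Elements and defaults:

- `b_i ~ Uniform(4, 12)` per gene: a baseline abundance making the matrices
  look like positive log-scale normalized expression, so the 50%-expression
  filter with floor 0 is meaningful. Setting the range to `(0, 0)` recovers
  the bare factor model (used by the noise-free identities in the tests).
- `w_i` — a deterministic per-gene multiplier, `linspace(1−δ, 1+δ)` with
  loading spread `δ = 0.25` in the default study. This gives each module a
  stable hub gradient: intramodular connectivity then has a reproducible
  pattern, which is what connectivity-based preservation statistics measure.
  With exchangeable genes (δ = 0), within-module connectivity differences
  are pure noise and a regenerated module cannot score on them. The
  multipliers are deterministic by position so that regenerating a module
  with fresh noise reproduces its connectivity pattern.
- Default study (`default_spec`): 150 samples; 2,000 mRNAs, 300 lncRNAs,
  35 miRNAs; 7 planted modules of 60 genes each — four sponge modules
  (α = 0.6, β = 0.8, q = 3; ~84% of module covariance miRNA-mediated), two
  decoys with planted target edges and one without (α = 1.51, matching the
  sponges' within-module correlation of ~0.70). Noise σ = 1.
- Targeting: each shared miRNA targets all of its module's lncRNAs and
  mRNAs; background edges are independent Bernoulli with density 0.002.
  With a 35-miRNA universe, higher background densities saturate the
  module-level target sets (every miRNA hits some module mRNA), which
  flattens the hypergeometric sharing test for any module; 0.002 (≈ 4
  background mRNA targets per miRNA) keeps the test informative while still
  exercising the null.
- Traits: a case/control flag (case fraction 0.5) and a 3-level diagnosis
  code (1/2/3) drawn independently of case status. Biomarker lncRNAs gain
  `effect × σ` in case samples. The default study shifts all 45 lncRNAs of
  module 4 by 1.5 σ (sized by a power calculation so the module eigengene–
  case correlation is reliably detectable at n = 150) and two background
  lncRNAs by 2.0 σ (whose population AUC is the closed form Φ(2/√2) ≈ 0.92).
- Test datasets for preservation: preserved modules are regenerated from
  the same law with fresh latent draws; all other rows are permuted across
  samples (or resampled with replacement if the sample count changes),
  preserving marginals while destroying between-gene structure.

What the generator does **not** emulate: read-count noise, library-size and
batch effects, normalization artifacts, correlated miRNA families,
database-derived target topologies, or overlapping/nested modules. Passing
tests demonstrate correctness of the statistics and recoverability of the
planted signal class — not performance on any real cohort.

## QC filters

A gene is kept when its value exceeds the expression floor (default 0 on
log-scale data) in at least `min_fraction` (default 0.5) of samples,
applied per RNA class. Sample outliers are scored by the standardized
sample-network connectivity: Pearson correlation between samples over the
combined mRNA + lncRNA rows (miRNAs excluded — a few dozen noisy rows),
`k_s = Σ_{t≠s} cor(s,t)`, `Z_s = (k_s − mean k)/sd k`; samples with
`Z < −2` are dropped in a single pass (no iteration). Both filters are
idempotent and keep the three matrices and the trait table aligned.

## Signed network and modules

- Similarity: `s = (1 + r)/2`, the standard signed linear transform.
- Soft power: default 18, overridable, or selected as the smallest power
  with signed scale-free R² ≥ 0.8 (10 equal-width connectivity bins,
  log-frequency regressed on log mean-k; the sign flips when frequency
  rises with k). If no candidate reaches the cutoff the argmax power is
  used with a warning. The run default is the fixed study power: module
  detection on the planted factor structure is not scale-free, and a fixed
  β keeps runs comparable; automatic selection remains available.
- TOM: unsigned topological overlap on the signed adjacency, diagonal 1.
- Tree cut: average linkage on `1 − TOM`, cut at 0.99 × the maximum merge
  height; subtrees below the cut that reach the minimum module size
  (default 50) become modules, renumbered by decreasing size, label 0 for
  the rest. Rationale: in a TOM dendrogram the uncorrelated bulk merges in
  a very narrow band just below the top join, so a *quantile* of merge
  heights lands inside that band, above the heights at which module
  branches attach — a quantile cut therefore returns one giant cluster. A
  fraction-of-maximum cut sits below the bulk band and isolates exactly the
  tight branches. The fraction and minimum size are exposed in the config.
- Eigengenes: per module, genes are standardized across samples and the ME
  is the first right singular vector, scaled to unit variance (ddof 1) and
  sign-aligned to correlate positively with the module's mean standardized
  profile; the share of variance of the first component is reported.
  Module–trait association is the Pearson correlation of each ME with each
  numeric trait, with unadjusted two-sided t-distribution p-values.

## Sponge-module identification

Candidates are modules with ≥ 3 lncRNAs and ≥ 1 mRNA.

1. **Sharing test.** With `N1` expressed miRNAs, `M1` targeting ≥ 1 module
   lncRNA, `K1` targeting ≥ 1 module mRNA, and `L1` doing both, the
   p-value is the hypergeometric tail `P(X ≥ L1)` for
   `X ~ HG(N1, M1, K1)`, computed through the log-gamma survival function
   (exact to enumeration for all N1 ≤ 20; the empty case L1 = 0 gives
   p = 1). Threshold 0.05 on the raw p.
2. **Canonical correlations.** First canonical correlation via the
   orthonormal-basis SVD method on centered data. *Dimensionality guard*:
   a group with more variables than `floor(n_samples/3)` is first projected
   onto its top principal components at that cap (exposed in config) —
   otherwise CC = 1 trivially whenever a group's rank reaches the sample
   count. The guard applies to all three group pairs. The conditioning
   group for PCC/SCC is exactly the L1 shared miRNAs.
3. **Null model.** The null hypothesizes that miRNAs do not influence the
   group correlation (population SCC = 0). Null datasets share the
   candidate's geometry — group widths after the guard, sample count, and
   lncRNA–mRNA canonical correlation binned to width 0.05 — while the
   miRNA group is independent standard normal. Within a bin, the factor
   loading of the null's shared latent factor is calibrated so that the
   null's expected *sample* CC matches the bin midpoint (estimated on a
   fixed set of pilot draws with common random numbers and inverted by
   bisection). Calibrating against the sample rather than the population
   CC matters: the sample CC of wide groups is strongly inflated, and a
   population-matched null is miscalibrated both for genuinely correlated
   modules and for structure-free data. Null group widths are capped at
   the CCA guard (the statistic only sees that many dimensions), which also
   keeps the simulation cost bounded. The empirical p-value uses the
   add-one estimator `(1 + #{SCC_null ≥ SCC_obs})/(1 + n_null)`; null
   distributions are cached per geometry/bin so the default 10⁶ draws are
   amortized across modules. On 500 decoy modules the rejection rate at
   α = 0.05 is ~0.04 and the p-value KS distance from uniform ~0.05
   (recomputed by `scripts/acceptance.py`).
4. **Multiplicity.** BH correction across the modules that reached the
   null-model stage (not across all detected modules); a module is flagged
   iff it has ≥ 3 lncRNAs, sharing p < 0.05, and adjusted p < 0.05.
5. **Interactions.** For flagged modules, every (lncRNA, mRNA) pair sharing
   ≥ 1 of the module's shared miRNAs is emitted once with the full shared
   set; lncRNAs are ranked by distinct mRNA partner count, ties broken by
   id.

## Module preservation

Signed adjacency is rebuilt in reference and test data on their common
genes with the *reference* power (re-selecting in the test set would
confound preservation). Per module: density = mean off-diagonal
intramodular adjacency in the test network; connectivity = the mean of two
reference-vs-test correlations — of the intramodular connectivity vectors
(kIM) and of the vectorized intramodular adjacency upper triangles. These
are the canonical representatives of the density-based and
connectivity-based statistic families. Each observed statistic is
standardized against `n_perm` (default 200) permutations that reassign the
module label to a uniformly random same-size gene set over the common
genes; modules are permuted independently (so one module's Z is invariant
to how others are labeled). `Z_summary` is the mean of the two Z's;
evidence classes: strong > 10, moderate (2, 10], none ≤ 2 (boundaries
assigned downward). Degenerate cases: a module with < 3 common genes is
skipped with a warning; zero permutation spread yields Z = 0 when the
observed value equals the permutation mean (e.g. connectivity correlations
identically 1 when test ≡ reference) and ±∞ with a warning otherwise.
Preserved modules can additionally be re-tested for SCC significance on the
test bundle (same statistics and null model, computed on the gene
intersection, requiring ≥ 3 surviving lncRNAs).

## ROC screening

Per-gene AUC by the rank/Mann–Whitney identity with midranks for ties;
orientation is chosen automatically so AUC ≥ 0.5 and the favored group is
recorded. Curves come from all distinct thresholds and span (0,0) to (1,1).
The screen flags candidates with AUC above the cutoff (default 0.7) and
supports intersection across datasets (pass everywhere). No confidence
intervals are computed.

## Reproducibility and problem sizes

A single global seed is expanded into per-stage seeds with numpy's
`SeedSequence`; all seeds are recorded in the run manifest, and reruns with
the same inputs and seed are byte-identical. The test suite and the
acceptance script run everything at desk scale: the default 2,300-gene
study for end-to-end recovery, 500 decoys at 10⁴ null draws for
calibration, 200 permutations for preservation, and 100-instance oracle
sweeps for TOM/CCA/AUC exactness; the full-scale 10⁶-draw null remains the
library default for real analyses.

## Known limitations

- The sharing test is weak when the miRNA universe is small and target
  sets are dense (it only sees binary "targets ≥ 1 module gene" events).
- Sample SCC is biased (typically negative at high CC with wide groups);
  inference is therefore only meaningful relative to the matched null, and
  the reported SCC point values should not be compared across modules of
  different geometry.
- The PCA dimension guard is a pragmatic regularization of CCA for
  p ≫ n modules; other choices (ridge-regularized CCA) would give slightly
  different CC scales.
- Z_summary values depend on the specific density/connectivity statistics
  aggregated and are comparable in spirit, not digit-for-digit, with other
  preservation implementations.
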