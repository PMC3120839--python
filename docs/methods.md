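# Methods

This note records the statistical model, the defaults and the judgment calls
behind `ctfingerprint`, in the order the pipeline runs them.

## Data model and normalization

A `CtMatrix` holds cells × genes cycle-threshold values in `(0, lod_ct]`
with nondetects stored exactly at the limit-of-detection floor
(`lod_ct = 40` cycles). Normalization produces
`e_ig = clamp(median_g(Ct) − Ct_ig, ±clamp_bound)` with `clamp_bound = 5`
cycles (a 2⁵ = 32-fold bound). Two conventions deserve emphasis:

* **Sign.** Higher normalized values mean *more* mRNA (Ct and abundance are
  inversely related). The subtraction order `median − Ct` was chosen so
  heatmaps and centroids read in the intuitive direction.
* **Pooling.** When several populations are analyzed jointly the per-gene
  median is taken over all cells pooled (`normalize_populations(...,
  pooled=True)`, the default), which keeps populations on one scale — a
  requirement for projecting one population onto centroids fit on another.
  Per-population centring is available for single-population displays.

Even-length medians are the mean of the two central order statistics.
Nondetects stay in every downstream computation as floor values; there is no
imputation. An optional max-nondetect-fraction gene filter exists but is off
by default, since dropping dark genes is a study-design decision, not a
statistical one.

## Coefficient-of-variance statistics

`gene_cov` is sample sd over mean (n−1 denominator). The multivariate form
is Van Valen's `cv_n = √(Σσ_i²)/√(Σµ_i²)`, a scale-invariant dispersion
index over a gene set. COV is a ratio statistic and is computed on a
positive scale: raw Ct by default, or the linear proxy `2^(lod−Ct)` behind a
flag (median-centred log2 expression has mean ≈ 0 and no meaningful COV).
Bootstrap standard errors resample cells with replacement, default 100,000
iterations (the test suite and acceptance script use 10,000–100,000
depending on the vector length); resamples with exactly zero mean are
redrawn and logged.

## Differential-distribution gene selection

Per-gene two-sample Kolmogorov–Smirnov tests with *asymptotic* two-sided
p-values: Ct data carry heavy ties at the detection floor, which invalidate
exact no-ties formulas, and the package logs when the tie fraction exceeds
5%. Bonferroni is implemented as `p_adj = min(1, p · n_tests)` with
`n_tests` defaulting to the shared panel size, and selection at
`p_adj < α = 0.01`. Tests run on the normalized (clamped) matrix by
default, matching the pipeline order; raw-Ct testing is a flag. The
alternate unsupervised route ranks genes by univariate COV (ties broken
lexicographically by gene id, so rankings are prefix-stable).

## Fuzzy c-means

Standard alternating optimization of `J_m = Σ u^m d²` with the membership
and weighted-mean centroid updates. Numerical choices:

* Memberships are computed in the log domain — the exponent `2/(m−1)`
  reaches 200 at m = 1.01 and would overflow `d^(−2/(m−1))` directly.
* Initialization is k-means++-style D²-weighted sampling, *jittered* off the
  data points (σ = 10⁻⁴ × data sd). A centroid that starts exactly on a
  cell gives that cell one-hot membership, and at large m the `u^m` weights
  of all other cells vanish, pinning a degenerate fixed point; the jitter
  removes it without affecting fits at practical m.
* Cells coincident with a centroid (d < 10⁻¹²) get membership 1 there.
* Convergence when the relative objective change or max membership change
  falls below `tol = 1e-6`; `max_iter = 1000`; 20 restarts by default, best
  objective kept; non-convergence is returned flagged with a warning.
* The objective is checked non-increasing in-loop with 10⁻⁹ relative slack.
  For Manhattan/Minkowski metrics the weighted-mean centroid update is the
  common generalized-FCM approximation rather than the metric-specific
  minimizer (e.g. the coordinate-wise weighted median for Manhattan), so
  monotonicity is not guaranteed; on a violation the iteration stops and the
  previous state is returned. This matches the drop-in metric-substitution
  use case and is documented as an approximation.
* Hard assignment is argmax membership with ties to the lowest cluster
  index; empty/starved clusters re-seed at the farthest point (logged).

k-means is Lloyd's algorithm with the same initialization and empty-cluster
rule. Projection applies the membership formula with centroids fixed (no
refit), using the fitted m and metric.

## AICc model selection

No standard likelihood attaches to a fuzzy partition, so the package adopts
a spherical-Gaussian mixture pseudo-likelihood with FCM memberships as
responsibilities — the module's principal interpretive choice:

    π_j = mean membership of cluster j
    σ̂² = Σ_ij u_ij d_ij² / (n g)          (pooled, Euclidean distances)
    logL = Σ_i ln Σ_j π_j N(x_i; c_j, σ̂² I)
    K = k·g + (k−1) + 1                     (centroids + weights + variance)
    AICc = −2 logL + 2K + 2K(K+1)/(n−K−1)

Rationale: it reduces to the exact spherical-Gaussian AIC at k = 1, varies
smoothly with m through the memberships, and yields interior optima in
(k, m). Likelihood distances are always Euclidean even when clustering used
another metric, because the Gaussian density is only defined for Euclidean
distance. The fuzziness m is treated as a selected hyperparameter, not a
counted parameter: counting it would add a constant 2 across the m-grid and
cannot change the argmin in m. The AICc sample size is the number of cells
(not cells × genes) — the conservative choice. Grid defaults are k = 1..6
and m = 1.05..3.00 in steps of 0.05 (so near-hard optima at m = 1.05 are
representable); ties break to smaller k, then smaller m (parsimony first).
Grid points where n ≤ K + 1 (AICc undefined) are skipped with a warning.
Akaike weights are normalized over all scored grid points, so duplicated
degenerate fits (k = 1 is identical at every m) share weight; Δ and
evidence ratios are unaffected.

## Stability diagnostics

* **Bootstrap of k**: subsets of `round(0.7 n)` cells drawn *without*
  replacement (a with-replacement flag exists), full grid re-optimization
  per subset, frequencies/mean/sd of the winning k (sd is the descriptive
  ddof = 0 form). The full m-grid is re-optimized per subset by default —
  the conservative reading — with the option to fix m.
* **Prediction strength** uses k-means only. Per fold, train and test sets
  are clustered separately; test cells are classified by nearest train
  centroid under the clustering metric, and ps(k) is the minimum over test
  clusters of the fraction of within-cluster pairs co-assigned by the train
  classification. Test clusters smaller than 2 contribute ps 1 (they cannot
  falsify co-membership; logged). ps(1) = 1 by definition; the chosen k is
  the largest with mean ps above the 0.8 threshold. Published variants of
  the procedure differ in small details; nearest-centroid classification is
  the one implemented here.
* **Gene-panel sensitivity** re-optimizes per panel and reports the
  adjusted Rand index against the first (reference) panel's partition.

## Synthetic data generator

`simulate` draws each cell's archetype from the mixture weights, then each
gene from that archetype's Gaussian Ct law — except burst genes, which use
`Ct = mean − LogNormal(0, s)` (bursts increase mRNA, hence the left-skewed
Ct tail; `s` defaults to 1.0) — applies per-gene dropout to the Ct-40 floor,
and clips to `(0, 40]`. Dropout is expression-independent within a gene but
the benchmark ties its probability to the gene's mean Ct by a logistic
centred at Ct 36, so only genes near the detection limit drop out
appreciably, as in real panels.

`make_benchmark_fixture` builds the three-population benchmark: 300 cells ×
43 genes per population, three shared archetypes, occupancies
(1/3, 1/3, 1/3), (0.04, 0.58, 0.38) and (0.68, 0.16, 0.16). Nine "signal"
genes (G01–G09) take three distinct archetype levels spaced 2 Ct apart in a
rotating pattern, so every pair of archetypes differs on every signal gene;
the other 34 genes are shared noise, five of them bursty. Design choices
within the benchmark: signal genes share a common within-archetype sd of
0.7 Ct so archetypes are near-spherical in clustering space (the
variance-grows-with-Ct trend is carried by the noise genes, sd 0.4–1.24);
the benchmark's burst magnitude is s = 0.6, below the signal genes' total
spread, so bursty tails mark a minority of cells without dominating
panel-wide variance — with both choices the signal genes top both the KS
and the COV rankings by construction, as the benchmark's structure intends.

What the generator does *not* emulate: gene–gene covariation within an
archetype (genes are conditionally independent), amplification-efficiency
and pre-amplification bias, cell-size/RT-efficiency global factors, and
kinetic (telegraph-model) transcription dynamics. Passing tests therefore
demonstrate that the pipeline recovers mixture structure of this
conditional-independence form at realistic noise levels — not that it is
robust to correlated technical artifacts.

## Problem sizes

Defaults target the instrument-scale dataset (hundreds of cells, ≤ 48
genes). The test suite and the acceptance script run the heavier procedures
at reduced but statistically adequate sizes, chosen once: reduced (k, m)
grids of k = 1..5 × m ∈ {1.05, 1.5, 2.0} with 2–3 restarts for repeated
re-optimization (recovery rates are insensitive to the finer m grid since
near-hard fits dominate), 200 bootstrap subsets, 10–20 prediction-strength
iterations, 1,000 null replicates for the type-I check, and 10,000–100,000
bootstrap resamples for COV standard errors. Full-scale settings (10,000
bootstrap subsets, 100 ps iterations, the complete 240-point grid) are all
reachable through function arguments or the CLI.

## Known limitations

* The pseudo-likelihood is a modeling convention; AICc values are
  comparable *within* a grid but not across different likelihood choices.
* Non-Euclidean centroid updates are approximate (see above).
* Asymptotic KS p-values are conservative-to-approximate under heavy ties;
  with >5% ties the package logs the condition rather than switching to a
  permutation test.
* Occupancy comparisons of projected populations inherit multinomial
  sampling error of the population draw itself (~±2 points at n = 300 for
  mid-range weights), which bounds how closely any projection can match
  generating weights.
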