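# ctfingerprint

Information-theoretic fingerprinting of single-cell qPCR data: does a
"purified" cell population consist of one transcriptional state, or of
several discrete subpopulations hiding inside the sort gate?

Single-cell qPCR panels (e.g. 48-assay × 48-sample dynamic arrays, 2,304
reactions per chip) measure a few dozen genes across hundreds of individual
cells as cycle-threshold (Ct) values — the qPCR cycle at which amplification
crosses detection, with each cycle ≈ a 2-fold change in starting mRNA and
failed reactions pinned at the Ct = 40 detection floor. Transcription is
intrinsically bursty, so every gene varies cell-to-cell even in a clonal
population; the analytic problem is to separate that stochastic noise from
genuine subpopulation structure. `ctfingerprint` implements a complete
pipeline for this question, built for sorted stem/progenitor populations but
applicable to any cells × genes Ct matrix.

## Method

1. **Normalization.** Each gene is centred on its median Ct over the pooled
   sample and converted to log2 fold change, `e = median_g(Ct) − Ct`
   (higher = more mRNA), clamped to ±5 cycles (a 32-fold bound); nondetects
   fall on the −5 floor.
2. **Variability.** Per-gene coefficient of variance `cv = σ/µ` with
   bootstrap standard errors (default 100,000 resamples), and Van Valen's
   multivariate generalization `cv_n = √(Σσ_i²)/√(Σµ_i²)` over a gene set.
3. **Feature selection.** Two-sample Kolmogorov–Smirnov tests per gene
   between two populations, Bonferroni-corrected (`p_adj = min(1, p·G)`,
   selected at `p_adj < 0.01`); alternatively the top-COV genes.
4. **Fuzzy c-means clustering.** Soft partitions minimizing
   `J_m = Σ_ij u_ij^m d(x_i, c_j)²` with memberships
   `u_ij = 1/Σ_l (d_ij/d_il)^{2/(m−1)}`; Euclidean, Manhattan or Minkowski-p
   distances; m → 1 recovers k-means, m → ∞ flattens memberships to 1/k.
5. **Model selection.** Every (k, m) on an exhaustive grid (k = 1..6,
   m = 1.05..3.00) is scored by a spherical-Gaussian mixture
   pseudo-likelihood with AICc (`AIC + 2K(K+1)/(n−K−1)`); AIC differences
   Δ_i, Akaike weights `w_i = e^{−Δ_i/2}/Σ e^{−Δ_l/2}` and evidence ratios
   quantify selection uncertainty.
6. **Projection.** Centroids fit on a reference population are held fixed
   and other populations are projected onto them, giving per-cluster
   occupancy fractions.
7. **Stability.** Bootstrap of the optimal cluster number over 70% cell
   subsets; Tibshirani–Walther prediction strength (5-fold cross-validated
   k-means co-membership, threshold 0.8); gene-panel and distance-metric
   sensitivity via the adjusted Rand index.

Because real single-cell qPCR datasets of this design are rarely deposited,
the package ships a first-class synthetic generator
(`ctfingerprint.synthetic_data`) that draws three-archetype mixtures with
the statistical structure such data exhibit (near-normal per-gene Ct, a
bursty left-skewed minority, variance growing with Ct, floor-pinned
dropout), so every stage is testable end to end.

## Worked example

```python
import ctfingerprint as cf

# three synthetic sorted populations sharing the same archetypes
fx = cf.make_benchmark_fixture(seed=1)
lo, hi, sp = cf.normalize_populations([fx.cd34lo, fx.cd34hi, fx.sp])

results = cf.select_differential_genes(lo, hi, alpha=0.01)
genes = [r.gene_id for r in results if r.selected]
print(f"{len(genes)} differential genes: {genes}")

best, scores = cf.optimize_grid(lo.subset_genes(genes), seed=0, n_restarts=3)
print(f"AICc optimum: k={best.k}, m={best.m}")

for name, e in [("cd34hi", hi), ("sp", sp)]:
    _, occ = cf.project_population(best, e.subset_genes(genes))
    print(name, "occupancy:", occ.fractions.round(3).tolist())
```

prints

```
9 differential genes: ['G01', 'G02', 'G03', 'G04', 'G05', 'G06', 'G07', 'G08', 'G09']
AICc optimum: k=3, m=1.05
cd34hi occupancy: [0.397, 0.577, 0.027]
sp occupancy: [0.2, 0.143, 0.657]
```

Reading: the KS screen finds exactly the 9 genes that carry
between-archetype shifts; the AICc trough identifies three clusters at a
near-hard fuzziness; projecting the skewed populations onto the reference
centroids recovers their generating archetype occupancies — the `cd34hi`
population is nearly absent (2.7%) from the cluster in which the
side-population analogue is strongly enriched (65.7%).

The same pipeline runs from the shell:

```sh
ctfingerprint simulate --seed 1 --outdir data/
ctfingerprint select data/cd34lo.csv data/cd34hi.csv
ctfingerprint optimize data/cd34lo.csv --seed 0
ctfingerprint run --config cfg.yaml     # full orchestrated run + manifest
```

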