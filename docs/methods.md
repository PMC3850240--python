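# Methods

## The estimand and the benchmark design

The package measures the *variable-selection* accuracy of ℓ1/ℓ2-penalized
regression in a GWAS-like regime: n = 1000 individuals, thousands to tens
of thousands of SNP predictors coded 0/1/2, and a small set of causal
SNPs whose genotypes are strongly correlated with each other (linkage
disequilibrium).  Selection accuracy is the pair (correct, false
positive): how many members of the known causal set carry a nonzero
coefficient at the tuned penalty, and how many non-causal SNPs do.

## Synthetic data

`simulate_base` draws genotypes as the sum of two independent
Bernoulli(0.5) matrices, so every entry is Binomial(2, 0.5) — a fixed
minor-allele frequency of 0.5 and no background LD.  The phenotype is
bimodal by construction: the first n/2 entries are N(2, 1), the last n/2
are N(−2, 1), and the vector is *not* sorted.  Total phenotypic variance
is therefore ≈ 5 (4 between the two groups, 1 within).

`embed_causal_block` makes a column causal by re-assigning its multiset
of genotype values in descending order down the rows, with rows ranked
only by phenotype *group* (the high-phenotype half first, each half in
original row order).  Two properties follow, and both are deliberate:

- all causal columns are sorted against the same row order, so any two of
  them differ only through their own Binomial genotype counts — mean
  pairwise causal correlation ≈ 0.97;
- the assignment is blind to the phenotype ranking *within* each half, so
  a causal SNP is a proxy for group membership only: r(x, y) ≈ 0.63,
  single-SNP R² ≈ 0.4.  The best attainable prediction from the causal
  block is essentially the group mean, leaving MSE ≈ 1 + shrinkage; in
  practice cross-validated MSE at the tuned λ sits near 2.9–3.0 out of
  the total variance 5.

An alternative reading — sorting causal columns against the *full*
phenotype ranking — reproduces the same 0.97 inter-column correlation but
makes each SNP track y far more closely (R² ≈ 0.78, CV MSE ≈ 0.95) and
makes selection much easier; it is inconsistent with the benchmark's
reported error levels and selection counts, which is why the group-level
sorting is the implemented semantics.

`degrade_ld` weakens a column's LD by choosing round(f·n) rows uniformly
without replacement and shuffling the values among those rows.  Permuting
a fraction f of both members of a column pair scales their correlation by
≈ (1−f)²; with f = 0.25, degrading 10 of 25 causal columns gives a mean
pairwise causal correlation ≈ 0.78 (`mixed`), and degrading all 25 gives
≈ 0.55 (`low`).

Causal columns sit in blocks of 5.  For the 25-causal design the block
centers are the canonical positions (1000, 10000, 20000, 30000, 40000) on
a 50000-SNP panel, scaled by p/50000 for other panel sizes (positions
carry no biological meaning; scaling preserves separation).  Other causal
counts spread blocks evenly over the panel.  One master seed drives
everything; per-replicate and per-column streams are spawned from it via
`numpy.random.SeedSequence`, so runs are exactly reproducible.

What the generator does *not* emulate: realistic allele-frequency
spectra (every SNP has MAF 0.5), background LD between non-causal SNPs,
dominance/epistasis, and pedigree or coalescent structure.  Passing tests
therefore certify the selectors' behavior under idealized, worst-case
*causal* collinearity — not performance on real panels.

## Elastic-net solver

The solver minimizes

    (1/2n)‖y − β₀ − Xβ‖² + λ Σⱼ pfⱼ [α|βⱼ| + ½(1−α)βⱼ²]

by cyclic coordinate descent on standardized predictors (zero mean, unit
1/n-variance; coefficients are returned on the original scale and the
intercept is never penalized).  One coordinate update is the soft
threshold of the partial-residual least-squares coefficient followed by
proportional ridge shrinkage:

    βⱼ ← S(⟨xⱼ, r₋ⱼ⟩/n, λα·pfⱼ) / (1 + λ(1−α)·pfⱼ).

The λ path has K = 100 points log-spaced from λ_max down to ε·λ_max with
ε = 0.001.  λ_max = maxⱼ |⟨xⱼ, r⟩|/(n·α·pfⱼ) over penalized columns,
where r is the centered response residualized on any unpenalized
covariates — this makes "every penalized coefficient is exactly zero at
λ_max" hold exactly even with covariates in the model.  For α = 0 no
finite λ zeroes the path; α is clamped to 0.001 for path construction
only.

Per λ the solver sweeps an ever-active set to convergence, then computes
the full gradient once to screen for KKT violations; violators are
admitted and the process repeats.  Warm starts carry coefficients and the
active set down the path.  Convergence is declared when a sweep moves no
coefficient by more than `sqrt(tol · Var(y))`, i.e. the squared-change
criterion max (Δβⱼ)² < tol·Var(y) with tol = 1e-7 — the convention of
coordinate-descent GLM software.  An absolute coefficient-change
tolerance of the same nominal size was considered and rejected: on
designs with blocks of 0.97-correlated predictors it needs hundreds of
sweeps per λ for precision that has no effect on selection, inflating the
path cost ~50-fold.  Tests that compare against high-precision oracles
tighten `tol` instead.

Zero-variance columns are skipped with coefficient 0.  Non-convergence at
`max_iter` sweeps is recorded per λ, not fatal.

## Cross-validation and tuning rules

The λ grid is computed once on the full data and shared across folds.
k = 10 folds of near-equal size are drawn from a dedicated RNG stream
(independent of the simulation stream).  `mean_mse[λ]` averages the
squared held-out errors over all n individuals; `se_mse[λ]` is the SD of
the k fold-level MSEs divided by √k.  `lambda_min` minimizes the curve;
`lambda_1se` is the largest λ with mean MSE ≤ min + SE(min).  Selection
reads the nonzero penalized coefficients off the full-data path at the
chosen grid point.  `repeated_cv_lambda` averages the chosen λ over
independent CV runs and uses the average as-is (not snapped to the grid)
for a final refit — the stabilization used for real-data analyses.
The MSE reported per cell is the CV-estimated MSE at the tuned λ (not a
training-refit MSE); it includes shrinkage bias, which is why it exceeds
the theoretical floor of ≈ 1 on the simulated designs.

## Single-marker scan and local fdr

The scan fits y ~ 1 + covariates + xⱼ per SNP by OLS, vectorized through
Frisch–Waugh projection, with a two-sided t-test for the slope.
Bonferroni selection keeps p < 0.05/p_total.

For the local false discovery rate, two-sided p-values are mapped to
z-scores; by default the signed form z = sign(β̂)·|Φ⁻¹(p/2)| (the literal
one-sided form Φ⁻¹(p), which folds all small p into the left tail, is
available by flag).  The marginal density f(z) is fitted by Poisson
regression of 120 histogram-bin counts on a natural cubic spline basis
with 7 df, normalized to a density; z-values outside the bin-mid range
use the clamped basis so the log-density stays bounded in the tails.  The
empirical null N(δ₀, σ₀²) and null proportion π₀ are estimated jointly by
maximum likelihood on the central 50% of the z-values: the likelihood
combines the truncated-normal shape of the central z's with the Binomial
probability of observing that central count, the count term being what
identifies σ₀ (the shape term alone is nearly flat in σ₀ over a central
window).  fdr(z) = π₀·φ((z−δ₀)/σ₀)/σ₀ / f̂(z), clipped to [0, 1]; SNPs
with fdr < 0.2 are flagged.

## Population structure

The similarity graph weights are the standardized-genotype inner products
Z Zᵀ/p, linearly rescaled so off-diagonals lie in [0, 1]; the embedding
uses the top eigenvectors of D^{−1/2} W D^{−1/2} with the trivial
leading eigenvector dropped and signs fixed (first nonzero entry
positive).  Significance is calibrated by a permutation null: each SNP
column is permuted independently across individuals, eigenvalues are
recomputed per simulation, and rank k is significant if the observed k-th
eigenvalue exceeds the maximum k-th null eigenvalue (per-rank false-
positive rate 1/(m+1) for m simulations); counting stops at the first
non-significant rank.  This is a standard spectral embedding with
simulation-based calibration, offered alongside a plain PCA mode; the
count is advisory — q is the user's choice.  Covariates enter the solver
with penalty factor 0 and are excluded from reported selections.

## Quality control

SNPs are dropped for call rate < 0.90, then MAF < 0.01 (allele counts on
called genotypes), then Hardy–Weinberg disequilibrium (one-df Pearson
chi-square of observed genotype counts against expectations at the
observed allele frequency, p < 1e-5; an exact test is not implemented).
Remaining missing entries are imputed with the column mean genotype
(2 × allele frequency), so imputed matrices are float-valued.

## Desk-scale problem sizes

The benchmark grid is run at reduced panel sizes chosen once:

- correlation targets: 20 seeds, p = 5000 (the causal-block construction
  is panel-size invariant);
- 25-causal selection cells: 11 replicates, p = 5000, n = 1000, K = 100,
  ε = 0.001, k = 10 — selection counts at these sizes match the
  full-scale pattern because results are insensitive to p over
  5000–100000 on this design;
- 100-causal extension: 5 replicates, p = 20000 (20 blocks of 5);
- Bonferroni scan: 2 replicates per LD setting.

Replicate medians at these sizes carry sampling noise of roughly ±1
selection for the sparse cells; the lasso median in the 100-causal cell
is the most size-sensitive quantity (pilot runs bracket the full-scale
value from below at p = 20000 and above at p = 50000).

## Known limitations

- Gaussian responses only (no logistic/Cox families), no interaction
  terms, single-threaded solver.
- The spectral embedding approximates eigenvector-covariate
  workflows used on real panels generically; counts of significant eigenvectors on real
  datasets depend on the original tool's internals and are out of scope.
- The local-fdr density fit needs a few hundred z-values to be stable;
  the scan refuses fewer values than histogram bins.
- π₀, σ₀ estimation assumes the central window is dominated by nulls;
  with dense signal (≫10% non-null) the empirical null inflates and the
  fdr becomes conservative.
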