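# Methods

`cattlegp` benchmarks whole-genome prediction of quantitative,
metabolite-like traits in a dairy-cattle cohort design: ~1,350 cows
genotyped at tens of thousands of autosomal SNPs, sampled in 21
herd/date batches, with days-in-milk (6 classes) and parity (4 classes)
as fixed effects. Because cohorts of this kind are rarely public, the
package ships a synthetic-cohort generator with the same structure, and
every quantitative claim the package makes is demonstrated on that
generator.

## Models

### Variance decomposition (animal models)

Model 1: `y = Xb + Wh + Za + e`; model 2 adds dominance and
additive-by-additive epistatic effects, `y = Xb + Wh + Za + Zd +
Zep_aa + e`. Here `b` holds the fixed DIM/parity classes (first level
of each factor dropped; optional genotype-PC covariates), `h` is an
i.i.d. batch effect, and the genetic effects covary per their kernels:

* additive `G = MM' / (2 Σ p_j(1 − p_j))` (VanRaden), `M` the
  allele-frequency-centred dosage matrix;
* dominance `D = WW' / Σ (2 p_j q_j)²` (Vitezica), with the
  HWE-centred coding (−2p², 2pq, −2q²);
* epistatic `GG = G ∘ G` (Hadamard product; not trace-rescaled by
  default, a flag enables trace/n normalisation).

Variances carry scaled inverse chi-square priors with df = 5 and scale
set so each prior mode equals an equal split of the observed
phenotypic variance across the fitted variances; fixed effects have a
flat prior. The Gibbs sampler draws each correlated vector in the
eigenbasis of its kernel (`a = Us`, diagonal full conditionals), so a
sweep costs two n×n matrix–vector products per kernel and one spectral
decomposition per kernel is reused for the entire chain.

Production chain settings are 500,000 sweeps, 50,000 burn-in, thinning
10 (45,000 retained samples); tests and benchmarks use shorter chains
(20,000–30,000 sweeps), which parameter-recovery results show are
sufficient at n ≈ 600. Convergence is monitored with the Geweke
diagnostic (first 10% vs last 50%, Newey–West long-run variances).

Variance fractions (h², d², ep²_aa, h²_batch) are posterior means of
per-sample ratios, not ratios of means. By default the batch variance
is included in every denominator, so fractions are relative to total
phenotypic variance; `include_batch=False` switches to the
genetic+residual denominator. Adjusted phenotypes are
`y* = y − X b̂ − W ĥ` with posterior-mean solutions; `y*` is the
response for all predictors.

### Predictors

All five are scikit-learn-style estimators (`fit(X, y)` /
`predict(X)`, X = dosage matrix); marker-centring statistics always
come from the training data.

* **GBLUP** — `y* = 1μ + Zg + e`, `g ~ N(0, G σ²_g)`. The variance
  ratio is estimated by profiled marginal likelihood over the
  eigenvalues of the training kernel; validation individuals are
  predicted by the conditional expectation `G_vt (G_tt + λI)⁻¹ (y−μ)`,
  which is algebraically identical to marker ridge regression with
  penalty `λ_ridge = denom · σ²_e/σ²_g` (tested to r ≥ 1 − 1e−8).
* **BayesB** — `y*_i = μ + Σ_w x_iw u_w + e_i` with the mixture prior
  `π·δ₀ + (1−π)·t(df = 5, scale S_B)`, represented hierarchically
  (normal effect with scaled-inv-chi-square variance). Defaults:
  π = 0.95 and S_B solved so the slab explains half of var(y*) a
  priori; chain 200,000/50,000/10 (15,000 retained). The sampler's
  single-marker posterior mean is checked against 1-D quadrature of
  the exact mixture posterior.
* **Elastic net** — loss `(1/2N)Σ(y_i − β₀ − x_i'β)² +
  λ((1−α)‖β‖₂² + α‖β‖₁)`, solved by coordinate descent (the penalty is
  re-parameterised to scikit-learn's form: `a = λ(2−α)`,
  `l1_ratio = α/(2−α)`). α runs over 0.0…1.0 step 0.1; λ defaults to
  50 log-spaced values from λ_max (the smallest λ zeroing all
  coefficients at α = 1) down to λ_max·1e−4 (a raw 0–1 step 0.1 grid is
  available by flag, since that reading of the printed grid is also
  defensible). The winner maximises inner 5-fold CV accuracy, ties
  broken by lower MSE, then smaller λ, then smaller α. Solutions
  satisfy the subgradient optimality conditions of the stated loss to
  1e−6 on fixtures when run at tight tolerance.
* **GBM** — gradient tree boosting with squared-error loss
  (scikit-learn backend). Hyperparameter grids: trees
  {100…3000 (11 values)}, learning rate 0.01…1 step 0.05, max depth
  0…50 step 5 (0 = unlimited; a literal depth-0 tree is degenerate),
  min observations per leaf {5, 20, 35, 50}; random search (36 draws
  by default) scored by inner 5-fold CV MSE. Per-marker relative
  influence is the normalised sum of squared-error reductions over all
  splits, on a percentage scale (sums to 100).
* **Stacking** — base learners ENET and GBM produce out-of-fold
  predictions on the training set (K = 5 folds); the meta-learner is
  non-negative least squares with intercept, with the weights then
  normalised to sum to 1. The normalisation makes a pair of identical
  base learners reproduce their common prediction exactly (rather than
  refitting its scale) and keeps the weights interpretable as a convex
  combination; it is the one deliberate departure from plain NNLS.

### Cross-validation designs

* **Genomic tenfold** — folds from the kernel-induced distance
  `d_ij = sqrt(G_ii + G_jj − 2G_ij)`: Ward hierarchical clustering cut
  at k groups, then balanced to ⌊n/k⌋/⌈n/k⌉ by greedily moving the
  member with the smallest average distance into an under-full fold.
  Close relatives therefore tend to stay within one fold. At n = 1,353
  this yields seven folds of 135 and three of 136. The construction is
  deterministic given (distance matrix, k, seed).
* **Batch-out** — per repeat, ⌊0.8·B⌋ batches train and the rest
  validate (16/5 at B = 21); whole batches travel together. Repeats
  draw disjoint validation batch sets while unused batches remain,
  then top up from used ones with a warning (5 repeats over 21 batches
  cannot hold every batch out exactly once).

### SNP preselection

Two steps, per CV fold: rank all markers by GBM relative influence
using only the training side (ties broken by genome order), keep the
top k (default 1,500), rebuild kernels/designs from the subset, refit,
predict the untouched validation side. BayesB is excluded by design —
its mixture prior already performs variable selection. VanRaden
denominators are recomputed from the selected subset.

### Metrics

Pearson and Spearman correlations between `y*` and `ŷ*`, RMSE
`sqrt(Σ(ŷ* − y*)²/n)`, the OLS slope of `y*` on `ŷ*` (1 = unbiased),
and the relative difference `RD = (r_m1 − r_m2)/r_m2 × 100` with GBLUP
as baseline. Metrics are computed per fold and then averaged; standard
errors are across folds/repeats. In fold summaries, a model emitting
constant predictions is scored accuracy 0 (no predictive ability); the
bare metric functions reject constant input.

## Synthetic cohort generator

* **Genotypes** — Balding–Nichols: ancestral frequency uniform on
  `maf_range`, per-subpopulation frequencies Beta-distributed with
  divergence `fst` (default two subpopulations, fst = 0.05); two
  latent-Gaussian haplotypes per individual thresholded at the
  Hardy–Weinberg quantile; markers in blocks of `ld_block_size` share
  an equicorrelated factor (`ld_rho`) inducing within-block LD; blocks
  never straddle the 29 autosomes.
* **Architecture** — additive effects on centred codes, dominance on
  the Vitezica coding, epistasis on products of centred codes of
  random marker pairs; all effect sizes standard normal before
  rescaling. Each realized component is rescaled on the cohort so its
  variance equals the target fraction exactly (phenotypic variance of
  the random parts normalised to 1), which makes the effect-size
  distribution immaterial to the variance targets.
* **Phenotypes** — one record per individual: fixed DIM/parity
  effects (class effects N(0, 0.3²), removed by adjustment), a batch
  effect (sizes from a Dirichlet(α = 5) draw over 21 batches; the
  `batch_confounding` knob orders batch membership along the genetic
  value to emulate herd/family confounding), the genetic components,
  and Gaussian residual absorbing the remaining variance fraction.

What the generator does **not** emulate: realistic LD decay and map
structure, pedigree/family structure beyond the two-subpopulation
divergence, repeated records, selection, non-Gaussian residuals
(several real metabolites are heavy-tailed), and genotyping error.
Passing benchmarks therefore demonstrate correctness and the
qualitative behaviour of the methods under the stated generative
model, not field performance on any real cohort.

## Benchmark problem sizes

The reference study conditions live in `cattlegp.benchmarks` and are
shared verbatim by the test suite and `scripts/acceptance.py`:

* variance-component recovery: 20 replicates, n = 600, m = 3,000,
  model-2 chains of 30,000 sweeps (5,000 burn-in, thin 10), truth
  (h², d², ep², batch) = (0.25, 0.10, 0.20, 0.20); posterior means are
  expected within ±0.10 of truth on average;
* non-additive ordering: 20 replicates, n = 400, m = 120, sparse
  strong epistasis (3 pairs, ep² = 0.32) plus dominance (d² = 0.15)
  over h² = 0.08, 75/25 holdout. At this scale boosting cannot detect
  many weak pairwise interactions, so the non-additive variance is
  concentrated in few strong ones — the regime where the full-scale
  ordering (Stack ≈ GBM > GBLUP) is reproducible on a desktop. The
  inner searches use trimmed subsets of the default grids and 3-fold
  inner CV;
* additive closeness of GBLUP/BayesB/ENET: 20 replicates at n = 400,
  m = 400, h² = 0.35 with a polygenic architecture (300 of 400 markers
  causal) — the regime where the three parametric predictors are
  expected to agree; a sparse architecture would instead favour the
  selection methods. BayesB runs with π = 0.5 and 4,000 sweeps here:
  a fixed π does not transport across panel sizes (5% of a 61k chip is
  ~3,000 markers, 5% of a 400-marker test panel is 20), so the
  benchmark matches the prior's effective model size to the reduced
  panel while the package default stays π = 0.95;
* batch-out penalty: 20 replicates at n = 400 with
  `batch_confounding = 0.8`;
* accuracy-vs-h² trend: 20 replicates × 10 traits (h² = 0.05…0.50)
  sharing one genotype panel per replicate, GBLUP tenfold.

## Numerical choices

* Kernel eigenbasis rotations in the Gibbs sampler run in float32 with
  a float64 residual refresh every 1,000 sweeps; posterior summaries
  match a full float64 run to four decimals on test problems while the
  sweep cost drops substantially. All other arithmetic is float64.
* Kernel PSD tolerance: smallest eigenvalue ≥ −1e−8·trace/n;
  zero-eigenvalue modes are dropped from the sampling basis.
* GBLUP adds jitter 1e−8·trace/n when the shifted spectrum is near
  singular; the no-signal boundary (γ → 0) returns the GLS mean.
* Degenerate inputs are contracts, not silent paths: monomorphic
  panels, all-missing markers, constant chains, π = 1, zero-split GBM
  rankings and k > panel size all raise (or warn, where the spec of
  the operation calls for a degraded model).

## Known limitations

REML appears only as a test oracle, not a user-facing estimator.
Repeated records, multi-trait models, pedigree matrices, and
dominance-by-additive or higher-order epistatic kernels are out of
scope. The batch-out repeat protocol reuses batches once the disjoint
pool is exhausted, which slightly couples later repeats. The elastic
net λ grid interpretation and the BayesB (π, S_B) hypervalues are
package defaults, configurable, because no single canonical choice
exists for this cohort design.
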