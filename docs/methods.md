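# Methods

## The simulation model

Phenotypes are generated under a linear mixed model

    y = X β + u + ε,          u = Z γ,

where `Z` holds the additive allele counts of `b = 1000` background markers
drawn uniformly without replacement, `γ_j ~ N(0, 0.1²)` i.i.d., and `ε` is
either Gaussian or mean-centered gamma noise.  The noise variance is tied to
the background via the heritability parameter `h`:

    σ² = Var(ε) = (1 − h)/h · Var(u),

so `Var(u)/(Var(u)+Var(ε)) = h` by construction (checked empirically at
±0.02 for n ≥ 500).  `h` here is the *background* heritability — the share
of the non-fixed-effect phenotype attributable to the polygenic term — not
the total narrow-sense heritability of `y`.

Fixed (causal) effects are added last.  Each causal marker `x_i` (drawn
disjoint from the background set, redrawn while constant in the sampled
rows) receives

    β_i = sqrt( (c_i / (1 − Σc)) · Var(u + ε) / Var(x_i) ),

where `Σc` sums all target fractions of the configuration.  Under
near-orthogonality of the terms this makes each effect's realized share of
the *total* phenotypic variance ≈ `c_i`, for any number of effects; with a
single effect it reduces to the familiar `c/(1−c)` scaling.  An alternative
reading — scaling each effect by `c_i/(1−c_i)` independently — under-delivers
the total causal fraction ( `S/(1+S)` with `S = Σ c/(1−c)` ≈ 0.23 instead of
0.30 for the 50/100-marker settings), so the joint denominator was adopted.

Multiplicative (epistatic) effects use the raw Hadamard product
`x_i ∘ x_j` as their design column.  Because the product covaries positively
with its marginal terms, the realized interaction fraction undershoots its
target slightly (≈ 0.17 measured vs. 0.20 targeted for the weak-epistasis
configuration) and the per-component variance shares of such configurations
sum to slightly below one; both effects are inherent to an uncentered
product term and are left uncorrected.

Skewed noise is mean-centered gamma with shape `k` and scale
`sqrt(σ²/k)`: the variance stays exactly `σ²` (so the heritability
calibration is unaffected) while the skewness `2/√k` is 1 for the weak
(k = 4) and 2 for the strong (k = 1) setting.  The built-in grid comprises
twelve configurations — sample-size series (n = 100/500/1000/2000, one
causal marker at c = 0.3), two epistatic settings (marginals 0.05/0.05 with
interaction 0.2; 0.01/0.01 with 0.28), two skewed settings, and additive
series with 5/20/50/100 causal markers whose fractions are drawn from
N(6,2²)/100, N(1.5,0.5²)/100, N(0.6,0.2²)/100, N(0.3,0.1²)/100 (non-positive
draws rejected) — crossed with h ∈ {0.7, 0.85, 0.95}.

## The synthetic genotype panel

The generator emulates a prepared selfing-species panel: homozygous calls
(values {0, 2}), per-marker target MAF uniform on `(maf_low, maf_high]`
(default (0.10, 0.5]), realized by thresholding a latent Gaussian.  Markers
whose *empirical* MAF leaves the band, or which duplicate an earlier column,
are redrawn, so the returned panel satisfies both properties exactly.
Optional LD blocks share a latent factor with loading `sqrt(ρ)`.

What this panel does **not** emulate: real LD decay along chromosomes,
population structure, and relatedness between samples.  The samples are
exchangeable and markers (outside explicit blocks) independent.  One visible
consequence: kernel/ridge predictors (RR-BLUP/GBLUP), which exploit genomic
relatedness, degrade as non-informative markers dilute the relationship
matrix — at 10,000 independent markers with a 1,000-marker background their
held-out explained variance drops well below what is observed on real,
LD-structured genotypes.  Sparse models (LASSO/Elastic Net/Bayes B) are
barely affected.  Recovery experiments therefore run on 2,000-marker panels,
where both model classes operate in an informative regime; passing tests
demonstrate correctness of the machinery and recovery under the stated
conditions, not field performance on real panels.

## Prediction models

* **RR-BLUP** `y = μ1 + Xw + e`, `w ~ N(0, σ²_g I)`: variance components by
  REML — the marker kernel `K = XX'` is projected onto the intercept's
  orthogonal complement, eigendecomposed once, and the restricted likelihood
  profiled over `λ = σ²_e/σ²_g` is maximized by bounded scalar search on
  `log λ ∈ [log 1e−5, log 1e5]`.  Marker-form and kernel(GBLUP)-form
  predictions agree to ≤ 1e−6 relative (tested), and a fixed-λ fit equals the
  direct ridge solution.
* **Bayes A/B/C**: single-site Gibbs samplers (numba-compiled) sharing a
  scaled-inv-χ² residual prior (ν = 5); effect priors are per-marker
  scaled-t (A), spike-at-zero + scaled-t slab (B), spike + common normal
  slab (C).  Slab scales follow the standard rule of matching the prior
  genetic variance to half the phenotypic variance; the spike mass π is
  sampled under a Beta prior (prior weight 10, mean 0.5) unless fixed.
  Default chain: 6,000 iterations, 1,000 burn-in; desk-scale runs shorten
  this via model overrides recorded in run metadata.
* **LASSO / Elastic Net** minimize `½‖y − X*w‖² + α(l₁·‖w‖₁ + (1−l₁)·‖w‖²₂)`
  with unpenalized bias; scikit-learn's coordinate descent is
  re-parameterized exactly onto this objective and the attained objective
  value is exposed (tested against random-search bounds and closed-form
  ridge at l₁ = 0).
* **SVR / RF / XGBoost** delegate to scikit-learn/xgboost; the contract
  guarantees seeded determinism and, for the ensembles, impurity/gain
  importances normalized to sum to one.  SVR standardizes inputs and targets
  on training data and parameterizes its tube width as a fraction of the
  training-phenotype sd.
* **Neural networks** run on a small in-repo numpy engine (dense, 1-D
  convolution, locally connected, batch-norm, dropout, max-pool; Adam;
  validation early stopping with best-weight restore; gradients verified
  against finite differences).  MLP consumes standardized additive inputs;
  CNN/LCNN consume the one-hot channel tensor.  Since nucleotide identities
  do not exist for synthetic 0/1/2 data, one-hot encoding is over genotype
  *states* (≤ 3 indicators per marker) rather than bases.

## Evaluation protocol

Nested cross-validation with 3 outer and 5 inner folds, stratified on
(default 10) phenotype quantile bins; bins smaller than the fold count are
merged upward.  Hyperparameters are tuned independently per outer fold by a
TPE-style sampler (random warm-up 10 trials, top-25% "good" density, 24
candidates per step) maximizing the mean inner-fold explained variance; a
trial is pruned when its *running mean* falls below the 80th percentile of
previous trials' running means at the same step (inactive for the first 10
completed trials — a percentile over fewer is noise).  The winner is refitted
on the full outer-training data and scored on the untouched test fold with
`v = 1 − Var(y − ŷ)/Var(y)` (n−1 variances throughout; the ratio is divisor-
invariant).  Standardization statistics live inside the models and are
computed on their training rows only, so no test information reaches any fit.

## Importance aggregation

Per fold, importances are |coefficients| (linear/Bayesian) or normalized
impurity reduction (ensembles); signs are retained in exports but magnitude
drives ranking (a strong negative coefficient is importance, not
anti-importance).  Each fold's top-1,000 magnitudes are min–max normalized
to [0, 1]; a marker in the top-1,000 of ≥ 1 fold gets the mean of its
normalized values over all folds (0 where absent).  Ties break by marker
order.  The 1%-of-maximum filter is applied to the averaged values.
Effect/importance correlation is plain Pearson on untransformed pairs where
both quantities are nonzero (log axes in scatter plots are presentation
only).

## Problem sizes, seeds, and numerical choices

* Desk-scale defaults: recovery pipelines use 1,000 samples × 2,000 markers
  and 25–50 optimization trials (full scale: 10,000 markers, 200 trials);
  the trial budget and all seeds are recorded in run metadata.
* The permutation-null benchmark (all twelve families on a
  phenotype permuted against its genotypes) runs at 480 samples × 36
  markers, 12 trials, with fixed 64-unit networks, 100-tree ensembles and
  500-iteration Bayes chains; at this scale every family's mean v is within
  ±0.1 of zero.  Fewer trials leave the tuner unable to find regularized
  settings, which is precisely the mechanism that keeps the null at zero.
* Degenerate inputs: constant phenotypes make explained variance undefined
  (error); constant importance vectors contribute zeros with a warning;
  monomorphic causal markers are redrawn with a bounded retry count;
  infeasible MAF bands (smallest representable MAF above the band) and
  infeasible convolution geometries error before any computation.
* SVR fits are capped at 200,000 libsvm iterations: ill-conditioned
  large-C fits on signal-free data otherwise stall the tuner without
  improving their inner-fold objective.

## Known limitations

* No real-data ingestion beyond delimited tables; no PLINK binary reader,
  LD pruning, imputation, or GWAS integration.
* Epistasis is limited to pairwise Hadamard products; no dominance,
  genotype-by-environment, or multi-trait simulation.
* The Gibbs samplers return posterior means only by default; retained
  traces are available but no convergence diagnostics are computed.
* The NN engine is CPU-only and intended for benchmark-scale inputs, not
  for panels with hundreds of thousands of markers.
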