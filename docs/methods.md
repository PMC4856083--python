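# Methods

## The model

`metgs` fits a single-stage linear mixed model to plot-level data from
replicated, possibly multi-environment, crop trials:

```
y = X τ + Z_g g + Z_u u + ε,          g = (I_s ⊗ M) u_m + u_e
```

* `y` stacks the `n = Σ n_t` plot responses of `s` trials;
* `τ` holds a mean per trial plus optional trial-specific linear row/column
  covariates, with design `X`;
* `g` is the genetic effect of each of `v` lines in each trial, with 0/1
  incidence `Z_g` (trials-major column order, structural zero columns for
  lines absent from a trial);
* `M` is the `v × p` matrix of {0,2} marker codes, `u_m` the `p·s` marker
  effects (RR-BLUP: i.i.d. Gaussian given the trial covariance), and `u_e`
  the `v·s` residual genetic effects — line variation the markers do not
  capture (non-additive effects, and additive variation at loci the panel
  misses);
* `u` collects scalar-variance design terms (replicate blocks per trial,
  trial-specific random row/column factors), each `u_i ~ N(0, θ_i² I)`;
* `ε` has per-trial heteroscedastic variance, `R = ⊕_t θ_t² I_{n_t}`.

Setting `g = u_e` gives the *phenotypic* model (total genetic value, lines
assumed unrelated); `g = (I_s⊗M) u_m` the *standard* RR-BLUP model; both
terms together the *partitioned* model, which separates marker-driven from
residual genetic variation because replicated plots identify line effects
independently of the marker structure.

### Trial covariance families

Both genetic terms carry a trial×trial covariance `Γ` Kronecker-multiplied
with an identity (markers, residual lines) or a relationship matrix:
`diag` (independent trials; equivalent to fitting trials separately),
`cs` (one main effect variance plus a common specific variance),
`cs_diag` (main effect plus trial-specific variances),
`fam1` (main effect plus one multiplicative factor; specific variances
constrained to zero by default — at two trials the free parameterization
is not identifiable, needing five parameters where three suffice), and
`us` (free symmetric PSD).  `fam0` is the zero-factor factor-analytic
model and coincides with `cs_diag`; at `s = 2`, `fam1` with zero specific
variances spans the same space as `us`.  Families with a main effect
decompose marker effects into a stable across-trial component plus
marker×trial interactions; `diag`/`us` provide per-trial totals only.

### Fitting on the line dimension and back-solving

When `p > v` the marker term is fitted as `u_g = (I_s⊗M) u_m` with
covariance `Γ_m ⊗ K`, `K = M Mᵀ` (the realized genomic relationship matrix,
deliberately unscaled — any scalar on `K` is absorbed by the variance
parameter and leaves likelihood, BLUPs and GEBVs unchanged; `K/p` and a
VanRaden-style denominator are available behind a flag).  Marker effects
are recovered afterwards:

```
ũ_m = (I_s ⊗ Mᵀ K⁻¹) ũ_g
```

exactly when `K` is invertible; a singular `K` (possible when `v > p` or
with duplicated genotypes) drops its null eigenvalues, which is the
Moore-Penrose treatment — the identity then holds in projection only and
the result is flagged.  For families with a main effect the same transform
is applied to the main and interaction BLUP components.  These are obtained
by conditional projection rather than by fitting two explicit random terms:
with `u_g = u_f + u_δ`, `var(u_f) = Γ_main ⊗ K` and `u_f ⊥ u_δ` a priori,
the joint BLUP satisfies `ũ_f = (Γ_main Γ⁻¹ ⊗ I) ũ_g`.  The two-term and
single-term formulations have identical likelihoods (verified in a test for
the `cs` family); the projection avoids incidence matrices that depend on
the factor loadings.

## REML estimation

Variance parameters are estimated by residual maximum likelihood.  The
likelihood is evaluated through the mixed-model equations: with
`W = [X, Z_1 … Z_J]` and `C = WᵀR⁻¹W + diag(0, G⁻¹)`,

```
-2 l_R = (n - rank X) log 2π + log|R| + Σ log|G_j| + log|C| + yᵀPy ,
```

which matches a brute-force dense multivariate-normal REML evaluation to
~1e-12 (tested).  Each genetic term is pre-rotated by the eigenvectors of
its `K`, so `G_j = Γ ⊗ D` with `D` diagonal and the per-evaluation cost is
one Cholesky of `C` (size `rank X + Σ q_j`).  Per-trial cross-products
`W_tᵀW_t` are precomputed once, making each evaluation O(m²) assembly plus
O(m³/3) factorization.

The exact REML score is assembled analytically from the inverse blocks of
`C` (the trace terms need only `Γ`-block diagonals of `C⁻¹`), and a
quasi-Newton search (L-BFGS-B) runs on transformed coordinates: variances
as logarithms, factor loadings and `us`-Cholesky off-diagonals free.  The
log scale enforces positivity; box bounds clamp log-variances to
`[1e-10, 1e4] × var(y)`, and estimates at the lower bound are reported as
boundary hits (they still count in AIC, matching the published
parameter-count arithmetic).  Because the REML surface can contain long
flat ridges (e.g. the marker-vs-residual-genetic trade-off), the optimizer
is restarted from its incumbent until a restart improves −2l by less than
1e-6; points where a trial step makes `C` numerically non-PD are evaluated
with an escalating diagonal jitter so the line search sees finite values.
Convergence failures are flagged on the returned object, never silent.
Starting values split var(y) equally across the random terms and the
residual; a fit can be warm-started from another fit's estimates (the
partitioned models are chained from the standard fit of the same form, and
cross-validation refits start at the full-data estimates).

Wald-type intervals for the variance parameters come from the inverse
observed information on the transformed scale (central finite differences
of the analytic score), computed on request.

### Model comparison

`AIC = 2·(number of random parameters) − 2·loglik`, ignoring fixed-effect
counts (constant across compared models); random parameters are the
structure parameters of each genetic term, one per scalar design term and
one residual variance per trial.  Likelihood-ratio tests are offered only
for nested pairs sharing the fixed design (standard REML caveat); variance
parameters tested on their boundary make the χ² reference conservative,
which a Monte-Carlo test confirms (rejection ≈ 2–4% at nominal 5%).

## Derived statistics

* **Generalized heritability** per trial, from the phenotypic model:
  `H² = 1 − ā / (2 θ̂²_g,t)` with `ā` the mean prediction-error variance of
  all pairwise line-BLUP differences in that trial.  On a balanced one-way
  design this reproduces `r σ_g² / (r σ_g² + σ_e²)` exactly (tested).
* **Marker-captured share of genetic variance**:
  `1 − θ̂²_e(partitioned) / θ̂²_g(phenotypic)` per trial, both fits DIAG on
  identical data.
* **Predictive ability**: OLS regression of genotypic values (line BLUPs
  of a phenotypic model fitted to all genotyped lines) on GEBVs of
  held-out lines; R² is the predictive ability, the residual mean square
  (df = n_val − 2) the accuracy, and the slope is recorded for the
  low-density sweep.

## Cross-validation and the low-density sweep

Lines are split into 10 groups — lines common to all trials are dealt
round-robin after shuffling and keep one label across every analysis;
trial-specific lines then fill the smallest groups.  CV10/CV20/CV40 hold
out every combination of 1/2/4 groups (10/45/210 iterations).  Each
iteration deletes all phenotype records of the validation lines, refits the
genomic model on the remainder, back-solves marker effects and predicts the
validation GEBVs with the chosen effect set (same-trial or opposite-trial
totals of a DIAG fit; per-trial totals or the main effect of a MET fit).
Failed refits are flagged and excluded from averages, never silently
dropped.

The low-density sweep truncates the *full-marker* training effects to
random subsets of increasing size (default 200 resamples per size) instead
of refitting per subset — the workflow reuses estimated effects, and a
refit-per-subset variant can be built from the same primitives.  Subsets
are drawn once per (size, resample) from a dedicated seed and reused
byte-identically across every compared model, so model differences cannot
be confounded with subset luck.  Slope, R² and MSE are all stored, so
"predictive ability" can be read either as the regression coefficient or as
R².

## The synthetic generator

`metgs.synthetic` draws data from exactly the model above: {0,2} genotypes
with per-marker MAF ~ U(0.05, 0.5) (monomorphic draws rejected), marker
effects `N(0, Γ_m ⊗ I_p)` (the RR-BLUP prior; sparse-effect architectures
are out of scope), residual genetic effects `N(0, Γ_e ⊗ I_v)`, per-trial
replicate blocks occupying contiguous column ranges of an 8-row layout
with fresh randomization per block, and heteroscedastic plot noise.

Default study conditions emulate the motivating barley height trials at
desk scale (`s=2`, `v=300`, `p=600`, 5 replicate blocks): trial means
94.8/87.9 cm, trial covariances proportional to the published partitioned
FAM1 estimates rescaled so that markers drive ≈75% and ≈73% of total
genetic variances ≈112 and ≈86, residual plot variances 39.2/95.7, block
variance 2.  With uncentered codes each marker of MAF `q` contributes
`4q(1−q)θ` to between-line variance (mean 0.73·θ under the default MAF
law), which is how `config_with_marker_share` calibrates an exact
marker-driven share for recovery studies.  Drawn genetic effects are
centered within trial by default so the configured trial means are the
response means; the shift is absorbed by the fitted intercepts either way,
and a flag disables centering for moment-matching tests.

What the generator does **not** emulate: linkage disequilibrium and map
structure (markers are independent), selection history, genotype-calling
error beyond what the preprocessing tests construct, and spatial trend
beyond blocks and the random column factor.  Passing tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to real-data violations of them.

## Marker preprocessing

Heterozygous calls on inbred lines are treated as calling errors and set
missing.  Markers are dropped if monomorphic among observed calls, more
than 20% missing, or at minor allele frequency ≤ 5% (strict inequality,
judged on observed calls, re-applied after imputation because imputation
shifts allele counts).  Missing calls are imputed by iterated k-nearest-
neighbour averaging over lines (RMS distance on shared observed markers,
default k=10, 5 rounds, snap tolerance 0.4 around the codes); markers whose
imputed values fail to converge to {0,2} are discarded.  The neighbour
count, round limit and tolerance are this package's concrete choices — the
original workflow used an external imputer specified only by its outcome —
so per-marker results on real data can differ.  Exact duplicate columns
are removed keeping the first by input order (deterministic ties).  The
pipeline is idempotent.

## Problem sizes used by the test suite

Stochastic checks run at sizes chosen to keep the default suite fast while
leaving each check well powered; all thresholds are stated in the tests
themselves and none is loosened to fit the size:

* parameter recovery / proportion recovery: `v=200, p=400`, 5 reps, 100
  replicates (coverage of 95% Wald intervals asserted ≥ 90% per parameter;
  mean recovered share within ±0.05 of the simulated 0.75);
* partitioned-vs-standard paired cross-validation: 20 replicates at
  `v=150, p=150`, 5 replicate plots, marker share 0.5 and low plot noise —
  a marker panel the size of the line set gives the relationship matrix a
  broad eigen-spectrum, so the marker/residual partition is well identified
  per replicate and the partitioned model's advantage is large relative to
  validation noise (the paired difference's sign is informative);
* LRT null calibration: 400 replicates of a 20-line boundary null.

## Known limitations

* Dense linear algebra throughout: fine to a few thousand plots and ~1500
  combined random dimensions; the published trials (n ≈ 7500, v ≈ 477)
  fit in minutes per model on one core, but much larger METs would need
  sparse/structured solvers.
* No spatial residual correlation (AR1⊗AR1) or spline field terms; spatial
  structure is limited to the design factors.
* `fam_k` with k > 1 (and its rotational identifiability constraints) is
  not implemented; at s=2 it is not needed.
* Wald intervals on log-variances behave poorly for components truly at
  zero; boundary flags should be consulted before interpreting them.
* The heritability and proportion statistics assume the phenotypic-model
  line term is DIAG within trial; other forms report per-trial diagonals.
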