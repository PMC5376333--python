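# Methods

## Model

Species-mean traits are analyzed on the log10 scale, so a power law
`y = a x^b` is the line `log10 y = log10 a + b log10 x` and the exponent
`b` is the slope. For `n` species the pair of traits is modelled as
matrix-normal,

    X ~ MN(1 a', R ⊗ C(λ)),

with `C` the Brownian-motion phylogenetic covariance (entry (i, j) = branch
length shared by the root-to-tip paths of tips i and j; diagonal =
root-to-tip distance), `C(λ)` the Pagel transformation multiplying
off-diagonal entries by λ ∈ [0, 1], `a` the 2-vector of root states and
`R` the 2×2 evolutionary rate matrix. Assumptions: the tree is rooted with
branch lengths proportional to expected variance accumulation; trait
evolution is homogeneous-rate Brownian motion after the λ rescaling;
within-species variation is negligible at the species-mean level (species
means are taken before fitting, matching the study design the pipeline
reproduces).

Given `C(λ)`, `a` is the GLS estimator `(1'C⁻¹1)⁻¹ 1'C⁻¹X`, residuals are
`E = X − 1a'`, and the ML rate matrix is `R_ML = E'C⁻¹E / n`. The profile
log-likelihood

    ℓ(λ) = −½ [ n·m·ln 2π + n·ln|R_ML| + m·ln|C(λ)| + n·m ]

(m = 2 traits; natural log internally, trait values on log10 scale — the
two never mix since the likelihood is evaluated on already-transformed
values) is maximized over λ ∈ [0, 1].

## RMA line and tests

The reduced-major-axis (standardized major axis) slope is
`β₁ = sign(R_xy) √(R_yy/R_xx)`, computed from `R = E'C⁻¹E/(n−1)`; slope,
intercept and correlation are invariant to the divisor. The intercept
passes through the GLS means. RMA is used, rather than OLS, because both
traits carry measurement and evolutionary error and the target quantity is
the scaling exponent, not a prediction rule. When `R_xy = 0` exactly the
slope sign is taken positive with a warning (log-morphometric covariances
are positive in practice).

- **Isometry test.** `T = |ln|β₁| − ln h| / √((1 − r²)/df)` with
  `r² = R_xy²/(R_xx R_yy)` and `df = n − 2`, referred two-sided to
  Student's t. This is the standard SMA log-slope test; it is symmetric in
  `β₁ ↔ 1/β₁` at `h = 1`, as direction-free RMA requires. `df = n − 1`
  is available as a configuration option since reported degrees of freedom
  in comparative studies vary.
- **Confidence interval.** `B = F(1−α; 1, df)(1 − r²)/df`;
  `CI = β₁(√(B+1) ∓ √B)` — the standard SMA interval; it always contains
  β₁ and satisfies `ci_low · ci_high = β₁²`.
- **λ LRT.** `Δ = 2(ℓ(λ̂) − ℓ(0))` against χ²₁. Because λ = 0 is a boundary
  point, the plain χ²₁ reference is conservative (simulated size ≈ 2–4% at
  nominal 5%); the ½χ²₀ + ½χ²₁ mixture is available as
  `lambda_lrt_boundary`.
- **Goodness of fit.** `R² = 1 − SS_res/SS_tot` with residuals from the
  RMA line and `SS_tot` around the ordinary arithmetic mean of y. Because
  the RMA line is not the least-squares line this R² can be negative for
  weakly correlated pairs (the residual-on-residual regression routinely
  shows this). A `gls` option centers on the GLS mean and weights both
  sums by C⁻¹ instead.

λ is estimated jointly on the bivariate data (a single λ for the pair),
which is the natural reading of a correlation structure applied to a
bivariate regression; per-trait λ is out of scope.

## Pipeline conventions

- **Cleaning rules** (applied per specimen before species means): a
  vaginal fold is any wall folding ≥ 0.5 mm; entries in [0.5, 1) mm are
  rounded to 1 mm for the cumulative sum; only folds ≥ 1 mm enter the fold
  count. The operation is idempotent on its own output.
- **Units.** By default all length traits are converted to mm before
  log10 (intercepts are unit-dependent; slopes, r², λ and all tests are
  not). `units='paper'` keeps native units (body and vaginal length cm,
  fold length mm).
- **Species set.** The three regressions use the complete-case species set
  (species with all three trait means present and positive, intersected
  with the tree); species missing from the tree are dropped with a logged
  warning. Species means sum values in sorted order so reports are exactly
  invariant to specimen-row permutation.
- **Residual regression.** The third fit regresses residuals of
  cumulative fold length on residuals of vaginal length, both taken from
  ordinary non-phylogenetic fits on body length. The residual-producing
  line is RMA by default (consistent with the fitting philosophy
  throughout); OLS is selectable, in which case residuals have exactly
  zero mean (recorded in the report's provenance block).
- Summary statistics use the sample (n − 1) standard deviation.

## Synthetic data generator

The generator emulates a stranding-network dissection dataset: an
ultrametric Yule (pure-birth) tree; species-mean log10 body length and the
two responses drawn jointly under λ-BM; 1–5 specimens per species with
multiplicative lognormal noise (`cv` parameterized, default 0.05 — calipers
and rulers on fresh carcasses measure tightly, but carcass condition
varies); per-specimen fold lists obtained by a Dirichlet split of the
cumulative fold length, with sub-millimeter wall foldings injected at 10%
probability per fold to exercise the cleaning rules.

The joint rate matrix of (log BL, log VL, log VFL) is built so each
response correlates ρ with body length, the responses correlate only
through body length (ρ²), and — the key construction — each pair's
**standardized major axis has slope exactly equal to the target
exponent**: R_xy = ρ·b·R_xx and R_yy = b²·R_xx. With an independent
additive deviation the SMA estimand would be b√(1 + var_dev/(b²·var_x)),
not b, and exponent-recovery experiments would be meaningless.

Defaults (chosen once to be realistic for the system emulated): 20
species; root log10 body length 2.5 (≈316 cm); evolutionary variance of
log10 BL 0.09 (≈120–1500 cm species range); evolutionary correlation 0.66;
VL exponent 1.4, VFL exponent 2.17; λ = 0.7; fold counts 1–13. The packaged
fixture trims to exactly 59 specimens across 20 species. Specimen fold
lengths are floored at 1 mm (the smallest recordable fold), and measured
values are rounded to field precision (0.1 cm body length, 0.01 cm vaginal
length, 0.01 mm folds).

What the generator does **not** emulate: sampling and stranding biases,
decomposition effects, maturity-dependent allometry, non-ultrametric
trees, non-BM (e.g. Ornstein–Uhlenbeck) trait evolution, and measurement
error correlated across traits within a specimen. Passing recovery and
calibration tests therefore demonstrates correctness of the estimator
under its own model, not robustness to these features of real data.

## Numerical choices

- λ optimization: 21-point grid pre-scan on [0, 1] followed by bounded
  scalar (Brent) refinement between the grid neighbors of the best point,
  absolute tolerance 1e-8; endpoints 0 and 1 always evaluated. On a star
  tree the likelihood is flat in λ; λ̂ = 0 is returned with an
  `identifiable = False` flag.
- All solves use Cholesky factorization; a non-positive-definite `C`
  (e.g. duplicate tip positions from zero-length terminal branches, which
  are flagged at parse time) raises with an actionable message.
- Non-ultrametric trees are accepted (the λ = 0 ⇔ ordinary-SMA
  equivalence then no longer holds and is only asserted on ultrametric
  trees).
- Two-tip trees support only a single trait column in the likelihood: the
  profiled bivariate rate matrix is singular at n = 2 (rank-1 residuals);
  fits require n ≥ 3.
- Degenerate cases: `r² = 1` with `β₁ ≠ h` reports p = 0 with a warning;
  `r² ≥ 1` collapses the CI to a point.

## Validation problem sizes

The simulation suites in `tests/` use: 200-tip Yule trees × 200 replicates
per λ ∈ {0, 0.5, 1} for parameter recovery (mean λ̂ within ±0.1, mean β̂₁
within ±0.05 of truth); 100-tip trees × 500 replicates for the two
rejection-rate calibrations (λ-LRT size ≤ 7%; isometry-test size within
3–8% at nominal 5%); 50-tip trees × 300 replicates for CI coverage
(≥ 90%); 50 random star-tree instances for the closed-form SMA
equivalence at 1e-10. One frozen test pins the core fit to values computed
independently with `phytools::phyl.RMA` in R on a 12-tip dataset (β to
2e-4, λ to 1e-3; that implementation's λ-adjusted degrees of freedom are
not compared, since this package reports df = n − 2 by design).

## Known limitations

- Single λ per bivariate fit; no per-trait λ, OU, or measurement-error
  models.
- The isometry test and CI treat r² and n as if λ were known; uncertainty
  in λ̂ is not propagated (standard practice, slightly anticonservative at
  small n).
- Multifurcations are handled in covariance construction but the Yule
  generator only produces bifurcating trees.
- The goodness-of-fit R² is scale-dependent through the intercept when
  units change; comparisons across unit policies should use slopes, r² or
  λ, which are invariant.
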