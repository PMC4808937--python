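# Methods

## The model

The data are bilateral surface-EMG recordings of four scapular muscles —
pectoralis major (PM), upper trapezius (UT), serratus anterior (SA) and
rhomboid major (RH) — taken at 10° increments of humeral elevation during
upward and downward arm movement, on the affected and unaffected side of
patients treated for unilateral breast cancer. Responses are analysed on
the natural-log millivolt scale. One *series* is the ordered vector of
readings over elevation for a fixed (patient, muscle, side, movement);
a complete patient contributes 4 muscles × 2 sides × 2 movements = 16
series.

Let `y_iksm` be the series of patient `i`, muscle `k`, side `s`, movement
`m`. The model ladder is:

1. **model3 — independent series.** `y_iksm ~ N(X_iksm beta_ksm, Sigma_k)`
   with a stationary AR(1) residual covariance per muscle,
   `Sigma_k[a, b] = sigma_k^2 rho_k^|a-b|`. All series are independent;
   the same `(rho_k, sigma_k^2)` is shared by all four side×movement
   series of muscle `k`.
2. **model4 — independent muscle intercepts.** Adds a random intercept
   `nu_ik` per patient and muscle, shared across that muscle's sides,
   movements and elevations, with `nu_ik ~ N(0, d_kk)` independent across
   muscles.
3. **model6 — correlated muscle intercepts.** The vector
   `nu_i = (nu_i1..nu_i4)' ~ N(0, D)` with `D` a full symmetric PSD 4×4
   matrix. Its off-diagonals carry the scientific signal of cross-muscle
   coupling: whether compromising one scapular muscle co-varies with the
   activity of the others.

The marginal covariance of one patient's stacked data is
`V_i = Z_i D Z_i' + blockdiag(Sigma_k per series)`, where `Z_i` is the
0/1 muscle-membership loading. model3/model4 are the `D = 0` and
`D` diagonal special cases, giving the ladder its 4, 6 and 10
covariance-parameter steps (8 AR(1) parameters are always present).

### Fixed effects

Every covariate receives four muscle-specific coefficients (the tests
later pool them). Three term groups:

* main effects: intercept, humeral elevation, upward movement, affected
  side, left-handedness, measured-side-is-dominant, age, days since
  surgery, SPADI pain, SPADI disability, WLE treatment, chemotherapy;
* affected-side interactions: elevation, dominant, duration and SPADI
  pain, each multiplied by the affected indicator;
* affected-only terms: exercise (last 6 months / current) and
  physiotherapy (current / ever), which are only meaningful on the
  operated arm and enter multiplied by the affected indicator.

Covariates conventionally reported "×100" (elevation, age, duration, both
SPADI scores) are divided by 100 *before* interactions are formed, so
coefficients land on the customary reporting scale. The default design
has 20 covariates per muscle, 80 columns; dropping the interaction group
removes 16 columns and dropping both arm-specific groups removes 32 —
these are exactly the fixed-effect degrees of freedom of the two
interaction likelihood-ratio comparisons.

The stored covariate `dominant_side_measured` is patient-level ("the
dominant hand is on the affected side"); the design derives the
series-level "measured side is dominant" indicator from it and the side
of each series.

## Estimation

For fixed covariance parameters the fixed effects have the closed GLS
form `beta = (sum_i X_i'V_i^-1 X_i)^-1 sum_i X_i'V_i^-1 y_i`, so the
optimizer works on the profiled deviance (−2 log likelihood) over an
unconstrained covariance parameterization: `log sigma_k^2`,
`arctanh rho_k`, and `D = LL'` in log-Cholesky form (logs of the diagonal
of `L`, free off-diagonals). This keeps every iterate inside the valid
region without constrained solvers. REML adds
`log det(sum_i X_i'V_i^-1 X_i)` to the criterion.

Numerical choices:

* **Grouped factorization.** Patients sharing a series layout share `V_i`
  exactly, so `V` is Cholesky-factorized once per layout group and all
  patients' right-hand sides are solved in one batched triangular solve.
  No global covariance matrix is ever formed; the largest per-patient
  block in the default design is 240×240 (4 muscles × 4 series × 15
  increments).
* **Analytic gradients.** Because the profiled beta is the GLS minimizer,
  the beta-dependence of the quadratic form drops out of the gradient
  (envelope theorem); each component is `sum(G ⊙ dV/dtheta)` with
  `G = m V^-1 − sum_i u_i u_i'`, `u_i = V^-1 r_i`, and a subtracted
  information-matrix term under REML. The gradient is verified against
  finite differences in the test suite.
* **Optimizer.** L-BFGS-B, relative-deviance tolerance 1e−8, projected
  gradient tolerance 1e−5, wide box bounds that only exclude numerically
  degenerate parameters (`|arctanh rho| ≤ 7` etc.). Starting values:
  sigma_k^2 at half the per-muscle OLS residual variance, rho_k = 0.5,
  D = 0.1·I. Optional seeded multistart perturbs the start. Convergence
  failures are flagged on the result, not raised; variance components
  within 1e−6 of zero raise a boundary warning.
* **ML vs REML.** ML is the default because likelihood-ratio tests
  between models with different fixed effects are only valid under ML.
  REML is available and is used by the parameter-recovery acceptance
  study, where unbiased variance components are the point.
* **AR(1) exponent.** By default the exponent is the within-series
  position difference (consecutive increments). An optional mode uses
  the elevation gap divided by 10 instead, for series with skipped
  increments; on complete grids the two coincide.
* **Degenerate inputs.** Length-1 series contribute a 1×1 block
  `sigma_k^2`. A rank-deficient design raises an error naming the most
  collinear columns. `sigma^2 = 0` is representable in the simulator (the
  noise-free limit) but rejected by every fitting routine.

## Inference

* Per-coefficient and *collective* Wald tests: the collective ("overall
  effect") test pools one covariate's four muscle coefficients into a
  4-df chi-square `(Cb)'(C Cov(b) C')^{-1}(Cb)`. Asymptotic chi-square
  references are used throughout — no denominator-df (Satterthwaite /
  Kenward-Roger) correction, a deliberate simplification that makes
  p-values slightly liberal in small samples.
* Likelihood-ratio tests between nested rungs: delta deviance against
  chi-square with df equal to the parameter-count difference. Negative
  deltas (optimizer noise) are clipped at zero with a warning. For
  variance components on the boundary of the parameter space (e.g.
  model3 vs model4) the naive chi-square p-value is conservative; a
  clearly-labelled 50:50 chi-square-mixture p-value (one-component
  boundary approximation) is attached as a secondary reading.
* The clinical hypothesis battery fits the full model and reports, by
  content: equality of arms (affected-side intercepts, the joint Wald on
  all arm-distinguishing terms, and the 16-df / 32-df interaction LRTs),
  SPADI pain and disability effects (unaffected-arm effect and the
  pain-by-arm interaction), collective tests per clinical risk factor,
  and per-interaction effect-modification tests. Raw p-values are
  reported; no multiplicity correction is applied.

## Residual diagnostics

Standardized residuals whiten each patient's residual vector with the
Cholesky factor of the fitted `V_i`; under a correctly specified model
they are exactly iid standard normal, which makes the "about 5% beyond
|2|" reference (exactly 4.55%) correct by construction. A marginal
variant (raw residual over marginal SD) is available; it is correlated
within patients but lives on the observation scale.

Deletion residuals compare each observation with its prediction from
fixed effects re-estimated *without* that observation, standardized by
`sqrt(V_jj + x_j' M_(-j)^{-1} x_j)`. Covariance parameters stay at the
full-fit values: a full covariance refit per deletion would be
computationally disproportionate and changes nothing to first order.
Deletion is per single observation, not per series. The fast path uses
exact Schur-complement / Sherman-Morrison downdates of the GLS normal
equations; a brute-force leave-one-out refit exists solely as an oracle
and matches to ~1e−14.

## The synthetic-data generator

The simulator draws complete studies from the generative side of the full
model: patient covariates, `nu_i ~ N(0, D)`, then per-series stationary
AR(1) noise via the recursion `e_1 ~ N(0, s2)`,
`e_j = rho e_{j-1} + N(0, s2(1−rho^2))`. The default conditions mirror
the real study design: 202 patients, elevations 10°–150° (15 increments),
2 sides × 2 movements × 4 muscles. Default truth values are realistic for
log-EMG of this population: autocorrelations (0.79, 0.85, 0.82, 0.80),
residual variances (0.31, 0.37, 0.33, 0.29), random-intercept variances
(0.33, 0.38, 0.29, 0.35) (ln mV)², with a common +0.5 cross-muscle
correlation reflecting the positive coupling of scapular muscles, and
coefficient magnitudes of the same order as published estimates.

Covariate distributions are configurable stand-ins, since the source
study reports only summaries: binary prevalences (WLE 0.7, chemo 0.5,
exercise 0.3–0.4, physiotherapy 0.2–0.6, handedness and dominance 0.5),
age ~ N(55, 10²) years, duration since surgery uniform on 180–2190 days,
and right-skewed gamma SPADI scores capped at their instrument maxima
(pain 0–500 mm, disability 0–800 mm). Randomness is hierarchical: one
global seed spawns independent per-patient and per-series streams, so
enlarging a study leaves earlier patients' data bit-identical.

What the simulator does *not* emulate: EMG waveform physiology or
amplitude non-Gaussianity, informative drop-out of high elevations
(every patient reaches the configured maximum unless a range is given),
measurement rounding, or covariate dependence (age, pain and exercise
are drawn independently). Passing tests therefore demonstrate that the
estimator and tests recover the *statistical* structure they assume, not
that the model fits any particular real dataset.

## Verification strategy and problem sizes

The suite anchors correctness on independent oracles: closed-form AR(1)
determinants and tridiagonal inverses; a hierarchical-likelihood oracle
that integrates the conditional model over the random effects with
tensor-product Gauss-Hermite quadrature (matched to 1e−6 relative on a
2-patient, 2-muscle instance); brute-force leave-one-out refits against
the fast deletion residuals; and finite-difference gradients against the
analytic ones.

Simulation-backed checks use sizes chosen to give stable Monte-Carlo
error at interactive runtimes: parameter recovery uses 50 replicates of
100 patients with 10 increments per series, fit by REML, asserting each
replicate mean within 3 Monte-Carlo SEs of truth; Wald-test calibration
uses 1000 replicates of 100 patients with 5 increments and a compact
four-covariate design, asserting empirical size in [0.03, 0.07] at
nominal 5% plus uniformity of the null p-values; the boundary-null LRT
check uses 120 replicates of 25 patients. The end-to-end acceptance
script runs the full 202-patient default design once.

## Known limitations

* Wald p-values are asymptotic; with few patients they run slightly
  liberal (no denominator-df approximation is attempted).
* The boundary-mixture p-value is the one-component approximation; the
  exact null for several variance components is a more complex
  chi-square mixture.
* ML variance components carry the usual O(p/N) downward bias; use REML
  when the variance estimates themselves are of interest.
* Missing covariates are handled by complete-case deletion at the
  patient level (with a warning), not imputation.
* Only the AR(1) residual family is implemented; the covariance module
  is the extension point for compound-symmetry or unstructured
  alternatives.
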