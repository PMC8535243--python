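# Methods

## The problem and the model

Provider billing summaries from fee-for-service claims (per-provider
averages of submitted charges and payments for a single procedure code)
yield a *billing aggressiveness* response: the ratio of the average
submitted charge to the average payment amount. Its distribution is
strongly right-skewed and leptokurtic, so mean regression describes the
bulk poorly and the tails — the conservative and the potentially
upcoding providers — not at all.

qbill therefore models the conditional quantiles. For quantile level
τ ∈ (0, 1),

    y_i = x_i' β*(τ) + e_i,      P(e_i ≤ 0 | x_i) = τ,

estimated by minimizing the summed check loss
ρ_τ(e) = e·(2τ − 2·I(e<0)) (the factor-2 convention; exactly twice the
Koenker loss, with identical minimizers). This is simultaneously the
maximum-likelihood fit under an asymmetric Laplace (ALD) error law with
density τ(1−τ)σ⁻¹·exp(−ρ_τ(e)/(2σ)), whose location parameter is the
conditional τ-quantile. The factor-2 convention is the package default
because that ALD density is then properly normalized; every reported
objective uses it, and `convention="standard"` is available on the loss.

### Exact fitting via the dual LP

Check-loss minimization is a linear program. We solve the *dual*:
maximize y'a subject to X'a = 0 (intercept included) and
a_i ∈ [τ−1, τ], with HiGHS. The primal coefficients are the marginals of
the equality constraints. The dual has n box-bounded variables and only
p+1 rows, which is 5–10× faster than the primal residual-split
formulation at the study's scale (n ≈ 10²–10³, p = 14) and numerically
identical (verified against the primal formulation and against an
exhaustive basic-solution oracle; the test suite keeps both checks). At
any optimum #{r_i<0} ≤ nτ and #{r_i>0} ≤ n(1−τ); this sign diagnostic is
exposed and asserted throughout.

When the minimizer is an interval (e.g. intercept-only fits with nτ an
integer) any LP vertex is accepted; tests assert the objective value,
not the non-unique argmin.

### Uncertainty

Confidence bands use the xy-pair bootstrap (percentile intervals,
B = 1000 by default), which remains valid under the heteroscedastic
location-scale structure the data exhibit. Significance stars follow
the convention [0, 0.001): ***, [0.001, 0.01): **, [0.01, 0.05): *,
applied to a two-sided proportion-based bootstrap p-value analogue,
2·min(P*(β ≤ 0), P*(β ≥ 0)). Rank-inversion and sandwich-covariance
intervals are deliberately out of scope.

## Penalized variable selection

Per quantile, for each λ on a grid (default: 100 log-spaced points in
[0.01, 1]) we solve

    min_{b0, b}  Σ_i ρ_τ(y_i − b0 − x_i'b) + λ·n·Σ_j |b_j|

on centered, unit-sd covariates (L1 penalties are scale-sensitive; the
intercept is never penalized), again through the dual LP (constraints
|X_j'a| ≤ λn/2 per slope on the standard-loss scale). The penalty is
parameterized as λ·n·Σ|b_j| so the [0.01, 1] grid corresponds to a
per-observation penalty of λ per unit standardized coefficient —
documented because λ scales are solver-convention-dependent.

Slopes with |b_j| < 0.001 on the standardized scale are then set to zero
(strict inequality; the intercept is never thresholded), defining the
candidate support Ŝ_λ. Each support is scored by the modified BIC for
quantile regression,

    BIC(S) = log( Σ_i ρ_τ(y_i − x_iS' β̂_S) ) + |S| · log(n)/(2n) · C_n,

with C_n → ∞; the default C_n = log(log n) follows the modified-BIC
literature for diverging model spaces, with `log_p` and constant
alternatives exposed (this is the single most consequential free
constant, so it is configurable everywhere). |S| counts slopes only.
λ̂ is the BIC argmin over the grid; ties resolve to the largest λ
(parsimony). Because the slope L1 norm is non-increasing in λ (a
two-point convexity argument gives (λ₂−λ₁)(‖b(λ₂)‖₁−‖b(λ₁)‖₁) ≤ 0),
once the path reaches all-zero slopes the remaining grid points reuse
that solution.

**Where the BIC is evaluated.** BIC(S) is defined at the candidate
model's maximum-likelihood estimator, so by default the loss is
recomputed at an *unpenalized refit* on the thresholded support
(memoized per support). Scoring the shrunken penalized coefficients
instead (`bic_at="penalized"`) systematically favors
one-variable-too-large models — at the λ sparse enough to zero the noise
variables, the surviving true coefficients are shrunk and their loss
inflated, so a less-shrunk superset at smaller λ wins — and measurably
breaks selection consistency in our simulations (71% vs 100% exact
support recovery under the strong-signal design below). The *reported*
estimates at λ̂ are the penalized ones by default; `refit=True`
reports the MLE refit on the selected support instead.

Degenerate cases: zero loss (interpolation) maps to BIC = −∞ with a
warning; C_n = log log n requires n ≥ 3.

## OLS baseline and diagnostics

The comparison fit is classical OLS (homoscedastic standard errors and
two-sided t-tests; HC1 behind a flag), backed by statsmodels behind the
module surface. Residual normality is tested with a Lilliefors statistic
(KS distance between the residual ECDF and a normal with estimated
mean/sd) whose p-value is Monte Carlo: mc_reps (default 10⁴) samples of
n standard normals pushed through the same estimate-then-KS step, with
p = (1 + #{D* ≥ D})/(mc_reps + 1). This is exact at any n, reproducible
given a seed, and its null p-values are verifiably uniform (asserted by
a KS test across independent replicates). Q-Q data use plotting
positions (i − 0.5)/n on standardized residuals.

## The synthetic claims generator

No public-claims extract ships with the package, so all validation runs
against a generator that emulates the claims ecosystem:

* **Covariates (14).** Service/beneficiary counts (negative binomial,
  floored at the public-file reporting minimum of 11; beneficiaries a
  binomial thinning of services, giving the realistic strong correlation
  between the two, r ≈ 0.97), payment averages (lognormal/normal on
  dollar scales matching published summaries: standardized payment mean
  25.6, sd 2.6), a state-level block of seven demographic/spending
  covariates plus a work-GPCI drawn once per state (40 states, GPCI
  centered at the national average 1.0), and provider-type aggregate
  aggressiveness (6 types; mammography-like mix dominated by diagnostic
  radiology, with general surgery notably more aggressive).
* **Response.** Location-scale construction on internally standardized
  covariates: y = [1, x̃]'b + ([1, x̃]'g)·ε, with ε i.i.d. ALD
  (exponential-difference sampler: σ(U/τ₀ − V/(1−τ₀)), exact, no
  rejection), shifted-lognormal, or Student-t. The conditional
  τ-quantile is exactly [1, x̃]'(b + g·F⁻¹(τ)), so the true
  quantile-coefficient function is known in closed form. Scale factors
  below 0.05 are clipped with a logged count (fatal above 5%).
* **Raw-file emission.** The generator inverts the feature engineering:
  it writes claim lines whose submitted charge equals y × allowed
  amount, plus state and locality lookup CSVs, so that the standard
  load → filter → assemble path reproduces the design and response to
  ≈1 ulp. The provider-type aggregate covariates are recomputed from the
  emitted sample exactly as assembly recomputes them.
* A single RNG stream per purpose, spawned from the seed
  (design, then noise), with a fixed draw order, keeps fixtures stable.

What the generator does **not** emulate: spatial correlation beyond
state-level clustering, fraud labels (the source data have none),
longitudinal structure, or the 89-locality fee-schedule crosswalk
(replaced by a one-row-per-state lookup). Passing tests therefore
validate the estimators and the pipeline mechanics, not claims about any
particular real-world extract.

### Named study configurations

* `default_truth` — pipeline demonstration: aggressiveness falls with
  the standardized payment, rises with HCC score and with the provider
  type's typical aggressiveness; a heteroscedasticity loading of 0.25 on
  the HCC score makes its effect grow with τ; right-skewed ALD noise
  (σ = 0.25, asymmetry 0.3).
* `recovery_truth` — parameter recovery: 3 active of 14 covariates at
  unit standardized effect, ALD σ = 0.025, asymmetry 0.3. The noise
  scale comes from an a priori power calculation: the asymptotic sd of a
  quantile-slope estimate is ≈ √(τ(1−τ)) / (f(F⁻¹(τ))·√n) · √VIF, and at
  τ = 0.99, n = 5000, with the count pair's VIF ≈ 16, σ = 0.025 puts the
  expected worst-coefficient error near 0.05 — half the 0.1 recovery
  tolerance the tests assert. This configuration validates
  *correctness* (convergence to the known β(τ)), intentionally not
  statistical efficiency at realistic noise.
* `selection_truth` / `null_truth` — support recovery: |b_j| = 1 on 3 of
  14 covariates (or none), homoscedastic symmetric ALD with sd exactly 1.
* `heavy_tail_truth` — mean-centered shifted-lognormal noise
  (σ_log = 1.2, marginal skewness ≈ 11) dominating a weak signal,
  reproducing the extreme right skew reported for real billing
  aggressiveness without targeting any specific published value.

## Data handling choices

* Aggressiveness denominator: the payment field is configurable
  (`allowed` default, `medicare_payment`, `standardized`), since "payment
  amount" is ambiguous across published conventions and the allowed
  amount is the usual choice for charge ratios.
* Provider-type aggregates include the focal provider (no leave-one-out)
  and are computed within the focal procedure; singleton types get
  sd = 0 so the design stays complete. The inclusion is a known, documented
  leakage caveat of this engineered covariate.
* Multiple qualifying rows per provider collapse by service-count-
  weighted means of the currency averages (recovering the pooled
  per-service mean) and summed counts.
* Proportion covariates live in [0, 1]; 0–100 inputs are detected by
  range and rescaled with a warning. Unmatched joins are dropped and
  counted, never silent; >50% unmatched is fatal as a schema-mismatch
  signal.

## Problem sizes and numerical tolerances

Oracle comparisons use 200 instances (n ≤ 12, p ≤ 2) at 1e-9 against
exhaustive enumeration and 50 single-covariate instances against a
coarse-to-fine grid search with an explicit Lipschitz resolution bound.
Recovery uses 20 seeds at n = 5000; support recovery 100 seeds at
n = 1000 per design; Lilliefors uniformity 200 null replicates at
n = 100 with 2000 Monte-Carlo draws each; the pipeline reproducibility
check runs n = 400 with B = 200 bootstrap replicates and a 50-point λ
grid. LP agreement tolerances are 1e-9 (unpenalized) and 1e-6
(λ = 0 endpoint vs the unpenalized fitter); BIC components are
recomputable from their parts to 1e-12.

## Known limitations

* Bootstrap bands are percentile-type; no studentization, and no claim
  of matching any published table's significance annotations, whose
  inference method is not reproducible from public information.
* The reported penalized estimates at λ̂ carry lasso shrinkage; use
  `refit=True` when unbiased-magnitude estimates matter.
* Quantile-curve crossing is not rearranged; with 7 well-separated
  quantiles and moderate p it has not arisen in testing, but it is not
  prevented.
* The streaming/at-scale ingestion of multi-million-row public files is
  out of scope; the reader is plain pandas CSV.
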