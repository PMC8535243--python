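# qbill

Quantile-regression variable selection for health-care billing
aggressiveness.

Fee-for-service claims summaries let one measure how aggressively each
provider bills a given procedure: the ratio of the average submitted
charge to the average payment amount. That ratio is heavily
right-skewed — most providers bill near the allowed amount, a tail bills
multiples of it — so ordinary mean regression answers the wrong
question: it describes the average provider, while auditors and policy
analysts care about the conservative and the aggressive tails, and about
*which* covariates matter *where* in the distribution.

qbill is a tested implementation of the quantile-regression study design
for this problem, aimed at biostatisticians and program-integrity
analysts working with provider-level claims summaries:

* **Claims ingest and feature engineering** (`qbill.claims_io`):
  validated loading of claims-shaped CSVs, study-population filtering
  (one procedure, individual entities, facility place of service),
  the aggressiveness response, and a 14-covariate provider-level design
  (counts, payment averages, a work-GPCI, state-level demographics and
  spending, provider-type aggregate aggressiveness).
* **Exact quantile regression** (`qbill.quantile_core`): check-loss
  minimization solved as a linear program (via its dual; HiGHS), the
  asymmetric-Laplace likelihood it corresponds to, residual-sign
  optimality diagnostics, and xy-pair bootstrap confidence bands with
  significance stars.
* **Penalized variable selection** (`qbill.penalized_selection`):
  L1-penalized quantile fits over a λ grid, a 0.001 zero-threshold rule,
  and the modified BIC, log Σρ_τ + |S|·log(n)/(2n)·C_n, minimized over
  the grid to pick λ̂ and the per-quantile covariate support.
* **An OLS baseline** (`qbill.ols_baseline`) with a Monte-Carlo
  Lilliefors normality test and Q-Q data — the standard evidence that
  mean regression is inadequate here.
* **A synthetic claims generator** (`qbill.synthetic_data`) with known
  quantile-varying ground truth β(τ) = b + g·F⁻¹(τ) via a
  location-scale construction, which also emits claims-shaped raw CSVs
  that round-trip through the ingest path.
* **A pipeline and CLI** (`qbill.pipeline`, `qbill` command) tying the
  stages together with seeded, byte-reproducible CSV/JSON artifacts.

The model: for quantile level τ, `y_i = x_i'β*(τ) + e_i` with
`P(e ≤ 0 | x) = τ`, fitted by minimizing Σ_i ρ_τ(y_i − x_i'β) with
ρ_τ(e) = e·(2τ − 2·I(e<0)), equivalently maximum likelihood under an
asymmetric Laplace error; the default quantile set is
{0.01, 0.05, 0.25, 0.50, 0.75, 0.95, 0.99}. See `docs/methods.md` for
the full methodology and design choices.

## Worked example

Run the full study on simulated claims (the generator's demonstration
truth has aggressiveness falling with the standardized payment amount,
rising with patient risk and with the provider type's typical
aggressiveness, and a heteroscedasticity loading that makes the risk
effect grow across quantiles):

```python
from qbill.pipeline import RunConfig, run_pipeline

paths = run_pipeline(RunConfig(outdir="demo", mode="simulate", n=400,
                               seed=7, bootstrap_B=200, lambda_points=50))
```

`demo/diagnostics.json` shows why mean regression is not enough — the
OLS residuals decisively fail normality:

```json
{"lilliefors_statistic": 0.1145, "lilliefors_p": 9.999e-05, "r_squared": 0.729}
```

`demo/quantile_coefficients.csv` gives the per-quantile estimates with
bootstrap stars. For two of the active covariates (original scale):

```
variable                   0.01    0.05    0.25    0.5     0.75    0.95    0.99
avg_standardized_payment  -0.428  -0.401  -0.416  -0.430  -0.386  -0.248  -0.272   *** at every τ
average_hcc_score          4.053   6.093   7.379   8.814   9.819  16.529  16.792   *** at every τ
```

The payment effect is negative everywhere, while the HCC (patient-risk)
effect *quadruples* from the conservative to the aggressive tail — the
quantile-varying structure the generator planted and a single OLS slope
cannot express. `demo/selection.csv` holds the BIC-selected sparse
models per quantile (unselected covariates reported as exactly 0): the
three truly active covariates — `avg_standardized_payment`,
`average_hcc_score`, `mean_agg_provider_type` — are kept at every τ
except the payment amount at τ = 0.99, with occasional small extras at
the extreme quantiles, where n = 400 leaves only a handful of tail
observations on either side.
`demo/comparison.csv` contains the OLS-interval-versus-quantile-band
data behind the usual coefficient-path figure.

The same stages are available as shell commands:

```bash
qbill simulate --n 400 --seed 7 --outdir raw/
qbill assemble --claims raw/claims.csv --states raw/state_covariates.csv \
               --locality raw/locality.csv --out analysis_table.csv
qbill quantreg --table analysis_table.csv --out quantile_coefficients.csv
qbill select   --table analysis_table.csv --lambda-min 0.01 --lambda-max 1 \
               --cn loglog_n --threshold 0.001 --out selection.csv
qbill run      --config run.yaml
```

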