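# vepkit

Toolkit for measuring household **health-poverty vulnerability** from a
cross-sectional household survey and analysing its drivers:

- **`vepkit.vep`** — vulnerability-as-expected-poverty via the three-stage
  FGLS income model: OLS of log income, OLS of squared residuals on the
  variance design, weighted re-estimation of both, then the vulnerability
  index `v = Φ((ln L − X·β̂)/√(X·θ̂))` against a relative poverty line,
  with threshold classification and binned distribution summaries. Also the
  prevalence sample-size formula `N = u² π(1−π)/δ²` and descriptive
  tabulation helpers.
- **`vepkit.quantiles`** — heterogeneity analysis of the index: VIF screen,
  OLS baseline, exact quantile regression (check loss minimised by the dual
  linear program, solved with HiGHS), paired-bootstrap standard errors,
  joint and pairwise Wald tests of coefficient equality across quantiles
  with V / inverted-V shape labels, farming/non-farming subgroup equality
  tests, interaction models, and a full quantile sweep.
- **`vepkit.pathmodel`** — recursive construct-level path analysis on
  unit-weighted composites of sign-aligned z-scored indicators: per-equation
  least squares, bootstrap SEs, direct/indirect/total standardized effect
  decomposition via `(I − B)⁻¹ − I`, model-implied covariance, and
  covariance-based fit indices (χ², GFI, AGFI, PGFI, IFI, CFI, SRMR, RMSEA).
- **`vepkit.synthetic`** — seeded survey generator with known ground truth:
  log-normal income with conditional mean `X·β` and variance `X·θ`,
  capital-driven utilization binaries through a logistic link, a recursive
  human → physical → social capital chain, and a standalone linear-DAG
  simulator for path-model recovery tests. Each variable block uses its own
  seed substream, so adding a variable never perturbs the others.
- **`vepkit.io`** — CSV survey I/O with schema validation and listwise
  deletion logging, pipeline configuration, and end-to-end orchestration.

## CLI

```bash
# generate a synthetic survey with known truth
vepkit simulate --n 4371 --seed 1 --out survey.csv

# estimate vulnerability (writes per-household index + flag and a JSON summary)
vepkit vep --in survey.csv --config model.yaml --line 9202 --threshold 0.5 \
    --out result.csv

# quantile analysis tables (VIF, OLS, cross-quantile Wald tests, subgroups)
vepkit quantiles --in result.csv --model qmodel.yaml --taus 0.25,0.5,0.75 \
    --boot 500 --seed 11 --out tables/

# composite path model with effect decomposition and fit indices
vepkit paths --in result.csv --boot 500 --seed 13 --out paths.json

# everything, driven by one YAML config
vepkit run --config pipeline.yaml
```

`model.yaml` lists `mean_covariates` / `variance_covariates` for the income
equations; `qmodel.yaml` lists the dependent column and covariates (see
`tests/test_io_cli.py` for working examples of every config file).

## Notes

- The vulnerability index standardizes by `√(X·θ̂)`; non-positive fitted
  variances are floored at `1e-6` and flagged per row.
- Percent summaries round half-up to 2 decimals; effect tables report 3
  decimals alongside full precision.
- Quantile fits are exact LP solutions, so the check-loss objective matches
  a brute-force interpolation oracle on small instances to machine
  precision.
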