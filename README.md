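# twingrowth

Developmental trajectories of emotional and conduct problems predicting
early-adult alcohol use, as a tested, reusable pipeline:

* **Piecewise latent growth SEM** — two segments per trait (parent reports
  at ages 4–9, self reports at ages 9–16, knotted at the age-9 rater
  switch), fitted by pattern-wise full-information maximum likelihood (FIML)
  with cluster-robust (sandwich) standard errors.
* **Phenotypic outcome models** — AUDIT scores (age-residualized; problem
  score log-transformed) regressed simultaneously on all eight growth
  factors plus covariates, with an ordered multi-group sex-difference
  constraint sequence (chi-square difference tests, exact modification
  search, Wald tests).
* **Twin ACE model comparison** — regression-method factor scores, then the
  correlated-factor Cholesky model vs. direct-path transmission vs. hybrid
  structures over MZ/DZ pairs, selected by AIC, with sex-indexed direct
  paths in a five-group model.
* **Synthetic cohorts** — a generator that reproduces the exact statistical
  structure the analyses assume (MZ genetic correlation 1, DZ 0.5, MAR
  missingness driven by sex/SES) plus a ground-truth manifest with
  closed-form implied moments, so everything is testable without any
  restricted data.

## CLI

```bash
twingrowth schema                          # data dictionary of the CSV layout
twingrowth simulate --seed 1 --out run/    # twins.csv + truth.json
twingrowth fit-growth run/twins.csv
twingrowth predict-alcohol run/twins.csv --outcome audit_total
twingrowth sex-test run/twins.csv --outcome audit_total
twingrowth twin-compare pairs.csv --predictors fs_em_ip,fs_cd_sa
twingrowth run-all --seed 1 --out run/     # full simulate-to-twin pipeline
```

`run-all` writes per-stage artifacts (fit JSON, report CSVs) plus a
`manifest.json` of content hashes; identical config + seed reproduces the
run bit-for-bit.

## Package layout

| module | contents |
| --- | --- |
| `twingrowth.io` | measurement schema, wide twin tables, prorated scale scores, age residualization, log transform, hazardous-use flag |
| `twingrowth.simulate` | `SimulationConfig`, ACE component draws, dataset generator, analytic implied moments, ground-truth manifest |
| `twingrowth.sem` | model specs (`SemModelSpec`), pattern-wise FIML, Fisher-scoring + L-BFGS-B fitting, observed/expected information, cluster-robust vcov, LR/Wald tests, modification search |
| `twingrowth.growth` | piecewise loading scheme, growth and outcome model builders, covariance pruning, standardized betas, sex-difference pipeline |
| `twingrowth.twin` | `AceStructure`/`AceParams`, implied pair covariance, factor scores, ACE fitting, AIC structure search, sex-indexed direct paths |
| `twingrowth.pipeline` / `twingrowth.cli` | end-to-end orchestration with stage artifacts and hash manifest |
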