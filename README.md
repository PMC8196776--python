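# xcprofile

Physiological profiling and race-time modelling for youth cross-country
cyclists. The package turns raw test batteries (lactate step tests,
field power-profile efforts, a graded maximal test, anthropometry and
strength trials) into per-athlete markers, and predicts official race
time from body-mass-normalised markers via a Spearman correlation screen
followed by VIF-gated backward-elimination / forward-selection multiple
regression. A synthetic cohort generator with known latent truth makes
every stage of the pipeline testable end to end.

## Modules

| Module | Purpose |
| --- | --- |
| `xcprofile.cohort` | Synthetic athlete cohorts: latent-ability-correlated markers, exponential lactate curves through the exact 2/4 mmol/L crossings, race time from the published linear equation plus noise; CSV writer/reader. |
| `xcprofile.lactate` | Lactate curve fitting (degree 3/4 OLS polynomials) and the five threshold markers: LT1 stage rule, LT2 maximal acceleration, fixed 2/4 mmol/L powers, Dmax. |
| `xcprofile.power` | Mean maximal power over rolling windows, critical power / W′ from the linear P–1/t fit, end-test maximal aerobic power, test-validity rule, W/kg normalisation. |
| `xcprofile.anthro` | Σ6 skinfolds, five-way tissue fractionation from a checksummed phantom-constants fixture, squat-jump height from flight time, isometric strength summaries. |
| `xcprofile.stats` | Shapiro–Wilk screen, Spearman with exact small-sample permutation p-values and bootstrap CIs, VIF filter, backward elimination, forward selection, race-time prediction. |
| `xcprofile.pipeline` / `xcprofile.cli` | simulate → markers → analyze → report orchestration with fixed CSV/JSON file contracts. |
| `xcprofile.reference` | Published cohort summary moments, comparison-table values and the reported race-time equation used as generator defaults and worked-example anchors. |

## Command-line usage

```bash
xcprofile simulate --out cohort/ --n 10 --seed 42
xcprofile markers  --cohort cohort/
xcprofile analyze  --cohort cohort/ --seed 42
xcprofile report   --cohort cohort/
```

`simulate` writes the cohort CSV contract (`athletes.csv`,
`lactate_tests.csv`, `power_efforts.csv`, `graded_test.csv`,
`anthropometry.csv`, `strength.csv`, `race.csv`, `truth.csv`) plus a
manifest; `markers` derives `markers.csv` (absolute W and W/kg columns,
per-athlete flags) with side tables `thresholds.csv`, `body_comp.csv`
and `strength_summary.csv`; `analyze` writes `report.json` /
`report.csv` with the correlation screen, VIF table, stepwise traces,
final model and per-athlete predictions. A YAML file passed via
`--config` overrides any `PipelineConfig` field (e.g. `n_boot`,
`alpha_screen`, `vif_threshold`).

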