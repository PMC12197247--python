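# cavsat

Multi-method propensity matching, ensemble weighting and counterfactual
treatment-effect estimation for deep-vein-thrombosis (DVT) therapy
comparison: combined anticoagulation + venoprotective therapy (**CAV**,
rivaroxaban + aescin) versus standard anticoagulation (**SAT**, rivaroxaban
alone).

## The problem

Retrospective inpatient cohorts of DVT patients are heavily unbalanced —
clinicians chose who received the add-on venoprotective agent, and the two
arms differ systematically in coagulation labs (APTT, TT), blood counts
(WBC, PLT) and gender. Comparing six clinical/economic outcomes —
improvement rate (IPR), daily improvement rate (DIR = IPR/LOS),
cost-effectiveness ratio (CER), daily improvement cost (DIC), cost–LOS
efficiency (CLE = CER/LOS) and length of stay (LOS) — therefore requires
causal adjustment, and no single matching algorithm is uniformly best.

`cavsat` implements the full chain:

1. **Matching** — four 1:1 algorithms on 17 baseline covariates: nearest
   neighbour with a logit-propensity caliper, Mahalanobis distance, optimal
   (assignment-problem) matching with exact constraints, and genetic search
   over covariate weights; standardized-mean-difference (SMD) balance
   diagnostics for each.
2. **Ensemble weighting** — each matched dataset is scored on mean SMD
   (25%), max SMD (15%), five-fold CV R² of outcome models (25%),
   Rosenbaum-bounds robustness at Γ = 1.5 (30%) and sample retention (5%);
   normalized shares combine into one weight per method.
3. **Counterfactual effects** — a T-learner (per-arm random forests)
   predicts both potential outcomes for every matched record; ITE = ŷ₁ − ŷ₀,
   with ATE/ATT/ATC as subpopulation means and a double-residual
   (residual-on-residual) estimate as an orthogonalized cross-check; final
   estimates are ensemble-weighted averages across the four methods.
4. **Sensitivity & structure** — Rosenbaum bounds swept over Γ ∈ [1, 2] per
   outcome and method, and a thresholded (|r| > 0.3) Spearman correlation
   network linking baseline covariates to outcomes.

Because the underlying hospital data are private, the package ships a
synthetic-cohort generator that reproduces the study conditions — reported
covariate marginals, a 48:348 confounded assignment, and outcome models
with *known injectable effects* — so the whole pipeline is testable and its
estimates can be validated against Monte-Carlo ground truth.

## Worked example

```bash
cavsat run-all --seed 1 --out results/demo \
  --config <(echo '{"simulation": {"n_total": 800}, "forest_size": 100,
                    "cv_forest_size": 50, "dr_forest_size": 50,
                    "genetic_generations": 5, "genetic_pop": 10}')
```

or equivalently in Python:

```python
from cavsat import PipelineConfig, run_pipeline
from cavsat.simulate import CohortParams, ground_truth

cfg = PipelineConfig(simulation={"n_total": 800}, forest_size=100,
                     cv_forest_size=50, dr_forest_size=50,
                     genetic_generations=5, genetic_pop=10, seed=1)
report = run_pipeline(cfg)
print(report.weights)
print(report.effects_table.query("outcome == 'ipr'"))
print(ground_truth(CohortParams(n_total=800, seed=1)).true_effect["ipr"])
```

This simulates an 800-patient cohort with a +6.4 percentage-point true IPR
effect under confounded assignment, excludes 13 zero-improvement records,
matches 95–99 pairs per method, and prints:

```
weights: {"genetic": 0.186, "mahalanobis": 0.174, "nearest_caliper": 0.292, "optimal_exact": 0.348}
ipr per-method ATE: genetic 4.77, mahalanobis 5.16, nearest_caliper 5.40, optimal_exact 4.47
ipr weighted ATE:   4.91        (Monte-Carlo truth: 6.40)
```

The weights say the optimal-exact and caliper matches earned the most trust
on this draw (best balance and robustness); the weighted ATE of 4.9 pp sits
about one sampling standard deviation below the 6.4 pp truth — single-seed
estimates at ~99 treated patients carry ±1.3 pp of noise, which is why the
validation suite averages 20 seeded replicates before comparing to truth.
The emitted artifacts include the 30-row effects table (6 outcomes × 4
methods + weighted average), per-method balance and ITE tables, the Γ-sweep
(`sensitivity.csv`) and the correlation network, in which APTT–DIC and
APTT–IPR edges appear exactly because the generator's cost and improvement
models load on APTT.

## Layout

```
src/cavsat/
  simulate.py     synthetic cohorts, confounded assignment, MC ground truth
  cohort.py       schema, validation, CSV round-trip
  outcomes.py     the six metrics + exclusion rule
  matching.py     propensity model, SMD, four matchers (sklearn-style)
  weighting.py    five-dimension quality scores -> ensemble weights
  effects.py      T-learner, ATE/ATT/ATC, double residual, importance
  sensitivity.py  Rosenbaum bounds, attenuated effects, Γ sweeps
  network.py      thresholded correlation network + GraphML export
  recovery.py     parameter-recovery harness
  pipeline.py     orchestration, config, report emission
  cli.py          `cavsat` command-line interface
```

See `docs/methods.md` for the models, defaults and numerical choices.
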