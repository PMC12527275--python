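# dctmle

Double cross-fit targeted maximum likelihood estimation (DC-TMLE) of the
average treatment effect (ATE) of a binary exposure on a continuous or
binary outcome.

The estimator divides the data into S (default 3) random splits, fits the
exposure (propensity) model and the outcome model on two different splits,
and targets the ATE on the third, rotating roles so every split serves each
purpose exactly once. The whole procedure is repeated `num_cf` times over
fresh random partitions; the overall ATE is the median (or mean) of the
per-repetition global estimates, with a variance that adds the
between-repetition spread to the influence-function variance. Nuisance
models are estimated with a from-scratch cross-validated stacking ensemble
("super-learner") whose simplex weights minimize V-fold cross-validated
risk over a configurable learner library.

## Layout

| Module | Contents |
| --- | --- |
| `dctmle.data` | `AnalyticDataset`, min-max outcome scaling, CSV reader, JSON result writer |
| `dctmle.superlearner` | learner registry, `fit_superlearner` / `predict_superlearner` |
| `dctmle.tmle` | propensity bounding, clever covariates, offset-logistic fluctuation, update, local ATE, EIF variance |
| `dctmle.crossfit` | split assignment and role rotation, repetitions, aggregation, `run_dc_tmle`, no-split reference `run_tmle_nocf` |
| `dctmle.simulate` | synthetic confounded DGP with known true ATE (plus a misspecified-covariate mode), Monte-Carlo harness |
| `dctmle.cli` | `dctmle fit` and `dctmle simulate` |

Registered learners: `mean`, `glm`, `l1_glm`, `random_forest`,
`gradient_boosting`, `spline_gam`, `neural_net` (all scikit-learn backed).

## CLI

Fit on a CSV (header row required; categorical covariates are expanded to
reference-dropped indicators; missing cells are rejected):

```sh
dctmle fit --data data.csv --outcome y --exposure a \
    --covariates age,sex,apache \
    --n-split 3 --num-cf 100 --cv-folds 10 \
    --learners-exposure l1_glm,random_forest,gradient_boosting \
    --seed 42 --workers 4 --out result.json
```

Prints `ATE <value> (95% CI <lo> to <hi>)` and writes a JSON document with
the estimate, variance, per-repetition trace and a full settings echo.

Run the simulation comparison (no-split TMLE vs DC-TMLE on synthetic data):

```sh
dctmle simulate --n-datasets 100 --n 3000 --true-ate 1.0 \
    --estimators tmle_nocf,dc_tmle --misspecify \
    --num-cf 10 --learners glm,random_forest --seed 1 --out-dir sim_out/
```

writes `simulation_results.csv` (one row per dataset x estimator) and
`simulation_summary.csv` (bias, empirical SE, mean model SE, 95% CI
coverage per estimator).

## Python API

```python
from dctmle import DGPConfig, LearnerSpec, RunSettings, generate_dataset, run_dc_tmle

dataset, truth = generate_dataset(DGPConfig(n=3000, true_ate=1.0, seed=7))
settings = RunSettings(
    num_cf=10,
    learners_exposure=(LearnerSpec("l1_glm"), LearnerSpec("random_forest")),
    seed=7,
)
result = run_dc_tmle(dataset, settings)
print(result.ate, (result.ci_lower, result.ci_upper))
```
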