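"""Synthetic confounded datasets with a known marginal effect, plus the
Monte-Carlo harness comparing the no-split and double cross-fit estimators.

The generator draws standard-normal covariates, assigns treatment through a
logistic model with quadratic and interaction terms, and builds the outcome
additively in treatment (no treatment-covariate interaction), so the
marginal effect equals ``true_ate`` exactly by construction. In the
misspecification mode the released covariate columns are nonlinear
transforms of the ones that actually drive treatment and outcome, so any
learner that uses the observed columns linearly is misspecified.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .crossfit import RunSettings, run_dc_tmle, run_tmle_nocf, _child_seed
from .data import AnalyticDataset
from .errors import DCTMLEError

__all__ = ["DGPConfig", "generate_dataset", "run_simulation_study", "ESTIMATORS"]

ESTIMATORS = ("tmle_nocf", "dc_tmle")


@dataclass(frozen=True)
class DGPConfig:
    n: int
    p: int = 4
    true_ate: float = 1.0
    confounding_strength: float = 1.0
    outcome_noise_sd: float = 1.0
    outcome_kind: str = "continuous"  # "continuous" | "binary"
    misspecify_observed: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.p < 4:
            raise ValueError("the generator uses 4 structural covariates; p >= 4")
        if self.outcome_kind not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome kind {self.outcome_kind!r}")
        if self.outcome_kind == "continuous" and not self.outcome_noise_sd > 0:
            raise ValueError("outcome_noise_sd must be positive for continuous outcomes")
        if self.outcome_kind == "binary" and abs(self.true_ate) > 0.25:
            raise ValueError("binary outcomes support |true_ate| <= 0.25")


def _propensity_index(w: np.ndarray, strength: float) -> np.ndarray:
    # Quadratic term and one interaction, centered so prevalence stays near 1/2.
    return strength * (
        0.5 * w[:, 0]
        - 0.5 * w[:, 1]
        + 0.1 * (w[:, 0] ** 2 - 1.0)
        + 0.1 * w[:, 2] * w[:, 3]
    )


def _outcome_index(w: np.ndarray) -> np.ndarray:
    # Nonlinear terms deliberately involve different covariate combinations
    # than the treatment model's, so nuisance-estimation errors in the two
    # models are close to orthogonal and their product (the second-order
    # remainder) stays small at moderate sample sizes.
    return (
        1.0 * w[:, 0]
        + 0.8 * w[:, 1]
        + 0.15 * (w[:, 1] ** 2 - 1.0)
        + 0.15 * w[:, 0] * w[:, 3]
        - 0.5 * w[:, 2]
    )


def _binary_base_risk(w: np.ndarray) -> np.ndarray:
    # Bounded inside (0.1, 0.6) before the treatment shift.
    return 0.35 + 0.15 * np.tanh(w[:, 0]) + 0.1 * np.tanh(w[:, 1] * w[:, 2])


def _misspecified_view(w: np.ndarray) -> np.ndarray:
    """Kang-and-Schafer-style observable transforms of the structural
    covariates; extra columns beyond the fourth pass through unchanged."""
    x = w.copy()
    x[:, 0] = np.exp(w[:, 0] / 2.0)
    x[:, 1] = w[:, 1] / (1.0 + np.exp(w[:, 0])) + 10.0
    x[:, 2] = (w[:, 0] * w[:, 2] / 25.0 + 0.6) ** 3
    x[:, 3] = (w[:, 1] + w[:, 3] + 20.0) ** 2
    return x


def generate_dataset(config: DGPConfig) -> tuple[AnalyticDataset, dict]:
    """Draw one dataset; return it with a truth record.

    The truth record carries the target effect, the true propensities, and
    the true conditional means under each arm (which differ by exactly
    ``true_ate`` for every subject).
    """
    rng = np.random.default_rng(config.seed)
    w = rng.standard_normal((config.n, config.p))
    propensity = expit(_propensity_index(w, config.confounding_strength))
    a = rng.binomial(1, propensity)

    if config.outcome_kind == "continuous":
        g = _outcome_index(w)
        mu0 = g
        mu1 = g + config.true_ate
        y = config.true_ate * a + g + rng.normal(0.0, config.outcome_noise_sd, config.n)
    else:
        base = _binary_base_risk(w)
        # Shift applied on the probability scale; bounds on base risk and
        # |true_ate| keep everything inside (0, 1) with no clipping.
        mu0 = base if config.true_ate >= 0 else base - config.true_ate
        mu1 = mu0 + config.true_ate
        p_obs = np.where(a == 1, mu1, mu0)
        y = rng.binomial(1, p_obs).astype(float)

    observed = _misspecified_view(w) if config.misspecify_observed else w
    covariates = pd.DataFrame(
        observed, columns=[f"c{j + 1}" for j in range(config.p)]
    )
    dataset = AnalyticDataset(
        outcome=y,
        exposure=a,
        covariates=covariates,
        outcome_kind=config.outcome_kind,
    )
    truth = {
        "theta0": config.true_ate,
        "propensity": propensity,
        "mu1": mu1,
        "mu0": mu0,
        "structural_covariates": w,
    }
    return dataset, truth


def run_simulation_study(
    scenario: DGPConfig,
    n_datasets: int,
    estimators: tuple[str, ...],
    settings: RunSettings,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monte-Carlo comparison of estimators on replicated synthetic data.

    Returns ``(results, summary)``: one row per (dataset, estimator) with
    estimate, model SE, CI and coverage indicator; and one summary row per
    estimator with bias, empirical SE, mean model SE, and coverage.
    Estimator failures are recorded as NA rows and excluded from summaries.
    """
    if n_datasets < 2:
        raise ValueError("n_datasets must be at least 2")
    for name in estimators:
        if name not in ESTIMATORS:
            raise ValueError(f"unknown estimator {name!r}; valid: {list(ESTIMATORS)}")

    rows = []
    master = scenario.seed if scenario.seed is not None else 0
    for d in range(n_datasets):
        data_seed = _child_seed(master, d)
        dataset, truth = generate_dataset(replace(scenario, seed=data_seed))
        for est_name in estimators:
            run_settings = replace(
                settings, seed=_child_seed(data_seed, ESTIMATORS.index(est_name) + 1)
            )
            try:
                if est_name == "dc_tmle":
                    res = run_dc_tmle(dataset, run_settings)
                else:
                    res = run_tmle_nocf(dataset, run_settings)
            except DCTMLEError:
                rows.append(
                    {
                        "estimator": est_name,
                        "dataset_id": d,
                        "estimate": np.nan,
                        "se": np.nan,
                        "ci_lower": np.nan,
                        "ci_upper": np.nan,
                        "covered": np.nan,
                    }
                )
                continue
            rows.append(
                {
                    "estimator": est_name,
                    "dataset_id": d,
                    "estimate": res.ate,
                    "se": res.std_error,
                    "ci_lower": res.ci_lower,
                    "ci_upper": res.ci_upper,
                    "covered": float(res.ci_lower <= scenario.true_ate <= res.ci_upper),
                }
            )
    results = pd.DataFrame(rows)

    summaries = []
    for est_name in estimators:
        sub = results[results["estimator"] == est_name]
        ok = sub.dropna(subset=["estimate"])
        summaries.append(
            {
                "estimator": est_name,
                "theta0": scenario.true_ate,
                "n_datasets": len(sub),
                "n_failed": int(len(sub) - len(ok)),
                "bias": float(ok["estimate"].mean() - scenario.true_ate),
                "empirical_se": float(ok["estimate"].std(ddof=1)),
                "mean_model_se": float(ok["se"].mean()),
                "coverage": float(ok["covered"].mean()),
            }
        )
    return results, pd.DataFrame(summaries)
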