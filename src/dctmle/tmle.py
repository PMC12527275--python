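"""Targeting engine: propensity bounding, clever covariates, fluctuation,
updated counterfactual predictions, local effect, and influence-function
variance for one evaluation split.

All outcome-model quantities live on the ``[0, 1]`` scale until the final
back-transform; the influence curve is evaluated on the original outcome
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logit

from .data import AnalyticDataset, OutcomeScale, scale_outcome, unscale_ate, unscale_predictions
from .errors import EstimationError, FluctuationError, SampleSizeError
from .superlearner import SuperLearnerModel, predict_superlearner

__all__ = [
    "NuisancePredictions",
    "FluctuationFit",
    "SplitEstimate",
    "propensity_bound",
    "bound_propensity",
    "clever_covariates",
    "fit_fluctuation",
    "update_predictions",
    "local_ate",
    "eif_variance",
    "run_split_tmle",
    "EXPOSURE_COLUMN",
]

# Name of the synthetic exposure column in the outcome-model design matrix.
EXPOSURE_COLUMN = "__exposure__"

# Initial outcome predictions are clipped away from {0, 1} before any logit.
DEFAULT_Q_BOUNDS = (1e-5, 1.0 - 1e-5)


@dataclass(frozen=True)
class NuisancePredictions:
    """Nuisance-model predictions aligned with one evaluation split."""

    pi_hat: np.ndarray  # bounded P(A=1 | L)
    mu1: np.ndarray  # scaled outcome prediction with A forced to 1
    mu0: np.ndarray  # scaled outcome prediction with A forced to 0
    mu_a: np.ndarray  # prediction at the observed exposure


@dataclass(frozen=True)
class FluctuationFit:
    eps1: float
    eps0: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.eps1) and np.isfinite(self.eps0)):
            raise FluctuationError(
                f"non-finite fluctuation coefficients ({self.eps1}, {self.eps0})"
            )


@dataclass(frozen=True)
class SplitEstimate:
    ate_local: float  # original outcome scale
    var_local: float
    n_eval: int

    def __post_init__(self) -> None:
        if self.var_local < 0:
            raise ValueError("var_local must be non-negative")


def propensity_bound(n_total: int) -> float:
    """Lower truncation bound ``5 / (sqrt(n) * log(n))`` for the propensity.

    ``n_total`` is the full analytic sample size; the upper bound is its
    complement.
    """
    if n_total < 2:
        raise SampleSizeError("need at least 2 observations")
    bound = 5.0 / (np.sqrt(n_total) * np.log(n_total))
    if bound >= 0.5:
        raise SampleSizeError(
            f"sample of {n_total} is too small: propensity bound {bound:.3f} >= 0.5"
        )
    return float(bound)


def bound_propensity(pi_hat: np.ndarray, bound: float) -> np.ndarray:
    return np.clip(np.asarray(pi_hat, dtype=float), bound, 1.0 - bound)


def clever_covariates(a: np.ndarray, pi_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(h1, h0) = (A / pi, (1 - A) / (1 - pi))``."""
    a = np.asarray(a, dtype=float)
    pi_hat = np.asarray(pi_hat, dtype=float)
    if (pi_hat <= 0).any() or (pi_hat >= 1).any():
        raise ValueError("pi_hat must be strictly inside (0, 1); bound it first")
    return a / pi_hat, (1.0 - a) / (1.0 - pi_hat)


def fit_fluctuation(
    y_star: np.ndarray,
    h1: np.ndarray,
    h0: np.ndarray,
    mu_a: np.ndarray,
    weighted: bool = False,
    a: np.ndarray | None = None,
) -> FluctuationFit:
    """Intercept-free logistic fluctuation of the initial outcome predictions.

    Default parameterization regresses ``y_star`` on the two clever
    covariates with offset ``logit(mu_a)`` under a (quasi-)binomial
    likelihood. With ``weighted=True`` the clever covariates act as case
    weights on arm indicators instead (asymptotically equivalent form).
    """
    y_star = np.asarray(y_star, dtype=float)
    mu_a = np.asarray(mu_a, dtype=float)
    if (mu_a <= 0).any() or (mu_a >= 1).any():
        raise ValueError("mu_a must be strictly inside (0, 1); truncate it first")
    offset = logit(mu_a)
    if weighted:
        if a is None:
            raise ValueError("weighted fluctuation requires the exposure vector")
        a = np.asarray(a, dtype=float)
        design = np.column_stack([a, 1.0 - a])
        model = sm.GLM(
            y_star,
            design,
            family=sm.families.Binomial(),
            offset=offset,
            var_weights=np.asarray(h1 + h0, dtype=float),
        )
    else:
        design = np.column_stack([h1, h0])
        model = sm.GLM(y_star, design, family=sm.families.Binomial(), offset=offset)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=100, tol=1e-10)
        except Exception as exc:  # noqa: BLE001
            raise FluctuationError(f"fluctuation regression failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FluctuationError(f"fluctuation produced non-finite coefficients: {res.params}")
    return FluctuationFit(eps1=float(res.params[0]), eps0=float(res.params[1]))


def update_predictions(
    mu1: np.ndarray,
    mu0: np.ndarray,
    pi_hat: np.ndarray,
    fit: FluctuationFit,
    weighted: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Tilt both counterfactual predictions for every row.

    The counterfactual clever covariates ``1 / pi`` and ``1 / (1 - pi)``
    scale the fluctuation, so rows in either arm update both potential
    outcomes. Under the weighted parameterization the coefficients already
    absorb the weights and the update is an unscaled shift.
    """
    mu1 = np.asarray(mu1, dtype=float)
    mu0 = np.asarray(mu0, dtype=float)
    if (mu1 <= 0).any() or (mu1 >= 1).any() or (mu0 <= 0).any() or (mu0 >= 1).any():
        raise ValueError("initial predictions must be strictly inside (0, 1)")
    if weighted:
        return expit(logit(mu1) + fit.eps1), expit(logit(mu0) + fit.eps0)
    pi_hat = np.asarray(pi_hat, dtype=float)
    return (
        expit(logit(mu1) + fit.eps1 / pi_hat),
        expit(logit(mu0) + fit.eps0 / (1.0 - pi_hat)),
    )


def local_ate(
    mu1_updated: np.ndarray, mu0_updated: np.ndarray, scale: OutcomeScale
) -> float:
    mu1_updated = np.asarray(mu1_updated, dtype=float)
    mu0_updated = np.asarray(mu0_updated, dtype=float)
    if mu1_updated.size == 0:
        raise EstimationError("empty evaluation split")
    return unscale_ate(float(np.mean(mu1_updated - mu0_updated)), scale)


def eif_variance(
    y: np.ndarray,
    a: np.ndarray,
    pi_hat: np.ndarray,
    mu1_u: np.ndarray,
    mu0_u: np.ndarray,
    ate_local: float,
    n_total: int | None = None,
) -> float:
    """Sample variance of the efficient influence curve divided by the
    analytic sample size.

    All arguments are on the ORIGINAL outcome scale (predictions already
    back-transformed). ``n_total`` defaults to the number of evaluation
    rows; the cross-fit driver passes the full sample size, so that the
    average of the S split variances estimates the sampling variance of the
    global (averaged) estimate rather than of a single split's estimate.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    n_eval = y.shape[0]
    if n_eval < 2:
        raise EstimationError("variance undefined for fewer than 2 evaluation rows")
    mu_a_u = np.where(a == 1, mu1_u, mu0_u)
    eic = (a / pi_hat - (1.0 - a) / (1.0 - pi_hat)) * (y - mu_a_u) + mu1_u - mu0_u - ate_local
    return float(np.var(eic, ddof=1) / (n_total if n_total is not None else n_eval))


def _split_tmle_details(
    dataset: AnalyticDataset,
    eval_rows: np.ndarray,
    exposure_model: SuperLearnerModel,
    outcome_model: SuperLearnerModel,
    scale: OutcomeScale,
    q_bounds: tuple[float, float] = DEFAULT_Q_BOUNDS,
    weighted_fluctuation: bool = False,
) -> dict:
    """Run the full targeting chain on one evaluation split; return all
    intermediates (used by :func:`run_split_tmle` and by diagnostics)."""
    idx = np.asarray(eval_rows, dtype=int)
    if idx.size == 0:
        raise EstimationError("empty evaluation split")
    a = dataset.exposure[idx]
    y = dataset.outcome[idx]
    if a.min() == a.max():
        raise EstimationError(
            "evaluation split contains a single exposure arm; cannot target"
        )
    y_star = scale_outcome(y, scale)

    exp_features = dataset.covariates[exposure_model.feature_names].iloc[idx]
    pi_raw = predict_superlearner(exposure_model, exp_features)
    bound = propensity_bound(dataset.n)
    pi_hat = bound_propensity(pi_raw, bound)

    out_cols = [c for c in outcome_model.feature_names if c != EXPOSURE_COLUMN]
    base = dataset.covariates[out_cols].iloc[idx].copy()
    lo, hi = q_bounds
    counterfactual = {}
    for a_value in (1.0, 0.0):
        design = base.copy()
        design[EXPOSURE_COLUMN] = a_value
        pred = predict_superlearner(outcome_model, design[outcome_model.feature_names])
        counterfactual[a_value] = np.clip(pred, lo, hi)
    mu1, mu0 = counterfactual[1.0], counterfactual[0.0]
    mu_a = np.where(a == 1, mu1, mu0)
    nuisance = NuisancePredictions(pi_hat=pi_hat, mu1=mu1, mu0=mu0, mu_a=mu_a)

    h1, h0 = clever_covariates(a, pi_hat)
    fit = fit_fluctuation(y_star, h1, h0, mu_a, weighted=weighted_fluctuation, a=a)
    mu1_u, mu0_u = update_predictions(mu1, mu0, pi_hat, fit, weighted=weighted_fluctuation)

    ate_loc = local_ate(mu1_u, mu0_u, scale)
    mu1_orig = unscale_predictions(mu1_u, scale)
    mu0_orig = unscale_predictions(mu0_u, scale)
    var_loc = eif_variance(y, a, pi_hat, mu1_orig, mu0_orig, ate_loc, n_total=dataset.n)
    return {
        "nuisance": nuisance,
        "fluctuation": fit,
        "h1": h1,
        "h0": h0,
        "y": y,
        "a": a,
        "y_star": y_star,
        "mu1_updated": mu1_u,
        "mu0_updated": mu0_u,
        "mu1_original": mu1_orig,
        "mu0_original": mu0_orig,
        "ate_local": ate_loc,
        "var_local": var_loc,
        "n_eval": int(idx.size),
    }


def run_split_tmle(
    dataset: AnalyticDataset,
    eval_rows: np.ndarray,
    exposure_model: SuperLearnerModel,
    outcome_model: SuperLearnerModel,
    scale: OutcomeScale,
    q_bounds: tuple[float, float] = DEFAULT_Q_BOUNDS,
    weighted_fluctuation: bool = False,
) -> SplitEstimate:
    """Targeted estimate on one evaluation split given nuisance models that
    were fitted on (two different) non-overlapping splits."""
    details = _split_tmle_details(
        dataset,
        eval_rows,
        exposure_model,
        outcome_model,
        scale,
        q_bounds=q_bounds,
        weighted_fluctuation=weighted_fluctuation,
    )
    return SplitEstimate(
        ate_local=details["ate_local"],
        var_local=details["var_local"],
        n_eval=details["n_eval"],
    )
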