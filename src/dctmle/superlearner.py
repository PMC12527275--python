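"""Cross-validated stacking ("Super-Learner") for the nuisance models.

Both nuisance functions — the exposure model ``E[A | L]`` and the outcome
model ``E[Y* | A, L]`` — are estimated by the same machinery: a library of
base learners is evaluated by V-fold cross-validation, ensemble weights on
the probability simplex are chosen to minimize the cross-validated risk
(squared error for the gaussian family, negative Bernoulli log-likelihood
for the binomial family), and the base learners are then refit on all
training rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import (
    LassoCV,
    LinearRegression,
    LogisticRegression,
    LogisticRegressionCV,
)
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler

from .errors import EstimationError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "LearnerSpec",
    "SuperLearnerModel",
    "REGISTERED_LEARNERS",
    "fit_superlearner",
    "predict_superlearner",
]

REGISTERED_LEARNERS = (
    "mean",
    "glm",
    "l1_glm",
    "random_forest",
    "gradient_boosting",
    "spline_gam",
    "neural_net",
)

_EPS = 1e-12


@dataclass(frozen=True)
class LearnerSpec:
    """A named base learner plus hyperparameter overrides."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in REGISTERED_LEARNERS:
            raise ValueError(
                f"unknown learner {self.name!r}; registered learners are "
                f"{sorted(REGISTERED_LEARNERS)}"
            )

    @classmethod
    def parse(cls, names: str | Sequence[str]) -> list["LearnerSpec"]:
        """Build specs from a comma-separated string or a list of names."""
        if isinstance(names, str):
            names = [s.strip() for s in names.split(",") if s.strip()]
        return [cls(name) for name in names]


def _build_learner(spec: LearnerSpec, family: str, seed: int):
    """Instantiate an unfitted scikit-learn estimator for one spec."""
    hp = dict(spec.hyperparameters)
    binom = family == "binomial"
    if spec.name == "mean":
        return DummyClassifier(strategy="prior") if binom else DummyRegressor()
    if spec.name == "glm":
        if binom:
            return LogisticRegression(
                penalty=None, max_iter=int(hp.pop("max_iter", 2000)), tol=1e-10
            )
        return LinearRegression()
    if spec.name == "l1_glm":
        cv = int(hp.pop("cv", 5))
        if binom:
            return LogisticRegressionCV(
                penalty="l1",
                solver="liblinear",
                Cs=int(hp.pop("Cs", 10)),
                cv=cv,
                max_iter=int(hp.pop("max_iter", 1000)),
                random_state=seed,
            )
        return LassoCV(cv=cv, alphas=int(hp.pop("n_alphas", 50)), random_state=seed)
    if spec.name == "random_forest":
        kw = dict(
            n_estimators=int(hp.pop("n_estimators", 500)),
            min_samples_leaf=int(hp.pop("min_samples_leaf", 20)),
            random_state=seed,
            **hp,
        )
        return RandomForestClassifier(**kw) if binom else RandomForestRegressor(**kw)
    if spec.name == "gradient_boosting":
        # xgboost is not a dependency; scikit-learn's gradient boosting with
        # early stopping on a held-out tenth plays the same role.
        kw = dict(
            n_estimators=int(hp.pop("n_estimators", 500)),
            max_depth=int(hp.pop("max_depth", 3)),
            learning_rate=float(hp.pop("learning_rate", 0.1)),
            n_iter_no_change=int(hp.pop("n_iter_no_change", 20)),
            validation_fraction=0.1,
            random_state=seed,
            **hp,
        )
        return GradientBoostingClassifier(**kw) if binom else GradientBoostingRegressor(**kw)
    if spec.name == "spline_gam":
        df = int(hp.pop("df", 4))
        spline = SplineTransformer(n_knots=max(df - 1, 2), degree=3)
        tail = (
            LogisticRegression(penalty=None, max_iter=2000)
            if binom
            else LinearRegression()
        )
        return Pipeline([("spline", spline), ("glm", tail)])
    if spec.name == "neural_net":
        kw = dict(
            hidden_layer_sizes=tuple(hp.pop("hidden_layer_sizes", (2,))),
            max_iter=int(hp.pop("max_iter", 1000)),
            random_state=seed,
            **hp,
        )
        net = MLPClassifier(**kw) if binom else MLPRegressor(**kw)
        return Pipeline([("scale", StandardScaler()), ("net", net)])
    raise AssertionError(f"unreachable: {spec.name}")


def _predict_learner(est, x: np.ndarray, family: str) -> np.ndarray:
    if family == "binomial" and hasattr(est, "predict_proba"):
        proba = est.predict_proba(x)
        classes = list(getattr(est, "classes_", [0, 1]))
        if 1 not in classes:
            return np.zeros(x.shape[0])
        return proba[:, classes.index(1)]
    pred = np.asarray(est.predict(x), dtype=float)
    return np.clip(pred, 0.0, 1.0) if family == "binomial" else pred


def _risk(pred: np.ndarray, y: np.ndarray, family: str) -> float:
    if family == "gaussian":
        return float(np.mean((y - pred) ** 2))
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def _simplex_weights(z: np.ndarray, y: np.ndarray, family: str) -> np.ndarray:
    """Minimize CV risk of the convex combination ``z @ w`` over the simplex."""
    n_learners = z.shape[1]
    if n_learners == 1:
        return np.array([1.0])

    if family == "gaussian":
        w0, _ = nnls(z, y)
        w0 = w0 / w0.sum() if w0.sum() > 0 else np.full(n_learners, 1.0 / n_learners)
    else:
        w0 = np.full(n_learners, 1.0 / n_learners)

    def objective(w: np.ndarray) -> float:
        return _risk(z @ w, y, family)

    res = minimize(
        objective,
        w0,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n_learners,
        constraints=[{"type": "eq", "fun": lambda w: np.sum(w) - 1.0}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    w = np.clip(res.x if res.success else w0, 0.0, None)
    total = w.sum()
    return w / total if total > 0 else np.full(n_learners, 1.0 / n_learners)


@dataclass
class SuperLearnerModel:
    """A fitted stacking ensemble for one nuisance function."""

    base_fits: list
    learner_names: list[str]
    weights: np.ndarray
    family: str
    cv_folds: int
    cv_risk: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < -1e-10).any() or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("ensemble weights must lie on the probability simplex")
        if not len(self.base_fits) == len(w) == len(self.cv_risk):
            raise ValueError("base_fits, weights and cv_risk must be aligned")

    @property
    def ensemble_cv_risk(self) -> float:
        return float(self._ensemble_risk)


def _as_matrix(x, feature_names: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        names = list(x.columns)
        if feature_names is not None:
            if set(names) != set(feature_names):
                raise SchemaError(
                    f"covariate columns {names} do not match training layout "
                    f"{feature_names}"
                )
            x = x[feature_names]
            names = list(feature_names)
        return x.to_numpy(dtype=float), names
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    names = feature_names or [f"x{j}" for j in range(arr.shape[1])]
    if feature_names is not None and arr.shape[1] != len(feature_names):
        raise SchemaError(
            f"expected {len(feature_names)} columns, got {arr.shape[1]}"
        )
    return arr, names


def fit_superlearner(
    x,
    y: np.ndarray,
    specs: Sequence[LearnerSpec],
    family: str,
    cv_folds: int = 10,
    random_state: int | None = None,
    stratify: bool | None = None,
) -> SuperLearnerModel:
    """Fit the stacking ensemble.

    Parameters
    ----------
    x : array or DataFrame, shape (n, p)
    y : response; {0, 1} for ``family="binomial"``, real for ``"gaussian"``.
    specs : library of base learners.
    family : "binomial" or "gaussian"; controls both the base-learner type
        and the cross-validated risk (Bernoulli log-loss vs squared error).
    cv_folds : V for the out-of-fold prediction matrix (>= 2).
    random_state : seed controlling fold assignment and stochastic learners.
    stratify : stratify CV folds by ``y``; defaults to True for binomial
        responses so both classes appear in every fold.
    """
    if family not in ("binomial", "gaussian"):
        raise ValueError(f"unknown family {family!r}")
    if not specs:
        raise ValueError("at least one learner spec is required")
    xmat, feature_names = _as_matrix(x)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if xmat.shape[0] != n:
        raise ValueError("x and y are not row-aligned")
    if not 2 <= cv_folds <= n:
        raise ValueError(f"cv_folds must be in [2, n]; got {cv_folds} with n={n}")
    is_binary = np.isin(y, [0.0, 1.0]).all()
    if family == "binomial" and not is_binary:
        raise ValueError("binomial family requires a 0/1 response")
    if stratify is None:
        stratify = family == "binomial" and is_binary

    seeds = np.random.SeedSequence(random_state).generate_state(len(specs) + 1)
    fold_seed = int(seeds[0])
    if stratify:
        splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=fold_seed)
        fold_iter = list(splitter.split(xmat, y))
    else:
        splitter = KFold(n_splits=cv_folds, shuffle=True, random_state=fold_seed)
        fold_iter = list(splitter.split(xmat))

    oof = np.full((n, len(specs)), np.nan)
    alive = np.ones(len(specs), dtype=bool)
    for j, spec in enumerate(specs):
        learner_seed = int(seeds[j + 1])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for train_idx, test_idx in fold_iter:
                    est = _build_learner(spec, family, learner_seed)
                    est.fit(xmat[train_idx], y[train_idx])
                    oof[test_idx, j] = _predict_learner(est, xmat[test_idx], family)
        except Exception as exc:  # noqa: BLE001 - any learner failure drops it
            alive[j] = False
            logger.warning("learner %r failed during CV and was dropped: %s", spec.name, exc)
    if not alive.any():
        raise EstimationError("all base learners failed during cross-validation")

    survivors = [spec for spec, ok in zip(specs, alive) if ok]
    z = oof[:, alive]
    cv_risk = np.array([_risk(z[:, j], y, family) for j in range(z.shape[1])])
    weights = _simplex_weights(z, y, family)

    base_fits = []
    names = []
    kept = np.ones(len(survivors), dtype=bool)
    for j, spec in enumerate(survivors):
        learner_seed = int(seeds[[i for i, ok in enumerate(alive) if ok][j] + 1])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = _build_learner(spec, family, learner_seed)
                est.fit(xmat, y)
        except Exception as exc:  # noqa: BLE001
            kept[j] = False
            logger.warning("learner %r failed on the full fold and was dropped: %s", spec.name, exc)
            continue
        base_fits.append(est)
        names.append(spec.name)
    if not base_fits:
        raise EstimationError("all base learners failed on the training fold")
    if not kept.all():
        weights = weights[kept]
        cv_risk = cv_risk[kept]
        total = weights.sum()
        weights = weights / total if total > 0 else np.full(len(base_fits), 1.0 / len(base_fits))

    model = SuperLearnerModel(
        base_fits=base_fits,
        learner_names=names,
        weights=weights,
        family=family,
        cv_folds=cv_folds,
        cv_risk=cv_risk,
        feature_names=feature_names,
    )
    model._ensemble_risk = _risk(z[:, kept] @ weights, y, family)
    return model


def predict_superlearner(model: SuperLearnerModel, x) -> np.ndarray:
    """Weighted combination of the base-learner predictions at ``x``."""
    xmat, _ = _as_matrix(x, model.feature_names)
    preds = np.column_stack(
        [_predict_learner(est, xmat, model.family) for est in model.base_fits]
    )
    combined = preds @ model.weights
    if model.family == "binomial":
        combined = np.clip(combined, 0.0, 1.0)
    return combined
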