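"""Analytic dataset container, outcome scaling, and CSV/JSON input-output.

The analytic dataset is one row per subject: a binary exposure, a continuous
or binary outcome on its original scale, and a numeric covariate matrix.
Categorical covariates are expanded to reference-dropped indicator columns
once, on the full dataset, so every fold of every split shares a single
design matrix.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ColumnError, DataError, DegenerateOutcomeError

__all__ = [
    "AnalyticDataset",
    "OutcomeScale",
    "DCResult",
    "read_analytic_csv",
    "scale_outcome",
    "unscale_predictions",
    "unscale_ate",
    "write_result_json",
    "read_result_json",
]


@dataclass(frozen=True)
class OutcomeScale:
    """Min-max scaling metadata for the outcome.

    For a continuous outcome, predictions live on the ``[0, 1]`` scale
    internally and are mapped back via ``y * (y_max - y_min) + y_min``.
    For a binary outcome the scaling is the identity.
    """

    y_min: float
    y_max: float
    kind: str  # "continuous" | "binary"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if self.kind == "continuous" and not self.y_max > self.y_min:
            raise DegenerateOutcomeError(
                f"outcome range is degenerate: y_min={self.y_min}, y_max={self.y_max}"
            )

    @property
    def span(self) -> float:
        return 1.0 if self.kind == "binary" else self.y_max - self.y_min

    @classmethod
    def from_outcome(cls, y: np.ndarray, kind: str) -> "OutcomeScale":
        y = np.asarray(y, dtype=float)
        if kind == "binary":
            return cls(0.0, 1.0, "binary")
        return cls(float(np.min(y)), float(np.max(y)), "continuous")


@dataclass(frozen=True)
class AnalyticDataset:
    """One row per subject: outcome, exposure in {0, 1}, numeric covariates."""

    outcome: np.ndarray
    exposure: np.ndarray
    covariates: pd.DataFrame
    outcome_kind: str  # "continuous" | "binary"

    def __post_init__(self) -> None:
        outcome = np.asarray(self.outcome, dtype=float)
        exposure = np.asarray(self.exposure)
        object.__setattr__(self, "outcome", outcome)
        n = outcome.shape[0]
        if exposure.shape[0] != n or self.covariates.shape[0] != n:
            raise DataError(
                "outcome, exposure and covariates must have the same number of rows"
            )
        if not np.isin(exposure, [0, 1]).all():
            bad = np.unique(exposure[~np.isin(exposure, [0, 1])])
            raise DataError(f"exposure must be coded 0/1; found values {bad.tolist()}")
        exposure = exposure.astype(int)
        object.__setattr__(self, "exposure", exposure)
        if exposure.min() == exposure.max():
            raise DataError("exposure must contain both 0 and 1")
        if np.isnan(outcome).any():
            raise DataError("outcome contains missing values")
        if self.covariates.isna().any().any():
            raise DataError("covariates contain missing values")
        if self.outcome_kind not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome kind {self.outcome_kind!r}")

    @property
    def n(self) -> int:
        return int(self.outcome.shape[0])

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def outcome_scale(self) -> OutcomeScale:
        return OutcomeScale.from_outcome(self.outcome, self.outcome_kind)


def _infer_outcome_kind(y: pd.Series) -> str:
    vals = pd.unique(y.dropna())
    return "binary" if np.isin(vals, [0, 1]).all() else "continuous"


def read_analytic_csv(
    path: str | Path,
    outcome_col: str,
    exposure_col: str,
    covariate_cols: Sequence[str],
) -> AnalyticDataset:
    """Read a rectangular analytic CSV into an :class:`AnalyticDataset`.

    Categorical (non-numeric) covariates are expanded to indicator columns
    with the reference level dropped. Missing cells are rejected with an
    error naming the offending rows; exposure values outside {0, 1} are a
    domain error. The outcome kind is inferred as binary iff the outcome
    takes only values in {0, 1}.
    """
    frame = pd.read_csv(path)
    wanted = [outcome_col, exposure_col, *covariate_cols]
    missing_cols = [c for c in wanted if c not in frame.columns]
    if missing_cols:
        raise ColumnError(f"columns not found in {path}: {missing_cols}")
    frame = frame[wanted]
    na_rows = frame.index[frame.isna().any(axis=1)]
    if len(na_rows):
        shown = na_rows[:20].tolist()
        raise DataError(
            f"missing values in rows {shown}"
            + (" (truncated)" if len(na_rows) > 20 else "")
        )

    covs = frame[list(covariate_cols)]
    categorical = [
        c for c in covs.columns if not pd.api.types.is_numeric_dtype(covs[c])
    ]
    if categorical:
        covs = pd.get_dummies(covs, columns=categorical, drop_first=True, dtype=float)
    covs = covs.astype(float).reset_index(drop=True)

    y = pd.to_numeric(frame[outcome_col])
    a_raw = frame[exposure_col]
    try:
        a = pd.to_numeric(a_raw).to_numpy()
    except (ValueError, TypeError) as exc:
        raise DataError(f"exposure column {exposure_col!r} is not numeric") from exc

    return AnalyticDataset(
        outcome=y.to_numpy(dtype=float),
        exposure=a,
        covariates=covs,
        outcome_kind=_infer_outcome_kind(y),
    )


def scale_outcome(y: np.ndarray, scale: OutcomeScale) -> np.ndarray:
    """Min-max scale ``y`` to ``[0, 1]``; identity for binary outcomes."""
    y = np.asarray(y, dtype=float)
    if scale.kind == "binary":
        return y
    if np.min(y) < scale.y_min or np.max(y) > scale.y_max:
        raise DataError("outcome values fall outside the declared scale range")
    return (y - scale.y_min) / scale.span


def unscale_predictions(y_star: np.ndarray, scale: OutcomeScale) -> np.ndarray:
    """Map per-observation predictions from ``[0, 1]`` back to original scale."""
    y_star = np.asarray(y_star, dtype=float)
    if scale.kind == "binary":
        return y_star
    return y_star * scale.span + scale.y_min

def unscale_ate(ate_star: float, scale: OutcomeScale) -> float:
    # The additive minimum cancels in the treated-minus-control difference,
    # so the effect back-transform multiplies by the range only.
    return float(ate_star) * scale.span


@dataclass(frozen=True)
class DCResult:
    """Overall estimate with Wald 95% CI and the per-repetition trace."""

    ate: float
    variance: float
    std_error: float
    ci_lower: float
    ci_upper: float
    per_repetition: list[tuple[float, float]]
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be non-negative")

    @classmethod
    def from_ate_variance(
        cls,
        ate: float,
        variance: float,
        per_repetition: list[tuple[float, float]],
        settings: dict | None = None,
    ) -> "DCResult":
        se = float(np.sqrt(variance))
        return cls(
            ate=float(ate),
            variance=float(variance),
            std_error=se,
            ci_lower=float(ate) - 1.96 * se,
            ci_upper=float(ate) + 1.96 * se,
            per_repetition=[(float(a), float(v)) for a, v in per_repetition],
            settings=dict(settings or {}),
        )


def write_result_json(result: DCResult, path: str | Path) -> None:
    """Serialize a :class:`DCResult` so that a reload is numerically exact."""
    from ._version import __version__

    doc = dataclasses.asdict(result)
    doc["per_repetition"] = [list(pair) for pair in result.per_repetition]
    doc["package_version"] = __version__
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, allow_nan=True)
        fh.write("\n")


def read_result_json(path: str | Path) -> DCResult:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return DCResult(
        ate=doc["ate"],
        variance=doc["variance"],
        std_error=doc["std_error"],
        ci_lower=doc["ci_lower"],
        ci_upper=doc["ci_upper"],
        per_repetition=[tuple(pair) for pair in doc["per_repetition"]],
        settings=doc.get("settings", {}),
    )
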