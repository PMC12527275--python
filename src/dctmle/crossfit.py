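"""Double cross-fit driver: split assignment, role rotation, repetition,
and aggregation into the overall estimate.

One repetition partitions the rows into S (default 3) folds, fits one
exposure model and one outcome model per fold, then evaluates each fold
using nuisance models from the two *other* folds. The whole procedure is
repeated k times over fresh random partitions; the overall effect is the
median (or mean) of the k global estimates, with variance aggregated as
within-repetition variance plus between-repetition squared deviation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed

from .data import AnalyticDataset, DCResult, OutcomeScale
from .errors import DCTMLEError, EstimationError, SampleSizeError
from .superlearner import LearnerSpec, fit_superlearner
from .tmle import EXPOSURE_COLUMN, SplitEstimate, run_split_tmle
from ._version import __version__

logger = logging.getLogger(__name__)

__all__ = [
    "RunSettings",
    "SplitAssignment",
    "RepetitionResult",
    "make_split_assignment",
    "run_one_repetition",
    "aggregate_repetitions",
    "run_dc_tmle",
    "run_tmle_nocf",
]

MAX_FAILED_FRACTION = 0.2


@dataclass(frozen=True)
class RunSettings:
    """Everything needed to reproduce a run, minus the data."""

    n_split: int = 3
    num_cf: int = 100
    cv_folds: int = 10
    learners_exposure: tuple[LearnerSpec, ...] = (
        LearnerSpec("l1_glm"),
        LearnerSpec("random_forest"),
        LearnerSpec("gradient_boosting"),
    )
    learners_outcome: tuple[LearnerSpec, ...] | None = None  # None -> same as exposure
    covariates_exposure: tuple[str, ...] | None = None  # None -> all covariates
    covariates_outcome: tuple[str, ...] | None = None
    aggregation: str = "median"
    seed: int = 0
    workers: int = 1
    weighted_fluctuation: bool = False

    def __post_init__(self) -> None:
        if self.n_split < 3:
            raise ValueError("n_split must be at least 3")
        if self.num_cf < 1:
            raise ValueError("num_cf must be at least 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.aggregation not in ("median", "mean"):
            raise ValueError("aggregation must be 'median' or 'mean'")

    @property
    def outcome_learners(self) -> tuple[LearnerSpec, ...]:
        return self.learners_outcome if self.learners_outcome is not None else self.learners_exposure

    def echo(self) -> dict:
        return {
            "n_split": self.n_split,
            "num_cf": self.num_cf,
            "cv_folds": self.cv_folds,
            "learners_exposure": [s.name for s in self.learners_exposure],
            "learners_outcome": [s.name for s in self.outcome_learners],
            "covariates_exposure": list(self.covariates_exposure) if self.covariates_exposure else None,
            "covariates_outcome": list(self.covariates_outcome) if self.covariates_outcome else None,
            "aggregation": self.aggregation,
            "seed": self.seed,
            "workers": self.workers,
            "weighted_fluctuation": self.weighted_fluctuation,
            "package_version": __version__,
        }


@dataclass(frozen=True)
class SplitAssignment:
    """Fold label per row plus the role rotation.

    ``rotation`` is a list of ``(eval_fold, exposure_fold, outcome_fold)``
    triples; fold labels run 1..S. Each fold holds each role exactly once
    and the three folds in any triple are pairwise distinct.
    """

    fold_of_row: np.ndarray
    rotation: tuple[tuple[int, int, int], ...]

    def rows_of_fold(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_row == fold)

    @property
    def n_split(self) -> int:
        return len(self.rotation)


def _rotation(n_split: int) -> tuple[tuple[int, int, int], ...]:
    # eval s -> exposure (s mod S)+1, outcome ((s+1) mod S)+1; for S=3 this
    # is ((1,2,3), (2,3,1), (3,1,2)).
    return tuple(
        (s, (s % n_split) + 1, ((s + 1) % n_split) + 1) for s in range(1, n_split + 1)
    )


def make_split_assignment(
    n: int, n_split: int = 3, random_state: int | None = None
) -> SplitAssignment:
    """Uniformly random partition of ``n`` rows into ``n_split`` nearly
    equal folds, sizes differing by at most one."""
    if n < 3 * n_split:
        raise SampleSizeError(
            f"need at least {3 * n_split} rows for {n_split} splits; got {n}"
        )
    rng = np.random.default_rng(random_state)
    perm = rng.permutation(n)
    fold_of_row = np.empty(n, dtype=int)
    for label, chunk in enumerate(np.array_split(perm, n_split), start=1):
        fold_of_row[chunk] = label
    return SplitAssignment(fold_of_row=fold_of_row, rotation=_rotation(n_split))


@dataclass(frozen=True)
class RepetitionResult:
    global_ate: float
    global_variance: float
    split_estimates: tuple[SplitEstimate, ...]


def _exposure_design(dataset: AnalyticDataset, settings: RunSettings):
    cols = list(settings.covariates_exposure or dataset.covariate_names)
    return dataset.covariates[cols]


def _outcome_design(dataset: AnalyticDataset, settings: RunSettings):
    cols = list(settings.covariates_outcome or dataset.covariate_names)
    design = dataset.covariates[cols].copy()
    design[EXPOSURE_COLUMN] = dataset.exposure.astype(float)
    return design


def run_one_repetition(
    dataset: AnalyticDataset,
    settings: RunSettings,
    random_state: int,
    scale: OutcomeScale | None = None,
) -> RepetitionResult:
    """One full split-fit-rotate-evaluate cycle (steps of a single repetition)."""
    scale = scale or dataset.outcome_scale()
    assignment = make_split_assignment(dataset.n, settings.n_split, random_state)

    from .data import scale_outcome

    y_star = scale_outcome(dataset.outcome, scale)
    x_exp = _exposure_design(dataset, settings)
    x_out = _outcome_design(dataset, settings)
    outcome_family = "binomial" if dataset.outcome_kind == "binary" else "gaussian"

    seeds = np.random.SeedSequence(random_state).generate_state(2 * settings.n_split + 1)
    exposure_models = {}
    outcome_models = {}
    for fold in range(1, settings.n_split + 1):
        rows = assignment.rows_of_fold(fold)
        a_fold = dataset.exposure[rows]
        if a_fold.min() == a_fold.max():
            raise EstimationError(
                f"fold {fold} contains a single exposure arm; repetition aborted"
            )
        exposure_models[fold] = fit_superlearner(
            x_exp.iloc[rows],
            a_fold,
            settings.learners_exposure,
            family="binomial",
            cv_folds=settings.cv_folds,
            random_state=int(seeds[2 * fold - 1]),
            stratify=True,
        )
        outcome_models[fold] = fit_superlearner(
            x_out.iloc[rows],
            y_star[rows],
            settings.outcome_learners,
            family=outcome_family,
            cv_folds=settings.cv_folds,
            random_state=int(seeds[2 * fold]),
        )

    estimates = []
    for eval_fold, exp_fold, out_fold in assignment.rotation:
        estimates.append(
            run_split_tmle(
                dataset,
                assignment.rows_of_fold(eval_fold),
                exposure_models[exp_fold],
                outcome_models[out_fold],
                scale,
                weighted_fluctuation=settings.weighted_fluctuation,
            )
        )
    return RepetitionResult(
        global_ate=float(np.mean([e.ate_local for e in estimates])),
        global_variance=float(np.mean([e.var_local for e in estimates])),
        split_estimates=tuple(estimates),
    )


def aggregate_repetitions(
    reps: list[RepetitionResult], method: str = "median", settings: dict | None = None
) -> DCResult:
    """Overall effect and variance across repetitions.

    Variance per repetition is its within-split variance plus the squared
    deviation of its global estimate from the overall estimate; the
    median (or mean) of those per-repetition sums is the overall variance.
    """
    if not reps:
        raise EstimationError("no successful repetitions to aggregate")
    if method not in ("median", "mean"):
        raise ValueError("method must be 'median' or 'mean'")
    agg = np.median if method == "median" else np.mean
    ates = np.array([r.global_ate for r in reps])
    variances = np.array([r.global_variance for r in reps])
    overall_ate = float(agg(ates))
    overall_var = float(agg(variances + (ates - overall_ate) ** 2))
    return DCResult.from_ate_variance(
        overall_ate,
        overall_var,
        per_repetition=[(r.global_ate, r.global_variance) for r in reps],
        settings=settings,
    )


def _child_seed(master_seed: int, repetition: int) -> int:
    # Seeds are keyed by repetition index so the stream is invariant to
    # worker count and execution order.
    return int(np.random.SeedSequence(entropy=master_seed, spawn_key=(repetition,)).generate_state(1)[0])


def _try_repetition(dataset, settings, seed, scale, index):
    try:
        return index, run_one_repetition(dataset, settings, seed, scale), None
    except DCTMLEError as exc:
        return index, None, str(exc)


def run_dc_tmle(dataset: AnalyticDataset, settings: RunSettings) -> DCResult:
    """Full double cross-fit run: k independent repetitions, aggregated.

    Results are bit-identical for a given master seed regardless of the
    worker count. Failed repetitions (degenerate splits) are recorded as
    NaN in the trace and excluded from aggregation; more than 20% failures
    is a hard error.
    """
    scale = dataset.outcome_scale()
    k = settings.num_cf
    seeds = [_child_seed(settings.seed, r) for r in range(k)]
    if settings.workers > 1:
        triples = Parallel(n_jobs=settings.workers)(
            delayed(_try_repetition)(dataset, settings, seed, scale, r)
            for r, seed in enumerate(seeds)
        )
    else:
        import time

        start = time.time()
        triples = []
        for r, seed in enumerate(seeds):
            triples.append(_try_repetition(dataset, settings, seed, scale, r))
            logger.info(
                "repetition %d/%d done (%.1f s elapsed)", r + 1, k, time.time() - start
            )
    triples.sort(key=lambda t: t[0])

    successes = [rep for _, rep, _ in triples if rep is not None]
    failures = [(idx, msg) for idx, rep, msg in triples if rep is None]
    if len(failures) > MAX_FAILED_FRACTION * k:
        raise EstimationError(
            f"{len(failures)}/{k} repetitions failed (>20%); likely positivity "
            f"problems. First failure: {failures[0][1]}"
        )
    for idx, msg in failures:
        warnings.warn(f"repetition {idx} skipped: {msg}", stacklevel=2)
        logger.warning("repetition %d skipped: %s", idx, msg)

    result = aggregate_repetitions(
        successes, method=settings.aggregation, settings=settings.echo()
    )
    # Rebuild the trace at full length k with NaN placeholders for failures.
    trace: list[tuple[float, float]] = []
    for _, rep, _ in triples:
        trace.append(
            (rep.global_ate, rep.global_variance)
            if rep is not None
            else (float("nan"), float("nan"))
        )
    return replace(result, per_repetition=trace)


def run_tmle_nocf(dataset: AnalyticDataset, settings: RunSettings) -> DCResult:
    """No-split TMLE reference: all three roles use the full data, k = 1.

    This is the conventional (non-cross-fit) estimator used as the
    comparator in the simulation harness.
    """
    scale = dataset.outcome_scale()
    y_star_family = "binomial" if dataset.outcome_kind == "binary" else "gaussian"

    from .data import scale_outcome

    seeds = np.random.SeedSequence(settings.seed).generate_state(2)
    exposure_model = fit_superlearner(
        _exposure_design(dataset, settings),
        dataset.exposure,
        settings.learners_exposure,
        family="binomial",
        cv_folds=settings.cv_folds,
        random_state=int(seeds[0]),
        stratify=True,
    )
    outcome_model = fit_superlearner(
        _outcome_design(dataset, settings),
        scale_outcome(dataset.outcome, scale),
        settings.outcome_learners,
        family=y_star_family,
        cv_folds=settings.cv_folds,
        random_state=int(seeds[1]),
    )
    estimate = run_split_tmle(
        dataset,
        np.arange(dataset.n),
        exposure_model,
        outcome_model,
        scale,
        weighted_fluctuation=settings.weighted_fluctuation,
    )
    return DCResult.from_ate_variance(
        estimate.ate_local,
        estimate.var_local,
        per_repetition=[(estimate.ate_local, estimate.var_local)],
        settings={**settings.echo(), "estimator": "tmle_nocf"},
    )
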