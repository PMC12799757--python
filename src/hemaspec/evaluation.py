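"""Leave-one-subject-out evaluation and error reporting.

Each subject's recordings are held out in turn while the model trains on all
other subjects' samples, so every prediction is for a subject the model has
never seen — the realistic forensic setting. Errors are summarized three
ways: the pooled RMSE over all held-out predictions (in days), a per-subject
mean absolute deviation, and age-window statistics (mean and SD of the
per-subject deviations across subjects, for hematomas up to day 7, after
day 7, and over the full observation period).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import (
    DAY7_HOURS,
    GenderStratifiedRegressor,
    HierarchicalAgeRegressor,
    LassoAgeRegressor,
)
from .normalization import FeatureDataset, normalize
from .spectra import Recording

__all__ = [
    "ExperimentConfig",
    "PredictionRecord",
    "CVReport",
    "lopo_folds",
    "rmse_days",
    "window_stats",
    "run_experiment",
    "exclusion_rerun",
    "ARCHITECTURES",
    "WINDOWS",
]

ARCHITECTURES = ("plain", "hierarchical", "gender")

#: Reporting windows by TRUE age; day-7 recordings fall in the young window.
WINDOWS = ("up_to_day7", "after_day7", "full")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one cross-validated experiment."""

    n_alphas: int = 100
    alpha_min_ratio: float = 1e-4
    inner_folds: int = 5
    rule: str = "min"  # or "1se"
    gate: str = "logistic"  # or "regression"
    threshold_hours: float = DAY7_HOURS
    clip_predictions: bool = False  # clip to [0, 504 h] if set
    seed: int = 0

    def lasso_kwargs(self) -> dict:
        return {
            "n_alphas": self.n_alphas,
            "alpha_min_ratio": self.alpha_min_ratio,
            "inner_folds": self.inner_folds,
            "rule": self.rule,
            "random_state": self.seed,
        }


@dataclass(frozen=True)
class PredictionRecord:
    """One held-out prediction."""

    subject_id: str
    sex: str
    true_hours: float
    predicted_hours: float
    model_tag: str

    def __post_init__(self) -> None:
        if self.true_hours < 0:
            raise ValueError("true age must be non-negative")
        if not np.isfinite(self.predicted_hours):
            raise ValueError("prediction must be finite")


@dataclass(frozen=True)
class CVReport:
    """Cross-validation results with pooled and per-subject summaries."""

    predictions: list[PredictionRecord]
    rmse_days: float
    per_subject_mad_days: dict[str, float]
    window_stats: dict[str, tuple[float, float | None]]
    model_tag: str
    config: ExperimentConfig = field(default_factory=ExperimentConfig)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": p.subject_id,
                    "sex": p.sex,
                    "true_hours": p.true_hours,
                    "predicted_hours": p.predicted_hours,
                    "model_tag": p.model_tag,
                }
                for p in self.predictions
            ]
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model_tag": self.model_tag,
            "rmse_days": self.rmse_days,
            "per_subject_mad_days": self.per_subject_mad_days,
            "window_stats": {
                w: {"M": m, "SD": sd} for w, (m, sd) in self.window_stats.items()
            },
            "config": self.config.__dict__,
            "predictions": self.to_frame().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def lopo_folds(dataset: FeatureDataset) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (train, test) index pair per subject; the folds partition the data."""
    subjects = np.unique(dataset.subject)
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    folds = []
    for s in subjects:
        test = np.flatnonzero(dataset.subject == s)
        train = np.flatnonzero(dataset.subject != s)
        folds.append((train, test))
    return folds


def rmse_days(predictions: list[PredictionRecord]) -> float:
    """Pooled root mean squared error over all predictions, in days.

    Sums with correctly-rounded accumulation (``math.fsum``) so the result
    is independent of prediction order and reproducible bit-for-bit by any
    recomputation using the same summation.
    """
    if not predictions:
        raise ValueError("cannot compute RMSE of an empty prediction list")
    sq = [((p.predicted_hours - p.true_hours) / 24.0) ** 2 for p in predictions]
    return math.sqrt(math.fsum(sq) / len(sq))


def per_subject_mad(predictions: list[PredictionRecord]) -> dict[str, float]:
    """Mean absolute deviation in days per subject."""
    by_subject: dict[str, list[float]] = {}
    for p in predictions:
        by_subject.setdefault(p.subject_id, []).append(
            abs(p.predicted_hours - p.true_hours) / 24.0
        )
    return {s: math.fsum(v) / len(v) for s, v in by_subject.items()}


def window_stats(
    predictions: list[PredictionRecord],
    threshold_hours: float = DAY7_HOURS,
) -> dict[str, tuple[float, float | None]]:
    """Across-subject mean (M) and sample SD of per-subject deviations per window.

    A prediction belongs to a window by its TRUE age; the day-7 boundary is
    inclusive below. Each subject contributes one mean absolute deviation per
    window; M and SD (n-1 denominator) are taken across subjects. Windows
    with no predictions are absent from the result; SD is None when only one
    subject has predictions in a window.
    """
    membership = {
        "up_to_day7": lambda t: t <= threshold_hours,
        "after_day7": lambda t: t > threshold_hours,
        "full": lambda t: True,
    }
    out: dict[str, tuple[float, float | None]] = {}
    for window, member in membership.items():
        subset = [p for p in predictions if member(p.true_hours)]
        if not subset:
            continue
        mads = list(per_subject_mad(subset).values())
        m = math.fsum(mads) / len(mads)
        sd = (
            math.sqrt(math.fsum((v - m) ** 2 for v in mads) / (len(mads) - 1))
            if len(mads) > 1
            else None
        )
        out[window] = (m, sd)
    return out


def _fit_and_predict(dataset, train, test, architecture, config):
    kw = config.lasso_kwargs()
    Xtr, ytr, gtr = dataset.X[train], dataset.y[train], dataset.subject[train]
    if architecture == "plain":
        model = LassoAgeRegressor(**kw).fit(Xtr, ytr, groups=gtr)
        return model.predict(dataset.X[test])
    if architecture == "hierarchical":
        model = HierarchicalAgeRegressor(
            estimator=LassoAgeRegressor(**kw),
            threshold_hours=config.threshold_hours,
            gate=config.gate,
        ).fit(Xtr, ytr, groups=gtr)
        return model.predict(dataset.X[test])
    if architecture == "gender":
        model = GenderStratifiedRegressor(estimator=LassoAgeRegressor(**kw)).fit(
            Xtr, ytr, groups=gtr, sex=dataset.sex[train]
        )
        return model.predict(dataset.X[test], sex=dataset.sex[test])
    raise ValueError(f"architecture must be one of {ARCHITECTURES}, got {architecture!r}")


def run_experiment(
    recordings: list[Recording],
    method: str,
    architecture: str = "plain",
    config: ExperimentConfig | None = None,
    excluded_train_keys: set[tuple[str, float]] | None = None,
) -> CVReport:
    """Normalize, run leave-one-subject-out CV, and assemble a report.

    ``excluded_train_keys`` removes specific recordings — identified by
    ``(subject_id, age_hours)`` — from every training fold while still
    predicting them when their subject is held out (the lighting-exclusion
    re-analysis).
    """
    config = config or ExperimentConfig()
    dataset = normalize(recordings, method)
    tag = f"{method}-{architecture}"

    excluded = np.zeros(dataset.n_samples, dtype=bool)
    if excluded_train_keys:
        keys = [(s, a) for s, a in zip(dataset.subject, dataset.y)]
        known = set(keys)
        unknown = set(excluded_train_keys) - known
        if unknown:
            raise KeyError(f"unknown recording keys: {sorted(unknown)}")
        excluded = np.array([k in excluded_train_keys for k in keys])

    predictions: list[PredictionRecord] = []
    for train, test in lopo_folds(dataset):
        held_out = set(dataset.subject[test])
        assert not held_out & set(dataset.subject[train]), "subject leakage across folds"
        train = train[~excluded[train]]
        pred = _fit_and_predict(dataset, train, test, architecture, config)
        if config.clip_predictions:
            pred = np.clip(pred, 0.0, 21 * 24.0)
        for i, j in enumerate(test):
            predictions.append(
                PredictionRecord(
                    subject_id=str(dataset.subject[j]),
                    sex=str(dataset.sex[j]),
                    true_hours=float(dataset.y[j]),
                    predicted_hours=float(pred[i]),
                    model_tag=tag,
                )
            )

    rmse = rmse_days(predictions)
    mad = per_subject_mad(predictions)
    # RMSE dominates the pooled mean absolute deviation (Jensen's inequality)
    pooled_mad = float(np.mean([abs(p.predicted_hours - p.true_hours) / 24.0 for p in predictions]))
    assert rmse >= pooled_mad - 1e-12
    return CVReport(
        predictions=predictions,
        rmse_days=rmse,
        per_subject_mad_days=mad,
        window_stats=window_stats(predictions, config.threshold_hours),
        model_tag=tag,
        config=config,
    )


def exclusion_rerun(
    recordings: list[Recording],
    excluded_keys: set[tuple[str, float]],
    method: str,
    architecture: str = "hierarchical",
    config: ExperimentConfig | None = None,
) -> CVReport:
    """Re-run an experiment with flagged recordings dropped from training only."""
    return run_experiment(
        recordings, method, architecture, config, excluded_train_keys=excluded_keys
    )
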