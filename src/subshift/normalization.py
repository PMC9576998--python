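"""Subject-wise feature normalization: whitening and baseline referencing.

Four feature spaces are supported.  ``none`` leaves features untouched.
``zscore`` whitens each subject's task features with that subject's own task
mean β and standard deviation γ.  ``baseline1`` / ``baseline2`` standardize
task features with statistics from the subject's rest (baseline 1) or
physical-activity-only (baseline 2) segment:

    x' = (x − β) / γ        (per feature, per subject)

Statistics are always per subject, never pooled across subjects; the sample
standard deviation uses ddof=1.  Zero-variance features raise rather than
being silently regularized — they usually indicate a dead channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .data import DataError, FeatureTable, ValidationError

__all__ = [
    "STRATEGIES",
    "GAMMA_TOLERANCE",
    "NormalizationParams",
    "DegenerateFeatureError",
    "fit_params",
    "fit_all_params",
    "apply_normalization",
    "SubjectNormalizer",
    "params_to_json",
    "params_from_json",
]

STRATEGIES = ("none", "zscore", "baseline1", "baseline2")
GAMMA_TOLERANCE = 1e-12

#: reference phase whose statistics define β/γ for each strategy
REFERENCE_PHASE = {"zscore": "task", "baseline1": "baseline1", "baseline2": "baseline2"}


class DegenerateFeatureError(DataError):
    """A feature has (near-)zero variance in the reference segment."""


@dataclass
class NormalizationParams:
    subject_id: str
    beta: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.beta.shape != self.gamma.shape or self.beta.ndim != 1:
            raise ValidationError("beta and gamma must be matching 1-D vectors")
        if (self.gamma <= GAMMA_TOLERANCE).any():
            raise DegenerateFeatureError(
                f"subject {self.subject_id!r}: gamma at or below tolerance"
            )


def fit_params(
    table: FeatureTable, subject: str, reference_phase: str
) -> NormalizationParams:
    """Per-feature mean/sd of one subject's rows in the reference phase."""
    rows = table.phase_rows(reference_phase)
    rows = rows[rows["subject"] == subject]
    if len(rows) < 2:
        raise DataError(
            f"subject {subject!r} has {len(rows)} rows in phase "
            f"{reference_phase!r}; need >= 2"
        )
    X = table.features(rows)
    beta = X.mean(axis=0)
    gamma = X.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(gamma <= GAMMA_TOLERANCE)
    if degenerate.size:
        names = [table.feature_columns[i] for i in degenerate]
        raise DegenerateFeatureError(
            f"subject {subject!r}: zero-variance feature(s) {names} in "
            f"phase {reference_phase!r}"
        )
    return NormalizationParams(subject, beta, gamma)


def fit_all_params(
    table: FeatureTable, strategy: str
) -> dict[str, NormalizationParams]:
    if strategy == "none":
        return {}
    if strategy not in REFERENCE_PHASE:
        raise ValidationError(f"unknown normalization strategy {strategy!r}")
    phase = REFERENCE_PHASE[strategy]
    return {s: fit_params(table, s, phase) for s in table.subjects}


def apply_normalization(
    table: FeatureTable,
    params: dict[str, NormalizationParams],
    strategy: str,
) -> FeatureTable:
    """Transform every task row with its subject's params; drop baseline rows.

    Downstream shift estimators consume task rows only, so the output contains
    the (possibly identity-) transformed task phase.
    """
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown normalization strategy {strategy!r}")
    task = table.phase_rows("task").copy()
    if strategy == "none":
        return table.with_frame(task)
    missing = [s for s in sorted(task["subject"].unique()) if s not in params]
    if missing:
        raise DataError(f"no normalization params for subjects {missing}")
    X = table.features(task)
    for subject, idx in task.groupby("subject", sort=False).indices.items():
        p = params[subject]
        X[idx] = (X[idx] - p.beta) / p.gamma
    task[table.feature_columns] = X
    return table.with_frame(task)


class SubjectNormalizer(BaseEstimator):
    """Transformer applying one of the four subject-wise feature spaces.

    Follows the fit/transform convention: :meth:`fit` learns per-subject β/γ
    from the reference phase, :meth:`transform` maps task rows into the
    normalized space.  ``params_`` holds the fitted statistics per subject.
    """

    def __init__(self, strategy: str = "zscore"):
        self.strategy = strategy

    def fit(self, table: FeatureTable, y=None) -> "SubjectNormalizer":
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"unknown normalization strategy {self.strategy!r}")
        self.params_ = fit_all_params(table, self.strategy)
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        if not hasattr(self, "params_"):
            raise ValidationError("SubjectNormalizer is not fitted")
        return apply_normalization(table, self.params_, self.strategy)

    def fit_transform(self, table: FeatureTable, y=None) -> FeatureTable:
        return self.fit(table).transform(table)


# ---------------------------------------------------------------------------
# JSON audit serialization


def params_to_json(params: dict[str, NormalizationParams]) -> str:
    payload = {
        s: {"beta": p.beta.tolist(), "gamma": p.gamma.tolist()}
        for s, p in sorted(params.items())
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def params_from_json(text: str) -> dict[str, NormalizationParams]:
    payload = json.loads(text)
    return {
        s: NormalizationParams(s, np.asarray(v["beta"]), np.asarray(v["gamma"]))
        for s, v in payload.items()
    }
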