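"""Leave-one-subject-out workload classification and the generalization gap.

Each fold trains a random-forest low/high-workload classifier on all subjects
but one (the pooled source domain) and tests on the excluded subject (the
target domain).  The source risk is estimated on a seeded per-subject holdout
taken out of the training pool before fitting; the generalization gap is the
absolute difference between source (training) accuracy and target (test)
accuracy, averaged per repetition.  Everything is repeated over the seeded
subsampling protocol so gaps are reported as mean ± sd.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier

from .data import (
    DataError,
    FeatureTable,
    SamplingProtocol,
    ValidationError,
    subsample,
)
from .normalization import SubjectNormalizer
from .util import derive_seed

__all__ = ["loso_split", "gap", "LOSOReport", "evaluate_loso", "LOSOEvaluator"]


def loso_split(
    table: FeatureTable, held_out: str
) -> tuple[FeatureTable, FeatureTable]:
    """(train, test) task tables: test = held-out subject, train = the rest."""
    task = table.phase_rows("task")
    subjects = sorted(task["subject"].unique())
    if held_out not in subjects:
        raise DataError(f"unknown subject {held_out!r}")
    if len(subjects) < 2:
        raise DataError("leave-one-subject-out needs at least two subjects")
    test = task[task["subject"] == held_out]
    train = task[task["subject"] != held_out]
    return table.with_frame(train), table.with_frame(test)


def gap(train_accuracy: float, test_accuracy: float) -> float:
    """Generalization gap: |train − test| accuracy."""
    for name, v in (("train", train_accuracy), ("test", test_accuracy)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} accuracy {v} outside [0, 1]")
    return abs(train_accuracy - test_accuracy)


@dataclass
class LOSOReport:
    """Per-held-out-subject accuracies and gaps, mean ± sd over repetitions.

    ``per_subject`` has one row per held-out subject with columns
    ``train_mean/train_sd/test_mean/test_sd/gap_mean/gap_sd``; ``pooled`` is
    the all-subjects row (mean/sd over every subject x repetition value).
    """

    per_subject: pd.DataFrame
    pooled: dict[str, float]
    runs: pd.DataFrame = field(default_factory=pd.DataFrame)
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_subject": self.per_subject.round(10).to_dict(orient="index"),
                "pooled": {k: round(v, 10) for k, v in self.pooled.items()},
                "metadata": self.metadata,
            },
            indent=2,
            sort_keys=True,
        )

    def to_frame(self) -> pd.DataFrame:
        """Table layout: per-subject + All rows, train/test/gap sub-rows."""
        rows = []
        for subject, r in self.per_subject.iterrows():
            for kind in ("train", "test", "gap"):
                rows.append(
                    {
                        "subject": subject,
                        "quantity": kind,
                        "mean": r[f"{kind}_mean"],
                        "sd": r[f"{kind}_sd"],
                    }
                )
        for kind in ("train", "test", "gap"):
            rows.append(
                {
                    "subject": "All",
                    "quantity": kind,
                    "mean": self.pooled[f"{kind}_mean"],
                    "sd": self.pooled[f"{kind}_sd"],
                }
            )
        return pd.DataFrame(rows)


def _holdout_indices(
    frame: pd.DataFrame, n_holdout: int, seed: int
) -> np.ndarray:
    """Seeded per-subject holdout, stratified by session."""
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    sessions = sorted(frame["session"].unique())
    base, extra = divmod(n_holdout, len(sessions))
    for s_idx, session in enumerate(sessions):
        idx = frame.index[frame["session"] == session].to_numpy()
        want = base + (1 if s_idx < extra else 0)
        if want > len(idx):
            raise DataError(
                f"session {session!r} of subject "
                f"{frame['subject'].iloc[0]!r} has {len(idx)} rows < {want}"
            )
        chosen.extend(np.sort(rng.choice(idx, size=want, replace=False)).tolist())
    return np.asarray(sorted(chosen))


def evaluate_loso(
    table: FeatureTable,
    strategy: str = "none",
    n_trees: int = 30,
    source_holdout: int = 200,
    protocol: SamplingProtocol = SamplingProtocol(),
) -> LOSOReport:
    """Repeated leave-one-subject-out evaluation under one feature space.

    Per repetition: subsample the table, fit the normalization, and for every
    held-out subject fit a ``n_trees``-tree random forest on the pooled
    training subjects minus a seeded ``source_holdout``-row stratified holdout
    per subject.  Training accuracy is measured on the pooled holdout (source
    risk), test accuracy on the held-out subject, and the gap per repetition.
    """
    records: list[dict] = []
    for r in range(protocol.n_repetitions):
        sub = subsample(table, protocol, r)
        normalized = SubjectNormalizer(strategy).fit_transform(sub)
        task = normalized.phase_rows("task")
        subjects = sorted(task["subject"].unique())
        for subject in subjects:
            counts = task.groupby("subject").size()
            small = counts[(counts <= source_holdout) & (counts.index != subject)]
            if len(small):
                raise DataError(
                    f"training subject(s) {sorted(small.index)} have "
                    f"<= source_holdout={source_holdout} task rows"
                )
        for held_idx, held_out in enumerate(subjects):
            train_tab, test_tab = loso_split(normalized, held_out)
            train_frame = train_tab.frame
            holdout_idx: list[int] = []
            for s_idx, subject in enumerate(
                sorted(train_frame["subject"].unique())
            ):
                sub_frame = train_frame[train_frame["subject"] == subject]
                holdout_idx.extend(
                    _holdout_indices(
                        sub_frame,
                        source_holdout,
                        derive_seed(protocol.base_seed, r, held_idx, s_idx),
                    ).tolist()
                )
            holdout_mask = train_frame.index.isin(holdout_idx)
            fit_frame = train_frame[~holdout_mask]
            holdout_frame = train_frame[holdout_mask]
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                random_state=derive_seed(protocol.base_seed, r, held_idx),
            )
            clf.fit(
                train_tab.features(fit_frame),
                fit_frame["label"].to_numpy(dtype=int),
            )
            train_acc = float(
                np.mean(
                    clf.predict(train_tab.features(holdout_frame))
                    == holdout_frame["label"].to_numpy(dtype=int)
                )
            )
            test_frame = test_tab.frame
            test_acc = float(
                np.mean(
                    clf.predict(test_tab.features(test_frame))
                    == test_frame["label"].to_numpy(dtype=int)
                )
            )
            records.append(
                {
                    "repetition": r,
                    "subject": held_out,
                    "train": train_acc,
                    "test": test_acc,
                    "gap": gap(train_acc, test_acc),
                }
            )
    runs = pd.DataFrame(records)
    per_subject = runs.groupby("subject")[["train", "test", "gap"]].agg(
        ["mean", "std"]
    )
    per_subject.columns = [f"{q}_{s.replace('std', 'sd')}" for q, s in per_subject.columns]
    per_subject = per_subject.fillna(0.0)
    pooled = {}
    for kind in ("train", "test", "gap"):
        values = runs[kind].to_numpy()
        pooled[f"{kind}_mean"] = float(values.mean())
        pooled[f"{kind}_sd"] = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return LOSOReport(
        per_subject,
        pooled,
        runs,
        {
            "strategy": strategy,
            "n_trees": n_trees,
            "source_holdout_per_subject": source_holdout,
            "protocol": protocol.__dict__.copy(),
        },
    )


class LOSOEvaluator(BaseEstimator):
    """Estimator-style wrapper around :func:`evaluate_loso`.

    ``fit`` runs the full repeated LOSO protocol and stores ``report_``,
    ``pooled_gap_`` and ``pooled_test_accuracy_``.
    """

    def __init__(
        self,
        strategy: str = "none",
        n_trees: int = 30,
        source_holdout: int = 200,
        protocol: SamplingProtocol = SamplingProtocol(),
    ):
        self.strategy = strategy
        self.n_trees = n_trees
        self.source_holdout = source_holdout
        self.protocol = protocol

    def fit(self, table: FeatureTable, y=None) -> "LOSOEvaluator":
        self.report_ = evaluate_loso(
            table,
            strategy=self.strategy,
            n_trees=self.n_trees,
            source_holdout=self.source_holdout,
            protocol=self.protocol,
        )
        self.pooled_gap_ = self.report_.pooled["gap_mean"]
        self.pooled_test_accuracy_ = self.report_.pooled["test_mean"]
        return self
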