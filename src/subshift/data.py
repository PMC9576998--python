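"""Feature-table data model, I/O, subject partitioning, and resampling protocol.

The central container is a :class:`FeatureTable`: per-epoch feature rows tagged
with a subject id, a session id, a recording phase (``task``, ``baseline1`` or
``baseline2``) and, for task rows, a binary workload label (0 = low, 1 = high).
One subject's task rows form a *domain* — a sample from that subject's
data-generating distribution — represented by :class:`DomainSample`.

Experiments are repeated over seeded subsamples of the table: a fixed number of
task rows is drawn per (subject, session) cell for each repetition, mirroring
the repeated-partition protocol used to report estimate variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "LABEL_NAMES",
    "SchemaError",
    "ValidationError",
    "DataError",
    "FeatureTable",
    "DomainSample",
    "SamplingProtocol",
    "read_feature_table",
    "write_feature_table",
    "partition_by_subject",
    "subsample",
    "split_disjoint",
]

PHASES = ("task", "baseline1", "baseline2")

#: canonical label encoding: low workload -> 0, high workload -> 1
LABEL_NAMES = {"low": 0, "high": 1}

META_COLUMNS = ("subject", "session", "phase", "label")


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class ValidationError(ValueError):
    """The data violate a table invariant (e.g. an unlabeled task row)."""


class DataError(ValueError):
    """The data are structurally valid but unusable for the requested operation."""


@dataclass
class FeatureTable:
    """Labeled per-epoch feature rows.

    Parameters
    ----------
    frame
        DataFrame with columns ``subject``, ``session``, ``phase``, ``label``
        plus one numeric column per feature.  ``label`` is float-coded 0/1 with
        NaN allowed on baseline rows only.
    feature_columns
        Ordered names of the feature columns (length F >= 1).
    """

    frame: pd.DataFrame
    feature_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.feature_columns:
            self.feature_columns = [
                c for c in self.frame.columns if c not in META_COLUMNS
            ]
        self.validate()

    # -- invariants ----------------------------------------------------------

    def validate(self) -> None:
        for col in META_COLUMNS:
            if col not in self.frame.columns:
                raise SchemaError(f"missing required column {col!r}")
        if len(self.feature_columns) < 1:
            raise SchemaError("feature table needs at least one feature column")
        for col in self.feature_columns:
            if col not in self.frame.columns:
                raise SchemaError(f"declared feature column {col!r} not present")
            values = self.frame[col]
            if not pd.api.types.is_numeric_dtype(values):
                bad = values[pd.to_numeric(values, errors="coerce").isna()]
                row = int(bad.index[0]) if len(bad) else -1
                raise ValidationError(
                    f"non-numeric value in feature column {col!r} at row {row}"
                )
            if not np.isfinite(values.to_numpy(dtype=float)).all():
                raise ValidationError(f"non-finite value in feature column {col!r}")
        unknown = set(self.frame["phase"].unique()) - set(PHASES)
        if unknown:
            raise ValidationError(f"unknown phase values {sorted(unknown)}")
        task = self.frame[self.frame["phase"] == "task"]
        if task["label"].isna().any():
            row = int(task.index[task["label"].isna()][0])
            raise ValidationError(f"task row {row} lacks a label")
        labeled = self.frame["label"].dropna()
        if not labeled.isin([0, 1]).all():
            raise ValidationError("labels must be binary (0/1 or low/high)")

    # -- convenience ---------------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.feature_columns)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.frame["subject"].unique())

    def phase_rows(self, phase: str) -> pd.DataFrame:
        if phase not in PHASES:
            raise ValidationError(f"unknown phase {phase!r}")
        return self.frame[self.frame["phase"] == phase]

    def features(self, frame: pd.DataFrame | None = None) -> np.ndarray:
        source = self.frame if frame is None else frame
        return source[self.feature_columns].to_numpy(dtype=float)

    def with_frame(self, frame: pd.DataFrame) -> "FeatureTable":
        return FeatureTable(frame.reset_index(drop=True), list(self.feature_columns))


@dataclass
class DomainSample:
    """One subject's feature matrix and labels — the unit domain D_i."""

    subject_id: str
    X: np.ndarray
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] < 1:
            raise ValidationError(
                f"domain {self.subject_id!r} needs an N x F matrix with N >= 1"
            )
        if self.y is not None:
            self.y = np.asarray(self.y)
            if self.y.shape != (self.X.shape[0],):
                raise ValidationError(
                    f"domain {self.subject_id!r}: labels do not match sample count"
                )
            if not np.isin(self.y, [0, 1]).all():
                raise ValidationError(f"domain {self.subject_id!r}: labels not binary")
            self.y = self.y.astype(int)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class SamplingProtocol:
    """Repeated-subsampling protocol: rows per (subject, session) cell and seed.

    Defaults follow the study conditions: 300 task rows per subject x session,
    30 repetitions, base seed 10.  Repetition ``r`` draws with seed
    ``base_seed + r`` so partitions are distinct but reproducible.
    """

    n_per_cell: int = 300
    n_repetitions: int = 30
    base_seed: int = 10

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValidationError("n_per_cell must be positive")
        if self.n_repetitions < 1:
            raise ValidationError("n_repetitions must be >= 1")


# ---------------------------------------------------------------------------
# I/O


def _sniff_separator(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _coerce_label(values: pd.Series) -> pd.Series:
    def one(v: object) -> float:
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return np.nan
        if isinstance(v, str):
            key = v.strip().lower()
            if key in LABEL_NAMES:
                return float(LABEL_NAMES[key])
            try:
                return float(key)
            except ValueError as exc:
                raise ValidationError(f"unparseable label value {v!r}") from exc
        return float(v)

    return values.map(one)


def read_feature_table(
    path: str, schema: dict[str, str] | None = None
) -> FeatureTable:
    """Read a delimited feature table (comma or tab, auto-detected by header).

    ``schema`` optionally maps the logical column names (``subject``,
    ``session``, ``phase``, ``label``) to the file's actual column names.  All
    remaining columns are treated as features.  When the label column is
    absent, task labels are derived from the session (each session corresponds
    to one workload level; the lexicographically first session maps to low).
    """
    schema = dict(schema or {})
    sep = _sniff_separator(path)
    raw = pd.read_csv(path, sep=sep, dtype={schema.get("subject", "subject"): str})
    rename = {schema.get(k, k): k for k in META_COLUMNS if schema.get(k, k) in raw.columns}
    frame = raw.rename(columns=rename)
    for col in ("subject", "session", "phase"):
        if col not in frame.columns:
            raise SchemaError(f"missing required column {schema.get(col, col)!r}")
    if "label" not in frame.columns:
        sessions = sorted(frame["session"].astype(str).unique())
        if len(sessions) != 2:
            raise SchemaError(
                "no label column and session count != 2; cannot derive labels"
            )
        session_label = {sessions[0]: 0.0, sessions[1]: 1.0}
        frame["label"] = frame["session"].astype(str).map(session_label)
        frame.loc[frame["phase"] != "task", "label"] = np.nan
    else:
        frame["label"] = _coerce_label(frame["label"])
    frame["subject"] = frame["subject"].astype(str)
    frame["session"] = frame["session"].astype(str)
    feature_columns = [c for c in frame.columns if c not in META_COLUMNS]
    if not feature_columns:
        raise SchemaError("no feature columns found")
    return FeatureTable(frame.reset_index(drop=True), feature_columns)


def write_feature_table(table: FeatureTable, path: str, sep: str = ",") -> None:
    frame = table.frame.copy()
    frame["label"] = frame["label"].map(
        lambda v: "" if pd.isna(v) else {0: "low", 1: "high"}[int(v)]
    )
    frame.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# partitioning and subsampling


def partition_by_subject(table: FeatureTable, phase: str = "task") -> list[DomainSample]:
    """Split a phase of the table into per-subject domains, lexicographic order."""
    rows = table.phase_rows(phase)
    if rows.empty:
        raise DataError(f"no rows in phase {phase!r}")
    all_subjects = table.subjects
    present = set(rows["subject"].unique())
    missing = [s for s in all_subjects if s not in present]
    if missing:
        raise DataError(f"phase {phase!r} absent for subjects {missing}")
    domains = []
    for subject in all_subjects:
        sub = rows[rows["subject"] == subject]
        labels = sub["label"]
        y = labels.to_numpy(dtype=float) if not labels.isna().any() else None
        domains.append(DomainSample(subject, table.features(sub), y))
    return domains


def subsample(
    table: FeatureTable, protocol: SamplingProtocol, repetition_index: int
) -> FeatureTable:
    """Draw ``n_per_cell`` task rows per (subject, session) cell, seeded.

    Repetition ``r`` uses seed ``base_seed + r``; identical inputs give
    byte-identical output.  Baseline rows pass through unchanged.  Selected
    rows keep their original order (order-normalized draw).
    """
    rng = np.random.default_rng(protocol.base_seed + repetition_index)
    frame = table.frame
    task_mask = frame["phase"] == "task"
    keep = frame.index[~task_mask].to_list()
    task = frame[task_mask]
    cells = sorted(
        task.groupby(["subject", "session"], sort=True).groups.items(),
        key=lambda kv: kv[0],
    )
    for (subject, session), idx in cells:
        idx = np.asarray(idx)
        if len(idx) < protocol.n_per_cell:
            raise DataError(
                f"cell (subject={subject!r}, session={session!r}) has "
                f"{len(idx)} rows < n_per_cell={protocol.n_per_cell}"
            )
        chosen = rng.choice(idx, size=protocol.n_per_cell, replace=False)
        keep.extend(np.sort(chosen).tolist())
    out = frame.loc[sorted(keep)]
    return table.with_frame(out)


def split_disjoint(
    domain: DomainSample, train_fraction: float, seed: int
) -> tuple[DomainSample, DomainSample]:
    """Label-stratified disjoint split of one domain into (train, test)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must lie in (0, 1)")
    if domain.y is None:
        raise ValidationError("split_disjoint requires a labeled domain")
    classes = np.unique(domain.y)
    if len(classes) < 2:
        raise DataError(f"domain {domain.subject_id!r} has a single class")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in classes:
        members = np.flatnonzero(domain.y == c)
        if len(members) < 2:
            raise DataError(
                f"domain {domain.subject_id!r}: class {c} has < 2 members"
            )
        perm = rng.permutation(members)
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_idx = np.sort(np.asarray(train_idx))
    test_idx = np.sort(np.asarray(test_idx))
    make = lambda idx: DomainSample(domain.subject_id, domain.X[idx], domain.y[idx])
    return make(train_idx), make(test_idx)
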