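"""Feature-table I/O, subject partitioning, subsampling, stratified splits."""

import numpy as np
import pandas as pd
import pytest

from subshift import (
    DataError,
    DomainSample,
    SamplingProtocol,
    SchemaError,
    ValidationError,
    partition_by_subject,
    read_feature_table,
    split_disjoint,
    subsample,
    write_feature_table,
)

CSV = """subject,session,phase,label,f1,f2
S0,low,task,low,0.1,0.2
S0,high,task,high,0.3,0.4
S1,low,task,low,0.5,0.6
S1,high,task,high,0.7,0.8
"""


def test_read_feature_table_parses_labeled_task_rows(tmp_path):
    path = tmp_path / "table.csv"
    path.write_text(CSV)
    table = read_feature_table(str(path))
    assert table.n_features == 2
    assert len(table.frame) == 4
    assert table.frame["label"].tolist() == [0.0, 1.0, 0.0, 1.0]


def test_read_feature_table_autodetects_tab_delimiter(tmp_path):
    path = tmp_path / "table.tsv"
    path.write_text(CSV.replace(",", "\t"))
    assert read_feature_table(str(path)).n_features == 2


def test_baseline_row_may_omit_label(tmp_path):
    path = tmp_path / "table.csv"
    path.write_text(CSV + "S0,rest,baseline1,,0.9,1.0\n")
    table = read_feature_table(str(path))
    assert table.frame["label"].isna().sum() == 1


def test_unlabeled_task_row_rejected(tmp_path):
    path = tmp_path / "table.csv"
    path.write_text(CSV + "S1,low,task,,0.9,1.0\n")
    with pytest.raises(ValidationError, match="lacks a label"):
        read_feature_table(str(path))


def test_missing_column_names_the_column(tmp_path):
    path = tmp_path / "table.csv"
    path.write_text("subject,session,label,f1\nS0,low,low,1.0\n")
    with pytest.raises(SchemaError, match="phase"):
        read_feature_table(str(path))


def test_non_numeric_feature_cell_rejected(tmp_path):
    path = tmp_path / "table.csv"
    path.write_text(CSV + "S1,high,task,high,oops,1.0\n")
    with pytest.raises(ValidationError, match="f1"):
        read_feature_table(str(path))


def test_labels_derived_from_session_when_column_absent(tmp_path):
    path = tmp_path / "table.csv"
    path.write_text(
        "subject,session,phase,f1\nS0,a,task,0.1\nS0,b,task,0.2\n"
    )
    table = read_feature_table(str(path))
    assert table.frame["label"].tolist() == [0.0, 1.0]


def test_roundtrip_write_read(tmp_path, small_table):
    path = tmp_path / "out.csv"
    write_feature_table(small_table, str(path))
    back = read_feature_table(str(path))
    np.testing.assert_allclose(back.features(), small_table.features())


def test_partition_orders_subjects_lexicographically(small_table):
    domains = partition_by_subject(small_table, "task")
    assert [d.subject_id for d in domains] == ["S0", "S1"]
    assert all(d.n == 24 for d in domains)


def test_partition_rows_cover_the_phase_exactly(small_table):
    domains = partition_by_subject(small_table, "task")
    total = sum(d.n for d in domains)
    assert total == len(small_table.phase_rows("task"))
    # per-subject rows match the filtered table exactly
    for d in domains:
        rows = small_table.phase_rows("task")
        rows = rows[rows["subject"] == d.subject_id]
        np.testing.assert_array_equal(d.X, small_table.features(rows))


def test_partition_empty_phase_errors(small_table):
    task_only = small_table.with_frame(small_table.phase_rows("task"))
    domains = partition_by_subject(task_only, "task")
    assert len(domains) == 2
    with pytest.raises(DataError):
        partition_by_subject(task_only, "baseline1")


def test_subsample_is_deterministic_and_contained(small_table):
    protocol = SamplingProtocol(n_per_cell=8, n_repetitions=2, base_seed=10)
    one = subsample(small_table, protocol, 0)
    two = subsample(small_table, protocol, 0)
    pd.testing.assert_frame_equal(one.frame, two.frame)
    other = subsample(small_table, protocol, 1)
    assert not one.frame.equals(other.frame)
    # containment: every subsampled row exists in the input
    merged = one.frame.merge(small_table.frame, how="left", indicator=True)
    assert (merged["_merge"] == "both").all()


def test_subsample_counts_and_baseline_passthrough(small_table):
    protocol = SamplingProtocol(n_per_cell=8, n_repetitions=1, base_seed=10)
    out = subsample(small_table, protocol, 0)
    task = out.phase_rows("task")
    assert task.groupby(["subject", "session"]).size().eq(8).all()
    assert len(out.phase_rows("baseline1")) == len(small_table.phase_rows("baseline1"))


def test_subsample_full_cell_returned_whole(small_table):
    protocol = SamplingProtocol(n_per_cell=12, n_repetitions=1, base_seed=10)
    out = subsample(small_table, protocol, 0)
    pd.testing.assert_frame_equal(
        out.phase_rows("task").reset_index(drop=True),
        small_table.phase_rows("task").reset_index(drop=True),
    )


def test_subsample_undersized_cell_names_cell(small_table):
    protocol = SamplingProtocol(n_per_cell=13, n_repetitions=1, base_seed=10)
    with pytest.raises(DataError, match=r"S0.*12 rows"):
        subsample(small_table, protocol, 0)


@pytest.mark.parametrize("seed", [0, 1, 7])
def test_split_disjoint_partitions_exactly(seed):
    rng = np.random.default_rng(seed)
    domain = DomainSample("S", rng.normal(size=(100, 3)), np.repeat([0, 1], 50))
    train, test = split_disjoint(domain, 0.5, seed)
    assert train.n == test.n == 50
    assert np.bincount(train.y).tolist() == [25, 25]
    # disjoint and exhaustive on row identities
    all_rows = {tuple(r) for r in domain.X}
    train_rows = {tuple(r) for r in train.X}
    test_rows = {tuple(r) for r in test.X}
    assert train_rows | test_rows == all_rows
    assert not train_rows & test_rows


def test_split_disjoint_smallest_balanced_case():
    domain = DomainSample("S", np.arange(8).reshape(4, 2), [0, 1, 0, 1])
    train, test = split_disjoint(domain, 0.5, 0)
    assert train.n == test.n == 2
    assert sorted(train.y) == sorted(test.y) == [0, 1]


def test_split_disjoint_single_class_errors():
    domain = DomainSample("S", np.zeros((4, 2)), [1, 1, 1, 1])
    with pytest.raises(DataError):
        split_disjoint(domain, 0.5, 0)
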