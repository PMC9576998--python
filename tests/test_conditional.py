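"""Conditional-shift estimation: k-NN labeling functions and disparity matrix."""

import numpy as np
import pytest

from subshift import (
    ConditionalShiftEstimator,
    DataError,
    DisparityMatrix,
    DomainSample,
    SamplingProtocol,
    aggregate_disparity,
    disparity_matrix,
    fit_labeling_function,
    pairwise_disparity,
    repeated_conditional_estimate,
)
from subshift.conditional import KNNLabelingFunction


def test_one_nn_predicts_nearest_reference():
    f = KNNLabelingFunction("S", 1, [[0.0], [1.0]], [0, 1])
    assert f.predict([[0.1]])[0] == 0
    assert f.predict([[0.9]])[0] == 1


def test_distance_tie_resolves_to_lowest_reference_index():
    f = KNNLabelingFunction("S", 1, [[0.0], [1.0]], [1, 0])
    # query 0.5 is equidistant; the lower-index reference (label 1) wins
    assert f.predict([[0.5]])[0] == 1


def test_vote_tie_resolves_to_label_zero():
    f = KNNLabelingFunction("S", 4, [[0.0], [1.0], [2.0], [3.0]], [0, 0, 1, 1])
    assert f.predict([[1.5]])[0] == 0


def test_fit_rejects_single_class_and_large_k():
    domain = DomainSample("S", np.arange(6).reshape(3, 2), [1, 1, 1])
    with pytest.raises(DataError):
        fit_labeling_function(domain, k=1)
    balanced = DomainSample("S", np.arange(8).reshape(4, 2), [0, 1, 0, 1])
    with pytest.raises(Exception):
        fit_labeling_function(balanced, k=5)


def test_pairwise_disparity_extremes():
    domain = DomainSample("A", [[0.0], [1.0]], [0, 1])
    agree = KNNLabelingFunction("B", 1, [[0.0], [1.0]], [0, 1])
    flip = KNNLabelingFunction("B", 1, [[0.0], [1.0]], [1, 0])
    assert pairwise_disparity(domain, agree) == 0.0
    assert pairwise_disparity(domain, flip) == 1.0


def test_pairwise_disparity_hand_worked_example():
    # domain i: 4 points labeled [0,0,1,0]; f~_j is 1-NN on {0.0->0, 1.0->1};
    # queries [0.1,0.2,0.9,0.8] predict [0,0,1,1] -> one disagreement of four
    domain = DomainSample("A", [[0.1], [0.2], [0.9], [0.8]], [0, 0, 1, 0])
    f_j = KNNLabelingFunction("B", 1, [[0.0], [1.0]], [0, 1])
    assert pairwise_disparity(domain, f_j) == 0.25


def test_pairwise_disparity_dimension_mismatch():
    domain = DomainSample("A", [[0.0, 1.0]], [0])
    f = KNNLabelingFunction("B", 1, [[0.0]], [0])
    with pytest.raises(DataError):
        pairwise_disparity(domain, f)


def make_separable(subject, n, rng, shift=0.0):
    # classes separated by a true margin along the first coordinate
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 2))
    X[:, 0] = (2.0 * y - 1.0) * rng.uniform(0.5, 2.5, size=n)
    return DomainSample(subject, X + shift, y)


def test_identical_separable_domains_give_small_disparity():
    rng = np.random.default_rng(0)
    domains = [make_separable(s, 200, rng) for s in ("A", "B")]
    matrix = disparity_matrix(domains, k=1, seed=0)
    assert matrix.D.max() < 0.05


def test_matrix_is_exactly_symmetric_with_min_rule():
    rng = np.random.default_rng(1)
    domains = [make_separable(s, 60, rng, shift=i) for i, s in enumerate("ABC")]
    matrix = disparity_matrix(domains, k=3, seed=1)
    np.testing.assert_array_equal(matrix.D, matrix.D.T)
    for i in range(3):
        for j in range(3):
            if i != j:
                assert matrix.D[i, j] == min(matrix.mu[i, j], matrix.mu[j, i])


def test_aggregate_closed_forms():
    zero = DisparityMatrix(["a", "b"], np.zeros((2, 2)), np.zeros((2, 2)))
    assert aggregate_disparity(zero) == 0.0
    ones = DisparityMatrix(["a", "b", "c"], np.ones((3, 3)), np.ones((3, 3)))
    assert aggregate_disparity(ones) == pytest.approx(1.0)
    half = DisparityMatrix(
        ["a", "b"], np.array([[0.0, 0.5], [0.5, 0.0]]), np.zeros((2, 2))
    )
    assert aggregate_disparity(half) == pytest.approx(np.sqrt(0.5) / 2)


def test_repeated_estimate_determinism_and_length(cohort):
    protocol = SamplingProtocol(n_per_cell=40, n_repetitions=2, base_seed=10)
    one = repeated_conditional_estimate(cohort, protocol, strategy="none", k=5)
    two = repeated_conditional_estimate(cohort, protocol, strategy="none", k=5)
    assert one.aggregates == two.aggregates
    assert len(one.aggregates) == 2
    np.testing.assert_array_equal(one.mean_matrix, two.mean_matrix)
    single = SamplingProtocol(n_per_cell=40, n_repetitions=1, base_seed=10)
    assert len(repeated_conditional_estimate(cohort, single).aggregates) == 1


def test_estimator_class_fits_from_arrays():
    rng = np.random.default_rng(2)
    domains = [make_separable(s, 80, rng) for s in ("B", "A")]
    X = np.vstack([d.X for d in domains])
    y = np.concatenate([d.y for d in domains])
    groups = np.concatenate([[d.subject_id] * d.n for d in domains])
    est = ConditionalShiftEstimator(k=3, random_state=0).fit(X, y, groups)
    assert est.subjects_ == ["A", "B"]  # lexicographic axis order
    assert est.disparity_matrix_.shape == (2, 2)
    assert 0.0 <= est.aggregate_ <= 1.0
    assert est.get_params()["k"] == 3
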