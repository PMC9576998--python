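"""Cross-subject conditional (labeling-function) shift estimation.

Each subject's unknown labeling rule f_i is approximated by a k-nearest-
neighbor classifier f̃_i trained on that subject's labeled sample.  The
disagreement of subject i's labels with subject j's approximated rule,

    μ_{i,j} = (1/N) Σ_n 1[ y_n^i ≠ f̃_j(x_n^i) ],

is the empirical estimate of E_{D_i}[|f_i − f_j|].  Pairs are symmetrized as
d_{i,j} = min(μ_{i,j}, μ_{j,i}) into a symmetric disparity matrix D whose
diagonal is estimated on a disjoint train/test split of each subject's own
data (it measures how well the labeling rule can be approximated at all; it
is 0 for perfect approximations).  The scalar aggregate is the Frobenius norm
of D rescaled to [0, 1] by dividing by M, the largest norm attainable by an
M x M matrix with entries in [0, 1].

The k-NN predictor is deterministic by contract: distance ties resolve to the
lowest reference-point index, vote ties to label 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .data import (
    DataError,
    DomainSample,
    FeatureTable,
    SamplingProtocol,
    ValidationError,
    partition_by_subject,
    split_disjoint,
    subsample,
)
from .normalization import SubjectNormalizer
from .util import derive_seed

__all__ = [
    "KNNLabelingFunction",
    "fit_labeling_function",
    "pairwise_disparity",
    "DisparityMatrix",
    "disparity_matrix",
    "aggregate_disparity",
    "ConditionalShiftEstimator",
    "RepeatedShiftResult",
    "repeated_conditional_estimate",
]


@dataclass
class KNNLabelingFunction:
    """Deterministic k-NN approximation f̃_j of one subject's labeling rule."""

    source_subject: str
    k: int
    X_ref: np.ndarray
    y_ref: np.ndarray

    def __post_init__(self) -> None:
        self.X_ref = np.asarray(self.X_ref, dtype=float)
        self.y_ref = np.asarray(self.y_ref, dtype=int)
        if self.k < 1 or self.k > len(self.X_ref):
            raise ValidationError(
                f"k={self.k} outside [1, N={len(self.X_ref)}] for subject "
                f"{self.source_subject!r}"
            )

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.X_ref.shape[1]:
            raise DataError(
                f"feature dimension {X.shape[1]} does not match reference "
                f"dimension {self.X_ref.shape[1]}"
            )
        dist = cdist(X, self.X_ref)
        # stable sort: equidistant references resolve to the lowest index
        order = np.argsort(dist, axis=1, kind="stable")[:, : self.k]
        votes = self.y_ref[order].sum(axis=1)
        # strict majority for label 1; exact tie resolves to label 0
        return (2 * votes > self.k).astype(int)


def fit_labeling_function(
    domain: DomainSample, k: int = 5, seed: int | None = None
) -> KNNLabelingFunction:
    """Train f̃_j on one domain.  The predictor is deterministic; ``seed`` is
    accepted for interface symmetry and recorded nowhere."""
    if domain.y is None:
        raise ValidationError(f"domain {domain.subject_id!r} is unlabeled")
    if len(np.unique(domain.y)) < 2:
        raise DataError(f"domain {domain.subject_id!r} has a single class")
    return KNNLabelingFunction(domain.subject_id, k, domain.X, domain.y)


def pairwise_disparity(domain_i: DomainSample, f_tilde_j: KNNLabelingFunction) -> float:
    """Empirical disagreement μ_{i,j} of domain i's labels with f̃_j."""
    if domain_i.y is None:
        raise ValidationError(f"domain {domain_i.subject_id!r} is unlabeled")
    pred = f_tilde_j.predict(domain_i.X)
    return float(np.mean(pred != domain_i.y))


@dataclass
class DisparityMatrix:
    """Symmetric M x M conditional-shift matrix with its raw μ entries."""

    subjects: list[str]
    D: np.ndarray
    mu: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        m = len(self.subjects)
        if self.D.shape != (m, m):
            raise ValidationError("disparity matrix shape does not match subjects")
        if not np.array_equal(self.D, self.D.T):
            raise ValidationError("disparity matrix must be exactly symmetric")
        if self.D.min() < 0 or self.D.max() > 1:
            raise ValidationError("disparity entries must lie in [0, 1]")


def disparity_matrix(
    domains: list[DomainSample],
    k: int = 5,
    train_fraction: float = 0.5,
    seed: int = 10,
) -> DisparityMatrix:
    """Full pairwise conditional-shift matrix over M >= 2 labeled domains.

    Off-diagonal: d_{i,j} = min(μ_{i,j}, μ_{j,i}) with f̃ fit on the full
    opposing domain.  Diagonal: disagreement of f̃_i fit on a stratified
    train half with the held-out half of the same subject.
    """
    m = len(domains)
    if m < 2:
        raise DataError("need at least two domains")
    approx = [fit_labeling_function(d, k=k) for d in domains]
    mu = np.zeros((m, m))
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            if i != j:
                mu[i, j] = pairwise_disparity(domains[i], approx[j])
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = min(mu[i, j], mu[j, i])
        train, test = split_disjoint(
            domains[i], train_fraction, derive_seed(seed, i)
        )
        f_self = fit_labeling_function(train, k=min(k, train.n))
        D[i, i] = mu[i, i] = pairwise_disparity(test, f_self)
    return DisparityMatrix(
        [d.subject_id for d in domains],
        D,
        mu,
        {"k": k, "seed": seed, "train_fraction": train_fraction},
    )


def aggregate_disparity(matrix: DisparityMatrix) -> float:
    """Frobenius norm of D rescaled to [0, 1] (divide by M)."""
    m = len(matrix.subjects)
    return float(np.linalg.norm(matrix.D, "fro") / m)


class ConditionalShiftEstimator(BaseEstimator):
    """Estimator interface for the conditional-shift disparity matrix.

    Parameters
    ----------
    k : neighbors of the labeling-function approximation (odd avoids vote ties).
    train_fraction : stratified split fraction for the diagonal self-estimates.
    random_state : seed for the diagonal splits.

    Attributes (after :meth:`fit`)
    ------------------------------
    subjects_ : lexicographically ordered subject ids (matrix axes).
    mu_ : raw M x M disagreement matrix μ.
    disparity_matrix_ : symmetrized M x M matrix D.
    aggregate_ : rescaled Frobenius aggregate in [0, 1].
    result_ : the full :class:`DisparityMatrix`.
    """

    def __init__(self, k: int = 5, train_fraction: float = 0.5, random_state: int = 10):
        self.k = k
        self.train_fraction = train_fraction
        self.random_state = random_state

    def fit(self, X, y=None, groups=None) -> "ConditionalShiftEstimator":
        """Fit from per-subject domains.

        ``X`` may be a list of :class:`DomainSample`, or an (N, F) array with
        ``y`` the binary labels and ``groups`` the subject id per row (domains
        are then formed in lexicographic subject order).
        """
        domains = _as_domains(X, y, groups)
        self.result_ = disparity_matrix(
            domains, k=self.k, train_fraction=self.train_fraction,
            seed=self.random_state,
        )
        self.subjects_ = self.result_.subjects
        self.mu_ = self.result_.mu
        self.disparity_matrix_ = self.result_.D
        self.aggregate_ = aggregate_disparity(self.result_)
        return self


def _as_domains(X, y=None, groups=None) -> list[DomainSample]:
    if isinstance(X, FeatureTable):
        return partition_by_subject(X, "task")
    if len(X) and isinstance(X[0], DomainSample):
        return sorted(X, key=lambda d: d.subject_id)
    if groups is None:
        raise ValidationError("groups (subject ids) required for array input")
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    domains = []
    for subject in sorted(np.unique(groups).tolist()):
        mask = groups == subject
        sub_y = None if y is None else np.asarray(y)[mask]
        domains.append(DomainSample(str(subject), X[mask], sub_y))
    return domains


# ---------------------------------------------------------------------------
# repeated protocol


@dataclass
class RepeatedShiftResult:
    """Aggregates over repetitions plus the element-wise mean matrix."""

    aggregates: list[float]
    mean: float
    sd: float
    subjects: list[str]
    mean_matrix: np.ndarray
    per_subject_mean: np.ndarray  # column means over off-diagonal entries
    metadata: dict = field(default_factory=dict)


def _repeated_estimate(
    table: FeatureTable,
    protocol: SamplingProtocol,
    strategy: str,
    matrix_fn,
    aggregate_fn,
) -> RepeatedShiftResult:
    aggregates: list[float] = []
    mean_matrix = None
    subjects: list[str] = []
    for r in range(protocol.n_repetitions):
        sub = subsample(table, protocol, r)
        normalized = SubjectNormalizer(strategy).fit_transform(sub)
        domains = partition_by_subject(normalized, "task")
        result = matrix_fn(domains, derive_seed(protocol.base_seed, r))
        values = result.D if hasattr(result, "D") else result.H
        subjects = result.subjects
        mean_matrix = values if mean_matrix is None else mean_matrix + values
        aggregates.append(aggregate_fn(result))
    mean_matrix = mean_matrix / protocol.n_repetitions
    off_diag = mean_matrix.copy()
    np.fill_diagonal(off_diag, np.nan)
    per_subject = np.nanmean(off_diag, axis=0)
    arr = np.asarray(aggregates)
    return RepeatedShiftResult(
        aggregates,
        float(arr.mean()),
        float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        subjects,
        mean_matrix,
        per_subject,
        {"strategy": strategy, "protocol": protocol.__dict__.copy()},
    )


def repeated_conditional_estimate(
    table: FeatureTable,
    protocol: SamplingProtocol = SamplingProtocol(),
    strategy: str = "none",
    k: int = 5,
    train_fraction: float = 0.5,
) -> RepeatedShiftResult:
    """One conditional-shift aggregate per seeded repetition, plus the mean
    disparity matrix and per-subject average cross-subject disparity."""
    result = _repeated_estimate(
        table,
        protocol,
        strategy,
        lambda domains, seed: disparity_matrix(
            domains, k=k, train_fraction=train_fraction, seed=seed
        ),
        aggregate_disparity,
    )
    result.metadata.update({"estimator": "conditional", "k": k})
    return result
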