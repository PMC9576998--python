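"""Cross-subject marginal shift via the H-divergence classifier proxy.

The H-divergence between two feature distributions,

    d_H[D_i, D_j] = 2 sup_{η ∈ H} | Pr_{D_i}[η(x)=1] − Pr_{D_j}[η(x)=1] |,

is estimable from the error ε of a binary classifier trained to tell the two
samples apart: a low discrimination error means a large divergence.  Here the
discriminator is a 20-tree random forest and ε is estimated by stratified
5-fold cross-validation on the pooled pair, with workload labels ignored (the
marginal estimator never reads y).  Matrix entries store the discriminator
*accuracy* (1 − ε): reported results in this field use that scale, where
higher values mean the pair is easier to discriminate, i.e. a larger marginal
shift.  ``h_divergence_proxy`` exposes the 2(1 − 2ε) transform.

Class balance per pair is enforced by a seeded truncation of the larger
sample, so chance level is exactly 0.5.  Diagonal entries are estimated from
a random half-vs-half split of a subject's own sample and sit at chance for
exchangeable data.  The scalar aggregate is ||H||_F / M, as for the
conditional disparity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .data import DataError, DomainSample, FeatureTable, SamplingProtocol
from .conditional import RepeatedShiftResult, _as_domains, _repeated_estimate
from .util import derive_seed

__all__ = [
    "pairwise_divergence",
    "h_divergence_proxy",
    "DivergenceMatrix",
    "divergence_matrix",
    "aggregate_divergence",
    "MarginalShiftEstimator",
    "repeated_marginal_estimate",
]


def pairwise_divergence(
    domain_i: DomainSample,
    domain_j: DomainSample,
    n_folds: int = 5,
    n_trees: int = 20,
    seed: int = 10,
    min_samples_leaf: int = 5,
) -> float:
    """Mean cross-validated accuracy of the pairwise subject discriminator.

    The two domains are pooled with labels = domain identity; equal sample
    sizes are enforced by seeded truncation of the larger domain.  Returns a
    value in [0, 1]; ~0.5 for indistinguishable marginals.
    """
    if domain_i.X.shape[1] != domain_j.X.shape[1]:
        raise DataError("feature dimensions differ between domains")
    n = min(domain_i.n, domain_j.n)
    if n < n_folds:
        raise DataError(
            f"domains need >= n_folds={n_folds} points each (smallest has {n})"
        )
    rng = np.random.default_rng(seed)

    def take(domain: DomainSample) -> np.ndarray:
        if domain.n == n:
            return domain.X
        idx = np.sort(rng.choice(domain.n, size=n, replace=False))
        return domain.X[idx]

    X = np.vstack([take(domain_i), take(domain_j)])
    d = np.repeat([0, 1], n)
    clf = RandomForestClassifier(
        n_estimators=n_trees, min_samples_leaf=min_samples_leaf, random_state=seed
    )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(clf, X, d, cv=cv, scoring="accuracy")
    return float(scores.mean())


def h_divergence_proxy(accuracy: float) -> float:
    """Proxy A-distance 2(1 − 2ε) from discriminator accuracy (ε = 1 − acc)."""
    return 2.0 * (1.0 - 2.0 * (1.0 - accuracy))


@dataclass
class DivergenceMatrix:
    """Symmetric M x M marginal-shift matrix of discriminator accuracies."""

    subjects: list[str]
    H: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        m = len(self.subjects)
        if self.H.shape != (m, m):
            raise DataError("divergence matrix shape does not match subjects")
        if not np.array_equal(self.H, self.H.T):
            raise DataError("divergence matrix must be exactly symmetric")
        if self.H.min() < 0 or self.H.max() > 1:
            raise DataError("divergence entries must lie in [0, 1]")
        self.metadata.setdefault("entry_semantics", "accuracy")

    def as_error(self) -> np.ndarray:
        """The same matrix on the error-rate scale ε = 1 − accuracy."""
        return 1.0 - self.H


def divergence_matrix(
    domains: list[DomainSample],
    n_trees: int = 20,
    n_folds: int = 5,
    seed: int = 10,
    min_samples_leaf: int = 5,
) -> DivergenceMatrix:
    """Pairwise marginal-shift matrix; each pair computed once (exact symmetry).

    The diagonal uses a seeded half-vs-half split of the subject's own data
    and is expected to sit at chance (≈0.5) — an honest finite-sample floor.
    """
    m = len(domains)
    if m < 2:
        raise DataError("need at least two domains")
    H = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            H[i, j] = H[j, i] = pairwise_divergence(
                domains[i], domains[j], n_folds=n_folds, n_trees=n_trees,
                seed=derive_seed(seed, i, j), min_samples_leaf=min_samples_leaf,
            )
    for i in range(m):
        d = domains[i]
        rng = np.random.default_rng(derive_seed(seed, i, i))
        perm = rng.permutation(d.n)
        half = d.n // 2
        left = DomainSample(d.subject_id, d.X[np.sort(perm[:half])])
        right = DomainSample(d.subject_id, d.X[np.sort(perm[half:])])
        H[i, i] = pairwise_divergence(
            left, right, n_folds=n_folds, n_trees=n_trees,
            seed=derive_seed(seed, i, i), min_samples_leaf=min_samples_leaf,
        )
    return DivergenceMatrix(
        [d.subject_id for d in domains],
        H,
        {"n_trees": n_trees, "n_folds": n_folds, "seed": seed,
         "min_samples_leaf": min_samples_leaf, "entry_semantics": "accuracy"},
    )


def aggregate_divergence(matrix: DivergenceMatrix) -> float:
    """Frobenius norm of H rescaled to [0, 1] (divide by M)."""
    m = len(matrix.subjects)
    return float(np.linalg.norm(matrix.H, "fro") / m)


class MarginalShiftEstimator(BaseEstimator):
    """Estimator interface for the marginal-shift divergence matrix.

    Parameters
    ----------
    n_trees : size of the random-forest subject discriminator.
    n_folds : stratified cross-validation folds per pair.
    random_state : base seed; per-cell seeds are derived from it.

    Attributes (after :meth:`fit`)
    ------------------------------
    subjects_, divergence_matrix_, aggregate_, result_ : as for the
    conditional estimator; entries are discriminator accuracies.
    """

    def __init__(
        self,
        n_trees: int = 20,
        n_folds: int = 5,
        min_samples_leaf: int = 5,
        random_state: int = 10,
    ):
        self.n_trees = n_trees
        self.n_folds = n_folds
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y=None, groups=None) -> "MarginalShiftEstimator":
        domains = _as_domains(X, y, groups)
        self.result_ = divergence_matrix(
            domains, n_trees=self.n_trees, n_folds=self.n_folds,
            min_samples_leaf=self.min_samples_leaf, seed=self.random_state,
        )
        self.subjects_ = self.result_.subjects
        self.divergence_matrix_ = self.result_.H
        self.aggregate_ = aggregate_divergence(self.result_)
        return self


def repeated_marginal_estimate(
    table: FeatureTable,
    protocol: SamplingProtocol = SamplingProtocol(),
    strategy: str = "none",
    n_trees: int = 20,
    n_folds: int = 5,
) -> RepeatedShiftResult:
    """One marginal-shift aggregate per seeded repetition plus the mean matrix."""
    result = _repeated_estimate(
        table,
        protocol,
        strategy,
        lambda domains, seed: divergence_matrix(
            domains, n_trees=n_trees, n_folds=n_folds, seed=seed
        ),
        aggregate_divergence,
    )
    result.metadata.update(
        {"estimator": "marginal", "n_trees": n_trees, "n_folds": n_folds}
    )
    return result
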