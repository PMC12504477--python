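"""Response-heterogeneity analysis.

Each response is a set of acupoints; within a case, heterogeneity of a
rater group is the mean pairwise Jaccard dissimilarity of its responses.
Because the two groups compared here differ sharply in size (a panel of
80 clinicians vs 10 LLM runs), uncertainty is characterised with
size-matched bootstrap percentile intervals, and homogeneity of
multivariate dispersions is tested with PERMDISP: the Jaccard distance
matrix is embedded by principal coordinates analysis (PCoA), distances
to group centroids are compared by a one-way F statistic, and the
p-value comes from permuting group labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core_data import CaseDataset, ValidationError

__all__ = [
    "DistanceMatrix",
    "BootstrapCI",
    "PCoAEmbedding",
    "DispersionTestResult",
    "jaccard_dissimilarity",
    "pairwise_distance_matrix",
    "mean_pairwise_dissimilarity",
    "bootstrap_difference_ci",
    "pcoa_embedding",
    "permdisp",
]

#: eigenvalues with |λ| below this fraction of max|λ| are treated as zero
EIGEN_TOL = 1e-8


def jaccard_dissimilarity(s1: frozenset[str] | set[str], s2: frozenset[str] | set[str]) -> float:
    """Jaccard dissimilarity ``1 - |s1 ∩ s2| / |s1 ∪ s2|``.

    Two empty sets are identical by convention (distance 0).
    """
    union = len(s1 | s2)
    if union == 0:
        return 0.0
    return 1.0 - len(s1 & s2) / union


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric dissimilarity matrix over labelled responses."""

    ids: tuple[str, ...]
    d: np.ndarray
    labels: Mapping[str, str]  # id -> group label

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValidationError("distance matrix is not symmetric")

    def group_indices(self, group: str) -> np.ndarray:
        idx = np.array([i for i, rid in enumerate(self.ids) if self.labels[rid] == group])
        return idx

    @property
    def group_labels(self) -> np.ndarray:
        return np.array([self.labels[rid] for rid in self.ids])


def pairwise_distance_matrix(dataset: CaseDataset, case_id: str) -> DistanceMatrix:
    """All pairwise Jaccard dissimilarities between responses of one case,
    across every group.  Row ids are ``group:rater_id`` in dataset order."""
    responses = dataset.case_responses(case_id)
    if len(responses) < 2:
        raise ValidationError(f"case {case_id!r} has fewer than 2 responses")
    codes = sorted(set().union(*(r.acupoints for r in responses)))
    if codes:
        index = {c: j for j, c in enumerate(codes)}
        X = np.zeros((len(responses), len(codes)), dtype=bool)
        for i, r in enumerate(responses):
            for c in r.acupoints:
                X[i, index[c]] = True
        d = squareform(pdist(X, metric="jaccard"))
    else:  # all responses empty: identical sets
        d = np.zeros((len(responses), len(responses)))
    ids = tuple(f"{r.group}:{r.rater_id}" for r in responses)
    labels = {f"{r.group}:{r.rater_id}": r.group for r in responses}
    return DistanceMatrix(ids=ids, d=d, labels=labels)


def _pair_mean(d: np.ndarray) -> float:
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def mean_pairwise_dissimilarity(matrix: DistanceMatrix, group: str) -> float:
    """Mean Jaccard dissimilarity over all unordered within-group pairs."""
    idx = matrix.group_indices(group)
    if len(idx) < 2:
        raise ValidationError(f"group {group!r} has fewer than 2 members")
    return _pair_mean(matrix.d[np.ix_(idx, idx)])


@dataclass(frozen=True)
class BootstrapCI:
    statistic_name: str
    point: float
    lower: float
    upper: float
    n_boot: int
    seed: int


def _bootstrap_group_means(
    d: np.ndarray, idx: np.ndarray, size: int, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean pairwise dissimilarity of ``n_boot`` with-replacement resamples
    of the rows in ``idx``, each of the given size.  Resamples collapsing
    to a single distinct response are redrawn."""
    sub = d[np.ix_(idx, idx)]
    m = len(idx)
    draws = rng.integers(0, m, size=(n_boot, size))
    # a resample must contain >= 2 distinct responses to define pairs
    bad = np.ptp(draws, axis=1) == 0 if m > 1 else np.ones(n_boot, dtype=bool)
    while bad.any():
        draws[bad] = rng.integers(0, m, size=(int(bad.sum()), size))
        bad = np.ptp(np.sort(draws, axis=1), axis=1) == 0
    iu = np.triu_indices(size, k=1)
    pair_d = sub[draws[:, iu[0]], draws[:, iu[1]]]
    return pair_d.mean(axis=1)


def bootstrap_difference_ci(
    dataset: CaseDataset,
    case_id: str,
    group_a: str,
    group_b: str,
    n_boot: int = 2000,
    match_size: bool = True,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap CI for the difference (a - b) in mean pairwise
    Jaccard dissimilarity between two groups of one case.

    Each replicate resamples responses with replacement within each
    group; with ``match_size`` both groups are resampled at the smaller
    group's size, removing the mechanical effect of unequal panel sizes.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    matrix = pairwise_distance_matrix(dataset, case_id)
    ia, ib = matrix.group_indices(group_a), matrix.group_indices(group_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValidationError("both groups need >= 2 responses")
    point = mean_pairwise_dissimilarity(matrix, group_a) - mean_pairwise_dissimilarity(
        matrix, group_b
    )
    size_a, size_b = len(ia), len(ib)
    if match_size:
        size_a = size_b = min(size_a, size_b)
    rng = np.random.default_rng(seed)
    reps_a = _bootstrap_group_means(matrix.d, ia, size_a, n_boot, rng)
    reps_b = _bootstrap_group_means(matrix.d, ib, size_b, n_boot, rng)
    diffs = reps_a - reps_b
    lower, upper = np.percentile(diffs, [2.5, 97.5])
    return BootstrapCI(
        statistic_name=f"mean_pairwise_dissimilarity[{group_a}-{group_b}]",
        point=float(point),
        lower=float(lower),
        upper=float(upper),
        n_boot=n_boot,
        seed=seed,
    )


@dataclass(frozen=True)
class PCoAEmbedding:
    """Principal-coordinates embedding split by eigenvalue sign.

    ``coords_pos`` spans the axes with positive eigenvalues (coordinates
    scaled by sqrt(λ)); ``coords_neg`` the imaginary axes with negative
    eigenvalues (scaled by sqrt(-λ)).  Non-Euclidean dissimilarities such
    as Jaccard matrices routinely produce negative eigenvalues.
    """

    coords_pos: np.ndarray
    coords_neg: np.ndarray
    eigvals_pos: np.ndarray
    eigvals_neg: np.ndarray


def pcoa_embedding(matrix: DistanceMatrix | np.ndarray) -> PCoAEmbedding:
    """Classical PCoA: Gower double-centering of ``-d²/2`` followed by an
    eigendecomposition, retaining every axis with ``|λ|`` above tolerance."""
    d = matrix.d if isinstance(matrix, DistanceMatrix) else np.asarray(matrix, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("PCoA input must be square")
    if not np.allclose(d, d.T):
        raise ValidationError("PCoA input must be symmetric")
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = j @ a @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]  # descending
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = np.max(np.abs(eigvals)) if n else 0.0
    if scale <= 0:
        return PCoAEmbedding(
            np.zeros((n, 0)), np.zeros((n, 0)), np.zeros(0), np.zeros(0)
        )
    keep = np.abs(eigvals) > EIGEN_TOL * scale
    pos = keep & (eigvals > 0)
    neg = keep & (eigvals < 0)
    coords_pos = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    coords_neg = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    return PCoAEmbedding(coords_pos, coords_neg, eigvals[pos], eigvals[neg])


@dataclass(frozen=True)
class DispersionTestResult:
    group_mean_dist: Mapping[str, float]
    F_stat: float
    p_value: float
    n_perm: int
    eigen_pos: int
    eigen_neg: int
    seed: int


def _centroid_distances(
    pos: np.ndarray, neg: np.ndarray, labels: np.ndarray, groups: Sequence[str]
) -> np.ndarray:
    """Distance of each point to its group centroid in the PCoA space.

    Squared distances on the imaginary (negative-eigenvalue) axes are
    subtracted from those on the real axes and the result floored at
    zero — the standard correction for non-Euclidean dissimilarities.
    """
    z = np.empty(len(labels))
    for g in groups:
        mask = labels == g
        d2 = np.zeros(int(mask.sum()))
        if pos.shape[1]:
            c = pos[mask].mean(axis=0)
            d2 += ((pos[mask] - c) ** 2).sum(axis=1)
        if neg.shape[1]:
            c = neg[mask].mean(axis=0)
            d2 -= ((neg[mask] - c) ** 2).sum(axis=1)
        z[mask] = np.sqrt(np.maximum(d2, 0.0))
    return z


def _anova_f(z: np.ndarray, labels: np.ndarray, groups: Sequence[str]) -> float:
    n = len(z)
    k = len(groups)
    grand = z.mean()
    ssb = ssw = 0.0
    for g in groups:
        zg = z[labels == g]
        ssb += len(zg) * (zg.mean() - grand) ** 2
        ssw += ((zg - zg.mean()) ** 2).sum()
    if ssw <= 0:
        return np.inf if ssb > 0 else 0.0
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def permdisp(
    matrix: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
) -> DispersionTestResult:
    """PERMDISP test for homogeneity of multivariate dispersions.

    Distances to group centroids are computed in the PCoA embedding of
    the dissimilarity matrix, the observed F is the one-way ANOVA F on
    those distances, and significance comes from permuting group labels
    with centroids re-derived under every permutation.  The p-value uses
    the ``(b + 1) / (n_perm + 1)`` convention, so its smallest attainable
    value is ``1 / (n_perm + 1)``.
    """
    labels = matrix.group_labels
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValidationError("PERMDISP needs at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 members")
    emb = pcoa_embedding(matrix)
    z_obs = _centroid_distances(emb.coords_pos, emb.coords_neg, labels, groups)
    f_obs = _anova_f(z_obs, labels, groups)
    group_mean = {
        g: float(z_obs[labels == g].mean()) for g in groups
    }
    rng = np.random.default_rng(seed)
    # permuted F values tied with the observed one must count toward b;
    # the tolerance absorbs floating-point noise between analytically
    # equal statistics computed under different labelings
    tie_tol = 1e-8 * max(1.0, abs(f_obs))
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        z = _centroid_distances(emb.coords_pos, emb.coords_neg, perm, groups)
        if _anova_f(z, perm, groups) >= f_obs - tie_tol:
            b += 1
    return DispersionTestResult(
        group_mean_dist=group_mean,
        F_stat=f_obs,
        p_value=(b + 1) / (n_perm + 1),
        n_perm=n_perm,
        eigen_pos=int(emb.eigvals_pos.size),
        eigen_neg=int(emb.eigvals_neg.size),
        seed=seed,
    )
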