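"""Ecological distances, ordination, PERMANOVA, and two-group clustering.

Distances follow the ecology conventions: Bray-Curtis for comparing
extraction protocols, Canberra for the per-subset analyses (both-zero
features skipped, no renormalization).  PCoA eigendecomposes the
double-centered squared distances; negative eigenvalues are reported but
their axes dropped, with no Lingoes/Cailliez correction.  PERMANOVA is a
one-way design with unrestricted raw-label permutations and a seeded
permutation stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .spectra_io import FeatureTable

logger = logging.getLogger("chemophylo")


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with sample ids and the metric name."""

    sample_ids: list[str]
    data: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(d)) > 1e-12) or np.any(d < -1e-12):
            raise ValueError("distances must be >= 0 with zero diagonal")
        np.fill_diagonal(d, 0.0)
        self.data = (d + d.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)


def _sample_matrix(table: FeatureTable) -> tuple[np.ndarray, list[str]]:
    # samples as rows, features as columns
    return table.areas.to_numpy(dtype=float).T, table.sample_ids


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y) per sample pair."""
    x, ids = _sample_matrix(table)
    zero = np.nonzero(x.sum(axis=1) == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero sample(s): {[ids[i] for i in zero]}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(ids, d, "braycurtis")


def canberra(table: FeatureTable) -> DistanceMatrix:
    """Canberra distance: sum over features with x+y > 0 of |x-y|/(x+y);
    features at zero in both samples contribute nothing."""
    x, ids = _sample_matrix(table)
    d = squareform(pdist(x, metric="canberra"))
    return DistanceMatrix(ids, d, "canberra")


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x retained (positive) axes
    eigenvalues: np.ndarray    # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per retained axis, over positive sum


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Principal coordinates analysis (classical MDS).

    Eigendecomposition of -0.5 * J D^2 J with J the centering matrix; axes
    ordered by descending eigenvalue, axes with non-positive eigenvalues
    dropped, proportion explained taken over the positive eigenvalue sum.
    On Euclidean distances this reproduces PCA scores up to axis sign.
    """
    n = dm.n
    if n < 3:
        raise ValueError("PCoA requires at least 3 samples")
    d2 = dm.data ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10 * max(abs(evals[0]), 1.0), 0.0)
    pos = evals > tol
    if pos.sum() == 0:
        raise ValueError("no positive eigenvalues; degenerate distance matrix")
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PC{i + 1}" for i in range(pos.sum())]
    prop = evals[pos] / evals[pos].sum()
    if (evals < -tol).any():
        logger.info("PCoA: %d negative eigenvalues (min %.3g) reported, axes "
                    "dropped", int((evals < -tol).sum()), evals.min())
    return PCoAResult(pd.DataFrame(coords, index=dm.sample_ids, columns=axes),
                      evals, prop)


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    groups: pd.Series
    ss_between: float
    ss_within: float


def _permanova_f(a: np.ndarray, labels: np.ndarray, group_sizes: np.ndarray,
                 ss_total: float) -> float:
    k = len(group_sizes)
    n = len(labels)
    ss_within = 0.0
    for g, ng in enumerate(group_sizes):
        z = labels == g
        ss_within += a[np.ix_(z, z)].sum() / (2.0 * ng)
    ss_between = ss_total - ss_within
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999,
              seed: int | None = 0) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    pseudo-F partitions the sum of squared distances (SS_total =
    sum_{x<y} D^2 / N; within-group terms analogous per group); the p-value
    is (1 + #{permuted F >= observed F}) / (1 + n_perm) over seeded
    unrestricted label permutations.  On univariate Euclidean data the
    pseudo-F equals the classical one-way ANOVA F.
    """
    labels_in = pd.Series(groups, index=dm.sample_ids) \
        if not isinstance(groups, pd.Series) else groups.reindex(dm.sample_ids)
    if labels_in.isna().any():
        raise ValueError("missing group label for some samples")
    codes, uniques = pd.factorize(labels_in.to_numpy())
    if len(uniques) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    a = dm.data ** 2
    n = dm.n
    ss_total = a.sum() / (2.0 * n)
    f_obs = _permanova_f(a, codes, sizes, ss_total)

    rng = np.random.default_rng(seed)
    # vectorized permutation F: per group indicator quadratic forms
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    ss_within = np.zeros(n_perm)
    for g, ng in enumerate(sizes):
        z = (perms == g).astype(float)           # (n_perm, n)
        ss_within += np.einsum("pi,ij,pj->p", z, a, z) / (2.0 * ng)
    k = len(sizes)
    f_perm = ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm)
    ssw = 0.0
    for g, ng in enumerate(sizes):
        z = codes == g
        ssw += a[np.ix_(z, z)].sum() / (2.0 * ng)
    return PermanovaResult(float(f_obs), float(p), n_perm, labels_in,
                           float(ss_total - ssw), float(ssw))


def cluster_two_groups(dm: DistanceMatrix) -> pd.Series:
    """Partition samples into two groups by exact 2-medoid clustering.

    All medoid pairs are enumerated (O(n^3), fine at study scale) and the
    partition minimizing the within-group distance sum is kept.  The group
    containing the lexicographically first sample id is labeled "A".  A
    degenerate (zero-separation) matrix yields a deterministic split and a
    logged flag.
    """
    n = dm.n
    if n < 4:
        raise ValueError("two-group clustering requires at least 4 samples")
    d = dm.data
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            assign = d[i] > d[j]  # True -> medoid j
            # medoids belong to themselves
            assign[i], assign[j] = False, True
            cost = d[i][~assign].sum() + d[j][assign].sum()
            key = (cost, i, j)
            if best is None or key < best[0:3]:
                best = (cost, i, j, assign.copy())
    cost, i, j, assign = best
    if cost == 0 and n > 1 and np.allclose(d, 0):
        logger.warning("cluster_two_groups: zero separation; arbitrary split")
    first = min(range(n), key=lambda t: dm.sample_ids[t])
    labels = np.where(assign == assign[first], "A", "B")
    return pd.Series(labels, index=dm.sample_ids, name="group")
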