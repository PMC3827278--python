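"""Statistics comparing distance matrices and the two analysis routes.

* Mantel permutation test for association between two labeled distance
  matrices (simultaneous row/column permutation of the second matrix;
  one-sided toward positive correlation, add-one p estimator).
* Classical (metric) multidimensional scaling by double-centering.
* A rank-based "elevation" diagnostic quantifying whether intensity-route
  distances involving the focal taxa sit systematically higher than the
  genotype-route distances for the same pairs.
* The topology-distance table across trees built from different intensity
  summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .trees import Tree, tree_topology_distance

__all__ = [
    "MantelResult",
    "MdsResult",
    "mantel_test",
    "classical_mds",
    "focal_elevation_statistic",
    "topology_distance_table",
]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must lie in (0, 1]")


@dataclass
class MdsResult:
    """Principal-coordinates embedding of a distance matrix."""

    coordinates: pd.DataFrame  # taxa x axes
    eigenvalues: np.ndarray  # all eigenvalues, nonincreasing


def _aligned_condensed(m1: DistanceMatrix, m2: DistanceMatrix):
    if set(m1.ids) != set(m2.ids):
        raise ValueError("matrices must share an identical label set")
    order = list(m1.ids)
    d1 = np.asarray(m1.data, float)
    d2 = np.asarray(m2.filter(order).data, float)
    return d1, d2


def mantel_test(
    m1: DistanceMatrix, m2: DistanceMatrix, permutations: int = 10000, seed: int = 0
) -> MantelResult:
    """One-sided Mantel test for positive association between two matrices.

    The statistic is the Pearson correlation of the lower-triangle vectors;
    the null distribution is generated by relabeling the second matrix with
    the same random permutation applied to rows and columns.  The p-value
    uses the add-one estimator (#{r_perm >= r_obs} + 1) / (P + 1), so the
    smallest attainable p is 1/(P+1).
    """
    d1, d2 = _aligned_condensed(m1, m2)
    n = d1.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 labels")
    tril = np.tril_indices(n, k=-1)
    v1 = d1[tril]
    if v1.std() == 0 or d2[tril].std() == 0:
        raise ValueError("constant distance matrix: Mantel statistic undefined")
    rng = np.random.default_rng(seed)

    v1c = v1 - v1.mean()
    denom1 = np.sqrt((v1c**2).sum())

    def corr(mat: np.ndarray) -> float:
        v = mat[tril]
        vc = v - v.mean()
        return float((v1c * vc).sum() / (denom1 * np.sqrt((vc**2).sum())))

    r_obs = corr(d2)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        if corr(d2[np.ix_(perm, perm)]) >= r_obs:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return MantelResult(r=r_obs, p=p, permutations=permutations, seed=seed)


def classical_mds(m: DistanceMatrix, k: int = 2) -> MdsResult:
    """Classical MDS (principal coordinates) of a labeled distance matrix.

    Double-centers -0.5 * J D^2 J, eigendecomposes, and scales the top-k
    eigenvectors by the square roots of their (positive) eigenvalues.  If
    fewer than k eigenvalues are positive the embedding is truncated.  Each
    axis is signed so its largest-magnitude coordinate is positive.
    """
    labels = list(m.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("classical MDS needs at least 3 labels")
    d = np.asarray(m.data, float)
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12, 1e-10 * abs(vals[0]))
    k_eff = min(k, int(pos.sum()))
    coords = vecs[:, :k_eff] * np.sqrt(vals[:k_eff])
    for ax in range(k_eff):
        col = coords[:, ax]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, ax] = -col
    frame = pd.DataFrame(
        coords, index=labels, columns=[f"axis{i + 1}" for i in range(k_eff)]
    )
    return MdsResult(coordinates=frame, eigenvalues=vals)


def _offdiag_ranks(d: np.ndarray) -> np.ndarray:
    """Rank-transform the condensed off-diagonal entries to [0, 1]."""
    from scipy.stats import rankdata

    ranks = rankdata(d)
    if len(ranks) == 1:
        return np.array([0.5])
    return (ranks - 1) / (len(ranks) - 1)


def focal_elevation_statistic(
    m_int: DistanceMatrix, m_fst: DistanceMatrix, focal_taxa: set[str]
) -> float:
    """Mean rank elevation of intensity distances over focal-involving pairs.

    Both matrices' lower-triangle entries are rank-transformed to [0, 1];
    the statistic is the mean of (intensity rank - genotype rank) over
    pairs that involve at least one focal taxon.  Positive values mean the
    intensity route places focal pairs systematically farther apart, in
    relative terms, than the genotype route does.
    """
    d1, d2 = _aligned_condensed(m_int, m_fst)
    labels = list(m_int.ids)
    focal_taxa = set(focal_taxa)
    unknown = focal_taxa - set(labels)
    if unknown:
        raise ValueError(f"focal taxa not in matrix: {sorted(unknown)}")
    if len(set(labels) - focal_taxa) < 2:
        raise ValueError("need at least two non-focal taxa")
    n = len(labels)
    tril = np.tril_indices(n, k=-1)
    involves = np.array(
        [labels[i] in focal_taxa or labels[j] in focal_taxa for i, j in zip(*tril)]
    )
    if not involves.any():
        raise ValueError("no pairs involve a focal taxon")
    r_int = _offdiag_ranks(d1[tril])
    r_fst = _offdiag_ranks(d2[tril])
    return float((r_int[involves] - r_fst[involves]).mean())


def topology_distance_table(trees: dict[str, Tree]) -> pd.DataFrame:
    """Symmetric table of pairwise topology distances across tree variants."""
    kinds = list(trees)
    n = len(kinds)
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = tree_topology_distance(trees[kinds[i]], trees[kinds[j]])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=kinds, columns=kinds)
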