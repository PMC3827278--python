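"""The genotype route: per-species allele statistics and Weir–Cockerham F_ST.

Per (taxon, SNP) the route needs the non-missing diploid count n_i, the
allele-B frequency p_i, and the observed heterozygote proportion h_i.  From
these, pairwise differentiation between two taxa at each locus is measured
with the Weir–Cockerham (1984) variance-component estimator for r = 2
populations, and a single weighted ("ratio of sums") theta per taxon pair
is obtained as sum_l a_l / sum_l (a_l + b_l + c_l) across loci — the
standard weighted-average F_ST.  Loci monomorphic in both taxa contribute
zero to both sums and therefore drop out.

Diagnostics of array ascertainment bias live here too: minor-allele-
frequency spectra per taxon and counts of SNPs at which two taxa are fixed
for the same allele (shared-monomorphic SNPs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .datatypes import GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesAlleleStats",
    "species_allele_stats",
    "maf_spectrum",
    "count_shared_monomorphic",
    "fst_components",
    "pairwise_fst_matrix",
    "shift_nonnegative",
]


@dataclass
class SpeciesAlleleStats:
    """Per-(taxon, SNP) allele statistics; NaN marks taxa with no data at a SNP.

    ``n``: non-missing diploid count; ``p``: allele-B frequency;
    ``h``: observed heterozygote proportion.  All taxa x SNPs DataFrames.
    """

    n: pd.DataFrame
    p: pd.DataFrame
    h: pd.DataFrame

    @property
    def taxa(self) -> list[str]:
        return list(self.n.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.n.columns)

    def maf(self) -> pd.DataFrame:
        return np.minimum(self.p, 1.0 - self.p)


def species_allele_stats(g: GenotypeTable, species_map: dict[str, str]) -> SpeciesAlleleStats:
    """Tally n, p and h per taxon per SNP from a dosage table."""
    unmapped = [s for s in g.sample_ids if s not in species_map]
    if unmapped:
        raise ValueError(f"samples missing from species map: {unmapped[:5]}")
    dosage = g.dosage
    taxa = sorted(set(species_map[s] for s in g.sample_ids))
    n_rows, p_rows, h_rows = [], [], []
    for taxon in taxa:
        members = [s for s in g.sample_ids if species_map[s] == taxon]
        block = dosage.loc[members].to_numpy(float)
        n = (~np.isnan(block)).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(block, axis=0) / (2.0 * n)
            h = (block == 1.0).sum(axis=0) / n
        p[n == 0] = np.nan
        h[n == 0] = np.nan
        n[n == 0] = np.nan
        n_rows.append(n)
        p_rows.append(p)
        h_rows.append(h)
    cols = dosage.columns
    return SpeciesAlleleStats(
        pd.DataFrame(n_rows, index=taxa, columns=cols),
        pd.DataFrame(p_rows, index=taxa, columns=cols),
        pd.DataFrame(h_rows, index=taxa, columns=cols),
    )


def maf_spectrum(stats: SpeciesAlleleStats, taxon: str, bins) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of a taxon's minor allele frequencies over defined SNPs.

    ``bins`` must partition [0, 0.5]; returns (counts, bin_edges).  The
    counts sum to the number of SNPs with a defined MAF for the taxon.
    """
    if taxon not in stats.taxa:
        raise KeyError(f"unknown taxon {taxon!r}")
    edges = np.asarray(bins, float)
    if edges[0] != 0.0 or edges[-1] != 0.5 or (np.diff(edges) <= 0).any():
        raise ValueError("bins must be increasing edges partitioning [0, 0.5]")
    maf = stats.maf().loc[taxon].to_numpy(float)
    maf = maf[~np.isnan(maf)]
    if maf.size == 0:
        raise ValueError(f"taxon {taxon!r} has no defined MAF at any SNP")
    counts, edges = np.histogram(maf, bins=edges)
    return counts, edges


def count_shared_monomorphic(stats: SpeciesAlleleStats, taxon_a: str, taxon_b: str) -> int:
    """SNPs at which both taxa are fixed for the same allele (p in {0, 1}, equal)."""
    pa = stats.p.loc[taxon_a].to_numpy(float)
    pb = stats.p.loc[taxon_b].to_numpy(float)
    both = ~np.isnan(pa) & ~np.isnan(pb)
    fixed = ((pa == 0.0) | (pa == 1.0)) & ((pb == 0.0) | (pb == 1.0)) & (pa == pb)
    return int((fixed & both).sum())


def fst_components(n1, p1, h1, n2, p2, h2):
    """Weir–Cockerham variance components (a, b, c) per locus for two populations.

    Vectorized over loci.  a estimates the among-population variance
    component, b the among-individual-within-population component, and c
    the within-individual component; theta = a / (a + b + c).
    """
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    h1 = np.asarray(h1, float)
    h2 = np.asarray(h2, float)
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def pairwise_fst(stats: SpeciesAlleleStats, taxon_a: str, taxon_b: str) -> float:
    """Weighted (ratio-of-sums) theta between two taxa across usable loci.

    Usable loci have n >= 2 non-missing diploids in each taxon; loci
    monomorphic in both taxa contribute zero to numerator and denominator.
    """
    n1 = stats.n.loc[taxon_a].to_numpy(float)
    n2 = stats.n.loc[taxon_b].to_numpy(float)
    p1 = stats.p.loc[taxon_a].to_numpy(float)
    p2 = stats.p.loc[taxon_b].to_numpy(float)
    h1 = stats.h.loc[taxon_a].to_numpy(float)
    h2 = stats.h.loc[taxon_b].to_numpy(float)
    usable = (~np.isnan(n1)) & (~np.isnan(n2)) & (n1 >= 2) & (n2 >= 2)
    if not usable.any():
        raise ValueError(f"no usable loci for pair ({taxon_a}, {taxon_b})")
    a, b, c = fst_components(
        n1[usable], p1[usable], h1[usable], n2[usable], p2[usable], h2[usable]
    )
    denom = (a + b + c).sum()
    if denom <= 0:
        raise ValueError(f"no informative loci for pair ({taxon_a}, {taxon_b})")
    return float(a.sum() / denom)


def pairwise_fst_matrix(stats: SpeciesAlleleStats, taxa: list[str] | None = None) -> DistanceMatrix:
    """All pairwise weighted thetas as a labeled matrix (negatives retained)."""
    if taxa is None:
        taxa = stats.taxa
    taxa = list(taxa)
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            theta = pairwise_fst(stats, taxa[i], taxa[j])
            out[i, j] = out[j, i] = theta
    return DistanceMatrix(out, ids=taxa)


def shift_nonnegative(m: DistanceMatrix) -> DistanceMatrix:
    """Shift off-diagonal entries up by the (negative) minimum, if any.

    Theta estimates can come out slightly negative; tree building expects
    nonnegative dissimilarities, so the whole off-diagonal is shifted by
    the same constant (the diagonal stays zero), which preserves ordering.
    """
    data = np.array(m.data, float)
    off = ~np.eye(len(data), dtype=bool)
    lo = data[off].min() if off.any() else 0.0
    if lo < 0:
        logger.info("shifting distance matrix up by %.6g to remove negative entries", -lo)
        data[off] -= lo
    return DistanceMatrix(data, ids=list(m.ids))
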