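"""The intensity route: "quantitative genotypes" from channel intensities.

Instead of forcing the two normalized channel values (X for allele A, Y for
allele B) into categorical genotype calls, each (sample, SNP) pair is
summarized by one of seven functions of (X, Y); the per-SNP median of that
summary within each taxon is the taxon's quantitative genotype at that SNP,
and taxa are compared by the Euclidean distance between their profile
vectors.  No genotype-quality filters apply on this route — intensity is
observed even where the genotype call is missing, and every array SNP is
used.

The seven summaries: X, Y, X+Y, X/(X+Y), ln(X/(X+Y)), ln(Y/(X+Y)), ln(X/Y).
The log forms rely on the strictly positive intensity floor guaranteed by
the simulator/reader, not on pseudocounts; ln(X/Y) is the default reported
statistic.
"""

from __future__ import annotations

import enum

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .datatypes import IntensityTable

__all__ = [
    "SummaryStatKind",
    "summary_statistic",
    "species_median_profiles",
    "euclidean_species_distance",
]


class SummaryStatKind(str, enum.Enum):
    """The closed set of seven per-call intensity summaries."""

    X = "X"
    Y = "Y"
    X_PLUS_Y = "X_PLUS_Y"
    X_FRAC = "X_FRAC"
    LN_X_FRAC = "LN_X_FRAC"
    LN_Y_FRAC = "LN_Y_FRAC"
    LN_XY = "LN_XY"


def summary_statistic(x, y, kind: SummaryStatKind):
    """Evaluate one of the seven summaries; inputs must be strictly positive.

    Identity: LN_XY == LN_X_FRAC - LN_Y_FRAC exactly (both are ln X - ln(X+Y)
    and ln Y - ln(X+Y); the difference cancels the shared term).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("intensities must be strictly positive (floor violated)")
    kind = SummaryStatKind(kind)
    if kind is SummaryStatKind.X:
        return x + 0.0
    if kind is SummaryStatKind.Y:
        return y + 0.0
    if kind is SummaryStatKind.X_PLUS_Y:
        return x + y
    if kind is SummaryStatKind.X_FRAC:
        return x / (x + y)
    if kind is SummaryStatKind.LN_X_FRAC:
        return np.log(x / (x + y))
    if kind is SummaryStatKind.LN_Y_FRAC:
        return np.log(y / (x + y))
    return np.log(x) - np.log(y)  # LN_XY, exactly LN_X_FRAC - LN_Y_FRAC


def species_median_profiles(
    intensities: IntensityTable,
    species_map: dict[str, str],
    kind: SummaryStatKind = SummaryStatKind.LN_XY,
) -> pd.DataFrame:
    """Per-taxon, per-SNP median of the chosen summary (taxa x SNPs).

    Medians are over all of a taxon's samples at every array SNP — genotype
    missingness is ignored because the intensities are observed regardless.
    An even sample count takes the mean of the two central order statistics.
    """
    unmapped = [s for s in intensities.sample_ids if s not in species_map]
    if unmapped:
        raise ValueError(f"samples missing from species map: {unmapped[:5]}")
    values = summary_statistic(
        intensities.x.to_numpy(float), intensities.y.to_numpy(float), kind
    )
    frame = pd.DataFrame(values, index=intensities.sample_ids, columns=intensities.snp_ids)
    taxa = sorted(set(species_map[s] for s in intensities.sample_ids))
    rows = []
    for taxon in taxa:
        members = [s for s in intensities.sample_ids if species_map[s] == taxon]
        rows.append(np.median(frame.loc[members].to_numpy(float), axis=0))
    return pd.DataFrame(rows, index=taxa, columns=intensities.snp_ids)


def euclidean_species_distance(profiles: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between taxon profile vectors."""
    vals = profiles.to_numpy(float)
    if not np.isfinite(vals).all():
        raise ValueError("profiles contain non-finite entries")
    sq = ((vals[:, None, :] - vals[None, :, :]) ** 2).sum(axis=2)
    d = np.sqrt(sq)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, ids=list(profiles.index))
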