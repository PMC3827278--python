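"""Genotype data curation: quality filters, LD pruning, PCA, label screening.

The filter chain runs in a fixed order — (1) calls below the GenCall
threshold are set to missing, (2) SNPs below the GenTrain threshold are
dropped, (3) SNPs exceeding the missingness ceiling are dropped, (4) SNPs
below the MAF floor (computed over remaining non-missing calls) are
dropped.  The order matters for survivor counts, so it is part of the
contract.  Intensities are never filtered; only the genotype route sees
this chain.

The curation screen codifies the by-eye step of removing samples that
cluster with another taxon in PC space: a sample is flagged when the
nearest taxon centroid is not its assigned taxon AND its own (leave-one-
out) centroid is more than ``margin`` times farther than the nearest one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FilterReport, GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_THRESHOLDS",
    "PcaResult",
    "apply_genotype_filters",
    "ld_prune",
    "genotype_pca",
    "flag_curation_errors",
]

DEFAULT_THRESHOLDS = {
    "gencall_min": 0.2,
    "gentrain_min": 0.3,
    "maf_min": 0.05,
    "missing_max": 0.20,
}


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x axes
    explained_variance: np.ndarray  # fraction per returned axis, nonincreasing
    k: int


def _gentrain_lookup(manifest) -> dict[str, float]:
    if isinstance(manifest, dict):
        return dict(manifest)
    return {rec.snp_id: rec.gentrain for rec in manifest}


def apply_genotype_filters(
    g: GenotypeTable, manifest, thresholds: dict | None = None
) -> tuple[GenotypeTable, FilterReport]:
    """Run the four-rule filter chain; returns the surviving table and a report."""
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    for key, val in th.items():
        if not (0.0 <= val <= 1.0):
            raise ValueError(f"threshold {key} must lie in [0, 1], got {val}")

    dosage = g.dosage.to_numpy(float).copy()
    gencall = g.gencall.to_numpy(float)
    snps = np.array(g.snp_ids)

    # (1) low-confidence calls become missing
    low = (gencall < th["gencall_min"]) & ~np.isnan(dosage)
    n_masked = int(low.sum())
    dosage[low] = np.nan

    # (2) SNP design quality
    gentrain = _gentrain_lookup(manifest)
    missing_manifest = [s for s in snps if s not in gentrain]
    if missing_manifest:
        raise ValueError(f"SNPs absent from manifest: {missing_manifest[:5]}")
    keep_gt = np.array([gentrain[s] >= th["gentrain_min"] for s in snps])
    n_gentrain = int((~keep_gt).sum())
    dosage = dosage[:, keep_gt]
    snps = snps[keep_gt]

    # (3) per-SNP missingness (strict >)
    miss_frac = np.isnan(dosage).mean(axis=0)
    keep_miss = miss_frac <= th["missing_max"]
    n_missing = int((~keep_miss).sum())
    dosage = dosage[:, keep_miss]
    snps = snps[keep_miss]

    # (4) MAF over remaining non-missing calls (strict <)
    n_called = (~np.isnan(dosage)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(dosage, axis=0) / (2.0 * n_called)
    maf = np.minimum(p, 1.0 - p)
    keep_maf = maf >= th["maf_min"]
    n_maf = int((~keep_maf).sum())
    dosage = dosage[:, keep_maf]
    snps = snps[keep_maf]

    out = GenotypeTable(
        pd.DataFrame(dosage, index=g.sample_ids, columns=snps),
        g.gencall.loc[:, snps],
    )
    report = FilterReport(
        n_snps_in=g.n_snps,
        n_snps_out=len(snps),
        n_samples_in=g.n_samples,
        n_samples_out=g.n_samples,
        n_calls_masked_gencall=n_masked,
        n_snps_removed_gentrain=n_gentrain,
        n_snps_removed_missing=n_missing,
        n_snps_removed_maf=n_maf,
        thresholds=th,
    )
    return out, report


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over shared calls."""
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok], b[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(
    g: GenotypeTable, window: int = 10, step: int = 3, r2_max: float = 0.5
) -> tuple[list[str], list[str]]:
    """Windowed pairwise LD pruning on dosage r-squared (composite LD).

    SNP columns must already be in map order.  Within each window of
    ``window`` SNPs, pairs are scanned in index order; when r^2 exceeds
    ``r2_max`` the member with the lower MAF is removed (tie: the higher
    index).  The window shifts by ``step`` and sweeps repeat until no
    removal occurs.  Returns (kept SNP ids, removed SNP ids).
    """
    snps = list(g.snp_ids)
    if len(snps) < 2:
        return snps, []
    dosage = g.dosage.to_numpy(float)
    n_called = (~np.isnan(dosage)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(dosage, axis=0) / (2.0 * np.maximum(n_called, 1))
    maf = np.minimum(p, 1.0 - p)

    kept = list(range(len(snps)))
    removed: list[int] = []
    changed = True
    while changed:
        changed = False
        start = 0
        while start < len(kept):
            win = kept[start : start + window]
            gone: set[int] = set()
            for a_pos in range(len(win)):
                if win[a_pos] in gone:
                    continue
                for b_pos in range(a_pos + 1, len(win)):
                    i, j = win[a_pos], win[b_pos]
                    if i in gone or j in gone:
                        continue
                    if _pairwise_r2(dosage[:, i], dosage[:, j]) > r2_max:
                        victim = j if maf[j] <= maf[i] else i
                        gone.add(victim)
                        if victim == i:
                            break
            if gone:
                changed = True
                removed.extend(sorted(gone))
                kept = [x for x in kept if x not in gone]
            start += step
    removed.sort()
    return [snps[i] for i in kept], [snps[i] for i in removed]


def genotype_pca(g: GenotypeTable, k: int) -> PcaResult:
    """PCA of the dosage matrix: mean-imputed, column-centered, not scaled.

    Coordinates are the top-k left singular directions scaled by the
    singular values; each axis is signed so its largest-magnitude SNP
    loading is positive.  Explained-variance fractions are relative to the
    total variance of the centered matrix.
    """
    n, m = g.dosage.shape
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(samples, SNPs)={min(n, m)}")
    x = g.dosage.to_numpy(float).copy()
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.where(np.isnan(x))
    x[nan_r, nan_c] = col_mean[nan_c]
    x -= x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for ax in range(k):
        load = vt[ax]
        if load[np.argmax(np.abs(load))] < 0:
            vt[ax] = -load
            u[:, ax] = -u[:, ax]
    coords = u[:, :k] * s[:k]
    total = (s**2).sum()
    explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    frame = pd.DataFrame(
        coords, index=g.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PcaResult(coordinates=frame, explained_variance=explained, k=k)


def flag_curation_errors(
    pca: PcaResult,
    species_map: dict[str, str],
    m_axes: int = 5,
    margin: float = 1.5,
) -> list[str]:
    """Samples whose PC-space position contradicts their taxon label.

    For each sample, distances in the top-m PC space to every taxon
    centroid are computed, with the sample's own centroid taken leave-one-
    out.  A sample is flagged iff the nearest centroid belongs to another
    taxon and its own centroid is more than ``margin`` times farther away.
    Singleton taxa can never be flagged (no leave-one-out centroid); a
    warning is logged for them.
    """
    coords = pca.coordinates
    m_eff = min(m_axes, coords.shape[1])
    xy = coords.to_numpy(float)[:, :m_eff]
    samples = list(coords.index)
    unmapped = [s for s in samples if s not in species_map]
    if unmapped:
        raise ValueError(f"samples missing from species map: {unmapped[:5]}")
    taxa = sorted(set(species_map[s] for s in samples))
    members = {t: [i for i, s in enumerate(samples) if species_map[s] == t] for t in taxa}
    big = [t for t in taxa if len(members[t]) >= 2]
    if len(big) < 2:
        raise ValueError("need at least two taxa with at least two samples each")
    for t in taxa:
        if len(members[t]) == 1:
            logger.warning("taxon %s has a single sample; it can never be flagged", t)
    sums = {t: xy[members[t]].sum(axis=0) for t in taxa}
    counts = {t: len(members[t]) for t in taxa}

    flagged = []
    for i, sample in enumerate(samples):
        own = species_map[sample]
        if counts[own] < 2:
            continue
        own_centroid = (sums[own] - xy[i]) / (counts[own] - 1)
        own_dist = np.linalg.norm(xy[i] - own_centroid)
        best_taxon, best_dist = own, own_dist
        for t in taxa:
            if t == own:
                continue
            d = np.linalg.norm(xy[i] - sums[t] / counts[t])
            if d < best_dist or (d == best_dist and t < best_taxon):
                best_taxon, best_dist = t, d
        if best_taxon != own and own_dist > margin * best_dist:
            flagged.append(sample)
    return flagged
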