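"""Core in-memory containers shared across the pipeline.

Genotypes are stored as B-allele dosages (0/1/2) with missing calls encoded
as NaN in a float matrix — never as 0, so a missing call can never be
confused with an AA homozygote.  Intensity tables hold the two normalized
channel values per (sample, SNP): X for allele A and Y for allele B.  Both
tables are rectangular pandas DataFrames indexed by sample id with SNP ids
as columns, and a genotype/intensity pair produced together always shares
identical row and column orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "IntensityTable",
    "FilterReport",
]


@dataclass
class GenotypeTable:
    """Samples x SNPs dosage matrix plus per-call GenCall-like scores.

    ``dosage`` entries are 0.0/1.0/2.0 (count of B alleles) or NaN for a
    missing call.  ``gencall`` has the same shape with scores in [0, 1];
    scores are retained even where the call is missing.
    """

    dosage: pd.DataFrame
    gencall: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosage.index.equals(self.gencall.index) or not self.dosage.columns.equals(
            self.gencall.columns
        ):
            raise ValueError("dosage and gencall tables must share sample/SNP orderings")
        vals = self.dosage.to_numpy(float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        gc = self.gencall.to_numpy(float)
        if np.nanmin(gc, initial=0.0) < 0 or np.nanmax(gc, initial=0.0) > 1:
            raise ValueError("GenCall scores must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def subset_snps(self, snp_ids) -> "GenotypeTable":
        return GenotypeTable(self.dosage[list(snp_ids)], self.gencall[list(snp_ids)])

    def subset_samples(self, sample_ids) -> "GenotypeTable":
        ids = list(sample_ids)
        return GenotypeTable(self.dosage.loc[ids], self.gencall.loc[ids])


@dataclass
class IntensityTable:
    """Samples x SNPs pairs of nonnegative normalized channel intensities."""

    x: pd.DataFrame
    y: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.x.index.equals(self.y.index) or not self.x.columns.equals(self.y.columns):
            raise ValueError("X and Y tables must share sample/SNP orderings")
        if (self.x.to_numpy(float) < 0).any() or (self.y.to_numpy(float) < 0).any():
            raise ValueError("intensities must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.x.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.x.columns)

    def subset_samples(self, sample_ids) -> "IntensityTable":
        ids = list(sample_ids)
        return IntensityTable(self.x.loc[ids], self.y.loc[ids])


@dataclass
class FilterReport:
    """Bookkeeping for the genotype QC filters.

    Removal counts are per rule, in the fixed order the rules are applied:
    low-GenCall call masking, GenTrain SNP drop, missingness SNP drop,
    MAF SNP drop.
    """

    n_snps_in: int
    n_snps_out: int
    n_samples_in: int
    n_samples_out: int
    n_calls_masked_gencall: int
    n_snps_removed_gentrain: int
    n_snps_removed_missing: int
    n_snps_removed_maf: int
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_snps_out > self.n_snps_in or self.n_samples_out > self.n_samples_in:
            raise ValueError("filter output cannot exceed input on either axis")
        removed = (
            self.n_snps_removed_gentrain
            + self.n_snps_removed_missing
            + self.n_snps_removed_maf
        )
        if removed != self.n_snps_in - self.n_snps_out:
            raise ValueError("per-rule SNP removal counts do not sum to n_in - n_out")

    def to_dict(self) -> dict:
        return {
            "n_snps_in": self.n_snps_in,
            "n_snps_out": self.n_snps_out,
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "n_calls_masked_gencall": self.n_calls_masked_gencall,
            "n_snps_removed_gentrain": self.n_snps_removed_gentrain,
            "n_snps_removed_missing": self.n_snps_removed_missing,
            "n_snps_removed_maf": self.n_snps_removed_maf,
            "thresholds": dict(self.thresholds),
        }
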