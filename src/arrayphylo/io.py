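"""Readers and writers for every on-disk format the pipeline touches.

Formats (all UTF-8, tab-separated, "." decimal):

* GenomeStudio-style "Final Report": long TSV, one row per (sample, SNP),
  columns ``sample_id  snp_id  allele1  allele2  gencall  x  y``.  Allele
  characters are A/B with "-" marking a missing call; X and Y are the
  normalized channel intensities for alleles A and B.
* SNP manifest: TSV with ``snp_id  gentrain  chrom  pos`` (1-based
  positions; extra columns preserved on read but ignored).
* Species map: two-column TSV mapping sample id to taxon label.
* Distance matrices: PHYLIP square format (count line, then one row per
  taxon with the label padded to 10 characters).

Distance matrices travel as :class:`skbio.DistanceMatrix` instances, which
enforce symmetry, a zero diagonal and unique labels.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .datatypes import GenotypeTable, IntensityTable

__all__ = [
    "FinalReportError",
    "SnpManifestRecord",
    "read_final_report",
    "write_final_report",
    "read_snp_manifest",
    "write_snp_manifest",
    "read_species_map",
    "write_species_map",
    "read_distance_matrix",
    "write_distance_matrix",
    "load_accession_counts",
]

FINAL_REPORT_COLUMNS = ["sample_id", "snp_id", "allele1", "allele2", "gencall", "x", "y"]
_ALLELE_ALPHABET = {"A", "B", "-"}
_DOSAGE = {("A", "A"): 0.0, ("A", "B"): 1.0, ("B", "A"): 1.0, ("B", "B"): 2.0}


class FinalReportError(ValueError):
    """Malformed final-report, manifest or species-map input."""


@dataclass(frozen=True)
class SnpManifestRecord:
    """Per-SNP array manifest entry: design quality score and map position."""

    snp_id: str
    gentrain: float
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.gentrain <= 1.0):
            raise FinalReportError(f"GenTrain score out of [0,1] for {self.snp_id}: {self.gentrain}")
        if self.pos < 1:
            raise FinalReportError(f"position must be >= 1 for {self.snp_id}: {self.pos}")


def read_final_report(path) -> tuple[GenotypeTable, IntensityTable]:
    """Parse a long-format final report into aligned genotype and intensity tables.

    Dosage is the count of B alleles (AA=0, AB/BA=1, BB=2); a "-" in either
    allele field marks the call missing (NaN) while the intensities are kept.
    Sample order and SNP order follow first appearance in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in FINAL_REPORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FinalReportError(f"final report missing columns: {missing_cols}")

    dup = df.duplicated(subset=["sample_id", "snp_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FinalReportError(
            f"duplicate (sample, SNP) pair: ({row['sample_id']}, {row['snp_id']})"
        )

    gencall = pd.to_numeric(df["gencall"], errors="raise").to_numpy(float)
    x = pd.to_numeric(df["x"], errors="raise").to_numpy(float)
    y = pd.to_numeric(df["y"], errors="raise").to_numpy(float)
    bad_gc = (gencall < 0) | (gencall > 1)
    if bad_gc.any():
        raise FinalReportError(f"GenCall outside [0,1] at data row {int(np.argmax(bad_gc)) + 1}")
    bad_int = (x < 0) | (y < 0)
    if bad_int.any():
        raise FinalReportError(f"negative intensity at data row {int(np.argmax(bad_int)) + 1}")

    a1 = df["allele1"].to_numpy(str)
    a2 = df["allele2"].to_numpy(str)
    bad_allele = ~np.isin(a1, list(_ALLELE_ALPHABET)) | ~np.isin(a2, list(_ALLELE_ALPHABET))
    if bad_allele.any():
        raise FinalReportError(
            f"allele character outside {{A,B,-}} at data row {int(np.argmax(bad_allele)) + 1}"
        )
    dosage = np.array(
        [_DOSAGE.get((u, v), np.nan) for u, v in zip(a1, a2)], dtype=float
    )

    samples = pd.unique(df["sample_id"])
    snps = pd.unique(df["snp_id"])
    work = df[["sample_id", "snp_id"]].copy()
    work["dosage"] = dosage
    work["gencall"] = gencall
    work["x"] = x
    work["y"] = y
    wide = work.pivot(index="sample_id", columns="snp_id")
    if wide["dosage"].isna().to_numpy().sum() != np.isnan(dosage).sum() or wide[
        "x"
    ].isna().to_numpy().any():
        raise FinalReportError("final report is not complete over samples x SNPs")
    wide = wide.reindex(index=samples)

    def grab(name: str) -> pd.DataFrame:
        out = wide[name].reindex(columns=snps)
        out.index.name = None
        out.columns.name = None
        return out

    return (
        GenotypeTable(grab("dosage"), grab("gencall")),
        IntensityTable(grab("x"), grab("y")),
    )


def write_final_report(g: GenotypeTable, i: IntensityTable, path) -> None:
    """Emit the long-format final report (inverse of :func:`read_final_report`)."""
    if g.sample_ids != i.sample_ids or g.snp_ids != i.snp_ids:
        raise FinalReportError("genotype and intensity tables are not aligned")
    allele = {0.0: ("A", "A"), 1.0: ("A", "B"), 2.0: ("B", "B")}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(FINAL_REPORT_COLUMNS) + "\n")
        dos = g.dosage.to_numpy(float)
        gc = g.gencall.to_numpy(float)
        xv = i.x.to_numpy(float)
        yv = i.y.to_numpy(float)
        for si, s in enumerate(g.sample_ids):
            for li, l in enumerate(g.snp_ids):
                d = dos[si, li]
                a1, a2 = allele.get(d, ("-", "-"))
                fh.write(
                    f"{s}\t{l}\t{a1}\t{a2}\t{gc[si, li]:.9g}\t{xv[si, li]:.9g}\t{yv[si, li]:.9g}\n"
                )


def read_snp_manifest(path) -> list[SnpManifestRecord]:
    """Read the SNP manifest, returning records sorted by (chrom, pos)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("snp_id", "gentrain", "chrom", "pos"):
        if col not in df.columns:
            raise FinalReportError(f"manifest missing column: {col}")
    if df["snp_id"].duplicated().any():
        dupid = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise FinalReportError(f"duplicate snp_id in manifest: {dupid}")
    try:
        gentrain = df["gentrain"].astype(float)
        pos = df["pos"].astype(int)
    except ValueError as exc:
        raise FinalReportError(f"non-numeric manifest field: {exc}") from exc
    records = [
        SnpManifestRecord(snp_id=r.snp_id, gentrain=g, chrom=r.chrom, pos=p)
        for r, g, p in zip(df.itertuples(), gentrain, pos)
    ]
    records.sort(key=lambda r: (r.chrom, r.pos, r.snp_id))
    return records


def write_snp_manifest(records: list[SnpManifestRecord], path) -> None:
    records = sorted(records, key=lambda r: (r.chrom, r.pos, r.snp_id))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("snp_id\tgentrain\tchrom\tpos\n")
        for r in records:
            fh.write(f"{r.snp_id}\t{r.gentrain:.9g}\t{r.chrom}\t{r.pos}\n")


def read_species_map(path) -> dict[str, str]:
    """Read the sample-to-taxon map; duplicate consistent rows collapse."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FinalReportError(f"species map line {lineno}: expected 2 columns")
            sample, taxon = parts
            if lineno == 1 and sample.lower() in {"sample_id", "sample"}:
                continue
            if sample in out and out[sample] != taxon:
                raise FinalReportError(
                    f"sample {sample} mapped to both {out[sample]!r} and {taxon!r}"
                )
            out[sample] = taxon
    return out


def write_species_map(species_map: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\ttaxon\n")
        for sample, taxon in species_map.items():
            fh.write(f"{sample}\t{taxon}\n")


def _phylip_labels(labels: list[str]) -> list[str]:
    """Pad/truncate labels to 10 characters, disambiguating deterministically."""
    used: set[str] = set()
    out = []
    for label in labels:
        name = label[:10]
        if name in used:
            k = 1
            while True:
                suffix = str(k)
                cand = label[: 10 - len(suffix)] + suffix
                if cand not in used:
                    name = cand
                    break
                k += 1
        used.add(name)
        out.append(name)
    return out


def write_distance_matrix(m: DistanceMatrix, path) -> None:
    """Write a labeled distance matrix in PHYLIP square format."""
    data = np.asarray(m.data, float)
    if np.abs(data - data.T).max(initial=0.0) > 1e-9:
        raise ValueError("distance matrix asymmetric beyond 1e-9")
    labels = _phylip_labels(list(m.ids))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(labels)}\n")
        for name, row in zip(labels, data):
            fh.write(name.ljust(10) + "  " + "  ".join(f"{v:.8f}" for v in row) + "\n")


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix written by :func:`write_distance_matrix`."""
    with open(path, encoding="utf-8") as fh:
        n = int(fh.readline().strip())
        labels, rows = [], []
        for _ in range(n):
            line = fh.readline()
            labels.append(line[:10].strip())
            rows.append([float(v) for v in line[10:].split()])
    data = np.array(rows, float)
    data = (data + data.T) / 2.0  # absorb formatting round-off
    np.fill_diagonal(data, 0.0)
    return DistanceMatrix(data, ids=labels)


def load_accession_counts() -> pd.DataFrame:
    """Per-taxon accession counts for the Vitis9kSNP germplasm panel.

    Columns: taxon, n_before_filters, n_after_filters (NaN where the taxon
    was dropped entirely by curation).
    """
    ref = importlib.resources.files("arrayphylo") / "data" / "vitis_accessions.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")
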