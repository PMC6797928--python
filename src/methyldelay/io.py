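"""Readers, writers and probe filtering for the methylome pipeline.

All tabular interchange is TSV: a beta matrix is probes x samples with a
header row of sample ids and probe ids in the first column; manifests and
sample sheets are plain TSV tables; genomic intervals travel as BED3
(0-based, half-open).  Filter reports are JSON-serialisable dicts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = [
    "probe_id",
    "chromosome",
    "position",
    "strand",
    "gene_symbol",
    "region_category",
    "cpg_island",
    "snp_flag",
    "transcript_count",
]

REGION_CATEGORIES = ("promoter", "gene body", "3'UTR", "intergenic")

SAMPLE_COLUMNS = ["sample_id", "diagnosis", "age_group", "age_years", "pmi_hours"]


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclasses.dataclass
class FilterReport:
    """Counts of probes removed by the array QC rules, by reason.

    A probe may fail several rules; it is counted once per rule it fails,
    but ``total_removed`` counts distinct probes.
    """

    n_input: int
    n_retained: int
    total_removed: int
    removed_missing: int
    removed_snp: int
    removed_detection_p: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def probe_interval(position: int) -> tuple[int, int]:
    """Convert a 1-based CpG cytosine position to a 0-based half-open interval.

    The CpG dinucleotide occupies two bases, so probe at position ``p`` maps
    to ``[p-1, p+1)``.
    """
    return position - 1, position + 1


# ---------------------------------------------------------------------------
# beta matrix


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples beta matrix from TSV.

    Empty cells become NaN (missing).  Values outside [0, 1] or duplicated
    probe ids raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate probe ids: {dupes[:5]}")
    values = df.to_numpy(dtype=float)
    bad = (values < 0) | (values > 1)
    if np.any(bad & ~np.isnan(values)):
        i, j = np.argwhere(bad & ~np.isnan(values))[0]
        raise ValidationError(
            f"beta value {values[i, j]} outside [0, 1] at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return df.astype(float)


def write_beta_matrix(betas: pd.DataFrame, path: str | Path) -> None:
    betas.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# manifest / sample sheet


def read_manifest(path: str | Path) -> pd.DataFrame:
    mf = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    missing = set(MANIFEST_COLUMNS) - set(mf.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    if mf["probe_id"].duplicated().any():
        raise ValidationError("duplicate probe ids in manifest")
    if (mf["position"] < 1).any():
        raise ValidationError("manifest positions must be >= 1 (1-based)")
    unknown = set(mf["region_category"]) - set(REGION_CATEGORIES)
    if unknown:
        raise ValidationError(f"unknown region categories: {sorted(unknown)}")
    mf["gene_symbol"] = mf["gene_symbol"].fillna("")
    return mf


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    ss = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(SAMPLE_COLUMNS) - set(ss.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    if ss["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids")
    return ss


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into a sorted (chrom, start, end) frame.

    Coordinates are kept exactly as stored (0-based, half-open); intervals
    are sorted by (chrom, start, end) on read.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0:
                raise ValidationError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            rows.append((chrom, start, end))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return sort_peaks(peaks)


def write_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    sort_peaks(peaks).to_csv(path, sep="\t", header=False, index=False)


def sort_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    return peaks.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# probe filtering


def filter_probes(
    betas: pd.DataFrame,
    manifest: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    detection_p_cutoff: float = 0.05,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply array QC: drop probes with missing values, SNP flags, or a
    detection p-value above the cutoff in any sample.

    Surviving values are returned untouched.  Raises
    :class:`ValidationError` if any matrix probe is absent from the manifest.
    """
    mf = manifest.set_index("probe_id")
    absent = betas.index.difference(mf.index)
    if len(absent):
        raise ValidationError(f"probes missing from manifest: {list(absent[:5])}")

    has_missing = betas.isna().any(axis=1)
    is_snp = mf.loc[betas.index, "snp_flag"].astype(bool).to_numpy()
    is_snp = pd.Series(is_snp, index=betas.index)
    if detection_p is not None:
        detp = detection_p.reindex(index=betas.index, columns=betas.columns)
        fails_detp = (detp > detection_p_cutoff).any(axis=1)
    else:
        fails_detp = pd.Series(False, index=betas.index)

    drop = has_missing | is_snp | fails_detp
    retained = betas.loc[~drop]
    report = FilterReport(
        n_input=len(betas),
        n_retained=len(retained),
        total_removed=int(drop.sum()),
        removed_missing=int(has_missing.sum()),
        removed_snp=int(is_snp.sum()),
        removed_detection_p=int(fails_detp.sum()),
    )
    return retained, report


def write_filter_report(report: FilterReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
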