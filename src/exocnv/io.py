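"""Readers and writers for the on-disk formats.

Coordinate conventions
----------------------
Internal intervals are 0-based half-open.  BED files keep that convention
unchanged; every other TSV (call sets, truth/gold tables, databases,
counts window columns) uses 1-based inclusive coordinates, matching how
genomic coordinates are printed in clinical reports.  The conversion is
``disk_start = internal_start + 1``, ``disk_end = internal_end``; it is
lossless and round-trips exactly.

Malformed rows raise :class:`FormatError` carrying the 1-based line
number of the offending row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CaptureDesign, ReadCountMatrix, chrom_sort_key

__all__ = [
    "FormatError",
    "read_bed",
    "write_bed",
    "read_design_bed",
    "write_design_bed",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_calls_tsv",
    "write_calls_tsv",
    "read_database_tsv",
    "write_database_tsv",
    "read_snp_tsv",
    "write_snp_tsv",
    "write_manifest",
]


class FormatError(ValueError):
    """A parsing error that names the offending file and line."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


def _to_disk(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)
    return out


def _from_disk(df: pd.DataFrame, path) -> pd.DataFrame:
    out = df.copy()
    out["start"] = out["start"].astype(int) - 1
    out["end"] = out["end"].astype(int)
    bad = out.index[(out["start"] < 0) | (out["end"] <= out["start"])]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise FormatError(path, int(bad[0]) + 2, "invalid 1-based inclusive coordinates")
    return out


def _read_tsv(path, columns: list[str], dtypes: dict) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(path, 1, f"unreadable TSV: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(path, 1, f"missing columns: {missing}")
    for col, typ in dtypes.items():
        if typ is str:
            continue
        for i, v in enumerate(df[col]):
            if v == "" and typ is float:
                continue
            try:
                typ(v)
            except (TypeError, ValueError):
                raise FormatError(path, i + 2, f"bad value {v!r} in column {col!r}") from None
        df[col] = df[col].mask(df[col] == "", np.nan).astype(
            typ if typ is not int else np.int64
        )
    return df


# -- BED ---------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into 0-based half-open ``chrom, start, end[, name]``."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(path, i, "BED rows need at least 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(path, i, "non-integer BED coordinates") from None
            if start < 0 or end <= start:
                raise FormatError(path, i, f"invalid BED interval {start}-{end}")
            rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else ""))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in df.columns else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_design_bed(design: CaptureDesign, path) -> None:
    """Capture design as BED4 with name ``gene|exon_index``; chromosome
    lengths ride along in a ``.chrom_sizes`` sidecar."""
    bed = design.regions[["chrom", "start", "end"]].copy()
    bed["name"] = [
        f"{g}|{e}" for g, e in zip(design.regions["gene"], design.regions["exon_index"])
    ]
    write_bed(bed, path)
    sizes = Path(str(path) + ".chrom_sizes")
    with open(sizes, "w") as fh:
        for chrom in sorted(design.chrom_lengths, key=chrom_sort_key):
            fh.write(f"{chrom}\t{design.chrom_lengths[chrom]}\n")


def read_design_bed(path) -> CaptureDesign:
    bed = read_bed(path)
    genes, exons = [], []
    for i, name in enumerate(bed["name"], start=1):
        if "|" not in name:
            raise FormatError(path, i, f"design name column must be gene|exon_index, got {name!r}")
        g, e = name.rsplit("|", 1)
        genes.append(g)
        exons.append(int(e))
    regions = bed[["chrom", "start", "end"]].copy()
    regions["gene"] = genes
    regions["exon_index"] = exons
    sizes_path = Path(str(path) + ".chrom_sizes")
    if sizes_path.exists():
        sizes = {}
        with open(sizes_path) as fh:
            for line in fh:
                chrom, length = line.split("\t")
                sizes[chrom] = int(length)
    else:  # fall back to the observed extent
        sizes = {c: int(g["end"].max()) + 1 for c, g in regions.groupby("chrom")}
    return CaptureDesign(regions, sizes)


# -- window counts -----------------------------------------------------------

def write_counts_tsv(counts: ReadCountMatrix, path) -> None:
    """Counts as TSV: ``chrom, start, end, window_id`` then one column per
    sample (window coordinates 1-based inclusive on disk)."""
    head = _to_disk(counts.windows[["chrom", "start", "end", "window_id"]])
    body = pd.DataFrame(counts.counts, columns=counts.sample_ids)
    pd.concat([head.reset_index(drop=True), body.reset_index(drop=True)], axis=1).to_csv(
        path, sep="\t", index=False
    )


def read_counts_tsv(path, sexes: dict[str, str] | None = None) -> ReadCountMatrix:
    df = _read_tsv(path, ["chrom", "start", "end", "window_id"],
                   {"chrom": str, "start": int, "end": int, "window_id": str})
    windows = _from_disk(df[["chrom", "start", "end", "window_id"]], path)
    sample_ids = [c for c in df.columns if c not in ("chrom", "start", "end", "window_id")]
    if not sample_ids:
        raise FormatError(path, 1, "counts TSV has no sample columns")
    try:
        counts = df[sample_ids].astype(np.int64).to_numpy()
    except ValueError:
        raise FormatError(path, 1, "non-integer read counts") from None
    return ReadCountMatrix(windows=windows, counts=counts, sample_ids=sample_ids,
                           sexes=sexes or {})


# -- call sets / truth / gold ------------------------------------------------

_CALL_COLUMNS = {
    "sample": str, "chrom": str, "start": int, "end": int,
}


def read_calls_tsv(path) -> pd.DataFrame:
    """A call/truth/gold table; coordinates converted to 0-based half-open.

    Required columns ``sample, chrom, start, end``; any further columns
    (``cn``, ``copy_number``, ``bayes_factor``, ...) are typed when known.
    """
    extra_types = {
        "cn": int, "copy_number": int, "n_windows": int,
        "bayes_factor": float, "observed_ratio": float, "mosaic_fraction": float,
        "event_class": str, "tier": str,
    }
    df = _read_tsv(path, list(_CALL_COLUMNS), dict(_CALL_COLUMNS))
    for col, typ in extra_types.items():
        if col in df.columns:
            for i, v in enumerate(df[col]):
                if v == "" and typ is not str:
                    continue
                try:
                    typ(v)
                except (TypeError, ValueError):
                    raise FormatError(path, i + 2, f"bad value {v!r} in column {col!r}") from None
            if typ is int:
                df[col] = df[col].astype(np.int64)
            elif typ is float:
                df[col] = df[col].mask(df[col] == "", np.nan).astype(float)
    return _from_disk(df, path)


def write_calls_tsv(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    _to_disk(df).to_csv(path, sep="\t", index=False, float_format=float_format)


# -- databases ---------------------------------------------------------------

_DB_COLUMNS = ["chrom", "start", "end", "source", "classification", "frequency", "dosage_type"]
_DB_CLASSES = {"pathogenic", "benign", "unknown"}
_DB_DOSAGE = {"loss", "gain"}


def read_database_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path, _DB_COLUMNS,
                   {"chrom": str, "start": int, "end": int, "source": str,
                    "classification": str, "frequency": float, "dosage_type": str})
    for i, row in enumerate(df.itertuples(index=False)):
        if row.classification not in _DB_CLASSES:
            raise FormatError(path, i + 2, f"unknown classification {row.classification!r}")
        if row.dosage_type not in _DB_DOSAGE:
            raise FormatError(path, i + 2, f"unknown dosage_type {row.dosage_type!r}")
        if not (pd.isna(row.frequency) or 0 <= row.frequency <= 1):
            raise FormatError(path, i + 2, f"frequency out of [0,1]: {row.frequency}")
    return _from_disk(df, path)


def write_database_tsv(df: pd.DataFrame, path) -> None:
    _to_disk(df[_DB_COLUMNS]).to_csv(path, sep="\t", index=False)


# -- SNP allele counts -------------------------------------------------------

_SNP_COLUMNS = ["sample", "chrom", "pos", "ref_count", "alt_count"]


def read_snp_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path, _SNP_COLUMNS,
                   {"sample": str, "chrom": str, "pos": int,
                    "ref_count": int, "alt_count": int})
    df["pos"] = df["pos"] - 1  # disk positions are 1-based
    return df


def write_snp_tsv(df: pd.DataFrame, path) -> None:
    out = df[_SNP_COLUMNS].copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


# -- run manifest ------------------------------------------------------------

def write_manifest(path, *, command: str, inputs: dict, outputs: dict,
                   config_hash: str, seed: int | None) -> None:
    """Machine-readable record of a pipeline invocation."""
    manifest = {
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
        "config_hash": config_hash,
        "seed": seed,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
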