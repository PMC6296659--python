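"""Shared domain types for exome copy-number analysis.

All coordinates held in memory are 0-based, half-open (BED convention).
The on-disk TSV formats use 1-based inclusive coordinates; conversion is
done exclusively in :mod:`exocnv.io`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "CaptureDesign",
    "TruthEvent",
    "ReadCountMatrix",
    "chrom_sort_key",
    "jaccard_similarity",
    "reciprocal_overlap",
]

_CHROM_RE = re.compile(r"^(?:chr)?(.+)$", re.IGNORECASE)


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome ordering: chr1 < chr2 < ... < chr22 < chrX < chrY."""
    body = _CHROM_RE.match(chrom).group(1)
    if body.isdigit():
        return (0, int(body), "")
    if body.upper() == "X":
        return (1, 0, "")
    if body.upper() == "Y":
        return (1, 1, "")
    return (2, 0, body)


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """A half-open genomic span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # 1-based inclusive, the human convention
        return f"{self.chrom}:{self.start + 1:,}-{self.end:,}"


def jaccard_similarity(a: GenomicInterval, b: GenomicInterval) -> float:
    """Basepair Jaccard coefficient |a ∩ b| / |a ∪ b| between two intervals.

    Intervals on different chromosomes, or disjoint intervals, score 0; the
    union of disjoint intervals is the sum of their lengths.
    """
    inter = a.intersection_length(b)
    union = a.length + b.length - inter
    return inter / union


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(|a∩b|/|a|, |a∩b|/|b|): the fraction of the *larger* requirement met."""
    inter = a.intersection_length(b)
    if inter == 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


class CaptureDesign:
    """An exome capture design: target regions with gene/exon labels.

    Parameters
    ----------
    regions : pandas.DataFrame
        Columns ``chrom, start, end, gene, exon_index`` (0-based half-open).
        Regions must be sortable to a non-overlapping tiling per chromosome.
    chrom_lengths : dict
        Chromosome name -> length in bp; every region must fit inside.
    """

    def __init__(self, regions: pd.DataFrame, chrom_lengths: dict[str, int]):
        req = ["chrom", "start", "end", "gene", "exon_index"]
        missing = [c for c in req if c not in regions.columns]
        if missing:
            raise ValueError(f"capture design missing columns: {missing}")
        regions = regions.copy()
        regions["_key"] = regions["chrom"].map(chrom_sort_key)
        regions = (
            regions.sort_values(["_key", "start"]).drop(columns="_key").reset_index(drop=True)
        )
        if (regions["end"] <= regions["start"]).any():
            raise ValueError("capture regions must have length >= 1 bp")
        for chrom, grp in regions.groupby("chrom", sort=False):
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise ValueError(f"overlapping capture regions on {chrom}")
            if chrom not in chrom_lengths:
                raise ValueError(f"region on unknown chromosome {chrom}")
            if grp["end"].max() > chrom_lengths[chrom]:
                raise ValueError(f"region beyond end of {chrom}")
        self.regions = regions
        self.chrom_lengths = dict(chrom_lengths)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.regions["chrom"].unique(), key=chrom_sort_key)

    def __len__(self) -> int:
        return len(self.regions)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CaptureDesign)
            and self.chrom_lengths == other.chrom_lengths
            and self.regions.equals(other.regions)
        )

    def region_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, r.start, r.end)
            for r in self.regions.itertuples(index=False)
        ]


_EVENT_CLASSES = {"focal_cnv", "aneuploidy", "polymorphic_cnv"}


@dataclass(frozen=True)
class TruthEvent:
    """A simulated copy-number alteration carried by one sample.

    ``copy_number`` is the integer CN of the affected cells (2 is disallowed:
    an event must change copy number); ``mosaic_fraction`` is the fraction of
    cells carrying it (1 = constitutional).
    """

    sample: str
    interval: GenomicInterval
    copy_number: int
    mosaic_fraction: float = 1.0
    event_class: str = "focal_cnv"

    def __post_init__(self):
        if self.copy_number == 2 or self.copy_number < 0:
            raise ValueError(f"event copy_number must be >= 0 and != 2, got {self.copy_number}")
        if not 0 < self.mosaic_fraction <= 1:
            raise ValueError(f"mosaic_fraction must be in (0, 1], got {self.mosaic_fraction}")
        if self.event_class not in _EVENT_CLASSES:
            raise ValueError(f"unknown event_class {self.event_class!r}")

    @property
    def is_deletion(self) -> bool:
        return self.copy_number < 2


def truth_to_frame(events: list[TruthEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": e.sample,
                "chrom": e.interval.chrom,
                "start": e.interval.start,
                "end": e.interval.end,
                "copy_number": e.copy_number,
                "mosaic_fraction": e.mosaic_fraction,
                "event_class": e.event_class,
            }
            for e in events
        ],
        columns=[
            "sample",
            "chrom",
            "start",
            "end",
            "copy_number",
            "mosaic_fraction",
            "event_class",
        ],
    )


def frame_to_truth(df: pd.DataFrame) -> list[TruthEvent]:
    return [
        TruthEvent(
            sample=str(r.sample),
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            copy_number=int(r.copy_number),
            mosaic_fraction=float(r.mosaic_fraction),
            event_class=str(r.event_class),
        )
        for r in df.itertuples(index=False)
    ]


@dataclass
class ReadCountMatrix:
    """Integer read counts per window per sample.

    ``windows`` holds one row per window (``chrom, start, end, window_id``),
    sorted by chromosome then start; ``counts`` is the (n_windows, n_samples)
    integer matrix aligned to it.
    """

    windows: pd.DataFrame
    counts: np.ndarray
    sample_ids: list[str]
    sexes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.windows), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.windows)} windows, {len(self.sample_ids)} samples)"
            )
        if (self.counts < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.windows["window_id"].duplicated().any():
            raise ValueError("window ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        keys = [chrom_sort_key(c) for c in self.windows["chrom"]]
        order = list(zip(keys, self.windows["start"].tolist()))
        if order != sorted(order):
            raise ValueError("windows must be sorted by chromosome then start")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def column(self, sample: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample)]

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return (self.windows["chrom"] == chrom).to_numpy()

    def window_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(w.chrom, w.start, w.end)
            for w in self.windows.itertuples(index=False)
        ]
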