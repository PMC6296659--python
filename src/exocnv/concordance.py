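"""Concordance of read-depth CNV calls against an array gold standard.

Gold-standard (array) calls are first stratified by detectability: a call
is *potentially detectable* when it overlaps at least one capture window,
*non-repeated* when no other patient carries a same-direction call at
>= 50% reciprocal overlap, and *adequately covered* when it overlaps a
characterised coding gene with usable cohort depth.  Calls are then
matched to same-sample, same-direction WES calls by basepair overlap, and
sensitivity is reported per stratum and direction.
"""

from __future__ import annotations

from fnmatch import fnmatch

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._util import round_half_up
from .core import CaptureDesign, GenomicInterval, ReadCountMatrix, jaccard_similarity, reciprocal_overlap

__all__ = [
    "classify_detectability",
    "match_calls",
    "stratified_sensitivity",
]

STRATA = ["all_detectable", "non_repeated", "non_repeated_covered"]


def _window_trees(counts: ReadCountMatrix) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in counts.windows.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), int(i))
            for i, (s, e) in zip(grp.index, zip(grp["start"], grp["end"]))
        )
    return trees


def _is_uncharacterized(gene: str, patterns: tuple[str, ...]) -> bool:
    return any(fnmatch(str(gene), p) for p in patterns)


def classify_detectability(gold: pd.DataFrame, design: CaptureDesign,
                           counts: ReadCountMatrix, min_depth: float = 10.0,
                           uncharacterized_patterns: tuple[str, ...] = ("LOC*", "LINC*"),
                           reciprocal: float = 0.5) -> pd.DataFrame:
    """Add detectability strata flags to a gold-standard call table.

    ``gold`` needs columns ``sample, chrom, start, end, copy_number``.
    """
    out = gold.reset_index(drop=True).copy()
    trees = _window_trees(counts)
    pot, cov = [], []
    for row in out.itertuples(index=False):
        tree = trees.get(row.chrom)
        hits = sorted(tree.overlap(int(row.start), int(row.end))) if tree else []
        pot.append(len(hits) > 0)
        if not hits:
            cov.append(False)
            continue
        widx = [h.data for h in hits]
        depth_ok = float(np.median(counts.counts[widx, :])) >= min_depth
        genes = design.regions[
            (design.regions["chrom"] == row.chrom)
            & (design.regions["start"] < row.end)
            & (design.regions["end"] > row.start)
        ]["gene"]
        gene_ok = any(not _is_uncharacterized(g, uncharacterized_patterns) for g in genes)
        cov.append(depth_ok and gene_ok)
    out["potentially_detectable"] = pot
    out["adequately_covered"] = cov

    nr = []
    for i, row in enumerate(out.itertuples(index=False)):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        repeated = False
        for j, other in enumerate(out.itertuples(index=False)):
            if j == i or other.sample == row.sample or other.chrom != row.chrom:
                continue
            if (int(other.copy_number) < 2) != (int(row.copy_number) < 2):
                continue
            o = GenomicInterval(other.chrom, int(other.start), int(other.end))
            if reciprocal_overlap(iv, o) >= reciprocal:
                repeated = True
                break
        nr.append(not repeated)
    out["non_repeated"] = nr
    return out


def match_calls(gold: pd.DataFrame, wes: pd.DataFrame, same_direction: bool = True,
                min_overlap_bp: int = 1) -> pd.DataFrame:
    """Match each gold call to WES calls in the same sample by overlap.

    A gold call is matched when a WES call in the same sample, on the same
    chromosome (and in the same direction, by default) overlaps it by at
    least ``min_overlap_bp``; its best match maximises the Jaccard
    similarity.  One WES call may match several gold calls.
    """
    out = gold.reset_index(drop=True).copy()
    matched, jac = [], []
    for row in out.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        cand = wes[(wes["sample"] == row.sample) & (wes["chrom"] == row.chrom)]
        best = None
        for w in cand.itertuples(index=False):
            if same_direction and (int(w.cn) < 2) != (int(row.copy_number) < 2):
                continue
            wiv = GenomicInterval(w.chrom, int(w.start), int(w.end))
            if iv.intersection_length(wiv) >= min_overlap_bp:
                j = jaccard_similarity(iv, wiv)
                if best is None or j > best:
                    best = j
        matched.append(best is not None)
        jac.append(best if best is not None else np.nan)
    out["matched"] = matched
    out["jaccard"] = jac
    return out


def sensitivity_percent(detected: int, total: int) -> float:
    """100 * detected / total, round-half-up to one decimal (NaN if total 0)."""
    if total == 0:
        return float("nan")
    return round_half_up(100.0 * detected / total, 1)


def stratified_sensitivity(rows: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity per detectability stratum and call direction.

    ``rows`` must carry the strata flags from :func:`classify_detectability`
    and the ``matched`` flag from :func:`match_calls`.  Strata are nested:
    all potentially detectable calls, the non-repeated subset, and the
    non-repeated and adequately covered subset.
    """
    masks = {
        "all_detectable": rows["potentially_detectable"],
        "non_repeated": rows["potentially_detectable"] & rows["non_repeated"],
        "non_repeated_covered": (rows["potentially_detectable"] & rows["non_repeated"]
                                 & rows["adequately_covered"]),
    }
    directions = {
        "deletion": rows["copy_number"] < 2,
        "duplication": rows["copy_number"] > 2,
    }
    records = []
    for stratum in STRATA:
        for direction, dmask in directions.items():
            sub = rows[masks[stratum] & dmask]
            detected = int(sub["matched"].sum())
            total = len(sub)
            records.append({
                "stratum": stratum,
                "direction": direction,
                "detected": detected,
                "total": total,
                "percent": sensitivity_percent(detected, total),
            })
    return pd.DataFrame(records)
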