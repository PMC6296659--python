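"""Annotation and tiered prioritisation of CNV calls.

Calls are annotated with basepair Jaccard similarity against curated
interval databases (an ISCA-like table of clinically classified CNVs and
a DGV-like table of population-polymorphic variants), overlapped exon
counts from the capture design, recurrence across the cohort, and the
consistency of heterozygous-SNP allele fractions with the called copy
number.  A three-level tier (high/medium/low) operationalises the usual
sign-out filters: Bayes-factor cutoffs at 20 and 100, a 100 kb size
criterion, a minimum exon count, an ISCA pathogenic-similarity criterion,
and a cap on recurrence in other samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .core import CaptureDesign, GenomicInterval, jaccard_similarity, reciprocal_overlap

__all__ = [
    "jaccard_similarity",
    "count_exons",
    "vaf_consistency",
    "cohort_recurrence",
    "assign_tier",
    "CallAnnotator",
]

ANNOTATION_COLUMNS = [
    "size_bp", "n_exons", "isca_best_similarity", "isca_class",
    "dgv_max_freq", "recurrence", "vaf_consistency", "tier",
]


def count_exons(interval: GenomicInterval, design: CaptureDesign) -> int:
    """Number of annotated exon targets overlapping the interval by >= 1 bp."""
    grp = design.regions[design.regions["chrom"] == interval.chrom]
    return int(((grp["start"] < interval.end) & (grp["end"] > interval.start)).sum())


def _band_width(depth: float, band_half_width: float) -> float:
    # binomial sampling noise dominates below ~30x
    if depth >= 30:
        return band_half_width
    return max(band_half_width, 2 * np.sqrt(0.25 / max(depth, 1.0)))


def vaf_consistency(cn: int, fractions: np.ndarray, depths: np.ndarray,
                    band_half_width: float = 0.1) -> float | None:
    """Fraction of het-site allele fractions inside the band expected for cn.

    Deletions (CN 0/1) expect hemizygous fractions in [0, w] or [1 - w, 1];
    single-copy gains expect fractions near 1/3 or 2/3; diploid near 1/2.
    Returns None when no sites overlap the call.
    """
    fractions = np.asarray(fractions, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if fractions.size == 0:
        return None
    w = np.array([_band_width(d, band_half_width) for d in depths])
    if cn <= 1:
        ok = (fractions <= w) | (fractions >= 1 - w)
    elif cn == 2:
        ok = np.abs(fractions - 0.5) <= w
    else:
        ok = (np.abs(fractions - 1 / 3) <= w) | (np.abs(fractions - 2 / 3) <= w)
    return float(ok.mean())


def _same_direction(cn_a: int, cn_b: int) -> bool:
    return (cn_a < 2) == (cn_b < 2)


def cohort_recurrence(call: pd.Series, all_calls: pd.DataFrame,
                      reciprocal: float = 0.5) -> int:
    """Distinct other samples carrying a same-direction call at >= reciprocal overlap."""
    iv = GenomicInterval(call["chrom"], int(call["start"]), int(call["end"]))
    others = all_calls[(all_calls["sample"] != call["sample"])
                       & (all_calls["chrom"] == call["chrom"])]
    hits = set()
    for o in others.itertuples(index=False):
        if not _same_direction(int(call["cn"]), int(o.cn)):
            continue
        if reciprocal_overlap(iv, GenomicInterval(o.chrom, int(o.start), int(o.end))) >= reciprocal:
            hits.add(o.sample)
    return len(hits)


def assign_tier(row: pd.Series, bf_high: float = 100.0, bf_medium: float = 20.0,
                size_high_bp: int = 100_000, min_exons_high: int = 3,
                isca_similarity_min: float = 0.5, recurrence_cap: int = 2) -> str:
    """Tier a fully annotated call as high/medium/low priority."""
    bf = float(row["bayes_factor"])
    rec_ok = int(row["recurrence"]) <= recurrence_cap
    isca_ok = (
        float(row["isca_best_similarity"]) >= isca_similarity_min
        and row.get("isca_class") == "pathogenic"
    )
    if (bf > bf_high and int(row["n_exons"]) >= min_exons_high and rec_ok
            and (int(row["size_bp"]) > size_high_bp or isca_ok)):
        return "high"
    if bf > bf_medium and rec_ok:
        return "medium"
    return "low"


class CallAnnotator(BaseEstimator, TransformerMixin):
    """Annotate a CNV call table and assign priority tiers.

    ``transform`` takes a call frame (columns ``sample, chrom, start, end,
    cn, bayes_factor, n_windows, observed_ratio``) and appends ``size_bp,
    n_exons, isca_best_similarity, isca_class, dgv_max_freq, recurrence,
    vaf_consistency, tier``.  Annotation is pure and idempotent: existing
    annotation columns are recomputed.

    Parameters
    ----------
    design : CaptureDesign, optional
        Exon targets for exon counting.
    isca : pandas.DataFrame, optional
        ISCA-like records (``chrom, start, end, source, classification,
        frequency, dosage_type``); similarity is computed only against
        same-direction records (loss vs deletion, gain vs duplication).
    dgv : pandas.DataFrame, optional
        DGV-like records; the maximum population frequency of any
        overlapping record is reported.
    snp_counts : pandas.DataFrame, optional
        Het-SNP allele counts (``sample, chrom, pos, ref_count, alt_count``).
    """

    def __init__(self, design: CaptureDesign | None = None,
                 isca: pd.DataFrame | None = None,
                 dgv: pd.DataFrame | None = None,
                 snp_counts: pd.DataFrame | None = None,
                 band_half_width: float = 0.1, reciprocal: float = 0.5,
                 bf_high: float = 100.0, bf_medium: float = 20.0,
                 size_high_bp: int = 100_000, min_exons_high: int = 3,
                 isca_similarity_min: float = 0.5, recurrence_cap: int = 2):
        self.design = design
        self.isca = isca
        self.dgv = dgv
        self.snp_counts = snp_counts
        self.band_half_width = band_half_width
        self.reciprocal = reciprocal
        self.bf_high = bf_high
        self.bf_medium = bf_medium
        self.size_high_bp = size_high_bp
        self.min_exons_high = min_exons_high
        self.isca_similarity_min = isca_similarity_min
        self.recurrence_cap = recurrence_cap

    def fit(self, X: pd.DataFrame, y=None):
        self.n_calls_ = len(X)
        return self

    def _isca_best(self, iv: GenomicInterval, cn: int) -> tuple[float, str]:
        if self.isca is None or self.isca.empty:
            return 0.0, ""
        best, best_class = 0.0, ""
        sub = self.isca[self.isca["chrom"] == iv.chrom]
        want = "loss" if cn < 2 else "gain"
        for rec in sub.itertuples(index=False):
            if rec.dosage_type != want:
                continue
            j = jaccard_similarity(iv, GenomicInterval(rec.chrom, int(rec.start), int(rec.end)))
            if j > best:
                best, best_class = j, rec.classification
        return best, best_class

    def _dgv_max_freq(self, iv: GenomicInterval) -> float:
        if self.dgv is None or self.dgv.empty:
            return 0.0
        sub = self.dgv[(self.dgv["chrom"] == iv.chrom)
                       & (self.dgv["start"] < iv.end) & (self.dgv["end"] > iv.start)]
        if sub.empty:
            return 0.0
        return float(pd.to_numeric(sub["frequency"], errors="coerce").fillna(0).max())

    def _vaf(self, sample: str, iv: GenomicInterval, cn: int) -> float | None:
        if self.snp_counts is None or self.snp_counts.empty:
            return None
        sub = self.snp_counts[
            (self.snp_counts["sample"] == sample)
            & (self.snp_counts["chrom"] == iv.chrom)
            & (self.snp_counts["pos"] >= iv.start)
            & (self.snp_counts["pos"] < iv.end)
        ]
        if sub.empty:
            return None
        depth = (sub["ref_count"] + sub["alt_count"]).to_numpy(dtype=float)
        frac = sub["alt_count"].to_numpy(dtype=float) / depth
        return vaf_consistency(cn, frac, depth, self.band_half_width)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        calls = X.drop(columns=[c for c in ANNOTATION_COLUMNS if c in X.columns]).copy()
        out = calls.reset_index(drop=True)
        size, nex, isim, icls, dfreq, rec, vaf = [], [], [], [], [], [], []
        for row in out.itertuples(index=False):
            iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
            size.append(iv.length)
            nex.append(count_exons(iv, self.design) if self.design is not None else 0)
            s, c = self._isca_best(iv, int(row.cn))
            isim.append(s)
            icls.append(c)
            dfreq.append(self._dgv_max_freq(iv))
            vaf.append(self._vaf(row.sample, iv, int(row.cn)))
        for i in range(len(out)):
            rec.append(cohort_recurrence(out.iloc[i], out, self.reciprocal))
        out["size_bp"] = size
        out["n_exons"] = nex
        out["isca_best_similarity"] = isim
        out["isca_class"] = icls
        out["dgv_max_freq"] = dfreq
        out["recurrence"] = rec
        out["vaf_consistency"] = vaf
        out["tier"] = [
            assign_tier(out.iloc[i], self.bf_high, self.bf_medium, self.size_high_bp,
                        self.min_exons_high, self.isca_similarity_min, self.recurrence_cap)
            for i in range(len(out))
        ]
        return out
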