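"""Whole-chromosome copy number and mosaicism from capture-restricted coverage.

Per-sample chromosomal read counts (restricted to capture windows) are
normalised so every sample has the same total, then expressed as a ratio
to the cross-sample mean for each chromosome.  Under diploidy these ratios
are approximately normal around 1, so single outlying samples are flagged
with the two-sided Grubbs test; the ratio itself gives the predicted
integer copy number and, for intermediate values, the mosaic cell
fraction (a whole-chromosome loss present in a fraction f of cells
depresses coverage to 1 - f/2 of expected on a disomic baseline, or
1 - f on the single-copy male chrY baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as student_t
from sklearn.base import BaseEstimator

from .core import ReadCountMatrix, chrom_sort_key

__all__ = [
    "ChromosomeRatioTable",
    "adjusted_chromosome_counts",
    "chromosome_ratios",
    "grubbs_critical_value",
    "grubbs_test",
    "estimate_mosaic_fraction",
    "AneuploidyDetector",
]


@dataclass
class ChromosomeRatioTable:
    """Adjusted per-chromosome counts and coverage ratios for a cohort."""

    adjusted: pd.DataFrame           # chromosomes x samples, normalised counts
    scale_factors: pd.Series         # k_s per sample
    ratios: pd.DataFrame | None = None
    sexes: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.adjusted.columns)


def adjusted_chromosome_counts(counts: ReadCountMatrix) -> ChromosomeRatioTable:
    """Sum window counts per chromosome and equalise per-sample totals.

    A_{c,s} = k_s * sum_w y_{w,s} with k_s = mean(total)/total_s, so after
    adjustment every sample's total equals the common mean total.
    """
    totals = counts.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        zero = [s for s, t in zip(counts.sample_ids, totals) if t == 0]
        raise ValueError(f"samples with zero total counts: {zero}")
    k = totals.mean() / totals
    per_chrom = (
        pd.DataFrame(counts.counts, columns=counts.sample_ids)
        .groupby(counts.windows["chrom"].to_numpy())
        .sum()
    )
    per_chrom = per_chrom.loc[sorted(per_chrom.index, key=chrom_sort_key)]
    adjusted = per_chrom * k
    return ChromosomeRatioTable(
        adjusted=adjusted,
        scale_factors=pd.Series(k, index=counts.sample_ids),
        sexes=dict(counts.sexes),
    )


def infer_sexes(table: ChromosomeRatioTable, male_share_threshold: float = 0.4,
                min_male_share: float = 1e-3) -> dict[str, str]:
    """Classify samples as male by their chrY share of adjusted counts.

    A sample is male when its chrY share exceeds ``male_share_threshold``
    times the male-typical (maximum) share; the threshold is deliberately
    below one half so that a 50%-mosaic loss of Y still groups with males.
    An all-female cohort is recognised by the maximum share itself being
    negligible (< ``min_male_share``).
    """
    if "chrY" not in table.adjusted.index:
        return {s: "F" for s in table.samples}
    share = table.adjusted.loc["chrY"] / table.adjusted.sum(axis=0)
    typical = share.max()
    if typical < min_male_share:
        return {s: "F" for s in table.samples}
    return {s: ("M" if share[s] > male_share_threshold * typical else "F")
            for s in table.samples}


def chromosome_ratios(table: ChromosomeRatioTable, sex_stratify: bool = True,
                      sexes: dict[str, str] | None = None,
                      male_share_threshold: float = 0.4,
                      include_self_in_mean: bool = True) -> ChromosomeRatioTable:
    """Coverage ratio of each sample to the cross-sample mean per chromosome.

    For chrX and chrY the mean is taken within the sample's sex group when
    ``sex_stratify`` is on (sex inferred from chrY share unless supplied).
    Chromosomes with zero group mean (e.g. chrY in females) get NaN ratios.
    """
    A = table.adjusted
    if A.shape[1] < 3:
        raise ValueError("chromosome ratios need at least 3 samples")
    if sexes is None:
        sexes = table.sexes or {}
        if sex_stratify and not sexes:
            sexes = infer_sexes(table, male_share_threshold)
    ratios = pd.DataFrame(index=A.index, columns=A.columns, dtype=float)
    sex_chroms = [c for c in ("chrX", "chrY") if c in A.index]
    auto = [c for c in A.index if c not in sex_chroms]

    def _ratio_block(block: pd.DataFrame) -> pd.DataFrame:
        if include_self_in_mean:
            mean = block.mean(axis=1)
            return block.div(mean, axis=0).where(mean != 0)
        n = block.shape[1]
        if n < 2:
            raise ValueError("need >= 2 samples to exclude self from the mean")
        loo = (block.sum(axis=1).to_numpy()[:, None] - block.to_numpy()) / (n - 1)
        out = block / loo
        return out.where(pd.DataFrame(loo, index=block.index, columns=block.columns) != 0)

    ratios.loc[auto] = _ratio_block(A.loc[auto])
    if sex_chroms:
        if sex_stratify:
            groups: dict[str, list[str]] = {"M": [], "F": []}
            for s in A.columns:
                groups[sexes.get(s, "F")].append(s)
            for g, members in groups.items():
                if not members:
                    continue
                if len(members) < 3:
                    raise ValueError(
                        f"sex group {g!r} has fewer than 3 samples; cannot stratify"
                    )
                ratios.loc[sex_chroms, members] = _ratio_block(A.loc[sex_chroms, members])
        else:
            ratios.loc[sex_chroms] = _ratio_block(A.loc[sex_chroms])
    return ChromosomeRatioTable(
        adjusted=A, scale_factors=table.scale_factors, ratios=ratios, sexes=dict(sexes)
    )


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit(alpha, n).

    ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t on n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = student_t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(values: np.ndarray, alpha: float = 0.05,
                iterative: bool = True) -> pd.DataFrame:
    """Two-sided Grubbs outlier test, optionally applied iteratively.

    Returns a frame aligned to ``values`` with columns ``g`` (each point's
    studentised deviation at its testing round), ``g_crit`` and
    ``outlier``.  With ``iterative`` the flagged point is removed and the
    test repeated until no rejection, or until 10% of the sample (at least
    one point) has been removed.  Zero variance means no outlier by
    definition; NaN entries are ignored.
    """
    x = np.asarray(values, dtype=float)
    n0 = int(np.isfinite(x).sum())
    if n0 < 3:
        raise ValueError("Grubbs test requires at least 3 finite values")
    out = pd.DataFrame({
        "g": np.full(len(x), np.nan),
        "g_crit": np.full(len(x), np.nan),
        "outlier": np.zeros(len(x), dtype=bool),
    })
    active = np.isfinite(x)
    max_removals = max(1, int(0.1 * n0))
    removed = 0
    while True:
        idx = np.nonzero(active)[0]
        n = len(idx)
        if n < 3:
            break
        xa = x[idx]
        s = xa.std(ddof=1)
        gcrit = grubbs_critical_value(n, alpha)
        if s == 0:
            out.loc[idx, "g"] = 0.0
            out.loc[idx, "g_crit"] = gcrit
            break
        g = np.abs(xa - xa.mean()) / s
        out.loc[idx, "g"] = g
        out.loc[idx, "g_crit"] = gcrit
        imax = int(np.argmax(g))
        if g[imax] > gcrit and removed < max_removals:
            out.loc[idx[imax], "outlier"] = True
            active[idx[imax]] = False
            removed += 1
            if not iterative:
                break
        else:
            break
    return out


def estimate_mosaic_fraction(ratio: float, baseline_ploidy: int) -> float:
    """Cell fraction carrying a single-copy gain/loss implied by a ratio.

    On a disomic baseline a fraction f shifts coverage by f/2 per copy, so
    f = 2|rho - 1| clipped to [0, 1] (1 at a constitutional trisomy or
    monosomy); on a monosomic baseline (male chrY) f = |1 - rho|.
    """
    if not np.isfinite(ratio) or ratio < 0:
        return float("nan")
    if baseline_ploidy == 2:
        return float(np.clip(2 * abs(ratio - 1), 0, 1))
    if baseline_ploidy == 1:
        return float(np.clip(abs(1 - ratio), 0, 1))
    if baseline_ploidy == 0:
        return float("nan")
    raise ValueError("baseline_ploidy must be 0, 1 or 2")


def _baseline_ploidy(chrom: str, sex: str) -> int:
    if chrom == "chrY":
        return 1 if sex == "M" else 0
    if chrom == "chrX":
        return 1 if sex == "M" else 2
    return 2


class AneuploidyDetector(BaseEstimator):
    """Grubbs-test screen for whole-chromosome gains and losses.

    Fit on a :class:`~exocnv.core.ReadCountMatrix`; ``results_`` holds one
    row per (sample, chromosome) with the coverage ratio, Grubbs statistic
    and critical value, outlier flag, predicted integer copy number and
    estimated mosaic fraction.  An aneuploidy is *reported* (``called``
    column, :meth:`aneuploidies`) when a sample is the Grubbs outlier for
    a chromosome and its mosaic fraction estimate reaches
    ``min_mosaic_fraction`` — a pure statistical outlier at a biologically
    negligible deviation is not an aneuploidy.

    Parameters
    ----------
    alpha : float, default 0.05
        Two-sided Grubbs significance level per chromosome.
    iterative : bool, default True
        Re-test after removing a flagged sample (cap: 10% of cohort), so
        two aneuploid samples do not mask each other.
    sex_stratify : bool, default True
        Compare chrX/chrY within inferred (or given) sex groups.
    min_mosaic_fraction : float, default 0.2
        Effect-size floor for reporting an aneuploidy.
    male_share_threshold : float, default 0.4
        Fraction of the male-typical chrY share above which a sample is
        classified male.
    include_self_in_mean : bool, default True
        Whether the cross-sample mean includes the sample under test.
    """

    def __init__(self, alpha: float = 0.05, iterative: bool = True,
                 sex_stratify: bool = True, min_mosaic_fraction: float = 0.2,
                 male_share_threshold: float = 0.4,
                 include_self_in_mean: bool = True):
        self.alpha = alpha
        self.iterative = iterative
        self.sex_stratify = sex_stratify
        self.min_mosaic_fraction = min_mosaic_fraction
        self.male_share_threshold = male_share_threshold
        self.include_self_in_mean = include_self_in_mean

    def fit(self, X: ReadCountMatrix, y=None, sexes: dict[str, str] | None = None):
        if not isinstance(X, ReadCountMatrix):
            raise TypeError("AneuploidyDetector.fit expects a ReadCountMatrix")
        table = adjusted_chromosome_counts(X)
        if sexes is not None:
            table.sexes = dict(sexes)
        table = chromosome_ratios(
            table, sex_stratify=self.sex_stratify,
            male_share_threshold=self.male_share_threshold,
            include_self_in_mean=self.include_self_in_mean,
        )
        self.table_ = table
        rows = []
        for chrom in table.ratios.index:
            r = table.ratios.loc[chrom]
            finite = r[np.isfinite(r.to_numpy(dtype=float))]
            if len(finite) >= 3:
                gt = grubbs_test(finite.to_numpy(dtype=float), alpha=self.alpha,
                                 iterative=self.iterative)
                gt.index = finite.index
            else:
                gt = pd.DataFrame(index=finite.index,
                                  columns=["g", "g_crit", "outlier"])
            for s in table.samples:
                rho = float(r[s]) if np.isfinite(r[s]) else float("nan")
                sex = table.sexes.get(s, "F")
                ploidy = _baseline_ploidy(chrom, sex)
                frac = estimate_mosaic_fraction(rho, ploidy)
                cn = (int(np.clip(np.floor(ploidy * rho + 0.5), 0, 4))
                      if np.isfinite(rho) else -1)
                is_out = bool(gt["outlier"].get(s, False))
                rows.append({
                    "sample": s,
                    "chrom": chrom,
                    "ratio": rho,
                    "g": float(gt["g"].get(s, np.nan)),
                    "g_crit": float(gt["g_crit"].get(s, np.nan)),
                    "outlier": is_out,
                    "predicted_cn": cn,
                    "mosaic_fraction": frac,
                    "called": bool(
                        is_out
                        and np.isfinite(frac)
                        and frac >= self.min_mosaic_fraction
                    ),
                })
        self.results_ = pd.DataFrame(rows)
        return self

    def aneuploidies(self) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "results_")
        return self.results_[self.results_["called"]].reset_index(drop=True)

    def summary_lines(self) -> list[str]:
        """Karyotype-style lines, e.g. ``S005: chr21x3 (f=1.00)``."""
        out = []
        for r in self.aneuploidies().itertuples(index=False):
            out.append(
                f"{r.sample}: {r.chrom}x{r.predicted_cn} "
                f"(ratio={r.ratio:.3f}, f={r.mosaic_fraction:.2f})"
            )
        return out
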