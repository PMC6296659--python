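"""Focal CNV calling from window read counts.

The model follows the read-depth framework used for targeted sequencing:
for a test sample, a reference set of similar samples is aggregated, the
test read count in each window is modelled as beta-binomial given the
window total (test + reference), and a 3-state hidden Markov model over
copy numbers {1, 2, 3} is decoded by the Viterbi algorithm.  Each maximal
non-diploid run becomes a call scored with a Bayes factor: the log10
likelihood ratio of the called state to the diploid state summed over the
call's windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import betabinom, binom
from sklearn.base import BaseEstimator

from .core import CaptureDesign, GenomicInterval, ReadCountMatrix

__all__ = [
    "bin_capture_regions",
    "select_reference",
    "fit_emission_params",
    "state_fraction",
    "call_cnvs",
    "genotype_ratio",
    "ReferenceSet",
    "EmissionParams",
    "CnvCall",
    "CnvCaller",
    "calls_to_frame",
]

_LN10 = np.log(10.0)
_STATES = (1, 2, 3)  # copy numbers; index 1 is diploid
_DIPLOID_IDX = 1
_THETA_TINY = 1e-12
_CN0_EPS = 1e-4


def bin_capture_regions(design: CaptureDesign, window_bp: int = 100) -> pd.DataFrame:
    """Tile every capture region left-to-right into windows of ``window_bp``.

    A final remainder shorter than ``window_bp`` becomes its own window when
    it is at least half a window long, and is otherwise merged into the
    preceding window; a region shorter than half a window is kept whole.
    Windows tile the regions exactly, with no gaps or overlaps.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if len(design) == 0:
        raise ValueError("cannot bin an empty capture design")
    rows = []
    for reg in design.regions.itertuples(index=False):
        length = reg.end - reg.start
        n_full, rem = divmod(length, window_bp)
        bounds = [reg.start + i * window_bp for i in range(n_full + 1)]
        if rem:
            if rem >= window_bp / 2 or n_full == 0:
                bounds.append(reg.end)  # remainder kept as its own window
            else:
                bounds[-1] = reg.end  # merged into the preceding window
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append((reg.chrom, s, e))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out["window_id"] = [f"w{i:07d}" for i in range(len(out))]
    return out


@dataclass
class ReferenceSet:
    """Aggregated background for one test sample."""

    test_sample: str
    members: list[str]
    aggregate: np.ndarray  # r_w: summed member counts per window
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.members:
            raise ValueError("reference set must have at least one member")
        if self.test_sample in self.members:
            raise ValueError("test sample cannot be its own reference")
        if (np.asarray(self.aggregate) < 0).any():
            raise ValueError("aggregated reference counts must be non-negative")


@dataclass
class EmissionParams:
    """Beta-binomial emission parameters for one test/reference pair.

    phi is the expected diploid test-read fraction (constant across windows
    under the global-ratio fit); theta the beta-binomial overdispersion
    (0 degenerates to binomial); q the per-window probability of leaving
    the diploid state; cnv_mean_windows the expected CNV length in windows.
    """

    phi: float
    theta: float
    q: float = 1e-4
    cnv_mean_windows: float = 50.0

    def __post_init__(self):
        if not 0 < self.phi < 1:
            raise ValueError(f"phi must be in (0, 1), got {self.phi}")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not 0 < self.q < 0.5:
            raise ValueError("q must be in (0, 0.5)")
        if self.cnv_mean_windows < 1:
            raise ValueError("cnv_mean_windows must be >= 1")


@dataclass
class CnvCall:
    sample: str
    interval: GenomicInterval
    cn: int
    bayes_factor: float
    n_windows: int
    observed_ratio: float

    def __post_init__(self):
        if not np.isfinite(self.bayes_factor):
            raise ValueError("bayes_factor must be finite")
        if self.n_windows < 1:
            raise ValueError("a call must span at least one window")

    @property
    def is_deletion(self) -> bool:
        return self.cn < 2


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample,
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "cn": c.cn,
                "bayes_factor": c.bayes_factor,
                "n_windows": c.n_windows,
                "observed_ratio": c.observed_ratio,
            }
            for c in calls
        ],
        columns=[
            "sample",
            "chrom",
            "start",
            "end",
            "cn",
            "bayes_factor",
            "n_windows",
            "observed_ratio",
        ],
    )


def _log_profiles(counts: np.ndarray) -> np.ndarray:
    """Log-CPM window profiles used for reference-candidate correlation."""
    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ValueError("sample with zero total counts")
    return np.log1p(counts / totals * 1e6)


def _predicted_variance(y: np.ndarray, r: np.ndarray, chroms: np.ndarray | None,
                        theta_floor: float) -> float:
    """Mean predicted sampling variance of the test fraction given a reference."""
    params = fit_emission_params(y, r, chroms=chroms, theta_floor=theta_floor)
    n = y + r
    ok = n > 0
    n = n[ok].astype(float)
    phi = params.phi
    v = phi * (1 - phi) * (1 + (n - 1) * params.theta) / n
    return float(v.mean())


def select_reference(test: str, counts: ReadCountMatrix, max_members: int = 10,
                     theta_floor: float = 0.0,
                     candidates: list[str] | None = None) -> ReferenceSet:
    """Choose background samples for ``test`` by read-count similarity.

    Candidates are ranked by Pearson correlation between log-transformed,
    total-normalised window profiles (ties broken by sample-id order) and
    added greedily while the predicted beta-binomial variance of the test
    fraction keeps decreasing, up to ``max_members``.  ``candidates``
    restricts the pool (e.g. to sex-matched samples).
    """
    if counts.n_samples < 2:
        raise ValueError("cannot build background from a single-sample cohort")
    if max_members < 1:
        raise ValueError("max_members must be >= 1")
    ti = counts.sample_index(test)
    prof = _log_profiles(counts.counts)
    z = prof - prof.mean(axis=0)
    denom = np.sqrt((z ** 2).sum(axis=0))
    denom[denom == 0] = 1.0
    corr = (z * z[:, [ti]]).sum(axis=0) / (denom * denom[ti])
    if candidates is None:
        candidates = counts.sample_ids
    candidates = [s for s in sorted(candidates) if s != test]
    if not candidates:
        raise ValueError("cannot build background: no eligible reference candidates")
    scores = {s: float(corr[counts.sample_index(s)]) for s in candidates}
    # stable sort on descending correlation keeps id-order tie-breaking
    ranked = sorted(candidates, key=lambda s: -scores[s])

    chroms = counts.windows["chrom"].to_numpy()
    y = counts.counts[:, ti]
    members: list[str] = []
    aggregate = np.zeros(counts.n_windows, dtype=np.int64)
    best_v = np.inf
    for cand in ranked:
        if len(members) >= max_members:
            break
        trial = aggregate + counts.column(cand)
        v = _predicted_variance(y, trial, chroms, theta_floor)
        if v < best_v:
            members.append(cand)
            aggregate = trial
            best_v = v
        else:
            break
    return ReferenceSet(test_sample=test, members=members, aggregate=aggregate, scores=scores)


def fit_emission_params(y: np.ndarray, r: np.ndarray, chroms: np.ndarray | None = None,
                        theta_floor: float = 0.0, q: float = 1e-4,
                        cnv_mean_windows: float = 50.0) -> EmissionParams:
    """Fit the diploid test fraction and overdispersion by moments.

    phi comes from the global count ratio t = Σy/Σr as t/(1+t); theta from
    the excess of the squared deviations of y around Binomial(n, phi) over
    their binomial expectation, pooled across autosomal windows and floored
    at ``theta_floor``.
    """
    y = np.asarray(y, dtype=float)
    r = np.asarray(r, dtype=float)
    if y.shape != r.shape:
        raise ValueError("test and reference count vectors differ in length")
    ty, tr = y.sum(), r.sum()
    if ty <= 0 or tr <= 0:
        raise ValueError("zero total counts in test or reference")
    t = ty / tr
    phi = t / (1 + t)

    mask = (y + r) > 1
    if chroms is not None:
        autosomal = ~np.isin(np.char.lower(chroms.astype(str)), ["chrx", "chry", "x", "y"])
        mask &= autosomal
    n = (y + r)[mask]
    yy = y[mask]
    base = n * phi * (1 - phi)
    num = ((yy - n * phi) ** 2 - base).sum()
    den = (base * (n - 1)).sum()
    theta = num / den if den > 0 else 0.0
    theta = max(float(theta), theta_floor, 0.0)
    return EmissionParams(phi=phi, theta=theta, q=q, cnv_mean_windows=cnv_mean_windows)


def state_fraction(phi: float, c: int, eps: float = _CN0_EPS) -> float:
    """Expected test-read fraction under copy number ``c`` given diploid phi.

    Dosage acts on the odds: the test contributes c/2 of its diploid share.
    The homozygous-deletion fraction is floored at ``eps`` so the emission
    stays proper.
    """
    if c < 0:
        raise ValueError("copy number must be >= 0")
    num = (c / 2.0) * phi
    frac = num / (num + (1 - phi))
    return max(frac, eps)


def _log_bb(y: np.ndarray, n: np.ndarray, f: float, theta: float) -> np.ndarray:
    """Log beta-binomial pmf with mean fraction f and overdispersion theta.

    Parameterisation alpha = f(1-theta)/theta, beta = (1-f)(1-theta)/theta;
    theta -> 0 degenerates to the binomial. Windows with n = 0 contribute 0.
    """
    out = np.zeros_like(y, dtype=float)
    ok = n > 0
    if theta <= _THETA_TINY:
        out[ok] = binom.logpmf(y[ok], n[ok], f)
    else:
        a = f * (1 - theta) / theta
        b = (1 - f) * (1 - theta) / theta
        out[ok] = betabinom.logpmf(y[ok], n[ok], a, b)
    return out


def hmm_log_params(q: float, cnv_mean_windows: float) -> tuple[np.ndarray, np.ndarray]:
    """Initial and transition log-probabilities over states (cn 1, 2, 3).

    The diploid state is sticky (stay probability 1 - q, leaving split
    evenly between loss and gain); CNV states persist with 1 - 1/L and
    return to diploid, never hopping directly between loss and gain.
    """
    L = cnv_mean_windows
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.array([q / 2, 1 - q, q / 2]))
        log_T = np.log(
            np.array(
                [
                    [1 - 1 / L, 1 / L, 0.0],
                    [q / 2, 1 - q, q / 2],
                    [0.0, 1 / L, 1 - 1 / L],
                ]
            )
        )
    return log_pi, log_T


def viterbi_decode(log_emissions: np.ndarray, q: float, cnv_mean_windows: float) -> np.ndarray:
    """Maximum a posteriori state path for one chromosome.

    ``log_emissions`` has shape (n_windows, 3) over copy numbers (1, 2, 3);
    returns the copy-number path.
    """
    log_pi, log_T = hmm_log_params(q, cnv_mean_windows)
    W = log_emissions.shape[0]
    delta = log_pi + log_emissions[0]
    back = np.zeros((W, 3), dtype=np.int8)
    for w in range(1, W):
        cand = delta[:, None] + log_T
        back[w] = np.argmax(cand, axis=0)
        delta = cand[back[w], np.arange(3)] + log_emissions[w]
    path = np.empty(W, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for w in range(W - 1, 0, -1):
        path[w - 1] = back[w, path[w]]
    return np.array(_STATES, dtype=np.int8)[path]


def genotype_ratio(y: np.ndarray, r: np.ndarray, phi: float) -> tuple[float, int]:
    """Observed/expected-diploid depth ratio over a set of windows.

    The expected diploid test count is the odds form (phi/(1-phi))·r_w,
    which is independent of the observed test count.  Returns the mean
    ratio and its rounded copy-number label clipped to [0, 4].
    """
    y = np.asarray(y, dtype=float)
    r = np.asarray(r, dtype=float)
    expected = phi / (1 - phi) * r
    ok = expected > 0
    if not ok.any():
        return float("nan"), 2
    ratio = float((y[ok] / expected[ok]).mean())
    label = int(np.clip(np.floor(2 * ratio + 0.5), 0, 4))
    return ratio, label


def call_cnvs(test: str, counts: ReadCountMatrix, reference: ReferenceSet,
              params: EmissionParams, min_ratio_cn0: float = 0.15) -> list[CnvCall]:
    """Segment one sample into CNV calls by Viterbi decoding per chromosome.

    Maximal runs of non-diploid states become calls spanning exactly their
    constituent windows; each call's Bayes factor is the summed per-window
    log10 emission ratio of the called state to diploid.  Deep losses
    (observed ratio below ``min_ratio_cn0``) are relabelled homozygous.
    """
    if len(reference.aggregate) != counts.n_windows:
        raise ValueError("reference aggregated over a different window set")
    y_all = counts.column(test).astype(np.int64)
    r_all = np.asarray(reference.aggregate, dtype=np.int64)
    fracs = [state_fraction(params.phi, c) for c in _STATES]
    calls: list[CnvCall] = []
    for chrom in counts.windows["chrom"].unique():
        mask = counts.chrom_mask(chrom)
        y, r = y_all[mask], r_all[mask]
        n = y + r
        emis = np.stack([_log_bb(y, n, f, params.theta) for f in fracs], axis=1)
        path = viterbi_decode(emis, params.q, params.cnv_mean_windows)
        starts = counts.windows.loc[mask, "start"].to_numpy()
        ends = counts.windows.loc[mask, "end"].to_numpy()
        w = 0
        W = len(path)
        while w < W:
            if path[w] == 2:
                w += 1
                continue
            state = path[w]
            j = w
            while j < W and path[j] == state:
                j += 1
            idx = np.arange(w, j)
            sidx = _STATES.index(state)
            bf = float((emis[idx, sidx] - emis[idx, _DIPLOID_IDX]).sum() / _LN10)
            ratio, _ = genotype_ratio(y[idx], r[idx], params.phi)
            cn = int(state)
            if np.isfinite(ratio) and ratio < min_ratio_cn0:
                cn = 0
            if bf > 0:
                calls.append(
                    CnvCall(
                        sample=test,
                        interval=GenomicInterval(chrom, int(starts[w]), int(ends[j - 1])),
                        cn=cn,
                        bayes_factor=bf,
                        n_windows=len(idx),
                        observed_ratio=ratio,
                    )
                )
            w = j
    return calls


class CnvCaller(BaseEstimator):
    """Read-depth CNV caller over a cohort count matrix.

    Fit on a :class:`ReadCountMatrix`; ``predict`` returns a call table for
    the requested samples (all samples by default), each called against a
    reference set selected from the rest of the cohort.

    Parameters
    ----------
    max_members : int, default 10
        Cap on reference-set size.
    q : float, default 1e-4
        Per-window probability of leaving the diploid HMM state.
    cnv_mean_windows : float, default 50
        Expected CNV length in windows (CNV-state stickiness 1 - 1/L).
    theta_floor : float, default 0.0
        Lower bound for the fitted overdispersion.
    min_ratio_cn0 : float, default 0.15
        Observed-ratio threshold below which a loss is relabelled CN 0.
    sex_match_reference : bool, default True
        On designs with sex chromosomes, restrict reference candidates to
        samples of the test sample's sex (known from the matrix or
        inferred from the chrY share); an opposite-sex background makes
        the whole of chrX/chrY look copy-altered.
    """

    def __init__(self, max_members: int = 10, q: float = 1e-4,
                 cnv_mean_windows: float = 50.0, theta_floor: float = 0.0,
                 min_ratio_cn0: float = 0.15, sex_match_reference: bool = True):
        self.max_members = max_members
        self.q = q
        self.cnv_mean_windows = cnv_mean_windows
        self.theta_floor = theta_floor
        self.min_ratio_cn0 = min_ratio_cn0
        self.sex_match_reference = sex_match_reference

    def fit(self, X: ReadCountMatrix, y=None):
        if not isinstance(X, ReadCountMatrix):
            raise TypeError("CnvCaller.fit expects a ReadCountMatrix")
        if X.n_samples < 2:
            raise ValueError("cannot build background from a single-sample cohort")
        self.X_ = X
        self.sample_ids_ = list(X.sample_ids)
        has_sex_chroms = X.windows["chrom"].isin(["chrX", "chrY"]).any()
        if self.sex_match_reference and has_sex_chroms:
            if X.sexes:
                self.sexes_ = dict(X.sexes)
            else:
                from .aneuploidy import adjusted_chromosome_counts, infer_sexes

                self.sexes_ = infer_sexes(adjusted_chromosome_counts(X))
        else:
            self.sexes_ = {}
        return self

    def _candidates_for(self, sample: str) -> list[str] | None:
        if not self.sexes_:
            return None
        sex = self.sexes_.get(sample)
        same = [s for s in self.sample_ids_ if s != sample and self.sexes_.get(s) == sex]
        return same or None  # fall back to the full cohort if sex is unique

    def predict_sample(self, sample: str) -> list[CnvCall]:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "X_")
        ref = select_reference(sample, self.X_, max_members=self.max_members,
                               theta_floor=self.theta_floor,
                               candidates=self._candidates_for(sample))
        params = fit_emission_params(
            self.X_.column(sample), ref.aggregate,
            chroms=self.X_.windows["chrom"].to_numpy(),
            theta_floor=self.theta_floor, q=self.q,
            cnv_mean_windows=self.cnv_mean_windows,
        )
        return call_cnvs(sample, self.X_, ref, params, min_ratio_cn0=self.min_ratio_cn0)

    def predict(self, samples: list[str] | None = None) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "X_")
        if samples is None:
            samples = self.sample_ids_
        calls: list[CnvCall] = []
        for s in samples:
            calls.extend(self.predict_sample(s))
        return calls_to_frame(calls)
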