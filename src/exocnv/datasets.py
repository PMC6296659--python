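"""Seeded synthetic exome cohorts for end-to-end testing of the pipeline.

The generator emulates the statistical structure that read-depth CNV
analysis assumes: overdispersed window counts proportional to copy number,
strong window-to-window capture-efficiency variation, sample-to-sample
depth variation, sex-dependent baselines on chrX/chrY, polymorphic regions
with divergent copy number across samples, mosaic events attenuated by
cell fraction, shifted heterozygous-SNP allele fractions inside CNVs, and
array-style gold-standard call sets with jittered breakpoints.

All randomness flows from one integer seed through a splittable
``numpy.random.SeedSequence``; no global state is touched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CaptureDesign,
    GenomicInterval,
    ReadCountMatrix,
    TruthEvent,
    chrom_sort_key,
)
from .depth import bin_capture_regions

__all__ = [
    "SimulatedCohort",
    "make_capture_design",
    "simulate_counts",
    "simulate_snp_allele_counts",
    "derive_array_callset",
    "whole_chromosome_event",
    "snap_to_targets",
    "make_pilot_cohort",
]


@dataclass
class SimulatedCohort:
    design: CaptureDesign
    counts: ReadCountMatrix
    truth: list[TruthEvent]
    snp_counts: pd.DataFrame | None
    seed: int

    def __post_init__(self):
        ids = set(self.counts.sample_ids)
        for e in self.truth:
            if e.sample not in ids:
                raise ValueError(f"truth event for unknown sample {e.sample!r}")

    @property
    def sexes(self) -> dict[str, str]:
        return self.counts.sexes


def make_capture_design(n_chromosomes: int, targets_per_chromosome: int,
                        target_length_bp: int, seed: int, *,
                        mean_gap_bp: int = 3000, targets_per_gene: int = 5,
                        uncharacterized_fraction: float = 0.05) -> CaptureDesign:
    """Generate a synthetic exome capture design.

    Chromosomes are labelled chr1..chrN; when ``n_chromosomes >= 4`` the
    last two are relabelled chrX and chrY.  Targets are non-overlapping,
    sorted, gamma-distributed in length around ``target_length_bp``, and
    separated by exponential gaps.  Consecutive runs of
    ``targets_per_gene`` targets share a gene symbol with 1-based exon
    indices; a small fraction of genes get LOC-style symbols emulating
    uncharacterized loci.
    """
    if n_chromosomes < 1 or targets_per_chromosome < 1 or target_length_bp < 1:
        raise ValueError("n_chromosomes, targets_per_chromosome and target_length_bp "
                         "must all be >= 1")
    names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    if n_chromosomes >= 4:
        names[-2], names[-1] = "chrX", "chrY"
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCA9]))
    rows = []
    chrom_lengths: dict[str, int] = {}
    gene_serial = 0
    for ci, chrom in enumerate(names):
        gaps = rng.exponential(mean_gap_bp, size=targets_per_chromosome) + 100
        lengths = np.maximum(
            40, rng.gamma(shape=4.0, scale=target_length_bp / 4.0,
                          size=targets_per_chromosome)
        ).astype(int)
        pos = 1000
        gene = None
        exon = 0
        for k in range(targets_per_chromosome):
            if k % targets_per_gene == 0:
                gene_serial += 1
                if rng.random() < uncharacterized_fraction:
                    gene = f"LOC{900000 + gene_serial}"
                else:
                    gene = f"GENE{ci + 1}_{gene_serial:04d}"
                exon = 0
            exon += 1
            start = pos
            end = start + int(lengths[k])
            rows.append((chrom, start, end, gene, exon))
            pos = end + int(gaps[k])
        chrom_lengths[chrom] = pos + 10 * mean_gap_bp
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "exon_index"])
    return CaptureDesign(regions, chrom_lengths)


def whole_chromosome_event(design: CaptureDesign, sample: str, chrom: str,
                           copy_number: int, mosaic_fraction: float = 1.0) -> TruthEvent:
    """An aneuploidy event spanning an entire design chromosome."""
    if chrom not in design.chrom_lengths:
        raise ValueError(f"unknown chromosome {chrom!r}")
    return TruthEvent(
        sample=sample,
        interval=GenomicInterval(chrom, 0, design.chrom_lengths[chrom]),
        copy_number=copy_number,
        mosaic_fraction=mosaic_fraction,
        event_class="aneuploidy",
    )


def snap_to_targets(design: CaptureDesign, chrom: str, size_bp: int,
                    anchor_frac: float = 0.2) -> GenomicInterval:
    """An interval starting at a capture target and spanning ~``size_bp``.

    Snapping both endpoints to targets keeps simulated events aligned with
    windowed signal, as real calls are.
    """
    t = design.regions[design.regions["chrom"] == chrom]
    if t.empty:
        raise ValueError(f"no targets on {chrom}")
    starts = t["start"].to_numpy()
    ends = t["end"].to_numpy()
    i0 = int(anchor_frac * len(t))
    fit = np.nonzero(ends - starts[i0] <= size_bp)[0]
    j = int(fit.max()) if len(fit) and fit.max() >= i0 else min(i0 + 1, len(t) - 1)
    return GenomicInterval(chrom, int(starts[i0]), int(ends[j]))


def _expand_polymorphic(events, sample_ids, frequency, rng):
    """Assign each polymorphic event template independently to a random subset."""
    out = []
    for e in events:
        if e.event_class != "polymorphic_cnv":
            out.append(e)
            continue
        carriers = [s for s in sample_ids if rng.random() < frequency]
        if not carriers:
            carriers = [sample_ids[int(rng.integers(len(sample_ids)))]]
        for s in carriers:
            out.append(dataclasses.replace(e, sample=s))
    return out


def simulate_counts(design: CaptureDesign, n_samples: int, mean_depth: float = 62.0,
                    dispersion: float = 0.01, events: list[TruthEvent] = (),
                    sample_depth_cv: float = 0.1, seed: int = 0, *,
                    sexes: list[str] | None = None, capture_sigma: float = 0.5,
                    polymorphic_frequency: float = 0.3,
                    window_bp: int = 100) -> SimulatedCohort:
    """Draw an overdispersed window-count matrix for a synthetic cohort.

    The count for sample s in window w has mean
    ``d_s * mu_w * mean_depth * CN / divisor`` where d_s is a per-sample
    depth factor (lognormal, CV ``sample_depth_cv``), mu_w a shared
    log-normal capture-efficiency factor (sigma ``capture_sigma``), CN the
    effective copy number after events (mosaics use base + f*(CN - base)),
    and the divisor is 2 except for chrY in males where the one-copy
    baseline itself defines full coverage.  Variance is
    ``mean * (1 + dispersion * mean)`` (negative binomial); dispersion 0
    degenerates to Poisson.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if dispersion < 0 or sample_depth_cv < 0:
        raise ValueError("dispersion and sample_depth_cv must be >= 0")
    ss = np.random.SeedSequence([int(seed), 0xC0DE])
    rng_mu, rng_depth, rng_sex, rng_poly, rng_counts = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )
    windows = bin_capture_regions(design, window_bp=window_bp)
    W = len(windows)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    if sexes is None:
        sexes = list(rng_sex.choice(["F", "M"], size=n_samples))
    elif len(sexes) != n_samples:
        raise ValueError("sexes must have one entry per sample")
    sexes = [str(s).upper() for s in sexes]
    if not set(sexes) <= {"F", "M"}:
        raise ValueError("sexes must be 'M' or 'F'")

    events = list(events)
    for e in events:
        if e.interval.chrom not in design.chrom_lengths:
            raise ValueError(f"event on unknown chromosome {e.interval.chrom!r}")
        if e.sample not in sample_ids:
            raise ValueError(f"event references unknown sample {e.sample!r}")
        if e.event_class == "aneuploidy" and (
            e.interval.start != 0
            or e.interval.end != design.chrom_lengths[e.interval.chrom]
        ):
            raise ValueError("aneuploidy events must span a whole chromosome")
    events = _expand_polymorphic(events, sample_ids, polymorphic_frequency, rng_poly)

    mu = rng_mu.lognormal(mean=-capture_sigma ** 2 / 2, sigma=capture_sigma, size=W)
    if sample_depth_cv > 0:
        sig = np.sqrt(np.log1p(sample_depth_cv ** 2))
        d = rng_depth.lognormal(mean=-sig ** 2 / 2, sigma=sig, size=n_samples)
    else:
        d = np.ones(n_samples)

    wchrom = windows["chrom"].to_numpy()
    wstart = windows["start"].to_numpy()
    wend = windows["end"].to_numpy()
    is_x = wchrom == "chrX"
    is_y = wchrom == "chrY"

    base = np.full((W, n_samples), 2.0)
    divisor = np.full((W, n_samples), 2.0)
    for si, sex in enumerate(sexes):
        if sex == "M":
            base[is_x, si] = 1.0
            base[is_y, si] = 1.0
            divisor[is_y, si] = 1.0
        else:
            base[is_y, si] = 0.0

    eff = base.copy()
    for e in events:
        si = sample_ids.index(e.sample)
        wmask = (wchrom == e.interval.chrom) & (wstart < e.interval.end) & (wend > e.interval.start)
        b = base[wmask, si]
        eff[wmask, si] = b + e.mosaic_fraction * (e.copy_number - b)

    m = mean_depth * mu[:, None] * d[None, :] * eff / divisor
    if dispersion > 0:
        r = 1.0 / dispersion
        counts = rng_counts.negative_binomial(r, r / (r + m))
    else:
        counts = rng_counts.poisson(m)
    matrix = ReadCountMatrix(
        windows=windows,
        counts=counts.astype(np.int64),
        sample_ids=sample_ids,
        sexes=dict(zip(sample_ids, sexes)),
    )
    return SimulatedCohort(design=design, counts=matrix, truth=events,
                           snp_counts=None, seed=int(seed))


def _site_alt_fraction(cn: int, f: float, rng, error_rate: float) -> float | None:
    """Alternate-allele fraction at a het site under an event (None = no DNA)."""
    if cn == 2:
        return 0.5
    if cn < 2:
        loss = 2 - cn  # copies lost per affected cell (1 or 2)
        if cn == 0 and f == 1.0:
            return None
        total = 2 - f * loss
        alt = 1.0 - (f * loss if rng.random() < 0.5 else 0.0)
        alt = min(max(alt, 0.0), total)
    else:
        extra = cn - 2
        total = 2 + f * extra
        alt = 1.0 + (f * extra if rng.random() < 0.5 else 0.0)
    p = alt / total
    return min(max(p, error_rate), 1 - error_rate)


def simulate_snp_allele_counts(cohort: SimulatedCohort, het_snps_per_kb: float = 0.2,
                               depth: float = 62.0, seed: int = 0, *,
                               error_rate: float = 0.005) -> SimulatedCohort:
    """Add per-sample heterozygous-SNP allele counts to a cohort.

    Sites are scattered over autosomal capture regions at the given
    density.  In diploid regions the alternate fraction is 1/2; inside a
    constitutional duplication it is 1/3 or 2/3 (random phase); inside a
    heterozygous deletion sites become hemizygous (fractions near 0 or 1,
    bounded by the sequencing error rate); mosaic events shift fractions
    by allele dosage.  Read counts are binomial at Poisson site depth
    scaled by copy number.
    """
    if het_snps_per_kb <= 0:
        raise ValueError("het_snps_per_kb must be > 0")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A9]))
    regions = cohort.design.regions
    autosomal = regions[~regions["chrom"].isin(["chrX", "chrY"])]
    events_by_sample: dict[str, list[TruthEvent]] = {}
    for e in cohort.truth:
        events_by_sample.setdefault(e.sample, []).append(e)

    rows = []
    for sample in cohort.counts.sample_ids:
        sev = events_by_sample.get(sample, [])
        for reg in autosomal.itertuples(index=False):
            n_sites = rng.poisson((reg.end - reg.start) / 1000.0 * het_snps_per_kb)
            if n_sites == 0:
                continue
            positions = np.sort(rng.integers(reg.start, reg.end, size=n_sites))
            for pos in positions:
                cn, f = 2, 1.0
                for e in sev:
                    if e.interval.chrom == reg.chrom and e.interval.start <= pos < e.interval.end:
                        cn, f = e.copy_number, e.mosaic_fraction
                        break
                p = _site_alt_fraction(cn, f, rng, error_rate)
                if p is None:
                    continue
                eff = 2 + f * (cn - 2)
                n = rng.poisson(depth * eff / 2.0)
                if n == 0:
                    continue
                alt = rng.binomial(n, p)
                rows.append((sample, reg.chrom, int(pos), int(n - alt), int(alt)))
    snp = pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref_count", "alt_count"])
    return dataclasses.replace(cohort, snp_counts=snp)


def derive_array_callset(truth: list[TruthEvent], breakpoint_jitter_bp: int = 2000,
                         min_size_bp: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Emulate the array-based gold-standard view of the simulated truth.

    Focal events at least ``min_size_bp`` long are emitted once each with
    endpoints perturbed by up to ±``breakpoint_jitter_bp``; aneuploidies
    are excluded (arrays report whole-chromosome events separately).
    """
    if breakpoint_jitter_bp < 0:
        raise ValueError("breakpoint_jitter_bp must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA88A]))
    rows = []
    for e in truth:
        if e.event_class == "aneuploidy" or e.interval.length < min_size_bp:
            continue
        j = breakpoint_jitter_bp
        start = e.interval.start + (int(rng.integers(-j, j + 1)) if j else 0)
        end = e.interval.end + (int(rng.integers(-j, j + 1)) if j else 0)
        start = max(0, start)
        end = max(start + 1, end)
        rows.append((e.sample, e.interval.chrom, start, end, e.copy_number,
                     e.mosaic_fraction, e.event_class))
    out = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                      "copy_number", "mosaic_fraction", "event_class"])
    out["_key"] = out["chrom"].map(chrom_sort_key)
    out = (out.sort_values(["sample", "_key", "start"]).drop(columns="_key")
           .reset_index(drop=True))
    return out


def make_pilot_cohort(seed: int, mean_depth: float = 62.0, dispersion: float = 0.01):
    """A scaled-down eight-sample validation cohort with five known events.

    Mirrors a blinded pilot design: five carrier samples — two focal
    deletions (~1.1 Mb and a near-chromosome ~5.7 Mb-scale loss), two
    ~1.4 Mb duplications, and one whole-chromosome trisomy — plus three
    event-free negatives, on a seven-chromosome design (five autosome
    analogues plus chrX/chrY).

    Returns
    -------
    cohort : SimulatedCohort
    """
    design = make_capture_design(7, 500, 200, seed=101, mean_gap_bp=12000)
    events = [
        TruthEvent("S001", snap_to_targets(design, "chr1", 1_100_000, 0.2), 1),
        TruthEvent("S002", snap_to_targets(design, "chr2", 1_400_000, 0.3), 3),
        TruthEvent("S003", snap_to_targets(design, "chr3", 5_700_000, 0.02), 1),
        TruthEvent("S004", snap_to_targets(design, "chr4", 1_400_000, 0.5), 3),
        whole_chromosome_event(design, "S005", "chr5", 3),
    ]
    return simulate_counts(
        design, 8, mean_depth=mean_depth, dispersion=dispersion, events=events,
        sample_depth_cv=0.1, seed=seed,
        sexes=["M", "F", "M", "F", "M", "F", "M", "F"],
    )
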