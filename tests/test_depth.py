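"""Read-depth caller: window binning, reference selection, emission fit,
Viterbi decoding against a brute-force oracle, and call properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import betabinom, binom

from exocnv import (
    CnvCaller,
    ReadCountMatrix,
    TruthEvent,
    bin_capture_regions,
    call_cnvs,
    fit_emission_params,
    make_capture_design,
    select_reference,
    simulate_counts,
    state_fraction,
)
from exocnv.core import CaptureDesign, GenomicInterval, reciprocal_overlap
from exocnv.depth import EmissionParams, ReferenceSet, genotype_ratio, viterbi_decode, _log_bb

from conftest import enumerate_best_path, path_log_prob


def _design_one_region(length):
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [length],
                            "gene": ["G1"], "exon_index": [1]})
    return CaptureDesign(regions, {"chr1": length + 10})


class TestBinCaptureRegions:
    @pytest.mark.parametrize("region_len,expected", [
        (250, [100, 100, 50]),   # remainder >= half a window stands alone
        (120, [120]),            # small remainder merges backwards
        (100, [100]),            # exact tiling
        (40, [40]),              # region shorter than half a window kept whole
        (199, [100, 99]),
        (150, [100, 50]),
    ])
    def test_remainder_rules(self, region_len, expected):
        w = bin_capture_regions(_design_one_region(region_len), window_bp=100)
        assert (w["end"] - w["start"]).tolist() == expected

    def test_windows_tile_regions_exactly(self, design4):
        w = bin_capture_regions(design4, window_bp=100)
        total = (w["end"] - w["start"]).sum()
        assert total == (design4.regions["end"] - design4.regions["start"]).sum()
        # no overlaps within chromosomes
        for _, grp in w.groupby("chrom"):
            assert (grp["start"].values[1:] >= grp["end"].values[:-1]).all()


def _matrix_from_columns(cols: dict[str, np.ndarray], n_windows: int) -> ReadCountMatrix:
    windows = pd.DataFrame({
        "chrom": ["chr1"] * n_windows,
        "start": np.arange(n_windows) * 100,
        "end": (np.arange(n_windows) + 1) * 100,
        "window_id": [f"w{i}" for i in range(n_windows)],
    })
    ids = list(cols)
    counts = np.column_stack([cols[s] for s in ids])
    return ReadCountMatrix(windows, counts, ids)


class TestSelectReference:
    def test_single_sample_cohort_is_an_error(self):
        m = _matrix_from_columns({"a": np.full(10, 50)}, 10)
        with pytest.raises(ValueError):
            select_reference("a", m)

    def test_identical_samples_tie_break_by_id_order(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=200)
        m = _matrix_from_columns({s: base.copy() for s in ["t", "d", "c", "b", "a"]}, 200)
        ref = select_reference("t", m, max_members=3)
        assert ref.members == ["a", "b", "c"]

    def test_correlated_sample_ranked_first(self):
        rng = np.random.default_rng(1)
        mu = rng.lognormal(0, 0.6, size=500)
        test = rng.poisson(100 * mu)
        friend = rng.poisson(100 * mu)
        stranger = rng.poisson(rng.permutation(100 * mu))
        m = _matrix_from_columns({"t": test, "friend": friend, "stranger": stranger}, 500)
        ref = select_reference("t", m)
        assert ref.members[0] == "friend"
        assert ref.scores["friend"] > ref.scores["stranger"]

    def test_max_members_cap(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(100, size=100).astype(float)
        cols = {f"s{i}": rng.poisson(base) for i in range(8)}
        m = _matrix_from_columns(cols, 100)
        ref = select_reference("s0", m, max_members=1)
        assert len(ref.members) == 1

    def test_reference_set_validation(self):
        with pytest.raises(ValueError):
            ReferenceSet("t", [], np.zeros(3))
        with pytest.raises(ValueError):
            ReferenceSet("t", ["t"], np.zeros(3))


class TestFitEmissionParams:
    def test_equal_counts_give_phi_half(self):
        y = np.full(200, 80.0)
        p = fit_emission_params(y, y.copy())
        assert p.phi == pytest.approx(0.5)

    def test_theta_vanishes_for_binomial_data(self):
        # no overdispersion in truth -> theta-hat ~ 0 at large window counts
        rng = np.random.default_rng(3)
        thetas = []
        for _ in range(100):
            n = rng.poisson(400, size=10_000)
            y = rng.binomial(n, 0.5)
            thetas.append(fit_emission_params(y, n - y).theta)
        assert np.mean(thetas) < 5e-4

    def test_theta_recovery_within_twenty_percent(self):
        rng = np.random.default_rng(4)
        theta = 0.01
        a, b = 0.5 * (1 - theta) / theta, 0.5 * (1 - theta) / theta
        est = []
        for _ in range(20):
            n = rng.poisson(400, size=10_000)
            y = betabinom.rvs(n, a, b, random_state=rng)
            est.append(fit_emission_params(y, n - y).theta)
        assert np.mean(est) == pytest.approx(theta, rel=0.2)

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            fit_emission_params(np.zeros(10), np.full(10, 5.0))


class TestStateFraction:
    @pytest.mark.parametrize("phi,c,expected", [
        (0.5, 2, 0.5),
        (0.5, 1, 1 / 3),
        (0.5, 3, 3 / 5),
        (0.2, 2, 0.2),
    ])
    def test_dosage_odds(self, phi, c, expected):
        assert state_fraction(phi, c) == pytest.approx(expected)

    def test_homozygous_deletion_floored(self):
        assert state_fraction(0.5, 0) == pytest.approx(1e-4)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0.05, 0.95))
    def test_monotone_in_copy_number(self, phi):
        fr = [state_fraction(phi, c) for c in (0, 1, 2, 3, 4)]
        assert all(a < b for a, b in zip(fr, fr[1:]))


class TestViterbi:
    def _random_instance(self, rng, n_windows):
        phi, theta = 0.5, float(rng.uniform(0, 0.02))
        n = rng.poisson(120, size=n_windows)
        cn = rng.choice([1, 2, 3], size=n_windows, p=[0.2, 0.6, 0.2])
        f_true = np.array([state_fraction(phi, c) for c in cn])
        y = rng.binomial(n, f_true)
        emis = np.stack(
            [_log_bb(y, n, state_fraction(phi, c), theta) for c in (1, 2, 3)], axis=1
        )
        return emis

    def test_matches_exhaustive_search_on_small_instances(self):
        rng = np.random.default_rng(5)
        q, L = 1e-4, 50.0
        for _ in range(50):
            W = int(rng.integers(2, 9))
            emis = self._random_instance(rng, W)
            path = viterbi_decode(emis, q, L)
            best_path, best_score, unique = enumerate_best_path(emis, q, L)
            assert path_log_prob(path, emis, q, L) == pytest.approx(best_score)
            if unique:
                assert np.array_equal(path, best_path)

    def test_flat_emissions_stay_diploid(self):
        emis = np.zeros((30, 3))
        assert (viterbi_decode(emis, 1e-4, 50.0) == 2).all()


class TestCallCnvs:
    def _diploid_setup(self, n_windows=300, depth=100, seed=6):
        rng = np.random.default_rng(seed)
        r = rng.poisson(depth * 10, size=n_windows)
        y = np.round(r / 10).astype(int)  # exactly at diploid expectation
        m = _matrix_from_columns({"t": y}, n_windows)
        ref = ReferenceSet("ref", ["x"], r)
        params = EmissionParams(phi=y.sum() / (y.sum() + r.sum()), theta=0.0)
        return m, ref, params

    def test_exact_diploid_counts_yield_no_calls(self):
        m, ref, params = self._diploid_setup()
        assert call_cnvs("t", m, ref, params) == []

    def test_simulated_het_deletion_recovered(self):
        # 20-window deletion at 100x with a 20-sample background
        design = make_capture_design(1, 100, 200, seed=15)
        w = bin_capture_regions(design)
        iv_w = w.iloc[40:60]
        iv = GenomicInterval("chr1", int(iv_w["start"].min()), int(iv_w["end"].max()))
        hits = 0
        for seed in range(100):
            cohort = simulate_counts(design, 21, mean_depth=100, dispersion=0.01,
                                     events=[TruthEvent("S001", iv, 1)], seed=seed,
                                     sexes=["F"] * 21)
            calls = CnvCaller(max_members=20).fit(cohort.counts).predict_sample("S001")
            if any(c.cn == 1 and reciprocal_overlap(c.interval, iv) >= 0.5
                   for c in calls):
                hits += 1
        assert hits >= 95

    def test_no_event_no_noise_cohorts_yield_zero_calls(self, design4):
        for seed in range(5):
            cohort = simulate_counts(design4, 8, mean_depth=80, dispersion=0.0,
                                     sample_depth_cv=0.0, capture_sigma=0.0,
                                     seed=seed, sexes=["F"] * 8)
            calls = CnvCaller().fit(cohort.counts).predict()
            assert len(calls) == 0

    def test_emitted_calls_have_positive_bayes_factor(self, null_cohort):
        calls = CnvCaller().fit(null_cohort.counts).predict()
        assert (calls["bayes_factor"] > 0).all()

    def test_doubling_counts_keeps_boundaries_and_raises_bf(self):
        # doubling test and reference counts doubles the evidence but not the signal
        design = make_capture_design(1, 80, 200, seed=16)
        w = bin_capture_regions(design)
        iv = GenomicInterval("chr1", int(w.iloc[30]["start"]), int(w.iloc[45]["end"]))
        cohort = simulate_counts(design, 10, mean_depth=60, dispersion=0.0,
                                 sample_depth_cv=0.0,
                                 events=[TruthEvent("S001", iv, 1)], seed=17,
                                 sexes=["F"] * 10)
        base = cohort.counts
        y = base.column("S001")
        r = base.counts.sum(axis=1) - y
        params = fit_emission_params(y, r, chroms=base.windows["chrom"].to_numpy())
        ref1 = ReferenceSet("S001", [s for s in base.sample_ids if s != "S001"], r)
        ref2 = ReferenceSet("S001", ref1.members, 2 * r)
        doubled = ReadCountMatrix(base.windows, base.counts * 2, base.sample_ids,
                                  base.sexes)
        c1 = call_cnvs("S001", base, ref1, params)
        c2 = call_cnvs("S001", doubled, ref2, params)
        assert len(c1) >= 1
        assert [(c.interval.start, c.interval.end, c.cn) for c in c1] == \
               [(c.interval.start, c.interval.end, c.cn) for c in c2]
        for a, b in zip(c1, c2):
            assert abs(b.bayes_factor) > abs(a.bayes_factor)

    def test_calls_never_span_chromosomes(self, design4):
        # one event per chromosome end/start; calls must stay within chromosomes
        cohort = simulate_counts(design4, 10, seed=19, sexes=["M"] * 5 + ["F"] * 5)
        calls = CnvCaller().fit(cohort.counts).predict()
        wchrom = cohort.counts.windows.groupby("chrom").agg(lo=("start", "min"),
                                                            hi=("end", "max"))
        for r in calls.itertuples(index=False):
            assert wchrom.loc[r.chrom, "lo"] <= r.start < r.end <= wchrom.loc[r.chrom, "hi"]

    def test_mismatched_reference_rejected(self):
        m, ref, params = self._diploid_setup()
        short_ref = ReferenceSet("ref", ["x"], ref.aggregate[:-10])
        with pytest.raises(ValueError):
            call_cnvs("t", m, short_ref, params)


class TestGenotypeRatio:
    def test_half_and_anderhalf_expectation(self):
        r = np.full(20, 1000.0)
        phi = 0.5
        ratio, label = genotype_ratio(np.full(20, 500.0), r, phi)
        assert ratio == pytest.approx(0.5)
        assert label == 1
        ratio, label = genotype_ratio(np.full(20, 1500.0), r, phi)
        assert ratio == pytest.approx(1.5)
        assert label == 3

    def test_mosaic_quarter_deletion(self):
        # effective CN 1.75 -> ratio 0.875, label 2
        r = np.full(20, 1000.0)
        ratio, label = genotype_ratio(np.full(20, 875.0), r, 0.5)
        assert ratio == pytest.approx(0.875)
        assert label == 2


def test_deep_loss_relabelled_homozygous():
    rng = np.random.default_rng(20)
    n_windows = 200
    r = rng.poisson(1000, size=n_windows)
    y = np.round(r / 10).astype(int)
    y[80:100] = 0  # total dropout
    m = _matrix_from_columns({"t": y}, n_windows)
    ref = ReferenceSet("ref", ["x"], r)
    params = EmissionParams(phi=1 / 11, theta=0.0)
    calls = call_cnvs("t", m, ref, params)
    assert len(calls) == 1
    assert calls[0].cn == 0
    assert calls[0].observed_ratio < 0.15
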