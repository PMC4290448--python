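import numpy as np
import pytest

from finchra.ephys_analysis import (
    CellRecord,
    EvokedTrace,
    HVC_GROUP_SUMMARY,
    MeasurementRejected,
    NoSaturationError,
    accept_second_sf,
    detect_max,
    detect_sf,
    estimate_n_inputs,
    estimate_receptor_ratio,
    fi_analysis,
    forward_amplitude_ratio,
    inputs_from_group_means,
)
from finchra.synthetic_ephys import (
    FiberGroundTruth,
    gen_current_clamp,
    gen_epsc_series,
    lif_rate_hz,
)

RATE = 100.0  # kHz
STIM = 20.0  # ms


def epsc_trace(amplitude, noise=0.0, seed=0, latency=8.0):
    """One synthetic sweep with a single EPSC of known size."""
    truth = FiberGroundTruth([10.0], [amplitude], [1.0], [latency])
    series = gen_epsc_series(
        truth, np.array([20.0]), n_trials=1, noise_rms=max(noise, 1e-9),
        seed=seed, sample_rate_khz=RATE, stim_time_ms=STIM, post_ms=40.0,
    )
    return series[0][1][0]


def flat_trace(noise=3.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int((STIM + 40.0) * RATE)
    return EvokedTrace(rng.normal(0, noise, n), RATE, STIM)


class TestDetectSF:
    def test_half_failures_recover_amplitude(self):
        traces = [epsc_trace(50.0, 3.0, seed=s) for s in range(4)] + [
            flat_trace(3.0, seed=s) for s in range(4, 8)
        ]
        sf = detect_sf(traces, noise_rms=3.0)
        assert sf.failure_rate == pytest.approx(0.5)
        assert sf.n_successes == 4
        assert sf.peak_amplitude_pA == pytest.approx(50.0, rel=0.05)
        assert 6.0 < sf.latency_to_peak_ms < 12.0

    def test_all_failures_rejected(self):
        with pytest.raises(MeasurementRejected):
            detect_sf([flat_trace(3.0, seed=s) for s in range(8)], noise_rms=3.0)

    def test_no_failures_rejected(self):
        traces = [epsc_trace(50.0, 3.0, seed=s) for s in range(8)]
        with pytest.raises(MeasurementRejected):
            detect_sf(traces, noise_rms=3.0)

    def test_cv_is_sd_over_mean_of_success_peaks(self):
        traces = [epsc_trace(a, seed=i) for i, a in enumerate([48, 50, 52, 50])]
        traces += [flat_trace(0.001, seed=s) for s in range(4)]
        sf = detect_sf(traces, noise_rms=3.0)
        expected = np.std([48, 50, 52, 50]) / np.mean([48, 50, 52, 50])
        assert sf.cv == pytest.approx(expected, abs=5e-3)

    def test_needs_at_least_four_sweeps(self):
        with pytest.raises(ValueError):
            detect_sf([flat_trace()] * 3)


class TestSecondSF:
    def test_identical_lists_excluded(self):
        include, p = accept_second_sf([20, 21, 19, 20], [20, 21, 19, 20])
        assert not include
        assert p == pytest.approx(1.0)

    def test_clearly_different_fibers_included(self):
        include, p = accept_second_sf([20, 21, 19, 20], [80, 82, 78, 81])
        assert include
        assert p < 1e-6

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            accept_second_sf([20.0], [30.0, 31.0])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(13)
        hits = sum(
            accept_second_sf(rng.normal(50, 5, 6), rng.normal(50, 5, 6))[0]
            for _ in range(800)
        )
        assert 0.025 < hits / 800 < 0.08


class TestDetectMAX:
    @staticmethod
    def series(seed=0):
        truth = FiberGroundTruth(
            [10, 15, 20, 30, 50.0], [100, 150, 200, 150, 200.0], [0.5] * 5, [8.0] * 5
        )
        intens = np.array([5, 10, 15, 20, 30, 50, 100, 200, 400.0])
        return gen_epsc_series(
            truth, intens, n_trials=6, noise_rms=3.0, seed=seed,
            sample_rate_khz=RATE, stim_time_ms=STIM, post_ms=40.0,
        )

    def test_recovers_saturating_amplitude(self):
        mx = detect_max(self.series())
        assert mx.peak_amplitude_nA == pytest.approx(0.8, rel=0.05)
        assert mx.cv <= 0.2

    def test_unsaturated_series_raises(self):
        # strictly growing recruitment: thresholds span the whole range
        truth = FiberGroundTruth(
            np.linspace(10, 900, 20), np.full(20, 100.0), [1.0] * 20, [8.0] * 20
        )
        series = gen_epsc_series(
            truth, np.array([10.0, 50, 100, 300, 600, 1000]), n_trials=4,
            noise_rms=3.0, seed=1, sample_rate_khz=RATE, stim_time_ms=STIM,
            post_ms=40.0,
        )
        with pytest.raises(NoSaturationError):
            detect_max(series)

    def test_noisy_plateau_rejected_by_cv_gate(self):
        rng = np.random.default_rng(5)
        series = []
        for inten in [10.0, 40.0, 150.0]:
            traces = []
            for k in range(6):
                amp = rng.choice([400.0, 900.0])  # CV >> 0.2
                traces.append(epsc_trace(amp, seed=int(rng.integers(1e6))))
            series.append((inten, traces))
        with pytest.raises(MeasurementRejected):
            detect_max(series, rel_tol=0.6)


class TestInputCounts:
    def test_printed_group_means_reproduce_published_counts(self):
        counts = {
            row.age_group: round(inputs_from_group_means(row.sf_mean_pA, row.max_mean_nA))
            for _, row in HVC_GROUP_SUMMARY.iterrows()
        }
        assert counts == {"subsong": 19, "plastic": 26, "adult": 11}

    def test_fold_changes_along_development(self):
        n = {
            row.age_group: inputs_from_group_means(row.sf_mean_pA, row.max_mean_nA)
            for _, row in HVC_GROUP_SUMMARY.iterrows()
        }
        assert n["plastic"] / n["subsong"] == pytest.approx(1.4, abs=0.05)
        assert n["plastic"] / n["adult"] == pytest.approx(2.4, abs=0.05)

    def test_noiseless_equal_inputs_exact_for_both_methods(self):
        cells = [
            CellRecord(f"c{i}", "test", [40.0], max_amplitude_nA=15 * 40.0 / 1000.0)
            for i in range(10)
        ]
        for method in ("mean_sf", "fiber_fraction"):
            est = estimate_n_inputs(cells, method)
            assert est.loc[0, "n_inputs"] == pytest.approx(15.0)

    def test_methods_agree_within_twenty_percent_on_heterogeneous_cells(self):
        rng = np.random.default_rng(3)
        cells = []
        for i in range(60):
            w = rng.lognormal(np.log(50), 0.6, size=12)
            sfs = rng.choice(w, size=2, replace=False)
            cells.append(
                CellRecord(f"c{i}", "grp", list(sfs), max_amplitude_nA=w.sum() / 1000)
            )
        a = estimate_n_inputs(cells, "mean_sf").loc[0, "n_inputs"]
        b = estimate_n_inputs(cells, "fiber_fraction").loc[0, "n_inputs"]
        assert abs(a - b) / a < 0.2

    def test_at_most_three_sfs_per_cell(self):
        with pytest.raises(ValueError):
            CellRecord("x", "grp", [10.0, 20.0, 30.0, 40.0])

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            estimate_n_inputs([CellRecord("x", "grp", [10.0], None)])


class TestReceptorRatio:
    def test_zero_ratio_is_pure_nmda(self):
        res = estimate_receptor_ratio(0.0)
        assert res.r == 0.0
        assert np.isinf(res.nmda_to_ampa)

    def test_plastic_song_ratio_maps_to_six_percent_ampa(self):
        assert estimate_receptor_ratio(0.10).r == pytest.approx(0.06, abs=0.005)

    def test_subsong_ratio_maps_to_nine_to_one(self):
        res = estimate_receptor_ratio(0.17)
        assert round(res.nmda_to_ampa) == 9

    def test_round_trip_is_identity(self):
        for r in np.linspace(0.0, 1.0, 21):
            back = estimate_receptor_ratio(forward_amplitude_ratio(r)).r
            assert back == pytest.approx(r, abs=1e-12)

    def test_inconsistent_ratio_rejected(self):
        with pytest.raises(ValueError):
            estimate_receptor_ratio(2.0)
        with pytest.raises(ValueError):
            estimate_receptor_ratio(-0.1)


class TestFIAnalysis:
    def test_non_adapting_lif_has_unit_adaptation_ratio(self):
        rec, _ = gen_current_clamp("lif", np.arange(200.0, 1601, 200), seed=2)
        fi = fi_analysis(rec)
        ok = ~np.isnan(fi.adaptation_ratio)
        assert ok.any()
        np.testing.assert_allclose(fi.adaptation_ratio[ok], 1.0, atol=0.1)

    def test_known_iff_decay_recovered_within_ten_percent(self):
        rec, truth = gen_current_clamp(
            "adapting_lif", np.array([600.0, 1200.0]), seed=3, tau_iff_ms=30.0
        )
        fi = fi_analysis(rec)
        ok = ~np.isnan(fi.decay_tau_ms)
        assert ok.any()
        np.testing.assert_allclose(fi.decay_tau_ms[ok], 30.0, rtol=0.10)

    def test_slope_matches_closed_form_secant_within_five_percent(self):
        intens = np.arange(200.0, 1401, 200)
        rec, _ = gen_current_clamp("lif", intens, seed=4)
        fi = fi_analysis(rec)
        secant = (lif_rate_hz(1400.0) - lif_rate_hz(200.0)) / 1.2  # Hz/nA
        assert fi.slope_hz_per_na == pytest.approx(secant, rel=0.05)
        assert fi.slope_r2 > 0.95

    def test_subthreshold_sweeps_excluded(self):
        rec, _ = gen_current_clamp("lif", np.array([-200.0, 0.0]), seed=5)
        fi = fi_analysis(rec)
        assert np.isnan(fi.mean_iff_hz).all()
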