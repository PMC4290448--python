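import numpy as np
import pytest

from finchra.spikegen import (
    LMANConfig,
    SpikeTrain,
    hvc_song,
    lman_bursty,
    lman_bursty_pair,
    lman_modulated,
    lman_poisson,
    load_trains,
    merge_trains,
    save_trains,
)


class TestSpikeTrain:
    def test_rejects_unsorted_or_out_of_range(self):
        with pytest.raises(ValueError):
            SpikeTrain(np.array([5.0, 2.0]), 10.0)
        with pytest.raises(ValueError):
            SpikeTrain(np.array([2.0, 11.0]), 10.0)

    def test_rate(self):
        t = SpikeTrain(np.arange(0.0, 1000.0, 25.0), 1000.0)
        assert t.rate_hz == pytest.approx(40.0)


class TestHvcSong:
    def test_first_neuron_burst_times(self):
        trains = hvc_song(100, 1000.0)
        np.testing.assert_allclose(trains[0].times, [0, 2, 4, 6, 8])

    def test_total_spikes_and_last_onset(self):
        trains = hvc_song(100, 1000.0)
        assert sum(t.n_spikes for t in trains) == 500
        assert trains[99].times[0] == pytest.approx(990.0)

    def test_inconsistent_tiling_rejected(self):
        with pytest.raises(ValueError):
            hvc_song(100, 900.0)

    def test_deterministic(self):
        a, b = hvc_song(10, 100.0), hvc_song(10, 100.0)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.times, y.times)


class TestPoisson:
    def test_zero_rate_is_empty(self):
        assert lman_poisson(0.0, 1000.0, seed=0).n_spikes == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            lman_poisson(-1.0, 1000.0)

    def test_seed_determinism(self):
        a = lman_poisson(80.0, 1000.0, seed=5)
        b = lman_poisson(80.0, 1000.0, seed=5)
        np.testing.assert_array_equal(a.times, b.times)

    def test_count_moments(self):
        counts = np.array(
            [lman_poisson(80.0, 1000.0, seed=s).n_spikes for s in range(3000)]
        )
        se = np.sqrt(80.0 / counts.size)
        assert abs(counts.mean() - 80.0) < 3 * se
        assert 0.9 < counts.var() / counts.mean() < 1.1  # Fano ~ 1

    def test_merging_two_forty_hz_matches_one_eighty(self):
        rng = np.random.default_rng(9)
        merged = [
            merge_trains([lman_poisson(40, 1000, rng), lman_poisson(40, 1000, rng)]).n_spikes
            for _ in range(2000)
        ]
        merged = np.asarray(merged)
        se = np.sqrt(80.0 / merged.size)
        assert abs(merged.mean() - 80.0) < 3 * se
        assert 0.9 < merged.var() / merged.mean() < 1.1


class TestBursty:
    def test_domain(self):
        with pytest.raises(ValueError):
            lman_bursty(-0.1)
        with pytest.raises(ValueError):
            lman_bursty(1.1)

    @pytest.mark.parametrize("b", [0.0, 0.3, 0.6, 1.0])
    def test_rate_conserved_for_every_burst_fraction(self, b):
        counts = np.array(
            [lman_bursty(b, 40.0, 1000.0, seed=s).n_spikes for s in range(2000)]
        )
        # tonic 40(1-b) Hz plus 8b Hz bursts of 5 spikes: expectation 40 Hz
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 40.0) < max(3 * se, 0.5)

    def test_pure_bursts_arrive_in_fives(self):
        t = lman_bursty(1.0, 40.0, 1000.0, seed=3)
        # burst events at 8 Hz, each 5 spikes 2 ms apart
        isis = np.diff(t.times)
        assert np.isclose(isis, 2.0).sum() >= 0.6 * isis.size

    def test_pair_doubles_the_rate(self):
        counts = np.array(
            [lman_bursty_pair(0.5, 40.0, 1000.0, seed=s).n_spikes for s in range(1000)]
        )
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 80.0) < max(3 * se, 0.8)


class TestModulated:
    def test_depth_domain(self):
        with pytest.raises(ValueError):
            lman_modulated(80.0, 1.0)

    def test_total_count_conserved(self):
        counts = np.array(
            [lman_modulated(80.0, 0.5, 1000.0, seed=s).n_spikes for s in range(2000)]
        )
        se = np.sqrt(80.0 / counts.size)
        assert abs(counts.mean() - 80.0) < 3 * se

    def test_psth_follows_half_depth_sine(self):
        all_times = np.concatenate(
            [lman_modulated(80.0, 0.5, 1000.0, seed=s).times for s in range(3000)]
        )
        hist, edges = np.histogram(all_times, bins=50, range=(0, 1000))
        centers = (edges[:-1] + edges[1:]) / 2
        basis = np.column_stack(
            [np.ones_like(centers), np.sin(2 * np.pi * centers / 1000.0)]
        )
        base, amp = np.linalg.lstsq(basis, hist.astype(float), rcond=None)[0]
        assert amp / base == pytest.approx(0.5, abs=0.05)

    def test_zero_depth_reduces_to_poisson_rate(self):
        counts = np.array(
            [lman_modulated(80.0, 0.0, 1000.0, seed=s).n_spikes for s in range(1500)]
        )
        assert abs(counts.mean() - 80.0) < 3 * np.sqrt(80.0 / counts.size)


class TestConfigAndIO:
    def test_config_rejects_mixed_axes(self):
        with pytest.raises(ValueError):
            LMANConfig(burst_fraction=0.3, mod_depth=0.5)

    def test_config_dispatch(self):
        assert LMANConfig().make(1000.0, seed=1).duration == 1000.0
        assert LMANConfig(burst_fraction=0.5).make(1000.0, seed=1).n_spikes > 0
        assert LMANConfig(mod_depth=0.5).make(1000.0, seed=1).n_spikes > 0

    def test_csv_round_trip(self, tmp_path):
        trains = [lman_poisson(40, 500.0, seed=s) for s in range(3)]
        for i, t in enumerate(trains):
            t.source = f"LMAN{i}"
        save_trains(trains, tmp_path / "spk.csv")
        back = load_trains(tmp_path / "spk.csv", duration=500.0)
        assert len(back) == 3
        for orig in trains:
            match = [b for b in back if b.source == orig.source]
            np.testing.assert_allclose(match[0].times, orig.times)

    def test_merge_requires_matching_durations(self):
        with pytest.raises(ValueError):
            merge_trains([lman_poisson(10, 100, seed=0), lman_poisson(10, 200, seed=1)])
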