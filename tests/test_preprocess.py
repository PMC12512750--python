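"""Cleaning, band optimization, time limiting and trial averaging."""

import numpy as np
import pytest

from mwicp.core import DegenerateInputError, FrequencyGrid
from mwicp.preprocess import (
    average_trials,
    detect_onset,
    locate_minima,
    optimal_band,
    optimal_frequency,
    refine_minimum,
    zeta1_clean,
)


def _brute_hampel_mask(x, window=11, k=3.0):
    half = window // 2
    padded = np.pad(x, half, mode="edge")
    mask = np.zeros(len(x), dtype=bool)
    for i in range(len(x)):
        w = padded[i:i + window]
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        mask[i] = abs(x[i] - med) > k * mad
    return mask


class TestZeta1:
    def test_constant_string_normalizes_to_zeros(self):
        res = zeta1_clean(np.array([5.0, 5.0, 5.0, 5.0]))
        np.testing.assert_array_equal(res["normalized"], 0.0)

    def test_single_spike_flagged_and_replaced(self):
        x = np.array([0.0, 0, 0, 100.0, 0, 0, 0])
        res = zeta1_clean(x)
        assert list(np.nonzero(res["mask"])[0]) == [3]
        assert res["cleaned"][3] == 0.0

    def test_normalized_moments(self):
        rng = np.random.default_rng(12)
        res = zeta1_clean(rng.normal(size=10_000))
        assert abs(res["normalized"].mean()) < 0.05
        assert abs(res["normalized"].std() - 1) < 0.05

    def test_mask_matches_bruteforce_hampel(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        x[[20, 150, 151, 280]] += [15, -20, 18, 25]
        res = zeta1_clean(x)
        np.testing.assert_array_equal(res["mask"],
                                      _brute_hampel_mask(x))

    def test_empty_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            zeta1_clean(np.array([]))


class TestLocateMinima:
    def test_tie_breaks_toward_lowest_frequency(self):
        grid = FrequencyGrid(2.0, 6.0, 41)
        curve = np.zeros(41)
        curve[[10, 20]] = -5.0
        loc, val = locate_minima(curve[None, :], grid)
        assert loc[0] == grid.frequencies_ghz[10]
        assert val[0] == -5.0

    def test_matches_exhaustive_scan(self):
        grid = FrequencyGrid(2.0, 6.0, 101)
        rng = np.random.default_rng(8)
        curves = rng.normal(size=(50, 101))
        locs, vals = locate_minima(curves, grid)
        for k in range(50):
            best_i, best_v = 0, curves[k, 0]
            for i in range(101):
                if curves[k, i] < best_v:
                    best_i, best_v = i, curves[k, i]
            assert locs[k] == grid.frequencies_ghz[best_i]
            assert vals[k] == best_v

    def test_location_invariant_under_monotone_transform(self):
        grid = FrequencyGrid(2.0, 6.0, 101)
        rng = np.random.default_rng(15)
        curves = rng.normal(size=(20, 101))
        locs, _ = locate_minima(curves, grid)
        for transform in (lambda y: 3 * y + 7, np.exp,
                          lambda y: np.arctan(y / 2)):
            locs_t, _ = locate_minima(transform(curves), grid)
            np.testing.assert_array_equal(locs, locs_t)

    def test_parabolic_refinement_recovers_offgrid_vertex(self):
        freqs = np.linspace(2.0, 3.0, 101)  # 10 MHz spacing
        true_f0 = 2.505  # exactly between two bins
        curve = (freqs - true_f0) ** 2
        loc, _ = refine_minimum(curve, freqs)
        assert loc == pytest.approx(true_f0, abs=1e-9)


class TestOptimalFrequency:
    def test_single_active_bin_is_selected(self):
        grid = FrequencyGrid(2.0, 6.0, 21)
        mags = np.zeros((30, 21))
        mags[:, 13] = np.linspace(0, 1, 30)
        assert optimal_frequency(mags, grid) == grid.frequencies_ghz[13]

    def test_matches_bruteforce_range_scan(self):
        grid = FrequencyGrid(2.0, 6.0, 51)
        rng = np.random.default_rng(77)
        for _ in range(25):
            mags = rng.normal(size=(20, 51))
            best_i, best_r = 0, -1.0
            for i in range(51):
                r = mags[:, i].max() - mags[:, i].min()
                if r > best_r:
                    best_i, best_r = i, r
            assert optimal_frequency(mags, grid) == \
                grid.frequencies_ghz[best_i]

    def test_constant_input_is_degenerate(self):
        grid = FrequencyGrid(2.0, 6.0, 21)
        with pytest.raises(DegenerateInputError):
            optimal_frequency(np.ones((10, 21)), grid)

    def test_located_minima_variant_tracks_revisited_bin(self):
        grid = FrequencyGrid(2.0, 6.0, 21)
        mags = np.zeros((10, 21))
        mags[:, 5] = -np.linspace(1, 3, 10)  # minimum always at bin 5
        assert optimal_frequency(mags, grid, variant="located-minima") == \
            grid.frequencies_ghz[5]


class TestOptimalBand:
    def test_default_halfwidth_around_sensor_a_resonance(self):
        band = optimal_band(3.565, 50.0, FrequencyGrid())
        assert band.f_lo_ghz == pytest.approx(3.515)
        assert band.f_hi_ghz == pytest.approx(3.615)

    def test_band_clipped_at_grid_start(self):
        grid = FrequencyGrid()
        band = optimal_band(2.0, 50.0, grid)
        assert band.f_lo_ghz == 2.0
        assert band.f_hi_ghz == pytest.approx(2.05)

    def test_unclipped_band_has_51_bins_on_default_grid(self):
        band = optimal_band(3.564, 50.0, FrequencyGrid())
        assert band.n_bins == 51


class TestTimeLimiting:
    def test_onset_matches_bruteforce_slope_scan(self):
        rate, half, thresh = 3.0, 2, 0.1
        p = np.concatenate([np.zeros(10), np.linspace(0, 20, 50)])
        onset = detect_onset(p, rate, thresh, half)
        # independent re-derivation: first centred LSQ slope above threshold
        expected = None
        for k in range(len(p)):
            a, b = max(0, k - half), min(len(p), k + half + 1)
            t = np.arange(a, b) / rate
            s = np.polyfit(t, p[a:b], 1)[0]
            if s > thresh:
                expected = k
                break
        assert onset == expected
        assert 10 - half <= onset <= 10

    def test_active_trajectory_keeps_all_leading_sweeps(self):
        p = np.linspace(0, 30, 40)
        assert detect_onset(p, 3.0) == 0

    def test_constant_pressure_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            detect_onset(np.full(30, 7.0), 3.0)

    def test_processed_trial_is_band_and_time_limited(
            self, processed_fast_trial, fast_trial):
        proc = processed_fast_trial
        assert proc.onset_index > 0
        assert proc.n_sweeps == proc.end_index - proc.onset_index + 1
        assert len(proc.freqs_ghz) == proc.band.n_bins
        assert proc.channels["sxx_mag"].shape == (
            proc.n_sweeps, proc.band.n_bins)
        # pressure onset trimmed: kept pressures rise monotonically overall
        assert proc.p_at_sweep[-1] > proc.p_at_sweep[0]


class TestAverageTrials:
    @staticmethod
    def _dummy_processed(values, n_sweeps=12, n_bins=3):
        from mwicp.preprocess import BandSelection, ProcessedTrial
        band = BandSelection(3.5, 50.0, np.arange(n_bins), 3.45, 3.55)
        channels = {name: np.full((n_sweeps, n_bins), float(values))
                    for name in ("sxx_mag", "sxy_mag", "sxx_phase",
                                 "sxy_phase")}
        return ProcessedTrial(
            sensor_id="A", trial_index=1, placement="20mm",
            freqs_ghz=np.linspace(3.45, 3.55, n_bins),
            channels=channels,
            p_at_sweep=np.linspace(0, 60, n_sweeps),
            t_at_sweep=np.full(n_sweeps, 23.0),
            band=band, onset_index=0, end_index=n_sweeps - 1,
            normalization={})

    def test_identical_trials_have_zero_sem(self):
        trials = [self._dummy_processed(4.0) for _ in range(5)]
        _, sem_ch, _, sem_p = average_trials(trials)
        np.testing.assert_array_equal(sem_ch["sxx_mag"], 0.0)
        np.testing.assert_array_equal(sem_p, 0.0)

    def test_sem_formula(self):
        trials = [self._dummy_processed(v) for v in (1, 2, 3, 4, 5)]
        mean_ch, sem_ch, _, _ = average_trials(trials)
        assert mean_ch["sxx_mag"][0, 0] == pytest.approx(3.0)
        assert sem_ch["sxx_mag"][0, 0] == pytest.approx(
            np.sqrt(2.5) / np.sqrt(5))

    def test_nonnominal_trial_count_warns_but_proceeds(self):
        trials = [self._dummy_processed(v) for v in (1, 2, 3, 4)]
        with pytest.warns(UserWarning, match="4 trials"):
            mean_ch, _, _, _ = average_trials(trials)
        assert mean_ch["sxx_mag"][0, 0] == pytest.approx(2.5)

    def test_mismatched_sensors_rejected(self):
        a = self._dummy_processed(1.0)
        b = self._dummy_processed(2.0)
        b.placement = "5mm"
        with pytest.raises(ValueError):
            average_trials([a, b] + [self._dummy_processed(1.0)] * 3)
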