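"""Peak matrix, band shares, modal ITF, reliability and the paired contrast."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from itfx.itf import (BandScheme, PeakMatrix, WindowSpec, band_shares,
                      compare_conditions, extract_itf, fallback_extract,
                      make_time_windows, peak_matrix, reliability_class)
from itfx.tfr import ERSPMap

GRID = np.arange(2.0, 15.1, 0.5)


def _ersp_from_profile(profile, channels=("Cz", "C3", "C4", "Pz", "P3", "P4"),
                       t0=-1000.0, t1=2500.0, fs=500.0):
    """ERSPMap whose ratio is profile(freq, time_ms), identical per channel."""
    times = t0 + np.arange(int((t1 - t0) * fs / 1000.0)) * 1000.0 / fs
    f, t = np.meshgrid(GRID, times, indexing="ij")
    plane = profile(f, t)
    ratio = np.tile(plane, (len(channels), 1, 1))
    return ERSPMap(ratio, GRID.copy(), times, list(channels))


def _ridge(freq_hz, gain=3.0):
    return lambda f, t: 1.0 + gain * np.exp(-((f - freq_hz) ** 2) / 0.1)


class TestWindows:
    def test_default_spec_gives_19_windows_with_printed_edges(self):
        w = make_time_windows(WindowSpec())
        assert len(w) == 19
        assert w[0] == (250.0, 350.0)
        assert w[1] == (300.0, 400.0)
        assert w[-1] == (1150.0, 1250.0)

    @pytest.mark.parametrize("spec,n", [
        (WindowSpec(0, 100, 100, 50), 1),
        (WindowSpec(0, 300, 100, 50), 5),
    ])
    def test_counts_by_enumeration(self, spec, n):
        assert len(make_time_windows(spec)) == n

    def test_width_larger_than_interval_rejected(self):
        with pytest.raises(ValueError, match="width"):
            WindowSpec(0, 100, 200, 50)

    @given(start=st.integers(0, 500), n_steps=st.integers(1, 30),
           width=st.integers(1, 20), step=st.integers(1, 10))
    @settings(max_examples=100, deadline=None)
    def test_count_formula_for_random_specs(self, start, n_steps, width, step):
        """Window count is floor((end-start-width)/step) + 1 for valid specs."""
        w_ms, s_ms = 10.0 * width, 10.0 * step
        end = start + w_ms + s_ms * (n_steps - 1)
        windows = make_time_windows(WindowSpec(start, end, w_ms, s_ms))
        assert len(windows) == n_steps
        assert all(b - a == w_ms for a, b in windows)


class TestPeakMatrix:
    def test_default_matrix_has_114_cells(self):
        m = peak_matrix(_ersp_from_profile(_ridge(5.5)))
        assert m.peak_freq_hz.shape == (19, 6)
        assert m.n_cells == 114

    def test_dominant_ridge_fills_every_cell(self):
        m = peak_matrix(_ersp_from_profile(_ridge(5.5)))
        assert np.all(m.peak_freq_hz == 5.5)

    def test_peaks_lie_on_the_grid(self):
        rng = np.random.default_rng(0)
        times = -1000.0 + np.arange(1750) * 2.0
        ratio = rng.uniform(0.5, 2.0, size=(6, len(GRID), 1750))
        m = peak_matrix(ERSPMap(ratio, GRID.copy(), times,
                                ["Cz", "C3", "C4", "Pz", "P3", "P4"]))
        assert set(np.unique(m.peak_freq_hz)) <= set(GRID)

    def test_missing_electrode_error_lists_available(self):
        ersp_map = _ersp_from_profile(_ridge(5.0), channels=("Cz", "Pz"))
        with pytest.raises(KeyError, match="available"):
            peak_matrix(ersp_map, electrodes=("Cz", "C3"))

    def test_matches_brute_force_oracle_on_random_maps(self):
        """Bit-exact agreement with an independent nested-loop argmax."""
        rng = np.random.default_rng(123)
        spec = WindowSpec(0.0, 200.0, 100.0, 50.0)
        for _ in range(100):
            n_t = 150
            times = np.arange(n_t) * 2.0  # 0..298 ms
            freqs = np.arange(2.0, 8.1, 0.5)
            chans = ["Cz", "Pz"]
            ratio = rng.uniform(0.1, 5.0, size=(2, len(freqs), n_t))
            m = peak_matrix(ERSPMap(ratio, freqs, times, chans), spec, chans)
            windows = make_time_windows(spec)
            for wi, (a, b) in enumerate(windows):
                for ci in range(len(chans)):
                    best_f, best_v = None, -np.inf
                    for fi in range(len(freqs)):
                        acc, cnt = 0.0, 0
                        for ti in range(n_t):
                            if a <= times[ti] < b:
                                acc += ratio[ci, fi, ti]
                                cnt += 1
                        mean = acc / cnt
                        if mean > best_v:
                            best_v, best_f = mean, freqs[fi]
                    assert m.peak_freq_hz[wi, ci] == best_f
                    assert m.peak_ersp[wi, ci] == best_v

    @given(n_steps=st.integers(1, 12), n_elec=st.integers(1, 6))
    @settings(max_examples=30, deadline=None)
    def test_cell_count_is_windows_times_electrodes(self, n_steps, n_elec):
        spec = WindowSpec(250.0, 250.0 + 100.0 + 50.0 * (n_steps - 1), 100.0, 50.0)
        chans = ["Cz", "C3", "C4", "Pz", "P3", "P4"][:n_elec]
        m = peak_matrix(_ersp_from_profile(_ridge(6.0)), spec, chans)
        assert m.n_cells == n_steps * n_elec


class TestBandShares:
    def _matrix(self, freqs):
        freqs = np.asarray(freqs, float)
        return PeakMatrix(freqs.reshape(-1, 1), np.ones_like(freqs).reshape(-1, 1),
                          [(0.0, 100.0)] * len(freqs), ["Cz"])

    def test_all_theta(self):
        s = band_shares(self._matrix([5.0] * 10))
        assert s == {"delta": 0.0, "theta": 100.0, "alpha": 0.0, "other": 0.0}

    def test_even_split_delta_theta(self):
        s = band_shares(self._matrix([3.0] * 57 + [5.0] * 57))
        assert s["delta"] == 50.0 and s["theta"] == 50.0

    def test_8hz_counts_as_alpha(self):
        s = band_shares(self._matrix([8.0]))
        assert s["alpha"] == 100.0

    def test_above_12hz_is_other_and_sum_is_exactly_100(self):
        s = band_shares(self._matrix([2.0, 4.0, 8.5, 12.5, 13.0, 14.5, 7.5]))
        assert s["other"] == pytest.approx(3 / 7 * 100)
        assert sum(s.values()) == pytest.approx(100.0, abs=1e-9)

    @given(st.lists(st.sampled_from(list(np.arange(2.0, 15.1, 0.5))),
                    min_size=1, max_size=150))
    @settings(max_examples=100, deadline=None)
    def test_shares_always_sum_to_100(self, freqs):
        assert sum(band_shares(self._matrix(freqs)).values()) == pytest.approx(
            100.0, abs=1e-9)


class TestExtractITF:
    def _matrix(self, freqs, ersps=None):
        freqs = np.asarray(freqs, float)
        ersps = np.ones_like(freqs) if ersps is None else np.asarray(ersps, float)
        return PeakMatrix(freqs.reshape(-1, 1), ersps.reshape(-1, 1),
                          [(0.0, 100.0)] * len(freqs), ["Cz"])

    def test_mode_and_reliability_by_count(self):
        r = extract_itf(self._matrix([4.5] * 60 + [5.0] * 20))
        assert r.itf_hz == 4.5
        assert r.reliability == pytest.approx(0.75)

    def test_unanimous_theta_is_singular(self):
        r = extract_itf(self._matrix([6.0] * 30))
        assert r.reliability == 1.0
        assert r.reliability_class == "singular"

    def test_double_mode_sets_tie_and_resolves_by_ersp_mass(self):
        # equal counts of 7.5 and 5.5; 5.5 cells carry more total ERSP
        freqs = [7.5] * 10 + [5.5] * 10
        ersps = [2.0] * 10 + [3.0] * 10
        r = extract_itf(self._matrix(freqs, ersps))
        assert r.tie
        assert sorted(r.tie_candidates) == [5.5, 7.5]
        assert r.itf_hz == 5.5

    def test_tie_with_equal_mass_breaks_to_lower_frequency(self):
        r = extract_itf(self._matrix([7.5] * 5 + [5.5] * 5))
        assert r.tie and r.itf_hz == 5.5

    def test_no_theta_cells_gives_class_none(self):
        r = extract_itf(self._matrix([3.0, 9.0, 10.0]))
        assert np.isnan(r.itf_hz)
        assert r.reliability_class == "none"
        assert r.n_theta_cells == 0

    def test_reliability_counts_only_theta_cells(self):
        # delta and alpha cells dilute band share but not reliability
        r = extract_itf(self._matrix([3.0] * 50 + [6.5] * 10))
        assert r.itf_hz == 6.5
        assert r.reliability == 1.0

    @given(st.lists(st.sampled_from(list(np.arange(2.0, 15.1, 0.5))),
                    min_size=2, max_size=120), st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_reliability_invariant_under_cell_permutation(self, freqs, rnd):
        a = extract_itf(self._matrix(freqs))
        shuffled = list(freqs)
        rnd.shuffle(shuffled)
        b = extract_itf(self._matrix(shuffled))
        assert a.reliability == b.reliability
        assert np.isnan(a.itf_hz) and np.isnan(b.itf_hz) or a.itf_hz == b.itf_hz


class TestReliabilityClass:
    @pytest.mark.parametrize("r,cls", [
        (1.00, "singular"), (0.81, "singular"),
        (0.80, "highly_reliable"), (0.70, "highly_reliable"), (0.51, "highly_reliable"),
        (0.50, "reliable"), (0.31, "reliable"),
        (0.30, "unreliable"), (0.15, "unreliable"),
        (0.149, "none"), (0.125, "none"), (0.0, "none"),
    ])
    def test_boundaries(self, r, cls):
        assert reliability_class(r) == cls

    @given(st.floats(0.0, 1.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_classes_partition_unit_interval(self, r):
        assert reliability_class(r) in {"singular", "highly_reliable", "reliable",
                                        "unreliable", "none"}

    def test_out_of_range_rejected(self):
        for bad in (-0.01, 1.01):
            with pytest.raises(ValueError):
                reliability_class(bad)


class TestFallback:
    def _map_with_po(self, central_freq, po_freq):
        channels = ("Cz", "C3", "C4", "Pz", "P3", "P4", "PO7", "PO8")
        times = -1000.0 + np.arange(1750) * 2.0
        f, _ = np.meshgrid(GRID, times, indexing="ij")
        central = 1.0 + 3.0 * np.exp(-((f - central_freq) ** 2) / 0.1)
        po = 1.0 + 6.0 * np.exp(-((f - po_freq) ** 2) / 0.1)
        ratio = np.stack([central] * 6 + [po] * 2)
        return ERSPMap(ratio, GRID.copy(), times, list(channels))

    def test_weak_central_theta_triggers_fallback_and_finds_planted(self):
        ersp_map = self._map_with_po(central_freq=2.5, po_freq=6.0)
        result, matrix = fallback_extract(ersp_map)
        assert result.fallback_used
        assert result.itf_hz == 6.0
        assert matrix.n_cells == 19 * 8

    def test_strong_central_theta_skips_fallback(self):
        result, _ = fallback_extract(self._map_with_po(6.0, 10.0))
        assert not result.fallback_used
        assert result.itf_hz == 6.0

    def test_zero_trigger_never_falls_back(self):
        result, _ = fallback_extract(self._map_with_po(2.5, 6.0),
                                     trigger_theta_share_pct=0.0)
        assert not result.fallback_used

    def test_missing_fallback_electrodes_degrade_gracefully(self):
        ersp_map = _ersp_from_profile(_ridge(2.5))  # no PO7/PO8 channels
        result, _ = fallback_extract(ersp_map)
        assert not result.fallback_used


class TestPairedComparison:
    def test_uniform_positive_difference_rejects(self):
        res = compare_conditions([60.0] * 10, [30.0] * 10)
        assert res.p_value < 0.05
        assert res.direction == "am_greater"

    def test_identical_samples_give_p_one(self):
        res = compare_conditions([40.0] * 8, [40.0] * 8)
        assert res.p_value == 1.0
        assert res.direction == "none"

    def test_sign_flip_symmetry(self):
        am = [55.0, 60.0, 48.0, 70.0, 52.0, 63.0]
        rs = [30.0, 35.0, 40.0, 31.0, 29.0, 45.0]
        a = compare_conditions(am, rs)
        b = compare_conditions(rs, am)
        assert a.p_value == b.p_value
        assert {a.direction, b.direction} == {"am_greater", "rest_greater"}

    def test_minimal_wilcoxon_statistic_matches_enumeration(self):
        """All-positive differences give statistic 0; exact one-sided mass of
        that extreme table is 2^-n, so the two-sided p is 2^(1-n)."""
        n = 10
        res = compare_conditions([60.0] * n, [30.0] * n)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2.0 ** (1 - n), rel=1e-6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="5"):
            compare_conditions([1.0] * 4, [0.0] * 4)
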