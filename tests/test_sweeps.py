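"""Tests of frequency curves, maps, synergy reports, and ratio lines."""

import numpy as np
import pytest

from daneuron import MinimalParams
from daneuron.sweeps import (
    FrequencyMap,
    frequency_curve,
    frequency_map,
    ratio_line_profile,
    synergy_report,
)

P = MinimalParams()


class TestFrequencyCurve:
    def test_nmda_curve_rises_then_falls(self):
        grid = np.round(np.arange(0.0, 1.21, 0.1), 10)
        curve = frequency_curve("minimal", P, "nmda", grid)
        f = np.array([fs.frequency or 0.0 for _, fs in curve])
        peak = int(np.argmax(f))
        assert 0 < peak < len(f) - 1
        assert np.all(np.diff(f[: peak + 1]) > 0)
        assert np.all(np.diff(f[peak:]) < 0)

    def test_ampa_curve_blocks(self):
        grid = np.round(np.arange(0.0, 0.021, 0.002), 10)
        curve = frequency_curve("minimal", P, "ampa", grid)
        regimes = [fs.regime for _, fs in curve]
        assert regimes[0] == "firing"
        assert regimes[-1] == "quiescent"
        fmax = max(fs.frequency or 0.0 for _, fs in curve)
        assert fmax < 10.0

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError):
            frequency_curve("minimal", P, "nmda", np.array([0.5, 0.1]))


class TestFrequencyMap:
    def test_row_zero_reproduces_curve(self, minimal_map, minimal_params):
        gn = minimal_map.gn_axis[::10]
        curve = frequency_curve("minimal", minimal_params, "nmda", gn)
        for (g, fs), j in zip(curve, range(0, len(minimal_map.gn_axis), 10)):
            want = minimal_map.frequency[0, j]
            if fs.frequency is None:
                assert np.isnan(want)
            else:
                assert fs.frequency == pytest.approx(want, rel=1e-9)

    def test_block_boundary_shifts_right_with_ampa(self, minimal_map):
        # g_N needed to fire grows with g_A over the blocked rows
        onset = []
        for i, ga in enumerate(minimal_map.ga_axis):
            firing = np.nonzero(minimal_map.regime[i] == "firing")[0]
            if len(firing):
                onset.append((ga, minimal_map.gn_axis[firing[0]]))
        gn_onset = np.array([g for _, g in onset])
        assert np.all(np.diff(gn_onset) >= 0)

    def test_large_ampa_small_nmda_is_quiescent(self, minimal_map):
        sel = minimal_map.regime[minimal_map.ga_axis >= 0.02][
            :, minimal_map.gn_axis <= 0.1
        ]
        assert np.all(sel == "quiescent")

    def test_invariants_enforced(self):
        ga = np.array([0.0, 0.1])
        gn = np.array([0.0, 0.1])
        freq = np.array([[1.0, np.nan], [np.nan, np.nan]])
        regime = np.array([["firing", "quiescent"],
                           ["quiescent", "quiescent"]], dtype=object)
        FrequencyMap("minimal", ga, gn, freq, regime)  # consistent: fine
        with pytest.raises(ValueError):
            FrequencyMap("minimal", ga, gn, np.full((2, 2), 1.0), regime)
        with pytest.raises(ValueError):
            FrequencyMap("minimal", ga[::-1], gn, freq, regime)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            frequency_map("minimal", P, np.array([]), np.array([0.0]))


class TestSynergyReport:
    def test_refined_argmax_moves_less_than_one_cell(
        self, minimal_map, minimal_synergy
    ):
        flat = np.nan_to_num(minimal_map.frequency, nan=0.0)
        i, j = np.unravel_index(int(np.argmax(flat)), flat.shape)
        ga_step = minimal_map.ga_axis[1] - minimal_map.ga_axis[0]
        gn_step = minimal_map.gn_axis[1] - minimal_map.gn_axis[0]
        assert abs(minimal_synergy.argmax[0] - minimal_map.ga_axis[i]) <= ga_step
        assert abs(minimal_synergy.argmax[1] - minimal_map.gn_axis[j]) <= gn_step

    def test_joint_maximum_dominates_nmda_only(self, minimal_synergy):
        assert minimal_synergy.f_joint >= minimal_synergy.f_nmda_only
        assert minimal_synergy.synergy_percent >= 0.0

    def test_degenerate_map_gives_zero_synergy(self):
        ga = np.array([0.0, 0.1])
        gn = np.array([0.0, 0.1])
        freq = np.array([[np.nan, 5.0], [np.nan, 3.0]])
        regime = np.array([["quiescent", "firing"],
                           ["quiescent", "firing"]], dtype=object)
        fmap = FrequencyMap("minimal", ga, gn, freq, regime)
        rep = synergy_report(fmap, refine=False)
        assert rep.synergy_percent == 0.0
        assert rep.argmax == (0.0, 0.1)

    def test_no_firing_on_nmda_line_is_an_error(self):
        ga = np.array([0.0, 0.1])
        gn = np.array([0.0, 0.1])
        freq = np.array([[np.nan, np.nan], [np.nan, 3.0]])
        regime = np.array([["quiescent", "quiescent"],
                           ["quiescent", "firing"]], dtype=object)
        fmap = FrequencyMap("minimal", ga, gn, freq, regime)
        with pytest.raises(ValueError, match="g_AMPA = 0"):
            synergy_report(fmap, refine=False)


class TestRatioLines:
    def test_zero_ratio_equals_nmda_only_curve(self):
        gn = np.round(np.arange(0.0, 1.21, 0.2), 10)
        prof = ratio_line_profile("minimal", P, 0.0, gn)
        curve = frequency_curve("minimal", P, "nmda", gn)
        for (g1, a), (g2, b) in zip(prof, curve):
            assert g1 == g2
            assert (a.frequency is None) == (b.frequency is None)
            if a.frequency is not None:
                assert a.frequency == pytest.approx(b.frequency, rel=1e-9)

    def test_control_ratio_outperforms_doubled_ratio(self):
        # the 1/30 conductance ratio line passes near the frequency-map
        # maximum; doubling AMPA relative to NMDA (1/15) cuts the peak
        gn = np.round(np.arange(0.0, 1.21, 0.05), 10)
        f30 = max(
            (fs.frequency or 0.0)
            for _, fs in ratio_line_profile("minimal", P, 1 / 30, gn)
        )
        f15 = max(
            (fs.frequency or 0.0)
            for _, fs in ratio_line_profile("minimal", P, 1 / 15, gn)
        )
        assert f30 > f15
        assert f15 < 0.8 * f30

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            ratio_line_profile("minimal", P, -0.1, np.array([0.1]))
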