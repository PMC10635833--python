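"""FRET unmixing, load correlation, colocalization and calcium traces."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condmech import synth
from condmech.imaging import (
    FretSet,
    delta_f_over_f,
    estimate_bleedthrough,
    fret_index_map,
    fret_vs_load,
    pearson_colocalization,
    pressure_to_displacement,
    scramble_blocks,
    scramble_null,
)


class TestBleedthrough:
    def test_exact_donor_slope(self, rng):
        i_dd = rng.uniform(10, 200, 500)
        d, a = estimate_bleedthrough((i_dd, 0.6 * i_dd),
                                     (rng.uniform(10, 200, 500),
                                      np.zeros(500)))
        assert d == pytest.approx(0.600, abs=1e-9)
        assert a == pytest.approx(0.0, abs=1e-9)

    def test_noisy_slope_within_two_percent(self):
        ds = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            i_dd = r.uniform(20, 200, 2000)
            i_da = 0.5 * i_dd * (1 + 0.05 * r.standard_normal(2000))
            i_aa = r.uniform(20, 200, 2000)
            d, _ = estimate_bleedthrough((i_dd, i_da), (i_aa, np.zeros(2000)))
            ds.append(d)
        assert np.median(ds) == pytest.approx(0.5, rel=0.02)

    def test_insufficient_bright_pixels_refused(self):
        with pytest.raises(ValueError, match="pixels above background"):
            estimate_bleedthrough((np.ones(50), np.ones(50)),
                                  (np.ones(50), np.ones(50)))


class TestFretIndex:
    def test_worked_value(self):
        # I_DD=100, I_DA=80, I_AA=50, d=0.5, a=0.2 -> cF=20, index=1/6
        fs = FretSet(i_dd=np.full((4, 4), 100.0), i_da=np.full((4, 4), 80.0),
                     i_aa=np.full((4, 4), 50.0), donor_bleed_d=0.5,
                     crossex_a=0.2, mask=np.ones((4, 4), bool))
        _, mean_index, _ = fret_index_map(fs)
        assert mean_index == pytest.approx(1.0 / 6.0, abs=1e-9)

    def test_round_trip_recovers_truth_map(self, rng):
        truth = rng.uniform(0.05, 0.7, (32, 32))
        fs = synth.simulate_fret_stacks(truth, 0.5, 0.2, seed=4)
        fs.mask = np.ones(truth.shape, bool)
        index, _, _ = fret_index_map(fs)
        np.testing.assert_allclose(index, truth, atol=1e-9)

    def test_zero_fret_control_maps_to_zero(self):
        # spacer-control analogue: no energy transfer anywhere
        fs = synth.simulate_fret_stacks(np.zeros((16, 16)), 0.5, 0.2, seed=5)
        fs.mask = np.ones((16, 16), bool)
        index, mean_index, _ = fret_index_map(fs)
        assert mean_index == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=10, deadline=None)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_gain_invariance(self, gain):
        # common multiplicative gain on all three channels cancels
        rng = np.random.default_rng(0)
        truth = rng.uniform(0.1, 0.5, (16, 16))
        fs = synth.simulate_fret_stacks(truth, 0.4, 0.3, seed=6)
        fs.mask = np.ones((16, 16), bool)
        _, m1, _ = fret_index_map(fs)
        scaled = FretSet(i_dd=fs.i_dd * gain, i_da=fs.i_da * gain,
                         i_aa=fs.i_aa * gain, donor_bleed_d=0.4,
                         crossex_a=0.3, mask=fs.mask)
        _, m2, _ = fret_index_map(scaled)
        assert m1 == pytest.approx(m2, rel=1e-9)


class TestFretVsLoad:
    def test_exact_decreasing_line(self):
        out = fret_vs_load(np.array([0, 1, 2, 3.0]),
                           np.array([0.5, 0.4, 0.3, 0.2]))
        assert out["rho"] == pytest.approx(-1.0)

    def test_monotone_tension_response_detected(self, rng):
        disp = np.linspace(0, 5, 8)
        fret = 0.5 - 0.05 * disp + rng.normal(0, 0.005, 8)
        out = fret_vs_load(disp, fret)
        assert out["rho"] < -0.9

    def test_type_one_error_calibration(self):
        # displacement-independent FRET: standard test rejects ~5% of runs
        rejections = 0
        n_runs = 1000
        for seed in range(n_runs):
            r = np.random.default_rng(seed)
            disp = np.linspace(0, 5, 10)
            fret = 0.4 + r.normal(0, 0.02, 10)
            out = fret_vs_load(disp, fret)
            rejections += out["p_standard"] < 0.05
        assert 0.03 <= rejections / n_runs <= 0.07

    def test_reversibility_flag(self):
        out = fret_vs_load(np.arange(4.0), np.array([0.5, 0.4, 0.3, 0.2]),
                           resting_before=0.50, resting_after=0.52)
        assert out["reversible"]

    def test_constant_input_refused(self):
        with pytest.raises(ValueError, match="undefined"):
            fret_vs_load(np.arange(4.0), np.full(4, 0.3))


class TestPearson:
    def test_proportional_channels(self, rng):
        ch1 = rng.uniform(0, 1, (8, 8))
        rho, _ = pearson_colocalization(ch1, 2.0 * ch1)
        assert rho == pytest.approx(1.0)

    def test_exact_antilinear(self):
        rho, _ = pearson_colocalization(np.array([[1, 2, 3, 4.0]]),
                                        np.array([[8, 6, 4, 2.0]]))
        assert rho == pytest.approx(-1.0)

    def test_independent_noise_uncorrelated(self):
        rhos = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            rhos.append(pearson_colocalization(
                r.standard_normal((64, 256)), r.standard_normal((64, 256)))[0])
        assert np.median(np.abs(rhos)) < 0.05

    def test_zero_variance_refused(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_colocalization(np.ones((4, 4)), np.eye(4))


class TestScrambleNull:
    def test_colocalized_rho_beats_null(self):
        ch1, ch2 = synth.simulate_coloc_images(coloc_fraction=1.0,
                                               noise_sd=1.0, seed=10)
        res = scramble_null(ch1, ch2, n_perm=200, seed=11)
        assert res.rho > np.percentile(res.null_rho, 95)
        assert res.p_empirical < 0.05

    def test_scramble_preserves_histogram(self, rng):
        img = rng.uniform(0, 1, (8, 64))
        blocks = [(i, i + 16) for i in range(0, 64, 16)]
        scr = scramble_blocks(img, blocks, rng.permutation(4))
        np.testing.assert_array_equal(np.sort(scr.ravel()),
                                      np.sort(img.ravel()))

    def test_zero_permutations_refused(self):
        ch1, ch2 = synth.simulate_coloc_images(seed=1)
        with pytest.raises(ValueError, match="n_perm"):
            scramble_null(ch1, ch2, n_perm=0)

    def test_too_few_blocks_refused(self):
        ch1, ch2 = synth.simulate_coloc_images(seed=1)
        with pytest.raises(ValueError, match="too coarse"):
            scramble_null(ch1, ch2, block_length_px=200, n_perm=100)

    def test_null_size_matches_permutations(self):
        ch1, ch2 = synth.simulate_coloc_images(coloc_fraction=0.5,
                                               noise_sd=1.0, seed=3)
        res = scramble_null(ch1, ch2, n_perm=150, seed=4)
        assert res.null_rho.size == 150


class TestCalcium:
    def test_peak_delta_f_over_f(self):
        trace = np.concatenate([np.full(100, 50.0), np.full(20, 150.0)])
        ca = delta_f_over_f(trace, n_baseline=100, smooth_window=1)
        assert ca.normalized.max() == pytest.approx(2.0)

    def test_constant_trace_is_zero(self):
        ca = delta_f_over_f(np.full(200, 80.0), n_baseline=100)
        np.testing.assert_allclose(ca.normalized, 0.0, atol=1e-12)

    def test_window_one_is_identity(self, rng):
        trace = 50 + rng.uniform(0, 10, 200)
        ca = delta_f_over_f(trace, n_baseline=100, smooth_window=1)
        np.testing.assert_allclose(ca.normalized, (trace - ca.f0) / ca.f0)

    def test_baseline_mean_near_zero(self, rng):
        trace = 50 + rng.normal(0, 2, 300)
        ca = delta_f_over_f(trace, n_baseline=100, smooth_window=5)
        assert abs(ca.normalized[:100].mean()) < 0.02

    def test_short_trace_refused(self):
        with pytest.raises(ValueError, match="shorter"):
            delta_f_over_f(np.ones(50), n_baseline=100)


class TestPressureTable:
    def test_linear_interpolation(self):
        table = pd.DataFrame({"pressure_kPa": [0, 100, 200],
                              "displacement_um": [0.0, 2.0, 6.0]})
        out = pressure_to_displacement(table, np.array([50.0, 150.0]))
        np.testing.assert_allclose(out, [1.0, 4.0])

    def test_out_of_range_refused(self):
        table = pd.DataFrame({"pressure_kPa": [0, 100],
                              "displacement_um": [0.0, 2.0]})
        with pytest.raises(ValueError, match="range"):
            pressure_to_displacement(table, np.array([150.0]))
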