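"""Diffusion analysis tests.

The windowed ADC fit is checked against a hand-rolled normal-equations
solver; the kurtosis fit against forward-generated signals whose global
minimum is the truth; the kurtosis-reduction simulation against a log-linear
closed-form oracle and the reference sensitivity anchors.
"""

import numpy as np
import pytest

from brainshift.diffusion import (
    SUPPLEMENTARY_HIGH_B,
    calibrate_kurtosis_reference,
    combine_directions,
    fit_adc_range,
    fit_ivim_kurtosis,
    fit_monoexponential,
    kurtosis_signal,
    simulate_kurtosis_effect,
)
from brainshift.phantom import DiffusionProtocol, IVIMKurtosisParams, ivim_kurtosis_signal


@pytest.fixture(scope="module")
def protocol():
    return DiffusionProtocol.default()


def _monoexp_series(protocol, adc, s0=1000.0):
    return s0 * np.exp(-np.asarray(protocol.b_values) * adc)


class TestCombineDirections:
    def test_geometric_mean_of_known_triplet(self, protocol):
        s = np.ones((protocol.n_b, 3))
        s[0] = (1.0, 4.0, 16.0)
        out = combine_directions(s, protocol)
        assert out[0] == pytest.approx(4.0, rel=1e-12)

    def test_identical_directions_pass_through(self, protocol, rng):
        base = rng.uniform(10, 100, size=(4, protocol.n_b))
        series = np.repeat(base[..., None], 3, axis=-1)
        assert np.allclose(combine_directions(series, protocol), base, rtol=1e-12)

    def test_zero_in_any_direction_gives_zero(self, protocol):
        s = np.ones((protocol.n_b, 3))
        s[3, 1] = 0.0
        assert combine_directions(s, protocol)[3] == 0.0

    def test_variance_reduction_under_independent_noise(self, protocol, rng):
        truth = _monoexp_series(protocol, 7e-4, s0=100.0)
        noisy = truth[None, :, None] + rng.normal(scale=2.0, size=(10_000, protocol.n_b, 3))
        combined = combine_directions(np.clip(noisy, 1e-6, None), protocol)
        assert combined[:, 0].var() < noisy[:, 0, 0].var()

    def test_missing_direction_rejected(self, protocol):
        with pytest.raises(ValueError, match="directions"):
            combine_directions(np.ones((protocol.n_b, 2)), protocol)


class TestRangeADC:
    def test_dmso_adc_identical_across_windows(self, protocol):
        """A mono-exponential signal at the control-phantom ADC returns
        680 um^2/s from the low, mid, and high windows alike."""
        series = _monoexp_series(protocol, 6.8e-4)
        for window in ("low", "mid", "high"):
            fit = fit_adc_range(series, protocol, window)
            assert fit.adc_map * 1e6 == pytest.approx(680.0, rel=1e-6)
            assert fit.s0_map == pytest.approx(1000.0, rel=1e-6)

    def test_window_ordering_on_ivim_kurtosis_signal(self, protocol):
        """Perfusion inflates the low-window ADC and kurtosis deflates the
        high-window ADC: ADC_low > ADC_mid > ADC_high."""
        params = IVIMKurtosisParams(s0=1000.0, f_ivim=0.1, d_star=1e-2, adc0=6e-4, k=0.6)
        series = ivim_kurtosis_signal(np.asarray(protocol.b_values), params)
        adc = {w: float(fit_adc_range(series, protocol, w).adc_map) for w in ("low", "mid", "high")}
        assert adc["low"] > adc["mid"] > adc["high"]

    def test_matches_normal_equations_oracle(self, protocol, rng):
        """OLS slope/intercept agree with the two-coefficient normal equations
        solved by hand on 100 random voxels."""
        series = rng.uniform(10.0, 1000.0, size=(100, protocol.n_b))
        fit = fit_adc_range(series, protocol, "mid")
        mask = protocol.window_mask("mid")
        b = np.asarray(protocol.b_values)[mask]
        n = b.size
        sx, sxx = b.sum(), (b * b).sum()
        for i in range(100):
            y = np.log(series[i, mask])
            det = n * sxx - sx * sx
            slope = (n * (b * y).sum() - sx * y.sum()) / det
            intercept = (sxx * y.sum() - sx * (b * y).sum()) / det
            if slope < 0:
                assert fit.adc_map[i] == pytest.approx(-slope, rel=1e-10)
                assert np.log(fit.s0_map[i]) == pytest.approx(intercept, rel=1e-10)
            else:
                assert not fit.valid_mask[i]

    def test_nonpositive_signal_masked(self, protocol):
        series = _monoexp_series(protocol, 6.8e-4)
        series[30] = 0.0
        fit = fit_adc_range(series, protocol, "mid")
        assert not fit.valid_mask

    def test_underfilled_window_rejected(self):
        proto = DiffusionProtocol((20.0, 100.0, 300.0, 600.0, 1200.0, 2000.0))
        with pytest.raises(ValueError, match="need >= 3"):
            fit_adc_range(np.ones(6), proto, "low")


class TestIVIMKurtosisFit:
    def test_noiseless_exact_recovery(self, protocol):
        truth = (1000.0, 6.2e-4, 0.623)
        b = np.asarray(protocol.b_values)
        series = np.where(b >= 235, kurtosis_signal(b, *truth), 1000.0)
        mid = fit_adc_range(series, protocol, "mid")
        fit = fit_ivim_kurtosis(series, protocol, mid)
        assert fit.s0_map == pytest.approx(truth[0], rel=1e-6)
        assert fit.adc0_map == pytest.approx(truth[1], rel=1e-6)
        assert fit.k_map == pytest.approx(truth[2], rel=1e-6)
        assert fit.converged_mask.all()

    def test_k_zero_signal_matches_stejskal_tanner(self, protocol):
        series = _monoexp_series(protocol, 6.2e-4)
        mid = fit_adc_range(series, protocol, "mid")
        fit = fit_ivim_kurtosis(series, protocol, mid)
        # the same b >= 235 subset fitted mono-exponentially
        sel = np.asarray(protocol.b_values) >= 235
        _, adc_st = fit_monoexponential(np.asarray(protocol.b_values)[sel], series[sel])
        assert fit.adc0_map == pytest.approx(adc_st, rel=1e-6)
        assert fit.k_map == pytest.approx(0.0, abs=1e-6)

    def test_out_of_bounds_kurtosis_pinned_and_flagged(self, protocol):
        b = np.asarray(protocol.b_values)
        series = np.where(b >= 235, kurtosis_signal(b, 1000.0, 6.2e-4, 2.5), 1000.0)
        mid = fit_adc_range(series, protocol, "mid")
        fit = fit_ivim_kurtosis(series, protocol, mid)
        assert fit.k_map == pytest.approx(2.0, abs=1e-9)
        assert fit.at_bound_mask

    def test_bounds_always_respected(self, protocol, rng):
        series = rng.uniform(50.0, 1000.0, size=(20, protocol.n_b))
        series *= np.exp(-np.asarray(protocol.b_values) * 6e-4)
        mid = fit_adc_range(series, protocol, "mid")
        fit = fit_ivim_kurtosis(series, protocol, mid)
        v = fit.valid_mask
        assert np.all(fit.k_map[v] >= 0.0) and np.all(fit.k_map[v] <= 2.0)
        assert np.all(fit.adc0_map[v] >= 0.5 * mid.adc_map[v] - 1e-15)
        assert np.all(fit.adc0_map[v] <= 2.0 * mid.adc_map[v] + 1e-15)
        assert np.all(fit.s0_map[v] >= 0.5 * mid.s0_map[v] - 1e-9)
        assert np.all(fit.s0_map[v] <= 2.0 * mid.s0_map[v] + 1e-9)

    def test_noisy_recovery_accuracy(self, protocol, rng):
        """Median ADC0 error <= 5% at sigma/S0 = 2%, K bias shrinking with noise."""
        truth = (1000.0, 6.2e-4, 0.623)
        b = np.asarray(protocol.b_values)
        clean = kurtosis_signal(b, *truth)
        k_bias = []
        for sd, n in ((20.0, 1000), (2.0, 300)):
            noisy = np.clip(clean + rng.normal(scale=sd, size=(n, b.size)), 1.0, None)
            mid = fit_adc_range(noisy, protocol, "mid")
            fit = fit_ivim_kurtosis(noisy, protocol, mid)
            err = np.abs(fit.adc0_map[fit.valid_mask] - truth[1]) / truth[1]
            assert np.median(err) <= 0.05
            k_bias.append(abs(np.median(fit.k_map[fit.valid_mask]) - truth[2]))
        assert k_bias[1] < max(k_bias[0], 0.02)

    def test_missing_mid_fit_rejected(self, protocol):
        with pytest.raises(ValueError, match="mid"):
            fit_ivim_kurtosis(np.ones(protocol.n_b), protocol, None)

    def test_invalid_mid_fit_voxels_inherit_invalid(self, protocol):
        series = np.zeros((2, protocol.n_b))
        series[0] = _monoexp_series(protocol, 6.2e-4)
        mid = fit_adc_range(series, protocol, "mid")
        fit = fit_ivim_kurtosis(series, protocol, mid)
        assert fit.valid_mask[0] and not fit.valid_mask[1]
        assert np.isnan(fit.k_map[1])


class TestRangeConsistency:
    @pytest.mark.parametrize("adc", [3e-4, 6.8e-4, 1.5e-3])
    def test_monoexponential_input_gives_equal_window_adcs(self, protocol, adc):
        series = _monoexp_series(protocol, adc)
        adcs = [float(fit_adc_range(series, protocol, w).adc_map) for w in ("low", "mid", "high")]
        assert adcs == pytest.approx([adc] * 3, rel=1e-6)


class TestKurtosisEffectSimulation:
    BASE = IVIMKurtosisParams(s0=1000.0, f_ivim=0.0, d_star=1.0, adc0=5e-4, k=1.0)

    def test_zero_reduction_is_identity(self):
        tab = simulate_kurtosis_effect(self.BASE, [0.0])
        assert tab["adc_pct_change"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_percent_increase_strictly_monotone_in_reduction(self):
        sweep = np.arange(0.1, 0.95, 0.1)
        tab = simulate_kurtosis_effect(self.BASE, sweep)
        pct = tab["adc_pct_change"].to_numpy()
        assert np.all(np.diff(pct) > 0)
        # log-linear closed-form oracle: same ordering and magnitudes within 15%
        b = np.asarray(SUPPLEMENTARY_HIGH_B)
        def loglin_adc(k):
            y = np.log(kurtosis_signal(b, 1000.0, 5e-4, k))
            return -np.polyfit(b, y, 1)[0]
        oracle = [100.0 * (loglin_adc(1.0 * (1 - r)) - loglin_adc(1.0)) / loglin_adc(1.0)
                  for r in sweep]
        assert pct == pytest.approx(oracle, rel=0.15)

    def test_calibrated_anchor_reproduces_companion_value(self):
        """Calibrating the 20% reduction to +9% puts the 40% reduction in the
        expected 16-19% band."""
        base = calibrate_kurtosis_reference(anchor_pct=9.0, anchor_reduction=0.2)
        tab = simulate_kurtosis_effect(base, [0.2, 0.4])
        assert tab["adc_pct_change"].iloc[0] == pytest.approx(9.0, abs=1e-6)
        assert 16.0 <= tab["adc_pct_change"].iloc[1] <= 19.0

    def test_invalid_reduction_rejected(self):
        with pytest.raises(ValueError, match="reduction"):
            simulate_kurtosis_effect(self.BASE, [1.0])

    def test_zero_base_kurtosis_rejected(self):
        flat = IVIMKurtosisParams(s0=1000.0, f_ivim=0.0, d_star=1.0, adc0=5e-4, k=0.0)
        with pytest.raises(ValueError, match="kurtosis"):
            simulate_kurtosis_effect(flat, [0.2])
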