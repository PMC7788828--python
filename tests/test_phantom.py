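"""Phantom construction and forward-model tests.

Every forward model is checked against an independently coded one-line
evaluation of its closed form; anatomy volumes are checked against the
probabilistic counting oracle (probability sum times voxel volume).
"""

import numpy as np
import pytest

import brainshift.phantom as ph
from brainshift.phantom import (
    CompartmentTruth,
    EffectSpec,
    FocalSite,
    IVIMKurtosisParams,
    TissueProbabilityMaps,
    VoxelGrid,
    apply_condition_effect,
    build_anatomy,
    focal_site_gm_gain,
    ivim_kurtosis_signal,
    simulate_cohort,
    simulate_dmso,
    simulate_dwi,
    simulate_mge,
    simulate_pdw,
)


class TestVoxelGrid:
    def test_volume_and_affine(self):
        g = VoxelGrid((32, 32, 24), (0.46, 0.46, 0.46))
        assert g.voxel_volume == pytest.approx(0.46**3)
        assert np.allclose(np.diag(g.affine)[:3], 0.46)
        g2 = VoxelGrid.from_affine(g.dims, g.affine)
        assert g2.voxel_size == pytest.approx(g.voxel_size)

    @pytest.mark.parametrize(
        "dims,vox",
        [((8, 32, 32), (0.23,) * 3), ((32, 32, 32), (0.0, 0.23, 0.23))],
    )
    def test_invalid_grid_rejected(self, dims, vox):
        with pytest.raises(ValueError):
            VoxelGrid(dims, vox)


class TestBuildAnatomy:
    def test_volumes_match_request_on_fine_grid(self):
        """CSF requested at the deeply-sedated group mean on the native
        0.23 mm grid is reproduced well within one voxel volume."""
        grid = VoxelGrid((72, 72, 56))
        truth = CompartmentTruth.default(csf_volume_mm3=190.0, parenchyma_volume_mm3=1841.0)
        maps = build_anatomy(grid, truth, seed=1)
        vv = grid.voxel_volume
        assert maps.volume("csf") == pytest.approx(190.0, abs=vv)
        assert maps.volume("gm") == pytest.approx(truth.gm_volume_mm3, abs=vv)
        assert maps.volume("wm") == pytest.approx(truth.wm_volume_mm3, abs=vv)
        assert (maps.p_csf > 0.5).any()

    def test_deterministic_for_fixed_seed(self, small_grid, small_truth):
        a = build_anatomy(small_grid, small_truth, seed=7)
        b = build_anatomy(small_grid, small_truth, seed=7)
        assert np.array_equal(a.p_csf, b.p_csf)
        assert np.array_equal(a.p_gm, b.p_gm)

    def test_zero_volume_rejected(self, small_grid):
        with pytest.raises(ValueError, match="volume"):
            CompartmentTruth.default(csf_volume_mm3=0.0)

    def test_infeasible_volumes_rejected(self, small_grid):
        big = CompartmentTruth.default(
            csf_volume_mm3=small_grid.volume, parenchyma_volume_mm3=small_grid.volume
        )
        with pytest.raises(ValueError, match="exceeds grid volume"):
            build_anatomy(small_grid, big, seed=0)


class TestConditionEffect:
    def test_identity_effect(self, small_anatomy):
        out = apply_condition_effect(small_anatomy, EffectSpec(csf_scale=1.0))
        assert np.allclose(out.p_csf, small_anatomy.p_csf)
        assert np.allclose(out.p_gm, small_anatomy.p_gm)

    def test_csf_rescaling_hits_target_and_conserves_tiv(self):
        """Scaling a 180 mm^3 CSF compartment by 190/180 lands on 190 mm^3
        (the reference group contrast) while conserving TIV."""
        grid = VoxelGrid((48, 48, 36), (0.46,) * 3)
        truth = CompartmentTruth.default(csf_volume_mm3=180.0, parenchyma_volume_mm3=1841.0)
        maps = build_anatomy(grid, truth, seed=3)
        out = apply_condition_effect(maps, EffectSpec(csf_scale=190.0 / 180.0))
        assert out.volume("csf") == pytest.approx(190.0, abs=grid.voxel_volume)
        assert out.tiv == pytest.approx(maps.tiv, rel=0.005)

    def test_csf_shrink_returns_mass_to_parenchyma(self, small_anatomy):
        out = apply_condition_effect(small_anatomy, EffectSpec(csf_scale=0.9))
        assert out.volume("csf") == pytest.approx(
            0.9 * small_anatomy.volume("csf"), abs=small_anatomy.grid.voxel_volume
        )
        assert out.tiv == pytest.approx(small_anatomy.tiv, rel=1e-9)

    def test_focal_site_gain_matches_bruteforce_oracle(self, small_anatomy):
        """GM gain equals the brute-force voxel-wise sum of the capped bump."""
        site = FocalSite(center_vox=(16, 16, 12), radius_mm=1.5, magnitude=0.4)
        expected = focal_site_gm_gain(small_anatomy, site)
        # independent brute-force: loop voxels, accumulate capped Gaussian bump
        g = small_anatomy.grid
        sigma = site.radius_mm / 2.0
        total = 0.0
        for i in range(g.dims[0]):
            for j in range(g.dims[1]):
                for k in range(g.dims[2]):
                    d2 = sum(
                        ((idx - c) * v) ** 2
                        for idx, c, v in zip((i, j, k), site.center_vox, g.voxel_size)
                    )
                    if d2 > site.radius_mm**2:
                        continue
                    bump = site.magnitude * np.exp(-d2 / (2 * sigma**2))
                    total += min(bump, 1.0 - small_anatomy.p_gm[i, j, k])
        expected_bf = total * g.voxel_volume
        assert expected == pytest.approx(expected_bf, rel=1e-12)
        out = apply_condition_effect(
            small_anatomy, EffectSpec(csf_scale=1.0, focal_sites=(site,))
        )
        gain = out.volume("gm") - small_anatomy.volume("gm")
        assert gain == pytest.approx(expected_bf, rel=1e-9)

    def test_overdraining_csf_rejected(self, small_anatomy):
        with pytest.raises(ValueError):
            apply_condition_effect(small_anatomy, EffectSpec(csf_scale=1e-9))


class TestPDWForwardModel:
    def test_noiseless_exact_mixture(self, small_anatomy, small_truth):
        vol, bias = simulate_pdw(small_anatomy, small_truth, 0.0, 0.0, seed=1)
        expected = (
            small_anatomy.p_gm * small_truth.gm.proton_density
            + small_anatomy.p_wm * small_truth.wm.proton_density
            + small_anatomy.p_csf * small_truth.csf.proton_density
        )
        assert np.allclose(vol, expected, rtol=1e-12, atol=1e-15)
        assert np.allclose(bias, 1.0)

    def test_noise_sd_matches_sample_moment(self, small_anatomy, small_truth):
        vol, _ = simulate_pdw(small_anatomy, small_truth, 0.0, 0.05, seed=2)
        bg = small_anatomy.p_background > 0.999
        assert bg.sum() >= 10_000
        assert vol[bg].std() == pytest.approx(0.05, rel=0.10)

    def test_seed_determinism(self, small_anatomy, small_truth):
        a, _ = simulate_pdw(small_anatomy, small_truth, 0.05, 0.02, seed=9)
        b, _ = simulate_pdw(small_anatomy, small_truth, 0.05, 0.02, seed=9)
        assert np.array_equal(a, b)

    def test_negative_noise_rejected(self, small_anatomy, small_truth):
        with pytest.raises(ValueError):
            simulate_pdw(small_anatomy, small_truth, 0.0, -1.0, seed=0)


class TestMGEForwardModel:
    def test_single_compartment_closed_form(self, small_anatomy, mge_protocol):
        truth = CompartmentTruth.default(
            csf_volume_mm3=95.0, parenchyma_volume_mm3=920.0,
            parenchyma_t2star_ms=30.0, csf_t2star_ms=30.0,
        )
        series = simulate_mge(small_anatomy, truth, mge_protocol, 0.0, seed=0)
        inside = small_anatomy.p_gm + small_anatomy.p_wm + small_anatomy.p_csf > 0.999
        tes = np.array(mge_protocol.echo_times_ms)
        # all compartments share T2*=30 ms, so S(TE)/S(TE_0) is exp(-(TE-TE_0)/30)
        ratio = series[inside] / series[inside][:, :1]
        assert np.allclose(ratio, np.exp(-(tes - tes[0]) / 30.0), rtol=1e-12)

    def test_two_compartment_hand_oracle(self, small_truth, mge_protocol):
        grid = VoxelGrid((16, 16, 16), (0.46,) * 3)
        p_gm = np.zeros(grid.dims)
        p_csf = np.zeros(grid.dims)
        p_gm[8, 8, 8] = 0.6
        p_csf[8, 8, 8] = 0.4
        p_csf[0, 0, 0] = 1.0  # satisfy the CSF-presence invariant
        maps = TissueProbabilityMaps(grid, p_gm, np.zeros(grid.dims), p_csf)
        series = simulate_mge(maps, small_truth, mge_protocol, 0.0, seed=0)
        te = mge_protocol.echo_times_ms[5]
        by_hand = 0.6 * small_truth.gm.proton_density * np.exp(
            -te / small_truth.gm.t2star_ms
        ) + 0.4 * small_truth.csf.proton_density * np.exp(-te / small_truth.csf.t2star_ms)
        assert series[8, 8, 8, 5] == pytest.approx(by_hand, rel=1e-12)

    def test_too_few_echoes_rejected(self, small_anatomy, small_truth):
        proto = ph.AcquisitionProtocol((2.0, 4.0))
        with pytest.raises(ValueError, match="3 echoes"):
            simulate_mge(small_anatomy, small_truth, proto, 0.0, seed=0)

    def test_non_positive_echo_time_rejected(self):
        with pytest.raises(ValueError):
            ph.AcquisitionProtocol((0.0, 2.0, 4.0))


class TestDWIForwardModel:
    def test_degenerate_monoexponential(self, small_grid, dwi_protocol):
        p_csf = np.zeros(small_grid.dims)
        p_csf[4, 4, 4] = 1.0
        p_gm = np.zeros(small_grid.dims)
        p_gm[8, 8, 8] = 1.0
        maps = TissueProbabilityMaps(small_grid, p_gm, np.zeros(small_grid.dims), p_csf)
        params = IVIMKurtosisParams(s0=1.0, f_ivim=0.0, d_star=1e-2, adc0=7e-4, k=0.0)
        props = ph.CompartmentProps(1.0, 30.0, params)
        truth = CompartmentTruth(props, props, props, 95.0, 570.0, 350.0)
        series = simulate_dwi(maps, truth, dwi_protocol, "gaussian", 0.0, seed=0)
        b = np.array(dwi_protocol.b_values)
        expected = np.exp(-b * 7e-4)
        for d in range(3):
            assert np.allclose(series[8, 8, 8, :, d], expected, rtol=1e-12)

    def test_kurtosis_upturn_above_monoexponential_extrapolation(self, dwi_protocol):
        params = IVIMKurtosisParams(s0=1.0, f_ivim=0.1, d_star=1e-2, adc0=6e-4, k=0.6)
        b = np.array(dwi_protocol.b_values)
        sig = ivim_kurtosis_signal(b, params)
        mid = (b >= 235) & (b <= 1016)
        slope, intercept = np.polyfit(b[mid], np.log(sig[mid]), 1)
        high = b >= 1117
        assert np.all(np.log(sig[high]) > slope * b[high] + intercept)

    def test_matches_direct_formula_oracle(self, small_anatomy, small_truth, dwi_protocol):
        series = simulate_dwi(small_anatomy, small_truth, dwi_protocol, "gaussian", 0.0, seed=0)
        idx = (16, 16, 12)
        b = np.array(dwi_protocol.b_values)
        oracle = sum(
            small_anatomy.prob(c)[idx]
            * (
                small_truth.props(c).diffusion.s0
                * (
                    small_truth.props(c).diffusion.f_ivim
                    * np.exp(-b * small_truth.props(c).diffusion.d_star)
                    + (1 - small_truth.props(c).diffusion.f_ivim)
                    * np.exp(
                        -b * small_truth.props(c).diffusion.adc0
                        + (b * small_truth.props(c).diffusion.adc0) ** 2
                        * small_truth.props(c).diffusion.k
                        / 6
                    )
                )
            )
            for c in ("gm", "wm", "csf")
        )
        assert np.allclose(series[idx][:, 0], oracle, rtol=1e-12)

    def test_unknown_noise_model_rejected(self, small_anatomy, small_truth, dwi_protocol):
        with pytest.raises(ValueError, match="noise model"):
            simulate_dwi(small_anatomy, small_truth, dwi_protocol, "poisson", 0.01, seed=0)

    def test_rician_noise_biases_background_upward(self, small_anatomy, small_truth, dwi_protocol):
        series = simulate_dwi(small_anatomy, small_truth, dwi_protocol, "rician", 0.05, seed=4)
        bg = small_anatomy.p_background > 0.999
        # Rician magnitude floor: background mean ~ sigma*sqrt(pi/2), not 0
        assert series[bg].mean() > 0.04


class TestDMSOPhantom:
    def test_log_signal_linear_with_requested_slope(self, dwi_protocol):
        tab = simulate_dmso(dwi_protocol, adc=6.8e-4, s0=1000.0)
        b = tab["b_s_mm2"].to_numpy()
        slope, intercept = np.polyfit(b, np.log(tab["signal"]), 1)
        assert slope == pytest.approx(-6.8e-4, rel=1e-9)
        assert np.exp(intercept) == pytest.approx(1000.0, rel=1e-9)

    def test_signal_ratio_closed_form(self, dwi_protocol):
        tab = simulate_dmso(dwi_protocol, adc=6.8e-4, s0=1000.0)
        s = tab.set_index("b_s_mm2")["signal"]
        assert s[2518.0] / s[20.0] == pytest.approx(np.exp(-2498 * 6.8e-4), rel=1e-12)

    def test_non_positive_adc_rejected(self, dwi_protocol):
        with pytest.raises(ValueError):
            simulate_dmso(dwi_protocol, adc=0.0)


class TestCohort:
    def test_paired_cohort_structure_and_average_effect(self, small_grid):
        truth = CompartmentTruth.default(csf_volume_mm3=95.0, parenchyma_volume_mm3=920.0)
        effect = EffectSpec(csf_scale=180.0 / 190.0, t2star_shift_ms=1.8)
        cohort = simulate_cohort(12, small_grid, truth, effect, seed=5)
        assert len(cohort) == 12
        ratios, shifts = [], []
        for sub in cohort:
            ratios.append(sub.maps["B"].volume("csf") / sub.maps["A"].volume("csf"))
            shifts.append(sub.truth["B"].gm.t2star_ms - sub.truth["A"].gm.t2star_ms)
            assert sub.maps["A"].tiv == pytest.approx(sub.maps["B"].tiv, rel=0.005)
        assert np.mean(ratios) == pytest.approx(180.0 / 190.0, rel=1e-6)
        assert np.mean(shifts) == pytest.approx(1.8, abs=1e-12)

    def test_same_seed_reproduces_cohort(self, small_grid, small_truth):
        a = simulate_cohort(2, small_grid, small_truth, EffectSpec(), seed=8)
        b = simulate_cohort(2, small_grid, small_truth, EffectSpec(), seed=8)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.maps["A"].p_csf, sb.maps["A"].p_csf)
            assert sa.truth["A"].gm.t2star_ms == sb.truth["A"].gm.t2star_ms
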