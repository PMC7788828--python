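"""End-to-end pipeline: simulate a paired cohort, run every estimator, and
write tables, stat maps, and a JSON summary.

Stage order per subject and condition: PDW simulation -> bias correction ->
EM segmentation -> compartment volumes; MGE simulation -> T2* fit -> trimmed
compartment means; DWI simulation -> geometric-mean direction combination ->
windowed ADC fits -> ROI-restricted kurtosis fit.  Group level: paired
t-tests on compartment totals and voxel-wise paired tests with BH-FDR on
smoothed CSF-posterior and T2* maps.  Everything is deterministic for a fixed
config (all stage seeds derive from the config seed), and every output embeds
the config hash.

The DWI stage runs on a central axial slab (the diffusion acquisition it
emulates was a thin 2-D multislice protocol, unlike the whole-head 3-D PDW
and MGE scans); ADC/kurtosis ROI metrics come from that slab.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import io as bio
from .config import RunConfig, config_hash, save_config
from .diffusion import combine_directions, fit_adc_range, fit_ivim_kurtosis
from .morphometry import compartment_volumes, correct_bias_with_priors, segment, smooth_map
from .phantom import (
    AcquisitionProtocol,
    CompartmentTruth,
    DiffusionProtocol,
    EffectSpec,
    FocalSite,
    TissueProbabilityMaps,
    VoxelGrid,
    build_anatomy,
    simulate_cohort,
    simulate_dwi,
    simulate_mge,
    simulate_pdw,
)
from .relaxometry import compartment_t2star_mean, fit_t2star
from .voxelstats import fdr_correct, paired_total_test, paired_ttest_map, roi_extract

logger = logging.getLogger("brainshift")

MM2S_TO_UM2S = 1.0e6  # ADC unit conversion applied only at the table boundary


def _stage_seed(subject_seed: int, stage: int) -> int:
    return int(np.random.SeedSequence((subject_seed, stage)).generate_state(1)[0] % (2**31 - 1))


def default_roi_masks(
    maps: TissueProbabilityMaps,
    n_rois: int = 3,
    radius_mm: float = 0.7,
    within: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Programmatic spherical ROIs placed at well-separated GM-interior voxels.

    Centers are successive maxima of the distance-to-non-GM transform
    (optionally restricted to the ``within`` region), each pick suppressing
    its neighbourhood, which lands the spheres deep in the GM rind away from
    compartment boundaries.
    """
    gm_core = maps.p_gm > 0.9
    if not gm_core.any():
        gm_core = maps.p_gm > 0.5
    if within is not None:
        gm_core = gm_core & np.asarray(within, dtype=bool)
    dist = ndimage.distance_transform_edt(gm_core, sampling=maps.grid.voxel_size)
    coords = [np.arange(d) for d in maps.grid.dims]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    rois: dict[str, np.ndarray] = {}
    work = dist.copy()
    for i in range(n_rois):
        c = np.unravel_index(np.argmax(work), work.shape)
        if work[c] <= 0:
            break
        d2 = (
            ((xx - c[0]) * maps.grid.voxel_size[0]) ** 2
            + ((yy - c[1]) * maps.grid.voxel_size[1]) ** 2
            + ((zz - c[2]) * maps.grid.voxel_size[2]) ** 2
        )
        rois[f"roi-{i + 1:02d}"] = (d2 <= radius_mm**2) & gm_core
        work[d2 <= (4.0 * radius_mm) ** 2] = 0.0  # keep picks apart
    if not rois:
        raise ValueError("could not place any GM ROI")
    return rois


def _slab(grid: VoxelGrid, n_slices: int) -> slice:
    n = min(max(int(n_slices), 16), grid.dims[2])
    z0 = (grid.dims[2] - n) // 2
    return slice(z0, z0 + n)


def _slab_maps(maps: TissueProbabilityMaps, zsl: slice) -> TissueProbabilityMaps:
    dims = maps.grid.dims
    sub_grid = VoxelGrid(
        (dims[0], dims[1], zsl.stop - zsl.start), maps.grid.voxel_size, maps.grid.origin
    )
    return TissueProbabilityMaps(
        sub_grid, maps.p_gm[:, :, zsl], maps.p_wm[:, :, zsl], maps.p_csf[:, :, zsl]
    )


def _subset_fit(fit, mask_flat: np.ndarray):
    """Restrict a RangeADCFit to a flat voxel subset (for the per-voxel NLS)."""
    from .diffusion import RangeADCFit

    return RangeADCFit(
        fit.window,
        fit.adc_map.reshape(-1)[mask_flat],
        fit.s0_map.reshape(-1)[mask_flat],
        fit.r2_map.reshape(-1)[mask_flat],
        fit.n_b_used.reshape(-1)[mask_flat],
        fit.valid_mask.reshape(-1)[mask_flat],
        fit.b_values,
    )


def run_pipeline(cfg: RunConfig, out_dir, dwi_slab_slices: int = 16) -> dict:
    """Run the full paired-cohort analysis; returns the summary dict.

    Writes volumes.csv, t2star.csv, adc_rois.csv, NIfTI stat maps, the
    configuration (YAML) and summary.json into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    logging.basicConfig(level=logging.INFO, format="%(name)s %(levelname)s %(message)s")
    logger.info("run config hash %s -> %s", chash, out)
    save_config(cfg, out / "config.yaml")

    grid = VoxelGrid(cfg.grid_dims, cfg.voxel_size_mm)
    base_truth = CompartmentTruth.default(
        csf_volume_mm3=cfg.csf_volume_mm3,
        parenchyma_volume_mm3=cfg.parenchyma_volume_mm3,
        parenchyma_t2star_ms=cfg.parenchyma_t2star_ms,
    )
    effect = EffectSpec(
        csf_scale=cfg.effect_csf_scale,
        focal_sites=tuple(
            FocalSite(tuple(c), r, m) for c, r, m in cfg.effect_focal_sites
        ),
        t2star_shift_ms=cfg.effect_t2star_shift_ms,
    )
    mge_protocol = AcquisitionProtocol.mge_default()
    dwi_protocol = DiffusionProtocol.default()
    bio.write_diffusion_protocol(
        dwi_protocol, out / "protocol.bval", out / "protocol.bvec", out / "protocol.yaml"
    )
    bio.write_acquisition_protocol(mge_protocol, out / "mge_protocol.yaml")

    stage = "simulate-cohort"
    try:
        cohort = simulate_cohort(
            cfg.n_subjects,
            grid,
            base_truth,
            effect,
            seed=cfg.seed,
            csf_volume_cv=cfg.csf_volume_cv,
            parenchyma_volume_cv=cfg.parenchyma_volume_cv,
            t2star_sd_ms=cfg.t2star_sd_ms,
        )
        # common-space template anatomy defines ROIs and the analysis mask
        template = build_anatomy(grid, base_truth, seed=cfg.seed)
        zsl = _slab(grid, dwi_slab_slices)
        slab_region = np.zeros(grid.dims, dtype=bool)
        slab_region[:, :, zsl] = True
        rois = default_roi_masks(template, cfg.n_rois, cfg.roi_radius_mm, within=slab_region)
        tiv_prob = smooth_map(
            template.p_gm + template.p_wm + template.p_csf, grid, cfg.smoothing_fwhm_mm
        )
        analysis_mask = tiv_prob > 0.5

        vol_rows, t2_rows, roi_frames = [], [], []
        csf_stacks = {c: [] for c in ("A", "B")}
        t2_stacks = {c: [] for c in ("A", "B")}
        for sub in cohort:
            for cond in ("A", "B"):
                stage = f"{sub.subject_id}/{cond}"
                maps, truth = sub.maps[cond], sub.truth[cond]
                cseed = _stage_seed(sub.seed, {"A": 0, "B": 1}[cond])

                # morphometry
                pdw, _ = simulate_pdw(
                    maps, truth, cfg.bias_amplitude, cfg.pdw_noise_sd, seed=cseed + 1
                )
                priors = TissueProbabilityMaps(
                    grid,
                    smooth_map(maps.p_gm, grid, cfg.smoothing_fwhm_mm),
                    smooth_map(maps.p_wm, grid, cfg.smoothing_fwhm_mm),
                    smooth_map(maps.p_csf, grid, cfg.smoothing_fwhm_mm),
                )
                corrected, _ = correct_bias_with_priors(
                    pdw, grid, priors, cfg.bias_correction_fwhm_mm
                )
                seg = segment(corrected, priors)
                vols = compartment_volumes(seg)
                vol_rows.append(
                    {
                        "subject": sub.subject_id,
                        "condition": cond,
                        "csf_mm3": vols.csf,
                        "gm_mm3": vols.gm,
                        "wm_mm3": vols.wm,
                        "parenchyma_mm3": vols.parenchyma,
                        "tiv_mm3": vols.tiv,
                    }
                )
                csf_stacks[cond].append(
                    smooth_map(seg.posteriors["csf"], grid, cfg.smoothing_fwhm_mm)
                )

                # relaxometry
                mge = simulate_mge(maps, truth, mge_protocol, cfg.mge_noise_sd, seed=cseed + 2)
                t2fit = fit_t2star(mge, mge_protocol)
                t2_rows.append(
                    {
                        "subject": sub.subject_id,
                        "condition": cond,
                        "parenchyma_t2star_ms": compartment_t2star_mean(
                            t2fit, maps, ("gm", "wm")
                        ),
                        "csf_t2star_ms": compartment_t2star_mean(t2fit, maps, ("csf",)),
                    }
                )
                t2_map = np.where(t2fit.valid_mask, t2fit.t2star_map, 0.0)
                t2_stacks[cond].append(smooth_map(t2_map, grid, cfg.smoothing_fwhm_mm))

                # diffusion (central slab)
                smaps = _slab_maps(maps, zsl)
                dwi = simulate_dwi(
                    smaps, truth, dwi_protocol, cfg.noise_model, cfg.dwi_noise_sd, seed=cseed + 3
                )
                combined = combine_directions(np.clip(dwi, 0.0, None), dwi_protocol)
                fits = {w: fit_adc_range(combined, dwi_protocol, w) for w in ("low", "mid", "high")}
                roi_union = np.zeros(smaps.grid.dims, dtype=bool)
                slab_rois = {k: v[:, :, zsl] for k, v in rois.items()}
                for r in slab_rois.values():
                    roi_union |= r
                flat = roi_union.reshape(-1)
                if cfg.kurtosis_fit_scope == "all":
                    kfit = fit_ivim_kurtosis(combined, dwi_protocol, fits["mid"])
                    k_map = kfit.k_map
                    k_valid = kfit.valid_mask
                else:
                    sub_series = combined.reshape(-1, dwi_protocol.n_b)[flat]
                    kfit = fit_ivim_kurtosis(
                        sub_series, dwi_protocol, _subset_fit(fits["mid"], flat)
                    )
                    k_map = np.full(smaps.grid.dims, np.nan).reshape(-1)
                    k_map[flat] = kfit.k_map
                    k_map = k_map.reshape(smaps.grid.dims)
                    k_valid = np.zeros(smaps.grid.dims, dtype=bool).reshape(-1)
                    k_valid[flat] = kfit.valid_mask
                    k_valid = k_valid.reshape(smaps.grid.dims)

                metric_maps = {
                    f"adc_{w}_um2_s": fits[w].adc_map * MM2S_TO_UM2S for w in fits
                }
                metric_maps["kurtosis"] = k_map
                valid_masks = {f"adc_{w}_um2_s": fits[w].valid_mask for w in fits}
                valid_masks["kurtosis"] = k_valid
                roi_frames.append(
                    roi_extract(
                        metric_maps,
                        slab_rois,
                        subject=sub.subject_id,
                        condition=cond,
                        valid_masks=valid_masks,
                        units={**{f"adc_{w}_um2_s": "um^2/s" for w in fits}, "kurtosis": ""},
                    )
                )
            logger.info("subject %s done (seed %d)", sub.subject_id, sub.seed)

        stage = "group-statistics"
        volumes = pd.DataFrame(vol_rows)
        t2star = pd.DataFrame(t2_rows)
        adc_rois = pd.concat(roi_frames, ignore_index=True)
        for df, name in ((volumes, "volumes.csv"), (t2star, "t2star.csv"), (adc_rois, "adc_rois.csv")):
            df.insert(0, "config_hash", chash)
            df.to_csv(out / name, index=False)

        summaries = {}
        va = volumes[volumes.condition == "A"]
        vb = volumes[volumes.condition == "B"]
        for metric in ("csf_mm3", "parenchyma_mm3", "tiv_mm3"):
            summaries[metric] = paired_total_test(va, vb, metric).__dict__
        ta = t2star[t2star.condition == "A"]
        tb = t2star[t2star.condition == "B"]
        summaries["parenchyma_t2star_ms"] = paired_total_test(
            ta, tb, "parenchyma_t2star_ms"
        ).__dict__

        stat_outputs = {}
        for name, stacks in (("csf_prob", csf_stacks), ("t2star", t2_stacks)):
            stat = paired_ttest_map(
                np.stack(stacks["A"]), np.stack(stacks["B"]), analysis_mask
            )
            stat = fdr_correct(stat, q_level=cfg.q_level)
            for layer, arr in (
                ("t", stat.t_map),
                ("p", stat.p_map),
                ("q", stat.q_map),
                ("sig", stat.significance_mask.astype(np.float64)),
            ):
                bio.write_volume(arr, grid, out / f"stat_{name}_{layer}.nii.gz")
            stat_outputs[name] = {
                "n_significant": int(stat.significance_mask.sum()),
                "n_mask": int(analysis_mask.sum()),
            }

        summary = {
            "config_hash": chash,
            "n_subjects": cfg.n_subjects,
            "seed": cfg.seed,
            "paired_tests": summaries,
            "voxelwise": stat_outputs,
            "units": {"volumes": "mm^3", "t2star": "ms", "adc": "um^2/s"},
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
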