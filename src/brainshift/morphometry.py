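"""Tissue segmentation and compartment volumetry.

The proton-density-weighted volume is bias-corrected (division by a heavily
smoothed log-intensity trend), segmented into GM/WM/CSF/background posteriors
by an expectation-maximization Gaussian-mixture fit with spatial priors, and
summarized as probabilistic compartment volumes (posterior mass times voxel
volume — no thresholding, which keeps partial-volume voxels unbiased).
Maps destined for voxel-wise statistics are smoothed with a small Gaussian
kernel (0.6 mm FWHM by default, reflective boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import FWHM_TO_SIGMA, TissueProbabilityMaps, VoxelGrid

__all__ = [
    "SegmentationResult",
    "CompartmentVolumes",
    "correct_bias",
    "correct_bias_with_priors",
    "segment",
    "compartment_volumes",
    "smooth_map",
]

CLASSES = ("gm", "wm", "csf", "background")


@dataclass
class SegmentationResult:
    """Posterior tissue maps with the mixture parameters that produced them."""

    posteriors: dict[str, np.ndarray]  # class -> posterior map, sums to 1 per voxel
    class_means: dict[str, float]
    class_variances: dict[str, float]
    iterations: int
    log_likelihood: list[float]
    converged: bool
    grid: VoxelGrid


@dataclass(frozen=True)
class CompartmentVolumes:
    """Compartment volumes in mm^3; parenchyma = GM+WM, TIV = parenchyma+CSF."""

    csf: float
    gm: float
    wm: float

    @property
    def parenchyma(self) -> float:
        return self.gm + self.wm

    @property
    def tiv(self) -> float:
        return self.csf + self.parenchyma


def _head_mask(volume: np.ndarray) -> np.ndarray:
    """Crude head mask: voxels above 20% of the robust maximum (both raw and
    smoothed, so neither background noise nor salt-and-pepper holes enter)."""
    sm = ndimage.gaussian_filter(volume, 2.0, mode="reflect")
    thr = 0.2 * np.percentile(sm, 99.9)
    return (sm > thr) & (volume > thr)


def correct_bias(
    pdw_volume: np.ndarray,
    grid: VoxelGrid,
    smoothing_fwhm_mm: float = 8.0,
    mask: np.ndarray | None = None,
    n_iter: int = 3,
    reference: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and remove a smooth multiplicative intensity field.

    The field is the heavily smoothed log-intensity trend inside the head mask
    (mask-normalized convolution so background does not bleed in), refined
    over ``n_iter`` passes — smoothing attenuates the trend it estimates, and
    re-estimating the residual trend of the corrected image recovers the
    attenuated part geometrically.

    ``reference`` is an optional predicted clean-intensity image (for example
    tissue priors mixed with class means, see :func:`correct_bias_with_priors`);
    when given, the trend is estimated on log(volume / reference), which stops
    genuine anatomy structure from leaking into the field.  The field is
    exponentiated and normalized to mean 1 inside the mask.  Returns
    ``(corrected_volume, estimated_field)``.
    """
    vol = np.asarray(pdw_volume, dtype=float)
    if mask is None:
        mask = _head_mask(vol)
    if not mask.any():
        raise ValueError("empty head mask")
    if (vol[mask] <= 0).any():
        raise ValueError("bias correction requires strictly positive voxels inside the mask")
    target = vol
    if reference is not None:
        reference = np.asarray(reference, dtype=float)
        if (reference[mask] <= 0).any():
            raise ValueError("reference image must be strictly positive inside the mask")
        target = vol / reference
    sigma = [smoothing_fwhm_mm / FWHM_TO_SIGMA / v for v in grid.voxel_size]
    den = ndimage.gaussian_filter(mask.astype(float), sigma, mode="reflect")
    log_field = np.zeros_like(vol)
    logv = np.zeros_like(vol)
    for _ in range(max(int(n_iter), 1)):
        logv[mask] = np.log(target[mask]) - log_field[mask]
        logv[~mask] = 0.0
        trend = ndimage.gaussian_filter(logv * mask, sigma, mode="reflect")
        trend /= np.maximum(den, 1e-12)
        trend -= trend[mask].mean()
        log_field += trend
    field = np.exp(log_field)
    field /= field[mask].mean()
    return vol / field, field


def correct_bias_with_priors(
    pdw_volume: np.ndarray,
    grid: VoxelGrid,
    priors: TissueProbabilityMaps,
    smoothing_fwhm_mm: float = 8.0,
    n_iter: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Model-based bias correction: the expected clean image (spatial priors
    mixed with prior-confident class means) is divided out before trend
    estimation, so compartment contrast does not masquerade as field.
    """
    vol = np.asarray(pdw_volume, dtype=float)
    prior_maps = {
        "gm": priors.p_gm,
        "wm": priors.p_wm,
        "csf": priors.p_csf,
    }
    reference = np.full_like(vol, np.nan)
    mask = np.zeros(vol.shape, dtype=bool)
    for c, prior in prior_maps.items():
        # deep voxels only: at compartment boundaries the priors and the true
        # edge disagree by a voxel or two, and those log-ratio outliers would
        # swamp the smooth trend
        deep = prior > 0.8
        if deep.sum() < 10:
            continue
        mu = float((prior[deep] * vol[deep]).sum() / prior[deep].sum())
        if mu <= 0:
            continue
        reference[deep] = mu
        mask |= deep
    if not mask.any():
        raise ValueError("priors leave no deep voxels to estimate the field from")
    reference[~mask] = 1.0  # unused outside the estimation mask
    return correct_bias(
        vol, grid, smoothing_fwhm_mm, mask=mask, n_iter=n_iter, reference=reference
    )


def _gaussian_pdf(y: np.ndarray, mean: float, var: float) -> np.ndarray:
    return np.exp(-0.5 * (y - mean) ** 2 / var) / np.sqrt(2.0 * np.pi * var)


def segment(
    pdw_volume: np.ndarray,
    priors: TissueProbabilityMaps,
    max_iter: int = 50,
    tol: float = 1e-7,
    var_floor_frac: float = 1e-6,
    update_variances: bool = False,
    confident_prior: float = 0.8,
    pve: bool = True,
    pve_local_fwhm_mm: float = 3.0,
) -> SegmentationResult:
    """Prior-weighted Gaussian-mixture EM segmentation into GM/WM/CSF/background.

    Responsibilities are prior_c(x) * N(y | mu_c, var_c) normalized per voxel;
    the M-step updates class means (and, optionally, variances) from the soft
    counts.  Class statistics are initialized from high-confidence voxels
    (prior above ``confident_prior``), and variances stay fixed at that
    initialization by default: thin compartments like CSF border two very
    different intensities (parenchyma and background), and letting their
    variance free makes the class absorb every partial-volume voxel in the
    image.  Updating only the means is still coordinate ascent, so the
    log-likelihood trace remains non-decreasing.

    Iterates until the relative log-likelihood change drops below ``tol`` or
    ``max_iter`` is reached (non-convergence is flagged, not raised).  The
    spatial priors are supplied in-space (all synthetic volumes share one
    common space, so no registration step exists).
    """
    y = np.asarray(pdw_volume, dtype=float)
    if y.shape != priors.grid.dims:
        raise ValueError(f"volume shape {y.shape} does not match priors grid {priors.grid.dims}")
    prior_maps = {
        "gm": priors.p_gm,
        "wm": priors.p_wm,
        "csf": priors.p_csf,
        "background": priors.p_background,
    }
    scale = float(np.percentile(np.abs(y), 99.9)) or 1.0
    var_floor = var_floor_frac * scale**2

    means: dict[str, float] = {}
    variances: dict[str, float] = {}
    for c in CLASSES:
        w = np.where(prior_maps[c] > confident_prior, prior_maps[c], 0.0)
        if w.sum() <= 0:
            w = prior_maps[c]
        wsum = w.sum()
        if wsum <= 0:
            means[c] = 0.0
            variances[c] = var_floor
            continue
        means[c] = float((w * y).sum() / wsum)
        variances[c] = max(float((w * (y - means[c]) ** 2).sum() / wsum), var_floor)

    # degenerate (near-flat) priors give every class the same starting mean;
    # break the symmetry with the PDW intensity ordering air < WM < GM < CSF,
    # taking tissue percentiles over foreground voxels only
    spread = max(means.values()) - min(means.values())
    if spread < 1e-3 * scale:
        fg = y > 0.2 * scale
        if fg.any() and (~fg).any():
            means["background"] = float(np.median(y[~fg]))
            pct = {"wm": 25.0, "gm": 60.0, "csf": 95.0}
            for c, p in pct.items():
                means[c] = float(np.percentile(y[fg], p))
            for c in CLASSES:
                variances[c] = max((0.05 * scale) ** 2, var_floor)
            update_variances = True

    ll_trace: list[float] = []
    posteriors: dict[str, np.ndarray] = {}
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dens = {c: prior_maps[c] * _gaussian_pdf(y, means[c], variances[c]) for c in CLASSES}
        total = sum(dens.values())
        total = np.maximum(total, 1e-300)
        posteriors = {c: dens[c] / total for c in CLASSES}
        ll = float(np.log(total).sum())
        ll_trace.append(ll)
        for c in CLASSES:
            r = posteriors[c]
            rsum = r.sum()
            if rsum <= 1e-12:
                continue
            means[c] = float((r * y).sum() / rsum)
            if update_variances:
                variances[c] = max(float((r * (y - means[c]) ** 2).sum() / rsum), var_floor)
        if len(ll_trace) >= 2:
            prev = ll_trace[-2]
            if abs(ll - prev) <= tol * abs(prev):
                converged = True
                break
    # recompute class means from prior-deep voxels (geometry defines purity;
    # intensity-confident voxels still include the partial-volume shell, which
    # would drag each mean toward its boundary and stretch the mixel fractions)
    for c in CLASSES:
        sel = prior_maps[c] > 0.95
        if sel.sum() < 10:
            sel = posteriors[c] > 0.9
        if sel.sum() >= 10:
            means[c] = float(y[sel].mean())
    if pve:
        local_means = _local_class_means(
            y, prior_maps, means, priors.grid, pve_local_fwhm_mm
        )
        posteriors = _pve_refine(y, prior_maps, local_means, posteriors)
    return SegmentationResult(
        posteriors, means, variances, it, ll_trace, converged, priors.grid
    )


def _local_class_means(
    y: np.ndarray,
    prior_maps: dict[str, np.ndarray],
    global_means: dict[str, float],
    grid: VoxelGrid,
    fwhm_mm: float,
) -> dict[str, np.ndarray]:
    """Per-voxel class intensity references from normalized convolution over
    prior-deep voxels.

    Residual intensity inhomogeneity (imperfect bias correction, field
    structure the corrector cannot see) shifts each class's effective
    intensity from region to region; mixing fractions computed against global
    means then misread entire pockets.  Local references — each class's deep
    voxels smoothed over a ``fwhm_mm`` neighbourhood — track those shifts.
    Voxels too far from any deep voxel of a class fall back to its global
    mean.
    """
    sigma = [fwhm_mm / FWHM_TO_SIGMA / v for v in grid.voxel_size]
    out = {}
    for c, prior in prior_maps.items():
        # thin structures (cisterns) never reach very high smoothed priors, so
        # the reference pool admits moderately deep voxels, prior-weighted
        deep = np.where(prior > 0.75, prior, 0.0)
        if (deep > 0).sum() < 10:
            out[c] = np.full(y.shape, global_means[c])
            continue
        num = ndimage.gaussian_filter(y * deep, sigma, mode="reflect")
        den = ndimage.gaussian_filter(deep, sigma, mode="reflect")
        local = np.where(den > 1e-3, num / np.maximum(den, 1e-12), global_means[c])
        out[c] = local
    return out


def _pve_refine(
    y: np.ndarray,
    prior_maps: dict[str, np.ndarray],
    means: dict[str, float],
    posteriors: dict[str, np.ndarray],
    pure_prior: float = 0.95,
    min_second_prior: float = 0.02,
) -> dict[str, np.ndarray]:
    """Partial-volume (mixel) refinement of EM posteriors.

    A voxel whose spatial priors name two plausible classes is modelled as a
    two-class mixture; its mixing fraction is read off the intensity axis,
    alpha = (y - mu2) / (mu1 - mu2), clipped to [0, 1].  This splits boundary
    voxels in proportion to their true tissue content (unbiased under additive
    noise), where a hard Gaussian classification would flip the whole voxel to
    one side.  Voxels with a dominant prior (> ``pure_prior``) or
    uninformative priors keep their EM posterior.
    """
    prior_stack = np.stack([prior_maps[c] for c in CLASSES])
    order = np.argsort(prior_stack, axis=0)
    top1, top2 = order[-1], order[-2]
    p1 = np.take_along_axis(prior_stack, top1[None], axis=0)[0]
    p2 = np.take_along_axis(prior_stack, top2[None], axis=0)[0]
    means_stack = np.stack([np.broadcast_to(means[c], y.shape) for c in CLASSES])
    mu1 = np.take_along_axis(means_stack, top1[None], axis=0)[0]
    mu2 = np.take_along_axis(means_stack, top2[None], axis=0)[0]
    denom = mu1 - mu2
    safe = np.where(np.abs(denom) > 1e-9, denom, np.inf)
    alpha = np.clip((y - mu2) / safe, 0.0, 1.0)
    # identical class means: fall back to the prior ratio
    alpha = np.where(np.abs(denom) > 1e-9, alpha, p1 / np.maximum(p1 + p2, 1e-12))
    mix = (p1 <= pure_prior) & (p2 >= min_second_prior)
    out = {}
    for ci, c in enumerate(CLASSES):
        ref = alpha * (top1 == ci) + (1.0 - alpha) * (top2 == ci)
        out[c] = np.where(mix, ref, posteriors[c])
    return out


def compartment_volumes(seg, grid: VoxelGrid | None = None) -> CompartmentVolumes:
    """Probabilistic compartment volumes: posterior mass times voxel volume.

    Accepts either a SegmentationResult or TissueProbabilityMaps.
    """
    if isinstance(seg, SegmentationResult):
        grid = grid or seg.grid
        maps = {c: seg.posteriors[c] for c in ("gm", "wm", "csf")}
    elif isinstance(seg, TissueProbabilityMaps):
        grid = grid or seg.grid
        maps = {"gm": seg.p_gm, "wm": seg.p_wm, "csf": seg.p_csf}
    else:
        raise TypeError(f"cannot compute volumes from {type(seg).__name__}")
    for name, arr in maps.items():
        if arr.shape != grid.dims:
            raise ValueError(f"{name} posterior shape {arr.shape} does not match grid {grid.dims}")
    vv = grid.voxel_volume
    return CompartmentVolumes(
        csf=float(maps["csf"].sum() * vv),
        gm=float(maps["gm"].sum() * vv),
        wm=float(maps["wm"].sum() * vv),
    )


def smooth_map(arr: np.ndarray, grid: VoxelGrid, fwhm_mm: float = 0.6) -> np.ndarray:
    """Gaussian smoothing with a kernel specified by FWHM in mm.

    sigma per axis = fwhm / 2.3548 / voxel_size; reflective boundary handling
    (conserves the map's total mass); fwhm = 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return np.asarray(arr, dtype=float).copy()
    sigma = [fwhm_mm / FWHM_TO_SIGMA / v for v in grid.voxel_size]
    return ndimage.gaussian_filter(np.asarray(arr, dtype=float), sigma, mode="reflect")
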