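"""Digital brain phantom: schematic anatomy, acquisition protocols and MR forward models.

The phantom emulates a small-animal brain as nested ellipsoidal compartments
(a ventricle-like CSF core, WM interior, GM rind, and an outer CSF shell)
defined as per-voxel membership probabilities on a regular grid.  From the
probability maps and per-compartment tissue properties it simulates the three
acquisitions the analysis pipeline consumes:

* a proton-density-weighted (PDW) volume with an optional smooth multiplicative
  bias field (B1-type inhomogeneity),
* a multi-gradient-echo (MGE) series with mono-exponential T2* decay per
  compartment,
* a diffusion-weighted (DWI) series following the biexponential
  IVIM + kurtosis signal model, acquired along three orthogonal directions,

plus a mono-exponential DMSO-like phantom signal table used as a fitting
control.  Ground truth (compartment volumes, T2*, diffusion parameters) is
carried alongside so every downstream estimator can be scored against it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "TissueProbabilityMaps",
    "IVIMKurtosisParams",
    "CompartmentProps",
    "CompartmentTruth",
    "AcquisitionProtocol",
    "DiffusionProtocol",
    "FocalSite",
    "EffectSpec",
    "build_anatomy",
    "apply_condition_effect",
    "simulate_pdw",
    "simulate_mge",
    "simulate_dwi",
    "simulate_dmso",
    "ivim_kurtosis_signal",
    "Subject",
    "simulate_cohort",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...

COMPARTMENTS = ("gm", "wm", "csf")


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D voxel grid with isotropic-or-not spacing in mm.

    The affine maps 0-based voxel indices to world coordinates in mm;
    only diagonal (axis-aligned) affines are produced here, which is all a
    common-space synthetic study needs.
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (0.23, 0.23, 0.23)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 16 for d in self.dims):
            raise ValueError(f"grid dims must be a triple with every dim >= 16, got {self.dims}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    @property
    def volume(self) -> float:
        """Total grid volume in mm^3."""
        return self.voxel_volume * float(np.prod(self.dims))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    @classmethod
    def from_affine(cls, dims, affine) -> "VoxelGrid":
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        voxel_size = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
        return cls(tuple(int(d) for d in dims), voxel_size, tuple(affine[:3, 3]))


@dataclass
class TissueProbabilityMaps:
    """Per-voxel GM/WM/CSF membership probabilities on a grid.

    Probabilities may sum to less than 1; the remainder is background.
    """

    grid: VoxelGrid
    p_gm: np.ndarray
    p_wm: np.ndarray
    p_csf: np.ndarray

    def __post_init__(self) -> None:
        for name in ("p_gm", "p_wm", "p_csf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.dims:
                raise ValueError(f"{name} shape {arr.shape} does not match grid {self.grid.dims}")
            if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
                raise ValueError(f"{name} has probabilities outside [0, 1]")
            setattr(self, name, np.clip(arr, 0.0, 1.0))
        total = self.p_gm + self.p_wm + self.p_csf
        if total.max() > 1 + 1e-6:
            raise ValueError("per-voxel GM+WM+CSF probability exceeds 1")
        excess = total > 1.0
        if excess.any():  # shave float crumbs so downstream background stays >= 0
            scale = np.where(excess, 1.0 / np.maximum(total, 1.0), 1.0)
            self.p_gm = self.p_gm * scale
            self.p_wm = self.p_wm * scale
            self.p_csf = self.p_csf * scale
        if not (self.p_csf > 0.5).any():
            raise ValueError("anatomy must contain at least one voxel with p_csf > 0.5")

    @property
    def p_background(self) -> np.ndarray:
        return np.clip(1.0 - self.p_gm - self.p_wm - self.p_csf, 0.0, 1.0)

    def prob(self, compartment: str) -> np.ndarray:
        return {"gm": self.p_gm, "wm": self.p_wm, "csf": self.p_csf}[compartment]

    def volume(self, compartment: str) -> float:
        """Probabilistic volume of a compartment in mm^3 (no thresholding)."""
        return float(self.prob(compartment).sum() * self.grid.voxel_volume)

    @property
    def tiv(self) -> float:
        """Total intracranial volume GM+WM+CSF in mm^3."""
        return sum(self.volume(c) for c in COMPARTMENTS)

    def copy(self) -> "TissueProbabilityMaps":
        return TissueProbabilityMaps(
            self.grid, self.p_gm.copy(), self.p_wm.copy(), self.p_csf.copy()
        )


# ---------------------------------------------------------------------------
# tissue truth


@dataclass(frozen=True)
class IVIMKurtosisParams:
    """Parameters of the biexponential IVIM + kurtosis diffusion signal model.

    S(b)/S0 = f_ivim * exp(-b D*) + (1 - f_ivim) * exp(-b ADC0 + (b ADC0)^2 K / 6)

    Units: S0 arbitrary, D_star and adc0 in mm^2/s (b in s/mm^2), f_ivim and K
    unitless.
    """

    s0: float
    f_ivim: float
    d_star: float
    adc0: float
    k: float

    def __post_init__(self) -> None:
        if not self.s0 > 0:
            raise ValueError("S0 must be positive")
        if not 0 <= self.f_ivim < 1:
            raise ValueError("f_ivim must lie in [0, 1)")
        if not self.adc0 > 0:
            raise ValueError("ADC0 must be positive")
        if not self.d_star > self.adc0:
            raise ValueError("the pseudo-diffusion coefficient D* must exceed ADC0")
        if self.k < 0:
            raise ValueError("kurtosis K must be non-negative")


def ivim_kurtosis_signal(b, params: IVIMKurtosisParams) -> np.ndarray:
    """Evaluate the IVIM + kurtosis model at b-values ``b`` (s/mm^2)."""
    b = np.asarray(b, dtype=float)
    fast = params.f_ivim * np.exp(-b * params.d_star)
    badc = b * params.adc0
    slow = (1.0 - params.f_ivim) * np.exp(-badc + badc**2 * params.k / 6.0)
    return params.s0 * (fast + slow)


@dataclass(frozen=True)
class CompartmentProps:
    """MR properties of one tissue compartment."""

    proton_density: float  # a.u.
    t2star_ms: float
    diffusion: IVIMKurtosisParams

    def __post_init__(self) -> None:
        if self.proton_density < 0:
            raise ValueError("proton density must be >= 0")
        if not self.t2star_ms > 0:
            raise ValueError("T2* must be positive")


@dataclass(frozen=True)
class CompartmentTruth:
    """Ground-truth tissue properties and target compartment volumes (mm^3)."""

    gm: CompartmentProps
    wm: CompartmentProps
    csf: CompartmentProps
    csf_volume_mm3: float
    gm_volume_mm3: float
    wm_volume_mm3: float

    def __post_init__(self) -> None:
        for name in ("csf_volume_mm3", "gm_volume_mm3", "wm_volume_mm3"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def props(self, compartment: str) -> CompartmentProps:
        return {"gm": self.gm, "wm": self.wm, "csf": self.csf}[compartment]

    @property
    def parenchyma_volume_mm3(self) -> float:
        return self.gm_volume_mm3 + self.wm_volume_mm3

    @property
    def tiv_mm3(self) -> float:
        return self.parenchyma_volume_mm3 + self.csf_volume_mm3

    @classmethod
    def default(
        cls,
        csf_volume_mm3: float = 190.0,
        parenchyma_volume_mm3: float = 1841.0,
        gm_fraction: float = 0.62,
        parenchyma_t2star_ms: float = 28.8,
        csf_t2star_ms: float = 60.0,
    ) -> "CompartmentTruth":
        """Rat-brain-scale defaults.

        Compartment volumes default to the deeply-sedated group means
        (CSF 190 mm^3, parenchyma 1841 mm^3); parenchymal T2* defaults to the
        corresponding 28.8 ms group mean.  GM/WM split of the parenchyma and
        the diffusion parameters are representative cortical/white-matter
        values at high field.
        """
        gm_v = parenchyma_volume_mm3 * gm_fraction
        wm_v = parenchyma_volume_mm3 - gm_v
        gm = CompartmentProps(
            proton_density=0.85,
            t2star_ms=parenchyma_t2star_ms,
            diffusion=IVIMKurtosisParams(
                s0=0.85, f_ivim=0.10, d_star=1.0e-2, adc0=7.0e-4, k=0.70
            ),
        )
        wm = CompartmentProps(
            proton_density=0.72,
            t2star_ms=parenchyma_t2star_ms,
            diffusion=IVIMKurtosisParams(
                s0=0.72, f_ivim=0.05, d_star=1.0e-2, adc0=6.0e-4, k=0.90
            ),
        )
        csf = CompartmentProps(
            proton_density=1.0,
            t2star_ms=csf_t2star_ms,
            diffusion=IVIMKurtosisParams(
                s0=1.0, f_ivim=0.0, d_star=1.0e-2, adc0=3.0e-3, k=0.0
            ),
        )
        return cls(gm, wm, csf, csf_volume_mm3, gm_v, wm_v)


# ---------------------------------------------------------------------------
# protocols


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Multi-echo gradient-echo timing: echo times and TR in ms."""

    echo_times_ms: tuple[float, ...]
    repetition_time_ms: float = 60.0

    def __post_init__(self) -> None:
        tes = tuple(float(t) for t in self.echo_times_ms)
        if any(t <= 0 for t in tes):
            raise ValueError("echo times must be positive")
        if any(b <= a for a, b in zip(tes, tes[1:])):
            raise ValueError("echo times must be strictly increasing")
        object.__setattr__(self, "echo_times_ms", tes)

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times_ms)

    @classmethod
    def mge_default(cls) -> "AcquisitionProtocol":
        """16 evenly spaced echoes from 2 to 32 ms (2 ms spacing)."""
        return cls(tuple(np.linspace(2.0, 32.0, 16)), repetition_time_ms=60.0)


#: the three named b-value fitting windows in s/mm^2
DEFAULT_RANGE_WINDOWS: dict[str, tuple[float, float]] = {
    "low": (20.0, 205.0),
    "mid": (235.0, 1016.0),
    "high": (1117.0, 2518.0),
}


@dataclass(frozen=True)
class DiffusionProtocol:
    """DWI protocol: b-values, 3 orthogonal directions, named fitting windows."""

    b_values: tuple[float, ...]
    directions: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )
    range_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGE_WINDOWS)
    )

    def __post_init__(self) -> None:
        bv = tuple(float(b) for b in self.b_values)
        if any(b2 < b1 for b1, b2 in zip(bv, bv[1:])):
            raise ValueError("b-values must be sorted ascending")
        if bv and bv[0] < 20.0 - 1e-9:
            raise ValueError("minimum b-value is 20 s/mm^2 (spoiler-gradient floor)")
        object.__setattr__(self, "b_values", bv)
        dirs = np.asarray(self.directions, dtype=float)
        if dirs.shape[1] != 3:
            raise ValueError("directions must be 3-vectors")
        norms = np.linalg.norm(dirs, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("directions must be unit vectors")
        gram = dirs @ dirs.T
        if not np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-6):
            raise ValueError("directions must be pairwise orthogonal")
        object.__setattr__(self, "directions", tuple(tuple(d) for d in dirs))
        # each b-value may fall in at most one window
        for b in bv:
            hits = [w for w, (lo, hi) in self.range_windows.items() if lo <= b <= hi]
            if len(hits) > 1:
                raise ValueError(f"b={b} falls in more than one window: {hits}")

    @property
    def n_b(self) -> int:
        return len(self.b_values)

    @property
    def n_directions(self) -> int:
        return len(self.directions)

    def window_mask(self, window: str) -> np.ndarray:
        """Boolean mask over b_values for a named window."""
        if window not in self.range_windows:
            raise KeyError(f"unknown window {window!r}; have {sorted(self.range_windows)}")
        lo, hi = self.range_windows[window]
        b = np.asarray(self.b_values)
        return (b >= lo) & (b <= hi)

    @classmethod
    def default(cls) -> "DiffusionProtocol":
        """57 b-values spanning 20-2518 s/mm^2.

        The individual b-values are distributed uniformly within the three
        fitting windows (15 low / 21 mid / 21 high, endpoints included), which
        preserves the reference window boundaries and the total count.
        """
        low = np.linspace(*DEFAULT_RANGE_WINDOWS["low"], 15)
        mid = np.linspace(*DEFAULT_RANGE_WINDOWS["mid"], 21)
        high = np.linspace(*DEFAULT_RANGE_WINDOWS["high"], 21)
        return cls(tuple(np.concatenate([low, mid, high])))


# ---------------------------------------------------------------------------
# condition effects


@dataclass(frozen=True)
class FocalSite:
    """A focal tissue-swelling site: Gaussian bump of GM probability."""

    center_vox: tuple[int, int, int]
    radius_mm: float
    magnitude: float  # peak added GM probability, before per-voxel capping

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.magnitude <= 0:
            raise ValueError("focal site radius and magnitude must be positive")


@dataclass(frozen=True)
class EffectSpec:
    """Between-condition effect applied to one member of each subject pair.

    csf_scale multiplies the CSF compartment volume (mass exchanged with the
    parenchyma at the CSF boundary so total intracranial volume is conserved);
    focal sites add GM probability locally; t2star_shift_ms is added to every
    compartment's T2* in the affected condition.
    """

    csf_scale: float = 1.0
    focal_sites: tuple[FocalSite, ...] = ()
    t2star_shift_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.csf_scale <= 0:
            raise ValueError("csf_scale must be positive")
        object.__setattr__(self, "focal_sites", tuple(self.focal_sites))

    @classmethod
    def iso_like(cls) -> "EffectSpec":
        """Default paired effect: CSF contraction 190->180 mm^3 equivalent
        (scale 180/190) with the mass returned to parenchyma, and a global
        +1.8 ms T2* shift (the reference 30.6 vs 28.8 ms group difference)."""
        return cls(csf_scale=180.0 / 190.0, t2star_shift_ms=1.8)


def shift_t2star(truth: CompartmentTruth, shift_ms: float) -> CompartmentTruth:
    """Return a copy of ``truth`` with every compartment T2* shifted by ``shift_ms``."""
    def bump(props: CompartmentProps) -> CompartmentProps:
        return replace(props, t2star_ms=props.t2star_ms + shift_ms)

    return replace(truth, gm=bump(truth.gm), wm=bump(truth.wm), csf=bump(truth.csf))


# ---------------------------------------------------------------------------
# anatomy construction


def _ellipsoidal_radius(grid: VoxelGrid, rng: np.random.Generator) -> np.ndarray:
    """Scalar nesting field: jittered anisotropic ellipsoidal radius (mm)."""
    dims = grid.dims
    vox = grid.voxel_size
    extent = np.array([d * v for d, v in zip(dims, vox)])
    center = extent / 2.0 + rng.normal(scale=0.02 * extent, size=3)
    # axis scales: mildly oblate brain-like shape with per-subject jitter
    axis = np.array([1.0, 1.15, 0.85]) * (1.0 + rng.normal(scale=0.05, size=3))
    coords = [
        (np.arange(dims[i]) + 0.5) * vox[i] - center[i] for i in range(3)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    return np.sqrt((xx / axis[0]) ** 2 + (yy / axis[1]) ** 2 + (zz / axis[2]) ** 2)


def _fill_by_order(
    order: np.ndarray, capacity: np.ndarray, n_vox: float, out: np.ndarray
) -> None:
    """Assign ``n_vox`` voxels' worth of probability mass to ``out`` along the
    ordered candidate list, consuming per-voxel ``capacity`` (both flat arrays
    indexed by voxel).  The voxel straddling the boundary receives fractional
    membership, so the probability sum matches the request to float precision.
    """
    if n_vox <= 0:
        return
    avail = capacity[order]
    cum = np.cumsum(avail)
    if n_vox > cum[-1] + 1e-9:
        raise ValueError("requested volumes exceed the grid")
    k = int(np.searchsorted(cum, n_vox))
    take = np.zeros_like(avail)
    take[:k] = avail[:k]
    take[k] = n_vox - (cum[k - 1] if k > 0 else 0.0)
    flat = out.reshape(-1)
    flat[order[: k + 1]] += take[: k + 1]
    capacity[order[: k + 1]] -= take[: k + 1]


def build_anatomy(
    grid: VoxelGrid,
    truth: CompartmentTruth,
    seed: int,
    ventricle_fraction: float = 0.4,
    cistern_cos: float = -0.45,
    pv_smooth_mm: float = 0.23,
) -> TissueProbabilityMaps:
    """Build nested-ellipsoid tissue probability maps matching the target volumes.

    Voxels are ordered by a jittered ellipsoidal radius and filled inside-out:
    a ventricle-like CSF core (``ventricle_fraction`` of the CSF volume), the
    WM interior, the GM rind, and the remaining CSF as a basal cistern-like
    pocket: the first unassigned voxels outside the GM rind within a downward
    angular sector (polar cosine below ``cistern_cos``).  Concentrating the
    outer CSF in a sector keeps it several voxels thick — like the cisterns
    that hold most subarachnoid CSF — instead of an unresolvable sub-voxel
    film over the whole surface.  Boundary voxels get fractional membership so
    each compartment's probability sum times the voxel volume matches its
    requested volume to float precision (well within one voxel volume).  A
    light Gaussian blur (``pv_smooth_mm`` FWHM) adds partial-volume mixing
    without changing any compartment's total mass (reflective boundaries
    conserve the convolution sum exactly).

    Deterministic for a fixed seed.
    """
    for name in ("csf_volume_mm3", "gm_volume_mm3", "wm_volume_mm3"):
        if not getattr(truth, name) > 0:
            raise ValueError(f"infeasible volume: {name} must be positive")
    if truth.tiv_mm3 >= grid.volume:
        raise ValueError(
            "infeasible volumes: GM+WM+CSF "
            f"({truth.tiv_mm3:.1f} mm^3) exceeds grid volume ({grid.volume:.1f} mm^3)"
        )
    if not 0 <= ventricle_fraction < 1:
        raise ValueError("ventricle_fraction must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    radius = _ellipsoidal_radius(grid, rng)
    order = np.argsort(radius, axis=None, kind="stable")

    vv = grid.voxel_volume
    n_csf_core = truth.csf_volume_mm3 * ventricle_fraction / vv
    n_csf_shell = truth.csf_volume_mm3 * (1.0 - ventricle_fraction) / vv
    n_wm = truth.wm_volume_mm3 / vv
    n_gm = truth.gm_volume_mm3 / vv

    p_gm = np.zeros(grid.dims)
    p_wm = np.zeros(grid.dims)
    p_csf = np.zeros(grid.dims)
    capacity = np.ones(int(np.prod(grid.dims)))
    _fill_by_order(order, capacity, n_csf_core, p_csf)
    _fill_by_order(order, capacity, n_wm, p_wm)
    _fill_by_order(order, capacity, n_gm, p_gm)
    # cisternal CSF: prefer the downward sector, fall back to the full shell
    dims = grid.dims
    vox = grid.voxel_size
    zc = (np.arange(dims[2]) + 0.5) * vox[2] - dims[2] * vox[2] / 2.0
    cosz = (zc[None, None, :] / np.maximum(radius, 1e-9)).reshape(-1)
    in_sector = cosz[order] < cistern_cos
    sector_order = np.concatenate([order[in_sector], order[~in_sector]])
    _fill_by_order(sector_order, capacity, n_csf_shell, p_csf)

    if pv_smooth_mm > 0:
        sigma_vox = [pv_smooth_mm / FWHM_TO_SIGMA / v for v in grid.voxel_size]
        p_gm = ndimage.gaussian_filter(p_gm, sigma_vox, mode="reflect")
        p_wm = ndimage.gaussian_filter(p_wm, sigma_vox, mode="reflect")
        p_csf = ndimage.gaussian_filter(p_csf, sigma_vox, mode="reflect")

    return TissueProbabilityMaps(grid, p_gm, p_wm, p_csf)


# ---------------------------------------------------------------------------
# condition effects on maps


def _transfer_csf_mass(maps: TissueProbabilityMaps, delta_vox: float) -> None:
    """Exchange ``delta_vox`` voxels of probability mass between CSF and
    parenchyma at the CSF boundary, in place.  Positive delta grows CSF."""
    if abs(delta_vox) < 1e-12:
        return
    p_gm, p_wm, p_csf = maps.p_gm, maps.p_wm, maps.p_csf
    parenchyma = p_gm + p_wm
    if delta_vox > 0:
        # grow CSF into the nearest parenchymal mass
        dist = ndimage.distance_transform_edt(p_csf <= 0.5, sampling=maps.grid.voxel_size)
        donors = parenchyma > 1e-9
        if parenchyma[donors].sum() < delta_vox:
            raise ValueError("csf_scale requires more parenchymal mass than available")
        flat_idx = np.flatnonzero(donors.reshape(-1))
        order = flat_idx[np.argsort(dist.reshape(-1)[flat_idx], kind="stable")]
        avail = parenchyma.reshape(-1)[order]
        cum = np.cumsum(avail)
        k = int(np.searchsorted(cum, delta_vox))
        take = np.zeros_like(avail)
        take[:k] = avail[:k]
        take[k] = delta_vox - (cum[k - 1] if k > 0 else 0.0)
        frac = np.zeros(p_csf.size)
        frac[order] = take / avail  # fraction of each voxel's parenchyma converted
        frac = frac.reshape(p_csf.shape)
        moved_gm = p_gm * frac
        moved_wm = p_wm * frac
        p_gm -= moved_gm
        p_wm -= moved_wm
        p_csf += moved_gm + moved_wm
    else:
        # shrink CSF: hand boundary CSF mass back to parenchyma
        need = -delta_vox
        dist = ndimage.distance_transform_edt(parenchyma <= 0.5, sampling=maps.grid.voxel_size)
        donors = p_csf > 1e-9
        if p_csf[donors].sum() < need:
            raise ValueError("csf_scale removes more CSF mass than available")
        flat_idx = np.flatnonzero(donors.reshape(-1))
        order = flat_idx[np.argsort(dist.reshape(-1)[flat_idx], kind="stable")]
        avail = p_csf.reshape(-1)[order]
        cum = np.cumsum(avail)
        k = int(np.searchsorted(cum, need))
        take = np.zeros_like(avail)
        take[:k] = avail[:k]
        take[k] = need - (cum[k - 1] if k > 0 else 0.0)
        moved = np.zeros(p_csf.size)
        moved[order] = take
        moved = moved.reshape(p_csf.shape)
        # split the returned mass by the local GM:WM ratio (smoothed so pure-CSF
        # voxels inherit their neighbourhood's ratio)
        sm_gm = ndimage.gaussian_filter(p_gm, 2.0, mode="reflect")
        sm_wm = ndimage.gaussian_filter(p_wm, 2.0, mode="reflect")
        denom = sm_gm + sm_wm
        gm_frac = np.where(denom > 1e-12, sm_gm / np.maximum(denom, 1e-12), 1.0)
        p_csf -= moved
        p_gm += moved * gm_frac
        p_wm += moved * (1.0 - gm_frac)


def _apply_focal_site(maps: TissueProbabilityMaps, site: FocalSite) -> None:
    """Add a capped Gaussian GM bump at a focal site, recruiting probability
    mass from CSF first, then WM, then background (in place)."""
    grid = maps.grid
    for c, d in zip(site.center_vox, grid.dims):
        if not 0 <= c < d:
            raise ValueError(f"focal site center {site.center_vox} outside grid {grid.dims}")
    coords = [
        ((np.arange(grid.dims[i]) - site.center_vox[i]) * grid.voxel_size[i]) for i in range(3)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    d2 = xx**2 + yy**2 + zz**2
    sigma = site.radius_mm / 2.0
    bump = site.magnitude * np.exp(-d2 / (2.0 * sigma**2))
    bump[d2 > site.radius_mm**2] = 0.0
    gain = np.minimum(bump, 1.0 - maps.p_gm)  # cannot push any voxel past 1
    from_csf = np.minimum(gain, maps.p_csf)
    from_wm = np.minimum(gain - from_csf, maps.p_wm)
    maps.p_csf -= from_csf
    maps.p_wm -= from_wm
    maps.p_gm += gain  # remainder (gain - from_csf - from_wm) recruits background


def focal_site_gm_gain(maps: TissueProbabilityMaps, site: FocalSite) -> float:
    """GM volume (mm^3) a focal site would add to ``maps`` (capped bump integral)."""
    grid = maps.grid
    coords = [
        ((np.arange(grid.dims[i]) - site.center_vox[i]) * grid.voxel_size[i]) for i in range(3)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    d2 = xx**2 + yy**2 + zz**2
    sigma = site.radius_mm / 2.0
    bump = site.magnitude * np.exp(-d2 / (2.0 * sigma**2))
    bump[d2 > site.radius_mm**2] = 0.0
    return float(np.minimum(bump, 1.0 - maps.p_gm).sum() * grid.voxel_volume)


def apply_condition_effect(
    maps: TissueProbabilityMaps, effect: EffectSpec
) -> TissueProbabilityMaps:
    """Apply a between-condition compartment effect to tissue probability maps.

    The CSF volume is rescaled by ``effect.csf_scale`` with the exchanged mass
    drawn from (or returned to) the parenchyma at the CSF boundary, so total
    intracranial volume is conserved exactly by that step.  Focal GM swelling
    sites are then added.  Returns new maps; the input is untouched.
    """
    out = maps.copy()
    v_csf = maps.volume("csf")
    delta_vox = v_csf * (effect.csf_scale - 1.0) / maps.grid.voxel_volume
    _transfer_csf_mass(out, delta_vox)
    for site in effect.focal_sites:
        _apply_focal_site(out, site)
    return TissueProbabilityMaps(out.grid, out.p_gm, out.p_wm, out.p_csf)


# ---------------------------------------------------------------------------
# forward models


def _add_noise(
    signal: np.ndarray, noise_sd: float, rng: np.random.Generator, noise_model: str
) -> np.ndarray:
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return signal
    if noise_model == "gaussian":
        return signal + rng.normal(scale=noise_sd, size=signal.shape)
    if noise_model == "rician":
        re = signal + rng.normal(scale=noise_sd, size=signal.shape)
        im = rng.normal(scale=noise_sd, size=signal.shape)
        return np.sqrt(re**2 + im**2)
    raise ValueError(f"unknown noise model {noise_model!r}; use 'gaussian' or 'rician'")


def polynomial_bias_field(
    grid: VoxelGrid, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative B1-type bias field: mean-1, second-order polynomial
    in normalized coordinates with peak deviation ~``amplitude``."""
    if amplitude == 0:
        return np.ones(grid.dims)
    coords = [np.linspace(-1.0, 1.0, d) for d in grid.dims]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    basis = [xx, yy, zz, xx * yy, xx * zz, yy * zz, xx**2, yy**2, zz**2]
    coeffs = rng.normal(size=len(basis))
    raw = sum(c * b for c, b in zip(coeffs, basis))
    raw -= raw.mean()
    peak = np.abs(raw).max()
    field = 1.0 + amplitude * raw / max(peak, 1e-12)
    return field / field.mean()


def simulate_pdw(
    maps: TissueProbabilityMaps,
    truth: CompartmentTruth,
    bias_amplitude: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a proton-density-weighted volume.

    Returns ``(volume, bias_field)``; the stored field lets bias-correction be
    scored against truth.  voxel = (sum_c p_c * PD_c) * bias + Gaussian noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    bias = polynomial_bias_field(maps.grid, bias_amplitude, rng)
    clean = sum(maps.prob(c) * truth.props(c).proton_density for c in COMPARTMENTS)
    return _add_noise(clean * bias, noise_sd, rng, "gaussian"), bias


def simulate_mge(
    maps: TissueProbabilityMaps,
    truth: CompartmentTruth,
    protocol: AcquisitionProtocol,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a multi-gradient-echo series, shape ``(*dims, n_echoes)``.

    Per voxel: S(TE) = sum_c p_c * PD_c * exp(-TE / T2*_c) + noise.
    """
    if protocol.n_echoes < 3:
        raise ValueError("at least 3 echoes are required")
    rng = np.random.default_rng(seed)
    tes = np.asarray(protocol.echo_times_ms)
    out = np.zeros(maps.grid.dims + (protocol.n_echoes,))
    for c in COMPARTMENTS:
        props = truth.props(c)
        decay = props.proton_density * np.exp(-tes / props.t2star_ms)
        out += maps.prob(c)[..., None] * decay
    return _add_noise(out, noise_sd, rng, "gaussian")


def simulate_dwi(
    maps: TissueProbabilityMaps,
    truth: CompartmentTruth,
    protocol: DiffusionProtocol,
    noise_model: str = "gaussian",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a diffusion-weighted series, shape ``(*dims, n_b, n_directions)``.

    Diffusion in the phantom is isotropic: the clean signal is identical along
    the three orthogonal directions; noise is drawn independently per
    direction.  Per voxel and b-value the clean signal mixes the compartments'
    IVIM + kurtosis decays weighted by membership probability.
    """
    if noise_model not in ("gaussian", "rician"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    rng = np.random.default_rng(seed)
    b = np.asarray(protocol.b_values)
    clean = np.zeros(maps.grid.dims + (protocol.n_b,))
    for c in COMPARTMENTS:
        decay = ivim_kurtosis_signal(b, truth.props(c).diffusion)
        clean += maps.prob(c)[..., None] * decay
    full = np.repeat(clean[..., None], protocol.n_directions, axis=-1)
    return _add_noise(full, noise_sd, rng, noise_model)


def simulate_dmso(
    protocol: DiffusionProtocol,
    adc: float = 6.8e-4,
    s0: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a mono-exponential DMSO-like phantom signal over all b-values.

    The default ADC of 6.8e-4 mm^2/s (680 um^2/s) reproduces the control
    phantom whose signal stays log-linear across the whole b-range.  Returns a
    table with columns ``b_s_mm2`` and ``signal``.
    """
    if adc <= 0:
        raise ValueError("adc must be positive")
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    rng = np.random.default_rng(seed)
    b = np.asarray(protocol.b_values)
    sig = _add_noise(s0 * np.exp(-b * adc), noise_sd, rng, "gaussian")
    return pd.DataFrame({"b_s_mm2": b, "signal": sig})


# ---------------------------------------------------------------------------
# paired cohort


@dataclass
class Subject:
    """One synthetic subject: shared anatomy with per-condition maps and truth."""

    subject_id: str
    maps: dict[str, TissueProbabilityMaps]  # condition -> maps
    truth: dict[str, CompartmentTruth]  # condition -> tissue truth
    seed: int


def simulate_cohort(
    n_subjects: int = 12,
    grid: VoxelGrid | None = None,
    base_truth: CompartmentTruth | None = None,
    effect: EffectSpec | None = None,
    seed: int = 0,
    csf_volume_cv: float = 0.105,
    parenchyma_volume_cv: float = 0.049,
    t2star_sd_ms: float = 1.1,
    conditions: tuple[str, str] = ("A", "B"),
) -> list[Subject]:
    """Generate a paired two-condition cohort with known ground truth.

    Each subject gets jittered anatomy (volume coefficients of variation and a
    T2* offset drawn once per subject, matching the reference between-animal
    spreads), shared across conditions; condition ``B`` then receives the
    ``effect`` (CSF rescaling with parenchymal exchange, focal GM sites, and a
    global T2* shift).  Defaults emulate the deeply-sedated vs isoflurane
    contrast: CSF 190 vs 180 mm^3, parenchyma exchanged accordingly, T2*
    28.8 vs 30.6 ms.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    grid = grid or VoxelGrid((96, 96, 64))
    base_truth = base_truth or CompartmentTruth.default()
    effect = effect if effect is not None else EffectSpec.iso_like()
    cond_a, cond_b = conditions
    ss = np.random.SeedSequence(seed)
    subjects: list[Subject] = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        csf_v = base_truth.csf_volume_mm3 * (1.0 + rng.normal(scale=csf_volume_cv))
        par_v = base_truth.parenchyma_volume_mm3 * (
            1.0 + rng.normal(scale=parenchyma_volume_cv)
        )
        t2_off = rng.normal(scale=t2star_sd_ms)
        gm_frac = base_truth.gm_volume_mm3 / base_truth.parenchyma_volume_mm3

        def jitter(props: CompartmentProps) -> CompartmentProps:
            return replace(props, t2star_ms=props.t2star_ms + t2_off)

        truth_a = replace(
            base_truth,
            gm=jitter(base_truth.gm),
            wm=jitter(base_truth.wm),
            csf=jitter(base_truth.csf),
            csf_volume_mm3=max(csf_v, 1.0),
            gm_volume_mm3=max(par_v * gm_frac, 1.0),
            wm_volume_mm3=max(par_v * (1.0 - gm_frac), 1.0),
        )
        maps_a = build_anatomy(grid, truth_a, seed=sub_seed)
        maps_b = apply_condition_effect(maps_a, effect)
        truth_b = shift_t2star(truth_a, effect.t2star_shift_ms)
        truth_b = replace(
            truth_b,
            csf_volume_mm3=maps_b.volume("csf"),
            gm_volume_mm3=maps_b.volume("gm"),
            wm_volume_mm3=maps_b.volume("wm"),
        )
        subjects.append(
            Subject(
                subject_id=f"sub-{i + 1:02d}",
                maps={cond_a: maps_a, cond_b: maps_b},
                truth={cond_a: truth_a, cond_b: truth_b},
                seed=sub_seed,
            )
        )
    return subjects
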