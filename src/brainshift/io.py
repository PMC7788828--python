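"""File formats: NIfTI-1 volumes, bval/bvec protocol files, YAML descriptors,
JSON truth sidecars."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom import (
    AcquisitionProtocol,
    CompartmentProps,
    CompartmentTruth,
    DiffusionProtocol,
    IVIMKurtosisParams,
    VoxelGrid,
)

__all__ = [
    "read_volume",
    "write_volume",
    "write_diffusion_protocol",
    "read_diffusion_protocol",
    "write_acquisition_protocol",
    "read_acquisition_protocol",
    "write_truth",
    "read_truth",
]

B_RANGE_DEFAULT = (20.0, 2518.0)


def write_volume(data: np.ndarray, grid: VoxelGrid, path) -> None:
    """Write a 3-D/4-D volume as NIfTI-1 with the grid's affine and voxel size."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), grid.affine)
    zooms = grid.voxel_size + (1.0,) * (img.ndim - 3)
    img.header.set_zooms(zooms[: img.ndim])
    nib.save(img, str(path))


def read_volume(path, ndim: int | None = None) -> tuple[np.ndarray, VoxelGrid]:
    """Read a NIfTI-1 volume; returns ``(data, grid)``.

    ``ndim`` asserts the expected dimensionality (3 for scalar maps, 4 for
    series) and raises on mismatch.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if ndim is not None and data.ndim != ndim:
        raise ValueError(f"{path}: expected a {ndim}-D volume, found {data.ndim}-D")
    grid = VoxelGrid.from_affine(data.shape[:3], img.affine)
    return data, grid


def assert_same_geometry(grid_a: VoxelGrid, grid_b: VoxelGrid, what: str = "volumes") -> None:
    if grid_a.dims != grid_b.dims or not np.allclose(grid_a.affine, grid_b.affine, atol=1e-6):
        raise ValueError(f"{what} do not share grid geometry: {grid_a} vs {grid_b}")


# ---------------------------------------------------------------------------
# diffusion protocol: FSL-style bval/bvec plus a YAML descriptor


def write_diffusion_protocol(
    protocol: DiffusionProtocol, bval_path, bvec_path, yaml_path=None
) -> None:
    """Write bval/bvec text files (space-separated, one row per axis in the
    bvec file) and optionally a YAML descriptor holding the window boundaries.

    One column per acquired volume: each b-value is repeated once per
    direction, direction cycling fastest.
    """
    b = np.repeat(protocol.b_values, protocol.n_directions)
    dirs = np.asarray(protocol.directions)
    vecs = np.tile(dirs.T, protocol.n_b)  # 3 x (n_b * n_dir)
    Path(bval_path).write_text(" ".join(f"{v:.10g}" for v in b) + "\n")
    Path(bvec_path).write_text(
        "\n".join(" ".join(f"{v:.10g}" for v in row) for row in vecs) + "\n"
    )
    if yaml_path is not None:
        Path(yaml_path).write_text(
            yaml.safe_dump(
                {
                    "range_windows_s_mm2": {
                        k: list(v) for k, v in protocol.range_windows.items()
                    }
                }
            )
        )


def read_diffusion_protocol(
    bval_path, bvec_path, yaml_path=None, b_range=B_RANGE_DEFAULT
) -> DiffusionProtocol:
    """Read a diffusion protocol from bval/bvec (and optional YAML windows).

    The column layout must repeat each b-value once per direction.  B-values
    outside the expected acquisition range trigger a warning, not an error;
    non-unit directions are an error (enforced by DiffusionProtocol).
    """
    bvals = np.loadtxt(bval_path, ndmin=1)
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise ValueError(f"bvec file must have 3 rows, found {bvecs.shape[0]}")
    if bvecs.shape[1] != bvals.size:
        raise ValueError(
            f"bval/bvec length mismatch: {bvals.size} b-values vs {bvecs.shape[1]} vectors"
        )
    if bvals.min() < b_range[0] or bvals.max() > b_range[1]:
        import warnings

        warnings.warn(
            f"b-values outside the expected range {b_range}: "
            f"[{bvals.min():g}, {bvals.max():g}]",
            stacklevel=2,
        )
    # columns cycle direction fastest; recover the unique direction set
    uniq_dirs = np.unique(np.round(bvecs.T, 9), axis=0)
    n_dir = len(uniq_dirs)
    if bvals.size % n_dir != 0:
        raise ValueError("each b-value must appear once per direction")
    b_unique = bvals.reshape(-1, n_dir)
    if not np.allclose(b_unique, b_unique[:, :1]):
        raise ValueError("bval file does not repeat each b-value once per direction")
    kwargs = {}
    if yaml_path is not None:
        spec = yaml.safe_load(Path(yaml_path).read_text())
        kwargs["range_windows"] = {
            k: tuple(v) for k, v in spec["range_windows_s_mm2"].items()
        }
    return DiffusionProtocol(
        tuple(b_unique[:, 0]), directions=tuple(map(tuple, uniq_dirs)), **kwargs
    )


# ---------------------------------------------------------------------------
# acquisition protocol YAML


def write_acquisition_protocol(protocol: AcquisitionProtocol, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "echo_times_ms": list(protocol.echo_times_ms),
                "repetition_time_ms": protocol.repetition_time_ms,
            }
        )
    )


def read_acquisition_protocol(path) -> AcquisitionProtocol:
    spec = yaml.safe_load(Path(path).read_text())
    return AcquisitionProtocol(
        tuple(spec["echo_times_ms"]), float(spec.get("repetition_time_ms", 60.0))
    )


# ---------------------------------------------------------------------------
# ground-truth sidecar JSON


def write_truth(truth: CompartmentTruth, path) -> None:
    Path(path).write_text(json.dumps(asdict(truth), indent=2, sort_keys=True))


def read_truth(path) -> CompartmentTruth:
    raw = json.loads(Path(path).read_text())

    def props(d) -> CompartmentProps:
        return CompartmentProps(
            proton_density=d["proton_density"],
            t2star_ms=d["t2star_ms"],
            diffusion=IVIMKurtosisParams(**d["diffusion"]),
        )

    return CompartmentTruth(
        gm=props(raw["gm"]),
        wm=props(raw["wm"]),
        csf=props(raw["csf"]),
        csf_volume_mm3=raw["csf_volume_mm3"],
        gm_volume_mm3=raw["gm_volume_mm3"],
        wm_volume_mm3=raw["wm_volume_mm3"],
    )
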