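"""T2* relaxometry: per-voxel mono-exponential fits and trimmed compartment means.

The multi-gradient-echo signal is modelled as S(TE) = S0 * exp(-TE / T2*).
T2* and S0 are estimated voxel-wise by ordinary least squares on
ln S versus TE (slope = -1/T2*, intercept = ln S0) — deterministic and
closed-form, which the 16-echo sampling supports well.  Voxels with any
non-positive echo or a non-decaying fit are flagged invalid rather than
silently zeroed.  Compartment summaries are percentile-trimmed means
(default 0.1-99%) over voxels whose membership probability exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .phantom import AcquisitionProtocol, TissueProbabilityMaps

__all__ = ["T2StarFit", "fit_t2star", "compartment_t2star_mean"]


@dataclass
class T2StarFit:
    """Per-voxel T2* map (ms), S0 map (a.u.), log-domain R^2 and validity mask."""

    t2star_map: np.ndarray
    s0_map: np.ndarray
    r2_map: np.ndarray
    valid_mask: np.ndarray
    echo_times_ms: tuple[float, ...]


def _loglinear_decay_fit(y: np.ndarray, x: np.ndarray):
    """Vectorized OLS of ln(y) on x over the last axis.

    Returns (rate, amplitude, r2, valid): y ~ amplitude * exp(-rate * x);
    voxels with any non-positive sample or non-positive fitted rate are
    invalid (rate/amplitude reported as NaN).
    """
    y = np.asarray(y, dtype=float)
    positive = (y > 0).all(axis=-1)
    logy = np.where(y > 0, np.log(np.where(y > 0, y, 1.0)), 0.0)
    xc = x - x.mean()
    sxx = float((xc**2).sum())
    ym = logy.mean(axis=-1)
    slope = (logy * xc).sum(axis=-1) / sxx
    intercept = ym - slope * x.mean()
    resid = logy - (intercept[..., None] + slope[..., None] * x)
    ss_res = (resid**2).sum(axis=-1)
    ss_tot = ((logy - ym[..., None]) ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0), 0.0)
    valid = positive & (slope < 0)
    rate = np.where(valid, -slope, np.nan)
    amplitude = np.where(valid, np.exp(intercept), np.nan)
    r2 = np.where(positive, r2, np.nan)
    return rate, amplitude, r2, valid


def fit_t2star(echo_series: np.ndarray, protocol: AcquisitionProtocol) -> T2StarFit:
    """Fit per-voxel T2* from a 4-D echo series, shape ``(*dims, n_echoes)``.

    Requires at least 3 echoes and a series whose last axis matches the
    protocol's echo count.
    """
    echo_series = np.asarray(echo_series, dtype=float)
    if protocol.n_echoes < 3:
        raise ValueError("T2* fitting needs at least 3 echoes")
    if echo_series.ndim < 2 or echo_series.shape[-1] != protocol.n_echoes:
        raise ValueError(
            f"series has {echo_series.shape[-1] if echo_series.ndim else 0} echoes, "
            f"protocol lists {protocol.n_echoes}"
        )
    tes = np.asarray(protocol.echo_times_ms, dtype=float)
    rate, s0, r2, valid = _loglinear_decay_fit(echo_series, tes)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2star = np.where(valid, 1.0 / rate, np.nan)
    return T2StarFit(t2star, s0, r2, valid, protocol.echo_times_ms)


def compartment_t2star_mean(
    fit: T2StarFit,
    maps: TissueProbabilityMaps,
    compartment_set: Iterable[str] = ("gm", "wm"),
    lo_pct: float = 0.1,
    hi_pct: float = 99.0,
) -> float:
    """Percentile-trimmed mean T2* (ms) over a compartment set.

    Voxels enter the pool when their summed membership probability over the
    set exceeds 0.5 and their fit is valid; values outside the
    [lo_pct, hi_pct] percentile interval are discarded to exclude outliers
    before averaging.
    """
    comp = tuple(compartment_set)
    unknown = set(comp) - {"gm", "wm", "csf"}
    if unknown:
        raise ValueError(f"unknown compartments {sorted(unknown)}")
    if not 0 <= lo_pct < hi_pct <= 100:
        raise ValueError("percentile bounds must satisfy 0 <= lo < hi <= 100")
    membership = sum(maps.prob(c) for c in comp)
    pool = fit.t2star_map[(membership > 0.5) & fit.valid_mask]
    if pool.size == 0:
        raise ValueError(f"no valid voxels with membership > 0.5 for {comp}")
    lo, hi = np.percentile(pool, [lo_pct, hi_pct])
    trimmed = pool[(pool >= lo) & (pool <= hi)]
    return float(trimmed.mean())
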