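"""Voxel-wise paired statistics with false-discovery-rate control.

Paired t-tests are computed per voxel on within-subject condition differences
(n-1 degrees of freedom, two-tailed p); multiplicity over the analysis mask is
handled by the Benjamini-Hochberg step-up procedure (Benjamini-Yekutieli
available as an option).  Scalar compartment totals (TIV, CSF, parenchyma,
compartment-mean T2*) get classical paired t-tests, and ROI means are
extracted into tidy tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatMap",
    "PairedTestSummary",
    "paired_ttest_map",
    "fdr_correct",
    "paired_total_test",
    "roi_extract",
]


@dataclass
class StatMap:
    """Voxel-wise paired-test result maps.

    q_map and significance_mask are filled in by fdr_correct; zero-variance
    voxels keep p = 1 by convention and are flagged rather than dropped, so
    the map geometry stays intact.
    """

    t_map: np.ndarray
    p_map: np.ndarray
    analysis_mask: np.ndarray
    n_pairs: int
    q_map: np.ndarray | None = None
    significance_mask: np.ndarray | None = None
    zero_variance_mask: np.ndarray | None = None
    q_level: float | None = None


@dataclass(frozen=True)
class PairedTestSummary:
    """Paired t-test on scalar totals."""

    metric: str
    n_pairs: int
    mean_a: float
    mean_b: float
    mean_difference: float
    t: float
    p: float
    pct_difference: float  # 100 * (mean_a - mean_b) / mean_b


def paired_ttest_map(
    stack_a: np.ndarray, stack_b: np.ndarray, analysis_mask: np.ndarray
) -> StatMap:
    """Per-voxel paired t-test between two subject stacks.

    Stacks have shape ``(n_subjects, *dims)`` with identical subject ordering.
    """
    a = np.asarray(stack_a, dtype=float)
    b = np.asarray(stack_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"stacks differ in shape: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 2:
        raise ValueError("paired test needs at least 2 subjects")
    mask = np.asarray(analysis_mask, dtype=bool)
    if mask.shape != a.shape[1:]:
        raise ValueError("analysis mask shape does not match the volumes")
    if not mask.any():
        raise ValueError("empty analysis mask")

    d = a - b
    mean_d = d.mean(axis=0)
    sd_d = d.std(axis=0, ddof=1)
    zero_var = (sd_d == 0) & mask
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd_d > 0, mean_d / (sd_d / np.sqrt(n)), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(zero_var, 1.0, p)
    t = np.where(zero_var, 0.0, t)
    t[~mask] = np.nan
    p[~mask] = np.nan
    return StatMap(t, p, mask, n, zero_variance_mask=zero_var)


def fdr_correct(
    stat: StatMap | np.ndarray,
    analysis_mask: np.ndarray | None = None,
    q_level: float = 0.05,
    method: str = "bh",
) -> StatMap:
    """Benjamini-Hochberg FDR adjustment over the analysis mask.

    Accepts a StatMap (returned filled in) or a raw p-map plus mask.
    Significance is the step-up rejection set, i.e. adjusted q <= q_level.
    ``method`` is 'bh' (independence/PRDS) or 'by' (arbitrary dependence).
    """
    if isinstance(stat, StatMap):
        p_map = stat.p_map
        mask = stat.analysis_mask if analysis_mask is None else np.asarray(analysis_mask, bool)
    else:
        if analysis_mask is None:
            raise ValueError("a raw p-map requires an explicit analysis mask")
        p_map = np.asarray(stat, dtype=float)
        mask = np.asarray(analysis_mask, dtype=bool)
        stat = StatMap(np.full_like(p_map, np.nan), p_map, mask, n_pairs=2)
    if not mask.any():
        raise ValueError("empty analysis mask")
    pvals = p_map[mask]
    if np.isnan(pvals).any() or pvals.min() < 0 or pvals.max() > 1:
        raise ValueError("p-values inside the mask must lie in [0, 1]")
    mt_method = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if mt_method is None:
        raise ValueError(f"unknown FDR method {method!r}; use 'bh' or 'by'")
    reject, q, _, _ = multipletests(pvals, alpha=q_level, method=mt_method)
    q_map = np.full(p_map.shape, np.nan)
    q_map[mask] = q
    sig = np.zeros(p_map.shape, dtype=bool)
    sig[mask] = reject
    stat.q_map = q_map
    stat.significance_mask = sig
    stat.q_level = q_level
    return stat


def paired_total_test(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    metric: str,
    subject_col: str = "subject",
) -> PairedTestSummary:
    """Classical two-tailed paired t-test on per-subject scalar totals.

    Tables carry one row per subject; rows are aligned on ``subject_col`` and
    must pair exactly.
    """
    for tab, name in ((table_a, "A"), (table_b, "B")):
        missing = {subject_col, metric} - set(tab.columns)
        if missing:
            raise ValueError(f"table {name} lacks columns {sorted(missing)}")
    a = table_a.set_index(subject_col)[metric].sort_index()
    b = table_b.set_index(subject_col)[metric].sort_index()
    if not a.index.equals(b.index):
        raise ValueError("subjects do not pair across the two tables")
    if len(a) < 2:
        raise ValueError("paired test needs at least 2 subjects")
    diff = a.to_numpy() - b.to_numpy()
    if np.allclose(diff, 0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(a.to_numpy(), b.to_numpy())
    mean_a, mean_b = float(a.mean()), float(b.mean())
    return PairedTestSummary(
        metric=metric,
        n_pairs=len(a),
        mean_a=mean_a,
        mean_b=mean_b,
        mean_difference=mean_a - mean_b,
        t=float(t),
        p=float(p),
        pct_difference=100.0 * (mean_a - mean_b) / mean_b if mean_b else float("nan"),
    )


def roi_extract(
    metric_maps: dict[str, np.ndarray],
    roi_masks: dict[str, np.ndarray],
    subject: str = "",
    condition: str = "",
    valid_masks: dict[str, np.ndarray] | None = None,
    units: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Mean of each metric map inside each ROI, as a tidy table.

    Invalid voxels (per-metric validity masks, or NaNs in the map) are
    excluded from the mean and counted; an ROI left empty after validity
    masking raises.
    """
    rows = []
    for roi_name, roi in roi_masks.items():
        roi = np.asarray(roi, dtype=bool)
        for metric, arr in metric_maps.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != roi.shape:
                raise ValueError(
                    f"ROI {roi_name!r} shape {roi.shape} does not match map {metric!r} {arr.shape}"
                )
            valid = np.isfinite(arr)
            if valid_masks and metric in valid_masks:
                valid &= np.asarray(valid_masks[metric], dtype=bool)
            sel = roi & valid
            if not sel.any():
                raise ValueError(f"ROI {roi_name!r} has no valid voxels for metric {metric!r}")
            rows.append(
                {
                    "roi": roi_name,
                    "subject": subject,
                    "condition": condition,
                    "metric": metric,
                    "value": float(arr[sel].mean()),
                    "n_valid": int(sel.sum()),
                    "n_invalid": int((roi & ~valid).sum()),
                    "units": (units or {}).get(metric, ""),
                }
            )
    return pd.DataFrame(rows)
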