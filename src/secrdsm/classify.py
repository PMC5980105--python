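"""Safe-harbor / attractive-sink classification of the habitat mask.

Mask points are split at the median of each covariate over the in-grid
region: above-median habitat value (RSF) with low mortality risk is
"safe harbor" (source-like); above-median RSF with high risk is an
"attractive sink". Category summaries report mean density, area, and
relative abundance (mean density x area).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import HabitatMask

CATEGORIES = (
    "safe_harbor",        # high RSF, low Risk
    "attractive_sink",    # high RSF, high Risk
    "low_rsf_low_risk",
    "low_rsf_high_risk",
)


def categorize_mask(
    mask: HabitatMask, rsf: str = "RSF", risk: str = "Risk",
    flag: str | None = "inside_grid",
) -> tuple[pd.Series, dict]:
    """Quadrant labels from median splits of RSF and Risk.

    "High" means strictly above the median (ties go low, for both
    covariates); medians are computed over the flagged (in-grid) points and
    reported in the returned threshold dict. Labels are rank-based, hence
    invariant to monotone rescaling of the covariates.
    """
    pts = mask.points
    for c in (rsf, risk):
        if c not in pts.columns:
            raise ValueError(f"mask lacks covariate {c!r}")
    keep = pts[flag].to_numpy(bool) if flag and flag in pts.columns else np.ones(len(pts), bool)
    v_rsf = pts[rsf].to_numpy(float)
    v_risk = pts[risk].to_numpy(float)
    med_rsf = float(np.median(v_rsf[keep]))
    med_risk = float(np.median(v_risk[keep]))
    if v_rsf[keep].min() == v_rsf[keep].max() or v_risk[keep].min() == v_risk[keep].max():
        raise ValueError("constant covariate: no median split possible")
    hi_rsf = v_rsf > med_rsf
    hi_risk = v_risk > med_risk
    labels = np.where(
        hi_rsf,
        np.where(hi_risk, "attractive_sink", "safe_harbor"),
        np.where(hi_risk, "low_rsf_high_risk", "low_rsf_low_risk"),
    )
    return (
        pd.Series(labels, index=pts.index, name="category"),
        {"rsf_median": med_rsf, "risk_median": med_risk},
    )


def category_summary(
    surface: pd.DataFrame,
    labels: pd.Series,
    mask: HabitatMask,
    flag: str | None = "inside_grid",
    center_counts: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-category mean density, area, and relative abundance.

    ``surface`` is a prediction table aligned with the mask (column
    ``density``, per 1000 km^2). The output also carries the overall mean
    density (the reference line a category deviates from) and the
    equal-density expected abundance proportional to category area. With
    ``center_counts`` (a category -> count Series of estimated home-range
    centres) an observed-centre abundance column is added for comparison.
    """
    if len(surface) != len(mask):
        raise ValueError("surface and mask must align")
    keep = (
        mask.points[flag].to_numpy(bool)
        if flag and flag in mask.points.columns
        else np.ones(len(mask), bool)
    )
    dens = surface["density"].to_numpy(float)
    lab = labels.to_numpy()
    a = mask.cell_area
    overall_mean = float(dens[keep].mean())
    total_area = float(keep.sum() * a)
    rows = []
    for cat in CATEGORIES:
        sel = keep & (lab == cat)
        n_pts = int(sel.sum())
        area = n_pts * a
        mean_d = float(dens[sel].mean()) if n_pts else 0.0
        rows.append(
            {
                "category": cat,
                "n_points": n_pts,
                "area_km2": area,
                "mean_density_per_1000km2": mean_d,
                "relative_abundance": mean_d * area / 1000.0,
                "equal_density_abundance": overall_mean * area / 1000.0,
                "empty": n_pts == 0,
            }
        )
    out = pd.DataFrame(rows)
    out["overall_mean_density_per_1000km2"] = overall_mean
    if center_counts is not None:
        out["center_count"] = out["category"].map(center_counts).fillna(0).astype(int)
    assert abs(out["area_km2"].sum() - total_area) < 1e-6  # categories partition
    return out
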