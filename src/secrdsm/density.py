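"""Density-surface models on the habitat mask.

Log-linear density models D(x) = exp(b0 + b' z(x)) (animals per 1000 km^2)
with z the mask covariates (habitat value RSF, mortality risk Risk), fit
jointly with the detection model by maximum likelihood. The candidate set is
the five-model family: constant, RSF, Risk, RSF+Risk, RSF x Risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .data import HabitatMask
from .raster import Raster

MODEL_TERMS = {
    "constant": (),
    "RSF": ("RSF",),
    "Risk": ("Risk",),
    "RSF+Risk": ("RSF", "Risk"),
    "RSF*Risk": ("RSF", "Risk", "RSF:Risk"),
}


@dataclass(frozen=True)
class DensityModelSpec:
    """One of the five candidate density surfaces, or custom terms.

    ``name`` may be a key of :data:`MODEL_TERMS`; otherwise ``terms`` must be
    given explicitly (covariate column names; ``"A:B"`` denotes the product
    of the standardized mains, which must both be present).
    """

    name: str = "constant"
    custom_terms: tuple[str, ...] | None = None

    @property
    def terms(self) -> tuple[str, ...]:
        if self.custom_terms is not None:
            t = tuple(self.custom_terms)
        elif self.name in MODEL_TERMS:
            t = MODEL_TERMS[self.name]
        else:
            raise ValueError(f"unknown density model {self.name!r}")
        for x in t:
            if ":" in x:
                a, b = x.split(":")
                if a not in t or b not in t:
                    raise ValueError("interaction requires both main effects")
        return t


def summarize_covariates_to_mask(
    raster: Raster, mask: HabitatMask, name: str, radius_km: float = 1.75,
    fill_flag: str = "inside_province",
) -> pd.Series:
    """Attach a raster covariate to the mask as a buffered mean.

    Each mask point receives the mean raster value within ``radius_km``; a
    point with no covered raster cell within the radius falls back to the
    value of its containing cell, and — mirroring the treatment of mask
    points beyond the covariate map edge — any still-missing point is filled
    from the nearest mask point that has a value. Filled points are flagged
    in a boolean ``<name>_filled`` column.
    """
    finite = np.isfinite(raster.values.ravel())
    if not finite.any():
        raise ValueError("raster has no non-missing values")
    centers = raster.center_grid()[finite]
    vals = raster.values.ravel()[finite]
    tree = cKDTree(centers)
    coords = mask.coords
    out = np.full(len(mask), np.nan)
    radius = max(radius_km, 0.0)
    neighbours = tree.query_ball_point(coords, r=radius)
    for i, nb in enumerate(neighbours):
        if nb:
            out[i] = vals[nb].mean()
    missing = ~np.isfinite(out)
    if missing.any():  # radius smaller than resolution: use the containing cell
        out[missing] = raster.sample(coords[missing, 0], coords[missing, 1])
    missing = ~np.isfinite(out)
    if missing.any():
        if missing.all():
            raise ValueError("no mask point overlaps the raster")
        have = np.flatnonzero(~missing)
        ftree = cKDTree(coords[have])
        _, j = ftree.query(coords[missing])
        out[missing] = out[have[j]]
    mask.points[name] = out
    mask.points[f"{name}_filled"] = missing
    return mask.points[name]


def fit_density_models(
    capture, layouts, mask, detection_spec, models=tuple(MODEL_TERMS), **fit_kwargs
):
    """Fit the candidate density surfaces with a shared detection model.

    Returns ``(fits, table)``: a dict of :class:`~secrdsm.model.SecrResults`
    keyed by model name and the AICc ranking table.
    """
    from .model import SecrModel, model_table

    fits = {}
    for name in models:
        m = SecrModel(capture, layouts, mask, detection=detection_spec,
                      density=DensityModelSpec(name))
        fits[name] = m.fit(**fit_kwargs)
    return fits, model_table(fits)


def predict_density(results, mask: HabitatMask | None = None) -> pd.DataFrame:
    """Per-mask-point density (animals per 1000 km^2) with delta-method SEs.

    Predicting onto a mask other than the fitted one reuses the fitted
    standardisation; covariate values outside the fitted range are flagged
    ``extrapolated`` with a warning (extrapolation beyond the sampled grid is
    legitimate but less certain).
    """
    engine = results.model.engine
    if mask is None or mask is engine.mask:
        mask = engine.mask
        Z = engine.Zd
        extrap = np.zeros(len(mask), bool)
    else:
        Z, extrap = _design_on_new_mask(engine, mask)
        if extrap.any():
            warnings.warn(
                f"{int(extrap.sum())} mask points outside the fitted covariate range",
                stacklevel=2,
            )
    bd = results.density_params
    Vd = results.density_vcov
    lp = Z @ bd
    se_lp = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Z, Vd, Z), 0.0))
    dens = np.exp(lp)
    out = pd.DataFrame(
        {
            "x": mask.points["x"],
            "y": mask.points["y"],
            "density": dens,
            "se": dens * se_lp,
            "lp": lp,
            "extrapolated": extrap,
        }
    )
    for flag in ("inside_grid", "inside_province"):
        if flag in mask.points:
            out[flag] = mask.points[flag].to_numpy(bool)
    return out


def _design_on_new_mask(engine, mask):
    pts = mask.points
    terms = engine.density.terms
    fitted = engine.mask.points
    ing = (
        fitted["inside_grid"].to_numpy(bool)
        if "inside_grid" in fitted
        else np.ones(len(fitted), bool)
    )
    cols = [np.ones(len(pts))]
    extrap = np.zeros(len(pts), bool)
    std = {}
    for t in terms:
        if ":" in t:
            continue
        v = pts[t].to_numpy(float)
        ref = fitted[t].to_numpy(float)
        mu, sd = ref[ing].mean(), ref[ing].std()
        std[t] = (v - mu) / (sd if sd > 0 else 1.0)
        extrap |= (v < ref.min()) | (v > ref.max())
    for t in terms:
        cols.append(std[t.split(":")[0]] * std[t.split(":")[1]] if ":" in t else std[t])
    return np.column_stack(cols), extrap


def region_abundance(results, flag: str = "inside_grid", surface: pd.DataFrame | None = None):
    """Abundance over the flagged mask region with a delta-method CI.

    N_hat = a * sum over flagged points of D_hat(x) (with densities per
    1000 km^2, a enters as cell_area/1000). Returns a dict with the
    abundance, its SE, a log-normal 95% CI, the region area, and the implied
    mean density per 1000 km^2.
    """
    engine = results.model.engine
    mask = engine.mask
    keep = mask.flag(flag)
    if not keep.any():
        raise ValueError(f"no mask points in region {flag!r}")
    if surface is None:
        surface = predict_density(results)
    dens = surface["density"].to_numpy(float)[keep]
    Z = engine.Zd[keep]
    scale = mask.cell_area / 1000.0
    N = scale * dens.sum()
    grad = scale * (dens[:, None] * Z).sum(axis=0)  # dN/d(beta_D)
    var = float(grad @ results.density_vcov @ grad)
    se = np.sqrt(max(var, 0.0))
    area = mask.area(flag)
    if N > 0 and se > 0:
        c = np.exp(1.959963985 * np.sqrt(np.log1p((se / N) ** 2)))
        lcl, ucl = N / c, N * c
    else:
        lcl = ucl = N
    return {
        "N": N,
        "se": se,
        "lcl": lcl,
        "ucl": ucl,
        "area_km2": area,
        "density_per_1000km2": 1000.0 * N / area,
        "density_se_per_1000km2": 1000.0 * se / area,
    }
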