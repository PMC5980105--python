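"""Density-surface models: covariate summarisation, prediction, abundance."""

import numpy as np
import pandas as pd
import pytest

from secrdsm import (
    DensityModelSpec,
    DetectionModelSpec,
    HabitatMask,
    Raster,
    SecrModel,
    StudyDesign,
    fit_density_models,
    predict_density,
    region_abundance,
    simulate_detections,
    simulate_population,
    place_detectors,
    summarize_covariates_to_mask,
)

from .conftest import make_mask


class TestSummarizeCovariates:
    def test_constant_raster(self):
        mask = make_mask(4, 4, spacing=2.0)
        r = Raster(np.full((20, 20), 7.0), -2.0, -2.0, 0.5)
        vals = summarize_covariates_to_mask(r, mask, "cov")
        assert np.allclose(vals, 7.0)

    def test_nearest_fill_at_missing_edge(self):
        mask = make_mask(4, 4, spacing=2.0)  # x in 0..6
        v = np.full((24, 24), 3.0)
        v[:, 12:] = np.nan  # strip x > 4 missing
        r = Raster(v, -2.0, -2.0, 0.5)
        vals = summarize_covariates_to_mask(r, mask, "cov", radius_km=0.6)
        assert np.allclose(vals, 3.0)  # missing points filled from nearest covered
        assert mask.points["cov_filled"].any()

    def test_radius_below_resolution_uses_containing_cell(self):
        mask = make_mask(3, 3, spacing=2.0)
        rng = np.random.default_rng(0)
        v = rng.uniform(size=(10, 10))
        r = Raster(v, -1.0, -1.0, 1.0)
        vals = summarize_covariates_to_mask(r, mask, "cov", radius_km=0.01)
        expect = r.sample(mask.points["x"], mask.points["y"])
        assert np.allclose(vals, expect)

    def test_all_missing_rejected(self):
        mask = make_mask(2, 2)
        r = Raster(np.full((4, 4), np.nan), 0, 0, 1.0)
        with pytest.raises(ValueError):
            summarize_covariates_to_mask(r, mask, "cov")


@pytest.fixture(scope="module")
def rsf_study():
    """Study simulated with positive RSF selection and no Risk effect."""
    design = StudyDesign(n_cells_x=8, n_cells_y=8)
    rng = np.random.default_rng(7)
    mask = HabitatMask.from_polygon(design.grid_polygon, 3.5, 14.0)
    n = len(mask)
    # smooth-ish covariates constructed directly on the mask
    mask.points["RSF"] = np.sin(mask.points["x"] / 15.0) + rng.normal(0, 0.3, n)
    mask.points["Risk"] = np.cos(mask.points["y"] / 11.0) + rng.normal(0, 0.3, n)
    layouts = place_detectors(design, rng)
    betas = {"intercept": np.log(35.0), "RSF": 0.8}
    centers = simulate_population(mask, betas, rng)
    capture, _ = simulate_detections(centers, layouts, (0.2, 3.5), rng)
    return {"design": design, "mask": mask, "layouts": layouts,
            "capture": capture, "betas": betas, "n_true": len(centers)}


class TestFitDensityModels:
    def test_nesting_and_ranking(self, rsf_study):
        s = rsf_study
        fits, table = fit_density_models(
            s["capture"], s["layouts"], s["mask"], DetectionModelSpec()
        )
        ll = {k: f.loglik for k, f in fits.items()}
        assert ll["RSF*Risk"] >= ll["RSF+Risk"] - 1e-4
        assert ll["RSF+Risk"] >= ll["RSF"] - 1e-4
        assert ll["RSF"] >= ll["constant"] - 1e-4
        # data generated under RSF: an RSF-containing model should lead
        assert "RSF" in table["model"].iloc[0]
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_surface_prediction_properties(self, rsf_study):
        s = rsf_study
        fit = SecrModel(
            s["capture"], s["layouts"], s["mask"],
            density=DensityModelSpec("RSF"),
        ).fit()
        surf = predict_density(fit)
        assert (surf["density"] >= 0).all()
        assert (surf["se"] >= 0).all()
        # log-link: density rises with RSF given positive fitted beta
        b_rsf = fit.density_params[1]
        assert b_rsf > 0
        hi = surf.loc[s["mask"].points["RSF"] > s["mask"].points["RSF"].median(), "density"]
        lo = surf.loc[s["mask"].points["RSF"] <= s["mask"].points["RSF"].median(), "density"]
        assert hi.mean() > lo.mean()


class TestPredictDensity:
    def test_constant_model_flat_surface(self, sim_constant_study):
        s = sim_constant_study
        fit = SecrModel(s["capture"], s["layouts"], s["mask"]).fit()
        surf = predict_density(fit)
        assert np.allclose(surf["density"], fit.density["estimate"], rtol=1e-10)

    def test_log_link_doubling(self, rsf_study):
        """beta = log 2 per (standardised) unit doubles density per unit."""
        s = rsf_study
        model = SecrModel(s["capture"], s["layouts"], s["mask"],
                          density=DensityModelSpec("RSF"))
        res = model.fit()
        theta = res.params.copy()
        theta[-1] = np.log(2.0)
        from secrdsm.model import SecrResults

        res2 = SecrResults(model, theta, res.loglik, res.vcov, True)
        surf = predict_density(res2)
        z = model.engine.Zd[:, 1]
        ratio = np.log2(surf["density"]) - z  # should be constant
        assert np.allclose(ratio, ratio.iloc[0], atol=1e-9)


class TestRegionAbundance:
    def test_uniform_density_exact_count(self, sim_constant_study):
        s = sim_constant_study
        fit = SecrModel(s["capture"], s["layouts"], s["mask"]).fit()
        ra = region_abundance(fit, "inside_grid")
        expect = fit.density["estimate"] * s["mask"].area("inside_grid") / 1000.0
        assert ra["N"] == pytest.approx(expect, rel=1e-10)
        assert ra["lcl"] < ra["N"] < ra["ucl"]

    def test_disjoint_regions_add(self, sim_constant_study):
        s = sim_constant_study
        mask = s["mask"]
        west = mask.points["x"] < 35.0
        mask.points["west"] = west & mask.points["inside_grid"]
        mask.points["east"] = ~west & mask.points["inside_grid"]
        fit = SecrModel(s["capture"], s["layouts"], mask).fit()
        total = region_abundance(fit, "inside_grid")["N"]
        parts = region_abundance(fit, "west")["N"] + region_abundance(fit, "east")["N"]
        assert parts == pytest.approx(total, rel=1e-10)

    def test_truth_recovered(self, rsf_study):
        s = rsf_study
        fits, table = fit_density_models(
            s["capture"], s["layouts"], s["mask"], DetectionModelSpec(),
            models=("RSF",),
        )
        ra = region_abundance(fits["RSF"], "inside_grid")
        # true N on the full mask scaled by in-grid share of intensity
        lp = s["betas"]["intercept"] + s["betas"]["RSF"] * s["mask"].points["RSF"]
        lam = np.exp(lp) * s["mask"].cell_area / 1000.0
        truth_in = lam[s["mask"].points["inside_grid"]].sum()
        assert ra["N"] == pytest.approx(truth_in, rel=0.30)

    def test_empty_region_rejected(self, sim_constant_study):
        s = sim_constant_study
        fit = SecrModel(s["capture"], s["layouts"], s["mask"]).fit()
        s["mask"].points["nowhere"] = False
        with pytest.raises(ValueError, match="nowhere"):
            region_abundance(fit, "nowhere")


def test_abundance_invariant_to_mask_refinement(sim_constant_study):
    """a * sum(D) over the grid stays within 1% under mask refinement."""
    s = sim_constant_study
    Ns = {}
    for spacing in (3.5, 1.75):
        mask = HabitatMask.from_polygon(s["design"].grid_polygon, spacing, 16.0)
        fit = SecrModel(s["capture"], s["layouts"], mask).fit()
        Ns[spacing] = region_abundance(fit, "inside_grid")["N"]
    assert Ns[1.75] == pytest.approx(Ns[3.5], rel=0.01)
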