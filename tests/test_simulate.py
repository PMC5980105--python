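"""Synthetic-study generator: determinism, distributional checks, design rules."""

import numpy as np
import pytest
from scipy import stats

from secrdsm import (
    LandscapeConfig,
    StudyDesign,
    generate_landscape,
    place_detectors,
    simulate_detections,
    simulate_population,
    simulate_study,
    simulate_telemetry,
)

from .conftest import make_layouts, make_mask


class TestLandscape:
    def test_same_seed_identical(self):
        cfg = LandscapeConfig(extent=(0, 0, 50, 50), seed=11)
        r1, k1 = generate_landscape(cfg)
        r2, k2 = generate_landscape(cfg)
        assert np.array_equal(r1.values, r2.values)
        assert np.array_equal(k1.values, k2.values)

    def test_no_smoothing_gives_independent_scores(self):
        cfg = LandscapeConfig(
            extent=(0, 0, 100, 100), resolution=1.0, autocorr_range=0.0,
            rsf_levels=2, risk_levels=2, seed=3,
        )
        rsf, _ = generate_landscape(cfg)
        v = rsf.values
        # lag-1 autocorrelation over 10,000 cells ~ 0
        r = np.corrcoef(v[:, :-1].ravel(), v[:, 1:].ravel())[0, 1]
        assert abs(r) < 0.05

    def test_correlogram_decays_with_distance(self):
        cfg = LandscapeConfig(
            extent=(0, 0, 120, 120), resolution=1.0, autocorr_range=14.0, seed=5
        )
        rsf, _ = generate_landscape(cfg)
        v = rsf.values

        def lag_corr(lag):
            return np.corrcoef(v[:, :-lag].ravel(), v[:, lag:].ravel())[0, 1]

        assert lag_corr(1) > lag_corr(20)
        assert lag_corr(1) > 0.5

    def test_values_are_ordinal_scores(self):
        cfg = LandscapeConfig(extent=(0, 0, 30, 30), rsf_levels=5, risk_levels=3, seed=2)
        rsf, risk = generate_landscape(cfg)
        assert set(np.unique(rsf.values)) <= set(range(1, 6))
        assert set(np.unique(risk.values)) <= set(range(1, 4))

    def test_correlation_between_surfaces(self):
        base = dict(extent=(0, 0, 80, 80), autocorr_range=5.0)
        r_hi = generate_landscape(LandscapeConfig(**base, correlation=0.9, seed=8))
        r_lo = generate_landscape(LandscapeConfig(**base, correlation=0.0, seed=8))
        c_hi = np.corrcoef(r_hi[0].values.ravel(), r_hi[1].values.ravel())[0, 1]
        c_lo = np.corrcoef(r_lo[0].values.ravel(), r_lo[1].values.ravel())[0, 1]
        assert c_hi > 0.6 > abs(c_lo) + 0.4

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            LandscapeConfig(extent=(0, 0, 0, 50))


class TestPlaceDetectors:
    def test_one_per_cell_per_occasion_all_moved(self):
        design = StudyDesign(n_cells_x=10, n_cells_y=10, n_occasions=4)
        lay = place_detectors(design, 1)
        assert len(lay.table) == 400
        assert all(len(lay.occasion(s)) == 100 for s in range(1, 5))
        assert len(lay.table[["x", "y"]].drop_duplicates()) == 400

    def test_fixed_sites_identical_across_occasions(self):
        design = StudyDesign(n_cells_x=4, n_cells_y=3, move_sites=False)
        lay = place_detectors(design, 2)
        first = lay.occasion(1)[["detector_id", "x", "y"]].reset_index(drop=True)
        for s in range(2, design.n_occasions + 1):
            cur = lay.occasion(s)[["detector_id", "x", "y"]].reset_index(drop=True)
            assert cur.equals(first)

    def test_detectors_stay_in_their_cells(self):
        design = StudyDesign(n_cells_x=5, n_cells_y=6, cell_size=7.0)
        lay = place_detectors(design, 3)
        for row in lay.table.itertuples():
            ix = row.detector_id % 5
            iy = row.detector_id // 5
            assert ix * 7.0 <= row.x <= (ix + 1) * 7.0
            assert iy * 7.0 <= row.y <= (iy + 1) * 7.0


class TestSimulatePopulation:
    def test_poisson_mean(self):
        # D = 10 per 1000 km^2 over 10,000 km^2 -> E[N] = 100
        mask = make_mask(10, 10, spacing=10.0)
        n = len(simulate_population(mask, {"intercept": np.log(10.0)}, 123))
        assert abs(n - 100) <= 3 * np.sqrt(100)

    def test_rsf_selection_shifts_centers(self):
        mask = make_mask(20, 20, spacing=5.0)
        betas = {"intercept": np.log(100.0), "RSF": 0.3}
        cen = simulate_population(mask, betas, 5)
        assert len(cen) > 500
        # mean RSF at centres should exceed the mask mean under positive selection
        from scipy.spatial import cKDTree

        _, idx = cKDTree(mask.coords).query(cen[["x", "y"]].to_numpy())
        assert mask.points["RSF"].iloc[idx].mean() > mask.points["RSF"].mean() + 0.3

    def test_uniform_when_only_intercept(self):
        # chi-square on quadrat counts non-significant at alpha=0.01 in >=95/100 runs
        mask = make_mask(12, 12, spacing=5.0)
        reject = 0
        for seed in range(100):
            cen = simulate_population(mask, {"intercept": np.log(150.0)}, seed)
            # quadrat edges aligned with mask cell boundaries (extent -2.5..57.5)
            qx = np.digitize(cen["x"], [12.5, 27.5, 42.5])
            qy = np.digitize(cen["y"], [12.5, 27.5, 42.5])
            counts = np.bincount(qx * 4 + qy, minlength=16)
            p = stats.chisquare(counts).pvalue
            reject += p < 0.01
        assert reject <= 5

    def test_overflow_guard(self):
        mask = make_mask(3, 3)
        with pytest.raises(ValueError, match="overflow"):
            simulate_population(mask, {"intercept": 60.0}, 1)

    def test_determinism(self):
        mask = make_mask(6, 6, spacing=5.0)
        a = simulate_population(mask, {"intercept": np.log(50.0)}, 9)
        b = simulate_population(mask, {"intercept": np.log(50.0)}, 9)
        assert a.equals(b)


class TestSimulateDetections:
    def test_certain_detection_at_zero_distance(self):
        import pandas as pd

        lay = make_layouts([(0.0, 0.0)], n_occasions=1)
        cen = pd.DataFrame({"animal_id": ["a"], "sex": ["F"], "x": [0.0], "y": [0.0]})
        cap, cen2 = simulate_detections(cen, lay, (1.0, 2.0), 1)
        assert cap.n_animals == 1 and cen2["detected"].all()

    def test_zero_g0_empty(self):
        import pandas as pd

        lay = make_layouts([(0.0, 0.0)], n_occasions=4)
        cen = pd.DataFrame({"animal_id": ["a"], "sex": ["F"], "x": [0.0], "y": [0.0]})
        cap, _ = simulate_detections(cen, lay, (0.0, 2.0), 1)
        assert cap.n_animals == 0 and len(cap.records) == 0

    def test_binomial_detection_count(self):
        import pandas as pd

        # 100 animals each 5 km from one detector, g0=0.2, sigma=5, 1 occasion
        lay = make_layouts([(0.0, 0.0)], n_occasions=1)
        cen = pd.DataFrame(
            {
                "animal_id": [f"a{i}" for i in range(100)],
                "sex": "F",
                "x": 5.0,
                "y": 0.0,
            }
        )
        p = 0.2 * np.exp(-0.5)
        cap, _ = simulate_detections(cen, lay, (0.2, 5.0), 11)
        sd = np.sqrt(100 * p * (1 - p))
        assert abs(cap.n_animals - 100 * p) <= 3 * sd

    def test_conservation_and_membership(self, sim_constant_study):
        cap = sim_constant_study["capture"]
        cen = sim_constant_study["centers"]
        # every animal in CaptureData has >= 1 detection; detected flag matches
        assert (cap.detections_per_animal() >= 1).all()
        assert set(cap.animals) == set(cen.loc[cen["detected"], "animal_id"])

    def test_detection_distances_match_halfnormal_kernel(self):
        import pandas as pd

        # single animal at a dense line of detectors: detection distances should
        # follow the half-normal sampling density ~ d * exp(-d^2/2s^2) in 2-D,
        # here collapsed to 1-D spacing so density ~ exp(-d^2/2s^2)
        sigma = 5.0
        xs = np.linspace(-30, 30, 1201)
        lay = make_layouts([(x, 0.0) for x in xs], n_occasions=1)
        cen = pd.DataFrame({"animal_id": ["a"], "sex": ["F"], "x": [0.0], "y": [0.0]})
        rng = np.random.default_rng(2)
        dists = []
        for _ in range(40):
            cap, _ = simulate_detections(cen, lay, (0.9, sigma), rng)
            got = lay.table.merge(cap.records, on=["occasion", "detector_id"])
            dists.extend(np.abs(got["x"]).tolist())
        assert len(dists) > 1000
        ks = stats.kstest(np.array(dists) / sigma, stats.halfnorm.cdf)
        assert ks.pvalue > 0.01


class TestSimulateTelemetry:
    def _centers(self, n=1):
        import pandas as pd

        return pd.DataFrame(
            {"animal_id": [f"a{i}" for i in range(n)], "sex": "F", "x": 3.0, "y": -2.0}
        )

    def test_zero_sigma_collapses_to_center(self):
        tel = simulate_telemetry(self._centers(), 1e-12, 20, 1)
        assert np.allclose(tel["x"], 3.0) and np.allclose(tel["y"], -2.0)

    def test_mean_converges_to_center(self):
        tel = simulate_telemetry(self._centers(), 2.0, 10_000, 2)
        assert abs(tel["x"].mean() - 3.0) < 0.05 * 2.0
        assert abs(tel["y"].mean() + 2.0) < 0.05 * 2.0

    def test_circular_normal_mass_within_one_sigma(self):
        tel = simulate_telemetry(self._centers(), 4.0, 10_000, 3)
        r = np.hypot(tel["x"] - 3.0, tel["y"] + 2.0)
        frac = (r < 4.0).mean()
        assert abs(frac - 0.3935) < 0.02


def test_simulate_study_deterministic():
    design = StudyDesign(n_cells_x=4, n_cells_y=4)
    kwargs = dict(
        detection_params={"F": (0.3, 3.0)},
        density_betas={"F": {"intercept": np.log(40.0)}},
        seed=77,
        telemetry_locations=5,
    )
    s1 = simulate_study(design, **kwargs)
    s2 = simulate_study(design, **kwargs)
    assert s1.layouts.table.equals(s2.layouts.table)
    assert s1.capture.records.equals(s2.capture.records)
    assert s1.telemetry.equals(s2.telemetry)
    assert s1.truth.centers.equals(s2.truth.centers)
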