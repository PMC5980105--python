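"""Closed-population (Huggins) models, telemetry residency, combined density."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from secrdsm import (
    ClosedPopulationModel,
    ResidencyModel,
    collapse_to_sessions,
    density_closed_telemetry,
    distance_from_edge,
    simulate_telemetry,
)
from secrdsm.closedpop import history_strings

from .conftest import make_capture, make_layouts


def _histories(strings, sexes=None):
    T = len(strings[0])
    df = pd.DataFrame(
        [[int(c) for c in s] for s in strings],
        columns=range(1, T + 1),
        index=pd.Index([f"a{i}" for i in range(len(strings))], name="animal_id"),
    )
    df["sex"] = sexes or "F"
    return df


class TestCollapse:
    def test_multi_site_occasion_collapses(self):
        lay = make_layouts([(0, 0), (1, 0), (2, 0)], n_occasions=4)
        cap = make_capture(
            [("a1", "F", 2, 0), ("a1", "F", 2, 1), ("a1", "F", 2, 2)], 4, lay
        )
        hist = collapse_to_sessions(cap)
        assert history_strings(hist).loc["a1"] == "0100"

    def test_pooling_never_exceeds_records(self, sim_constant_study):
        cap = sim_constant_study["capture"]
        hist = collapse_to_sessions(cap)
        occ = [c for c in hist.columns if c != "sex"]
        assert hist[occ].to_numpy().sum() <= len(cap.records)

    def test_efficiency_statistic(self, sim_constant_study):
        cap = sim_constant_study["capture"]
        hist = collapse_to_sessions(cap)
        occ = [c for c in hist.columns if c != "sex"]
        share = (hist[occ].sum(axis=1) > 1).mean()
        assert share == pytest.approx(cap.efficiency())


class TestFitClosed:
    def test_m0_matches_grid_search(self):
        hist = _histories(["11", "10", "01", "10"])
        res = ClosedPopulationModel(hist, "M0").fit()
        # independent brute-force maximiser of the conditional likelihood
        grid = np.linspace(0.01, 0.99, 9801)
        ll = np.empty_like(grid)
        H = hist[[1, 2]].to_numpy()
        for i, p in enumerate(grid):
            lp = (H * np.log(p) + (1 - H) * np.log1p(-p)).sum()
            ll[i] = lp - len(H) * np.log(1 - (1 - p) ** 2)
        p_grid = grid[np.argmax(ll)]
        assert res.p[0] == pytest.approx(p_grid, abs=1e-4)
        assert res.loglik >= ll.max() - 1e-6

    def test_certain_detection_gives_n(self):
        hist = _histories(["11", "11", "11"])
        res = ClosedPopulationModel(hist, "M0").fit()
        assert res.N_hat == pytest.approx(3.0, abs=1e-3)

    def test_ht_at_least_n(self):
        for model in ("M0", "Mt", "Mb", "Mh2"):
            hist = _histories(["1100", "0110", "0001", "1000", "1111"])
            res = ClosedPopulationModel(hist, model).fit()
            assert res.N_hat >= len(hist) - 1e-9

    def test_simulation_recovers_abundance(self):
        # N=200, p=0.4, T=4; median over replicates within 5%
        rng = np.random.default_rng(5)
        est = []
        for _ in range(60):
            H = (rng.uniform(size=(200, 4)) < 0.4).astype(int)
            H = H[H.sum(axis=1) > 0]
            df = pd.DataFrame(H, columns=range(1, 5))
            df["sex"] = "F"
            df.index.name = "animal_id"
            est.append(ClosedPopulationModel(df, "M0").fit().N_hat)
        assert np.median(est) == pytest.approx(200, rel=0.05)

    def test_mt_recovers_time_variation(self):
        rng = np.random.default_rng(8)
        p_t = np.array([0.6, 0.2, 0.4, 0.3])
        H = (rng.uniform(size=(500, 4)) < p_t).astype(int)
        H = H[H.sum(axis=1) > 0]
        df = pd.DataFrame(H, columns=range(1, 5))
        df["sex"] = "F"
        res = ClosedPopulationModel(df, "Mt").fit()
        assert np.allclose(res.p, p_t, atol=0.08)

    def test_abundance_interval_contains_estimate(self):
        hist = _histories(["1100", "0110", "0001", "1000", "1111", "0100"])
        ab = ClosedPopulationModel(hist, "M0").fit().abundance()
        assert ab["lcl"] <= ab["N"] <= ab["ucl"]


class TestResidency:
    GRID = box(0.0, 0.0, 60.0, 60.0)

    def _telemetry(self, centers_dist, sigma, n_loc=60, seed=0):
        """Animals with centres at given distances from the west edge."""
        cen = pd.DataFrame(
            {
                "animal_id": [f"t{i}" for i in range(len(centers_dist))],
                "sex": "F",
                "x": centers_dist,
                "y": 30.0,
            }
        )
        return simulate_telemetry(cen, sigma, n_loc, seed)

    def test_signed_distance(self):
        d = distance_from_edge([30.0, -5.0], [30.0, 30.0], self.GRID)
        assert d[0] == pytest.approx(30.0)
        assert d[1] == pytest.approx(-5.0)

    def test_all_inside_flagged_boundary(self):
        tel = self._telemetry([30.0, 25.0, 35.0], sigma=0.5)
        with pytest.warns(UserWarning, match="boundary"):
            res = ResidencyModel(tel, self.GRID).fit()
        assert (res.predict([10.0, 20.0]) > 0.99).all()

    def test_positive_slope_recovered(self):
        rng = np.random.default_rng(3)
        ok = 0
        for rep in range(20):
            tel = self._telemetry(
                np.linspace(2.0, 28.0, 12), sigma=8.0, n_loc=40, seed=rng
            )
            res = ResidencyModel(tel, self.GRID).fit()
            ok += res.slope > 0
        assert ok >= 19

    def test_deep_interior_residency_near_one(self):
        tel = self._telemetry([20.0, 25.0, 30.0, 16.0, 28.0], sigma=3.0, seed=4)
        res = ResidencyModel(tel, self.GRID).fit()
        assert (res.predict(np.array([16.0, 25.0])) > 0.95).all()

    def test_animal_without_inside_locations_excluded(self):
        tel = pd.concat(
            [
                self._telemetry([20.0, 25.0, 30.0], sigma=2.0),
                pd.DataFrame(
                    {"animal_id": "out", "sex": "F", "x": [-40.0, -45.0], "y": 30.0}
                ),
            ]
        )
        with pytest.warns(UserWarning, match="excluded"):
            model = ResidencyModel(tel, self.GRID)
        assert "out" not in set(model.table["animal_id"])


class TestCombinedDensity:
    def _closed(self):
        hist = _histories(["1100", "0110", "0011", "1000", "1111", "0100",
                           "1010", "0101"])
        return ClosedPopulationModel(hist, "M0").fit()

    def test_full_residency_reduces_to_n_over_a(self):
        closed = self._closed()
        d = np.full(closed.n, 20.0)
        out = density_closed_telemetry(closed, 1.0, d, grid_area_km2=3600.0)
        assert out["density_per_1000km2"] == pytest.approx(
            1000.0 * closed.N_hat / 3600.0, rel=1e-10
        )

    def test_half_residency_halves_density(self):
        closed = self._closed()
        d = np.full(closed.n, 20.0)
        full = density_closed_telemetry(closed, 1.0, d, 3600.0)
        half = density_closed_telemetry(closed, 0.5, d, 3600.0)
        assert half["density_per_1000km2"] == pytest.approx(
            full["density_per_1000km2"] / 2.0, rel=1e-10
        )

    def test_mean_vs_per_animal_variants(self):
        closed = self._closed()
        grid = box(0, 0, 60, 60)
        tel = TestResidency()._telemetry(np.linspace(3.0, 28.0, 10), 6.0, seed=9)
        resid = ResidencyModel(tel, grid).fit()
        d = np.linspace(4.0, 25.0, closed.n)
        a = density_closed_telemetry(closed, resid, d, 3600.0, per_animal=True)
        b = density_closed_telemetry(closed, resid, d, 3600.0, per_animal=False)
        # equal-p* closed model: the two weightings coincide
        assert a["density_per_1000km2"] == pytest.approx(
            b["density_per_1000km2"], rel=1e-9
        )
        assert a["lcl"] < a["density_per_1000km2"] < a["ucl"]

    def test_bad_grid_area_rejected(self):
        with pytest.raises(ValueError):
            density_closed_telemetry(self._closed(), 1.0, np.zeros(8), 0.0)
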