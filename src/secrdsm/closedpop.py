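"""Closed-population (Huggins) abundance and telemetry-residency density.

The comparison estimator to SECR: detections are pooled over detectors
within each occasion, detection parameters are estimated by conditional
likelihood (M0 / Mt / Mb / Mh2), abundance by Horvitz-Thompson summation
N-hat = sum_i 1 / p*_i, and density on the grid is corrected for partial
residency predicted from telemetry as a function of an animal's mean
distance from the grid edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit
from statsmodels.tools.numdiff import approx_fprime, approx_hess2

from .data import CaptureData

Z95 = 1.959963984540054

CLOSED_MODELS = ("M0", "Mt", "Mb", "Mh2")


def collapse_to_sessions(capture: CaptureData) -> pd.DataFrame:
    """Animal x occasion binary matrix (detector identity discarded).

    Columns are 1..n_occasions; a ``sex`` column is appended.
    """
    S = capture.n_occasions
    animals = capture.animals
    mat = pd.DataFrame(0, index=pd.Index(animals, name="animal_id"), columns=range(1, S + 1))
    for (a, s), _ in capture.records.groupby(["animal_id", "occasion"]):
        mat.loc[a, s] = 1
    mat["sex"] = capture.sex_of().reindex(animals)
    return mat


def history_strings(histories: pd.DataFrame) -> pd.Series:
    occ = [c for c in histories.columns if c != "sex"]
    return histories[occ].astype(int).astype(str).agg("".join, axis=1)


class ClosedPopulationModel:
    """Huggins-style closed model fit by conditional likelihood.

    Parameters
    ----------
    histories : DataFrame
        Output of :func:`collapse_to_sessions` (a ``sex`` column is ignored).
    model : {"M0", "Mt", "Mb", "Mh2"}
        Constant, time-varying, behavioural (first capture vs recapture), or
        2-class mixture detection.
    """

    def __init__(self, histories: pd.DataFrame, model: str = "M0"):
        if model not in CLOSED_MODELS:
            raise ValueError(f"unknown closed model {model!r}")
        occ = [c for c in histories.columns if c != "sex"]
        H = histories[occ].to_numpy(int)
        if H.ndim != 2 or H.shape[1] < 2:
            raise ValueError("need at least 2 occasions")
        if H.shape[0] < 1 or (H.sum(axis=1) == 0).any():
            raise ValueError("every included animal needs >= 1 detection")
        self.H = H
        self.n, self.T = H.shape
        self.model = model
        self.animal_ids = list(histories.index)
        self.k = {"M0": 1, "Mt": self.T, "Mb": 2, "Mh2": 3}[model]

    # ------------------------------------------------------------ likelihood
    def _probs(self, theta):
        """Per-animal log Pr(history) and first-capture probability p*."""
        H, T, n = self.H, self.T, self.n
        if self.model == "M0":
            p = expit(theta[0])
            P = np.full((n, T), p)
            ll = (H * np.log(P) + (1 - H) * np.log1p(-P)).sum(axis=1)
            pstar = -np.expm1(T * np.log1p(-p))
            return ll, np.full(n, pstar)
        if self.model == "Mt":
            p = expit(theta)
            ll = (H * np.log(p)[None, :] + (1 - H) * np.log1p(-p)[None, :]).sum(axis=1)
            pstar = -np.expm1(np.log1p(-p).sum())
            return ll, np.full(n, pstar)
        if self.model == "Mb":
            p, c = expit(theta[0]), expit(theta[1])
            first = H.argmax(axis=1)  # index of first detection
            ll = np.empty(n)
            for i in range(n):
                f = first[i]
                pre = f * np.log1p(-p)
                post = (
                    H[i, f + 1 :] * np.log(c) + (1 - H[i, f + 1 :]) * np.log1p(-c)
                ).sum()
                ll[i] = pre + np.log(p) + post
            pstar = -np.expm1(T * np.log1p(-p))
            return ll, np.full(n, pstar)
        # Mh2: mixture over two detection classes, shared mixing weight
        pi2 = expit(theta[0])
        p1, p2 = expit(theta[1]), expit(theta[2])
        ll1 = (H * np.log(p1) + (1 - H) * np.log1p(-p1)).sum(axis=1)
        ll2 = (H * np.log(p2) + (1 - H) * np.log1p(-p2)).sum(axis=1)
        m = np.maximum(ll1, ll2)
        ll = m + np.log((1 - pi2) * np.exp(ll1 - m) + pi2 * np.exp(ll2 - m))
        pstar = (1 - pi2) * (-np.expm1(T * np.log1p(-p1))) + pi2 * (
            -np.expm1(T * np.log1p(-p2))
        )
        return ll, np.full(n, pstar)

    def loglik(self, theta) -> float:
        ll, pstar = self._probs(np.asarray(theta, float))
        return float(ll.sum() - np.log(pstar).sum())

    def start_values(self) -> np.ndarray:
        rate = np.clip(self.H.mean(), 0.05, 0.95)
        lp = np.log(rate / (1 - rate))
        if self.model == "M0":
            return np.array([lp])
        if self.model == "Mt":
            return np.full(self.T, lp)
        if self.model == "Mb":
            return np.array([lp, lp])
        return np.array([0.0, lp - 1.0, lp + 1.0])

    def fit(self, start=None) -> "ClosedPopulationResults":
        theta0 = np.asarray(start, float) if start is not None else self.start_values()
        res = optimize.minimize(
            lambda t: -self.loglik(t), theta0, method="L-BFGS-B",
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        H = approx_hess2(res.x, lambda t: -self.loglik(t))
        try:
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(H)
        boundary = bool(np.any(np.abs(res.x) > 12))
        if self.model == "Mh2" and boundary:
            warnings.warn("Mh2 estimate at parameter boundary", stacklevel=2)
        return ClosedPopulationResults(self, res.x, -res.fun, vcov, bool(res.success))


class ClosedPopulationResults:
    """Conditional-likelihood estimates and Horvitz-Thompson abundance."""

    def __init__(self, model, params, loglik, vcov, converged):
        self.model = model
        self.params = np.asarray(params, float)
        self.loglik = float(loglik)
        self.vcov = np.asarray(vcov, float)
        self.converged = converged
        self.n = model.n
        self.k = model.k

    @property
    def p(self) -> np.ndarray:
        """Detection probabilities on the natural scale."""
        return expit(self.params)

    def pstar(self, params=None) -> np.ndarray:
        _, ps = self.model._probs(self.params if params is None else params)
        return ps

    @property
    def N_hat(self) -> float:
        return float((1.0 / self.pstar()).sum())

    def abundance(self) -> dict:
        """N-hat with variance combining HT and parameter uncertainty.

        The interval is log-normal on the undetected count f0 = N - n.
        """
        ps = self.pstar()
        N = float((1.0 / ps).sum())
        var_ht = float(((1.0 - ps) / ps**2).sum())
        grad = approx_fprime(
            self.params, lambda t: float((1.0 / self.pstar(t)).sum()), centered=True
        ).ravel()
        var = var_ht + float(grad @ self.vcov @ grad)
        se = np.sqrt(max(var, 0.0))
        f0 = max(N - self.n, 1e-12)
        c = np.exp(Z95 * np.sqrt(np.log1p((se / f0) ** 2)))
        return {
            "N": N,
            "se": se,
            "lcl": self.n + f0 / c,
            "ucl": self.n + f0 * c,
            "var_ht": var_ht,
        }

    def aicc(self) -> float:
        from .model import aicc as _aicc

        return _aicc(self.loglik, self.k, self.n)


# --------------------------------------------------------------- residency


def distance_from_edge(x, y, polygon) -> np.ndarray:
    """Signed Euclidean distance to the polygon boundary: positive inside."""
    pts = shapely.points(np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]))
    d = shapely.distance(pts, polygon.boundary)
    inside = shapely.contains(polygon, pts)
    return np.where(inside, d, -d)


class ResidencyModel:
    """Binomial (logit) regression of telemetry residency on distance from edge.

    Per animal, residency is the fraction of telemetry locations inside the
    grid polygon; the covariate is the mean distance from the grid edge of
    the *inside-grid* locations only, so it is comparable with mean
    DNA-detection locations of uncollared animals.
    """

    def __init__(self, telemetry: pd.DataFrame, grid_polygon):
        rows = []
        for a, g in telemetry.groupby("animal_id"):
            d = distance_from_edge(g["x"].to_numpy(), g["y"].to_numpy(), grid_polygon)
            inside = d > 0
            if not inside.any():
                warnings.warn(
                    f"animal {a!r} has no inside-grid locations; excluded", stacklevel=2
                )
                continue
            rows.append(
                {
                    "animal_id": a,
                    "sex": g["sex"].iloc[0],
                    "inside": int(inside.sum()),
                    "total": int(len(g)),
                    "mean_edge_distance": float(d[inside].mean()),
                }
            )
        if len(rows) < 2:
            raise ValueError("need >= 2 animals with inside-grid locations")
        self.table = pd.DataFrame(rows)
        self.grid_polygon = grid_polygon

    def fit(self) -> "ResidencyResults":
        t = self.table
        endog = np.column_stack([t["inside"], t["total"] - t["inside"]])
        exog = sm.add_constant(t["mean_edge_distance"].to_numpy(float))
        glm = sm.GLM(endog, exog, family=sm.families.Binomial())
        if (t["inside"] == t["total"]).all():
            warnings.warn(
                "all telemetry locations inside the grid: residency intercept "
                "at the parameter boundary", stacklevel=2,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # perfect-separation chatter
            res = glm.fit(maxiter=200)
        return ResidencyResults(self, res)


class ResidencyResults:
    def __init__(self, model: ResidencyModel, glm_results):
        self.model = model
        self.glm = glm_results
        self.params = np.asarray(glm_results.params, float)
        self.vcov = np.asarray(glm_results.cov_params(), float)

    @property
    def slope(self) -> float:
        return float(self.params[1])

    def plot(self, ax=None, **kwargs):
        """Predicted residency vs distance from the grid edge, with the data."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.table
        d = np.linspace(t["mean_edge_distance"].min(), t["mean_edge_distance"].max(), 100)
        ax.plot(d, self.predict(d), **kwargs)
        ax.scatter(t["mean_edge_distance"], t["inside"] / t["total"], s=12, alpha=0.6)
        ax.set_xlabel("mean distance from grid edge (km)")
        ax.set_ylabel("residency")
        return ax

    def predict(self, distance, params=None) -> np.ndarray:
        """Predicted residency in (0, 1) at a distance-from-edge (km).

        Distances outside the fitted range are clamped predictions with a
        warning (the logit keeps them inside (0, 1) regardless).
        """
        d = np.atleast_1d(np.asarray(distance, float))
        fitted = self.model.table["mean_edge_distance"]
        if (d < fitted.min() - 1e-9).any() or (d > fitted.max() + 1e-9).any():
            warnings.warn("residency predicted outside fitted distance range", stacklevel=2)
        b = self.params if params is None else params
        return expit(b[0] + b[1] * d)


def density_closed_telemetry(
    closed: ClosedPopulationResults,
    residency: ResidencyResults | float,
    detected_distances,
    grid_area_km2: float,
    per_animal: bool = True,
) -> dict:
    """Residency-corrected density (animals per 1000 km^2) on the grid.

    D-hat = sum_i r-hat(dist_i) / p*_i / A: Horvitz-Thompson abundance with
    each detected animal weighted by its predicted residency at its mean
    DNA-detection distance from the grid edge. ``per_animal=False`` uses the
    mean predicted residency as a single multiplier instead. A constant
    residency may be passed directly in place of a fitted model.

    Variance combines the HT component with delta-method propagation over
    the (independent) closed-model and residency-model parameters.
    """
    if grid_area_km2 <= 0:
        raise ValueError("grid area must be positive")
    d = np.asarray(detected_distances, float)
    if d.shape != (closed.n,):
        raise ValueError("need one distance per detected animal")
    fixed_r = not hasattr(residency, "predict")

    def dens(theta_c, theta_r):
        ps = closed.pstar(theta_c)
        if fixed_r:
            r = np.full(closed.n, float(residency))
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = np.clip(residency.predict(d, params=theta_r), 0.0, 1.0)
        if per_animal:
            total = float((r / ps).sum())
        else:
            total = float(r.mean() * (1.0 / ps).sum())
        return 1000.0 * total / grid_area_km2

    theta_c = closed.params
    theta_r = None if fixed_r else residency.params
    D = dens(theta_c, theta_r)
    ps = closed.pstar()
    r = (
        np.full(closed.n, float(residency))
        if fixed_r
        else np.clip(residency.predict(d), 0.0, 1.0)
    )
    var_ht = float((r**2 * (1 - ps) / ps**2).sum()) * (1000.0 / grid_area_km2) ** 2
    gc = approx_fprime(theta_c, lambda t: dens(t, theta_r), centered=True).ravel()
    var = var_ht + float(gc @ closed.vcov @ gc)
    if not fixed_r:
        gr = approx_fprime(theta_r, lambda t: dens(theta_c, t), centered=True).ravel()
        var += float(gr @ residency.vcov @ gr)
    se = np.sqrt(max(var, 0.0))
    if D > 0 and se > 0:
        c = np.exp(Z95 * np.sqrt(np.log1p((se / D) ** 2)))
        lcl, ucl = D / c, D * c
    else:
        lcl = ucl = D
    return {"density_per_1000km2": D, "se": se, "lcl": lcl, "ucl": ucl,
            "mean_residency": float(r.mean())}
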