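"""Maximum-likelihood SECR model fitting, AICc selection, and esa diagnostics.

Usage mirrors statsmodels::

    model = SecrModel(capture, layouts, mask,
                      detection=DetectionModelSpec(g0_terms=("TRI_site",)),
                      density=DensityModelSpec("RSF"))
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from statsmodels.tools.numdiff import approx_hess2

from .data import CaptureData, DetectorLayouts, HabitatMask
from .density import DensityModelSpec
from .detect import DetectionModelSpec, detection_prob
from .likelihood import SecrLikelihood

Z95 = 1.959963984540054


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; n is the number of detected individuals."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} must exceed k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


class SecrModel:
    """Spatially explicit capture-recapture model for one data set.

    Parameters
    ----------
    capture : CaptureData
        Detections of identified individuals (typically one sex; the study
        fits sexes separately).
    layouts : DetectorLayouts
    mask : HabitatMask
    detection : DetectionModelSpec, optional
    density : DensityModelSpec, optional
    """

    def __init__(
        self,
        capture: CaptureData,
        layouts: DetectorLayouts,
        mask: HabitatMask,
        detection: DetectionModelSpec | None = None,
        density: DensityModelSpec | None = None,
    ):
        if capture.n_animals < 1:
            raise ValueError("need at least one detected animal to fit")
        self.capture = capture
        self.layouts = layouts
        self.mask = mask
        self.detection = detection or DetectionModelSpec()
        self.density = density or DensityModelSpec("constant")
        self.engine = SecrLikelihood(capture, layouts, mask, self.detection, self.density)

    # ----------------------------------------------------------------- fitting
    def loglik(self, theta) -> float:
        return self.engine.loglik(theta)

    def start_values(self) -> np.ndarray:
        """Data-driven starting values on the link scales."""
        eng = self.engine
        recs = self.capture.records
        # sigma from the spread of each animal's detection sites (RPSV-like)
        idx = self.layouts.column_index()
        xy = self.layouts.coords()
        ss, cnt = 0.0, 0
        for _, g in recs.groupby("animal_id"):
            cols = [idx[(int(s), d)] for s, d in zip(g["occasion"], g["detector_id"])]
            if len(cols) > 1:
                pts = xy[cols]
                mu = pts.mean(axis=0)
                ss += ((pts - mu) ** 2).sum()
                cnt += len(cols) - 1
        if cnt > 0 and ss > 0:
            sigma0 = float(np.sqrt(ss / (2.0 * cnt)))
        else:
            sigma0 = 2.0 * self.mask.spacing
        sigma0 = max(sigma0, 0.5 * self.mask.spacing)
        # g0 from mean detections per animal across SK exposure near the centre
        mean_det = recs.groupby("animal_id").size().mean()
        eff_sites = max(
            np.pi * sigma0**2 / max(self.mask.spacing, 1e-9) ** 2, 1.0
        )
        g00 = float(np.clip(mean_det / (eff_sites * self.capture.n_occasions), 0.01, 0.7))
        # density: naive n over mask area, per 1000 km^2
        d0 = max(1000.0 * self.capture.n_animals / self.mask.area(), 1e-3)
        theta = np.zeros(eng.n_params)
        names = eng.param_names
        theta[names.index("g0: (Intercept)")] = np.log(g00 / (1 - g00))
        theta[names.index("sigma: (Intercept)")] = np.log(sigma0)
        theta[names.index("D: (Intercept)")] = np.log(d0)
        if eng.detection.has_mixture:
            theta[names.index("pmix: logit(pi2)")] = 0.0
            if "g0: h2 delta" in names:
                theta[names.index("g0: h2 delta")] = 0.5
            if "sigma: h2 delta" in names:
                theta[names.index("sigma: h2 delta")] = 0.5
        return theta

    def fit(self, start=None, method: str = "L-BFGS-B", maxiter: int = 500) -> "SecrResults":
        """Maximise the likelihood by quasi-Newton iteration.

        Non-convergence is flagged on the result, never silent; a boundary
        estimate (g0 -> 1) raises a warning.
        """
        eng = self.engine
        theta0 = np.asarray(start, float) if start is not None else self.start_values()

        def nll(t):
            try:
                return -eng.loglik(t)
            except FloatingPointError:
                return 1e12

        with np.errstate(over="ignore", under="ignore"):
            res = optimize.minimize(
                nll, theta0, method=method,
                options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
            )
        theta = res.x
        ll = -res.fun
        with np.errstate(over="ignore", under="ignore"):
            H = approx_hess2(theta, nll)
        vcov = _safe_inverse(H)
        g0_lp = theta[eng.param_names.index("g0: (Intercept)")]
        if expit(g0_lp) > 0.999:
            warnings.warn("g0 estimate at boundary (g0 -> 1)", stacklevel=2)
        return SecrResults(self, theta, ll, vcov, bool(res.success), res)

    # alias matching the field's naming
    fit_secr = fit


def _safe_inverse(H):
    try:
        vcov = np.linalg.inv(H)
        if np.all(np.isfinite(vcov)) and np.all(np.diag(vcov) > -1e-8):
            return vcov
    except np.linalg.LinAlgError:
        pass
    return np.linalg.pinv(H)


class SecrResults:
    """Fitted SECR model: estimates, uncertainty, AICc, predictions."""

    def __init__(self, model: SecrModel, params, loglik, vcov, converged, optres=None):
        self.model = model
        self.params = np.asarray(params, float)
        self.loglik = float(loglik)
        self.vcov = np.asarray(vcov, float)
        self.converged = bool(converged)
        self.optres = optres
        self.param_names = list(model.engine.param_names)
        self.n = model.capture.n_animals
        self.k = len(self.params)
        # sigma is identifiable only with spatial recaptures
        recs = model.capture.records
        multi = recs.groupby("animal_id")["detector_id"].nunique()
        self.sigma_identifiable = bool((multi > 1).any())

    # ------------------------------------------------------------- inference
    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.vcov), 0.0))

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)

    @property
    def expected_n(self) -> float:
        """Expected number of detected animals under the fit (Lambda-hat)."""
        return self.model.engine.expected_detected(self.params)

    def _link_param(self, name):
        i = self.param_names.index(name)
        return self.params[i], self.bse[i]

    def _positive_estimate(self, name):
        """Back-transform a log-link parameter with a log-normal-style CI."""
        lp, se = self._link_param(name)
        est = np.exp(lp)
        return {
            "estimate": est,
            "se": est * se,  # delta method
            "lcl": np.exp(lp - Z95 * se),
            "ucl": np.exp(lp + Z95 * se),
        }

    @property
    def g0(self) -> dict:
        """g0 at mean covariates (first mixture class), with a logit-scale CI."""
        lp, se = self._link_param("g0: (Intercept)")
        p = expit(lp)
        return {
            "estimate": p,
            "se": p * (1 - p) * se,
            "lcl": expit(lp - Z95 * se),
            "ucl": expit(lp + Z95 * se),
        }

    @property
    def sigma(self) -> dict:
        """Spatial scale of movement (km) at mean covariates."""
        out = self._positive_estimate("sigma: (Intercept)")
        if not self.sigma_identifiable:
            out = {key: float("nan") for key in out}
            out["unidentifiable"] = True
        return out

    @property
    def density(self) -> dict:
        """Baseline density (animals per 1000 km^2), exp(beta_D0)."""
        return self._positive_estimate("D: (Intercept)")

    @property
    def density_params(self) -> np.ndarray:
        i0 = self.param_names.index("D: (Intercept)")
        return self.params[i0:]

    @property
    def density_vcov(self) -> np.ndarray:
        i0 = self.param_names.index("D: (Intercept)")
        return self.vcov[i0:, i0:]

    # ------------------------------------------------------------ predictions
    def predict_density(self, mask: HabitatMask | None = None) -> pd.DataFrame:
        from .density import predict_density

        return predict_density(self, mask)

    def region_abundance(self, flag: str = "inside_grid") -> dict:
        from .density import region_abundance

        return region_abundance(self, flag)

    def detection_function(self, distances) -> np.ndarray:
        """Fitted half-normal kernel at mean covariates (class 1)."""
        return detection_prob(distances, self.g0["estimate"], self.sigma["estimate"])

    def plot_detection_function(self, ax=None, max_distance=None, **kwargs):
        """Plot the fitted half-normal detection kernel vs distance (km)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if max_distance is None:
            s = self.sigma["estimate"]
            max_distance = 4.0 * (s if np.isfinite(s) else self.model.mask.spacing)
        d = np.linspace(0.0, max_distance, 200)
        ax.plot(d, self.detection_function(d), **kwargs)
        ax.set_xlabel("distance from home range centre (km)")
        ax.set_ylabel("detection probability")
        return ax

    def plot_density_surface(self, ax=None, flag=None, **kwargs):
        """Scatter map of the predicted density surface over the mask."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        surf = self.predict_density()
        keep = surf[flag].to_numpy(bool) if flag else np.ones(len(surf), bool)
        sc = ax.scatter(
            surf["x"][keep], surf["y"][keep], c=surf["density"][keep],
            marker="s", **kwargs,
        )
        plt.colorbar(sc, ax=ax, label="density per 1000 km$^2$")
        ax.set_aspect("equal")
        ax.set_xlabel("x (km)")
        ax.set_ylabel("y (km)")
        return ax

    # ---------------------------------------------------------------- summary
    def summary(self) -> str:
        eng = self.model.engine
        lines = [
            "SECR model fit (maximum likelihood)",
            f"  detection: {self.model.detection.describe()}",
            f"  density:   {self.model.density.name}",
            f"  n detected = {self.n}, detectors/occ = {self.model.layouts.n_detectors_per_occasion}, "
            f"occasions = {self.model.capture.n_occasions}, mask points = {len(eng.mask)}",
            f"  logLik = {self.loglik:.3f}   k = {self.k}   AICc = {self.aicc:.3f}   "
            f"converged = {self.converged}",
            "",
            f"  {'parameter':<22}{'coef':>10}{'se':>10}",
        ]
        for name, b, s in zip(self.param_names, self.params, self.bse):
            lines.append(f"  {name:<22}{b:>10.4f}{s:>10.4f}")
        lines.append("")
        g, sg, d = self.g0, self.sigma, self.density
        lines.append(
            f"  g0    = {g['estimate']:.4f}  (95% CI {g['lcl']:.4f}-{g['ucl']:.4f})"
        )
        if self.sigma_identifiable:
            lines.append(
                f"  sigma = {sg['estimate']:.3f} km  (95% CI {sg['lcl']:.3f}-{sg['ucl']:.3f})"
            )
        else:
            lines.append("  sigma unidentifiable (no spatial recaptures); estimate suppressed")
        lines.append(
            f"  D     = {d['estimate']:.3f} /1000 km^2  (95% CI {d['lcl']:.3f}-{d['ucl']:.3f})"
        )
        lines.append(f"  E[n detected] = {self.expected_n:.2f}")
        return "\n".join(lines)


def model_table(fits: dict[str, SecrResults]) -> pd.DataFrame:
    """AICc ranking with Akaike weights and a tied-support flag.

    All fits must be on identical data. ``tied_with_constant`` marks models
    within 2 AICc units of the constant-density model (the convention used to
    report covariate models not clearly better than the null).
    """
    keys = list(fits)
    ns = {fits[k].n for k in keys}
    occ = {fits[k].model.capture.n_occasions for k in keys}
    if len(ns) > 1 or len(occ) > 1:
        raise ValueError("model_table requires fits on identical data")
    rows = []
    for k in keys:
        f = fits[k]
        rows.append({"model": k, "loglik": f.loglik, "k": f.k, "AICc": f.aicc})
    tab = pd.DataFrame(rows)
    tab["dAICc"] = tab["AICc"] - tab["AICc"].min()
    w = np.exp(-tab["dAICc"] / 2.0)
    tab["weight"] = w / w.sum()
    if "constant" in set(tab["model"]):
        base = float(tab.loc[tab["model"] == "constant", "AICc"].iloc[0])
        tab["tied_with_constant"] = (tab["model"] != "constant") & (
            (tab["AICc"] - base).abs() < 2.0
        )
    return tab.sort_values("AICc", kind="mergesort").reset_index(drop=True)


def esa_curve(
    capture: CaptureData,
    layouts: DetectorLayouts,
    grid_polygon,
    g0: float,
    sigma: float,
    buffer_widths,
    spacing: float = 3.5,
) -> pd.DataFrame:
    """Density vs mask buffer width (effective-sampling-area diagnostic).

    For each buffer, builds a mask of that extent around the grid polygon and
    reports esa = a * sum_m pdot(x_m) and the implied density n/esa. Used to
    choose the smallest buffer at which the estimate has stabilised.
    """
    buffer_widths = sorted(float(b) for b in buffer_widths)
    if buffer_widths and buffer_widths[0] < spacing and buffer_widths[0] != 0.0:
        raise ValueError("buffer width below mask spacing")
    n = capture.n_animals
    xy = layouts.coords()
    rows = []
    for b in buffer_widths:
        mask = HabitatMask.from_polygon(grid_polygon, spacing, buffer=b)
        mc = mask.coords
        d2 = ((mc[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        p = np.clip(g0 * np.exp(-d2 / (2.0 * sigma**2)), 0, 1 - 1e-12)
        pd_m = -np.expm1(np.log1p(-p).sum(axis=1))
        esa = mask.cell_area * pd_m.sum()  # km^2
        rows.append({"buffer": b, "esa_km2": esa, "density_per_1000km2": 1000.0 * n / esa})
    out = pd.DataFrame(rows)
    out["rel_change"] = out["density_per_1000km2"].pct_change().abs()
    return out


def choose_buffer(curve: pd.DataFrame, tol: float = 0.01) -> float:
    """Smallest buffer where the density estimate changes < ``tol`` per step."""
    ok = curve["rel_change"] < tol
    for i in range(1, len(curve)):
        if ok.iloc[i]:
            return float(curve["buffer"].iloc[i])
    return float(curve["buffer"].iloc[-1])
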