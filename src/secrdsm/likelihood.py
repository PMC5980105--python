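"""Full SECR likelihood for binary proximity detectors on a habitat mask.

The model treats animal activity centres as an inhomogeneous Poisson point
process with intensity D(x) on the mask (log link), and detections as
independent Bernoulli trials per animal x detector x occasion with a
half-normal kernel. With mask cell area ``a`` (km^2) the log-likelihood of
the n observed capture histories is

    logL = sum_i log[ a * sum_m D(x_m) Pr(omega_i | x_m) ] - Lambda - log n!

where Lambda = a * sum_m D(x_m) * pdot(x_m) is the expected number of
detected animals. Densities are parameterised per 1000 km^2 throughout.

Behavioural-response terms (b, bk) modify detection only for occasions after
the triggering first detection; Lambda and pdot always use the naive
(pre-response) parameters, since an undetected animal never triggers the
response.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln, logsumexp

from .data import CaptureData, DetectorLayouts, HabitatMask
from .density import DensityModelSpec
from .detect import SPECIAL_TERMS, DetectionModelSpec

_PMAX = 1.0 - 1e-12


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


class SecrLikelihood:
    """Vectorised evaluator of the SECR log-likelihood.

    Precomputes squared mask-detector distances, z-scored design matrices for
    the g0/sigma linear predictors over the stacked detector-occasion
    columns, and the per-animal detection column indices.
    """

    def __init__(
        self,
        capture: CaptureData,
        layouts: DetectorLayouts,
        mask: HabitatMask,
        detection: DetectionModelSpec | None = None,
        density: DensityModelSpec | None = None,
    ):
        self.capture = capture
        self.layouts = layouts
        self.mask = mask
        self.detection = detection or DetectionModelSpec()
        self.density = density or DensityModelSpec("constant")

        xy = layouts.coords()  # (SK, 2)
        mc = mask.coords  # (M, 2)
        dx = mc[:, 0][:, None] - xy[:, 0][None, :]
        dy = mc[:, 1][:, None] - xy[:, 1][None, :]
        self.d2 = dx * dx + dy * dy  # (M, SK)
        self.n_cols = xy.shape[0]
        self.occ = layouts.table["occasion"].to_numpy(int)

        self.Xg, self.g_names = self._design(self.detection.g0_terms, "g0")
        self.Xs, self.s_names = self._design(self.detection.sigma_terms, "sigma")
        self.Zd, self.d_names = self._density_design()

        self.param_names = list(self.g_names) + list(self.s_names)
        if self.detection.has_mixture:
            self.param_names.append("pmix: logit(pi2)")
        self.param_names += list(self.d_names)
        self.n_params = len(self.param_names)

        self._index_capture()

    # ------------------------------------------------------------------ setup
    def _design(self, terms, label):
        cols = [np.ones(self.n_cols)]
        names = [f"{label}: (Intercept)"]
        for t in terms:
            if t in ("b", "bk", "h2"):
                continue  # handled structurally, not as a column
            if t == "trend":
                v = self.occ.astype(float)
            else:
                if t not in self.layouts.table.columns:
                    raise ValueError(f"unknown detection covariate {t!r}")
                v = self.layouts.table[t].to_numpy(float)
            cols.append(_standardize(v))
            names.append(f"{label}: {t}")
        for t in terms:  # behavioural offsets come after covariates
            if t == "b":
                names.append(f"{label}: b")
            elif t == "bk":
                names.append(f"{label}: bk")
        for t in terms:
            if t == "h2":
                names.append(f"{label}: h2 delta")
        return np.column_stack(cols), names

    def _density_design(self):
        names = ["D: (Intercept)"]
        cols = [np.ones(len(self.mask))]
        pts = self.mask.points
        ing = pts["inside_grid"].to_numpy(bool) if "inside_grid" in pts else np.ones(len(pts), bool)
        std = {}
        for t in self.density.terms:
            if ":" in t:
                continue
            if t not in pts.columns:
                raise ValueError(f"mask lacks density covariate {t!r}")
            v = pts[t].to_numpy(float)
            mu, sd = v[ing].mean(), v[ing].std()
            std[t] = (v - mu) / (sd if sd > 0 else 1.0)
        for t in self.density.terms:
            if ":" in t:
                a, b = t.split(":")
                cols.append(std[a] * std[b])
            else:
                cols.append(std[t])
            names.append(f"D: {t}")
        return np.column_stack(cols), names

    def _index_capture(self):
        idx = self.layouts.column_index()
        recs = self.capture.records
        self.animal_ids = self.capture.animals
        self.det_cols: list[np.ndarray] = []
        self.b_cols: list[np.ndarray] = []  # columns where the b response is on
        self.bk_cols: list[np.ndarray] = []
        rows, cols_flat = [], []
        need_b = "b" in self.detection.g0_terms + self.detection.sigma_terms
        need_bk = "bk" in self.detection.g0_terms + self.detection.sigma_terms
        by_animal = {a: g for a, g in recs.groupby("animal_id")}
        tab = self.layouts.table
        for a in self.animal_ids:
            g = by_animal[a]
            cols = np.array(
                sorted(idx[(int(s), d)] for s, d in zip(g["occasion"], g["detector_id"])),
                dtype=int,
            )
            self.det_cols.append(cols)
            rows.extend([len(self.det_cols) - 1] * len(cols))
            cols_flat.extend(cols.tolist())
            if need_b:
                first = int(g["occasion"].min())
                self.b_cols.append(np.flatnonzero(self.occ > first))
            else:
                self.b_cols.append(np.empty(0, int))
            if need_bk:
                on = np.zeros(self.n_cols, bool)
                for did, gg in g.groupby("detector_id"):
                    first = int(gg["occasion"].min())
                    on |= (tab["detector_id"].to_numpy() == did) & (self.occ > first)
                self.bk_cols.append(np.flatnonzero(on))
            else:
                self.bk_cols.append(np.empty(0, int))
        self.n = len(self.animal_ids)
        # sparse animal-by-column detection indicator restricted to the union
        # of detected columns (fast path for models without b/bk responses)
        from scipy import sparse

        self.union_cols = np.unique(np.asarray(cols_flat, dtype=int))
        remap = {c: j for j, c in enumerate(self.union_cols)}
        data = np.ones(len(cols_flat))
        self.delta = sparse.csr_matrix(
            (data, (rows, [remap[c] for c in cols_flat])),
            shape=(self.n, len(self.union_cols)),
        )

    # --------------------------------------------------------------- unpacking
    def split(self, theta):
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(f"theta must have length {self.n_params}")
        kg = self.Xg.shape[1]
        ks = self.Xs.shape[1]
        out = {"bg": theta[:kg]}
        pos = kg
        gt, st = self.detection.g0_terms, self.detection.sigma_terms
        out["g_b"] = theta[pos] if "b" in gt else 0.0
        pos += "b" in gt
        out["g_bk"] = theta[pos] if "bk" in gt else 0.0
        pos += "bk" in gt
        out["g_h2"] = theta[pos] if "h2" in gt else 0.0
        pos += "h2" in gt
        out["bs"] = theta[pos : pos + ks]
        pos += ks
        out["s_b"] = theta[pos] if "b" in st else 0.0
        pos += "b" in st
        out["s_bk"] = theta[pos] if "bk" in st else 0.0
        pos += "bk" in st
        out["s_h2"] = theta[pos] if "h2" in st else 0.0
        pos += "h2" in st
        if self.detection.has_mixture:
            out["logit_pi2"] = theta[pos]
            pos += 1
        out["bd"] = theta[pos:]
        if len(out["bd"]) != self.Zd.shape[1]:
            raise ValueError("parameter vector does not match design")
        return out

    def _p_matrix(self, lp_g, lp_s):
        """Detection probability matrix (M, SK) from link-scale predictors."""
        g0 = expit(lp_g)[None, :]
        sig = np.exp(lp_s)[None, :]
        p = g0 * np.exp(-self.d2 / (2.0 * sig * sig))
        return np.clip(p, 0.0, _PMAX)

    def class_predictors(self, pars):
        """Naive (pre-response) link predictors per mixture class."""
        lp_g = self.Xg @ pars["bg"]
        lp_s = self.Xs @ pars["bs"]
        out = []
        for u in range(self.detection.n_classes):
            dg = pars["g_h2"] if u == 1 else 0.0
            ds = pars["s_h2"] if u == 1 else 0.0
            out.append((lp_g + dg, lp_s + ds))
        return out

    def mixture_weights(self, pars):
        if not self.detection.has_mixture:
            return np.array([1.0])
        pi2 = expit(pars["logit_pi2"])
        return np.array([1.0 - pi2, pi2])

    # -------------------------------------------------------------- likelihood
    def log_intensity(self, pars):
        """log expected animals per mask cell: log(a * D_m / 1000)."""
        lp = self.Zd @ pars["bd"]
        if not np.all(np.isfinite(lp)):
            bad = int(np.flatnonzero(~np.isfinite(lp))[0])
            raise FloatingPointError(
                f"non-finite density linear predictor at mask point {bad}"
            )
        return lp + np.log(self.mask.cell_area / 1000.0)

    def loglik(self, theta) -> float:
        pars = self.split(theta)
        if not np.all(np.isfinite(np.asarray(theta, float))):
            raise FloatingPointError("non-finite parameter in theta")
        log_lam = self.log_intensity(pars)  # (M,)
        weights = self.mixture_weights(pars)
        preds = self.class_predictors(pars)

        if len(weights) == 1 and not self.detection.has_behaviour:
            return self._loglik_fast(log_lam, *preds[0])

        total_lambda = 0.0
        per_animal = np.full((len(weights), self.n, len(self.mask)), -np.inf)
        for u, (lp_g, lp_s) in enumerate(preds):
            P = self._p_matrix(lp_g, lp_s)
            L0 = np.log1p(-P)
            B0 = L0.sum(axis=1)  # log Pr(no detection | m)
            pdot_u = -np.expm1(B0)
            total_lambda += weights[u] * float(np.exp(log_lam) @ pdot_u)
            if self.n == 0:
                continue
            L1 = np.log(np.maximum(P, 1e-300))
            D10 = L1 - L0
            if not self.detection.has_behaviour:
                for i, cols in enumerate(self.det_cols):
                    per_animal[u, i] = B0 + D10[:, cols].sum(axis=1)
            else:
                for i, cols in enumerate(self.det_cols):
                    ll = self._animal_loglik_behaviour(i, cols, lp_g, lp_s, pars, P, L0, B0)
                    per_animal[u, i] = ll
        if self.n:
            # mixture-average in probability space, integrate over the mask
            logw = np.log(weights)[:, None, None]
            log_pr = logsumexp(per_animal + logw, axis=0)  # (n, M)
            log_lik_i = logsumexp(log_lam[None, :] + log_pr, axis=1)
            if not np.all(np.isfinite(log_lik_i)):
                bad = self.animal_ids[int(np.flatnonzero(~np.isfinite(log_lik_i))[0])]
                raise FloatingPointError(f"zero marginal likelihood for animal {bad!r}")
            data_term = float(log_lik_i.sum())
        else:
            data_term = 0.0
        return data_term - total_lambda - float(gammaln(self.n + 1))

    def _loglik_fast(self, log_lam, lp_g, lp_s) -> float:
        """Single-class, no-behaviour likelihood with minimal allocations."""
        P = self._p_matrix(lp_g, lp_s)
        L0 = np.log1p(-P)
        B0 = L0.sum(axis=1)
        lam = np.exp(log_lam)
        total_lambda = float(lam @ (-np.expm1(B0)))
        if self.n == 0:
            return -total_lambda
        Pu = P[:, self.union_cols]
        D10 = np.log(np.maximum(Pu, 1e-300)) - L0[:, self.union_cols]
        log_pr = B0[None, :] + (self.delta @ D10.T)  # (n, M)
        A = log_lam[None, :] + log_pr
        amax = A.max(axis=1)
        log_lik_i = amax + np.log(np.exp(A - amax[:, None]).sum(axis=1))
        if not np.all(np.isfinite(log_lik_i)):
            bad = self.animal_ids[int(np.flatnonzero(~np.isfinite(log_lik_i))[0])]
            raise FloatingPointError(f"zero marginal likelihood for animal {bad!r}")
        return float(log_lik_i.sum()) - total_lambda - float(gammaln(self.n + 1))

    def _animal_loglik_behaviour(self, i, cols, lp_g, lp_s, pars, P, L0, B0):
        """Per-animal log Pr(history | m) with b/bk response columns switched."""
        resp = np.zeros(self.n_cols, bool)
        gt, st = self.detection.g0_terms, self.detection.sigma_terms
        lp_g_i = lp_g.copy()
        lp_s_i = lp_s.copy()
        bcols, bkcols = self.b_cols[i], self.bk_cols[i]
        if "b" in gt:
            lp_g_i[bcols] += pars["g_b"]
        if "b" in st:
            lp_s_i[bcols] += pars["s_b"]
        if "bk" in gt:
            lp_g_i[bkcols] += pars["g_bk"]
        if "bk" in st:
            lp_s_i[bkcols] += pars["s_bk"]
        resp[bcols] = True
        resp[bkcols] = True
        rcols = np.flatnonzero(resp)
        ll = B0.copy()
        if rcols.size:
            g0r = expit(lp_g_i[rcols])[None, :]
            sigr = np.exp(lp_s_i[rcols])[None, :]
            Pr = np.clip(
                g0r * np.exp(-self.d2[:, rcols] / (2.0 * sigr * sigr)), 0.0, _PMAX
            )
            ll += (np.log1p(-Pr) - L0[:, rcols]).sum(axis=1)
            # detected columns: swap in the response-adjusted p where needed
            Pfull = P
            for c in cols:
                j = np.searchsorted(rcols, c)
                if j < rcols.size and rcols[j] == c:
                    pc = Pr[:, j]
                else:
                    pc = Pfull[:, c]
                ll += np.log(np.maximum(pc, 1e-300)) - np.log1p(-pc)
        else:
            D10 = np.log(np.maximum(P[:, cols], 1e-300)) - L0[:, cols]
            ll += D10.sum(axis=1)
        return ll

    # ------------------------------------------------------------- diagnostics
    def expected_detected(self, theta) -> float:
        """Lambda: expected number of animals detected at least once."""
        pars = self.split(theta)
        log_lam = self.log_intensity(pars)
        weights = self.mixture_weights(pars)
        tot = 0.0
        for u, (lp_g, lp_s) in enumerate(self.class_predictors(pars)):
            P = self._p_matrix(lp_g, lp_s)
            pdot_u = -np.expm1(np.log1p(-P).sum(axis=1))
            tot += weights[u] * float(np.exp(log_lam) @ pdot_u)
        return tot

    def pdot_vector(self, theta) -> np.ndarray:
        """Mixture-averaged pdot at every mask point."""
        pars = self.split(theta)
        weights = self.mixture_weights(pars)
        out = np.zeros(len(self.mask))
        for u, (lp_g, lp_s) in enumerate(self.class_predictors(pars)):
            P = self._p_matrix(lp_g, lp_s)
            out += weights[u] * (-np.expm1(np.log1p(-P).sum(axis=1)))
        return out

    def animal_log_posterior(self, theta) -> np.ndarray:
        """(n, M) log of D(x_m) * Pr(omega_i | x_m), unnormalised."""
        pars = self.split(theta)
        log_lam = self.log_intensity(pars)
        weights = self.mixture_weights(pars)
        preds = self.class_predictors(pars)
        per = np.full((len(weights), self.n, len(self.mask)), -np.inf)
        for u, (lp_g, lp_s) in enumerate(preds):
            P = self._p_matrix(lp_g, lp_s)
            L0 = np.log1p(-P)
            B0 = L0.sum(axis=1)
            if not self.detection.has_behaviour:
                L1 = np.log(np.maximum(P, 1e-300))
                D10 = L1 - L0
                for i, cols in enumerate(self.det_cols):
                    per[u, i] = B0 + D10[:, cols].sum(axis=1)
            else:
                for i, cols in enumerate(self.det_cols):
                    per[u, i] = self._animal_loglik_behaviour(
                        i, cols, lp_g, lp_s, pars, P, L0, B0
                    )
        logw = np.log(weights)[:, None, None]
        return logsumexp(per + logw, axis=0) + log_lam[None, :]


def secr_loglik(capture, layouts, mask, detection, density, theta) -> float:
    """One-shot SECR log-likelihood (see :class:`SecrLikelihood`)."""
    return SecrLikelihood(capture, layouts, mask, detection, density).loglik(theta)
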