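"""Independent straight-line SECR likelihood for oracle tests.

Deliberately naive: explicit Python loops over mask points, animals,
occasions and detectors, recomputing every quantity (standardisation,
half-normal kernel, mixture weighting, behavioural switches) from first
principles. Kept free of any import from secrdsm.likelihood.
"""

import math

import numpy as np


def _std(v):
    v = np.asarray(v, float)
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def brute_loglik(capture, layouts, mask, detection, density, theta):
    """Direct mask-summation SECR log-likelihood."""
    tab = layouts.table.sort_values(["occasion", "detector_id"], kind="mergesort")
    ncols = len(tab)
    occ = tab["occasion"].to_numpy(int)
    det_ids = tab["detector_id"].tolist()
    xs = tab["x"].to_numpy(float)
    ys = tab["y"].to_numpy(float)

    # --- rebuild design columns exactly as documented (z-scored covariates)
    def design(terms):
        cols = [np.ones(ncols)]
        for t in terms:
            if t in ("b", "bk", "h2"):
                continue
            cols.append(_std(occ if t == "trend" else tab[t].to_numpy(float)))
        return np.column_stack(cols)

    Xg = design(detection.g0_terms)
    Xs = design(detection.sigma_terms)
    theta = np.asarray(theta, float)
    pos = 0
    bg = theta[pos : pos + Xg.shape[1]]
    pos += Xg.shape[1]
    g_b = g_bk = g_h2 = 0.0
    if "b" in detection.g0_terms:
        g_b = theta[pos]; pos += 1
    if "bk" in detection.g0_terms:
        g_bk = theta[pos]; pos += 1
    if "h2" in detection.g0_terms:
        g_h2 = theta[pos]; pos += 1
    bs = theta[pos : pos + Xs.shape[1]]
    pos += Xs.shape[1]
    s_b = s_bk = s_h2 = 0.0
    if "b" in detection.sigma_terms:
        s_b = theta[pos]; pos += 1
    if "bk" in detection.sigma_terms:
        s_bk = theta[pos]; pos += 1
    if "h2" in detection.sigma_terms:
        s_h2 = theta[pos]; pos += 1
    mixture = "h2" in detection.g0_terms or "h2" in detection.sigma_terms
    if mixture:
        pi2 = 1.0 / (1.0 + math.exp(-theta[pos])); pos += 1
        weights = [1.0 - pi2, pi2]
    else:
        weights = [1.0]
    bd = theta[pos:]

    # --- density design over the mask (z-scored over in-grid points)
    pts = mask.points
    ing = pts["inside_grid"].to_numpy(bool) if "inside_grid" in pts else np.ones(len(pts), bool)
    zcols = [np.ones(len(pts))]
    std = {}
    for t in density.terms:
        if ":" in t:
            continue
        v = pts[t].to_numpy(float)
        mu, sd = v[ing].mean(), v[ing].std()
        std[t] = (v - mu) / (sd if sd > 0 else 1.0)
    for t in density.terms:
        if ":" in t:
            a_, b_ = t.split(":")
            zcols.append(std[a_] * std[b_])
        else:
            zcols.append(std[t])
    Z = np.column_stack(zcols)
    D = np.exp(Z @ bd)  # per 1000 km^2
    a = mask.cell_area / 1000.0

    animals = sorted(capture.records["animal_id"].unique().tolist())
    n = len(animals)
    det_sets = {}
    first_occ = {}
    first_at_site = {}
    for aid in animals:
        g = capture.records[capture.records["animal_id"] == aid]
        det_sets[aid] = {
            (int(s), d) for s, d in zip(g["occasion"], g["detector_id"])
        }
        first_occ[aid] = int(g["occasion"].min())
        first_at_site[aid] = {
            d: int(gg["occasion"].min()) for d, gg in g.groupby("detector_id")
        }

    def p_col(j, u, aid=None):
        """Detection probability at column j for class u, animal aid (or naive)."""
        lg = float(Xg[j] @ bg) + (g_h2 if u == 1 else 0.0)
        ls = float(Xs[j] @ bs) + (s_h2 if u == 1 else 0.0)
        if aid is not None:
            if occ[j] > first_occ[aid]:
                lg += g_b
                ls += s_b
            fs = first_at_site[aid].get(det_ids[j])
            if fs is not None and occ[j] > fs:
                lg += g_bk
                ls += s_bk
        g0 = 1.0 / (1.0 + math.exp(-lg))
        sigma = math.exp(ls)
        return g0, sigma

    Lambda = 0.0
    log_lik = []
    for aid in animals:
        log_lik.append(-math.inf)
    for m in range(len(pts)):
        mx, my = pts["x"].iloc[m], pts["y"].iloc[m]
        pdot_mix = 0.0
        for u, w in enumerate(weights):
            prod = 1.0
            for j in range(ncols):
                g0, sg = p_col(j, u)
                dist = math.hypot(xs[j] - mx, ys[j] - my)
                prod *= 1.0 - g0 * math.exp(-(dist**2) / (2 * sg**2))
            pdot_mix += w * (1.0 - prod)
        Lambda += a * D[m] * pdot_mix
        for i, aid in enumerate(animals):
            pr = 0.0
            for u, w in enumerate(weights):
                term = 1.0
                for j in range(ncols):
                    g0, sg = p_col(j, u, aid)
                    dist = math.hypot(xs[j] - mx, ys[j] - my)
                    p = g0 * math.exp(-(dist**2) / (2 * sg**2))
                    if (int(occ[j]), det_ids[j]) in det_sets[aid]:
                        term *= p
                    else:
                        term *= 1.0 - p
                pr += w * term
            contrib = a * D[m] * pr
            if contrib > 0:
                log_lik[i] = np.logaddexp(log_lik[i], math.log(contrib))
    return float(sum(log_lik) - Lambda - math.lgamma(n + 1))
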