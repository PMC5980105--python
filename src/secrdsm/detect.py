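"""Half-normal detection kernel and detection-model specification.

The detection model is the binary proximity-detector form: each animal i with
activity centre X is detected at detector k in occasion s independently with

    p_sk(X) = g0_sk * exp(-d(X, x_sk)^2 / (2 * sigma_sk^2))

where g0 (logit link) and sigma (log link) may depend on site covariates, a
linear session trend, behavioural responses, or a 2-class finite mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: special model terms that are not layout covariate columns
SPECIAL_TERMS = ("trend", "b", "bk", "h2")


def detection_prob(distance, g0, sigma):
    """Half-normal detection probability g0 * exp(-d^2 / (2 sigma^2)).

    Parameters
    ----------
    distance : array_like, km, >= 0
    g0 : probability of detection at distance zero
    sigma : spatial scale of movement, km, > 0
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    g0 = np.asarray(g0, dtype=float)
    if np.any((g0 < 0) | (g0 > 1)):
        raise ValueError("g0 must lie in [0, 1]")
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = g0 * np.exp(-(d**2) / (2.0 * sigma**2))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DetectionModelSpec:
    """Terms entering the g0 and sigma linear predictors.

    Each entry is either a layout covariate column name (entered z-scored over
    detector-occasions), or one of the specials:

    - ``"trend"``: linear trend in occasion index (link scale);
    - ``"b"``: permanent behavioural response after an animal's first
      detection anywhere;
    - ``"bk"``: site-specific behavioural response after the first detection
      at that site;
    - ``"h2"``: 2-class finite mixture (unobserved heterogeneity) on this
      parameter, with one shared mixing proportion.

    The intercept is always present and is not listed.
    """

    g0_terms: tuple[str, ...] = ()
    sigma_terms: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "g0_terms", tuple(self.g0_terms))
        object.__setattr__(self, "sigma_terms", tuple(self.sigma_terms))
        for terms in (self.g0_terms, self.sigma_terms):
            if len(set(terms)) != len(terms):
                raise ValueError("duplicate detection-model terms")

    @property
    def has_mixture(self) -> bool:
        return "h2" in self.g0_terms or "h2" in self.sigma_terms

    @property
    def has_behaviour(self) -> bool:
        return any(t in ("b", "bk") for t in self.g0_terms + self.sigma_terms)

    @property
    def n_classes(self) -> int:
        return 2 if self.has_mixture else 1

    def describe(self) -> str:
        g = "+".join(("1",) + self.g0_terms)
        s = "+".join(("1",) + self.sigma_terms)
        return f"g0~{g}, sigma~{s}"


def pdot(center, layouts, g0, sigma):
    """Probability an animal centred at ``center`` is detected at least once.

    Constant (g0, sigma) across detectors and occasions; the full
    covariate-dependent version lives in the likelihood engine.
    """
    center = np.asarray(center, dtype=float)
    xy = layouts.coords()
    d = np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1])
    p = detection_prob(d, g0, sigma)
    # complement of detection anywhere, product over all detector-occasions
    return float(-np.expm1(np.log1p(-np.minimum(p, 1 - 1e-15)).sum()))


def capture_history_prob(history, center, layouts, g0, sigma):
    """Probability of a specific binary capture history given the centre.

    ``history`` is a set/list of (occasion, detector_id) detections; all other
    detector-occasion cells are non-detections. Constant-parameter form used
    by tests and small diagnostics.
    """
    idx = layouts.column_index()
    cols = []
    for s, d in history:
        if (int(s), d) not in idx:
            raise ValueError(f"history references unknown detector {(s, d)!r}")
        cols.append(idx[(int(s), d)])
    center = np.asarray(center, dtype=float)
    xy = layouts.coords()
    dists = np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1])
    p = np.minimum(detection_prob(dists, g0, sigma), 1 - 1e-15)
    ll = np.log1p(-p).sum()
    for c in cols:
        ll += np.log(p[c]) - np.log1p(-p[c])
    return float(np.exp(ll))
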