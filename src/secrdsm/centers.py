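"""Per-animal home-range-centre estimation from a fitted SECR model.

The posterior over mask points for animal i is proportional to
D-hat(x_m) * Pr(omega_i | x_m); the mode (tabulated against region flags)
and the posterior-mean centroid are both reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp


@dataclass
class CenterEstimate:
    animal_id: object
    sex: object
    weights: np.ndarray  # posterior over mask points, sums to 1
    mode_index: int
    mode_xy: tuple[float, float]
    mean_xy: tuple[float, float]


def center_posterior(results, animal_id) -> CenterEstimate:
    """Posterior distribution of one animal's activity centre over the mask.

    Computed in log space; ties in the mode break toward the lowest
    mask-point index.
    """
    eng = results.model.engine
    if animal_id not in eng.animal_ids:
        raise ValueError(f"animal {animal_id!r} not in capture data")
    i = eng.animal_ids.index(animal_id)
    log_post = eng.animal_log_posterior(results.params)[i]
    norm = logsumexp(log_post)
    if not np.isfinite(norm):
        raise ValueError(f"all-zero posterior weights for animal {animal_id!r}")
    w = np.exp(log_post - norm)
    mode = int(np.argmax(w))  # argmax returns the first (lowest) index on ties
    coords = eng.mask.coords
    mean_xy = tuple(w @ coords)
    sex = eng.capture.records.loc[
        eng.capture.records["animal_id"] == animal_id, "sex"
    ].iloc[0]
    return CenterEstimate(
        animal_id, sex, w, mode, tuple(coords[mode]), mean_xy
    )


def estimate_centers(results) -> pd.DataFrame:
    """Mode and mean centre estimates for every detected animal.

    Region flags on the mask are evaluated at the posterior mode.
    """
    eng = results.model.engine
    log_post = eng.animal_log_posterior(results.params)
    coords = eng.mask.coords
    sex = eng.capture.sex_of()
    rows = []
    flags = [
        c for c in eng.mask.points.columns
        if eng.mask.points[c].dtype == bool and not c.endswith("_filled")
    ]
    for i, a in enumerate(eng.animal_ids):
        norm = logsumexp(log_post[i])
        if not np.isfinite(norm):
            raise ValueError(f"all-zero posterior weights for animal {a!r}")
        w = np.exp(log_post[i] - norm)
        mode = int(np.argmax(w))
        mean_xy = w @ coords
        row = {
            "animal_id": a,
            "sex": sex[a],
            "mode_x": coords[mode, 0],
            "mode_y": coords[mode, 1],
            "mean_x": mean_xy[0],
            "mean_y": mean_xy[1],
        }
        for f in flags:
            row[f] = bool(eng.mask.points[f].iloc[mode])
        rows.append(row)
    return pd.DataFrame(rows)


def proportion_in_region(centers: pd.DataFrame, region) -> tuple[int, int, float]:
    """(count, total, percent) of centre modes in a region.

    ``region`` is a boolean mask-flag column name present in ``centers`` or a
    boolean array aligned with its rows. Percent is rounded to one decimal,
    the convention for reported tallies.
    """
    if len(centers) == 0:
        raise ValueError("no centres supplied")
    flag = (
        centers[region].to_numpy(bool)
        if isinstance(region, str)
        else np.asarray(region, bool)
    )
    count = int(flag.sum())
    total = len(centers)
    return count, total, round(100.0 * count / total, 1)
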