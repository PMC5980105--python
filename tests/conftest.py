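import numpy as np
import pandas as pd
import pytest

from secrdsm import (
    CaptureData,
    DetectorLayouts,
    HabitatMask,
    StudyDesign,
    place_detectors,
    simulate_detections,
    simulate_population,
)


def make_layouts(positions, n_occasions=2, covariates=None):
    """Layouts with the same detector positions every occasion."""
    frames = []
    for s in range(1, n_occasions + 1):
        df = pd.DataFrame(
            {
                "occasion": s,
                "detector_id": range(len(positions)),
                "x": [p[0] for p in positions],
                "y": [p[1] for p in positions],
            }
        )
        for name, vals in (covariates or {}).items():
            df[name] = vals
        frames.append(df)
    return DetectorLayouts(pd.concat(frames, ignore_index=True))


def make_mask(nx=3, ny=3, spacing=2.0, origin=(0.0, 0.0), rng=None):
    xs = origin[0] + spacing * np.arange(nx)
    ys = origin[1] + spacing * np.arange(ny)
    xx, yy = np.meshgrid(xs, ys)
    df = pd.DataFrame({"x": xx.ravel(), "y": yy.ravel()})
    df["inside_grid"] = True
    rng = rng or np.random.default_rng(7)
    df["RSF"] = rng.uniform(1, 10, len(df))
    df["Risk"] = rng.uniform(1, 10, len(df))
    return HabitatMask(df, spacing)


def make_capture(records, n_occasions, layouts=None):
    """records: list of (animal_id, sex, occasion, detector_id)."""
    df = pd.DataFrame(records, columns=["animal_id", "sex", "occasion", "detector_id"])
    return CaptureData(df, n_occasions, layouts)


@pytest.fixture
def tiny_layouts():
    return make_layouts([(0.0, 0.0), (4.0, 0.0)], n_occasions=2,
                        covariates={"TRI_site": [0.3, -1.1]})


@pytest.fixture
def tiny_mask():
    return make_mask(3, 3, spacing=2.0, origin=(-1.0, -1.0))


@pytest.fixture
def tiny_capture(tiny_layouts):
    return make_capture(
        [("a1", "F", 1, 0), ("a1", "F", 2, 1), ("a2", "F", 1, 1)],
        n_occasions=2,
        layouts=tiny_layouts,
    )


@pytest.fixture(scope="session")
def sim_constant_study():
    """Moderate single-sex study under constant density, shared across tests."""
    design = StudyDesign(n_cells_x=10, n_cells_y=10)
    rng = np.random.default_rng(42)
    layouts = place_detectors(design, rng)
    mask = HabitatMask.from_polygon(design.grid_polygon, 3.5, 16.0)
    centers = simulate_population(mask, {"intercept": np.log(30.0)}, rng)
    capture, centers = simulate_detections(centers, layouts, (0.15, 4.0), rng)
    return {
        "design": design,
        "layouts": layouts,
        "mask": mask,
        "centers": centers,
        "capture": capture,
        "truth": {"D": 30.0, "g0": 0.15, "sigma": 4.0},
    }
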