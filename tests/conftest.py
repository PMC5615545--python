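import numpy as np
import pytest
import shapely

from microkrige.geometry import Building, UrbanScene, WalkRoute
from microkrige.preprocess import clean_points_frame, preprocess_records
from microkrige.synthdata import default_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def bare_scene(extent, buildings=(), roads=()):
    """Scene without generator metadata, for hand-built geometry tests."""
    return UrbanScene(extent=extent, buildings=list(buildings), roads=list(roads))


@pytest.fixture
def open_scene():
    return bare_scene((200.0, 200.0))


@pytest.fixture
def wall_scene():
    # a sealing wall across the whole extent, with a corridor above y=160
    wall = Building(shapely.box(95.0, 0.0, 105.0, 200.0), 30.0)
    return bare_scene((200.0, 200.0), buildings=[wall])


@pytest.fixture(scope="session")
def demo():
    """The canonical synthetic bundle (seed 1), preprocessed and thinned."""
    data = default_dataset(seed=1)
    clean = preprocess_records(data["records"])[::5]
    frame = clean_points_frame(clean)
    data["clean_frame"] = frame
    data["points"] = frame[["x", "y"]].to_numpy()
    return data


@pytest.fixture
def scatter20(rng):
    pts = rng.uniform(0.0, 100.0, (20, 2))
    vals = 20.0 + 5.0 * np.sin(pts[:, 0] / 15.0) + rng.normal(0, 1, 20)
    return pts, vals
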