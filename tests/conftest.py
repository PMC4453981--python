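import numpy as np
import pytest
import yaml

from beadsas import fixtures, io_formats, sphere_models


def params_dict(**overrides):
    """A complete, valid analysis-parameter mapping for tests."""
    base = {
        "wide": {"qmin": 0.05, "qmax": 2.0},
        "rg": {"qmin": 0.05, "qmax": 0.6, "fitmin": 0.1, "fitmax": 0.35},
        "rxs1": {"qmin": 0.3, "qmax": 1.0, "fitmin": 0.4, "fitmax": 0.6},
        "rxs2": {"qmin": 0.6, "qmax": 1.4, "fitmin": 0.7, "fitmax": 0.9},
        "sphere": {"cutoff": 4, "boxside": 0.55},
        "hydrate": {"positions": 26, "cutoff": 10},
        "curve": {"qmax": 2.0, "npoints": 200, "radbins": 2000,
                  "smear": False},
        "rfac": {"qmin": 0.1, "qmax": 1.5},
    }
    for dotted, value in overrides.items():
        block, field = dotted.split(".")
        base[block][field] = value
    return base


def write_params(tmp_path, mapping, name="params.yml"):
    path = tmp_path / name
    path.write_text(yaml.safe_dump(mapping))
    return path


@pytest.fixture
def params(tmp_path):
    return io_formats.read_params(write_params(tmp_path, params_dict()))


@pytest.fixture(scope="session")
def ball_cloud():
    """Dense uniform ball of 6000 points, radius 3 nm (analytic truths in
    metadata)."""
    return fixtures.make_atom_cloud(
        fixtures.FixtureSpec("ball", radius=3.0, n_points=6000, seed=7))


@pytest.fixture(scope="session")
def ball_model(ball_cloud):
    return sphere_models.grid_transform(ball_cloud, 0.5, cutoff=4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
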