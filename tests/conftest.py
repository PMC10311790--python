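import numpy as np
import pandas as pd
import pytest

from agbupscale.grids import Grid, RasterStack
from agbupscale.pointcloud import PointCloud
from agbupscale.synth import AllometryModel, SceneConfig, SyntheticStand, generate_stand


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def one_ha_stand():
    return generate_stand({"larch": 0.5, "chinese_pine": 0.5}, 600.0,
                          (0.0, 0.0, 100.0, 100.0), seed=7)


@pytest.fixture
def allometry():
    return AllometryModel()


@pytest.fixture
def normalized_cloud(rng):
    """A plot-like cloud: ground returns near 0 and a vegetation canopy."""
    n_ground, n_veg = 40, 160
    hg = rng.uniform(0.0, 0.15, n_ground)
    hv = rng.uniform(2.0, 18.0, n_veg)
    hn = np.concatenate([hg, hv])
    n = len(hn)
    pc = PointCloud.from_arrays(
        rng.uniform(0, 25, n), rng.uniform(0, 25, n), hn,
        intensity=rng.uniform(100, 900, n), range_=np.full(n, 300.0),
        scan_angle=rng.uniform(-12, 12, n))
    pc.df["hn"] = hn
    pc.df["cls"] = np.where(hn > 0.2, 5, 2)
    return pc


@pytest.fixture
def optical_stack(rng):
    """A 64×64 synthetic reflectance stack with all ten bands."""
    grid = Grid(xmin=0.0, ymax=640.0, nrows=64, ncols=64, px=10.0)
    stack = RasterStack(grid)
    base = 0.25 + 0.05 * np.sin(np.linspace(0, 6, 64))[:, None] * np.ones((64, 64))
    for i, b in enumerate(("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8a",
                           "B11", "B12")):
        stack.add(b, np.clip(base + 0.02 * i + 0.01 * rng.standard_normal((64, 64)),
                             0.01, 0.9), group="a")
    return stack


@pytest.fixture
def sar_stack(rng):
    grid = Grid(xmin=0.0, ymax=640.0, nrows=64, ncols=64, px=10.0)
    stack = RasterStack(grid)
    stack.add("VV", -12.0 + rng.standard_normal((64, 64)), group="c")
    stack.add("VH", -18.0 + rng.standard_normal((64, 64)), group="c")
    return stack
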