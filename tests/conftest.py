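import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from microquant import synthgen

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def gen_config():
    """Generator at its default (study) conditions, fixed seed."""
    return synthgen.GeneratorConfig(seed=123)


@pytest.fixture
def clean_config():
    """Noise-free, background-free generator for exact-value oracles."""
    cfg = synthgen.GeneratorConfig(seed=123)
    cfg.noise.shot_scale = 0.0
    cfg.noise.read_sigma = 0.0
    cfg.background.offset = 0.0
    cfg.background.gradient_slope = 0.0
    return cfg


@pytest.fixture
def clean_droplet(clean_config):
    """One noiseless rendered droplet (150 μm, 20 cells) with ground truth."""
    spec = synthgen.DropletSpec(
        "clean-1", diameter_um=150.0, n_cells=20, marker_scale=1.0, live_fraction=1.0
    )
    return synthgen.render_microtissue(clean_config, spec, seed=7)


@pytest.fixture
def two_arm_design():
    return pd.DataFrame(
        {
            "condition": ["control", "activated"],
            "activated": [False, True],
            "n_droplets": [5, 5],
            "timepoint_days": [7.0, 7.0],
        }
    )


def analytic_disk(size=256, radius=50.0, value=100.0, center=None):
    """A crisp disk on a zero background — the pixel-count oracle scene."""
    if center is None:
        center = ((size - 1) / 2.0, (size - 1) / 2.0)
    yy, xx = np.mgrid[0:size, 0:size]
    disk = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    return disk.astype(float) * value


@pytest.fixture
def disk_image():
    return analytic_disk()
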