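import numpy as np
import pytest

import nanopsd as n
from nanopsd.simulate import NanoclusterTruth, PSDTruth, SyntheticScene


@pytest.fixture(scope="session")
def small_config():
    """A 5x5 um field with the standard generative settings."""
    return n.SimulationConfig(field_width_nm=5000, field_height_nm=5000)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return n.sample_scene(small_config, seed=7)


def make_pair_scene(separation_nm, field_nm=3000.0, axes=(86.0, 189.0),
                    seed=0, molecule_count=150):
    """One 2-NC PSD at the field centre with a given centre separation."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, np.pi)
    cx = cy = field_nm / 2.0
    dx = separation_nm / 2.0 * np.cos(theta)
    dy = separation_nm / 2.0 * np.sin(theta)
    short, long = axes
    ncs = [
        NanoclusterTruth((cx - dx, cy - dy), long, short,
                         rng.uniform(0, np.pi), molecule_count),
        NanoclusterTruth((cx + dx, cy + dy), long, short,
                         rng.uniform(0, np.pi), molecule_count),
    ]
    return SyntheticScene(field_nm, field_nm, [PSDTruth(ncs)], seed)


def make_single_nc_scene(field_nm=3000.0, axes=(86.0, 189.0), orientation=0.0,
                         molecule_count=150, centre=None):
    cx, cy = centre if centre else (field_nm / 2.0, field_nm / 2.0)
    short, long = axes
    nc = NanoclusterTruth((cx, cy), long, short, orientation, molecule_count)
    return SyntheticScene(field_nm, field_nm, [PSDTruth([nc])], 0)
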