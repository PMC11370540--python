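import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from synaptoloc.pipeline import default_analysis_config
from synaptoloc.synthetic_data import SynthConfig, generate_fov, render_spots


@pytest.fixture(scope="session")
def small_fov():
    """A modest FOV with full ground truth shared across recovery tests."""
    config = SynthConfig(
        fov_size_px=(512, 512),
        n_ct_synapses=30,
        n_sensory_synapses=4,
        seed=1,
    )
    images, truth = generate_fov(config)
    return config, images, truth


@pytest.fixture(scope="session")
def analysis_config():
    return default_analysis_config()


@pytest.fixture()
def spot_image():
    """Factory: render Gaussian spots (positions in px) on a zero background."""

    def make(shape, positions_px, amplitudes, sigma_px=2.0):
        positions_nm = np.asarray(positions_px, dtype=float)[:, ::-1] * 50.0  # (r,c)->(x,y)
        return render_spots(
            shape,
            positions_nm,
            np.asarray(amplitudes, dtype=float),
            sigma_nm=sigma_px * 50.0,
            pixel_size_nm=50.0,
        )

    return make
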