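import numpy as np
import pytest

from acinarca.imaging import ImagingMovie
from acinarca.synthetic import GeneratorParams, StimulusProtocol, make_field, render_movie


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def small_movie(rng):
    """30 s, 10 fps, 64x64 px movie of positive noise around 1000 counts."""
    frames = rng.normal(1000, 5, size=(300, 64, 64)).astype(np.float64)
    return ImagingMovie(frames=frames, pixel_um=1.0, fps=10.0, stim_window=(10.0, 22.0))


@pytest.fixture
def quiet_params():
    """Small noiseless field: 64 um at 1 um/px -> 2x2 grid of acini."""
    return GeneratorParams(
        field_size_um=64.0, pixel_um=1.0, responder_prob=1.0,
        latency_mean_s=2.0, latency_sd_s=0.3, noise_sd_dff=0.0, seed=11,
    )


@pytest.fixture
def default_protocol():
    return StimulusProtocol()


@pytest.fixture
def rendered_field(quiet_params, default_protocol):
    geom = make_field(quiet_params)
    movie, truth = render_movie(geom, quiet_params, default_protocol)
    return geom, movie, truth
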