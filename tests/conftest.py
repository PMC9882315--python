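import numpy as np
import pytest

from hyphaquant import synthio


@pytest.fixture()
def hypha():
    """A 40-um straight hypha, tip on the left."""
    return synthio.straight_hypha(40.0)


@pytest.fixture()
def noiseless_optics():
    return synthio.OpticsParams(read_noise_sd=0.0, seed=7)


def render_shape(hypha, pixel_size_um=synthio.DEFAULT_PIXEL_SIZE_UM):
    ny = int(np.ceil(2 * hypha.tip_xy[0] / pixel_size_um)) + 1
    nx = int(np.ceil((hypha.length_um + 2) / pixel_size_um)) + 1
    return ny, nx


@pytest.fixture()
def simulate_and_render():
    """Factory: simulate motility on a hypha and render it, one call."""

    def _run(hypha, params, duration_s=30.0, optics=None, apply_poisson=False):
        optics = optics or synthio.OpticsParams(read_noise_sd=0.0, seed=params.seed + 1)
        truth = synthio.simulate_motility(hypha, params, duration_s)
        movie = synthio.render_movie(
            hypha, truth, optics, render_shape(hypha), apply_poisson=apply_poisson
        )
        return movie, truth

    return _run
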