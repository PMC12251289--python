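import numpy as np
import pytest

from tfmuq import synth
from tfmuq.elastic import (
    SubstrateModel,
    build_spectral_kernel,
    assemble_dense_operator,
)


@pytest.fixture(scope="session")
def substrate():
    return SubstrateModel(E=5000.0, nu=0.45, h=50.0)


@pytest.fixture(scope="session")
def small_operator(substrate):
    """Dense elastic operator on an 8x8 window grid (11 um spacing)."""
    kernel = build_spectral_kernel(substrate, (8, 8), 11.0)
    return assemble_dense_operator(kernel)


@pytest.fixture(scope="session")
def medium_operator(substrate):
    """Dense elastic operator on a 16x16 window grid (11 um spacing)."""
    kernel = build_spectral_kernel(substrate, (16, 16), 11.0)
    return assemble_dense_operator(kernel)


def make_image_pair(
    shape=(256, 256),
    displacement=(2.0, 0.6),
    density=8e-3,
    snr_db=50.0,
    seed=0,
):
    """Synthetic bead image pair under a uniform shift."""
    rng = np.random.default_rng(seed)
    beads = synth.generate_bead_field(shape, density, rng)
    moved = synth.apply_displacement(
        beads, synth.DisplacementSpec.uniform(displacement), shape
    )
    ref = synth.add_pixel_noise(synth.render_image(beads, shape), snr_db, rng)
    ses = synth.add_pixel_noise(synth.render_image(moved, shape), snr_db, rng)
    return ref, ses


@pytest.fixture()
def uniform_pair():
    return make_image_pair()
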