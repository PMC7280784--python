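import numpy as np
import pytest

from mtrepair.mechanics import (
    FilamentShape,
    MechanicalParams,
    UniformFlow,
    equilibrium_shape,
)

PIXEL = 0.063  # um per camera pixel


@pytest.fixture(scope="session")
def perp_flow():
    """Uniform flow perpendicular to the clamp axis, 100 um/s."""
    return UniformFlow(0.0, 100.0)


@pytest.fixture(scope="session")
def default_params():
    return MechanicalParams(kappa=50.0, mu=1e-3, g=1.0)


@pytest.fixture(scope="session")
def bent_shape(default_params, perp_flow):
    """Forward-model equilibrium shape at kappa = 50, L = 10 um."""
    return equilibrium_shape(default_params, 10.0, perp_flow, n_nodes=61)


def noisy_measured(shape, rng, sigma=PIXEL, offset=None):
    """A measured version of a model shape: noise + resampling, fit-ready."""
    pts = shape.points + rng.normal(0.0, sigma, shape.points.shape)
    if offset is not None:
        pts = pts + np.asarray(offset)
    return FilamentShape.from_points_resampled(
        pts, n_points=shape.n_points, smoothing=2 * shape.n_points * sigma**2
    )
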