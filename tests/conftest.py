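import numpy as np
import pytest

from tractobench import (
    assemble_phantom,
    bottleneck_phantom,
    canonical_phantom,
)


@pytest.fixture(scope="session")
def canonical():
    """Canonical 5-bundle phantom (crossing + arc + bottleneck), built once."""
    spec = canonical_phantom(rng_seed=0)
    field, bundles = assemble_phantom(spec)
    return spec, field, bundles


@pytest.fixture(scope="session")
def bottleneck():
    """Minimal two-bundle bottleneck phantom, built once."""
    spec = bottleneck_phantom(rng_seed=0)
    field, bundles = assemble_phantom(spec)
    return spec, field, bundles


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_streamline(rng, n_points=8, scale=20.0):
    """A smooth-ish random polyline: random walk with distinct steps."""
    steps = rng.normal(size=(n_points - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    start = rng.uniform(0, scale, size=3)
    return np.vstack([start, start + np.cumsum(steps * rng.uniform(
        0.5, 2.0, size=(n_points - 1, 1)), axis=0)])
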