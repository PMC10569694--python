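import numpy as np
import pytest

from stereocount import (
    PhantomSpec,
    compute_features,
    generate_phantom,
    sample_annotations,
    train,
)

# a small, fast phantom for unit tests: ~0.0013 mm^3, ~40 nuclei
SMALL_SPEC = PhantomSpec(extent=(18, 64, 64), spacing=(4.0, 1.8, 1.8), seed=7)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_features(small_phantom):
    volume, _ = small_phantom
    return compute_features(volume)


@pytest.fixture(scope="session")
def small_annotations(small_phantom):
    _, truth = small_phantom
    return sample_annotations(truth, n_nuclei=15, seed=7)


@pytest.fixture(scope="session")
def small_model(small_features, small_annotations):
    return train(small_features, small_annotations, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def render_sphere_mask(shape, spacing, center_um, radius_um):
    """Analytic sphere rasterizer used as an independent construction
    oracle by several tests (no dependency on the package's renderer)."""
    sp = np.asarray(spacing, dtype=float)
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, sp)], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_um))
    return d2 <= radius_um**2
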