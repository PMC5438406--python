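"""Shared fixtures: phantoms and surfaces are expensive, built once."""

import numpy as np
import pytest

from neomorph import PhantomSpec, make_phantom
from neomorph.morphometry import extract_inner_surface, extract_outer_surface


@pytest.fixture(scope="session")
def sphere_phantom():
    """Default concentric-sphere phantom at 0.5 mm with closed-form truth."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def sphere_surfaces(sphere_phantom):
    """Inner and outer cortical surfaces of the sphere phantom."""
    vol, _ = sphere_phantom
    return extract_inner_surface(vol), extract_outer_surface(vol)


@pytest.fixture(scope="session")
def coarse_phantom():
    """1 mm phantom: cheap input for determinism/contract tests."""
    return make_phantom(PhantomSpec(spacing=(1.0,) * 3, shape=(90,) * 3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
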