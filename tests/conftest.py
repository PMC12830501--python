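"""Shared fixtures: small Monte Carlo kernel sets and toy phantoms.

Session-scoped so the (comparatively expensive) positron transport runs once.
"""

import numpy as np
import pytest

from gaprc.kernels import (BONE, GA68, LUNG, WATER, build_kernel,
                           make_default_kernels, transport_positrons)

PET_VOXEL = (2.73, 2.73, 2.80)


@pytest.fixture(scope="session")
def water_endpoints():
    return transport_positrons(GA68, WATER, 50_000, seed=11)


@pytest.fixture(scope="session")
def water_kernel(water_endpoints):
    return build_kernel(water_endpoints, PET_VOXEL, 8.8, WATER)


@pytest.fixture(scope="session")
def small_kernels():
    """Per-tissue kernels at reduced Monte Carlo size for operator tests."""
    return make_default_kernels(PET_VOXEL, n=40_000, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
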