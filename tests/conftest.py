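"""Shared fixtures: small bundles and generator outputs reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from cortnet.sourcemodel import (
    compute_inverse_operator,
    make_identity_bundle,
    make_toy_bundle,
)

FS = 250.0


@pytest.fixture(scope="session")
def identity_bundle():
    return make_identity_bundle(12)


@pytest.fixture(scope="session")
def toy_bundle():
    """Small spherical head model (fast; full-size geometry is exercised
    in the acceptance tests)."""
    return make_toy_bundle(n_sensors=32, n_sources=256, n_parcels=16, seed=0)


@pytest.fixture(scope="session")
def toy_inverse(toy_bundle):
    return compute_inverse_operator(toy_bundle)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
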