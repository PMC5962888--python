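"""Shared fixtures: geometry, lead fields and small simulated recordings.

Everything heavy (lead field on the reduced 812-vertex grid, simulated
blocks) is session-scoped so the suite builds each object once.
"""

from __future__ import annotations

import numpy as np
import pytest

from teptools.forward import lead_field
from teptools.headmodel import (
    build_source_space,
    build_sphere_model,
    define_parcels,
)
from teptools.montage import build_montage, cluster_map


@pytest.fixture(scope="session")
def montage():
    return build_montage()

@pytest.fixture(scope="session")
def clusters(montage):
    return cluster_map(montage)


@pytest.fixture(scope="session")
def sphere():
    return build_sphere_model()


@pytest.fixture(scope="session")
def space_reduced():
    return build_source_space(n_sources=812)


@pytest.fixture(scope="session")
def parcels_reduced(space_reduced):
    return define_parcels(space_reduced)


@pytest.fixture(scope="session")
def leadfield_reduced(sphere, montage, space_reduced):
    return lead_field(sphere, montage, space_reduced)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240517)
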