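"""Shared fixtures: toy crystals and simulated data, built once per session."""

import numpy as np
import pytest

from gridhar.density import (
    AsphericalDeformationSource,
    BondDeformation,
    SphericalPromoleculeSource,
    form_factors_from_source,
)
from gridhar.synthetic import SimulationSpec, make_toy_structure, simulate_reflections


@pytest.fixture(scope="session")
def sph_source():
    return SphericalPromoleculeSource()


@pytest.fixture(scope="session")
def diatomic(sph_source):
    """Noise-free C-H diatomic in P1 with its simulated data."""
    structure = make_toy_structure("diatomic_P1")
    spec = SimulationSpec(kind="diatomic_P1", d_min=0.9)
    reflections = simulate_reflections(structure, sph_source, spec)
    return structure, reflections


@pytest.fixture(scope="session")
def inversion_pair(sph_source):
    """Centrosymmetric N-H toy (origin pinned by symmetry), noise-free data."""
    structure = make_toy_structure("inversion_pair_P-1")
    spec = SimulationSpec(kind="inversion_pair_P-1", d_min=0.9)
    reflections = simulate_reflections(structure, sph_source, spec)
    return structure, reflections


@pytest.fixture(scope="session")
def special_toy(sph_source):
    """Special-position toy with noise-free data and its form factors."""
    structure = make_toy_structure("special_position_toy")
    spec = SimulationSpec(kind="special_position_toy", d_min=0.9)
    reflections = simulate_reflections(structure, sph_source, spec)
    ff = form_factors_from_source(structure, sph_source, reflections.hkl)
    return structure, reflections, ff


@pytest.fixture(scope="session")
def deformed_diatomic():
    """C-H diatomic with the H valence density pulled toward C, plus data."""
    structure = make_toy_structure("diatomic_P1")
    source = AsphericalDeformationSource([BondDeformation("H1", "C1", p=1.0)])
    spec = SimulationSpec(kind="diatomic_P1", d_min=0.9)
    reflections = simulate_reflections(structure, source, spec)
    return structure, source, reflections
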