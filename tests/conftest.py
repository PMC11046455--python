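"""Shared fixtures: expensive electronic-structure objects are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from apace_pdft.apc import ActiveSpace
from apace_pdft.backend import build_grid, run_casscf, run_mean_field
from apace_pdft.fixtures import make_h2, make_h_atom, two_h_atoms


@pytest.fixture(scope="session")
def h2_eq():
    return make_h2(0.74)


@pytest.fixture(scope="session")
def h2_scf(h2_eq):
    return run_mean_field(h2_eq, "cc-pvdz")


@pytest.fixture(scope="session")
def h2_cas(h2_scf, h2_eq):
    space = ActiveSpace(2, 2, [0, 1], ["from_docc", "from_virtual"])
    return run_casscf(h2_scf, space, h2_eq)


@pytest.fixture(scope="session")
def h2_grid(h2_eq):
    return build_grid(h2_eq, "cc-pvdz", level=2)


@pytest.fixture(scope="session")
def h2_far():
    return two_h_atoms(100.0)


@pytest.fixture(scope="session")
def h2_far_scf(h2_far):
    return run_mean_field(h2_far, "cc-pvdz")


@pytest.fixture(scope="session")
def h_atom_scf():
    return run_mean_field(make_h_atom(), "cc-pvdz")


@pytest.fixture(scope="session")
def h2_sto_scf():
    return run_mean_field(make_h2(0.74), "sto-3g")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
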