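import numpy as np
import pytest

from ce1p.constants import ANGSTROM_TO_BOHR
from ce1p.fixtures import water_dimer, water_monomer
from ce1p.wfn import Molecule, compute_monomer_wavefunction


@pytest.fixture(scope="session")
def water_wfn():
    return compute_monomer_wavefunction(water_monomer())


@pytest.fixture(scope="session")
def water_pair():
    molA, molB = water_dimer()
    wA = compute_monomer_wavefunction(molA)
    wB = compute_monomer_wavefunction(molB)
    return wA, wB


@pytest.fixture(scope="session")
def water_components(water_pair):
    from ce1p.ce_terms import interaction_components

    return interaction_components(*water_pair)


@pytest.fixture(scope="session")
def na_cation():
    return compute_monomer_wavefunction(Molecule(("Na",), [[0, 0, 0]], charge=1))


@pytest.fixture(scope="session")
def cl_anion():
    return compute_monomer_wavefunction(Molecule(("Cl",), [[0, 0, 0]], charge=-1))


@pytest.fixture(scope="session")
def helium():
    return compute_monomer_wavefunction(Molecule(("He",), [[0, 0, 0]]))


def he_at(z_bohr: float):
    return compute_monomer_wavefunction(Molecule(("He",), [[0, 0, z_bohr]]))


@pytest.fixture(scope="session")
def h2_wfn():
    # H2 at equilibrium 1.4 bohr
    return compute_monomer_wavefunction(
        Molecule(("H", "H"), [[0, 0, 0], [0, 0, 1.4]]))
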