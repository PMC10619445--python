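"""Wavefunction provider, rigid-motion transforms, superposition, Löwdin."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import ce1p.integrals as ints
from ce1p import molden, archive
from ce1p.fixtures import water_monomer
from ce1p.grids import molecular_grid
from ce1p.wfn import (Molecule, OpenShellError, ProviderError, Wavefunction,
                      compute_monomer_wavefunction, concatenate,
                      lowdin_monomer_charges, lowdin_orthonormalize,
                      transform_wavefunction, read_xyz, write_xyz)


def rot(seed):
    R = Rotation.random(random_state=seed).as_matrix()
    return R if np.linalg.det(R) > 0 else -R


class TestProvider:
    def test_water_electron_count(self, water_wfn):
        assert water_wfn.mo_coeff.shape[1] == 5
        assert water_wfn.n_electrons == 10.0
        water_wfn.validate()

    def test_sodium_cation(self, na_cation):
        assert na_cation.n_electrons == 10.0
        assert na_cation.charge == 1
        na_cation.validate()

    def test_determinism(self, helium):
        w2 = compute_monomer_wavefunction(Molecule(("He",), [[0, 0, 0]]))
        assert abs(w2.scf_energy - helium.scf_energy) < 1e-10
        assert np.abs(np.abs(w2.mo_coeff) - np.abs(helium.mo_coeff)).max() < 1e-8

    def test_open_shell_rejected(self):
        with pytest.raises(OpenShellError):
            compute_monomer_wavefunction(Molecule(("H",), [[0, 0, 0]]))

    def test_unknown_method_and_element(self):
        with pytest.raises(ProviderError):
            compute_monomer_wavefunction(water_monomer(), method="MP2")
        with pytest.raises(ProviderError):
            compute_monomer_wavefunction(water_monomer(), method="B3LYP")
        with pytest.raises(ValueError, match="[Uu]nknown element|not covered"):
            compute_monomer_wavefunction(Molecule(("Xx",), [[0, 0, 0]]))


class TestTransform:
    def test_identity_is_bitwise(self, water_wfn):
        w2 = transform_wavefunction(water_wfn, np.eye(3), np.zeros(3))
        assert np.array_equal(w2.mo_coeff, water_wfn.mo_coeff)

    def test_density_preserved_at_mapped_points(self, water_wfn):
        R, t = rot(3), np.array([1.0, -2.0, 0.5])
        w2 = transform_wavefunction(water_wfn, R, t)
        w2.validate()  # orthonormality in the transformed metric
        pts = np.random.default_rng(0).normal(scale=1.5, size=(50, 3))
        assert np.abs(water_wfn.density_at(pts)
                      - w2.density_at(pts @ R.T + t)).max() < 1e-10

    def test_group_property(self, water_wfn):
        R1, t1 = rot(4), np.array([0.3, 0.1, -0.2])
        R2, t2 = rot(5), np.array([-1.0, 0.4, 0.8])
        wa = transform_wavefunction(transform_wavefunction(water_wfn, R1, t1), R2, t2)
        wb = transform_wavefunction(water_wfn, R2 @ R1, R2 @ t1 + t2)
        assert np.abs(wa.mo_coeff - wb.mo_coeff).max() < 1e-12

    def test_improper_rejected(self, water_wfn):
        with pytest.raises(Exception):
            transform_wavefunction(water_wfn, -np.eye(3))


class TestConcatenate:
    def test_with_empty(self, water_wfn):
        empty = Wavefunction([], [], np.zeros((0, 0)), np.zeros(0), 0.0,
                             water_wfn.method, water_wfn.basis, 0)
        d = concatenate(water_wfn, empty)
        assert np.array_equal(d.mo_coeff, water_wfn.mo_coeff)
        assert d.n_electrons == water_wfn.n_electrons

    def test_occupation_additivity_and_grid_count(self, water_pair):
        wA, wB = water_pair
        d = concatenate(wA, wB)
        assert d.n_electrons == wA.n_electrons + wB.n_electrons
        grid = molecular_grid([a.symbol for a in d.atoms], d.positions)
        n = float(np.dot(grid.weights, d.density_at(grid.points)))
        assert n == pytest.approx(20.0, abs=1e-5)

    def test_mismatched_labels_rejected(self, water_wfn, water_pair):
        other = water_pair[1].copy()
        other.method = "B3LYP"
        with pytest.raises(ValueError, match="method/basis"):
            concatenate(water_wfn, other)

    def test_coincident_nuclei_rejected(self, water_wfn):
        with pytest.raises(ValueError, match="coincident"):
            concatenate(water_wfn, water_wfn.copy())


class TestLowdin:
    def test_far_identical_neutrals_zero_charge(self, water_wfn):
        wB = transform_wavefunction(water_wfn, np.eye(3), np.array([0, 0, 40.0]))
        d = lowdin_orthonormalize(concatenate(water_wfn, wB))
        qA, qB = lowdin_monomer_charges(d, range(3))
        assert abs(qA) < 1e-6 and abs(qB) < 1e-6

    def test_charge_conservation(self, na_cation, cl_anion):
        wB = transform_wavefunction(cl_anion, np.eye(3), np.array([0, 0, 6.0]))
        d = lowdin_orthonormalize(concatenate(na_cation, wB))
        qA, qB = lowdin_monomer_charges(d, [0])
        assert qA + qB == pytest.approx(0.0, abs=1e-10)

    def test_h2_pair_matches_dense_oracle(self, h2_wfn):
        wB = transform_wavefunction(h2_wfn, np.eye(3), np.array([0, 0, 5.0]))
        d = lowdin_orthonormalize(concatenate(h2_wfn, wB))
        qA, qB = lowdin_monomer_charges(d, [0, 1])
        # independent full-matrix computation
        S = ints.overlap(d.shell_arrays)
        w_, V = np.linalg.eigh(S)
        S12 = V @ np.diag(np.sqrt(w_)) @ V.T
        P = d.density()
        pop = np.diag(S12 @ P @ S12)
        ao_atom = []
        for sh in d.shells:
            ao_atom.extend([sh.center] * sh.nbf)
        ao_atom = np.array(ao_atom)
        qA_ref = 2.0 - pop[ao_atom < 2].sum()
        assert qA == pytest.approx(qA_ref, abs=1e-10)
        assert qB == pytest.approx(-qA_ref, abs=1e-10)


class TestIO:
    def test_molden_roundtrip(self, water_wfn, tmp_path):
        p = tmp_path / "w.molden"
        molden.write_molden(p, water_wfn)
        w2 = molden.read_molden(p)
        w2.validate()
        assert np.abs(w2.mo_coeff - water_wfn.mo_coeff).max() < 1e-12
        assert w2.method == water_wfn.method
        assert abs(w2.scf_energy - water_wfn.scf_energy) < 1e-12

    def test_archive_roundtrip(self, water_wfn, tmp_path):
        p = tmp_path / "w.h5"
        archive.save_wavefunction(p, water_wfn)
        w2 = archive.load_wavefunction(p)
        w2.validate()
        assert np.array_equal(w2.mo_coeff, water_wfn.mo_coeff)
        assert w2.basis == water_wfn.basis

    def test_xyz_roundtrip(self, tmp_path):
        mol = water_monomer()
        p = tmp_path / "w.xyz"
        write_xyz(p, mol, "test")
        mol2 = read_xyz(p)
        assert mol2.symbols == mol.symbols
        assert np.abs(mol2.positions - mol.positions).max() < 1e-8
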