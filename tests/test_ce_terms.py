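"""Interaction-energy components: oracles, limits and presets."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ce1p.ce_terms import (InteractionComponents, charge_transfer_check,
                           coulomb_energy, coulomb_exchange_repulsion,
                           electric_field, exchange_repulsion,
                           polarization_energy, preset_scale_factors,
                           total_interaction)
from ce1p.constants import HARTREE_TO_KJMOL
from ce1p.grids import molecular_grid
from ce1p.wfn import Molecule, compute_monomer_wavefunction, transform_wavefunction
from ce1p.xdm import AtomicXDMData
from conftest import he_at


def fake_xdm(symbol, alpha):
    # unit-volume-ratio data with a prescribed effective polarizability
    return AtomicXDMData(symbol, 1.0, 1.0, 1.0, 1.0, 1.0, alpha)


class TestCoulomb:
    def test_ion_pair_point_multipole_limit(self, na_cation, cl_anion):
        wB = transform_wavefunction(cl_anion, np.eye(3), np.array([0, 0, 20.0]))
        e = coulomb_energy(na_cation, wB)
        assert e == pytest.approx(-1 / 20.0, abs=1e-3)

    def test_neutral_long_range(self, helium):
        e = coulomb_energy(helium, he_at(30.0))
        assert abs(e) < 1e-6

    def test_rigid_rotation_invariance(self, h2_wfn):
        wB = transform_wavefunction(h2_wfn, np.eye(3), np.array([0, 0, 5.0]))
        e0 = coulomb_energy(h2_wfn, wB)
        R = Rotation.random(random_state=9).as_matrix()
        if np.linalg.det(R) < 0:
            R = -R
        e1 = coulomb_energy(transform_wavefunction(h2_wfn, R),
                            transform_wavefunction(wB, R))
        assert abs(e1 - e0) < 1e-9

    def test_far_copy_vs_taylor_multipole_oracle(self, water_wfn):
        """E_coul at 25 bohr vs a Taylor expansion of the partner potential
        through second moments (independent grid + finite-difference route)."""
        from ce1p.ce_terms import electrostatic_potential

        t = np.array([0.0, 0.0, 25.0])
        wB = transform_wavefunction(water_wfn, np.eye(3), t)
        e = coulomb_energy(water_wfn, wB)
        # multipole moments of A about its nuclear centroid, on a Becke grid
        syms = [a.symbol for a in water_wfn.atoms]
        grid = molecular_grid(syms, water_wfn.positions)
        rho = water_wfn.density_at(grid.points)
        center = water_wfn.positions.mean(axis=0)
        disp = grid.points - center
        q = -np.dot(grid.weights, rho)
        mu = -(grid.weights[:, None] * rho[:, None] * disp).sum(axis=0)
        Q = -(grid.weights[:, None, None] * rho[:, None, None]
              * disp[:, :, None] * disp[:, None, :]).sum(axis=0)
        for a in water_wfn.atoms:
            d = a.position - center
            q += a.nuclear_charge
            mu += a.nuclear_charge * d
            Q += a.nuclear_charge * np.outer(d, d)
        # derivatives of B's potential at the centroid (finite differences)
        h = 1e-3
        pts = [center]
        for i in range(3):
            e_i = np.zeros(3)
            e_i[i] = h
            pts += [center + e_i, center - e_i]
        for i in range(3):
            for j in range(i + 1, 3):
                e_i, e_j = np.zeros(3), np.zeros(3)
                e_i[i] = h
                e_j[j] = h
                pts += [center + e_i + e_j, center + e_i - e_j,
                        center - e_i + e_j, center - e_i - e_j]
        phi = electrostatic_potential(wB, np.array(pts))
        grad = np.array([(phi[1 + 2 * i] - phi[2 + 2 * i]) / (2 * h)
                         for i in range(3)])
        hess = np.zeros((3, 3))
        for i in range(3):
            hess[i, i] = (phi[1 + 2 * i] + phi[2 + 2 * i] - 2 * phi[0]) / h ** 2
        k = 7
        for i in range(3):
            for j in range(i + 1, 3):
                hess[i, j] = hess[j, i] = (phi[k] - phi[k + 1] - phi[k + 2]
                                           + phi[k + 3]) / (4 * h * h)
                k += 4
        e_mp = q * phi[0] + mu @ grad + 0.5 * np.einsum("ab,ab->", Q, hess)
        assert e == pytest.approx(e_mp, rel=0.01)


class TestExchangeRepulsion:
    def test_zero_cross_overlap_kills_repulsion(self, water_pair):
        _, e_rep = exchange_repulsion(*water_pair, _zero_cross_overlap=True)
        assert abs(e_rep) < 5e-11   # algebraic zero up to float cancellation

    def test_far_separation_limits(self, helium):
        e_exch, e_rep = exchange_repulsion(helium, he_at(40.0))
        assert abs(e_exch) < 1e-12
        assert abs(e_rep) < 1e-10

    def test_h2_pair_against_dense_determinant_oracle(self, h2_wfn):
        import ce1p.integrals as ints
        from ce1p.scf import nuclear_repulsion
        from ce1p.wfn import concatenate, lowdin_orthonormalize

        wB = transform_wavefunction(h2_wfn, np.eye(3), np.array([0, 0, 5.0]))
        e_exch, e_rep = exchange_repulsion(h2_wfn, wB)
        assert e_rep > 0 and e_exch < 0
        # brute force with the full ERI tensor and einsum contractions
        d = concatenate(h2_wfn, wB)
        sa = d.shell_arrays
        eri = ints.eri_full(sa)
        T = ints.kinetic(sa)

        def det_E(P, Vn, Enn):
            J = np.einsum("pqrs,rs->pq", eri, P)
            K = np.einsum("prqs,rs->pq", eri, P)
            return (np.einsum("ij,ij->", P, T + Vn) +
                    0.5 * np.einsum("ij,ij->", P, J) -
                    0.25 * np.einsum("ij,ij->", P, K) + Enn)

        na = h2_wfn.nbf
        PA = np.zeros((2 * na, 2 * na))
        PA[:na, :na] = h2_wfn.density()
        PB = np.zeros_like(PA)
        PB[na:, na:] = wB.density()
        VA = ints.nuclear_attraction(sa, h2_wfn.nuclear_charges, h2_wfn.positions)
        VB = ints.nuclear_attraction(sa, wB.nuclear_charges, wB.positions)
        EnnA = nuclear_repulsion(h2_wfn.nuclear_charges, h2_wfn.positions)
        EnnB = nuclear_repulsion(wB.nuclear_charges, wB.positions)
        EnnAB = nuclear_repulsion(d.nuclear_charges, d.positions)
        Pt = lowdin_orthonormalize(d).density()
        e_coul_ref = (np.einsum("pqrs,pq,rs->", eri, PA, PB)
                      + np.einsum("ij,ij->", PA, VB)
                      + np.einsum("ij,ij->", PB, VA) + EnnAB - EnnA - EnnB)
        e_exch_ref = -0.5 * np.einsum("prqs,pq,rs->", eri, PA, PB)
        e_rep_ref = (det_E(Pt, VA + VB, EnnAB) - det_E(PA, VA, EnnA)
                     - det_E(PB, VB, EnnB) - e_coul_ref - e_exch_ref)
        assert e_exch == pytest.approx(e_exch_ref, abs=1e-9)
        assert e_rep == pytest.approx(e_rep_ref, abs=1e-9)
        e_coul = coulomb_energy(h2_wfn, wB)
        assert e_coul == pytest.approx(e_coul_ref, abs=1e-9)

    def test_helium_repulsion_decays_monotonically(self, helium):
        reps = []
        for r in (4.0, 5.0, 6.0, 7.0, 8.0):
            _, e_rep = exchange_repulsion(helium, he_at(r))
            reps.append(e_rep)
        assert all(a > b > 0 for a, b in zip(reps, reps[1:]))


class TestPolarization:
    def test_formula_arithmetic(self):
        # single site alpha=1 in |F|=0.1 au -> -0.005 hartree = -13.127 kJ/mol
        e = -0.5 * 1.0 * 0.1 ** 2
        assert e * HARTREE_TO_KJMOL == pytest.approx(-13.127, abs=1e-2)

    def test_point_charge_field_oracle(self, helium, na_cation):
        # He probe (alpha forced to 1) in the field of Na+ 12 bohr away:
        # the ion's field is a point-charge field to high accuracy.
        wB = transform_wavefunction(na_cation, np.eye(3), np.array([0, 0, 12.0]))
        e = polarization_energy(helium, wB,
                                xdmA=[fake_xdm("He", 1.0)],
                                xdmB=[fake_xdm("Na", 0.0)])
        assert e == pytest.approx(-0.5 * (1 / 144.0) ** 2, abs=1e-6)
        F = electric_field(wB, np.zeros((1, 3)))
        assert np.linalg.norm(F) == pytest.approx(1 / 144.0, rel=1e-4)

    def test_zero_field_and_sign(self, helium):
        e = polarization_energy(helium, he_at(35.0))
        assert e <= 0 and abs(e) < 1e-10


class TestChargeTransfer:
    def test_far_ions_not_flagged_and_conservation(self, na_cation, cl_anion):
        wB = transform_wavefunction(cl_anion, np.eye(3), np.array([0, 0, 12.0]))
        rep = charge_transfer_check(na_cation, wB)
        assert not rep.flagged
        assert rep.q_a + rep.q_b == pytest.approx(0.0, abs=1e-9)
        assert rep.max_deviation < 0.1

    def test_strict_inequality_at_threshold(self, water_pair):
        rep = charge_transfer_check(*water_pair)
        assert not rep.flagged
        # deviation exactly equal to the threshold must not flag
        rep2 = charge_transfer_check(*water_pair, threshold=rep.max_deviation)
        assert not rep2.flagged
        rep3 = charge_transfer_check(*water_pair,
                                     threshold=rep.max_deviation * 0.999)
        assert rep3.flagged

    def test_invalid_threshold(self, water_pair):
        with pytest.raises(ValueError):
            charge_transfer_check(*water_pair, threshold=0.0)


class TestPresets:
    def test_ce1p_for_all_methods(self):
        for m in ("HF", "LDA", "BLYP", "B3LYP", "wB97X", "wB97M-V"):
            s = preset_scale_factors("CE-1p", m)
            assert (s.k_coul, s.k_exch, s.k_disp) == (1.0, 1.0, 1.0)
            assert s.k_rep == s.k_pol == 0.78

    def test_ce2p(self):
        s = preset_scale_factors("CE-2p")
        assert s.k_exch == s.k_rep == 0.485
        assert s.k_pol == 0.803

    def test_ce5p_table(self):
        s = preset_scale_factors("CE-5p", "wB97M-V")
        assert (s.k_coul, s.k_exch, s.k_rep, s.k_pol, s.k_disp) == \
            (1.005, 0.670, 0.600, 0.793, 1.051)
        s = preset_scale_factors("CE-5p", "HF")
        assert (s.k_coul, s.k_exch, s.k_rep, s.k_pol, s.k_disp) == \
            (0.999, 1.487, 1.109, 0.780, 0.990)
        with pytest.raises(ValueError):
            preset_scale_factors("CE-5p", "PBE0")

    def test_legacy_behind_experimental_flag(self):
        with pytest.raises(ValueError):
            preset_scale_factors("CE-B3LYP")
        s = preset_scale_factors("CE-B3LYP", experimental=True)
        assert s.k_exch == s.k_rep == 0.6177

    def test_total_interaction_examples(self):
        c = InteractionComponents(-100.0, -20.0, 80.0, -30.0, -40.0)
        s = preset_scale_factors("CE-1p")
        assert total_interaction(c, s) == pytest.approx(-121.0, abs=1e-12)
        z = InteractionComponents(0, 0, 0, 0, 0)
        for model in ("CE-1p", "CE-2p"):
            assert total_interaction(z, preset_scale_factors(model)) == 0.0
        u = InteractionComponents(1.0, 1.0, 1.0, 1.0, 1.0)
        assert total_interaction(u, preset_scale_factors("CE-5p", "wB97M-V")) \
            == pytest.approx(4.119, abs=1e-12)


class TestPipeline:
    def test_reproducibility_run_to_run(self, water_components):
        from ce1p.fixtures import water_dimer
        from ce1p.ce_terms import interaction_components

        molA, molB = water_dimer()
        wA = compute_monomer_wavefunction(molA)
        wB = compute_monomer_wavefunction(molB)
        c2 = interaction_components(wA, wB)
        assert np.abs(c2.as_array() - water_components.as_array()).max() < 1e-9

    def test_transformed_vs_fresh_wavefunction_components(self, water_pair):
        """Components from a rotated wavefunction match a fresh SCF at the
        rotated geometry."""
        from ce1p.ce_terms import interaction_components

        wA, wB = water_pair
        R = Rotation.random(random_state=21).as_matrix()
        if np.linalg.det(R) < 0:
            R = -R
        t = np.array([0.5, -0.3, 1.0])
        wBr = transform_wavefunction(wB, R, t)
        wB_fresh = compute_monomer_wavefunction(
            Molecule(("O", "H", "H"), (wB.positions @ R.T) + t))
        wAr = transform_wavefunction(wA, R, t)
        wA_fresh = compute_monomer_wavefunction(
            Molecule(("O", "H", "H"), (wA.positions @ R.T) + t))
        c1 = interaction_components(wAr, wBr)
        c2 = interaction_components(wA_fresh, wB_fresh)
        assert np.abs(c1.as_array() - c2.as_array()).max() < 1e-7
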