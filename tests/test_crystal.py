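"""Crystal ingestion, molecule extraction, dimer enumeration, lattice sums."""

import numpy as np
import pytest

from ce1p import crystal as cr
from ce1p import fixtures as fx
from ce1p.constants import ANGSTROM_TO_BOHR


class TestCif:
    def test_p1_toy_roundtrip(self, tmp_path):
        c = cr.CrystalStructure(np.array([4.0, 5.0, 6.0]),
                                np.array([90.0, 90.0, 90.0]),
                                [(np.eye(3), np.zeros(3))],
                                [("He", np.array([0.1, 0.2, 0.3]), 1.0),
                                 ("Ne", np.array([0.6, 0.7, 0.8]), 1.0)])
        p = tmp_path / "toy.cif"
        fx.write_cif(p, c)
        c2 = cr.read_cif(p)
        assert np.allclose(c2.lengths, c.lengths)
        assert np.allclose(c2.angles, c.angles)
        assert c2.sites[0][0] == "He"
        assert np.allclose(c2.sites[1][1], [0.6, 0.7, 0.8], atol=1e-6)

    def test_partial_occupancy_rejected(self, tmp_path):
        p = tmp_path / "bad.cif"
        p.write_text("""data_bad
_cell_length_a 5.0
_cell_length_b 5.0
_cell_length_c 5.0
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
_atom_site_occupancy
Na1 Na 0.0 0.0 0.0 0.5
""")
        with pytest.raises(cr.DisorderError, match="Na"):
            cr.read_cif(p)

    def test_missing_symmetry_assumes_p1(self, tmp_path):
        p = tmp_path / "nosym.cif"
        p.write_text("""data_nosym
_cell_length_a 4.0
_cell_length_b 4.0
_cell_length_c 4.0
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_atom_site_label
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
Ar1 0.0 0.0 0.0
""")
        with pytest.warns(UserWarning, match="P1"):
            c = cr.read_cif(p)
        assert len(c.sym_ops) == 1

    def test_p21c_group_closure(self):
        c = fx.make_p21c_water_crystal()
        assert c.symmetry_closure_order() == 4


class TestExtraction:
    def test_nacl_monatomic_ions(self):
        uq, inst = cr.extract_molecules(fx.make_nacl_structure())
        assert sorted(u.symbols[0] for u in uq) == ["Cl", "Na"]
        assert all(len(u.symbols) == 1 for u in uq)
        assert len(inst) == 8

    def test_urea_like_single_molecule(self):
        uq, inst = cr.extract_molecules(fx.make_urea_like_crystal())
        assert len(uq) == 1
        assert len(uq[0].symbols) == 8
        assert sorted(uq[0].symbols) == ["C", "H", "H", "H", "H", "N", "N", "O"]

    def test_boundary_straddling_reassembly(self):
        # shift the molecule so it wraps around the cell boundary
        c = fx.make_urea_like_crystal(origin_frac=(0.95, 0.95, 0.9))
        uq, _ = cr.extract_molecules(c)
        assert len(uq) == 1 and len(uq[0].symbols) == 8
        pos = uq[0].positions
        syms = uq[0].symbols
        for i, s in enumerate(syms):
            if s != "H":
                continue
            dmin = min(np.linalg.norm(pos[i] - pos[j])
                       for j in range(len(syms)) if syms[j] in "CNO")
            assert dmin < 1.8

    def test_polymeric_rejected(self):
        # a 1D covalent chain: C atoms 1.4 angstrom apart across the boundary
        c = cr.CrystalStructure(np.array([1.4, 8.0, 8.0]),
                                np.array([90.0, 90.0, 90.0]),
                                [(np.eye(3), np.zeros(3))],
                                [("C", np.zeros(3), 1.0)])
        with pytest.raises(cr.NotMolecularCrystalError):
            cr.extract_molecules(c)


class TestNormalizeXH:
    def test_ch_moved_to_table_length(self):
        syms = ["C", "H"]
        pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.95]])
        out = cr.normalize_xh(syms, pos)
        assert np.linalg.norm(out[1] - out[0]) == pytest.approx(1.083, abs=1e-10)
        assert np.allclose(out[1][:2], 0.0)        # direction unchanged
        assert np.allclose(out[0], pos[0])         # heavy atom untouched

    def test_idempotent_at_table_length(self):
        syms = ["O", "H"]
        pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.983, 0.0]])
        out = cr.normalize_xh(syms, pos)
        assert np.abs(out - pos).max() < 1e-12

    def test_no_hydrogen_unchanged(self):
        syms = ["Na"]
        pos = np.array([[1.0, 2.0, 3.0]])
        assert np.abs(cr.normalize_xh(syms, pos) - pos).max() == 0.0


class TestEnumeration:
    def test_simple_cubic_shells(self):
        sc = fx.make_simple_cubic("Ar", 4.0)
        uq, recs = cr.enumerate_dimers(sc, 4.5)
        assert len(recs) == 1
        assert recs[0].multiplicity == 6
        assert recs[0].closest_contact == pytest.approx(4.0, abs=1e-8)
        uq, recs = cr.enumerate_dimers(sc, 6.0)
        assert sorted(r.multiplicity for r in recs) == [6, 12]

    def test_classes_invariant_under_origin_shift(self):
        c1 = fx.make_urea_like_crystal(origin_frac=(0.25, 0.25, 0.3))
        c2 = fx.make_urea_like_crystal(origin_frac=(0.65, 0.15, 0.8))
        _, r1 = cr.enumerate_dimers(c1, 6.0)
        _, r2 = cr.enumerate_dimers(c2, 6.0)
        m1 = sorted((round(r.centroid_distance, 3), r.multiplicity) for r in r1)
        m2 = sorted((round(r.centroid_distance, 3), r.multiplicity) for r in r2)
        assert m1 == m2

    def test_empty_below_nearest_contact(self):
        sc = fx.make_simple_cubic("Ar", 4.0)
        with pytest.warns(UserWarning, match="no dimers"):
            _, recs = cr.enumerate_dimers(sc, 2.0)
        assert recs == []

    def test_contact_leq_centroid(self):
        _, recs = cr.enumerate_dimers(fx.make_urea_like_crystal(), 8.0)
        for r in recs:
            assert r.closest_contact <= r.centroid_distance + 1e-9


class TestLatticeStub:
    def test_toy_pair_model(self):
        sc = fx.make_simple_cubic("Ar", 4.0)

        def pair_energy(rec):
            return -10.0 if rec.closest_contact < 4.5 else 0.0

        rep = cr.lattice_energy_stub(sc, pair_energy, cutoff=8.0)
        assert rep.total == pytest.approx(-30.0, abs=1e-10)

    def test_origin_shift_invariance(self):
        def pair_energy(rec):
            return -np.exp(-rec.centroid_distance / 3.0)

        r1 = cr.lattice_energy_stub(fx.make_urea_like_crystal(),
                                    pair_energy, cutoff=10.0)
        c2 = fx.make_urea_like_crystal(origin_frac=(0.7, 0.05, 0.55))
        r2 = cr.lattice_energy_stub(c2, pair_energy, cutoff=10.0)
        assert r1.total == pytest.approx(r2.total, abs=1e-6)
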