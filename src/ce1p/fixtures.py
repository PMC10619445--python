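"""Synthetic fixtures and analytic oracles.

Everything a test or demo needs can be generated here with no downloads:
point-charge pseudo-monomers with closed-form fields, a rigid water dimer
and its separation series, an ideal rock-salt NaCl lattice, and small
synthetic molecular crystals (a P2_1/c ice-like packing and a P1 urea-like
packing; both are idealized constructions, not deposited structures).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ANGSTROM_TO_BOHR
from .crystal import CrystalStructure
from .wfn import Molecule

# ---------------------------------------------------------------------------
# point-charge pseudo-monomers (analytic electrostatics oracle)
# ---------------------------------------------------------------------------


@dataclass
class PointChargeSet:
    charges: np.ndarray          # (n,)
    positions: np.ndarray        # (n,3) bohr

    def potential(self, points) -> np.ndarray:
        pts = np.asarray(points, float).reshape(-1, 3)
        d = np.linalg.norm(pts[:, None, :] - self.positions[None, :, :], axis=2)
        return (self.charges[None, :] / d).sum(axis=1)

    def field(self, points) -> np.ndarray:
        pts = np.asarray(points, float).reshape(-1, 3)
        dvec = pts[:, None, :] - self.positions[None, :, :]
        r = np.linalg.norm(dvec, axis=2)
        return (self.charges[None, :, None] * dvec / r[:, :, None] ** 3).sum(axis=1)

    def interaction(self, other: "PointChargeSet") -> float:
        d = np.linalg.norm(self.positions[:, None, :] - other.positions[None, :, :], axis=2)
        return float((self.charges[:, None] * other.charges[None, :] / d).sum())

    def total_charge(self) -> float:
        return float(self.charges.sum())

    def dipole(self) -> np.ndarray:
        return (self.charges[:, None] * self.positions).sum(axis=0)


def make_point_charge_fixture(n: int, seed: int = 0, extent: float = 2.0,
                              neutral: bool = False) -> PointChargeSet:
    """Seeded random point-charge pseudo-monomer (bohr)."""
    rng = np.random.default_rng(seed)
    q = rng.uniform(-1.0, 1.0, n)
    if neutral and n > 1:
        q -= q.mean()
    pos = rng.uniform(-extent, extent, (n, 3))
    return PointChargeSet(q, pos)


# ---------------------------------------------------------------------------
# water monomer / dimer / separation series
# ---------------------------------------------------------------------------

# rigid hydrogen-bonded water dimer (angstrom); donor second
WATER_DIMER_ANGSTROM = {
    "A": np.array([[-0.702196054, -0.056060256, 0.009942262],
                   [-1.022193224, 0.846775782, -0.011488714],
                   [0.257521062, 0.042121496, 0.005218999]]),
    "B": np.array([[2.220871067, 0.026716792, 0.000620476],
                   [2.597492682, -0.411663274, 0.766744858],
                   [2.593135384, -0.449496183, -0.744782026]]),
}


def water_monomer() -> Molecule:
    return Molecule(("O", "H", "H"),
                    WATER_DIMER_ANGSTROM["A"] * ANGSTROM_TO_BOHR)


def water_dimer(scale: float = 1.0) -> tuple[Molecule, Molecule]:
    """Rigid water dimer; ``scale`` multiplies the equilibrium O...H axis
    separation (1.0 = reference geometry)."""
    A = WATER_DIMER_ANGSTROM["A"]
    B = WATER_DIMER_ANGSTROM["B"]
    # displacement axis: acceptor O -> donor O
    axis = B[0] - A[0]
    axis = axis / np.linalg.norm(axis)
    shift = (scale - 1.0) * np.linalg.norm(B[0] - A[0]) * axis
    molA = Molecule(("O", "H", "H"), A * ANGSTROM_TO_BOHR)
    molB = Molecule(("O", "H", "H"), (B + shift) * ANGSTROM_TO_BOHR)
    return molA, molB


def make_water_dimer_series(scales) -> list:
    """Rigid-monomer separation series (mimics scaled-separation benchmarks)."""
    return [water_dimer(s) for s in scales]


# ---------------------------------------------------------------------------
# crystals
# ---------------------------------------------------------------------------


def make_nacl_structure(a: float = 5.64) -> CrystalStructure:
    """Ideal rock-salt NaCl, conventional cubic cell, expressed in P1.

    a = 5.64 angstrom is the standard room-temperature lattice parameter.
    """
    fcc = [(0, 0, 0), (0, 0.5, 0.5), (0.5, 0, 0.5), (0.5, 0.5, 0)]
    sites = [("Na", np.array(f, float), 1.0) for f in fcc]
    sites += [("Cl", np.mod(np.array(f, float) + (0.5, 0, 0), 1.0), 1.0) for f in fcc]
    return CrystalStructure(np.array([a, a, a]), np.array([90.0, 90.0, 90.0]),
                            [(np.eye(3), np.zeros(3))], sites)


def make_simple_cubic(symbol: str = "Ar", a: float = 4.0) -> CrystalStructure:
    """One-atom simple cubic lattice (dimer-enumeration oracle)."""
    return CrystalStructure(np.array([a, a, a]), np.array([90.0, 90.0, 90.0]),
                            [(np.eye(3), np.zeros(3))],
                            [(symbol, np.zeros(3), 1.0)])


P21C_OPS = [
    (np.eye(3), np.zeros(3)),
    (-np.eye(3), np.zeros(3)),
    (np.diag([-1.0, 1.0, -1.0]), np.array([0.0, 0.5, 0.5])),
    (np.diag([1.0, -1.0, 1.0]), np.array([0.0, 0.5, 0.5])),
]


def make_p21c_water_crystal(a: float = 7.0, b: float = 7.5, c: float = 7.2,
                            beta: float = 98.0) -> CrystalStructure:
    """Synthetic P2_1/c packing of a rigid water molecule.

    An idealized construction (not a deposited ice structure) used for
    symmetry/closure and molecule-extraction tests.
    """
    r, th = 0.9572, np.deg2rad(104.52)
    local = np.array([[0.0, 0.0, 0.0],
                      [r * np.sin(th / 2), 0.0, r * np.cos(th / 2)],
                      [-r * np.sin(th / 2), 0.0, r * np.cos(th / 2)]])
    cryst = CrystalStructure(np.array([a, b, c]), np.array([90.0, beta, 90.0]),
                             [op for op in P21C_OPS],
                             [("O", np.array([0.13, 0.11, 0.12]), 1.0),
                              ("H", np.zeros(3), 1.0), ("H", np.zeros(3), 1.0)])
    # place the H's consistently with the O site in fractional coordinates
    L = cryst.lattice_matrix()
    o_cart = np.array([0.13, 0.11, 0.12]) @ L
    Linv = np.linalg.inv(L)
    h1 = (o_cart + local[1]) @ Linv
    h2 = (o_cart + local[2]) @ Linv
    cryst.sites = [("O", np.array([0.13, 0.11, 0.12]), 1.0),
                   ("H", h1, 1.0), ("H", h2, 1.0)]
    return cryst


def urea_like_molecule() -> tuple:
    """Idealized planar urea geometry (angstrom): 8 atoms, C2v."""
    cn, co, nh = 1.35, 1.26, 1.01
    half = np.deg2rad(114.0 / 2)
    C = np.array([0.0, 0.0, 0.0])
    O = np.array([0.0, 0.0, co])
    N1 = np.array([cn * np.sin(half), 0.0, -cn * np.cos(half)])
    N2 = np.array([-cn * np.sin(half), 0.0, -cn * np.cos(half)])

    def h_pair(N, sign):
        u1 = np.array([sign * np.sin(half + np.deg2rad(60)), 0.0,
                       -np.cos(half + np.deg2rad(60))])
        u2 = np.array([sign * np.sin(half - np.deg2rad(60)), 0.0,
                       -np.cos(half - np.deg2rad(60))])
        return N + nh * u1, N + nh * u2

    H1a, H1b = h_pair(N1, +1)
    H2a, H2b = h_pair(N2, -1)
    syms = ["C", "O", "N", "N", "H", "H", "H", "H"]
    pos = np.array([C, O, N1, N2, H1a, H1b, H2a, H2b])
    return syms, pos


def make_urea_like_crystal(a: float = 5.6, b: float = 5.6, c: float = 4.7,
                           origin_frac=(0.25, 0.25, 0.3)) -> CrystalStructure:
    """Synthetic P1 cell holding one idealized urea-like molecule."""
    syms, pos = urea_like_molecule()
    cryst = CrystalStructure(np.array([a, b, c]), np.array([90.0, 90.0, 90.0]),
                             [(np.eye(3), np.zeros(3))],
                             [("C", np.zeros(3), 1.0)])
    L = cryst.lattice_matrix()
    Linv = np.linalg.inv(L)
    origin = np.asarray(origin_frac) @ L
    sites = []
    for s, p in zip(syms, pos):
        sites.append((s, np.mod((origin + p) @ Linv, 1.0), 1.0))
    cryst.sites = sites
    return cryst


def write_cif(path, cryst: CrystalStructure, name: str = "fixture"):
    """Minimal CIF 1.1 writer for fixture structures."""
    def op_to_xyz(R, t):
        import gemmi
        tr = gemmi.Op()
        den = tr.DEN
        tr.rot = [[int(round(x * den)) for x in row] for row in np.asarray(R)]
        tr.tran = [int(round(x * den)) for x in np.asarray(t)]
        return tr.triplet()

    lines = [f"data_{name}"]
    for tag, v in zip(("a", "b", "c"), cryst.lengths):
        lines.append(f"_cell_length_{tag} {v:.6f}")
    for tag, v in zip(("alpha", "beta", "gamma"), cryst.angles):
        lines.append(f"_cell_angle_{tag} {v:.6f}")
    lines.append("loop_")
    lines.append("_symmetry_equiv_pos_as_xyz")
    for R, t in cryst.sym_ops:
        lines.append(f"'{op_to_xyz(R, t)}'")
    lines.append("loop_")
    lines.append("_atom_site_label")
    lines.append("_atom_site_type_symbol")
    lines.append("_atom_site_fract_x")
    lines.append("_atom_site_fract_y")
    lines.append("_atom_site_fract_z")
    lines.append("_atom_site_occupancy")
    for i, (sym, f, occ) in enumerate(cryst.sites):
        lines.append(f"{sym}{i + 1} {sym} {f[0]:.6f} {f[1]:.6f} {f[2]:.6f} {occ:.3f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
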