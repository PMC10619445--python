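"""Monomer wavefunction model and rigid-motion transformations.

A :class:`Wavefunction` carries one closed-shell monomer: atoms, contracted
Gaussian shells, the occupied MO coefficients and occupations.  Monomer
wavefunctions are produced once (in-process RHF provider, or read from a
Molden file) and then *re-used* under rigid rotations/translations — the
coefficient transformation only needs the per-shell rotation matrices of
:mod:`ce1p.rotations` — which is what makes crystal work cheap.

Internal units: bohr and hartree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np

from . import basis as basismod
from . import integrals as ints
from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, atomic_number
from .scf import restricted_hf

SUPPORTED_METHODS = ("HF", "LDA", "BLYP", "B3LYP", "wB97X", "wB97M-V")
INPROCESS_METHODS = ("HF",)


class OpenShellError(ValueError):
    pass


class ProviderError(RuntimeError):
    pass


@dataclass(frozen=True)
class Molecule:
    """Plain geometry: element symbols, positions in bohr, net charge."""

    symbols: tuple
    positions: np.ndarray
    charge: int = 0

    def __post_init__(self):
        object.__setattr__(self, "positions",
                           np.asarray(self.positions, float).reshape(-1, 3))
        if len(self.symbols) != len(self.positions):
            raise ValueError("symbol/position length mismatch")

    @property
    def n_electrons(self) -> int:
        return sum(atomic_number(s) for s in self.symbols) - self.charge


def read_xyz(path, charge: int = 0) -> Molecule:
    """XYZ file in angstrom; an optional 'charge=N' token in the comment
    line overrides the argument."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0].split()[0])
    comment = lines[1] if len(lines) > 1 else ""
    for tok in comment.split():
        if tok.lower().startswith("charge="):
            charge = int(tok.split("=")[1])
    syms, pos = [], []
    for ln in lines[2:2 + n]:
        parts = ln.split()
        syms.append(parts[0])
        pos.append([float(x) for x in parts[1:4]])
    return Molecule(tuple(syms), np.array(pos) * ANGSTROM_TO_BOHR, charge)


def write_xyz(path, mol: Molecule, comment: str = ""):
    with open(path, "w") as fh:
        fh.write(f"{len(mol.symbols)}\n{comment} charge={mol.charge}\n")
        for s, p in zip(mol.symbols, mol.positions * BOHR_TO_ANGSTROM):
            fh.write(f"{s} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n")


@dataclass(frozen=True)
class AtomSite:
    """One nucleus: symbol, (effective) nuclear charge, position in bohr.

    ``alpha_free`` / ``v_free`` (bohr^3) are the free-species polarizability
    and Hirshfeld volume used by the polarization/dispersion models; they are
    resolved lazily by :mod:`ce1p.xdm` when left as None.
    """

    symbol: str
    nuclear_charge: float
    position: np.ndarray
    alpha_free: float | None = None
    v_free: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, float).reshape(3))
        if self.nuclear_charge <= 0:
            raise ValueError("nuclear charge must be positive")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")


@dataclass(frozen=True)
class BasisShell:
    """Contracted Gaussian shell attached to atom ``center`` (an index)."""

    center: int
    l: int
    pure: bool
    exps: np.ndarray
    coefs: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "exps", np.asarray(self.exps, float))
        object.__setattr__(self, "coefs", np.asarray(self.coefs, float))
        if self.l < 0:
            raise ValueError("angular momentum must be >= 0")
        if np.any(self.exps <= 0):
            raise ValueError("primitive exponents must be strictly positive")

    @property
    def nbf(self) -> int:
        return 2 * self.l + 1 if self.pure else (self.l + 1) * (self.l + 2) // 2


@dataclass
class Wavefunction:
    """Closed-shell monomer wavefunction (occupied MOs only)."""

    atoms: list
    shells: list
    mo_coeff: np.ndarray          # (nbf, nocc)
    occupations: np.ndarray       # (nocc,), all 2.0 for closed shell
    scf_energy: float
    method: str = "HF"
    basis: str = basismod.DEFAULT_BASIS
    charge: int = 0

    # -- derived -------------------------------------------------------------
    @cached_property
    def shell_arrays(self) -> ints.ShellArrays:
        from types import SimpleNamespace
        items = [SimpleNamespace(l=sh.l, pure=sh.pure,
                                 center=self.atoms[sh.center].position,
                                 exps=sh.exps, coefs=sh.coefs)
                 for sh in self.shells]
        return ints.ShellArrays.build(items)

    @cached_property
    def overlap(self) -> np.ndarray:
        return ints.overlap(self.shell_arrays)

    @property
    def nbf(self) -> int:
        return sum(sh.nbf for sh in self.shells)

    @property
    def n_electrons(self) -> float:
        return float(np.sum(self.occupations))

    @property
    def nuclear_charges(self) -> np.ndarray:
        return np.array([a.nuclear_charge for a in self.atoms])

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def density(self) -> np.ndarray:
        return (self.mo_coeff * self.occupations) @ self.mo_coeff.T

    def density_at(self, points) -> np.ndarray:
        ao = ints.ao_values(self.shell_arrays, points)
        mo = ao @ self.mo_coeff
        return (mo * mo * self.occupations).sum(axis=1)

    def validate(self, tol: float = 1e-8):
        """Check the Wavefunction invariants; raises on violation."""
        if np.any(np.abs(self.occupations - 2.0) > 1e-12):
            raise OpenShellError("restricted closed shell requires all occupations == 2")
        M = self.mo_coeff.T @ self.overlap @ self.mo_coeff
        dev = np.abs(M - np.eye(M.shape[0])).max()
        if dev > tol:
            raise ValueError(f"occupied MOs not orthonormal (max deviation {dev:.2e})")
        nz = self.nuclear_charges.sum()
        if abs(self.n_electrons + self.charge - nz) > 1e-9:
            raise ValueError("electron count + net charge inconsistent with nuclear charges")

    def copy(self) -> "Wavefunction":
        w = Wavefunction(list(self.atoms), list(self.shells),
                         self.mo_coeff.copy(), self.occupations.copy(),
                         self.scf_energy, self.method, self.basis, self.charge)
        return w


# ---------------------------------------------------------------------------
# provider
# ---------------------------------------------------------------------------


def compute_monomer_wavefunction(mol: Molecule, method: str = "HF",
                                 basis: str = basismod.DEFAULT_BASIS) -> Wavefunction:
    """Run the delegated SCF engine and wrap the result.

    The in-process provider covers HF; other method labels must come from a
    file-based provider (see :func:`ce1p.molden.read_molden`).
    """
    if method not in SUPPORTED_METHODS:
        raise ProviderError(f"unknown method label {method!r}")
    if method not in INPROCESS_METHODS:
        raise ProviderError(
            f"method {method!r} is not available in-process; supply a Molden "
            f"file from an external engine instead"
        )
    ne = mol.n_electrons
    if ne % 2 != 0:
        raise OpenShellError(
            f"open-shell species (N_elec = {ne}) are not supported"
        )
    shell_descr = basismod.shells_for_molecule(mol.symbols, basis)
    shells = [BasisShell(i, l, pure, e, c) for (i, l, pure, e, c) in shell_descr]
    atoms = [AtomSite(s, float(atomic_number(s)), p)
             for s, p in zip(mol.symbols, mol.positions)]
    wf = Wavefunction(atoms, shells, np.empty((0, 0)), np.empty(0), 0.0,
                      method, basis, mol.charge)
    res = restricted_hf(wf.shell_arrays, wf.nuclear_charges, mol.positions, ne)
    nocc = int(round(ne / 2))
    wf.mo_coeff = res.mo_coeff[:, :nocc]
    wf.occupations = np.full(nocc, 2.0)
    wf.scf_energy = res.energy
    wf.validate()
    return wf


# ---------------------------------------------------------------------------
# rigid motion
# ---------------------------------------------------------------------------


def transform_wavefunction(w: Wavefunction, R: np.ndarray, t=np.zeros(3)) -> Wavefunction:
    """Map the wavefunction under x -> R x + t (R a proper rotation)."""
    from .rotations import check_rotation, rotation_blocks, cartesian_rotation_block

    R = np.asarray(R, float)
    t = np.asarray(t, float).reshape(3)
    check_rotation(R)
    atoms = [replace(a, position=R @ a.position + t) for a in w.atoms]
    blocks = []
    for sh in w.shells:
        if sh.pure:
            blocks.append(rotation_blocks(sh.l, R))
        else:
            blocks.append(cartesian_rotation_block(sh.l, R))
    nbf = w.nbf
    C = np.zeros_like(w.mo_coeff)
    off = 0
    for sh, B in zip(w.shells, blocks):
        n = sh.nbf
        C[off:off + n] = B @ w.mo_coeff[off:off + n]
        off += n
    out = Wavefunction(atoms, list(w.shells), C, w.occupations.copy(),
                       w.scf_energy, w.method, w.basis, w.charge)
    return out


def transform_wavefunction_orthogonal(w: Wavefunction, M: np.ndarray,
                                      t=np.zeros(3)) -> Wavefunction:
    """Like :func:`transform_wavefunction` but also accepts improper
    orthogonal maps (inversions/mirrors), as produced by crystal symmetry."""
    from .rotations import orthogonal_shell_block

    M = np.asarray(M, float)
    t = np.asarray(t, float).reshape(3)
    if np.abs(M @ M.T - np.eye(3)).max() > 1e-8:
        raise ValueError("transformation must be orthogonal")
    atoms = [replace(a, position=M @ a.position + t) for a in w.atoms]
    C = np.zeros_like(w.mo_coeff)
    off = 0
    for sh in w.shells:
        n = sh.nbf
        B = orthogonal_shell_block(sh.l, M, sh.pure)
        C[off:off + n] = B @ w.mo_coeff[off:off + n]
        off += n
    return Wavefunction(atoms, list(w.shells), C, w.occupations.copy(),
                        w.scf_energy, w.method, w.basis, w.charge)


def concatenate(wA: Wavefunction, wB: Wavefunction) -> Wavefunction:
    """Superpose two monomers (block-stacked MOs, *not* orthonormalized)."""
    if wA.method != wB.method or wA.basis != wB.basis:
        raise ValueError("cannot concatenate wavefunctions with different method/basis labels")
    for sa in wA.shells:
        for sb in wB.shells:
            if sa.l >= 2 and sb.l >= 2 and sa.pure != sb.pure:
                raise ValueError("mixed pure/Cartesian shell conventions")
    posA, posB = wA.positions, wB.positions
    if len(posA) and len(posB):
        d = np.linalg.norm(posA[:, None, :] - posB[None, :, :], axis=2)
        if d.min() < 1e-6:
            raise ValueError("coincident nuclei between monomers")
    atoms = list(wA.atoms) + list(wB.atoms)
    shells = list(wA.shells) + [replace(sh, center=sh.center + len(wA.atoms))
                                for sh in wB.shells]
    na, nb = wA.nbf, wB.nbf
    ka, kb = wA.mo_coeff.shape[1], wB.mo_coeff.shape[1]
    C = np.zeros((na + nb, ka + kb))
    C[:na, :ka] = wA.mo_coeff
    C[na:, ka:] = wB.mo_coeff
    occ = np.concatenate([wA.occupations, wB.occupations])
    return Wavefunction(atoms, shells, C, occ,
                        wA.scf_energy + wB.scf_energy, wA.method, wA.basis,
                        wA.charge + wB.charge)


def lowdin_orthonormalize(w: Wavefunction) -> Wavefunction:
    """Symmetrically orthonormalize the occupied MOs in the overlap metric."""
    S = w.overlap
    M = w.mo_coeff.T @ S @ w.mo_coeff
    evals, V = np.linalg.eigh(M)
    if evals[0] <= 1e-10:
        raise np.linalg.LinAlgError(
            f"linear dependence in combined occupied space "
            f"(smallest eigenvalue {evals[0]:.3e})"
        )
    Mm12 = V @ np.diag(evals ** -0.5) @ V.T
    out = w.copy()
    out.mo_coeff = w.mo_coeff @ Mm12
    return out


def lowdin_monomer_charges(dimer: Wavefunction, atoms_A) -> tuple[float, float]:
    """Löwdin net charges (q_A, q_B) of the two monomers in a dimer.

    ``atoms_A``: indices of the atoms belonging to monomer A.  Populations
    come from diag(S^1/2 P S^1/2); the two charges sum to the net charge
    exactly (up to round-off).
    """
    S = dimer.overlap
    evals, V = np.linalg.eigh(S)
    if evals[0] <= 1e-10:
        raise np.linalg.LinAlgError(
            f"singular overlap matrix (smallest eigenvalue {evals[0]:.3e})"
        )
    S12 = V @ np.diag(np.sqrt(evals)) @ V.T
    P = dimer.density()
    pop = np.diag(S12 @ P @ S12)
    # map AO -> atom
    ao_atom = []
    for sh in dimer.shells:
        ao_atom.extend([sh.center] * sh.nbf)
    ao_atom = np.array(ao_atom)
    atoms_A = set(int(i) for i in atoms_A)
    popA = pop[np.isin(ao_atom, list(atoms_A))].sum()
    popB = pop.sum() - popA
    ZA = sum(a.nuclear_charge for i, a in enumerate(dimer.atoms) if i in atoms_A)
    ZB = dimer.nuclear_charges.sum() - ZA
    return float(ZA - popA), float(ZB - popB)
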