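"""Molden-format wavefunction exchange (the file-based provider).

Writes and reads a pure-spherical-dialect Molden file ([5D7F9G] flagged in
the header).  This is how orbitals from external SCF engines (any method
label) enter the package.  Only occupied MOs are required.

Orderings follow the Molden convention on file (p: x,y,z; pure shells:
m = 0, +1, -1, +2, -2, ...) and are permuted to the package's internal
m = -l..+l ordering on read.
"""

from __future__ import annotations

import re

import numpy as np

from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, atomic_number
from .wfn import AtomSite, BasisShell, Wavefunction

_L_LETTER = {0: "s", 1: "p", 2: "d", 3: "f", 4: "g"}
_LETTER_L = {v: k for k, v in _L_LETTER.items()}


def _molden_perm(l: int, pure: bool) -> list:
    """internal index for each on-file position within one shell."""
    if l == 0:
        return [0]
    if l == 1:
        return [2, 0, 1]          # file x,y,z -> internal (y,z,x)
    if not pure:
        return list(range((l + 1) * (l + 2) // 2))
    seq = [0]
    for m in range(1, l + 1):
        seq += [m, -m]
    return [m + l for m in seq]


def write_molden(path, w: Wavefunction, mo_energies=None):
    lines = ["[Molden Format]",
             f"[Title]\n ce1p method={w.method} basis={w.basis} "
             f"charge={w.charge} scf_energy={float(w.scf_energy):.14e}"]
    lines.append("[Atoms] Angs")
    for i, a in enumerate(w.atoms):
        p = a.position * BOHR_TO_ANGSTROM
        lines.append(f"{a.symbol:3s} {i + 1:4d} {int(round(a.nuclear_charge)):4d} "
                     f"{p[0]: .10f} {p[1]: .10f} {p[2]: .10f}")
    lines.append("[GTO]")
    for i in range(len(w.atoms)):
        lines.append(f"{i + 1} 0")
        for sh in w.shells:
            if sh.center != i:
                continue
            lines.append(f" {_L_LETTER[sh.l]} {len(sh.exps):3d} 1.00")
            for e, c in zip(sh.exps, sh.coefs):
                lines.append(f"  {e: .10e} {c: .10e}")
        lines.append("")
    lines.append("[5D7F]")
    lines.append("[9G]")
    lines.append("[MO]")
    if mo_energies is None:
        mo_energies = np.zeros(w.mo_coeff.shape[1])
    # build permutation internal -> file
    perm = []
    off = 0
    for sh in w.shells:
        perm.extend(off + np.array(_molden_perm(sh.l, sh.pure)))
        off += sh.nbf
    perm = np.array(perm)
    for k in range(w.mo_coeff.shape[1]):
        lines.append(" Sym= A")
        lines.append(f" Ene= {mo_energies[k]: .10f}")
        lines.append(" Spin= Alpha")
        lines.append(f" Occup= {w.occupations[k]:.6f}")
        col = w.mo_coeff[perm, k]
        for j, v in enumerate(col):
            lines.append(f" {j + 1:4d} {v: .12e}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_molden(path, method: str | None = None,
                basis: str | None = None) -> Wavefunction:
    with open(path) as fh:
        text = fh.read()
    pure = "[5D" in text or "[5d" in text
    if not pure:
        raise ValueError("only the pure-spherical Molden dialect is supported "
                         "(missing [5D] flag)")
    meta = dict(re.findall(r"(\w+)=([^\s]+)", text.split("[Atoms]")[0]))
    method = method or meta.get("method", "unknown")
    basis = basis or meta.get("basis", "unknown")
    charge = int(meta.get("charge", 0))
    scf_energy = float(meta.get("scf_energy", 0.0))

    sections = re.split(r"\[([A-Za-z0-9 ]+)\]", text)
    content = {}
    for i in range(1, len(sections) - 1, 2):
        content[sections[i].split()[0].lower()] = sections[i + 1]

    m_unit = re.search(r"\[Atoms\]\s*(\S+)", text, re.I)
    atoms_unit = ANGSTROM_TO_BOHR if (m_unit and
                                      m_unit.group(1).lower().startswith("angs")) else 1.0
    atoms = []
    for ln in content["atoms"].strip().splitlines():
        parts = ln.split()
        if len(parts) == 1:  # unit tag line
            continue
        if len(parts) < 6:
            continue
        sym = parts[0]
        pos = np.array([float(x) for x in parts[3:6]]) * atoms_unit
        atoms.append(AtomSite(sym, float(atomic_number(sym)), pos))

    shells = []
    cur_atom = None
    lines = iter(content["gto"].strip().splitlines())
    for ln in lines:
        parts = ln.split()
        if not parts:
            cur_atom = None
            continue
        if len(parts) == 2 and parts[0].isdigit():
            cur_atom = int(parts[0]) - 1
            continue
        if parts[0].lower() in _LETTER_L:
            l = _LETTER_L[parts[0].lower()]
            nprim = int(parts[1])
            exps, coefs = [], []
            for _ in range(nprim):
                e, c = next(lines).replace("D", "E").replace("d", "e").split()[:2]
                exps.append(float(e))
                coefs.append(float(c))
            shells.append(BasisShell(cur_atom, l, True, exps, coefs))

    # MO section
    mo_text = content["mo"]
    occ_list, cols = [], []
    for mo_block in re.split(r"Sym=", mo_text)[1:]:
        occ = float(re.search(r"Occup=\s*([-\d.Ee+]+)", mo_block).group(1))
        coeffs = {}
        for m in re.finditer(r"^\s*(\d+)\s+([-\d.Ee+]+)\s*$", mo_block, re.M):
            coeffs[int(m.group(1)) - 1] = float(m.group(2))
        if occ > 1e-12:
            occ_list.append(occ)
            col = np.zeros(max(coeffs) + 1)
            for j, v in coeffs.items():
                col[j] = v
            cols.append(col)
    nbf = sum(sh.nbf for sh in shells)
    C_file = np.zeros((nbf, len(cols)))
    for k, col in enumerate(cols):
        C_file[:len(col), k] = col
    perm = []
    off = 0
    for sh in shells:
        perm.extend(off + np.array(_molden_perm(sh.l, sh.pure)))
        off += sh.nbf
    perm = np.array(perm)
    C = np.zeros_like(C_file)
    C[perm, :] = C_file
    return Wavefunction(atoms, shells, C, np.array(occ_list), scf_energy,
                        method, basis, charge)
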