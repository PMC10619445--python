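"""Molecular-crystal machinery: CIF ingestion, molecule extraction, X-H
normalization, symmetry-unique dimer enumeration and direct-summation
lattice energies with pairwise or crystal-field polarization.

Geometry bookkeeping in this module is in angstrom and fractional
coordinates (the crystallographic units); conversion to bohr happens only
when wavefunctions are built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import (ANGSTROM_TO_BOHR, HARTREE_TO_KJMOL, XH_BOND_LENGTHS,
                        COVALENT_RADIUS)

# elements treated as non-bonding during molecule extraction (ionic species
# in molecular/ionic crystals rather than covalent network formers)
NONBONDING_ELEMENTS = frozenset({"Li", "Na", "K", "Rb", "Cs", "Mg", "Ca"})

BOND_FACTOR = 1.25


class NotMolecularCrystalError(ValueError):
    pass


class DisorderError(ValueError):
    pass


# ---------------------------------------------------------------------------
# structure container
# ---------------------------------------------------------------------------


@dataclass
class CrystalStructure:
    lengths: np.ndarray            # (3,) angstrom
    angles: np.ndarray             # (3,) degrees
    sym_ops: list                  # list of (rot 3x3, trans 3) fractional
    sites: list                    # list of (symbol, frac(3,), occupancy)

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, float)
        self.angles = np.asarray(self.angles, float)
        if self.cell_volume() <= 0:
            raise ValueError("cell volume must be positive")
        for sym, frac, occ in self.sites:
            if abs(occ - 1.0) > 1e-6:
                raise DisorderError(
                    f"site {sym} at {np.round(np.asarray(frac), 4)} has occupancy "
                    f"{occ}; disordered/partial-occupancy structures are rejected"
                )

    # -- geometry ------------------------------------------------------------
    def lattice_matrix(self) -> np.ndarray:
        """Rows are the cell vectors a, b, c in angstrom (cartesian = frac @ L)."""
        a, b, c = self.lengths
        al, be, ga = np.deg2rad(self.angles)
        v1 = np.array([a, 0, 0])
        v2 = np.array([b * np.cos(ga), b * np.sin(ga), 0])
        cx = c * np.cos(be)
        cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
        cz = np.sqrt(max(c ** 2 - cx ** 2 - cy ** 2, 0.0))
        v3 = np.array([cx, cy, cz])
        return np.array([v1, v2, v3])

    def cell_volume(self) -> float:
        return float(abs(np.linalg.det(self.lattice_matrix())))

    def to_cartesian(self, frac) -> np.ndarray:
        return np.asarray(frac, float) @ self.lattice_matrix()

    # -- symmetry ------------------------------------------------------------
    def symmetry_closure_order(self, tol: float = 1e-6) -> int:
        """Order of the closure of the stored operations (mod lattice)."""
        def key(op):
            R, t = op
            return (tuple(np.round(np.asarray(R).ravel(), 6)),
                    tuple(np.round(np.mod(np.asarray(t), 1.0), 6)))

        ops = {key(op): op for op in self.sym_ops}
        changed = True
        while changed:
            changed = False
            cur = list(ops.values())
            for R1, t1 in cur:
                for R2, t2 in cur:
                    R = np.asarray(R1) @ np.asarray(R2)
                    t = np.asarray(R1) @ np.asarray(t2) + np.asarray(t1)
                    k = key((R, t))
                    if k not in ops:
                        ops[k] = (R, np.mod(t, 1.0))
                        changed = True
                        if len(ops) > 192:
                            raise ValueError("symmetry operations do not close")
        return len(ops)

    def expand_sites(self, tol: float = 1e-4):
        """All atoms in one unit cell: (symbol, frac wrapped to [0,1))."""
        out_sym, out_frac = [], []
        for sym, frac, _ in self.sites:
            for R, t in self.sym_ops:
                f = np.mod(np.asarray(R, float) @ np.asarray(frac, float)
                           + np.asarray(t, float), 1.0)
                dup = False
                for g in out_frac:
                    d = np.abs(f - g)
                    d = np.minimum(d, 1.0 - d)
                    if np.linalg.norm(self.to_cartesian(d)) < tol:
                        dup = True
                        break
                if not dup:
                    out_sym.append(sym)
                    out_frac.append(f)
        return out_sym, np.array(out_frac).reshape(-1, 3)


def read_cif(path) -> CrystalStructure:
    """Parse a (single-block) CIF 1.1 file via gemmi."""
    import gemmi

    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    def num(tag):
        v = block.find_value(tag)
        if v is None:
            raise ValueError(f"CIF missing {tag}")
        return float(gemmi.cif.as_number(v))

    lengths = [num("_cell_length_a"), num("_cell_length_b"), num("_cell_length_c")]
    angles = [num("_cell_angle_alpha"), num("_cell_angle_beta"), num("_cell_angle_gamma")]

    ops = []
    for tag in ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz"):
        col = block.find_loop(tag)
        if col:
            for triplet in col:
                op = gemmi.Op(gemmi.cif.as_string(triplet))
                R = np.array(op.rot, float) / op.DEN
                t = np.array(op.tran, float) / op.DEN
                ops.append((R, t))
            break
    if not ops:
        hm = block.find_value("_symmetry_space_group_name_H-M") or \
            block.find_value("_space_group_name_H-M_alt")
        if hm:
            sg = gemmi.SpaceGroup(gemmi.cif.as_string(hm))
            for op in sg.operations():
                ops.append((np.array(op.rot, float) / op.DEN,
                            np.array(op.tran, float) / op.DEN))
    if not ops:
        warnings.warn("CIF has no symmetry information; assuming P1")
        ops = [(np.eye(3), np.zeros(3))]

    sites = []
    table = block.find(["_atom_site_label", "_atom_site_fract_x",
                        "_atom_site_fract_y", "_atom_site_fract_z"])
    occ_col = block.find_loop("_atom_site_occupancy")
    occs = [float(gemmi.cif.as_number(v)) for v in occ_col] if occ_col else None
    type_col = block.find_loop("_atom_site_type_symbol")
    types = [gemmi.cif.as_string(v) for v in type_col] if type_col else None
    for i, row in enumerate(table):
        label = row[0]
        sym = types[i] if types else label
        sym = "".join(ch for ch in sym if ch.isalpha())
        sym = sym[:2] if len(sym) > 1 and sym[:2].capitalize() in COVALENT_RADIUS else sym[0]
        sym = sym.capitalize()
        frac = np.array([float(gemmi.cif.as_number(row[j])) for j in (1, 2, 3)])
        occ = occs[i] if occs else 1.0
        sites.append((sym, frac, occ))
    if not sites:
        raise ValueError("CIF contains no atom sites")
    return CrystalStructure(np.array(lengths), np.array(angles), ops, sites)


# ---------------------------------------------------------------------------
# molecule extraction
# ---------------------------------------------------------------------------


@dataclass
class UniqueMolecule:
    symbols: list
    positions: np.ndarray      # cartesian angstrom, reference placement
    charge: int = 0

    @property
    def centroid(self):
        return self.positions.mean(axis=0)

    def fingerprint(self) -> tuple:
        n = len(self.symbols)
        d = []
        for i in range(n):
            for j in range(i + 1, n):
                d.append(round(float(np.linalg.norm(self.positions[i] - self.positions[j])), 3))
        return (tuple(sorted(self.symbols)), tuple(sorted(d)))


@dataclass
class MoleculeInstance:
    unique_index: int
    M: np.ndarray              # orthogonal cartesian map from unique reference
    t: np.ndarray              # cartesian translation (angstrom)
    positions: np.ndarray      # cartesian angstrom
    symbols: list


def _bonded(sym1, sym2, dist, factor=BOND_FACTOR):
    if sym1 in NONBONDING_ELEMENTS or sym2 in NONBONDING_ELEMENTS:
        return False
    r1 = COVALENT_RADIUS.get(sym1, 1.2)
    r2 = COVALENT_RADIUS.get(sym2, 1.2)
    return dist < factor * (r1 + r2)


def extract_molecules(c: CrystalStructure, bond_factor: float = BOND_FACTOR):
    """Whole molecules in the cell: (uniques, instances).

    Connected components of the covalent-bond graph are reassembled across
    periodic boundaries; infinite (polymeric) connectivity raises.
    """
    syms, fracs = c.expand_sites()
    L = c.lattice_matrix()
    nat = len(syms)
    # neighbour offsets for periodic bonding
    offsets = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                        for k in (-1, 0, 1)])
    adj = [[] for _ in range(nat)]
    for i in range(nat):
        for j in range(nat):
            for off in offsets:
                if i == j and not off.any():
                    continue
                d = np.linalg.norm((fracs[j] + off - fracs[i]) @ L)
                if d < 1e-4:
                    continue
                if _bonded(syms[i], syms[j], d, bond_factor):
                    adj[i].append((j, off.copy()))
    # BFS with image tracking
    assigned = [None] * nat       # (component, shift)
    comps = []
    for start in range(nat):
        if assigned[start] is not None:
            continue
        comp_id = len(comps)
        assigned[start] = (comp_id, np.zeros(3))
        queue = [start]
        members = [start]
        while queue:
            i = queue.pop()
            si = assigned[i][1]
            for j, off in adj[i]:
                sj = si + off
                if assigned[j] is None:
                    assigned[j] = (comp_id, sj)
                    queue.append(j)
                    members.append(j)
                elif assigned[j][0] == comp_id:
                    if np.linalg.norm(assigned[j][1] - sj) > 1e-6:
                        raise NotMolecularCrystalError(
                            "infinite (polymeric) connectivity detected; "
                            "not a molecular crystal"
                        )
        comps.append(members)
    # build molecules (cartesian, unwrapped)
    molecules = []
    for members in comps:
        ms = [syms[i] for i in members]
        mf = np.array([fracs[i] + assigned[i][1] for i in members])
        molecules.append((ms, mf @ L))
    # group into symmetry-unique classes by fingerprint
    uniques: list[UniqueMolecule] = []
    instances: list[MoleculeInstance] = []
    for ms, pos in molecules:
        um = UniqueMolecule(ms, pos)
        fp = um.fingerprint()
        found = None
        for ui, u in enumerate(uniques):
            if u.fingerprint() == fp:
                found = ui
                break
        if found is None:
            uniques.append(um)
            instances.append(MoleculeInstance(len(uniques) - 1, np.eye(3),
                                              np.zeros(3), pos, ms))
        else:
            M, t = _map_between(c, uniques[found], ms, pos)
            instances.append(MoleculeInstance(found, M, t, pos, ms))
    return uniques, instances


def _map_between(c: CrystalStructure, u: UniqueMolecule, syms, pos,
                 tol: float = 1e-4):
    """Find an orthogonal (M, t) with M u.positions + t == pos (as a set)."""
    L = c.lattice_matrix()
    for R, _ in c.sym_ops:
        # column-vector cartesian map: x' = L^T R (L^T)^-1 x
        Mcart = L.T @ np.asarray(R, float) @ np.linalg.inv(L.T)
        if np.abs(Mcart @ Mcart.T - np.eye(3)).max() > 1e-6:
            continue
        t = np.asarray(pos).mean(axis=0) - Mcart @ u.centroid
        mapped = (Mcart @ u.positions.T).T + t
        if _same_point_set(u.symbols, mapped, syms, pos, tol):
            return Mcart, t
    # fall back: identity-rotation translation
    t = np.asarray(pos).mean(axis=0) - u.centroid
    mapped = u.positions + t
    if _same_point_set(u.symbols, mapped, syms, pos, tol):
        return np.eye(3), t
    raise ValueError("could not map molecule instance onto its unique reference")


def _same_point_set(sym1, pos1, sym2, pos2, tol):
    if len(sym1) != len(sym2):
        return False
    used = set()
    for s, p in zip(sym1, pos1):
        ok = False
        for j, (s2, p2) in enumerate(zip(sym2, pos2)):
            if j in used or s2 != s:
                continue
            if np.linalg.norm(p - p2) < tol:
                used.add(j)
                ok = True
                break
        if not ok:
            return False
    return True


# ---------------------------------------------------------------------------
# X-H normalization
# ---------------------------------------------------------------------------


def normalize_xh(symbols, positions, table: dict | None = None,
                 bond_factor: float = BOND_FACTOR):
    """Move each H along its existing X->H bond direction to the tabulated
    average crystallographic length; heavy atoms untouched."""
    if table is None:
        table = XH_BOND_LENGTHS
    pos = np.array(positions, float, copy=True)
    for i, s in enumerate(symbols):
        if s != "H":
            continue
        best, bestd = None, np.inf
        for j, s2 in enumerate(symbols):
            if j == i or s2 == "H":
                continue
            d = np.linalg.norm(pos[i] - pos[j])
            if d < bestd and _bonded(s, s2, d, bond_factor):
                best, bestd = j, d
        if best is None or symbols[best] not in table:
            continue
        direction = (pos[i] - pos[best]) / bestd
        pos[i] = pos[best] + direction * table[symbols[best]]
    return pos


# ---------------------------------------------------------------------------
# dimer enumeration
# ---------------------------------------------------------------------------


@dataclass
class DimerRecord:
    class_id: int
    central_unique: int
    neighbor_unique: int
    M: np.ndarray                  # neighbour map from its unique reference
    t: np.ndarray                  # angstrom
    closest_contact: float         # angstrom
    centroid_distance: float       # angstrom
    multiplicity: int = 1
    components: object = None      # InteractionComponents, filled on demand


def _dimer_key(central_pos, neighbor_pos) -> tuple:
    d = np.linalg.norm(central_pos[:, None, :] - neighbor_pos[None, :, :], axis=2)
    return tuple(np.sort(np.round(d, 3).ravel()))


def neighbor_instances(c: CrystalStructure, cutoff: float,
                       criterion: str = "closest-contact",
                       uniques=None, instances=None):
    """All neighbour molecule instances within ``cutoff`` of each unique
    central molecule.

    Returns (uniques, {central_index: [DimerRecord, ...]}) with one record
    per *instance* (multiplicity 1); distances in angstrom.
    """
    if criterion not in ("closest-contact", "centroid"):
        raise ValueError("criterion must be 'closest-contact' or 'centroid'")
    if uniques is None or instances is None:
        uniques, instances = extract_molecules(c)
    L = c.lattice_matrix()
    V = abs(np.linalg.det(L))
    heights = np.array([V / np.linalg.norm(np.cross(L[(i + 1) % 3], L[(i + 2) % 3]))
                        for i in range(3)])
    ext = max(np.linalg.norm(u.positions - u.centroid, axis=1).max()
              if len(u.symbols) > 1 else 0.0 for u in uniques)
    reach = cutoff + 2 * ext + 1.0
    hkl_max = np.ceil(reach / heights).astype(int)
    out = {cu: [] for cu in range(len(uniques))}
    for cu, central in enumerate(uniques):
        cpos = central.positions
        for inst in instances:
            for h in range(-hkl_max[0], hkl_max[0] + 1):
                for k in range(-hkl_max[1], hkl_max[1] + 1):
                    for l_ in range(-hkl_max[2], hkl_max[2] + 1):
                        shift = np.array([h, k, l_], float) @ L
                        npos = inst.positions + shift
                        cd = np.linalg.norm(npos.mean(axis=0) - cpos.mean(axis=0))
                        if cd < 1e-4:
                            continue  # the central molecule itself
                        cc = np.linalg.norm(
                            cpos[:, None, :] - npos[None, :, :], axis=2).min()
                        dist = cd if criterion == "centroid" else cc
                        if dist > cutoff:
                            continue
                        out[cu].append(DimerRecord(
                            -1, cu, inst.unique_index, inst.M.copy(),
                            inst.t + shift, float(cc), float(cd)))
    return uniques, out


def enumerate_dimers(c: CrystalStructure, cutoff: float,
                     criterion: str = "closest-contact"):
    """Symmetry-unique dimer classes around each unique central molecule.

    Classes are identified by the sorted multiset of inter-monomer atom
    distances (1e-3 angstrom resolution); multiplicities count the
    symmetry-equivalent occurrences per unique central molecule.
    """
    uniques, per_central = neighbor_instances(c, cutoff, criterion)
    records: dict = {}
    counts: dict = {}
    found_any = False
    for cu, recs in per_central.items():
        cpos = uniques[cu].positions
        for rec in recs:
            found_any = True
            npos = (rec.M @ uniques[rec.neighbor_unique].positions.T).T + rec.t
            key = (cu, rec.neighbor_unique) + _dimer_key(cpos, npos)
            if key in records:
                counts[key] += 1
            else:
                rec.class_id = len(records)
                records[key] = rec
                counts[key] = 1
    if not found_any:
        warnings.warn("cutoff smaller than the nearest contact; no dimers found")
    out = []
    for key, rec in records.items():
        rec.multiplicity = counts[key]
        out.append(rec)
    return uniques, out


# ---------------------------------------------------------------------------
# lattice energies
# ---------------------------------------------------------------------------


@dataclass
class LatticeEnergyReport:
    per_molecule: list             # kJ/mol per unique molecule
    total: float                   # kJ/mol per formula unit (sum over uniques)
    components: dict               # component breakdown (kJ/mol, summed)
    cutoff: float                  # angstrom
    convergence_trace: list        # [(cutoff, total kJ/mol), ...]
    polarization_mode: str
    converged: bool = True


def lattice_energy_stub(c: CrystalStructure, pair_energy, cutoff: float = 15.0,
                        criterion: str = "closest-contact") -> LatticeEnergyReport:
    """Direct summation with a user-supplied pair-energy backend.

    ``pair_energy(record) -> kJ/mol`` (scaled total for one dimer).
    """
    uniques, records = enumerate_dimers(c, cutoff, criterion)
    per = np.zeros(len(uniques))
    for rec in records:
        per[rec.central_unique] += 0.5 * rec.multiplicity * pair_energy(rec)
    return LatticeEnergyReport([float(x) for x in per], float(per.sum()), {},
                               cutoff, [(cutoff, float(per.sum()))], "pairwise")


# ---------------------------------------------------------------------------
# quantum-mechanical backends
# ---------------------------------------------------------------------------


def _unique_wavefunctions(uniques, charges, method, basis, xh_table=None):
    from .wfn import Molecule, compute_monomer_wavefunction

    wfs = []
    for i, u in enumerate(uniques):
        pos = u.positions
        if xh_table is not None:
            pos = normalize_xh(u.symbols, pos, xh_table)
        q = 0 if charges is None else int(charges.get(i, 0))
        mol = Molecule(tuple(u.symbols), pos * ANGSTROM_TO_BOHR, q)
        wfs.append(compute_monomer_wavefunction(mol, method, basis))
    return wfs


def lattice_energy(c: CrystalStructure, model: str = "CE-1p",
                   method: str = "HF", basis: str = "svp-like",
                   cutoff: float = 15.0, pol_mode: str = "pairwise",
                   dispersion_mode: str = "monomer", charges: dict | None = None,
                   criterion: str = "closest-contact",
                   convergence_probe: float = 5.0,
                   xh_normalize: bool = False,
                   convergence_threshold: float = 1.0) -> LatticeEnergyReport:
    """Direct-summation lattice energy per mole of molecules (kJ/mol).

    ``pairwise``: E_lat = 1/2 sum over dimer classes of multiplicity x
    scaled pair energy.  ``crystal-field``: the polarization component is
    replaced wholesale by the many-body expression with the vector field of
    all neighbours summed before squaring.

    Direct summation of E_coul is conditionally convergent for charged
    (ionic) species: a warning is emitted and the trace should be checked.
    """
    from .ce_terms import (interaction_components, polarization_energy,
                           preset_scale_factors, total_interaction, electric_field)
    from .wfn import transform_wavefunction_orthogonal
    from .xdm import atomic_moments_volumes

    if pol_mode not in ("pairwise", "crystal-field"):
        raise ValueError("pol_mode must be 'pairwise' or 'crystal-field'")
    if charges and any(q != 0 for q in charges.values()):
        warnings.warn("ionic species: direct summation of E_coul is "
                      "conditionally convergent; inspect the trace")
    scales = preset_scale_factors(model, method) if isinstance(model, str) else model
    if cutoff <= 0:
        convergence_probe = 0.0
    full_cut = cutoff + convergence_probe
    uniques, records = enumerate_dimers(c, full_cut, criterion)
    if not records:
        return LatticeEnergyReport([0.0] * len(uniques), 0.0,
                                   dict.fromkeys(
                                       ["e_coul", "e_exch", "e_rep", "e_pol",
                                        "e_disp"], 0.0),
                                   cutoff, [(cutoff, 0.0)], pol_mode, True)
    xh_table = XH_BOND_LENGTHS if xh_normalize else None
    wfs = _unique_wavefunctions(uniques, charges, method, basis, xh_table)
    xdms = [atomic_moments_volumes(w) for w in wfs]

    for rec in records:
        wB = transform_wavefunction_orthogonal(
            wfs[rec.neighbor_unique], rec.M, rec.t * ANGSTROM_TO_BOHR)
        # per-atom XDM data are rigid-motion invariant scalars: reuse the
        # unique molecule's values for every symmetry image
        rec.components = interaction_components(
            wfs[rec.central_unique], wB, dispersion_mode,
            xdmA=xdms[rec.central_unique], xdmB=xdms[rec.neighbor_unique])

    def total_at(cut):
        per = np.zeros(len(uniques))
        comp_sum = np.zeros(5)
        crit = "centroid_distance" if criterion == "centroid" else "closest_contact"
        for rec in records:
            if getattr(rec, crit) > cut:
                continue
            e = total_interaction(rec.components, scales)
            per[rec.central_unique] += 0.5 * rec.multiplicity * e * HARTREE_TO_KJMOL
            comp_sum += 0.5 * rec.multiplicity * rec.components.as_array() * HARTREE_TO_KJMOL
        return per, comp_sum

    per, comp_sum = total_at(cutoff)
    per_probe, _ = total_at(full_cut)
    comps = dict(zip(["e_coul", "e_exch", "e_rep", "e_pol", "e_disp"], comp_sum))

    if pol_mode == "crystal-field":
        _, per_central = neighbor_instances(c, cutoff, criterion,
                                            uniques=uniques,
                                            instances=extract_molecules(c)[1])
        e_pol_cf = 0.0
        for cu, recs in per_central.items():
            pts = uniques[cu].positions * ANGSTROM_TO_BOHR
            F = np.zeros((len(pts), 3))
            for rec in recs:
                wB = transform_wavefunction_orthogonal(
                    wfs[rec.neighbor_unique], rec.M, rec.t * ANGSTROM_TO_BOHR)
                F += electric_field(wB, pts)
            alphas = np.array([x.alpha for x in xdms[cu]])
            e_pol_cf += float(-0.5 * np.sum(alphas * np.sum(F ** 2, axis=1)))
        e_pol_cf *= HARTREE_TO_KJMOL
        delta = e_pol_cf * scales.k_pol - comps["e_pol"] * scales.k_pol
        per = per + delta / max(len(uniques), 1)
        per_probe = per_probe + delta / max(len(uniques), 1)
        comps["e_pol"] = e_pol_cf

    trace = [(cutoff, float(per.sum())), (full_cut, float(per_probe.sum()))]
    converged = abs(trace[1][1] - trace[0][1]) <= convergence_threshold
    if not converged:
        warnings.warn(f"lattice sum not converged at {cutoff} angstrom: "
                      f"{trace[0][1]:.2f} vs {trace[1][1]:.2f} kJ/mol")
    return LatticeEnergyReport([float(x) for x in per], float(per.sum()),
                               comps, cutoff, trace, pol_mode, converged)


def lattice_polarization(c: CrystalStructure, charges: dict,
                         method: str = "HF", basis: str = "svp-like",
                         cutoff_qm: float = 16.0, far_cutoff: float = 250.0,
                         criterion: str = "centroid") -> dict:
    """Pairwise-summed vs crystal-field polarization of an (ionic) crystal.

    Near neighbours (within ``cutoff_qm`` angstrom) contribute fields from
    their actual frozen charge distributions; more distant instances out to
    ``far_cutoff`` are treated as point charges at their centroids (exact to
    machine precision at those separations), plus an analytic continuum tail
    for the pairwise |F|^2 sum.  Energies in kJ/mol per formula unit.
    """
    from .ce_terms import electric_field
    from .wfn import transform_wavefunction_orthogonal
    from .xdm import atomic_moments_volumes

    uniques, instances = extract_molecules(c)
    wfs = _unique_wavefunctions(uniques, charges, method, basis)
    xdms = [atomic_moments_volumes(w) for w in wfs]
    alphas = [np.array([x.alpha for x in xd]) for xd in xdms]
    qnet = {i: float(charges.get(i, 0)) for i in range(len(uniques))}

    _, per_central = neighbor_instances(c, cutoff_qm, criterion,
                                        uniques=uniques, instances=instances)

    L = c.lattice_matrix()
    V = abs(np.linalg.det(L))
    e_pairwise = 0.0
    e_crystal = 0.0
    n_neighbors = 0
    for cu in range(len(uniques)):
        pts = uniques[cu].positions * ANGSTROM_TO_BOHR
        a_c = alphas[cu]
        Fsum = np.zeros((len(pts), 3))
        s_pair = 0.0     # sum over neighbours of alpha-weighted |F_n(r_c)|^2
        s_back = 0.0     # polarization of the neighbours by the central
        for rec in per_central[cu]:
            n_neighbors += 1
            wB = transform_wavefunction_orthogonal(
                wfs[rec.neighbor_unique], rec.M, rec.t * ANGSTROM_TO_BOHR)
            F = electric_field(wB, pts)
            Fsum += F
            s_pair += float(np.sum(a_c * np.sum(F ** 2, axis=1)))
            Fc = electric_field(wfs[cu], wB.positions)
            s_back += float(np.sum(alphas[rec.neighbor_unique] * np.sum(Fc ** 2, axis=1)))
        # far region: point charges at instance centroids
        heights = np.array([V / np.linalg.norm(np.cross(L[(i + 1) % 3], L[(i + 2) % 3]))
                            for i in range(3)])
        nmax = np.ceil(far_cutoff / heights).astype(int)
        rng_h = np.arange(-nmax[0], nmax[0] + 1)
        rng_k = np.arange(-nmax[1], nmax[1] + 1)
        rng_l = np.arange(-nmax[2], nmax[2] + 1)
        HH, KK, LL = np.meshgrid(rng_h, rng_k, rng_l, indexing="ij")
        shifts = np.stack([HH.ravel(), KK.ravel(), LL.ravel()], axis=1).astype(float) @ L
        c_cent = uniques[cu].centroid
        for inst in instances:
            qn = qnet[inst.unique_index]
            cent = inst.positions.mean(axis=0)
            pos = cent[None, :] + shifts      # angstrom
            r = np.linalg.norm(pos - c_cent[None, :], axis=1)
            far = (r > cutoff_qm) & (r <= far_cutoff)
            r_b = r[far] * ANGSTROM_TO_BOHR
            if qn != 0.0:
                # fields of far point charges at the central atoms
                dvec = (pos[far][:, None, :] - uniques[cu].positions[None, :, :]) * ANGSTROM_TO_BOHR
                rr = np.linalg.norm(dvec, axis=2)
                Fpc = -qn * dvec / rr[:, :, None] ** 3   # field at central site
                Fsum += Fpc.sum(axis=0)
                s_pair += float(np.sum(a_c[None, :] * np.sum(Fpc ** 2, axis=2)))
            # back-polarization of far neighbours by the central net charge
            if qnet[cu] != 0.0:
                a_n_tot = float(np.sum(alphas[inst.unique_index]))
                s_back += a_n_tot * qnet[cu] ** 2 * float(np.sum(1.0 / r_b[r_b > 0] ** 4))
        # analytic continuum tail beyond far_cutoff for the 1/r^4 sums
        R_b = far_cutoff * ANGSTROM_TO_BOHR
        Vb = V * ANGSTROM_TO_BOHR ** 3
        q2_dens = sum(qnet[inst.unique_index] ** 2 for inst in instances) / Vb
        adens = sum(float(np.sum(alphas[inst.unique_index])) for inst in instances) / Vb
        s_pair += float(np.sum(a_c)) * q2_dens * 4 * np.pi / R_b
        s_back += adens * qnet[cu] ** 2 * 4 * np.pi / R_b

        e_pairwise += 0.5 * (-0.5 * s_pair - 0.5 * s_back)
        e_crystal += float(-0.5 * np.sum(a_c * np.sum(Fsum ** 2, axis=1)))

    return {
        "pairwise_kjmol": e_pairwise * HARTREE_TO_KJMOL,
        "crystal_field_kjmol": e_crystal * HARTREE_TO_KJMOL,
        "n_neighbors": n_neighbors,
        "alphas": [list(map(float, a)) for a in alphas],
        "cutoff_qm": cutoff_qm,
        "far_cutoff": far_cutoff,
    }
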