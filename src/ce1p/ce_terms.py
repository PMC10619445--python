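"""The five interaction-energy components and their scaled combinations.

For a dimer of frozen monomer wavefunctions A and B:

* ``E_coul``  - classical electrostatics between the two total (electronic
  + nuclear) frozen charge distributions;
* ``E_exch``  - inter-monomer HF exchange of the frozen monomer densities
  (pre-orthogonalization, the package's normative definition);
* ``E_rep``   - the energy rise caused by symmetric (Löwdin)
  orthonormalization of the superposed occupied MOs: the orthonormalized
  determinant energy minus E_A + E_B + E_coul + E_exch;
* ``E_pol``   - -1/2 sum_i alpha_i |F(r_i)|^2 with atom-in-molecule
  polarizabilities from XDM Hirshfeld volumes, fields evaluated at nuclei;
* ``E_disp``  - damped XDM dispersion (monomer or dimer coefficients).

A model total is the exact linear combination sum_t k_t E_t defined by a
:class:`ScaleFactorSet` (CE-1p / CE-2p / CE-5p presets or fitted factors).
All energies in hartree internally.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import integrals as ints
from .constants import HARTREE_TO_KJMOL
from .scf import nuclear_repulsion
from .wfn import Wavefunction, concatenate, lowdin_monomer_charges, lowdin_orthonormalize
from .xdm import XDMParams, atomic_moments_volumes, dispersion_interaction

DEFAULT_CT_THRESHOLD = 0.33  # electrons


@dataclass
class InteractionComponents:
    e_coul: float
    e_exch: float
    e_rep: float
    e_pol: float
    e_disp: float
    dispersion_mode: str = "monomer"

    def as_array(self) -> np.ndarray:
        return np.array([self.e_coul, self.e_exch, self.e_rep, self.e_pol, self.e_disp])

    def total(self, scales: "ScaleFactorSet") -> float:
        return total_interaction(self, scales)

    def as_kjmol(self) -> dict:
        d = {k: v * HARTREE_TO_KJMOL for k, v in list(asdict(self).items())[:5]}
        d["dispersion_mode"] = self.dispersion_mode
        return d


@dataclass(frozen=True)
class ScaleFactorSet:
    name: str
    k_coul: float
    k_exch: float
    k_rep: float
    k_pol: float
    k_disp: float

    def as_array(self) -> np.ndarray:
        return np.array([self.k_coul, self.k_exch, self.k_rep, self.k_pol, self.k_disp])


@dataclass(frozen=True)
class ChargeTransferReport:
    q_a: float
    q_b: float
    formal_a: float
    formal_b: float
    max_deviation: float
    flagged: bool
    threshold: float


# ---------------------------------------------------------------------------
# scale-factor presets
# ---------------------------------------------------------------------------

CE1P_K = 0.78

_CE5P = {
    "HF":      (0.999, 1.487, 1.109, 0.780, 0.990),
    "LDA":     (1.011, 0.717, 0.600, 0.824, 1.036),
    "BLYP":    (1.011, 0.761, 0.600, 0.826, 1.039),
    "B3LYP":   (1.007, 0.702, 0.600, 0.808, 1.068),
    "wB97X":   (1.005, 0.666, 0.600, 0.794, 1.065),
    "wB97M-V": (1.005, 0.670, 0.600, 0.793, 1.051),
}

# Prior-generation models (scaled exch-rep as one term, D2-era dispersion);
# only the exch-rep factor 0.6177 of CE-B3LYP is load-bearing here.
_LEGACY = {
    "CE-HF":    (1.019, 0.811, 0.811, 0.651, 0.901),
    "CE-B3LYP": (1.057, 0.6177, 0.6177, 0.740, 0.871),
}

_METHOD_ALIASES = {
    "hf": "HF", "lda": "LDA", "blyp": "BLYP", "b3lyp": "B3LYP",
    "wb97x": "wB97X", "ωb97x": "wB97X",
    "wb97m-v": "wB97M-V", "ωb97m-v": "wB97M-V",
}


def _canon_method(method: str) -> str:
    m = _METHOD_ALIASES.get(method.lower())
    if m is None:
        raise ValueError(f"unknown method label {method!r}")
    return m


def preset_scale_factors(model: str, method: str = "wB97M-V",
                         experimental: bool = False) -> ScaleFactorSet:
    """Published scale-factor sets for CE-1p / CE-2p / CE-5p."""
    name = model.upper().replace("_", "-")
    if name == "CE-1P":
        return ScaleFactorSet("CE-1p", 1.0, 1.0, CE1P_K, CE1P_K, 1.0)
    if name == "CE-2P":
        return ScaleFactorSet("CE-2p", 1.0, 0.485, 0.485, 0.803, 1.0)
    if name == "CE-5P":
        m = _canon_method(method)
        k = _CE5P[m]
        return ScaleFactorSet(f"CE-5p/{m}", *k)
    if name in _LEGACY:
        if not experimental:
            raise ValueError(
                f"{name} is a legacy preset; pass experimental=True to use it"
            )
        return ScaleFactorSet(name, *_LEGACY[name])
    raise ValueError(f"unknown model {model!r}")


def total_interaction(c: InteractionComponents, s: ScaleFactorSet) -> float:
    """The exact linear combination of the five components (no recomputation)."""
    return float(np.dot(c.as_array(), s.as_array()))


# ---------------------------------------------------------------------------
# electrostatics helpers
# ---------------------------------------------------------------------------


def electric_field(w: Wavefunction, points) -> np.ndarray:
    """Total electric field (a.u.) of the frozen monomer at given points."""
    pts = np.asarray(points, float).reshape(-1, 3)
    _, Gel = ints.electron_esp_grad(w.shell_arrays, w.density(), pts)
    F = Gel.copy()  # electronic contribution: +grad of integral rho/|r-P|
    for a in w.atoms:
        d = pts - a.position
        r3 = np.linalg.norm(d, axis=1) ** 3
        F += a.nuclear_charge * d / r3[:, None]
    return F


def electrostatic_potential(w: Wavefunction, points) -> np.ndarray:
    """phi(P) = sum_k Z_k/|P-R_k| - integral rho(r)/|r-P|."""
    pts = np.asarray(points, float).reshape(-1, 3)
    Vel, _ = ints.electron_esp_grad(w.shell_arrays, w.density(), pts)
    phi = -Vel
    for a in w.atoms:
        phi += a.nuclear_charge / np.linalg.norm(pts - a.position, axis=1)
    return phi


def _padded_densities(wA: Wavefunction, wB: Wavefunction, dimer: Wavefunction):
    na, nb = wA.nbf, wB.nbf
    PA = np.zeros((na + nb, na + nb))
    PB = np.zeros_like(PA)
    PA[:na, :na] = wA.density()
    PB[na:, na:] = wB.density()
    return PA, PB


def coulomb_energy(wA: Wavefunction, wB: Wavefunction, dimer: Wavefunction | None = None) -> float:
    """Classical electrostatic interaction of the frozen charge distributions."""
    if dimer is None:
        dimer = concatenate(wA, wB)
    sa = dimer.shell_arrays
    PA, PB = _padded_densities(wA, wB, dimer)
    Js, _ = ints.build_jk(sa, [PB])
    e_ee = float(np.einsum("ij,ij->", PA, Js[0]))
    VB = ints.nuclear_attraction(sa, wB.nuclear_charges, wB.positions)
    VA = ints.nuclear_attraction(sa, wA.nuclear_charges, wA.positions)
    e_en = float(np.einsum("ij,ij->", PA, VB) + np.einsum("ij,ij->", PB, VA))
    ZZ = 0.0
    for a in wA.atoms:
        for b in wB.atoms:
            ZZ += a.nuclear_charge * b.nuclear_charge / np.linalg.norm(a.position - b.position)
    return e_ee + e_en + ZZ


def exchange_repulsion(wA: Wavefunction, wB: Wavefunction,
                       dimer: Wavefunction | None = None,
                       _zero_cross_overlap: bool = False):
    """(E_exch, E_rep) from the superposed-and-orthonormalized dimer.

    ``_zero_cross_overlap`` is a test hook: it removes the inter-monomer
    overlap block before the Löwdin step, which must drive E_rep to zero
    identically.
    """
    _, e_exch, e_rep = coulomb_exchange_repulsion(
        wA, wB, dimer, _zero_cross_overlap=_zero_cross_overlap)
    return e_exch, e_rep


def coulomb_exchange_repulsion(wA: Wavefunction, wB: Wavefunction,
                               dimer: Wavefunction | None = None,
                               _zero_cross_overlap: bool = False):
    """(E_coul, E_exch, E_rep) sharing one set of J/K builds."""
    if dimer is None:
        dimer = concatenate(wA, wB)
    sa = dimer.shell_arrays
    na = wA.nbf
    PA, PB = _padded_densities(wA, wB, dimer)

    if _zero_cross_overlap:
        S = dimer.overlap.copy()
        S[:na, na:] = 0.0
        S[na:, :na] = 0.0
        M = dimer.mo_coeff.T @ S @ dimer.mo_coeff
        evals, V = np.linalg.eigh(M)
        Ct = dimer.mo_coeff @ V @ np.diag(evals ** -0.5) @ V.T
        Pt = (Ct * dimer.occupations) @ Ct.T
    else:
        ortho = lowdin_orthonormalize(dimer)
        Pt = ortho.density()

    Js, Ks = ints.build_jk(sa, [PA, PB, Pt])
    e_exch = -0.5 * float(np.einsum("ij,ij->", PA, Ks[1]))

    T = ints.kinetic(sa)
    VA = ints.nuclear_attraction(sa, wA.nuclear_charges, wA.positions)
    VB = ints.nuclear_attraction(sa, wB.nuclear_charges, wB.positions)
    h = T + VA + VB

    def det_energy(P, J, K, Vnuc_own, Enn):
        return (float(np.einsum("ij,ij->", P, T + Vnuc_own))
                + 0.5 * float(np.einsum("ij,ij->", P, J))
                - 0.25 * float(np.einsum("ij,ij->", P, K)) + Enn)

    EnnA = nuclear_repulsion(wA.nuclear_charges, wA.positions)
    EnnB = nuclear_repulsion(wB.nuclear_charges, wB.positions)
    EnnAB = nuclear_repulsion(dimer.nuclear_charges, dimer.positions)
    eA = det_energy(PA, Js[0], Ks[0], VA, EnnA)
    eB = det_energy(PB, Js[1], Ks[1], VB, EnnB)
    eAB = (float(np.einsum("ij,ij->", Pt, h))
           + 0.5 * float(np.einsum("ij,ij->", Pt, Js[2]))
           - 0.25 * float(np.einsum("ij,ij->", Pt, Ks[2])) + EnnAB)

    e_coul = (float(np.einsum("ij,ij->", PA, Js[1]))
              + float(np.einsum("ij,ij->", PA, VB))
              + float(np.einsum("ij,ij->", PB, VA))
              + (EnnAB - EnnA - EnnB))
    e_rep = eAB - eA - eB - e_coul - e_exch
    return e_coul, e_exch, e_rep


def polarization_energy(wA: Wavefunction, wB: Wavefunction,
                        xdmA=None, xdmB=None) -> float:
    """-1/2 sum alpha_i |F_other(r_i)|^2, always <= 0."""
    if xdmA is None:
        xdmA = atomic_moments_volumes(wA)
    if xdmB is None:
        xdmB = atomic_moments_volumes(wB)
    aA = np.array([x.alpha for x in xdmA])
    aB = np.array([x.alpha for x in xdmB])
    FB = electric_field(wB, wA.positions)
    FA = electric_field(wA, wB.positions)
    return float(-0.5 * np.sum(aA * np.sum(FB ** 2, axis=1))
                 - 0.5 * np.sum(aB * np.sum(FA ** 2, axis=1)))


def charge_transfer_check(wA: Wavefunction, wB: Wavefunction,
                          threshold: float = DEFAULT_CT_THRESHOLD,
                          dimer: Wavefunction | None = None) -> ChargeTransferReport:
    """Löwdin charge-transfer screen (used to exclude dimers from fits)."""
    if threshold <= 0:
        raise ValueError("charge-transfer threshold must be positive")
    if dimer is None:
        dimer = concatenate(wA, wB)
    ortho = lowdin_orthonormalize(dimer)
    qa, qb = lowdin_monomer_charges(ortho, range(len(wA.atoms)))
    dev = max(abs(qa - wA.charge), abs(qb - wB.charge))
    return ChargeTransferReport(qa, qb, float(wA.charge), float(wB.charge),
                                dev, bool(dev > threshold), threshold)


def interaction_components(wA: Wavefunction, wB: Wavefunction,
                           dispersion_mode: str = "monomer",
                           xdm_params: XDMParams = XDMParams(),
                           xdmA=None, xdmB=None) -> InteractionComponents:
    """All five raw components for a dimer of frozen monomers."""
    dimer = concatenate(wA, wB)
    if xdmA is None:
        xdmA = atomic_moments_volumes(wA)
    if xdmB is None:
        xdmB = atomic_moments_volumes(wB)
    e_coul, e_exch, e_rep = coulomb_exchange_repulsion(wA, wB, dimer)
    e_pol = polarization_energy(wA, wB, xdmA, xdmB)
    e_disp = dispersion_interaction(wA, wB, dispersion_mode, xdm_params,
                                    xdmA=xdmA, xdmB=xdmB)
    return InteractionComponents(e_coul, e_exch, e_rep, e_pol, e_disp,
                                 dispersion_mode)
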