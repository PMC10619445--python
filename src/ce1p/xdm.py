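"""Exchange-hole dipole moment (XDM) dispersion.

Pipeline: Becke-Roussel exchange-hole dipoles on a molecular grid,
Hirshfeld-stockholder partitioning into atomic hole-moment expectations
<M_1^2>, <M_2^2>, <M_3^2> and volumes V, effective atom-in-molecule
polarizabilities alpha = alpha' V/V', pairwise C6/C8/C10 from the standard
second-order combining rules, and damped -sum_n C_n/(r^n + R_vdW^n) pair
energies with R_vdW = a1 R_crit + a2.

Dimer dispersion interactions come in two flavours: ``monomer`` (cross
pairs i in A, j in B with monomer coefficients) and ``dimer`` (total minus
monomer totals, with coefficients from the concatenated dimer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import integrals as ints
from .constants import ANGSTROM_TO_BOHR  # noqa: F401  (used via XDMParams)
from .freeatoms import get_free_atom, reference_charge_for
from .grids import IntegrationGrid, molecular_grid

RHO_FLOOR = 1e-14


@dataclass(frozen=True)
class XDMParams:
    """Becke-Johnson damping parameters (a2 stored in angstrom, used in bohr)."""

    a1: float = 0.65
    a2_angstrom: float = 1.70

    def __post_init__(self):
        if self.a1 < 0 or self.a2_angstrom < 0:
            raise ValueError("damping parameters must be non-negative")

    @property
    def a2_bohr(self) -> float:
        return self.a2_angstrom * ANGSTROM_TO_BOHR


@dataclass
class AtomicXDMData:
    symbol: str
    m1: float               # <M_1^2> (a.u.)
    m2: float               # <M_2^2>
    m3: float               # <M_3^2>
    volume: float           # Hirshfeld volume V (bohr^3)
    v_free: float           # free-species volume V' (bohr^3)
    alpha_free: float       # free-species polarizability alpha' (bohr^3)

    @property
    def alpha(self) -> float:
        """Effective in-molecule polarizability alpha' V / V'."""
        return self.alpha_free * self.volume / self.v_free


@dataclass
class PairDispersion:
    c6: float
    c8: float
    c10: float
    r_crit: float = 0.0      # bohr
    r_vdw: float = 0.0       # bohr


# ---------------------------------------------------------------------------
# Becke-Roussel hole
# ---------------------------------------------------------------------------


def br_equation_lhs(x):
    """x e^{-2x/3}/(x-2); monotone decreasing on (0,2) and on (2, inf)."""
    x = np.asarray(x, float)
    return x * np.exp(-2.0 * x / 3.0) / (x - 2.0)


def solve_br_x(y, tol: float = 1e-10, max_iter: int = 100) -> np.ndarray:
    """Invert the BR equation by bracketed bisection on the proper branch."""
    y = np.atleast_1d(np.asarray(y, float))
    x = np.zeros_like(y)
    pos = y > 0
    if np.any(pos):
        lo = np.full(pos.sum(), 2.0 + 1e-14)
        hi = np.full(pos.sum(), 4.0)
        yv = y[pos]
        for _ in range(80):
            bad = br_equation_lhs(hi) > yv
            if not np.any(bad):
                break
            hi[bad] = 2.0 + (hi[bad] - 2.0) * 2.0
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            f = br_equation_lhs(mid)
            high = f > yv          # f too large -> x too small -> move lo up
            lo = np.where(high, mid, lo)
            hi = np.where(high, hi, mid)
            if np.max(hi - lo) < tol:
                break
        x[pos] = 0.5 * (lo + hi)
    neg = y < 0
    if np.any(neg):
        lo = np.full(neg.sum(), 1e-14)
        hi = np.full(neg.sum(), 2.0 - 1e-14)
        yv = y[neg]
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            f = br_equation_lhs(mid)
            high = f > yv
            lo = np.where(high, mid, lo)
            hi = np.where(high, hi, mid)
            if np.max(hi - lo) < tol:
                break
        x[neg] = 0.5 * (lo + hi)
    return x


def br_hole_dipole(rho_s, grad2_s, lap_s, tau_s):
    """BR hole displacement d (= b) per point from spin densities.

    Parameters are the spin density, its squared gradient magnitude, its
    laplacian and the (no-1/2 convention) spin kinetic-energy density.
    Points with rho below the floor return d = 0.
    """
    rho_s = np.atleast_1d(np.asarray(rho_s, float))
    grad2_s = np.atleast_1d(np.asarray(grad2_s, float))
    lap_s = np.atleast_1d(np.asarray(lap_s, float))
    tau_s = np.atleast_1d(np.asarray(tau_s, float))
    d = np.zeros_like(rho_s)
    ok = rho_s > RHO_FLOOR
    if not np.any(ok):
        return d
    rho = rho_s[ok]
    D = tau_s[ok] - 0.25 * grad2_s[ok] / rho
    Q = (lap_s[ok] - 2.0 * D) / 6.0
    y = 2.0 / 3.0 * np.pi ** (2.0 / 3.0) * rho ** (5.0 / 3.0) / np.where(Q == 0.0, 1e-300, Q)
    x = solve_br_x(y)
    b3 = x ** 3 * np.exp(-x) / (8.0 * np.pi * rho)
    dd = np.cbrt(b3)
    dd[Q == 0.0] = 0.0
    d[ok] = dd
    return d


# ---------------------------------------------------------------------------
# Hirshfeld partitioning and atomic moments
# ---------------------------------------------------------------------------


def build_grid(w, n_radial: int = 75, n_theta: int = 17) -> IntegrationGrid:
    syms = [a.symbol for a in w.atoms]
    return molecular_grid(syms, w.positions, n_radial, n_theta)


def hirshfeld_weights(grid: IntegrationGrid, atoms, charges=None) -> np.ndarray:
    """Stockholder weights w_i(r) = rho_i^free / sum_j rho_j^free, shape (N, nat)."""
    nat = len(atoms)
    if charges is None:
        charges = [0] * nat
    rho_free = np.zeros((grid.n_points, nat))
    for i, a in enumerate(atoms):
        fa = get_free_atom(a.symbol, int(charges[i]))
        r = np.linalg.norm(grid.points - a.position, axis=1)
        rho_free[:, i] = fa.density(r)
    tot = rho_free.sum(axis=1)
    tot = np.where(tot <= 0, 1.0, tot)
    return rho_free / tot[:, None]


def _density_derivs(w, points, batch: int = 20000):
    """rho, |grad rho|^2, laplacian(rho), tau on points (total density)."""
    n = len(points)
    rho = np.empty(n)
    g2 = np.empty(n)
    lap = np.empty(n)
    tau = np.empty(n)
    C = w.mo_coeff
    occ = w.occupations
    for s in range(0, n, batch):
        pts = points[s:s + batch]
        ao, aox, aoy, aoz, aol = ints.ao_values(w.shell_arrays, pts, derivs=True)
        mo = ao @ C
        mox, moy, moz = aox @ C, aoy @ C, aoz @ C
        mol_ = aol @ C
        rho[s:s + batch] = (mo * mo * occ).sum(axis=1)
        gx = 2 * (mo * mox * occ).sum(axis=1)
        gy = 2 * (mo * moy * occ).sum(axis=1)
        gz = 2 * (mo * moz * occ).sum(axis=1)
        g2[s:s + batch] = gx ** 2 + gy ** 2 + gz ** 2
        t = ((mox ** 2 + moy ** 2 + moz ** 2) * occ).sum(axis=1)
        tau[s:s + batch] = t
        lap[s:s + batch] = 2 * ((mo * mol_ * occ).sum(axis=1)) + 2 * t
    return rho, g2, lap, tau


def atomic_moments_volumes(w, grid: IntegrationGrid | None = None,
                           weights: np.ndarray | None = None) -> list:
    """Per-atom XDM data (<M_l^2>, Hirshfeld V, effective alpha inputs)."""
    if grid is None:
        grid = build_grid(w)
    ref_charge = reference_charge_for(w)
    charges = [ref_charge] * len(w.atoms)
    if weights is None:
        weights = hirshfeld_weights(grid, w.atoms, charges)
    rho, g2, lap, tau = _density_derivs(w, grid.points)
    # closed-shell spin components
    d_s = br_hole_dipole(0.5 * rho, 0.25 * g2, 0.5 * lap, 0.5 * tau)
    out = []
    gw = grid.weights
    for i, a in enumerate(w.atoms):
        ri = np.linalg.norm(grid.points - a.position, axis=1)
        wi = weights[:, i] * gw
        moms = []
        for l_ in (1, 2, 3):
            integrand = rho * (ri ** l_ - (ri - d_s) ** l_) ** 2
            moms.append(float(np.dot(wi, integrand)))
        V = float(np.dot(wi, rho * ri ** 3))
        fa = get_free_atom(a.symbol, charges[i])
        if a.alpha_free is not None:
            alpha_free = a.alpha_free
        else:
            alpha_free = fa.alpha_free
        v_free = a.v_free if a.v_free is not None else fa.v_free
        out.append(AtomicXDMData(a.symbol, moms[0], moms[1], moms[2], V,
                                 v_free, alpha_free))
    return out


def effective_polarizabilities(xdm_list) -> np.ndarray:
    return np.array([x.alpha for x in xdm_list])


# ---------------------------------------------------------------------------
# pair coefficients and damped energies
# ---------------------------------------------------------------------------


def pair_coefficients(a: AtomicXDMData, b: AtomicXDMData) -> PairDispersion:
    """C6/C8/C10 from the second-order XDM combining rules (symmetric)."""
    aa, ab = a.alpha, b.alpha
    den = a.m1 * ab + b.m1 * aa
    if den <= 0:
        return PairDispersion(0.0, 0.0, 0.0)
    pref = aa * ab / den
    c6 = pref * a.m1 * b.m1
    c8 = 1.5 * pref * (a.m1 * b.m2 + a.m2 * b.m1)
    c10 = 2.0 * pref * (a.m1 * b.m3 + a.m3 * b.m1) + 4.2 * pref * a.m2 * b.m2
    return PairDispersion(c6, c8, c10)


def critical_radius(c6: float, c8: float, c10: float) -> float:
    """Mean of the three pairwise equal-term radii (zero pairs dropped)."""
    radii = []
    if c6 > 0 and c8 > 0:
        radii.append(np.sqrt(c8 / c6))
    if c6 > 0 and c10 > 0:
        radii.append((c10 / c6) ** 0.25)
    if c8 > 0 and c10 > 0:
        radii.append(np.sqrt(c10 / c8))
    if not radii:
        return 0.0
    return float(np.mean(radii))


def vdw_radius(r_crit: float, params: XDMParams) -> float:
    return params.a1 * r_crit + params.a2_bohr


def pair_dispersion(a: AtomicXDMData, b: AtomicXDMData,
                    params: XDMParams) -> PairDispersion:
    pd = pair_coefficients(a, b)
    pd.r_crit = critical_radius(pd.c6, pd.c8, pd.c10)
    pd.r_vdw = vdw_radius(pd.r_crit, params)
    return pd


def damped_pair_energy(pd: PairDispersion, r: float) -> float:
    """-sum_n C_n / (r^n + R_vdW^n); finite at r = 0."""
    if r < 1e-12 and pd.r_vdw < 1e-12:
        raise ValueError("coincident atoms with zero van der Waals radius")
    e = 0.0
    for n, c in ((6, pd.c6), (8, pd.c8), (10, pd.c10)):
        e -= c / (r ** n + pd.r_vdw ** n)
    return e


def dispersion_sum(xdm_i, pos_i, xdm_j, pos_j, params: XDMParams,
                   cross_only: bool = True) -> float:
    """Damped dispersion between two atom sets (cross pairs)."""
    e = 0.0
    for i, xi in enumerate(xdm_i):
        for j, xj in enumerate(xdm_j):
            r = float(np.linalg.norm(np.asarray(pos_i[i]) - np.asarray(pos_j[j])))
            if r < 1e-10:
                raise ValueError(f"coincident atoms {i}/{j} in dispersion sum")
            e += damped_pair_energy(pair_dispersion(xi, xj, params), r)
    return e


def dispersion_total(xdm_list, positions, params: XDMParams) -> float:
    """Total (intra-set) damped dispersion energy of one atom set."""
    e = 0.0
    n = len(xdm_list)
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(np.asarray(positions[i]) - np.asarray(positions[j])))
            e += damped_pair_energy(pair_dispersion(xdm_list[i], xdm_list[j], params), r)
    return e


def dispersion_interaction(wA, wB, mode: str = "monomer",
                           params: XDMParams = XDMParams(),
                           xdmA=None, xdmB=None) -> float:
    """Dispersion interaction energy (hartree) of a dimer, <= 0.

    ``monomer``: cross-pair sum with monomer-derived coefficients.
    ``dimer``: total-minus-monomers difference with coefficients from the
    concatenated dimer wavefunction.
    """
    from .wfn import concatenate

    if mode not in ("monomer", "dimer"):
        raise ValueError("dispersion mode must be 'monomer' or 'dimer'")
    if mode == "monomer":
        if xdmA is None:
            xdmA = atomic_moments_volumes(wA)
        if xdmB is None:
            xdmB = atomic_moments_volumes(wB)
        return dispersion_sum(xdmA, wA.positions, xdmB, wB.positions, params)
    wAB = concatenate(wA, wB)
    xdmAB = atomic_moments_volumes(wAB)
    posAB = wAB.positions
    eAB = dispersion_total(xdmAB, posAB, params)
    if xdmA is None:
        xdmA = atomic_moments_volumes(wA)
    if xdmB is None:
        xdmB = atomic_moments_volumes(wB)
    eA = dispersion_total(xdmA, wA.positions, params)
    eB = dispersion_total(xdmB, wB.positions, params)
    return eAB - eA - eB
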