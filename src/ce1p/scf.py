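"""Restricted Hartree-Fock with optional fractional occupations.

This is the package's in-process wavefunction provider: a straightforward
DIIS-accelerated RHF in a contracted Gaussian basis.  Fractional occupation
of a degenerate frontier manifold is supported so that open-shell *atoms*
can be solved as spherically averaged species (used for the free-atom
reference densities); molecular calculations are closed-shell only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from . import integrals as ints


class SCFConvergenceError(RuntimeError):
    pass


@dataclass
class SCFResult:
    energy: float                 # total electronic + nuclear energy (hartree)
    mo_coeff: np.ndarray          # (nbf, nmo), all MOs
    mo_energy: np.ndarray         # (nmo,)
    occupations: np.ndarray       # (nmo,), electrons per MO
    converged: bool
    n_iter: int

    @property
    def density(self) -> np.ndarray:
        C = self.mo_coeff
        return (C * self.occupations) @ C.T


def _sym_orth(S: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    w, V = np.linalg.eigh(S)
    if w[0] < tol:
        raise np.linalg.LinAlgError(
            f"overlap matrix near-singular (smallest eigenvalue {w[0]:.3e})"
        )
    return V @ np.diag(w ** -0.5) @ V.T


def _aufbau_occupations(eps: np.ndarray, nelec: float, degen_tol: float = 1e-6) -> np.ndarray:
    """Fill MOs with up to 2 electrons each, splitting electrons equally
    over a degenerate frontier manifold (spherical-atom averaging)."""
    occ = np.zeros_like(eps)
    left = float(nelec)
    i = 0
    n = len(eps)
    while left > 1e-12 and i < n:
        j = i
        while j + 1 < n and eps[j + 1] - eps[i] < degen_tol:
            j += 1
        g = j - i + 1
        put = min(left, 2.0 * g)
        occ[i:j + 1] = put / g
        left -= put
        i = j + 1
    if left > 1e-12:
        raise ValueError("not enough basis functions for the electron count")
    return occ


def nuclear_repulsion(charges, positions) -> float:
    Z = np.asarray(charges, float)
    R = np.asarray(positions, float).reshape(-1, 3)
    e = 0.0
    for i in range(len(Z)):
        for j in range(i + 1, len(Z)):
            e += Z[i] * Z[j] / np.linalg.norm(R[i] - R[j])
    return e


def restricted_hf(
    sa: ints.ShellArrays,
    charges,
    positions,
    n_electrons: float,
    *,
    conv_energy: float = 1e-10,
    conv_grad: float = 1e-8,
    max_iter: int = 200,
    fractional: bool = False,
    diis_size: int = 8,
) -> SCFResult:
    """Solve RHF; ``fractional`` enables spherical-averaging occupations."""
    if n_electrons <= 0:
        raise ValueError("electron count must be positive")
    if not fractional and abs(n_electrons / 2.0 - round(n_electrons / 2.0)) > 1e-12:
        raise ValueError("closed-shell RHF requires an even electron count")
    S, T = ints.overlap_kinetic(sa)
    V = ints.nuclear_attraction(sa, charges, positions)
    h = T + V
    X = _sym_orth(S)
    Enn = nuclear_repulsion(charges, positions)

    # core guess
    eps, Cp = np.linalg.eigh(X.T @ h @ X)
    C = X @ Cp
    occ = _aufbau_occupations(eps, n_electrons) if fractional else _closed_occ(eps, n_electrons)
    D = (C * occ) @ C.T

    one_electron = abs(n_electrons - 1.0) < 1e-12
    if one_electron:
        # a single electron has no self-interaction: the core problem is exact
        D = (C * occ) @ C.T
        E = np.einsum("ij,ij->", D, h) + Enn
        return SCFResult(E, C, eps, occ, True, 1)

    E_old = 0.0
    focks, errs = [], []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Js, Ks = ints.build_jk(sa, [D])
        F = h + Js[0] - 0.5 * Ks[0]
        E = 0.5 * np.einsum("ij,ij->", D, h + F) + Enn
        err = F @ D @ S - S @ D @ F
        gnorm = np.abs(err).max()
        # DIIS
        focks.append(F)
        errs.append(X.T @ err @ X)
        if len(focks) > diis_size:
            focks.pop(0)
            errs.pop(0)
        if len(focks) > 1:
            n = len(focks)
            B = -np.ones((n + 1, n + 1))
            B[n, n] = 0.0
            for i in range(n):
                for j in range(n):
                    B[i, j] = np.einsum("ij,ij->", errs[i], errs[j])
            rhs = np.zeros(n + 1)
            rhs[n] = -1.0
            try:
                c = np.linalg.solve(B, rhs)[:n]
                F = sum(ci * Fi for ci, Fi in zip(c, focks))
            except np.linalg.LinAlgError:
                pass
        eps, Cp = np.linalg.eigh(X.T @ F @ X)
        C = X @ Cp
        occ = _aufbau_occupations(eps, n_electrons) if fractional else _closed_occ(eps, n_electrons)
        D_new = (C * occ) @ C.T
        dE = abs(E - E_old)
        if dE < conv_energy and gnorm < conv_grad:
            converged = True
            D = D_new
            break
        D = D_new
        E_old = E
    if not converged:
        raise SCFConvergenceError(
            f"SCF failed to converge in {max_iter} iterations "
            f"(dE={dE:.2e}, |FDS-SDF|={gnorm:.2e})"
        )
    # final consistent energy
    Js, Ks = ints.build_jk(sa, [D])
    F = h + Js[0] - 0.5 * Ks[0]
    E = 0.5 * np.einsum("ij,ij->", D, h + F) + Enn
    eps, Cp = np.linalg.eigh(X.T @ F @ X)
    C = X @ Cp
    occ = _aufbau_occupations(eps, n_electrons) if fractional else _closed_occ(eps, n_electrons)
    return SCFResult(E, C, eps, occ, converged, it)


def _closed_occ(eps: np.ndarray, nelec: float) -> np.ndarray:
    occ = np.zeros_like(eps)
    nocc = int(round(nelec / 2.0))
    occ[:nocc] = 2.0
    return occ
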