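"""Free-species reference atoms: spherically averaged densities and volumes.

Hirshfeld partitioning and the Eq.-style effective polarizabilities need
gas-phase reference densities rho_free(r) and free volumes V' = <r^3>.
These are computed on demand with the package's own fractional-occupation
RHF (spherically averaged atoms) in the built-in basis, and cached.

A *bare monatomic ion* references its own charge state (the free species it
actually is); polyatomic molecules reference neutral atoms, the standard
stockholder choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from types import SimpleNamespace

import numpy as np

from . import basis as basismod
from . import integrals as ints
from .constants import atomic_number, free_polarizability
from .scf import restricted_hf


@dataclass(frozen=True)
class FreeAtom:
    symbol: str
    charge: int
    energy: float
    v_free: float            # <r^3> volume integral (bohr^3)
    alpha_free: float        # tabulated free polarizability (bohr^3)
    _r: np.ndarray           # radial table (bohr)
    _logrho: np.ndarray

    def density(self, r) -> np.ndarray:
        """Spherically averaged density at radial distance(s) r."""
        r = np.asarray(r, float)
        lr = np.interp(r, self._r, self._logrho)
        # exponential extrapolation beyond the table
        tail = r > self._r[-1]
        if np.any(tail):
            slope = (self._logrho[-1] - self._logrho[-2]) / (self._r[-1] - self._r[-2])
            lr = np.where(tail, self._logrho[-1] + slope * (r - self._r[-1]), lr)
        return np.exp(lr)


@lru_cache(maxsize=None)
def get_free_atom(symbol: str, charge: int = 0,
                  basis: str = basismod.DEFAULT_BASIS) -> FreeAtom:
    Z = atomic_number(symbol)
    nelec = Z - charge
    if nelec <= 0:
        raise ValueError(f"{symbol}^{charge:+d} has no electrons")
    shells = [SimpleNamespace(l=l, pure=True, center=np.zeros(3), exps=e, coefs=c)
              for (_, l, _, e, c) in basismod.shells_for_molecule([symbol], basis)]
    sa = ints.ShellArrays.build(shells)
    res = restricted_hf(sa, [float(Z)], [[0.0, 0.0, 0.0]], float(nelec),
                        fractional=True, conv_energy=1e-10, conv_grad=1e-7)
    # radial density table (spherical average over a small angular set)
    r = np.geomspace(1e-6, 40.0, 600)
    from .grids import angular_grid
    dirs, dw = angular_grid(6)
    pts = (r[:, None, None] * dirs[None, :, :]).reshape(-1, 3)
    ao = ints.ao_values(sa, pts)
    mo = ao @ res.mo_coeff
    rho = (mo * mo * res.occupations).sum(axis=1).reshape(len(r), len(dirs))
    rho_sph = (rho * dw).sum(axis=1) / (4 * np.pi)
    rho_sph = np.maximum(rho_sph, 1e-300)
    # V' = integral rho r^3 d3r  (radial quadrature on the table)
    v_free = float(np.trapezoid(4 * np.pi * rho_sph * r ** 5, r))
    return FreeAtom(symbol, charge, res.energy, v_free,
                    free_polarizability(symbol, charge), r, np.log(rho_sph))


def reference_charge_for(wavefunction) -> int:
    """Charge state used for the free reference of each atom in a species."""
    if len(wavefunction.atoms) == 1 and wavefunction.charge != 0:
        return int(wavefunction.charge)
    return 0
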