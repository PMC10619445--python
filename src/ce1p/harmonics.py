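"""Real spherical harmonics and Cartesian-to-pure transformation matrices.

Conventions (fixed package-wide):

* real (tesseral) harmonics without the Condon-Shortley phase,
* within a shell the functions are ordered m = -l ... +l, which for l = 1
  gives the (y, z, x) ordering of the p functions.
"""

from __future__ import annotations

from functools import lru_cache

import math

import numpy as np
from scipy.special import lpmv

from .integrals import cartesian_components, primitive_norm, _double_factorial


def real_sph_harm(l: int, m: int, theta, phi):
    """Real spherical harmonic y_lm(theta, phi), unit L2 norm on the sphere."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    am = abs(m)
    # associated Legendre without Condon-Shortley phase
    plm = (-1.0) ** am * lpmv(am, l, np.cos(theta))
    norm = np.sqrt(
        (2 * l + 1)
        / (4 * np.pi)
        * math.factorial(l - am)
        / math.factorial(l + am)
    )
    if m > 0:
        return np.sqrt(2.0) * norm * plm * np.cos(am * phi)
    if m < 0:
        return np.sqrt(2.0) * norm * plm * np.sin(am * phi)
    return norm * plm


def _gauss_moment(n: int, gamma: float) -> float:
    """integral x^n exp(-gamma x^2) dx over the real line."""
    if n % 2 == 1:
        return 0.0
    return _double_factorial(n - 1) / (2.0 * gamma) ** (n // 2) * np.sqrt(np.pi / gamma)


@lru_cache(maxsize=None)
def cart_prim_overlap_unit(l: int) -> np.ndarray:
    """Overlap of same-centre cartesian components of one alpha=1 primitive.

    Components carry the shared x^l radial norm; the resulting matrix is
    exponent independent, which is all the pure-transform construction needs.
    """
    comps = cartesian_components(l)
    N = primitive_norm(1.0, l)
    n = len(comps)
    S = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            i = comps[a] + comps[b]
            S[a, b] = N * N * _gauss_moment(i[0], 2.0) * _gauss_moment(i[1], 2.0) * _gauss_moment(i[2], 2.0)
    return S


@lru_cache(maxsize=None)
def cart_to_pure(l: int) -> np.ndarray:
    """Matrix T, shape (2l+1, ncart): pure AO_m = sum_c T[m,c] cart AO_c.

    Rows ordered m = -l..+l.  Built by sampling solid harmonics on a
    deterministic set of directions (exact: the monomials span the space),
    then normalizing each row against the one-primitive cartesian overlap.
    """
    comps = cartesian_components(l)
    nc = len(comps)
    rng = np.random.default_rng(20231031)
    npts = max(4 * nc, 24)
    v = rng.normal(size=(npts, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    theta = np.arccos(np.clip(v[:, 2], -1, 1))
    phi = np.arctan2(v[:, 1], v[:, 0])
    M = np.empty((npts, nc))
    for c, (i, j, k) in enumerate(comps):
        M[:, c] = v[:, 0] ** i * v[:, 1] ** j * v[:, 2] ** k
    Y = np.empty((npts, 2 * l + 1))
    for m in range(-l, l + 1):
        Y[:, m + l] = real_sph_harm(l, m, theta, phi)
    X, *_ = np.linalg.lstsq(M, Y, rcond=None)
    T = X.T  # (2l+1, ncart), coefficients in monomial basis (r^l y_lm)
    S = cart_prim_overlap_unit(l)
    for row in range(2 * l + 1):
        nrm = T[row] @ S @ T[row]
        T[row] /= np.sqrt(nrm)
    # clean numerical noise
    T[np.abs(T) < 1e-12] = 0.0
    return T
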