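"""Rotation matrices for real-spherical-harmonic and Cartesian shells.

Pure shells use the recurrence of Ivanic & Ruedenberg on real solid
harmonics (m ordered -l..+l, so the l = 1 block acts on (y, z, x)).
Cartesian shells use the induced monomial transformation.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .integrals import cartesian_components, component_norm_ratio


class ImproperRotationError(ValueError):
    pass


def check_rotation(R: np.ndarray, tol: float = 1e-8):
    R = np.asarray(R, float)
    if R.shape != (3, 3):
        raise ImproperRotationError("rotation must be a 3x3 matrix")
    if np.abs(R @ R.T - np.eye(3)).max() > tol:
        raise ImproperRotationError("matrix is not orthogonal")
    if np.linalg.det(R) < 0:
        raise ImproperRotationError("improper rotation (det = -1) rejected")
    return R


def rotation_blocks(l: int, R: np.ndarray) -> np.ndarray:
    """(2l+1)x(2l+1) orthogonal matrix D with  y_lm(R^-1 r) = sum_m' D[m',m] y_lm'(r).

    Transformed-shell MO coefficients are obtained as c' = D c.
    """
    R = check_rotation(np.asarray(R, float))
    if l == 0:
        return np.ones((1, 1))
    # l=1 block in (y,z,x) ordering: D[a,b] = R[o_a, o_b]
    o = np.array([1, 2, 0])
    D1 = R[np.ix_(o, o)]
    if l == 1:
        return D1
    D = D1
    for ll in range(2, l + 1):
        D = _ir_step(ll, D1, D)
    return D


def _ir_step(l: int, r: np.ndarray, Dlm1: np.ndarray) -> np.ndarray:
    """One Ivanic-Ruedenberg recurrence step: D_{l-1} -> D_l.

    ``r`` is the l=1 block indexed [-1,0,1] (i.e. (y,z,x)); ``Dlm1`` is the
    (2l-1)x(2l-1) block for l-1.
    """

    def rr(i, j):
        return r[i + 1, j + 1]

    def dd(mu, mp):
        return Dlm1[mu + (l - 1), mp + (l - 1)]

    def P(i, mu, mp):
        if abs(mp) < l:
            return rr(i, 0) * dd(mu, mp)
        if mp == l:
            return rr(i, 1) * dd(mu, l - 1) - rr(i, -1) * dd(mu, -(l - 1))
        return rr(i, 1) * dd(mu, -(l - 1)) + rr(i, -1) * dd(mu, l - 1)

    out = np.zeros((2 * l + 1, 2 * l + 1))
    for m in range(-l, l + 1):
        for mp in range(-l, l + 1):
            denom = (l + mp) * (l - mp) if abs(mp) < l else (2 * l) * (2 * l - 1)
            u = np.sqrt((l + m) * (l - m) / denom)
            dm0 = 1.0 if m == 0 else 0.0
            v = 0.5 * np.sqrt((1 + dm0) * (l + abs(m) - 1) * (l + abs(m)) / denom) * (1 - 2 * dm0)
            w = -0.5 * np.sqrt((l - abs(m) - 1) * (l - abs(m)) / denom) * (1 - dm0)
            val = 0.0
            if u != 0.0:
                val += u * P(0, m, mp)
            if v != 0.0:
                if m == 0:
                    V = P(1, 1, mp) + P(-1, -1, mp)
                elif m > 0:
                    d1 = 1.0 if m == 1 else 0.0
                    V = P(1, m - 1, mp) * np.sqrt(1 + d1) - P(-1, -m + 1, mp) * (1 - d1)
                else:
                    d1 = 1.0 if m == -1 else 0.0
                    V = P(1, m + 1, mp) * (1 - d1) + P(-1, -m - 1, mp) * np.sqrt(1 + d1)
                val += v * V
            if w != 0.0:
                if m > 0:
                    W = P(1, m + 1, mp) + P(-1, -m - 1, mp)
                else:
                    W = P(1, m - 1, mp) - P(-1, -m + 1, mp)
                val += w * W
            out[m + l, mp + l] = val
    return out


@lru_cache(maxsize=128)
def _cart_sample(l: int):
    comps = cartesian_components(l)
    rng = np.random.default_rng(1998 + l)
    pts = rng.normal(size=(4 * len(comps), 3))
    M = np.stack([pts[:, 0] ** i * pts[:, 1] ** j * pts[:, 2] ** k
                  for (i, j, k) in comps], axis=1)
    return comps, pts, M, np.linalg.pinv(M)


def cartesian_rotation_block(l: int, R: np.ndarray) -> np.ndarray:
    """Transformation of (renormalized) Cartesian shell components under R."""
    R = check_rotation(np.asarray(R, float))
    if l == 0:
        return np.ones((1, 1))
    comps, pts, M, Minv = _cart_sample(l)
    q = pts @ R  # rows: R^-1 applied to each point (R^T = R^-1)
    Mrot = np.stack([q[:, 0] ** i * q[:, 1] ** j * q[:, 2] ** k
                     for (i, j, k) in comps], axis=1)
    # monomial_c(R^-1 r) = sum_c' D[c',c] monomial_c'(r)
    D = (Minv @ Mrot)
    ratios = component_norm_ratio(l)
    D = ratios[:, None] * D * (1.0 / ratios)[None, :]
    Dn = D.copy()
    Dn[np.abs(Dn) < 1e-13] = 0.0
    return Dn


def orthogonal_shell_block(l: int, M: np.ndarray, pure: bool = True) -> np.ndarray:
    """Shell transformation for any orthogonal M (proper or improper).

    Crystal symmetry operations include inversions and mirrors; for pure
    shells an improper M factors as (-1)^l times the rotation block of -M.
    """
    M = np.asarray(M, float)
    if not pure:
        return cartesian_rotation_block_any(l, M)
    if np.linalg.det(M) > 0:
        return rotation_blocks(l, M)
    return (-1.0) ** l * rotation_blocks(l, -M)


def cartesian_rotation_block_any(l: int, M: np.ndarray) -> np.ndarray:
    """Cartesian shell transformation for any orthogonal M."""
    M = np.asarray(M, float)
    if np.abs(M @ M.T - np.eye(3)).max() > 1e-8:
        raise ImproperRotationError("matrix is not orthogonal")
    if l == 0:
        return np.ones((1, 1))
    comps, pts, Msamp, Minv = _cart_sample(l)
    q = pts @ M
    Mrot = np.stack([q[:, 0] ** i * q[:, 1] ** j * q[:, 2] ** k
                     for (i, j, k) in comps], axis=1)
    D = Minv @ Mrot
    ratios = component_norm_ratio(l)
    D = ratios[:, None] * D * (1.0 / ratios)[None, :]
    D[np.abs(D) < 1e-13] = 0.0
    return D
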