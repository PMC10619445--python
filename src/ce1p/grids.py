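"""Becke-partitioned atom-centred integration grids.

Radial quadrature: Gauss-Chebyshev (second kind) nodes under the Becke
rational map r = R_m (1+x)/(1-x), with the map radius R_m set per element
from Bragg-Slater radii.  Angular quadrature: Gauss-Legendre in cos(theta)
times a uniform azimuthal grid, which integrates spherical harmonics up to
degree ~2*n_theta exactly.  Cell weights follow Becke's fuzzy-polyhedra
scheme (three smoothing iterations, no atomic-size adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import bragg_radius_bohr

DEFAULT_N_RADIAL = 75
DEFAULT_N_THETA = 17


@dataclass
class IntegrationGrid:
    points: np.ndarray       # (N,3) bohr
    weights: np.ndarray      # (N,) includes radial, angular and cell weights
    atom_index: np.ndarray   # (N,) owning atom

    def __post_init__(self):
        if np.any(self.weights <= 0):
            # Becke weights can underflow to zero far from the owner; drop them
            keep = self.weights > 0
            self.points = self.points[keep]
            self.weights = self.weights[keep]
            self.atom_index = self.atom_index[keep]

    @property
    def n_points(self) -> int:
        return len(self.weights)


def radial_grid(n: int, r_map: float):
    """Nodes/weights for integral f(r) r^2 dr on (0, inf)."""
    i = np.arange(1, n + 1)
    theta = i * np.pi / (n + 1)
    x = np.cos(theta)
    w_gc = np.pi / (n + 1) * np.sin(theta)  # for integral g(x) dx on (-1,1)
    r = r_map * (1 + x) / (1 - x)
    dr = 2 * r_map / (1 - x) ** 2
    return r[::-1], (w_gc * dr * r ** 2)[::-1]


def angular_grid(n_theta: int):
    """Unit-sphere nodes/weights (integrate to 4*pi)."""
    x, w = np.polynomial.legendre.leggauss(n_theta)
    n_phi = 2 * n_theta
    phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    st = np.sqrt(1 - x ** 2)
    pts = np.empty((n_theta * n_phi, 3))
    wts = np.empty(n_theta * n_phi)
    k = 0
    for it in range(n_theta):
        for ip in range(n_phi):
            pts[k] = (st[it] * np.cos(phi[ip]), st[it] * np.sin(phi[ip]), x[it])
            wts[k] = w[it] * 2 * np.pi / n_phi
            k += 1
    return pts, wts


def becke_weights(points: np.ndarray, centers: np.ndarray, owner: np.ndarray,
                  k_iter: int = 3) -> np.ndarray:
    """Becke partition-of-unity cell weights for each point's owning atom."""
    nat = len(centers)
    if nat == 1:
        return np.ones(len(points))
    d = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=2)  # (N, nat)
    Rij = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    P = np.ones((len(points), nat))
    for i in range(nat):
        for j in range(nat):
            if i == j:
                continue
            mu = (d[:, i] - d[:, j]) / Rij[i, j]
            f = mu
            for _ in range(k_iter):
                f = 1.5 * f - 0.5 * f ** 3
            P[:, i] *= 0.5 * (1.0 - f)
    tot = P.sum(axis=1)
    tot[tot == 0] = 1.0
    return P[np.arange(len(points)), owner] / tot


def molecular_grid(symbols, centers, n_radial: int = DEFAULT_N_RADIAL,
                   n_theta: int = DEFAULT_N_THETA) -> IntegrationGrid:
    centers = np.asarray(centers, float).reshape(-1, 3)
    ang_pts, ang_wts = angular_grid(n_theta)
    all_pts, all_wts, all_idx = [], [], []
    for ia, (sym, c) in enumerate(zip(symbols, centers)):
        r, wr = radial_grid(n_radial, bragg_radius_bohr(sym))
        pts = (r[:, None, None] * ang_pts[None, :, :]).reshape(-1, 3) + c
        wts = (wr[:, None] * ang_wts[None, :]).reshape(-1)
        all_pts.append(pts)
        all_wts.append(wts)
        all_idx.append(np.full(len(wts), ia))
    pts = np.concatenate(all_pts)
    wts = np.concatenate(all_wts)
    idx = np.concatenate(all_idx)
    cell = becke_weights(pts, centers, idx)
    return IntegrationGrid(pts, wts * cell, idx)
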