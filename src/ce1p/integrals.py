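"""Gaussian-basis molecular integrals (McMurchie-Davidson scheme).

Provides overlap, kinetic, nuclear attraction, electrostatic potential and
field, two-electron repulsion (as direct J/K builds or full tensors) and
basis-function evaluation on grids, for segmented-contracted Cartesian or
pure-spherical shells up to l = 4.

The flattened :class:`ShellArrays` layout is what the numba kernels consume;
:mod:`ce1p.wfn` builds it from its shell objects.  All quantities are in
hartree/bohr.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

LMAX = 4

# ---------------------------------------------------------------------------
# Cartesian component tables (lexicographic: xx, xy, xz, yy, yz, zz for l=2)
# ---------------------------------------------------------------------------


def cartesian_components(l: int) -> np.ndarray:
    comps = [(i, j, l - i - j) for i in range(l, -1, -1) for j in range(l - i, -1, -1)]
    return np.array(comps, dtype=np.int64)


def ncart(l: int) -> int:
    return (l + 1) * (l + 2) // 2


def npure(l: int) -> int:
    return 2 * l + 1


_COMPS_FLAT = np.concatenate([cartesian_components(l) for l in range(LMAX + 3)])
_COMPS_OFF = np.cumsum([0] + [ncart(l) for l in range(LMAX + 3)])[:-1].astype(np.int64)


def _double_factorial(n: int) -> float:
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(alpha: float, l: int) -> float:
    """Norm of an x^l-type Cartesian Gaussian primitive."""
    return (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0) / np.sqrt(
        _double_factorial(2 * l - 1)
    )


def component_norm_ratio(l: int) -> np.ndarray:
    """Per-component renormalization for exposed Cartesian shells.

    With the shared x^l radial norm, a component x^i y^j z^k has self-overlap
    (2i-1)!!(2j-1)!!(2k-1)!!/(2l-1)!!; this returns the factors restoring unit
    norm per component.
    """
    comps = cartesian_components(l)
    dfl = _double_factorial(2 * l - 1)
    out = np.empty(len(comps))
    for n, (i, j, k) in enumerate(comps):
        out[n] = np.sqrt(
            dfl
            / (
                _double_factorial(2 * i - 1)
                * _double_factorial(2 * j - 1)
                * _double_factorial(2 * k - 1)
            )
        )
    return out


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _boys(mmax, T, out):
    """Boys functions F_0..F_mmax at T (stable up/down recursions)."""
    if T < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2.0 * m + 1.0)
        return
    if T < 35.0:
        # series for F_mmax, then downward
        num = 1.0
        den = 2.0 * mmax + 1.0
        term = 1.0 / den
        s = term
        k = 1
        while True:
            term *= 2.0 * T / (den + 2.0 * k)
            s += term
            if term < 1e-17 * s or k > 300:
                break
            k += 1
        eT = np.exp(-T)
        out[mmax] = s * eT
        for m in range(mmax - 1, -1, -1):
            out[m] = (2.0 * T * out[m + 1] + eT) / (2.0 * m + 1.0)
    else:
        eT = np.exp(-T) if T < 700.0 else 0.0
        out[0] = 0.5 * np.sqrt(np.pi / T)
        for m in range(mmax):
            out[m + 1] = ((2.0 * m + 1.0) * out[m] - eT) / (2.0 * T)


@njit(cache=True)
def _fill_E(l1, l2, a, b, AB, E):
    """Hermite expansion coefficients E[t,i,j] (one dimension)."""
    p = a + b
    mu = a * b / p
    E[:, :, :] = 0.0
    E[0, 0, 0] = np.exp(-mu * AB * AB)
    XPA = -b * AB / p
    XPB = a * AB / p
    for i in range(l1):
        for t in range(i + 2):
            v = XPA * E[t, i, 0]
            if t > 0:
                v += E[t - 1, i, 0] / (2.0 * p)
            if t + 1 <= i:
                v += (t + 1.0) * E[t + 1, i, 0]
            E[t, i + 1, 0] = v
    for i in range(l1 + 1):
        for j in range(l2):
            for t in range(i + j + 2):
                v = XPB * E[t, i, j]
                if t > 0:
                    v += E[t - 1, i, j] / (2.0 * p)
                if t + 1 <= i + j:
                    v += (t + 1.0) * E[t + 1, i, j]
                E[t, i, j + 1] = v


@njit(cache=True)
def _fill_R(nmax, p, X, Y, Z, R):
    """Hermite Coulomb integrals R[t,u,v] up to total order nmax.

    R_{tuv} = (d/dPx)^t (d/dPy)^u (d/dPz)^v F_0-type kernel at P-C = (X,Y,Z).
    """
    T = p * (X * X + Y * Y + Z * Z)
    F = np.empty(nmax + 1)
    _boys(nmax, T, F)
    # aux[n, t, u, v]
    aux = np.zeros((nmax + 1, nmax + 1, nmax + 1, nmax + 1))
    f = 1.0
    for n in range(nmax + 1):
        aux[n, 0, 0, 0] = f * F[n]
        f *= -2.0 * p
    for t in range(nmax):
        for n in range(nmax - t):
            for u in range(nmax + 1):
                for v in range(nmax + 1):
                    if t + 1 + u + v > nmax:
                        continue
                    val = X * aux[n + 1, t, u, v]
                    if t > 0:
                        val += t * aux[n + 1, t - 1, u, v]
                    aux[n, t + 1, u, v] = val
    # after t recursion only rows with u=v=0 are valid sources for u recursion
    for u in range(nmax):
        for n in range(nmax - u):
            for t in range(nmax + 1):
                for v in range(nmax + 1):
                    if t + u + 1 + v > nmax:
                        continue
                    val = Y * aux[n + 1, t, u, v]
                    if u > 0:
                        val += u * aux[n + 1, t, u - 1, v]
                    aux[n, t, u + 1, v] = val
    for v in range(nmax):
        for n in range(nmax - v):
            for t in range(nmax + 1):
                for u in range(nmax + 1):
                    if t + u + v + 1 > nmax:
                        continue
                    val = Z * aux[n + 1, t, u, v]
                    if v > 0:
                        val += v * aux[n + 1, t, u, v - 1]
                    aux[n, t, u, v + 1] = val
    for t in range(nmax + 1):
        for u in range(nmax + 1):
            for v in range(nmax + 1):
                if t + u + v <= nmax:
                    R[t, u, v] = aux[0, t, u, v]


@njit(cache=True)
def _overlap_kinetic_cart(ls, centers, pstart, pcount, exps, coefs,
                          cart_off, nc_tot, comps_flat, comps_off):
    S = np.zeros((nc_tot, nc_tot))
    T = np.zeros((nc_tot, nc_tot))
    nsh = ls.shape[0]
    for A in range(nsh):
        la = ls[A]
        ca = comps_off[la]
        na = (la + 1) * (la + 2) // 2
        for B in range(A, nsh):
            lb = ls[B]
            cb = comps_off[lb]
            nb = (lb + 1) * (lb + 2) // 2
            Sblk = np.zeros((na, nb))
            Tblk = np.zeros((na, nb))
            for pa in range(pstart[A], pstart[A] + pcount[A]):
                a = exps[pa]
                for pb in range(pstart[B], pstart[B] + pcount[B]):
                    b = exps[pb]
                    cc = coefs[pa] * coefs[pb]
                    p = a + b
                    pref = (np.pi / p) ** 1.5
                    # per-dimension E arrays; need up to lb+2 on the ket
                    Ex = np.zeros((la + lb + 3, la + 1, lb + 3))
                    Ey = np.zeros((la + lb + 3, la + 1, lb + 3))
                    Ez = np.zeros((la + lb + 3, la + 1, lb + 3))
                    _fill_E(la, lb + 2, a, b, centers[A, 0] - centers[B, 0], Ex)
                    _fill_E(la, lb + 2, a, b, centers[A, 1] - centers[B, 1], Ey)
                    _fill_E(la, lb + 2, a, b, centers[A, 2] - centers[B, 2], Ez)
                    for ia in range(na):
                        i1 = comps_flat[ca + ia, 0]
                        j1 = comps_flat[ca + ia, 1]
                        k1 = comps_flat[ca + ia, 2]
                        for ib in range(nb):
                            i2 = comps_flat[cb + ib, 0]
                            j2 = comps_flat[cb + ib, 1]
                            k2 = comps_flat[cb + ib, 2]
                            sx = Ex[0, i1, i2]
                            sy = Ey[0, j1, j2]
                            sz = Ez[0, k1, k2]
                            Sblk[ia, ib] += cc * pref * sx * sy * sz
                            # kinetic: -1/2 sum of second derivatives on ket
                            tx = b * (2.0 * i2 + 1.0) * Ex[0, i1, i2] - 2.0 * b * b * Ex[0, i1, i2 + 2]
                            if i2 >= 2:
                                tx -= 0.5 * i2 * (i2 - 1.0) * Ex[0, i1, i2 - 2]
                            ty = b * (2.0 * j2 + 1.0) * Ey[0, j1, j2] - 2.0 * b * b * Ey[0, j1, j2 + 2]
                            if j2 >= 2:
                                ty -= 0.5 * j2 * (j2 - 1.0) * Ey[0, j1, j2 - 2]
                            tz = b * (2.0 * k2 + 1.0) * Ez[0, k1, k2] - 2.0 * b * b * Ez[0, k1, k2 + 2]
                            if k2 >= 2:
                                tz -= 0.5 * k2 * (k2 - 1.0) * Ez[0, k1, k2 - 2]
                            Tblk[ia, ib] += cc * pref * (tx * sy * sz + sx * ty * sz + sx * sy * tz)
            for ia in range(na):
                for ib in range(nb):
                    S[cart_off[A] + ia, cart_off[B] + ib] = Sblk[ia, ib]
                    S[cart_off[B] + ib, cart_off[A] + ia] = Sblk[ia, ib]
                    T[cart_off[A] + ia, cart_off[B] + ib] = Tblk[ia, ib]
                    T[cart_off[B] + ib, cart_off[A] + ia] = Tblk[ia, ib]
    return S, T


@njit(cache=True)
def _nuclear_cart(ls, centers, pstart, pcount, exps, coefs,
                  cart_off, nc_tot, comps_flat, comps_off, Zs, Zpos):
    V = np.zeros((nc_tot, nc_tot))
    nsh = ls.shape[0]
    for A in range(nsh):
        la = ls[A]
        ca = comps_off[la]
        na = (la + 1) * (la + 2) // 2
        for B in range(A, nsh):
            lb = ls[B]
            cb = comps_off[lb]
            nb = (lb + 1) * (lb + 2) // 2
            lt = la + lb
            Vblk = np.zeros((na, nb))
            for pa in range(pstart[A], pstart[A] + pcount[A]):
                a = exps[pa]
                for pb in range(pstart[B], pstart[B] + pcount[B]):
                    b = exps[pb]
                    cc = coefs[pa] * coefs[pb]
                    p = a + b
                    Px = (a * centers[A, 0] + b * centers[B, 0]) / p
                    Py = (a * centers[A, 1] + b * centers[B, 1]) / p
                    Pz = (a * centers[A, 2] + b * centers[B, 2]) / p
                    Ex = np.zeros((lt + 1, la + 1, lb + 1))
                    Ey = np.zeros((lt + 1, la + 1, lb + 1))
                    Ez = np.zeros((lt + 1, la + 1, lb + 1))
                    _fill_E(la, lb, a, b, centers[A, 0] - centers[B, 0], Ex)
                    _fill_E(la, lb, a, b, centers[A, 1] - centers[B, 1], Ey)
                    _fill_E(la, lb, a, b, centers[A, 2] - centers[B, 2], Ez)
                    R = np.zeros((lt + 1, lt + 1, lt + 1))
                    for iz in range(Zs.shape[0]):
                        _fill_R(lt, p, Px - Zpos[iz, 0], Py - Zpos[iz, 1], Pz - Zpos[iz, 2], R)
                        pref = -Zs[iz] * 2.0 * np.pi / p * cc
                        for ia in range(na):
                            i1 = comps_flat[ca + ia, 0]
                            j1 = comps_flat[ca + ia, 1]
                            k1 = comps_flat[ca + ia, 2]
                            for ib in range(nb):
                                i2 = comps_flat[cb + ib, 0]
                                j2 = comps_flat[cb + ib, 1]
                                k2 = comps_flat[cb + ib, 2]
                                acc = 0.0
                                for t in range(i1 + i2 + 1):
                                    for u in range(j1 + j2 + 1):
                                        for v in range(k1 + k2 + 1):
                                            acc += Ex[t, i1, i2] * Ey[u, j1, j2] * Ez[v, k1, k2] * R[t, u, v]
                                Vblk[ia, ib] += pref * acc
            for ia in range(na):
                for ib in range(nb):
                    V[cart_off[A] + ia, cart_off[B] + ib] = Vblk[ia, ib]
                    V[cart_off[B] + ib, cart_off[A] + ia] = Vblk[ia, ib]
    return V


@njit(cache=True)
def _esp_field_cart(ls, centers, pstart, pcount, exps, coefs,
                    cart_off, nc_tot, comps_flat, comps_off, D, points):
    """Electron-density electrostatic potential integral and its gradient.

    Returns per point:  Vel = sum_{munu} D_munu (munu| 1/|r-P| )  and
    Gel[k] = d(Vel)/dP_k.  (Physics signs are applied by the caller.)
    """
    npts = points.shape[0]
    Vel = np.zeros(npts)
    Gel = np.zeros((npts, 3))
    nsh = ls.shape[0]
    for A in range(nsh):
        la = ls[A]
        ca = comps_off[la]
        na = (la + 1) * (la + 2) // 2
        for B in range(A, nsh):
            lb = ls[B]
            cb = comps_off[lb]
            nb = (lb + 1) * (lb + 2) // 2
            lt = la + lb
            # screen by density block magnitude
            dmax = 0.0
            for ia in range(na):
                for ib in range(nb):
                    v = abs(D[cart_off[A] + ia, cart_off[B] + ib])
                    if v > dmax:
                        dmax = v
            if dmax < 1e-14:
                continue
            sym = 1.0 if A == B else 2.0
            for pa in range(pstart[A], pstart[A] + pcount[A]):
                a = exps[pa]
                for pb in range(pstart[B], pstart[B] + pcount[B]):
                    b = exps[pb]
                    cc = coefs[pa] * coefs[pb]
                    p = a + b
                    mu_ab = a * b / p
                    rab2 = 0.0
                    for k in range(3):
                        d = centers[A, k] - centers[B, k]
                        rab2 += d * d
                    if mu_ab * rab2 > 46.0:  # exp(-46) ~ 1e-20
                        continue
                    Px = (a * centers[A, 0] + b * centers[B, 0]) / p
                    Py = (a * centers[A, 1] + b * centers[B, 1]) / p
                    Pz = (a * centers[A, 2] + b * centers[B, 2]) / p
                    Ex = np.zeros((lt + 1, la + 1, lb + 1))
                    Ey = np.zeros((lt + 1, la + 1, lb + 1))
                    Ez = np.zeros((lt + 1, la + 1, lb + 1))
                    _fill_E(la, lb, a, b, centers[A, 0] - centers[B, 0], Ex)
                    _fill_E(la, lb, a, b, centers[A, 1] - centers[B, 1], Ey)
                    _fill_E(la, lb, a, b, centers[A, 2] - centers[B, 2], Ez)
                    R = np.zeros((lt + 2, lt + 2, lt + 2))
                    for ip in range(npts):
                        _fill_R(lt + 1, p, Px - points[ip, 0], Py - points[ip, 1],
                                Pz - points[ip, 2], R)
                        pref = 2.0 * np.pi / p * cc * sym
                        for ia in range(na):
                            i1 = comps_flat[ca + ia, 0]
                            j1 = comps_flat[ca + ia, 1]
                            k1 = comps_flat[ca + ia, 2]
                            for ib in range(nb):
                                dab = D[cart_off[A] + ia, cart_off[B] + ib]
                                if A == B:
                                    dab = 0.5 * (dab + D[cart_off[B] + ib, cart_off[A] + ia])
                                else:
                                    dab = 0.5 * (dab + D[cart_off[B] + ib, cart_off[A] + ia])
                                if abs(dab) < 1e-16:
                                    continue
                                i2 = comps_flat[cb + ib, 0]
                                j2 = comps_flat[cb + ib, 1]
                                k2 = comps_flat[cb + ib, 2]
                                acc = 0.0
                                gx = 0.0
                                gy = 0.0
                                gz = 0.0
                                for t in range(i1 + i2 + 1):
                                    for u in range(j1 + j2 + 1):
                                        for v in range(k1 + k2 + 1):
                                            e = Ex[t, i1, i2] * Ey[u, j1, j2] * Ez[v, k1, k2]
                                            acc += e * R[t, u, v]
                                            # d/dP_k of R_{tuv}(P - C): here the
                                            # derivative wrt the field point C is
                                            # -d/d(X_PC), i.e. -R_{t+1,u,v} etc.
                                            gx -= e * R[t + 1, u, v]
                                            gy -= e * R[t, u + 1, v]
                                            gz -= e * R[t, u, v + 1]
                                Vel[ip] += pref * dab * acc
                                Gel[ip, 0] += pref * dab * gx
                                Gel[ip, 1] += pref * dab * gy
                                Gel[ip, 2] += pref * dab * gz
    return Vel, Gel


@njit(cache=True)
def _eri_block(la, lb, lc, ld, Acen, Bcen, Ccen, Dcen,
               ea, ca_, eb, cb_, ec, cc_, ed, cd_,
               comps_flat, comps_off):
    na = (la + 1) * (la + 2) // 2
    nb = (lb + 1) * (lb + 2) // 2
    nc = (lc + 1) * (lc + 2) // 2
    nd = (ld + 1) * (ld + 2) // 2
    lab = la + lb
    lcd = lc + ld
    ltot = lab + lcd
    blk = np.zeros((na, nb, nc, nd))
    oa = comps_off[la]
    ob = comps_off[lb]
    oc = comps_off[lc]
    od = comps_off[ld]
    for pa in range(ea.shape[0]):
        a = ea[pa]
        for pb in range(eb.shape[0]):
            b = eb[pb]
            p = a + b
            mu = a * b / p
            rab2 = 0.0
            for k in range(3):
                d = Acen[k] - Bcen[k]
                rab2 += d * d
            if mu * rab2 > 46.0:
                continue
            cab = ca_[pa] * cb_[pb]
            Px = (a * Acen[0] + b * Bcen[0]) / p
            Py = (a * Acen[1] + b * Bcen[1]) / p
            Pz = (a * Acen[2] + b * Bcen[2]) / p
            Exab = np.zeros((lab + 1, la + 1, lb + 1))
            Eyab = np.zeros((lab + 1, la + 1, lb + 1))
            Ezab = np.zeros((lab + 1, la + 1, lb + 1))
            _fill_E(la, lb, a, b, Acen[0] - Bcen[0], Exab)
            _fill_E(la, lb, a, b, Acen[1] - Bcen[1], Eyab)
            _fill_E(la, lb, a, b, Acen[2] - Bcen[2], Ezab)
            for pc in range(ec.shape[0]):
                c = ec[pc]
                for pd in range(ed.shape[0]):
                    d_ = ed[pd]
                    q = c + d_
                    muq = c * d_ / q
                    rcd2 = 0.0
                    for k in range(3):
                        dd = Ccen[k] - Dcen[k]
                        rcd2 += dd * dd
                    if muq * rcd2 > 46.0:
                        continue
                    ccd = cc_[pc] * cd_[pd]
                    Qx = (c * Ccen[0] + d_ * Dcen[0]) / q
                    Qy = (c * Ccen[1] + d_ * Dcen[1]) / q
                    Qz = (c * Ccen[2] + d_ * Dcen[2]) / q
                    Excd = np.zeros((lcd + 1, lc + 1, ld + 1))
                    Eycd = np.zeros((lcd + 1, lc + 1, ld + 1))
                    Ezcd = np.zeros((lcd + 1, lc + 1, ld + 1))
                    _fill_E(lc, ld, c, d_, Ccen[0] - Dcen[0], Excd)
                    _fill_E(lc, ld, c, d_, Ccen[1] - Dcen[1], Eycd)
                    _fill_E(lc, ld, c, d_, Ccen[2] - Dcen[2], Ezcd)
                    alpha = p * q / (p + q)
                    R = np.zeros((ltot + 1, ltot + 1, ltot + 1))
                    _fill_R(ltot, alpha, Px - Qx, Py - Qy, Pz - Qz, R)
                    pref = cab * ccd * 2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
                    for ia in range(na):
                        i1 = comps_flat[oa + ia, 0]
                        j1 = comps_flat[oa + ia, 1]
                        k1 = comps_flat[oa + ia, 2]
                        for ib in range(nb):
                            i2 = comps_flat[ob + ib, 0]
                            j2 = comps_flat[ob + ib, 1]
                            k2 = comps_flat[ob + ib, 2]
                            for ic in range(nc):
                                i3 = comps_flat[oc + ic, 0]
                                j3 = comps_flat[oc + ic, 1]
                                k3 = comps_flat[oc + ic, 2]
                                for idd in range(nd):
                                    i4 = comps_flat[od + idd, 0]
                                    j4 = comps_flat[od + idd, 1]
                                    k4 = comps_flat[od + idd, 2]
                                    acc = 0.0
                                    for t in range(i1 + i2 + 1):
                                        ex1 = Exab[t, i1, i2]
                                        if ex1 == 0.0:
                                            continue
                                        for u in range(j1 + j2 + 1):
                                            ey1 = Eyab[u, j1, j2]
                                            if ey1 == 0.0:
                                                continue
                                            for v in range(k1 + k2 + 1):
                                                ez1 = Ezab[v, k1, k2]
                                                if ez1 == 0.0:
                                                    continue
                                                e1 = ex1 * ey1 * ez1
                                                for t2 in range(i3 + i4 + 1):
                                                    ex2 = Excd[t2, i3, i4]
                                                    if ex2 == 0.0:
                                                        continue
                                                    for u2 in range(j3 + j4 + 1):
                                                        ey2 = Eycd[u2, j3, j4]
                                                        if ey2 == 0.0:
                                                            continue
                                                        for v2 in range(k3 + k4 + 1):
                                                            ez2 = Ezcd[v2, k3, k4]
                                                            if ez2 == 0.0:
                                                                continue
                                                            sign = 1.0
                                                            if (t2 + u2 + v2) % 2 == 1:
                                                                sign = -1.0
                                                            acc += e1 * ex2 * ey2 * ez2 * sign * R[t + t2, u + u2, v + v2]
                                    blk[ia, ib, ic, idd] += pref * acc
    return blk


@njit(cache=True)
def _jk_cart(ls, centers, pstart, pcount, exps, coefs,
             cart_off, nc_tot, comps_flat, comps_off, Ds):
    """Direct J and K builds for a stack of (symmetric) cartesian densities.

    J_mn = sum_ls D_ls (mn|ls);  K_mn = sum_ls D_ls (ml|ns).
    """
    nD = Ds.shape[0]
    Js = np.zeros((nD, nc_tot, nc_tot))
    Ks = np.zeros((nD, nc_tot, nc_tot))
    nsh = ls.shape[0]
    images = np.empty((8, 4), dtype=np.int64)
    for A in range(nsh):
        for B in range(A + 1):
            for C in range(A + 1):
                dmaxsh = C + 1 if C < A else B + 1
                for Dsh in range(dmaxsh):
                    blk = _eri_block(
                        ls[A], ls[B], ls[C], ls[Dsh],
                        centers[A], centers[B], centers[C], centers[Dsh],
                        exps[pstart[A]:pstart[A] + pcount[A]],
                        coefs[pstart[A]:pstart[A] + pcount[A]],
                        exps[pstart[B]:pstart[B] + pcount[B]],
                        coefs[pstart[B]:pstart[B] + pcount[B]],
                        exps[pstart[C]:pstart[C] + pcount[C]],
                        coefs[pstart[C]:pstart[C] + pcount[C]],
                        exps[pstart[Dsh]:pstart[Dsh] + pcount[Dsh]],
                        coefs[pstart[Dsh]:pstart[Dsh] + pcount[Dsh]],
                        comps_flat, comps_off)
                    # permutation images of (A,B,C,D)
                    images[0, 0] = A; images[0, 1] = B; images[0, 2] = C; images[0, 3] = Dsh
                    images[1, 0] = B; images[1, 1] = A; images[1, 2] = C; images[1, 3] = Dsh
                    images[2, 0] = A; images[2, 1] = B; images[2, 2] = Dsh; images[2, 3] = C
                    images[3, 0] = B; images[3, 1] = A; images[3, 2] = Dsh; images[3, 3] = C
                    images[4, 0] = C; images[4, 1] = Dsh; images[4, 2] = A; images[4, 3] = B
                    images[5, 0] = Dsh; images[5, 1] = C; images[5, 2] = A; images[5, 3] = B
                    images[6, 0] = C; images[6, 1] = Dsh; images[6, 2] = B; images[6, 3] = A
                    images[7, 0] = Dsh; images[7, 1] = C; images[7, 2] = B; images[7, 3] = A
                    na = (ls[A] + 1) * (ls[A] + 2) // 2
                    nb = (ls[B] + 1) * (ls[B] + 2) // 2
                    ncc = (ls[C] + 1) * (ls[C] + 2) // 2
                    ndd = (ls[Dsh] + 1) * (ls[Dsh] + 2) // 2
                    for m in range(8):
                        dup = False
                        for m2 in range(m):
                            if (images[m, 0] == images[m2, 0] and images[m, 1] == images[m2, 1]
                                    and images[m, 2] == images[m2, 2] and images[m, 3] == images[m2, 3]):
                                dup = True
                                break
                        if dup:
                            continue
                        for ia in range(na):
                            for ib in range(nb):
                                for ic in range(ncc):
                                    for idd in range(ndd):
                                        v = blk[ia, ib, ic, idd]
                                        if v == 0.0:
                                            continue
                                        # indices of this image in AO order
                                        if m == 0:
                                            w, x, y, z = ia, ib, ic, idd
                                        elif m == 1:
                                            w, x, y, z = ib, ia, ic, idd
                                        elif m == 2:
                                            w, x, y, z = ia, ib, idd, ic
                                        elif m == 3:
                                            w, x, y, z = ib, ia, idd, ic
                                        elif m == 4:
                                            w, x, y, z = ic, idd, ia, ib
                                        elif m == 5:
                                            w, x, y, z = idd, ic, ia, ib
                                        elif m == 6:
                                            w, x, y, z = ic, idd, ib, ia
                                        else:
                                            w, x, y, z = idd, ic, ib, ia
                                        po = cart_off[images[m, 0]] + w
                                        qo = cart_off[images[m, 1]] + x
                                        ro = cart_off[images[m, 2]] + y
                                        so = cart_off[images[m, 3]] + z
                                        for n in range(nD):
                                            Js[n, po, qo] += Ds[n, ro, so] * v
                                            Ks[n, po, ro] += Ds[n, qo, so] * v
    return Js, Ks


@njit(cache=True)
def _eri_full_cart(ls, centers, pstart, pcount, exps, coefs,
                   cart_off, nc_tot, comps_flat, comps_off):
    out = np.zeros((nc_tot, nc_tot, nc_tot, nc_tot))
    nsh = ls.shape[0]
    for A in range(nsh):
        for B in range(nsh):
            for C in range(nsh):
                for Dsh in range(nsh):
                    blk = _eri_block(
                        ls[A], ls[B], ls[C], ls[Dsh],
                        centers[A], centers[B], centers[C], centers[Dsh],
                        exps[pstart[A]:pstart[A] + pcount[A]],
                        coefs[pstart[A]:pstart[A] + pcount[A]],
                        exps[pstart[B]:pstart[B] + pcount[B]],
                        coefs[pstart[B]:pstart[B] + pcount[B]],
                        exps[pstart[C]:pstart[C] + pcount[C]],
                        coefs[pstart[C]:pstart[C] + pcount[C]],
                        exps[pstart[Dsh]:pstart[Dsh] + pcount[Dsh]],
                        coefs[pstart[Dsh]:pstart[Dsh] + pcount[Dsh]],
                        comps_flat, comps_off)
                    na = (ls[A] + 1) * (ls[A] + 2) // 2
                    nb = (ls[B] + 1) * (ls[B] + 2) // 2
                    ncc = (ls[C] + 1) * (ls[C] + 2) // 2
                    ndd = (ls[Dsh] + 1) * (ls[Dsh] + 2) // 2
                    for ia in range(na):
                        for ib in range(nb):
                            for ic in range(ncc):
                                for idd in range(ndd):
                                    out[cart_off[A] + ia, cart_off[B] + ib,
                                        cart_off[C] + ic, cart_off[Dsh] + idd] = blk[ia, ib, ic, idd]
    return out


@njit(cache=True)
def _ao_values_cart(ls, centers, pstart, pcount, exps, coefs,
                    cart_off, nc_tot, comps_flat, comps_off, points):
    """AO values, gradients and laplacians on grid points (cartesian AOs)."""
    npts = points.shape[0]
    ao = np.zeros((npts, nc_tot))
    aox = np.zeros((npts, nc_tot))
    aoy = np.zeros((npts, nc_tot))
    aoz = np.zeros((npts, nc_tot))
    aol = np.zeros((npts, nc_tot))
    nsh = ls.shape[0]
    for ip in range(npts):
        for A in range(nsh):
            la = ls[A]
            ca = comps_off[la]
            na = (la + 1) * (la + 2) // 2
            dx = points[ip, 0] - centers[A, 0]
            dy = points[ip, 1] - centers[A, 1]
            dz = points[ip, 2] - centers[A, 2]
            r2 = dx * dx + dy * dy + dz * dz
            g = 0.0
            ga = 0.0
            gaa = 0.0
            for pa in range(pstart[A], pstart[A] + pcount[A]):
                al = exps[pa]
                e = al * r2
                if e > 60.0:
                    continue
                ev = coefs[pa] * np.exp(-e)
                g += ev
                ga += al * ev
                gaa += al * al * ev
            if g == 0.0 and ga == 0.0:
                continue
            # powers of dx,dy,dz up to la+2
            for ia in range(na):
                i = comps_flat[ca + ia, 0]
                j = comps_flat[ca + ia, 1]
                k = comps_flat[ca + ia, 2]
                xi = dx ** i
                yj = dy ** j
                zk = dz ** k
                poly = xi * yj * zk
                v = poly * g
                # d/dx (x^i g) = i x^{i-1} g - 2a x^{i+1} g  (a-weighted in ga)
                if i > 0:
                    dvx = i * dx ** (i - 1) * yj * zk * g - 2.0 * dx ** (i + 1) * yj * zk * ga
                else:
                    dvx = -2.0 * dx * yj * zk * ga
                if j > 0:
                    dvy = j * xi * dy ** (j - 1) * zk * g - 2.0 * xi * dy ** (j + 1) * zk * ga
                else:
                    dvy = -2.0 * xi * dy * zk * ga
                if k > 0:
                    dvz = k * xi * yj * dz ** (k - 1) * g - 2.0 * xi * yj * dz ** (k + 1) * ga
                else:
                    dvz = -2.0 * xi * yj * dz * ga
                # laplacian of x^i y^j z^k e^{-a r^2}, summed over primitives
                lap = 0.0
                if i >= 2:
                    lap += i * (i - 1.0) * dx ** (i - 2) * yj * zk * g
                if j >= 2:
                    lap += j * (j - 1.0) * xi * dy ** (j - 2) * zk * g
                if k >= 2:
                    lap += k * (k - 1.0) * xi * yj * dz ** (k - 2) * g
                lap -= 2.0 * (2.0 * (i + j + k) + 3.0) * poly * ga
                lap += 4.0 * poly * r2 * gaa
                idx = cart_off[A] + ia
                ao[ip, idx] = v
                aox[ip, idx] = dvx
                aoy[ip, idx] = dvy
                aoz[ip, idx] = dvz
                aol[ip, idx] = lap
    return ao, aox, aoy, aoz, aol


# ---------------------------------------------------------------------------
# Python-level basis container and wrappers
# ---------------------------------------------------------------------------


@dataclass
class ShellArrays:
    """Flattened shell data consumed by the numba kernels.

    ``tmat`` maps cartesian AOs to the exposed AO basis (pure-spherical rows
    for pure shells, per-component renormalized rows for cartesian shells).
    """

    ls: np.ndarray          # (nsh,) int64
    centers: np.ndarray     # (nsh,3)
    pstart: np.ndarray      # (nsh,) int64
    pcount: np.ndarray      # (nsh,) int64
    exps: np.ndarray        # (nprim,)
    coefs: np.ndarray       # (nprim,) includes primitive + contraction norms
    pure: np.ndarray        # (nsh,) bool
    cart_off: np.ndarray    # (nsh,) int64
    ao_off: np.ndarray      # (nsh,) int64
    nc_tot: int
    nbf: int
    tmat: np.ndarray        # (nbf, nc_tot)

    @classmethod
    def build(cls, shells) -> "ShellArrays":
        """shells: iterable with .l, .pure, .center (bohr), .exps, .coefs.

        Contraction coefficients are taken as given on *normalized
        primitives*; the contracted function is renormalized here.
        """
        from .harmonics import cart_to_pure

        ls, centers, pstart, pcount, exps, coefs, pure = [], [], [], [], [], [], []
        for sh in shells:
            l = int(sh.l)
            if l > LMAX:
                raise ValueError(f"angular momentum l={l} beyond supported maximum {LMAX}")
            e = np.asarray(sh.exps, dtype=float)
            c = np.asarray(sh.coefs, dtype=float)
            if np.any(e <= 0):
                raise ValueError("primitive exponents must be strictly positive")
            pn = np.array([primitive_norm(a, l) for a in e])
            cc = c * pn
            # normalize contracted x^l component
            s = 0.0
            for i in range(len(e)):
                for j in range(len(e)):
                    g = e[i] + e[j]
                    s += cc[i] * cc[j] * _double_factorial(2 * l - 1) / (2.0 * g) ** l * (np.pi / g) ** 1.5
            cc /= np.sqrt(s)
            ls.append(l)
            centers.append(np.asarray(sh.center, dtype=float))
            pstart.append(len(exps))
            pcount.append(len(e))
            exps.extend(e.tolist())
            coefs.extend(cc.tolist())
            pure.append(bool(sh.pure))
        ls = np.array(ls, dtype=np.int64)
        centers = np.array(centers, dtype=np.float64).reshape(-1, 3)
        pstart = np.array(pstart, dtype=np.int64)
        pcount = np.array(pcount, dtype=np.int64)
        exps = np.array(exps, dtype=np.float64)
        coefs = np.array(coefs, dtype=np.float64)
        pure = np.array(pure, dtype=bool)
        cart_off = np.zeros(len(ls), dtype=np.int64)
        ao_off = np.zeros(len(ls), dtype=np.int64)
        co = ao = 0
        for i, l in enumerate(ls):
            cart_off[i] = co
            ao_off[i] = ao
            co += ncart(l)
            ao += npure(l) if pure[i] else ncart(l)
        nc_tot, nbf = co, ao
        tmat = np.zeros((nbf, nc_tot))
        for i, l in enumerate(ls):
            if pure[i]:
                T = cart_to_pure(int(l))
                tmat[ao_off[i]:ao_off[i] + npure(l), cart_off[i]:cart_off[i] + ncart(l)] = T
            else:
                ratios = component_norm_ratio(int(l))
                for c in range(ncart(l)):
                    tmat[ao_off[i] + c, cart_off[i] + c] = ratios[c]
        return cls(ls, centers, pstart, pcount, exps, coefs, pure,
                   cart_off, ao_off, nc_tot, nbf, tmat)

    # -- matrix transforms ---------------------------------------------------
    def to_ao(self, M_cart: np.ndarray) -> np.ndarray:
        return self.tmat @ M_cart @ self.tmat.T

    def density_to_cart(self, D_ao: np.ndarray) -> np.ndarray:
        """Contravariant density transform: Tr(D_ao O_ao) = Tr(D_cart O_cart)."""
        return self.tmat.T @ D_ao @ self.tmat

    def _kernel_args(self):
        return (self.ls, self.centers, self.pstart, self.pcount, self.exps,
                self.coefs, self.cart_off, self.nc_tot, _COMPS_FLAT, _COMPS_OFF)


def overlap(sa: ShellArrays) -> np.ndarray:
    S, _ = _overlap_kinetic_cart(*sa._kernel_args())
    return sa.to_ao(S)


def kinetic(sa: ShellArrays) -> np.ndarray:
    _, T = _overlap_kinetic_cart(*sa._kernel_args())
    return sa.to_ao(T)


def overlap_kinetic(sa: ShellArrays):
    S, T = _overlap_kinetic_cart(*sa._kernel_args())
    return sa.to_ao(S), sa.to_ao(T)


def nuclear_attraction(sa: ShellArrays, charges, positions) -> np.ndarray:
    Z = np.asarray(charges, dtype=float)
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    V = _nuclear_cart(*sa._kernel_args(), Z, pos)
    return sa.to_ao(V)


def electron_esp_grad(sa: ShellArrays, D_ao: np.ndarray, points) -> tuple[np.ndarray, np.ndarray]:
    """(integral rho/|r-P|, its gradient wrt P) for density matrix D_ao."""
    pts = np.ascontiguousarray(np.asarray(points, dtype=float).reshape(-1, 3))
    Dc = np.ascontiguousarray(sa.density_to_cart(np.asarray(D_ao, dtype=float)))
    return _esp_field_cart(*sa._kernel_args(), Dc, pts)


def build_jk(sa: ShellArrays, D_list) -> tuple[list, list]:
    """J and K matrices (exposed AO basis) for each density in D_list."""
    Ds = np.ascontiguousarray(
        np.stack([sa.density_to_cart(np.asarray(D, dtype=float)) for D in D_list])
    )
    Js, Ks = _jk_cart(*sa._kernel_args(), Ds)
    return ([sa.to_ao(Js[i]) for i in range(len(D_list))],
            [sa.to_ao(Ks[i]) for i in range(len(D_list))])


def eri_full(sa: ShellArrays) -> np.ndarray:
    """Full (mn|ls) tensor in the exposed AO basis; small systems only."""
    if sa.nbf > 80:
        raise ValueError("eri_full is restricted to small bases; use build_jk")
    eri_c = _eri_full_cart(*sa._kernel_args())
    t = sa.tmat
    out = np.einsum("pi,qj,rk,sl,ijkl->pqrs", t, t, t, t, eri_c, optimize=True)
    return out


def ao_values(sa: ShellArrays, points, derivs: bool = False):
    """AO values (and optionally gradients + laplacians) at points.

    Returns ``ao`` of shape (npts, nbf); with ``derivs`` also
    (ao_x, ao_y, ao_z, ao_lap).
    """
    pts = np.ascontiguousarray(np.asarray(points, dtype=float).reshape(-1, 3))
    ao, aox, aoy, aoz, aol = _ao_values_cart(*sa._kernel_args(), pts)
    t = sa.tmat.T
    if not derivs:
        return ao @ t
    return ao @ t, aox @ t, aoy @ t, aoz @ t, aol @ t
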