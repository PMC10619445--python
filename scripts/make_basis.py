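"""Generate the package's built-in "svp-like" Gaussian basis set.

For each supported element an even-tempered primitive set (alpha_0 * beta^i)
is optimized by minimizing the spherically averaged atomic Hartree-Fock
energy, then general contractions are formed from the occupied atomic
orbitals; the most diffuse primitives stay uncontracted (split valence) and
a single fixed polarization shell is appended.  The result is written to
src/ce1p/data/svp_like.json.

Run from the repository root:  python scripts/make_basis.py
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from types import SimpleNamespace

import numpy as np
from scipy.optimize import minimize

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ce1p import integrals as ints  # noqa: E402
from ce1p.scf import restricted_hf, SCFConvergenceError  # noqa: E402

# element: (Z, n_s, n_p, [(pol_l, pol_exp)], n_extra_diffuse)
CONFIG = {
    "H": (1, 4, 0, [(1, 0.80)], 0),
    "He": (2, 5, 0, [(1, 1.00)], 0),
    "C": (6, 9, 5, [(2, 0.80)], 0),
    "N": (7, 9, 5, [(2, 1.00)], 0),
    "O": (8, 9, 5, [(2, 1.20)], 0),
    "F": (9, 9, 5, [(2, 1.40)], 0),
    "Ne": (10, 9, 5, [(2, 1.80)], 0),
    "Na": (11, 11, 7, [], 0),
    "Cl": (17, 11, 8, [(2, 0.65)], 1),
    "Ar": (18, 11, 8, [(2, 0.85)], 0),
}

N_FREE_S = 2   # most diffuse s primitives left uncontracted
N_FREE_P = 2


def even_tempered(a0: float, beta: float, n: int) -> np.ndarray:
    return a0 * beta ** np.arange(n)


def atom_shells(exps_s, exps_p):
    shells = [SimpleNamespace(l=0, pure=True, center=np.zeros(3), exps=[a], coefs=[1.0])
              for a in exps_s]
    shells += [SimpleNamespace(l=1, pure=True, center=np.zeros(3), exps=[a], coefs=[1.0])
               for a in exps_p]
    return shells


def atomic_energy(params, ns, npp, Z):
    try:
        if npp:
            a0s, bs, a0p, bp = np.exp(params)
            es, ep = even_tempered(a0s, bs, ns), even_tempered(a0p, bp, npp)
        else:
            a0s, bs = np.exp(params)
            es, ep = even_tempered(a0s, bs, ns), []
        sa = ints.ShellArrays.build(atom_shells(es, ep))
        r = restricted_hf(sa, [float(Z)], [[0, 0, 0]], float(Z), fractional=True,
                          conv_energy=1e-9, conv_grad=1e-6)
        return r.energy
    except (SCFConvergenceError, np.linalg.LinAlgError, ValueError):
        return 1e3


def optimize_element(sym):
    Z, ns, npp, pols, nxd = CONFIG[sym]
    x0 = [np.log(0.035 * Z ** 1.2), np.log(3.0)]
    if npp:
        x0 += [np.log(0.06 * Z ** 1.0), np.log(3.0)]
    res = minimize(atomic_energy, x0, args=(ns, npp, Z), method="Nelder-Mead",
                   options={"maxiter": 400, "xatol": 5e-4, "fatol": 1e-7})
    print(f"  {sym}: E = {res.fun:.6f} hartree, params {np.exp(res.x)}")
    if npp:
        a0s, bs, a0p, bp = np.exp(res.x)
        es, ep = even_tempered(a0s, bs, ns), even_tempered(a0p, bp, npp)
    else:
        a0s, bs = np.exp(res.x)
        es, ep = even_tempered(a0s, bs, ns), np.array([])
    return Z, es, ep, pols, nxd, res.fun


def radial_coeffs_from_mos(sa, result, n_s, n_p):
    """Occupied-AO radial contraction vectors per l from the atomic SCF."""
    C = result.mo_coeff
    occ = result.occupations
    s_rows = np.arange(n_s)                       # s AOs come first
    p_rows = np.arange(n_s, n_s + 3 * n_p)
    s_vecs, p_vecs = [], []
    seen_p = set()
    for i in range(C.shape[1]):
        if occ[i] < 1e-8:
            continue
        cs = C[s_rows, i] if n_s else np.array([])
        cp = C[p_rows, i] if n_p else np.array([])
        ws, wp = np.sum(cs ** 2), np.sum(cp ** 2)
        if ws >= wp:
            v = cs / np.linalg.norm(cs)
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            s_vecs.append(v)
        else:
            M = cp.reshape(n_p, 3)
            U, sv, Vt = np.linalg.svd(M, full_matrices=False)
            v = U[:, 0]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            key = tuple(np.round(v, 6))
            if key not in seen_p:
                seen_p.add(key)
                p_vecs.append(v)
    return s_vecs, p_vecs


def build_element(sym):
    Z, es, ep, pols, nxd, e_opt = optimize_element(sym)
    sa = ints.ShellArrays.build(atom_shells(es, ep))
    r = restricted_hf(sa, [float(Z)], [[0, 0, 0]], float(Z), fractional=True,
                      conv_energy=1e-10, conv_grad=1e-7)
    s_vecs, p_vecs = radial_coeffs_from_mos(sa, r, len(es), len(ep))
    # even-tempered lists run tight->diffuse?  They run a0 (most diffuse)
    # upward, so the *first* primitives are the diffuse ones.
    shells = []
    for v in s_vecs:
        shells.append({"l": 0, "exps": list(map(float, es)), "coefs": [float(x) for x in v]})
    free_s = list(es[:N_FREE_S])
    if nxd:
        free_s.append(float(es[0] / (es[1] / es[0])))
    for a in free_s:
        shells.append({"l": 0, "exps": [float(a)], "coefs": [1.0]})
    for v in p_vecs:
        shells.append({"l": 1, "exps": list(map(float, ep)), "coefs": [float(x) for x in v]})
    if len(ep):
        free_p = list(ep[:N_FREE_P])
        if nxd:
            free_p.append(float(ep[0] / (ep[1] / ep[0])))
        for a in free_p:
            shells.append({"l": 1, "exps": [float(a)], "coefs": [1.0]})
    for pl, pe in pols:
        shells.append({"l": int(pl), "exps": [float(pe)], "coefs": [1.0]})
    return {"Z": Z, "atomic_hf_energy": float(e_opt), "shells": shells}


def main():
    out = {"label": "svp-like-2025.1",
           "description": ("Synthetic split-valence-polarization basis generated by "
                           "scripts/make_basis.py: even-tempered primitives optimized on "
                           "spherically averaged atomic HF energies, occupied-AO general "
                           "contractions, uncontracted diffuse tail, fixed polarization "
                           "shells."),
           "elements": {}}
    for sym in CONFIG:
        print(f"optimizing {sym} ...")
        out["elements"][sym] = build_element(sym)
    path = Path(__file__).resolve().parents[1] / "src" / "ce1p" / "data" / "svp_like.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(out, indent=1))
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
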