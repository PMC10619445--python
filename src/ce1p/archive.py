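"""Versioned wavefunction archive (HDF5 container) for exact round-trips."""

from __future__ import annotations

import numpy as np

from .wfn import AtomSite, BasisShell, Wavefunction

ARCHIVE_VERSION = 1


def save_wavefunction(path, w: Wavefunction):
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["version"] = ARCHIVE_VERSION
        f.attrs["method"] = w.method
        f.attrs["basis"] = w.basis
        f.attrs["charge"] = w.charge
        f.attrs["scf_energy"] = w.scf_energy
        f.create_dataset("symbols", data=np.array([a.symbol for a in w.atoms], dtype="S4"))
        f.create_dataset("nuclear_charges", data=w.nuclear_charges)
        f.create_dataset("positions", data=w.positions)
        f.create_dataset("shell_center", data=np.array([s.center for s in w.shells]))
        f.create_dataset("shell_l", data=np.array([s.l for s in w.shells]))
        f.create_dataset("shell_pure", data=np.array([s.pure for s in w.shells]))
        f.create_dataset("shell_nprim", data=np.array([len(s.exps) for s in w.shells]))
        f.create_dataset("prim_exps", data=np.concatenate([s.exps for s in w.shells]))
        f.create_dataset("prim_coefs", data=np.concatenate([s.coefs for s in w.shells]))
        f.create_dataset("mo_coeff", data=w.mo_coeff)
        f.create_dataset("occupations", data=w.occupations)


def load_wavefunction(path) -> Wavefunction:
    import h5py

    with h5py.File(path, "r") as f:
        if int(f.attrs["version"]) > ARCHIVE_VERSION:
            raise ValueError("archive written by a newer format version")
        syms = [s.decode() for s in f["symbols"][()]]
        Z = f["nuclear_charges"][()]
        pos = f["positions"][()]
        atoms = [AtomSite(s, float(z), p) for s, z, p in zip(syms, Z, pos)]
        nprim = f["shell_nprim"][()]
        exps = f["prim_exps"][()]
        coefs = f["prim_coefs"][()]
        shells = []
        off = 0
        for c, l, pure, n in zip(f["shell_center"][()], f["shell_l"][()],
                                 f["shell_pure"][()], nprim):
            shells.append(BasisShell(int(c), int(l), bool(pure),
                                     exps[off:off + n], coefs[off:off + n]))
            off += n
        return Wavefunction(atoms, shells, f["mo_coeff"][()], f["occupations"][()],
                            float(f.attrs["scf_energy"]), str(f.attrs["method"]),
                            str(f.attrs["basis"]), int(f.attrs["charge"]))
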