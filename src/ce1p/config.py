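"""Run configuration with documented defaults and TOML round-tripping."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, fields


@dataclass
class RunConfig:
    """All knobs a run can turn, with their defaults.

    method: wavefunction source label (in-process engine: HF)
    basis: basis-set label
    model: scale-factor preset (CE-1p / CE-2p / CE-5p)
    dispersion_mode: XDM coefficients from 'monomer' or 'dimer' density
    ct_threshold: charge-transfer screen threshold (electrons)
    n_radial / n_theta: integration-grid sizes per atom
    cutoff: neighbour cutoff for lattice sums (angstrom)
    pol_mode: 'pairwise' or 'crystal-field' lattice polarization
    seed: seed for any stochastic fixture generation
    """

    method: str = "HF"
    basis: str = "svp-like"
    model: str = "CE-1p"
    dispersion_mode: str = "monomer"
    ct_threshold: float = 0.33
    n_radial: int = 75
    n_theta: int = 17
    cutoff: float = 15.0
    pol_mode: str = "pairwise"
    seed: int = 0

    def to_toml(self) -> str:
        out = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, str):
                out.append(f'{f.name} = "{v}"')
            else:
                out.append(f"{f.name} = {v}")
        return "\n".join(out) + "\n"

    @classmethod
    def from_toml(cls, text: str) -> "RunConfig":
        import tomllib

        data = tomllib.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_toml(fh.read())

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_toml())

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]

    def override(self, **kwargs) -> "RunConfig":
        d = asdict(self)
        for k, v in kwargs.items():
            if v is not None:
                d[k] = v
        return RunConfig(**d)
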