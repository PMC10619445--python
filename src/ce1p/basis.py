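"""Built-in Gaussian basis set handling.

The package ships one self-contained split-valence-polarization set
("svp-like", see ``scripts/make_basis.py`` for its construction).  Shells
are pure-spherical for d and higher.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

DEFAULT_BASIS = "svp-like"
_ALIASES = {"svp-like": "svp_like", "def2-svp": "svp_like"}


class BasisUnavailableError(ValueError):
    pass


@lru_cache(maxsize=None)
def _load(name: str) -> dict:
    fname = _ALIASES.get(name.lower())
    if fname is None:
        raise BasisUnavailableError(
            f"unknown basis {name!r}; available: {sorted(_ALIASES)}"
        )
    with resources.files("ce1p.data").joinpath(f"{fname}.json").open() as fh:
        return json.load(fh)


def basis_label(name: str = DEFAULT_BASIS) -> str:
    return _load(name)["label"]


def supported_elements(name: str = DEFAULT_BASIS) -> list[str]:
    return sorted(_load(name)["elements"])


def element_shells(symbol: str, name: str = DEFAULT_BASIS) -> list[dict]:
    data = _load(name)
    try:
        return data["elements"][symbol]["shells"]
    except KeyError:
        raise BasisUnavailableError(
            f"element {symbol} not covered by basis {name!r}"
        ) from None


def shells_for_molecule(symbols, name: str = DEFAULT_BASIS):
    """Per-atom shell descriptions: list of (atom_index, l, pure, exps, coefs)."""
    out = []
    for i, sym in enumerate(symbols):
        for sh in element_shells(sym, name):
            out.append((i, int(sh["l"]), True, np.array(sh["exps"]), np.array(sh["coefs"])))
    return out
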