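"""Scale-factor fitting over component/reference tables.

Three procedures define the model family: a one-dimensional k-scan
(k_rep = k_pol = k) for CE-1p, a two-parameter (k_exch-rep, k_pol) minimum
for CE-2p, and bounded least squares over all five factors for CE-5p
(default bounds [0,3], k_rep in [0.6,3]).  The loss is RMSD; a MAD loss is
available for sensitivity studies.  Rows flagged by the charge-transfer
screen are excluded before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear, minimize

from .ce_terms import ScaleFactorSet

COMPONENT_COLUMNS = ["e_coul", "e_exch", "e_rep", "e_pol", "e_disp"]
CSV_COLUMNS = ["dimer_id"] + COMPONENT_COLUMNS + ["reference"]


@dataclass(frozen=True)
class ErrorStats:
    mad: float
    msd: float
    rmsd: float
    n: int


def error_stats(predictions, references) -> ErrorStats:
    """MAD / MSD / RMSD of prediction - reference."""
    p = np.asarray(predictions, float)
    r = np.asarray(references, float)
    if p.shape != r.shape:
        raise ValueError("prediction/reference length mismatch")
    if p.size == 0:
        raise ValueError("need at least one residual")
    d = p - r
    return ErrorStats(float(np.mean(np.abs(d))), float(np.mean(d)),
                      float(np.sqrt(np.mean(d ** 2))), int(p.size))


class ComponentTable:
    """Rows of (dimer id, five components, reference energy), all kJ/mol.

    Optional columns: ``group`` (stratified statistics) and ``ct_flagged``
    (charge-transfer screen; flagged rows are excluded from fits).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"component table missing columns: {missing}")
        vals = df[COMPONENT_COLUMNS + ["reference"]].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("component table contains non-finite values")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "ComponentTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path):
        self.df.to_csv(path, index=False)

    @classmethod
    def from_rows(cls, rows) -> "ComponentTable":
        return cls(pd.DataFrame(rows))

    def __len__(self):
        return len(self.df)

    def fit_arrays(self):
        """(components (n,5), references (n,), n_excluded) after CT screen."""
        df = self.df
        if "ct_flagged" in df.columns:
            keep = ~df["ct_flagged"].astype(bool)
            nex = int((~keep).sum())
            df = df[keep]
        else:
            nex = 0
        return (df[COMPONENT_COLUMNS].to_numpy(float),
                df["reference"].to_numpy(float), nex)

    def group_stats(self, predictions) -> dict:
        """Per-group error statistics (requires a ``group`` column)."""
        if "group" not in self.df.columns:
            raise ValueError("table has no group column")
        out = {}
        p = np.asarray(predictions, float)
        for g, idx in self.df.groupby("group").groups.items():
            out[g] = error_stats(p[np.asarray(idx)],
                                 self.df.loc[idx, "reference"].to_numpy(float))
        return out


@dataclass
class FitResult:
    scales: ScaleFactorSet
    stats: ErrorStats
    curve: np.ndarray | None = None          # (nk, 2): k, rmsd
    surface: np.ndarray | None = None        # (n1, n2) rmsd grid
    surface_axes: tuple | None = None
    active_bounds: dict = field(default_factory=dict)
    n_excluded: int = 0
    flags: list = field(default_factory=list)


def _loss(residuals, kind):
    if kind == "rmsd":
        return float(np.sqrt(np.mean(residuals ** 2)))
    if kind == "mad":
        return float(np.mean(np.abs(residuals)))
    raise ValueError("loss must be 'rmsd' or 'mad'")


def scan_k(table: ComponentTable, grid, loss: str = "rmsd") -> FitResult:
    """CE-1p fit: error over a grid of k = k_rep = k_pol; ties -> smaller k."""
    grid = np.sort(np.asarray(grid, float))
    if grid.size == 0:
        raise ValueError("k grid must be non-empty")
    X, y, nex = table.fit_arrays()
    base = X[:, 0] + X[:, 1] + X[:, 4]       # coul + exch + disp
    scaled = X[:, 2] + X[:, 3]               # rep + pol
    curve = np.empty((grid.size, 2))
    for i, k in enumerate(grid):
        curve[i] = (k, _loss(base + k * scaled - y, loss))
    ibest = int(np.argmin(curve[:, 1]))      # first minimum = smallest k
    k = float(grid[ibest])
    scales = ScaleFactorSet("CE-1p(fit)", 1.0, 1.0, k, k, 1.0)
    stats = error_stats(base + k * scaled, y)
    return FitResult(scales, stats, curve=curve, n_excluded=nex)


def fit_two_parameter(table: ComponentTable, grid_er=None, grid_pol=None,
                      loss: str = "rmsd") -> FitResult:
    """CE-2p fit: minimize over (k_exch-rep, k_pol); also reports the error
    surface on a grid for inspection."""
    X, y, nex = table.fit_arrays()
    if len(y) < 2:
        raise ValueError("need at least two rows")
    base = X[:, 0] + X[:, 4]
    er = X[:, 1] + X[:, 2]
    pol = X[:, 3]
    flags = []
    A = np.stack([er, pol], axis=1)
    rhs = y - base
    if np.allclose(er, 0.0):
        flags.append("k_exch-rep unidentifiable (E_exch+E_rep identically zero)")
    if np.allclose(pol, 0.0):
        flags.append("k_pol unidentifiable (E_pol identically zero)")
    if loss == "rmsd" and not flags:
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    else:
        x0 = np.array([0.5, 0.8])
        res = minimize(lambda v: _loss(base + v[0] * er + v[1] * pol - y, loss),
                       x0, method="Nelder-Mead")
        sol = res.x
    if flags:
        # pin unidentifiable parameters at 1
        if np.allclose(er, 0.0):
            sol = np.array([1.0, sol[1] if not np.allclose(pol, 0) else 1.0])
            if not np.allclose(pol, 0.0):
                sol[1] = float(np.linalg.lstsq(pol[:, None], rhs, rcond=None)[0][0])
        elif np.allclose(pol, 0.0):
            sol = np.array([float(np.linalg.lstsq(er[:, None], rhs, rcond=None)[0][0]), 1.0])
    k_er, k_pol = float(sol[0]), float(sol[1])
    if grid_er is None:
        grid_er = np.linspace(max(0.0, k_er - 0.5), k_er + 0.5, 21)
    if grid_pol is None:
        grid_pol = np.linspace(max(0.0, k_pol - 0.5), k_pol + 0.5, 21)
    surface = np.empty((len(grid_er), len(grid_pol)))
    for i, a in enumerate(grid_er):
        for j, b in enumerate(grid_pol):
            surface[i, j] = _loss(base + a * er + b * pol - y, loss)
    scales = ScaleFactorSet("CE-2p(fit)", 1.0, k_er, k_er, k_pol, 1.0)
    stats = error_stats(base + k_er * er + k_pol * pol, y)
    return FitResult(scales, stats, surface=surface,
                     surface_axes=(np.asarray(grid_er), np.asarray(grid_pol)),
                     n_excluded=nex, flags=flags)


DEFAULT_5P_BOUNDS = ([0.0, 0.0, 0.6, 0.0, 0.0], [3.0, 3.0, 3.0, 3.0, 3.0])


def fit_five_parameter(table: ComponentTable, bounds=None,
                       loss: str = "rmsd") -> FitResult:
    """CE-5p fit: bounded least squares over all five scale factors."""
    X, y, nex = table.fit_arrays()
    if len(y) < 5:
        raise ValueError("need at least five rows")
    if bounds is None:
        bounds = DEFAULT_5P_BOUNDS
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    if loss == "rmsd":
        res = lsq_linear(X, y, bounds=(lo, hi))
        sol = res.x
    else:
        r0 = lsq_linear(X, y, bounds=(lo, hi))
        res = minimize(lambda v: _loss(X @ v - y, loss), r0.x, method="Powell",
                       bounds=list(zip(lo, hi)))
        sol = res.x
    names = ["k_coul", "k_exch", "k_rep", "k_pol", "k_disp"]
    active = {}
    for i, nm in enumerate(names):
        if abs(sol[i] - lo[i]) < 1e-8:
            active[nm] = "lower"
        elif abs(sol[i] - hi[i]) < 1e-8:
            active[nm] = "upper"
    scales = ScaleFactorSet("CE-5p(fit)", *[float(v) for v in sol])
    stats = error_stats(X @ sol, y)
    return FitResult(scales, stats, active_bounds=active, n_excluded=nex)
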