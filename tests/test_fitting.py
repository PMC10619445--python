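"""Error statistics and the three scale-factor fitting procedures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ce1p.ce_terms import ScaleFactorSet
from ce1p.fitting import (ComponentTable, error_stats, fit_five_parameter,
                          fit_two_parameter, scan_k)


def synth_table(n, scales, seed=0, noise=0.0, groups=None):
    """Table whose references are generated by a known scale-factor set."""
    rng = np.random.default_rng(seed)
    comps = np.stack([
        rng.normal(-30, 25, n),          # e_coul
        rng.normal(-12, 8, n),           # e_exch
        np.abs(rng.normal(25, 15, n)),   # e_rep
        -np.abs(rng.normal(6, 4, n)),    # e_pol
        -np.abs(rng.normal(8, 5, n)),    # e_disp
    ], axis=1)
    k = np.asarray(scales, float)
    ref = comps @ k + rng.normal(0, noise, n)
    df = pd.DataFrame(comps, columns=["e_coul", "e_exch", "e_rep", "e_pol", "e_disp"])
    df.insert(0, "dimer_id", [f"d{i}" for i in range(n)])
    df["reference"] = ref
    if groups is not None:
        df["group"] = groups
    return ComponentTable(df)


class TestErrorStats:
    @pytest.mark.parametrize("res,mad,msd,rmsd", [
        ([1.0, -1.0], 1.0, 0.0, 1.0),
        ([0.0, 0.0, 0.0], 0.0, 0.0, 0.0),
        ([3.0, 4.0], 3.5, 3.5, np.sqrt(12.5)),
    ])
    def test_examples(self, res, mad, msd, rmsd):
        s = error_stats(np.asarray(res), np.zeros(len(res)))
        assert (s.mad, s.msd) == pytest.approx((mad, msd))
        assert s.rmsd == pytest.approx(rmsd)
        assert s.n == len(res)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10 ** 6), n=st.integers(1, 50))
    def test_inequalities(self, seed, n):
        rng = np.random.default_rng(seed)
        r = rng.normal(0, rng.uniform(0.1, 10), n)
        s = error_stats(r, np.zeros(n))
        assert s.rmsd >= s.mad - 1e-12
        assert s.mad >= abs(s.msd) - 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            error_stats([1.0], [1.0, 2.0])


class TestScanK:
    def test_exact_recovery(self):
        t = synth_table(100, [1, 1, 0.70, 0.70, 1], seed=1)
        res = scan_k(t, np.arange(0.5, 1.0, 0.01))
        assert res.scales.k_rep == pytest.approx(0.70, abs=1e-12)
        assert res.stats.rmsd < 1e-10
        assert res.curve[:, 1].min() == res.stats.rmsd

    def test_noisy_recovery(self):
        t = synth_table(500, [1, 1, 0.70, 0.70, 1], seed=2, noise=1.0)
        res = scan_k(t, np.arange(0.4, 1.0, 0.005))
        assert abs(res.scales.k_rep - 0.70) < 0.05

    def test_single_point_grid(self):
        t = synth_table(20, [1, 1, 0.70, 0.70, 1], seed=3)
        res = scan_k(t, [0.9])
        assert res.scales.k_rep == 0.9
        assert res.curve.shape == (1, 2)

    def test_optimum_not_above_grid(self):
        t = synth_table(80, [1, 1, 0.78, 0.78, 1], seed=4, noise=2.0)
        res = scan_k(t, np.arange(0.0, 1.5, 0.01))
        assert np.all(res.stats.rmsd <= res.curve[:, 1] + 1e-12)

    def test_empty_grid(self):
        t = synth_table(10, [1, 1, 0.7, 0.7, 1])
        with pytest.raises(ValueError):
            scan_k(t, [])


class TestTwoParameter:
    def test_exact_recovery(self):
        t = synth_table(60, [1, 0.5, 0.5, 0.8, 1], seed=5)
        res = fit_two_parameter(t)
        assert res.scales.k_exch == pytest.approx(0.5, abs=1e-8)
        assert res.scales.k_pol == pytest.approx(0.8, abs=1e-8)
        assert res.stats.rmsd < 1e-9

    def test_surface_optimality(self):
        t = synth_table(60, [1, 0.5, 0.5, 0.8, 1], seed=6, noise=1.5)
        res = fit_two_parameter(t)
        assert res.surface.min() >= res.stats.rmsd - 1e-9

    def test_degenerate_exch_rep_flagged(self):
        t = synth_table(30, [1, 0.5, 0.5, 0.8, 1], seed=7)
        df = t.df.copy()
        df["e_exch"] = 0.0
        df["e_rep"] = 0.0
        df["reference"] = (df["e_coul"] + df["e_disp"] + 0.8 * df["e_pol"])
        res = fit_two_parameter(ComponentTable(df))
        assert any("unidentifiable" in f for f in res.flags)


class TestFiveParameter:
    TRUE = [1.0, 0.7, 0.8, 0.8, 1.05]

    def test_interior_recovery(self):
        t = synth_table(200, self.TRUE, seed=8)
        res = fit_five_parameter(t)
        assert np.allclose(res.scales.as_array(), self.TRUE, atol=1e-6)
        assert res.active_bounds == {}

    def test_bound_activation(self):
        t = synth_table(200, [1.0, 0.7, 0.4, 0.8, 1.0], seed=9)
        res = fit_five_parameter(t)
        assert res.scales.k_rep == pytest.approx(0.6, abs=1e-8)
        assert res.active_bounds.get("k_rep") == "lower"

    def test_relaxation_property(self):
        t = synth_table(200, [1.0, 0.7, 0.4, 0.8, 1.0], seed=10, noise=1.0)
        bounded = fit_five_parameter(t)
        free = fit_five_parameter(t, bounds=([-10] * 5, [10] * 5))
        assert free.stats.rmsd <= bounded.stats.rmsd + 1e-10

    def test_determinism(self):
        t = synth_table(100, self.TRUE, seed=11, noise=0.5)
        r1 = fit_five_parameter(t)
        r2 = fit_five_parameter(t)
        assert np.array_equal(r1.scales.as_array(), r2.scales.as_array())


class TestTableFeatures:
    def test_ct_exclusion_counted(self):
        t = synth_table(50, [1, 1, 0.7, 0.7, 1], seed=12)
        df = t.df.copy()
        df["ct_flagged"] = [i < 5 for i in range(50)]
        res = scan_k(ComponentTable(df), np.arange(0.5, 0.9, 0.01))
        assert res.n_excluded == 5

    def test_group_stats(self):
        groups = ["neutral"] * 20 + ["salt"] * 20
        t = synth_table(40, [1, 1, 0.7, 0.7, 1], seed=13, groups=groups)
        X, y, _ = t.fit_arrays()
        preds = X @ np.array([1, 1, 0.7, 0.7, 1.0])
        gs = t.group_stats(preds)
        assert set(gs) == {"neutral", "salt"}
        assert gs["neutral"].n == 20

    def test_csv_roundtrip(self, tmp_path):
        t = synth_table(10, [1, 1, 0.7, 0.7, 1], seed=14)
        p = tmp_path / "t.csv"
        t.to_csv(p)
        t2 = ComponentTable.from_csv(p)
        assert len(t2) == 10
        assert np.allclose(t2.df["reference"], t.df["reference"])

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ComponentTable(pd.DataFrame({"dimer_id": ["a"], "e_coul": [1.0]}))
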