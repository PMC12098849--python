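"""Parallel-line CCS fits, DeltaCCS, deviation metrics and recalibration."""

import numpy as np
import pandas as pd
import pytest

from mirmsi import ccs, synthetic
from mirmsi.ccs import (
    cross_platform_compare,
    delta_ccs,
    fit_series,
    mean_relative_deviation,
    recalibrate_ccs,
)


def _table(noise=0.0, intercepts=(("SM4", 160.0), ("SM3", 188.2)),
           n_replicates=1, seed=0):
    return synthetic.make_ccs_table(synthetic.CcsPhantomSpec(
        intercepts=intercepts, noise_sigma=noise,
        n_replicates=n_replicates, seed=seed))


class TestFitSeries:
    def test_noiseless_recovers_offset_exactly(self):
        df = _table(noise=0.0)
        fit = fit_series(df, model="poly2_parallel")
        assert fit.intercepts["SM3"] - fit.intercepts["SM4"] == pytest.approx(
            28.2, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.shared["a"] == pytest.approx(-0.05, abs=1e-9)
        assert fit.shared["b"] == pytest.approx(6.0, abs=1e-7)

    def test_linear_rss_dominates_quadratic(self):
        # data generated from a quadratic: the nested linear model must fit
        # strictly worse
        df = _table(noise=0.0)
        quad = fit_series(df, model="poly2_parallel")
        lin = fit_series(df, model="linear")
        assert lin.rss > quad.rss

    def test_nested_rss_inequality_any_data(self):
        rng = np.random.default_rng(1)
        df = _table(noise=1.0, seed=3)
        df["ccs_A2"] += rng.normal(0, 2.0, len(df))
        quad = fit_series(df, model="poly2_parallel")
        lin = fit_series(df, model="linear")
        assert quad.rss <= lin.rss + 1e-9

    def test_power23_preferred_on_power_law_data(self):
        n = np.arange(32, 47, dtype=float)
        rows = []
        for g, c in (("SM4", 40.0), ("SM3", 68.0)):
            for x in n:
                rows.append({"subclass": g, "n": x,
                             "ccs_A2": 20.0 * x ** (2 / 3) + c})
        df = pd.DataFrame(rows)
        p23 = fit_series(df, model="power23")
        lin = fit_series(df, model="linear")
        assert p23.rss < lin.rss

    def test_exact_interpolating_quadratic(self):
        df = pd.DataFrame({
            "subclass": ["SM4"] * 3, "n": [1.0, 2.0, 3.0],
            "ccs_A2": [2.0, 5.0, 10.0],  # y = x^2 + 1
        })
        fit = fit_series(df, model="poly2_parallel")
        assert fit.shared["a"] == pytest.approx(1.0, abs=1e-9)
        assert fit.shared["b"] == pytest.approx(0.0, abs=1e-9)
        assert fit.intercepts["SM4"] == pytest.approx(1.0, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_names_group(self):
        df = pd.DataFrame({"subclass": ["SM4", "SM4", "SM3", "SM3"],
                           "n": [1.0, 2.0, 1.0, 2.0],
                           "ccs_A2": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="SM4|SM3"):
            fit_series(df, model="poly2_parallel")


class TestDeltaCcs:
    def test_same_group_zero(self):
        fit = fit_series(_table(noise=0.1, seed=4))
        d = delta_ccs(fit, "SM4", "SM4")
        assert d.value == 0.0 and d.uncertainty == 0.0

    def test_antisymmetric(self):
        fit = fit_series(_table(noise=0.2, seed=5))
        ab = delta_ccs(fit, "SM3", "SM4")
        ba = delta_ccs(fit, "SM4", "SM3")
        assert ab.value == pytest.approx(-ba.value)
        assert ab.uncertainty == pytest.approx(ba.uncertainty)

    def test_replicate_mode_uses_mean_and_sd(self):
        df = _table(noise=0.2, n_replicates=4, seed=6)
        d = delta_ccs(df, "SM3", "SM4")
        assert d.n_replicates == 4
        assert d.value == pytest.approx(28.2, abs=0.5)
        assert d.uncertainty > 0

    def test_missing_group_rejected(self):
        fit = fit_series(_table())
        with pytest.raises(ValueError):
            delta_ccs(fit, "SM3", "GM3")

    def test_monte_carlo_recovery(self):
        # Table-2-scale conditions: offset 28.2, noise 0.2 A^2, 4 replicates
        values, ses = [], []
        for seed in range(30):
            df = _table(noise=0.2, n_replicates=4, seed=seed)
            fit = fit_series(df)
            d = delta_ccs(fit, "SM3", "SM4")
            values.append(d.value)
            ses.append(d.uncertainty)
        mean = np.mean(values)
        se_of_mean = np.std(values, ddof=1) / np.sqrt(len(values))
        assert abs(mean - 28.2) < 3 * se_of_mean + 1e-6


class TestDeviationMetrics:
    def test_identical_lists_zero(self):
        a = _table()[["shorthand", "ccs_A2"]]
        eps, table = mean_relative_deviation(a, a.copy())
        assert eps == 0.0
        assert (table["epsilon_pct"] == 0).all()

    def test_formula_direct(self):
        e = pd.DataFrame({"shorthand": ["x"], "ccs_A2": [200.0]})
        p = pd.DataFrame({"shorthand": ["x"], "ccs_A2": [202.0]})
        eps, _ = mean_relative_deviation(e, p)
        assert eps == pytest.approx(1.0)

    def test_mean_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        keys = [f"s{i}" for i in range(25)]
        ex = pd.DataFrame({"shorthand": keys,
                           "ccs_A2": rng.uniform(150, 350, 25)})
        pr = ex.copy()
        pr["ccs_A2"] = pr["ccs_A2"] * rng.uniform(0.95, 1.05, 25)
        eps, _ = mean_relative_deviation(ex, pr)
        brute = np.mean([
            100 * abs(e - p) / e
            for e, p in zip(ex["ccs_A2"], pr["ccs_A2"])
        ])
        assert eps == pytest.approx(brute, rel=1e-12)

    def test_unmatched_keys_listed(self):
        e = pd.DataFrame({"shorthand": ["a", "b"], "ccs_A2": [1.0, 2.0]})
        p = pd.DataFrame({"shorthand": ["a", "c"], "ccs_A2": [1.0, 2.0]})
        with pytest.raises(ValueError, match="b"):
            mean_relative_deviation(e, p)


class TestCrossPlatform:
    def test_identical_datasets(self):
        a = _table()[["shorthand", "ccs_A2"]]
        res = cross_platform_compare(a, a.copy())
        assert res["slope"] == pytest.approx(1.0)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-9)
        assert res["r2"] == pytest.approx(1.0)
        assert res["eps_bar_pct"] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_half_percent_offset(self):
        a = _table()[["shorthand", "ccs_A2"]]
        b = a.copy()
        b["ccs_A2"] = b["ccs_A2"] * 1.005
        res = cross_platform_compare(a, b)
        assert res["eps_bar_pct"] == pytest.approx(0.5, abs=1e-9)
        assert res["r2"] == pytest.approx(1.0)

    def test_r2_matches_textbook_on_four_points(self):
        msi = pd.DataFrame({"shorthand": list("abcd"),
                            "ccs_A2": [1.0, 2.0, 3.0, 4.0]})
        lc = pd.DataFrame({"shorthand": list("abcd"),
                           "ccs_A2": [1.1, 1.9, 3.2, 3.8]})
        res = cross_platform_compare(msi, lc)
        x = msi["ccs_A2"].to_numpy()
        y = lc["ccs_A2"].to_numpy()
        r = np.corrcoef(x, y)[0, 1]
        assert res["r2"] == pytest.approx(r**2, rel=1e-12)

    def test_too_few_shared_rejected(self):
        a = pd.DataFrame({"shorthand": ["a", "b"], "ccs_A2": [1.0, 2.0]})
        with pytest.raises(ValueError):
            cross_platform_compare(a, a.copy())


class TestRecalibration:
    def test_zero_deviation_unchanged(self):
        rec = _table()
        pairs = pd.DataFrame({"ccs_off": [200.0, 210.0],
                              "ccs_ref": [200.0, 210.0]})
        out = recalibrate_ccs(rec, pairs)
        assert np.allclose(out["ccs_A2"], rec["ccs_A2"])

    def test_uniform_offset_removed(self):
        rec = _table()
        pairs = pd.DataFrame({"ccs_off": [202.0, 101.0],
                              "ccs_ref": [200.0, 100.0]})
        out = recalibrate_ccs(rec, pairs)
        assert np.allclose(out["ccs_A2"], rec["ccs_A2"] / 1.01)

    def test_nonuniform_offsets_zero_residual_mean(self):
        rng = np.random.default_rng(8)
        ref = rng.uniform(180, 320, 12)
        off = ref * (1 + rng.normal(0.01, 0.003, 12))
        pairs = pd.DataFrame({"ccs_off": off, "ccs_ref": ref})
        factor = (off / ref).mean()
        shifted = off / factor
        assert np.mean(shifted / ref) == pytest.approx(1.0, abs=1e-9)
        rec = pd.DataFrame({"shorthand": [f"s{i}" for i in range(12)],
                            "ccs_A2": off})
        out = recalibrate_ccs(rec, pairs)
        assert np.allclose(out["ccs_A2"], shifted)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            recalibrate_ccs(_table(), pd.DataFrame(columns=["ccs_off",
                                                            "ccs_ref"]))


def test_mason_schamp_helper_plausible_scale():
    # a singly charged lipid around m/z 800 at 1/K0 ~ 1.45 has CCS in the
    # low hundreds of square angstroms
    val = ccs.inv_k0_to_ccs(1.45, -1, 848.56)
    assert 200 < val < 400
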