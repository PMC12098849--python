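"""Clean-peak rules, EIM extraction/deconvolution, purity and scheduling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mirmsi import synthetic, tims
from mirmsi.constants import C13_C12_DELTA
from mirmsi.lipids import MolecularFormula, isotope_pattern
from mirmsi.tims import (
    EIM,
    CleanRuleConfig,
    GaussianComponent,
    Precursor,
    classify_clean,
    extract_eim,
    fit_gaussians,
    purity_ratio,
    schedule_precursors,
)

from conftest import random_peak_frame

TARGET_FORMULA = "C44H83NO12S"  # SM4 38:2;O3 neutral composition


def brute_force_clean(df, target_mz, formula, mode, cfg=None):
    """Plain-loop oracle for the clean/non-clean rule."""
    cfg = cfg or CleanRuleConfig()
    target = df[np.isclose(df["mz"], target_mz, rtol=0, atol=1e-6)]
    t_int = target["intensity"].sum()
    t_mob = (target["inv_k0"] * target["intensity"]).sum() / t_int
    env = isotope_pattern(MolecularFormula.from_string(formula), 2)
    ref = t_int * env[1]
    for _, row in df.iterrows():
        if abs(row["mz"] - target_mz) > cfg.mass_window_da:
            continue
        own = any(
            abs(row["mz"] - (target_mz + j * C13_C12_DELTA))
            <= cfg.isotope_ppm * 1e-6 * (target_mz + j * C13_C12_DELTA)
            for j in range(cfg.n_isotopes)
        )
        if own:
            continue
        if row["intensity"] <= ref:
            continue
        if mode == "tims" and abs(row["inv_k0"] - t_mob) > cfg.mobility_window:
            continue
        return "non_clean"
    return "clean"


class TestClassifyClean:
    def test_isolated_peak_clean(self):
        df = pd.DataFrame({"x": 0, "y": 0, "mz": [848.556322],
                           "intensity": [100.0], "inv_k0": [1.446]})
        verdict, interf = classify_clean(df, 848.556322,
                                         formula=TARGET_FORMULA, mode="qtof")
        assert verdict == "clean" and interf.empty

    def test_strong_interferent_non_clean_qtof(self):
        df = pd.DataFrame({"x": 0, "y": 0,
                           "mz": [848.556322, 849.056322],
                           "intensity": [100.0, 100.0],  # 2x the M+1 ref
                           "inv_k0": [1.446, 1.446]})
        env = isotope_pattern(MolecularFormula.from_string(TARGET_FORMULA), 2)
        assert 100.0 > 2 * 100.0 * env[1] * 0.9  # sanity: above the M+1 ref
        verdict, interf = classify_clean(df, 848.556322,
                                         formula=TARGET_FORMULA, mode="qtof")
        assert verdict == "non_clean" and len(interf) == 1

    def test_mobility_separation_rescues(self, near_isobar_frame):
        # the near-isobar pair: non-clean under the mass-only rule, clean
        # once the mobility window applies
        qtof, _ = classify_clean(near_isobar_frame, 848.556322,
                                 formula=TARGET_FORMULA, mode="qtof")
        tims_v, _ = classify_clean(near_isobar_frame, 848.556322,
                                   formula=TARGET_FORMULA, mode="tims")
        assert qtof == "non_clean" and tims_v == "clean"

    def test_own_isotopologues_not_interferents(self):
        df = pd.DataFrame({"x": 0, "y": 0,
                           "mz": [848.556322, 848.556322 + C13_C12_DELTA],
                           "intensity": [100.0, 52.0],
                           "inv_k0": [1.446, 1.446]})
        verdict, _ = classify_clean(df, 848.556322,
                                    formula=TARGET_FORMULA, mode="qtof")
        assert verdict == "clean"

    def test_tims_without_mobility_rejected(self):
        df = pd.DataFrame({"x": 0, "y": 0, "mz": [848.556322],
                           "intensity": [100.0]})
        with pytest.raises(ValueError):
            classify_clean(df, 848.556322, formula=TARGET_FORMULA, mode="tims")

    def test_missing_target_rejected(self):
        df = pd.DataFrame({"x": 0, "y": 0, "mz": [700.0],
                           "intensity": [1.0], "inv_k0": [1.0]})
        with pytest.raises(ValueError):
            classify_clean(df, 848.556322, formula=TARGET_FORMULA)

    @pytest.mark.parametrize("mode", ["qtof", "tims"])
    def test_agrees_with_bruteforce_oracle(self, mode):
        rng = np.random.default_rng(42)
        for _ in range(200):
            df, target = random_peak_frame(rng)
            verdict, _ = classify_clean(df, target, formula=TARGET_FORMULA,
                                        mode=mode)
            assert verdict == brute_force_clean(df, target, TARGET_FORMULA,
                                                mode)


class TestExtractEim:
    def test_single_species_single_mode(self):
        frame = synthetic.make_tims_phantom(synthetic.TimsPhantomSpec(
            species=(synthetic.TimsSpecies(800.0, 1.40, 100.0),)))
        eim = extract_eim(frame, 800.0, tol=0.01)
        assert eim.mobility[np.argmax(eim.intensity)] == pytest.approx(1.40,
                                                                       abs=0.002)

    def test_two_species_bimodal(self):
        frame = synthetic.make_tims_phantom(synthetic.TimsPhantomSpec(
            species=(synthetic.TimsSpecies(800.0, 1.35, 100.0),
                     synthetic.TimsSpecies(800.01, 1.45, 80.0)),
            ramp_ms=480.0))
        eim = extract_eim(frame, 800.005, tol=0.05)
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(eim.intensity, height=eim.intensity.max() * 0.1)
        modes = eim.mobility[peaks]
        assert np.any(np.abs(modes - 1.35) < 0.002)
        assert np.any(np.abs(modes - 1.45) < 0.002)

    def test_zero_tolerance_exact_matches_only(self):
        df = pd.DataFrame({"x": 0, "y": 0, "mz": [800.0, 800.5],
                           "intensity": [10.0, 20.0], "inv_k0": [1.3, 1.4]})
        eim = extract_eim(df, 800.0, tol=0.0)
        assert eim.total == pytest.approx(10.0)

    def test_empty_selection_warns(self):
        df = pd.DataFrame({"x": 0, "y": 0, "mz": [700.0],
                           "intensity": [1.0], "inv_k0": [1.0]})
        with pytest.warns(UserWarning):
            eim = extract_eim(df, 900.0, tol=0.01)
        assert eim.total == 0.0


class TestFitGaussians:
    def _eim_from_components(self, comps, noise=0.0, seed=0):
        x = np.arange(1.30, 1.60, 0.001)
        y = np.zeros_like(x)
        for c in comps:
            y += c.amplitude * np.exp(-0.5 * ((x - c.mean) / c.sigma) ** 2)
        if noise:
            y += np.random.default_rng(seed).normal(0, noise * y.max(), x.size)
            y = np.clip(y, 0, None)
        return EIM(x, y, (0, 0))

    def test_single_noiseless_recovery(self):
        truth = GaussianComponent(1.45, 0.004, 120.0)
        eim = self._eim_from_components([truth])
        comps, rss = fit_gaussians(eim, 1)
        assert comps[0].mean == pytest.approx(truth.mean, rel=1e-6)
        assert comps[0].sigma == pytest.approx(truth.sigma, rel=1e-6)
        assert comps[0].amplitude == pytest.approx(truth.amplitude, rel=1e-6)
        assert rss < 1e-12

    def test_two_components_with_noise(self):
        a = GaussianComponent(1.42, 0.004, 100.0)
        b = GaussianComponent(1.432, 0.004, 60.0)  # 3 sigma apart
        eim = self._eim_from_components([a, b], noise=0.01, seed=1)
        comps, _ = fit_gaussians(eim, 2)
        assert comps[0].mean == pytest.approx(1.42, rel=0.02)
        assert comps[1].mean == pytest.approx(1.432, rel=0.02)

    def test_overfitting_unimodal_flags_degenerate(self):
        eim = self._eim_from_components([GaussianComponent(1.45, 0.005, 100.0)])
        comps, _ = fit_gaussians(eim, 2)
        amps = sorted(c.amplitude for c in comps)
        # either one amplitude collapses or both sit on the same peak
        degenerate = (amps[0] < 0.01 * amps[1]
                      or abs(comps[0].mean - comps[1].mean) < 0.005)
        assert degenerate

    def test_too_few_points_rejected(self):
        eim = EIM(np.array([1.0, 1.1]), np.array([1.0, 2.0]), (0, 0))
        with pytest.raises(ValueError):
            fit_gaussians(eim, 1)


class TestPurityRatio:
    def test_fully_separated(self):
        comps = [GaussianComponent(1.40, 0.003, 100.0),
                 GaussianComponent(1.55, 0.003, 100.0)]
        res = purity_ratio(comps, (1.39, 1.41), target_index=0)
        assert res["target_share"] > 0.999

    def test_coincident_equal_components(self):
        comps = [GaussianComponent(1.45, 0.004, 50.0),
                 GaussianComponent(1.45, 0.004, 50.0)]
        res = purity_ratio(comps, (1.44, 1.46))
        assert np.allclose(res["shares"], 0.5)

    def test_shares_sum_to_one(self):
        rng = np.random.default_rng(3)
        comps = [GaussianComponent(m, s, a) for m, s, a in
                 zip(rng.uniform(1.3, 1.6, 5), rng.uniform(0.002, 0.01, 5),
                     rng.uniform(10, 100, 5))]
        res = purity_ratio(comps, (1.35, 1.55))
        assert res["shares"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_ratio_increases_with_resolution(self):
        # ramp 120 -> 480 ms shrinks sigma 4x; target/interferent AUC ratio
        # inside the isolation window must strictly increase
        window = (1.436, 1.456)
        ratios = []
        for ramp in (120.0, 480.0):
            sigma = synthetic.TimsPhantomSpec(species=(), ramp_ms=ramp).sigma
            comps = [GaussianComponent(1.446, sigma, 100.0),
                     GaussianComponent(1.475, sigma, 150.0)]
            ratios.append(purity_ratio(comps, window)["target_interferent_ratio"])
        assert ratios[1] > ratios[0]

    def test_empty_window_rejected(self):
        comps = [GaussianComponent(1.45, 0.004, 10.0)]
        with pytest.raises(ValueError):
            purity_ratio(comps, (1.46, 1.44))


def brute_force_min_batches(precursors, cap):
    """Exact minimum batch count by exhaustive partition search."""
    n = len(precursors)
    best = [n]

    def feasible(batch):
        return len(batch) <= cap and not any(
            a.overlaps(b) for a, b in itertools.combinations(batch, 2))

    def rec(i, batches):
        if len(batches) >= best[0]:
            return
        if i == n:
            best[0] = len(batches)
            return
        p = precursors[i]
        for b in batches:
            if feasible(b + [p]):
                b.append(p)
                rec(i + 1, batches)
                b.pop()
        rec(i + 1, batches + [[p]])

    rec(0, [])
    return best[0]


class TestScheduling:
    def test_twenty_disjoint_two_batches(self):
        cands = [Precursor(f"p{i}", i * 0.01, i * 0.01 + 0.005)
                 for i in range(20)]
        batches = schedule_precursors(cands, max_per_batch=15)
        assert sorted(len(b) for b in batches) == [5, 15]

    def test_overlapping_never_share(self):
        a = Precursor("a", 1.40, 1.45)
        b = Precursor("b", 1.44, 1.50)
        batches = schedule_precursors([a, b])
        assert len(batches) == 2

    def test_empty_input(self):
        assert schedule_precursors([]) == []

    def test_every_candidate_assigned_once(self):
        rng = np.random.default_rng(4)
        cands = [Precursor(f"p{i}", lo, lo + rng.uniform(0.002, 0.03))
                 for i, lo in enumerate(rng.uniform(0.8, 1.8, 40))]
        batches = schedule_precursors(cands, max_per_batch=15)
        names = [p.name for b in batches for p in b]
        assert sorted(names) == sorted(c.name for c in cands)
        for b in batches:
            assert len(b) <= 15
            assert not any(x.overlaps(y)
                           for x, y in itertools.combinations(b, 2))

    def test_near_optimal_on_small_instances(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            n = int(rng.integers(2, 11))
            cands = [Precursor(f"p{i}", lo, lo + rng.uniform(0.01, 0.3))
                     for i, lo in enumerate(rng.uniform(0.0, 1.0, n))]
            got = len(schedule_precursors(cands, max_per_batch=15))
            opt = brute_force_min_batches(cands, cap=15)
            assert got <= opt + 1
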