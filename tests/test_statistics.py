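"""Barcodes, permutation global test, allometry."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fishct.errors import DegenerateControlError, FishCTError
from fishct.phantom import CohortSpec, cohort_truth_table
from fishct.statistics import (
    allometric_normalize,
    fit_allometry,
    global_test,
    global_test_statistic,
    phenome_wide_table,
    standard_scores,
)

from conftest import scaled_spec
from helpers import global_test_p_exact


def _wide(rng, n=6, cells=8, loc=10.0):
    cols = pd.MultiIndex.from_product([["M"], range(1, cells + 1)])
    return pd.DataFrame(rng.normal(loc, 2.0, (n, cells)),
                        index=[f"f{i}" for i in range(n)], columns=cols)


class TestBarcodes:
    def test_target_equal_to_control_mean_is_zero(self, rng):
        control = _wide(rng)
        target = control.mean(axis=0).to_frame().T
        bc = standard_scores(target, control)
        assert np.allclose(bc.z.to_numpy(), 0.0)

    def test_one_sd_shift_in_one_cell(self, rng):
        control = _wide(rng)
        target = control.mean(axis=0).to_frame().T.copy()
        cell = control.columns[3]
        target[cell] += control[cell].std(ddof=1)
        bc = standard_scores(target, control)
        z = bc.z.iloc[0]
        assert z[cell] == pytest.approx(1.0)
        others = z.drop(cell)
        assert np.allclose(others, 0.0, atol=1e-12)

    def test_zero_control_sd_degenerate(self, rng):
        control = _wide(rng)
        control[control.columns[0]] = 5.0
        with pytest.raises(DegenerateControlError):
            standard_scores(control.iloc[:2], control)

    def test_group_mode_single_row(self, rng):
        control, target = _wide(rng), _wide(rng, n=4, loc=12.0)
        bc = standard_scores(target, control, mode="group")
        assert bc.z.shape[0] == 1

    def test_control_vs_itself_group_barcode_zero(self, rng):
        control = _wide(rng, n=8)
        bc = standard_scores(control, control, mode="group")
        assert np.allclose(bc.z.to_numpy(), 0.0, atol=1e-12)

    def test_shift_equivariance_contract(self, rng):
        """Adding a constant to a measure for every fish (targets AND
        controls) leaves z unchanged; adding it to targets only shifts z."""
        control, target = _wide(rng), _wide(rng, n=3)
        z0 = standard_scores(target, control).z
        z_both = standard_scores(target + 7.0, control + 7.0).z
        z_tgt = standard_scores(target + 7.0, control).z
        pd.testing.assert_frame_equal(z0, z_both)
        assert not np.allclose(z0.to_numpy(), z_tgt.to_numpy())

    def test_simulated_effect_recovered(self, rng):
        """Group-mean z converges to the constructed delta/sigma."""
        delta = 1.5
        control = _wide(rng, n=400)
        target = _wide(rng, n=400)
        cell = control.columns[2]
        target[cell] += delta * 2.0  # sigma = 2
        bc = standard_scores(target, control, mode="group")
        assert bc.z.iloc[0][cell] == pytest.approx(delta, abs=0.2)

    def test_cohort_truth_tables_recover_group_effect(self):
        """End-to-end on generator truth: the mutant group's mean z on
        centrum length matches the constructed effect size in control-SD
        units (Monte-Carlo tolerance)."""
        cspec = CohortSpec(
            control=scaled_spec(0.7, noise_sd=0, n_vertebrae=20),
            groups={"control": {}, "mutant": {"centrum_length": 0.9}},
            n_per_group=100,
            scale_sd=0.05,
            vary=("centrum_length",),  # centrum volume scales linearly with it
            seed=11,
        )
        table = cohort_truth_table(cspec)
        wide = phenome_wide_table(table, measures=["Cent.Vol"])
        meta = wide.attrs["meta"]
        control = wide[(meta["group"] == "control").to_numpy()]
        mutant = wide[(meta["group"] == "mutant").to_numpy()]
        bc = standard_scores(mutant, control, mode="group")
        expected = (0.9 - 1.0) / 0.05  # multiplicative effect over lognormal sd
        mean_z = bc.z.iloc[0].mean()
        assert mean_z == pytest.approx(expected, abs=0.6)  # ~3 sigma MC band


class TestGlobalTest:
    def test_identical_groups_not_significant(self, rng):
        X = rng.normal(size=(6, 20))
        X = np.vstack([X, X])  # group b identical row-for-row to group a
        groups = ["a"] * 6 + ["b"] * 6
        res = global_test(X, groups, n_permutations=999, seed=0)
        assert res.p_value > 0.3

    def test_matches_exact_enumeration(self, rng):
        X = rng.normal(size=(8, 5))
        X[4:] += 0.8
        groups = np.array(["a"] * 4 + ["b"] * 4)
        y = (groups == "b").astype(float)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        exact = global_test_p_exact(Xs, y, global_test_statistic)
        res = global_test(X, groups, n_permutations=9999, seed=3)
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_seed_reproducible(self, rng):
        X = rng.normal(size=(12, 20))
        groups = ["a"] * 6 + ["b"] * 6
        p1 = global_test(X, groups, 999, seed=5).p_value
        p2 = global_test(X, groups, 999, seed=5).p_value
        assert p1 == p2

    def test_power_against_strong_shift(self, rng):
        for _ in range(10):
            X = rng.normal(size=(20, 20))
            X[10:] += 2.0  # 2 sigma on every vertebra
            p = global_test(X, ["a"] * 10 + ["b"] * 10, 999, seed=0).p_value
            assert p <= 0.01

    def test_affine_covariate_invariance(self, rng):
        X = rng.normal(size=(14, 20))
        groups = ["a"] * 7 + ["b"] * 7
        scale = rng.uniform(0.1, 30.0, size=20)
        shift = rng.normal(0, 50.0, size=20)
        p1 = global_test(X, groups, 999, seed=2).p_value
        p2 = global_test(X * scale + shift, groups, 999, seed=2).p_value
        assert p1 == p2

    def test_degenerate_inputs(self, rng):
        X = rng.normal(size=(8, 5))
        X[:, 2] = 1.0
        with pytest.raises(DegenerateControlError):
            global_test(X, ["a"] * 4 + ["b"] * 4, 999)
        with pytest.raises(FishCTError):
            global_test(rng.normal(size=(5, 5)), ["a"] * 4 + ["b"], 999)

    def test_null_pvalues_uniform(self, rng):
        """KS test against uniform over repeated null simulations."""
        pvals = [
            global_test(rng.normal(size=(12, 20)), ["a"] * 6 + ["b"] * 6,
                        999, seed=int(rng.integers(2**31))).p_value
            for _ in range(400)
        ]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_pooled_controls_match_wildtype_only(self, rng):
        """When heterozygotes are indistinguishable from wildtypes, pooling
        them into the control group changes nothing beyond Monte-Carlo
        noise (the rationale for pooling +/+ and +/- clutchmates)."""
        reject_pooled = reject_wt = 0
        n_sim = 120
        for k in range(n_sim):
            wt = rng.normal(size=(6, 20))
            het = rng.normal(size=(6, 20))       # same distribution as wt
            mut = rng.normal(0.8, 1.0, size=(6, 20))
            X_pooled = np.vstack([wt, het, mut])
            g_pooled = ["c"] * 12 + ["m"] * 6
            X_wt = np.vstack([wt, mut])
            g_wt = ["c"] * 6 + ["m"] * 6
            reject_pooled += global_test(X_pooled, g_pooled, 499, seed=k).p_value <= 0.05
            reject_wt += global_test(X_wt, g_wt, 499, seed=k).p_value <= 0.05
        assert reject_pooled / n_sim == pytest.approx(reject_wt / n_sim, abs=0.15)


class TestAllometry:
    def test_noiseless_power_law_recovered(self, rng):
        sl = rng.uniform(9000, 16000, 60)
        a, b = 2.5e-4, 1.37
        model = fit_allometry(sl, a * sl**b)
        assert model.exponent == pytest.approx(b, abs=1e-10)
        assert model.coefficient == pytest.approx(a, rel=1e-8)

    def test_b_zero_identity_normalization(self, rng):
        sl = rng.uniform(9000, 16000, 60)
        m = np.full(60, 3.3)
        model = fit_allometry(sl, m)
        assert model.exponent == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(allometric_normalize(m, sl, model), m)

    def test_reference_fish_unchanged(self, rng):
        sl = rng.uniform(9000, 16000, 30)
        m = 1e-3 * sl**1.2
        model = fit_allometry(sl, m)
        out = allometric_normalize(np.array([5.0]), np.array([model.reference_sl]), model)
        assert out[0] == pytest.approx(5.0)

    def test_linear_measure_normalizes_to_constant(self, rng):
        sl = rng.uniform(9000, 16000, 50)
        c = 0.002
        model = fit_allometry(sl, c * sl)
        out = allometric_normalize(c * sl, sl, model)
        assert np.allclose(out, c * model.reference_sl)

    def test_exponent_ci_coverage(self, rng):
        """The OLS 95% CI on b covers the truth in >= 93/100 noisy
        replicates."""
        import statsmodels.api as sm

        b_true, cover = 1.4, 0
        for _ in range(100):
            sl = rng.uniform(9000, 16000, 40)
            m = 3e-4 * sl**b_true * np.exp(rng.normal(0, 0.08, 40))
            fit = sm.OLS(np.log(m), sm.add_constant(np.log(sl))).fit()
            lo, hi = fit.conf_int()[1]
            cover += lo <= b_true <= hi
        assert cover >= 93

    def test_normalization_removes_sl_correlation(self, rng):
        sl = rng.uniform(9000, 16000, 200)
        m = 3e-4 * sl**1.4 * np.exp(rng.normal(0, 0.1, 200))
        model = fit_allometry(sl, m)
        r = np.corrcoef(allometric_normalize(m, sl, model), sl)[0, 1]
        assert abs(r) < 0.1

    def test_nonpositive_inputs_rejected(self, rng):
        with pytest.raises(FishCTError):
            fit_allometry(np.array([1e4, 1.2e4]), np.array([1.0, -2.0]))
        model = fit_allometry(np.array([1e4, 1.2e4, 1.4e4]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(FishCTError):
            allometric_normalize(np.array([1.0]), np.array([-5.0]), model)
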