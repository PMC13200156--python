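"""Regional GLM with TIV covariate, FDR correction, and rectification."""

import numpy as np
import pytest
import statsmodels.api as sm

from ndmap import (
    GMVTable,
    RegionalContrast,
    fdr_correct,
    fit_regional_glm,
    rectify_contrast,
)


def _table(values, group, tiv, craving=None):
    s, n = values.shape
    return GMVTable(
        values=values,
        subject_ids=[f"s{i}" for i in range(s)],
        group=np.asarray(group),
        tiv=np.asarray(tiv, dtype=float),
        region_ids=[f"r{j}" for j in range(n)],
        craving=craving,
    )


def _random_table(rng, s=20, n=5, effect=None, tiv_liters=False):
    group = np.array(["case"] * (s // 2) + ["control"] * (s - s // 2))
    if tiv_liters:
        # well-conditioned units so the normal-equations oracle is exact
        tiv = rng.normal(1.5, 0.15, size=s)
        values = rng.normal(5000, 200, size=(s, n)) + 2000.0 * tiv[:, None]
    else:
        tiv = rng.normal(1.5e6, 1.5e5, size=s)
        values = rng.normal(5000, 200, size=(s, n)) + 0.002 * tiv[:, None]
    if effect is not None:
        values[group == "case"] -= effect
    return _table(values, group, tiv)


class TestRegionalGLM:
    def test_identical_groups_give_null_contrast(self, rng):
        values = np.tile(rng.uniform(4000, 9000, size=6), (12, 1))
        group = ["case"] * 6 + ["control"] * 6
        tiv = rng.normal(1.5e6, 1e5, size=12)
        with pytest.warns(UserWarning, match="constant"):
            rc = fit_regional_glm(_table(values, group, tiv))
        np.testing.assert_array_equal(rc.tvalue, np.zeros(6))
        np.testing.assert_array_equal(rc.pvalue, np.ones(6))

    def test_matches_normal_equations_oracle(self, rng):
        table = _random_table(
            rng, s=20, n=5, effect=rng.normal(0, 100, size=5), tiv_liters=True
        )
        rc = fit_regional_glm(table)
        indicator = (table.group == "control").astype(float)
        x = np.column_stack([np.ones(20), indicator, table.tiv])
        for j in range(5):
            # independent route: explicit normal equations
            xtx = x.T @ x
            beta = np.linalg.solve(xtx, x.T @ table.values[:, j])
            resid = table.values[:, j] - x @ beta
            sigma2 = resid @ resid / (20 - 3)
            se = np.sqrt(sigma2 * np.linalg.inv(xtx)[1, 1])
            assert rc.estimate[j] == pytest.approx(beta[1], rel=1e-10, abs=1e-8)
            assert rc.tvalue[j] == pytest.approx(beta[1] / se, rel=1e-8)

    def test_matches_statsmodels(self, rng):
        table = _random_table(rng, s=30, n=3, effect=np.array([50.0, -80.0, 0.0]))
        rc = fit_regional_glm(table)
        indicator = (table.group == "control").astype(float)
        x = sm.add_constant(np.column_stack([indicator, table.tiv]))
        for j in range(3):
            fit = sm.OLS(table.values[:, j], x).fit()
            assert rc.estimate[j] == pytest.approx(fit.params[1], rel=1e-8)
            assert rc.tvalue[j] == pytest.approx(fit.tvalues[1], rel=1e-6)
            assert rc.pvalue[j] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_study_scale_shapes(self):
        """453 subjects x 246 regions yields length-246 outputs."""
        from ndmap import SyntheticSpec, generate_dataset

        spec = SyntheticSpec(n_regions=246, n_modules=8, rng_seed=0)
        _, table = generate_dataset(spec)
        assert (table.group == "case").sum() == 288
        assert (table.group == "control").sum() == 165
        rc = fit_regional_glm(table)
        assert rc.tvalue.shape == rc.pvalue.shape == rc.p_fdr.shape == (246,)

    def test_sign_convention_loss_positive(self, rng):
        # plant a large case volume LOSS in region 0 only
        effect = np.array([500.0, 0.0, 0.0])
        table = _random_table(rng, s=60, n=3, effect=effect)
        rc = fit_regional_glm(table)
        assert rc.tvalue[0] > 3
        assert rc.direction_convention == "loss_positive"
        flipped = fit_regional_glm(table, direction="gain_positive")
        np.testing.assert_allclose(flipped.tvalue, -rc.tvalue, atol=1e-10)

    def test_tiv_confound_absorbed(self, rng):
        table = _random_table(rng, s=40, n=4)
        rc1 = fit_regional_glm(table)
        shifted = _table(
            table.values + 0.01 * table.tiv[:, None], table.group, table.tiv
        )
        rc2 = fit_regional_glm(shifted)
        np.testing.assert_allclose(rc1.tvalue, rc2.tvalue, atol=1e-8)

    def test_collinear_design_rejected(self, rng):
        values = rng.normal(5000, 100, size=(10, 2))
        group = ["case"] * 5 + ["control"] * 5
        tiv = np.ones(10) * 1.5e6  # constant TIV: collinear with intercept
        with pytest.raises(ValueError, match="rank deficient"):
            fit_regional_glm(_table(values, group, tiv))

    def test_too_few_subjects_rejected(self, rng):
        values = rng.normal(5000, 100, size=(5, 2))
        group = ["case"] * 2 + ["control"] * 3
        tiv = rng.normal(1.5e6, 1e5, size=5)
        with pytest.raises(ValueError, match=">=3 subjects"):
            fit_regional_glm(_table(values, group, tiv))


class TestFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_correct([0.5]), [0.5])

    def test_hand_stepup_m5(self):
        # p(k) * m / k = [.05, .05, .05, .05, .05]; monotone min from the top
        got = fdr_correct([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(got, [0.05] * 5, atol=1e-12)

    def test_matches_bruteforce_stepup(self, rng):
        p = rng.random(100)
        got = fdr_correct(p)
        # brute force over all ranks
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            expected[i] = running
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert np.all(got >= p)

    def test_nan_rejected_with_index(self):
        with pytest.raises(ValueError, match="index 2"):
            fdr_correct([0.1, 0.2, np.nan])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of"):
            fdr_correct([0.1, 1.2])


class TestRectify:
    def _rc(self, t):
        t = np.asarray(t, dtype=float)
        return RegionalContrast(
            estimate=t * 10,
            tvalue=t,
            pvalue=np.full(t.size, 0.5),
            p_fdr=np.full(t.size, 0.5),
            direction_convention="loss_positive",
            region_ids=[f"r{i}" for i in range(t.size)],
        )

    def test_atrophy_halfwave(self):
        np.testing.assert_array_equal(
            rectify_contrast(self._rc([2, -1, 0]), "atrophy"), [2, 0, 0]
        )

    def test_expansion_signflip(self):
        np.testing.assert_array_equal(
            rectify_contrast(self._rc([2, -1, 0]), "expansion"), [0, 1, 0]
        )

    def test_decomposition_identity(self, rng):
        t = rng.normal(size=30)
        rc = self._rc(t)
        total = rectify_contrast(rc, "atrophy") + rectify_contrast(rc, "expansion")
        np.testing.assert_allclose(total, np.abs(t), atol=0)

    def test_estimate_statistic_switch(self):
        rc = self._rc([2, -1, 0])
        np.testing.assert_array_equal(
            rectify_contrast(rc, "atrophy", statistic="estimate"), [20, 0, 0]
        )

    def test_no_signal_is_error(self):
        with pytest.raises(ValueError, match="no signal"):
            rectify_contrast(self._rc([1, 2, 3]), "expansion")
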