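"""Alternating regression: OLS correctness, regressor elimination,
non-predictable responses, ensemble averaging, and IQR selection."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from armonize import (
    ArmConfig,
    ConfigError,
    ProfileMatrix,
    RankDeficiencyError,
    SelectionError,
    ensemble_average,
    fit_response,
    iqr_select,
    rotate,
)
from armonize.simulate import SimConfig, gen_profile_matrix


def _matrix(cols: dict) -> ProfileMatrix:
    n = len(next(iter(cols.values())))
    return ProfileMatrix(
        pd.DataFrame(cols, index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"))
    )


class TestFitResponse:
    def test_identity_regression(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        m = _matrix({"A": a, "B": a.copy(), "C": rng.normal(0, 1, 50)})
        fit = fit_response(m, "B")
        assert fit.regressors_retained == ["A"] or "A" in fit.regressors_retained
        assert fit.coefficients["A"] == pytest.approx(1.0, abs=1e-10)
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_signal_regressor_kept_noise_eliminated(self):
        rng = np.random.default_rng(7)
        n = 200
        a = rng.normal(0, 1, n)
        m = _matrix(
            {
                "A": a,
                "noise1": rng.normal(0, 1, n),
                "noise2": rng.normal(0, 1, n),
                "resp": a + rng.normal(0, 0.05, n),
            }
        )
        fit = fit_response(m, "resp")
        assert fit.regressors_retained == ["A"]
        assert abs(fit.coefficients["A"] - 1.0) < 0.05
        assert fit.r2 > 0.99
        assert fit.predictable

    def test_independent_response_not_predictable(self):
        rng = np.random.default_rng(21)
        n = 500
        m = _matrix(
            {
                "A": rng.normal(0, 1, n),
                "B": rng.normal(0, 1, n),
                "C": rng.normal(0, 1, n),
                "resp": rng.normal(0, 2, n),
            }
        )
        fit = fit_response(m, "resp")
        assert not fit.predictable
        assert fit.regressors_retained == []
        assert list(fit.coefficients.index) == ["intercept"]

    def test_ols_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        n, p = 120, 3
        X = rng.normal(0, 1, (n, p))
        beta = np.array([1.5, -2.0, 0.8])
        y = 0.3 + X @ beta + rng.normal(0, 0.1, n)
        cols = {f"x{j}": X[:, j] for j in range(p)}
        cols["y"] = y
        fit = fit_response(_matrix(cols), "y")
        Xd = np.column_stack([np.ones(n), X])
        expected = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        got = np.array(
            [fit.coefficients["intercept"]] + [fit.coefficients[f"x{j}"] for j in range(p)]
        )
        np.testing.assert_allclose(got, expected, rtol=1e-8)

    def test_collinear_regressors_raise_rank_error(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 40)
        m = _matrix({"A": a, "Acopy": 2 * a, "B": rng.normal(0, 1, 40), "resp": a})
        with pytest.raises(RankDeficiencyError):
            fit_response(m, "resp")

    def test_too_few_rows_raise_fit_error(self):
        from armonize import FitError

        m = _matrix({"A": [1.0, 2.0, 3.0], "B": [2.0, 1.0, 3.0], "resp": [1.0, 2.0, 1.0]})
        with pytest.raises(FitError, match="resp"):
            fit_response(m, "resp")

    def test_unknown_response_is_config_error(self, linear_matrix):
        with pytest.raises(ConfigError):
            fit_response(linear_matrix, "nope")


class TestRotate:
    def test_one_fit_per_method_with_adapted_domains(self):
        cfg = SimConfig(n_genes=300, seed=3)
        matrix, _ = gen_profile_matrix(cfg)
        fits = rotate(matrix)
        assert [f.response for f in fits] == matrix.methods
        for f in fits:
            observed = matrix.data[f.response].notna()
            complete = observed & matrix.data[f.regressors_retained].notna().all(axis=1)
            assert f.n_obs == int(complete.sum())

    def test_identical_profiles_are_rank_deficient(self):
        a = np.arange(20.0)
        m = _matrix({"A": a, "B": a.copy(), "C": a.copy()})
        with pytest.raises(RankDeficiencyError):
            rotate(m)

    def test_needs_three_methods(self):
        m = _matrix({"A": np.arange(10.0), "B": np.arange(10.0) ** 2})
        with pytest.raises(ConfigError):
            rotate(m)

    def test_exact_linear_combination_recovered(self, linear_matrix):
        fit = fit_response(linear_matrix, "E")
        assert set(fit.regressors_retained) == {"A", "B"}
        assert fit.coefficients["A"] == pytest.approx(2.0, abs=0.01)
        assert fit.coefficients["B"] == pytest.approx(-1.0, abs=0.01)
        assert fit.coefficients["intercept"] == pytest.approx(0.5, abs=0.01)


class TestEnsembleAverage:
    def test_fixed_point_on_identical_profiles(self):
        rng = np.random.default_rng(2)
        v = rng.normal(0, 2, 100)
        noise = 1e-8
        m = _matrix({c: v + rng.normal(0, noise, 100) for c in "ABCD"})
        fits = rotate(m)
        profile = ensemble_average(fits)
        np.testing.assert_allclose(profile.table["mean"].to_numpy(), v, atol=1e-6)

    def test_single_covering_rotation_passes_through(self):
        rng = np.random.default_rng(8)
        n = 60
        a = rng.normal(0, 1, n)
        b = a + rng.normal(0, 0.01, n)
        c = a + rng.normal(0, 0.01, n)
        data = pd.DataFrame(
            {"A": a, "B": b, "C": c},
            index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
        )
        # g0 observed only by A and B: only the A and B rotations can cover it
        data.loc["g0", "C"] = np.nan
        fits = rotate(ProfileMatrix(data))
        profile = ensemble_average(fits)
        contributing = [
            f.response for f in fits if f.predictable and "g0" in f.fitted.index
        ]
        expected = np.mean(
            [f.fitted["g0"] for f in fits if f.response in contributing]
        )
        assert profile.table.loc["g0", "n_contributing"] == len(contributing)
        assert profile.table.loc["g0", "mean"] == pytest.approx(expected)

    def test_non_predictable_excluded_with_reason(self):
        cfg = SimConfig(n_genes=2000, seed=0)
        matrix, truth = gen_profile_matrix(cfg)
        fits = rotate(matrix)
        profile = ensemble_average(fits)
        assert truth.outlier_method in profile.excluded_responses
        assert truth.outlier_method not in profile.included_responses

    def test_matches_independent_end_to_end_oracle(self):
        """Full rotation + averaging equals a separate scipy/numpy
        re-implementation on a small complete matrix."""
        rng = np.random.default_rng(17)
        n = 150
        theta = rng.normal(0, 2, n)
        cols = {c: theta + rng.normal(0, 0.3, n) for c in "ABCD"}
        matrix = _matrix(cols)
        cfg = ArmConfig()
        got = ensemble_average(rotate(matrix, cfg), cfg)

        # ---- independent oracle: plain numpy OLS with t-test elimination ----
        def ols(y, X):
            Xd = np.column_stack([np.ones(len(y)), X])
            coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
            resid = y - Xd @ coef
            dof = len(y) - Xd.shape[1]
            s2 = resid @ resid / dof
            cov = s2 * np.linalg.inv(Xd.T @ Xd)
            tstat = coef / np.sqrt(np.diag(cov))
            pvals = 2 * scipy.stats.t.sf(np.abs(tstat), dof)
            # overall F-test
            ss_tot = np.sum((y - y.mean()) ** 2)
            ss_res = resid @ resid
            k = X.shape[1]
            f = ((ss_tot - ss_res) / k) / (ss_res / dof)
            f_p = scipy.stats.f.sf(f, k, dof)
            return coef, pvals[1:], f_p, Xd @ coef

        df = matrix.data
        fitted_all = {}
        for resp in df.columns:
            regs = [c for c in df.columns if c != resp]
            thr = 0.05 / len(regs)
            y = df[resp].to_numpy()
            cur = list(regs)
            coef, pv, f_p, fitted = ols(y, df[cur].to_numpy())
            if f_p >= 0.05:
                continue
            while cur:
                coef, pv, _, fitted = ols(y, df[cur].to_numpy())
                if pv.max() < thr:
                    break
                cur.pop(int(np.argmax(pv)))
            if cur:
                fitted_all[resp] = fitted
        oracle_mean = np.mean(np.column_stack(list(fitted_all.values())), axis=1)
        assert set(fitted_all) == set(got.included_responses)
        np.testing.assert_allclose(
            got.table["mean"].to_numpy(), oracle_mean, rtol=1e-10
        )

    def test_zero_predictable_fits_is_error(self):
        from armonize import NumericalError

        rng = np.random.default_rng(30)
        m = _matrix({c: rng.normal(0, 1, 400) for c in "ABCD"})
        fits = rotate(m)
        if any(f.predictable for f in fits):
            pytest.skip("chance significance in this draw")
        with pytest.raises(NumericalError):
            ensemble_average([f for f in fits if not f.predictable])


class TestIqrSelect:
    def test_constant_vector_selects_nothing(self):
        sel = iqr_select(pd.Series([5.0] * 10, index=[f"g{i}" for i in range(10)]), k=1.5)
        assert sel.iqr == 0
        assert sel.selected == set()

    def test_injected_outliers_found(self):
        vals = list(range(1, 101)) + [-1000, 1000]
        idx = [f"g{i}" for i in range(102)]
        sel = iqr_select(pd.Series(vals, index=idx), k=1.5)
        assert sel.selected == {"g100", "g101"}
        assert sel.direction["g100"] == "below"
        assert sel.direction["g101"] == "above"

    def test_matches_sorted_array_oracle(self):
        rng = np.random.default_rng(77)
        vals = pd.Series(rng.normal(0, 1, 1000), index=[f"g{i}" for i in range(1000)])
        sel = iqr_select(vals, k=3)
        # brute-force oracle on the sorted array
        arr = np.sort(vals.to_numpy())
        n = len(arr)

        def quantile(q):
            pos = (n - 1) * q
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            return arr[lo] + (pos - lo) * (arr[hi] - arr[lo])

        q1, q3 = quantile(0.25), quantile(0.75)
        lf, uf = q1 - 3 * (q3 - q1), q3 + 3 * (q3 - q1)
        expected = {g for g, v in vals.items() if v < lf or v > uf}
        assert sel.selected == expected
        assert sel.q1 == pytest.approx(q1)
        assert sel.q3 == pytest.approx(q3)

    def test_too_few_values(self):
        with pytest.raises(SelectionError):
            iqr_select(pd.Series([1.0, 2.0, 3.0]), k=1.5)

    def test_fence_membership_is_strict(self):
        # quartiles of 0,0,0,0,10: q1=0, q3=0+? use explicit vector where a
        # point lands exactly on the fence and must not be selected
        vals = pd.Series([0.0, 1.0, 2.0, 3.0, 4.5], index=list("abcde"))
        sel = iqr_select(vals, k=0.75)
        # q1=1, q3=3, iqr=2, fences [-0.5, 4.5]; 4.5 sits on the fence
        assert sel.upper_fence == pytest.approx(4.5)
        assert "e" not in sel.selected


class TestInvariants:
    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.1, 10.0, allow_nan=False))
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(13)
        n = 120
        theta = rng.normal(0, 2, n)
        cols = {m: theta + rng.normal(0, 0.4, n) for m in "ABCD"}
        m1 = _matrix(cols)
        m2 = _matrix({k: v * c for k, v in cols.items()})
        cfg = ArmConfig()
        p1 = ensemble_average(rotate(m1, cfg), cfg)
        p2 = ensemble_average(rotate(m2, cfg), cfg)
        np.testing.assert_allclose(
            p2.table["mean"].to_numpy(), c * p1.table["mean"].to_numpy(), rtol=1e-8
        )
        s1 = iqr_select(p1.table["mean"], 1.5)
        s2 = iqr_select(p2.table["mean"], 1.5)
        assert s1.selected == s2.selected
        assert s2.upper_fence == pytest.approx(c * s1.upper_fence, rel=1e-8)

    def test_method_order_invariance(self):
        cfg = SimConfig(n_genes=300, seed=5)
        matrix, _ = gen_profile_matrix(cfg)
        shuffled = ProfileMatrix(matrix.data[matrix.data.columns[::-1]])
        arm_cfg = ArmConfig()
        p1 = ensemble_average(rotate(matrix, arm_cfg), arm_cfg)
        p2 = ensemble_average(rotate(shuffled, arm_cfg), arm_cfg)
        assert sorted(p1.included_responses) == sorted(p2.included_responses)
        pd.testing.assert_series_equal(
            p1.table["mean"].sort_index(), p2.table["mean"].sort_index()
        )
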