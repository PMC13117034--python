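"""Standardization, univariate screening, lasso selection, feature schema."""

import numpy as np
import pandas as pd
import pytest

from daaemil.exceptions import DomainError
from daaemil.synthetic import CohortConfig, generate_cohort
from daaemil.tabular import (CATEGORICAL, CONTINUOUS, FeatureTable,
                             RadiomicsSchema, default_lambda_grid,
                             enumerate_radiomics_space, extract_radiomics,
                             lasso_fit, select_lambda_cv, univariate_screen,
                             zscore)


def table_of(columns: dict, kinds=None) -> FeatureTable:
    df = pd.DataFrame(columns)
    return FeatureTable(np.arange(len(df)), df, kinds or {})


def lasso_cd_oracle(X, y, lam, sweeps=20000, tol=1e-12):
    """Independent cyclic coordinate descent on (1/2M)RSS + lam*||b||_1."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    M, p = X.shape
    beta = np.zeros(p)
    b0 = y.mean()
    for _ in range(sweeps):
        delta = 0.0
        b0_new = (y - X @ beta).mean()
        delta = max(delta, abs(b0_new - b0))
        b0 = b0_new
        for j in range(p):
            r = y - b0 - X @ beta + X[:, j] * beta[j]
            rho = X[:, j] @ r / M
            z = X[:, j] @ X[:, j] / M
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / z
            delta = max(delta, abs(new - beta[j]))
            beta[j] = new
        if delta < tol:
            break
    return b0, beta


class TestZscore:
    def test_unit_column_standardizes_to_centered_steps(self):
        out = zscore(table_of({"x": [1.0, 2.0, 3.0]}))
        assert np.allclose(out.data["x"], [-1.0, 0.0, 1.0])

    def test_zero_variance_column_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            out = zscore(table_of({"x": [5.0, 5.0, 5.0], "y": [1.0, 2.0, 4.0]}))
        assert out.columns == ["y"]

    def test_matches_direct_mean_sd_oracle(self):
        x = np.array([2.0, 4, 4, 4, 5, 5, 7, 9])
        out = zscore(table_of({"x": x}))
        s = np.sqrt(((x - 5.0) ** 2).sum() / (len(x) - 1))
        assert np.allclose(out.data["x"], (x - 5.0) / s, atol=1e-12)

    def test_idempotent_and_moments(self):
        rng = np.random.default_rng(0)
        t = table_of({f"c{j}": rng.normal(j, j + 1, size=40) for j in range(4)})
        z1 = zscore(t)
        z2 = zscore(z1)
        for col in z1.columns:
            assert z1.data[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert z1.data[col].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(z1.data[col], z2.data[col], atol=1e-9)

    def test_categorical_passthrough(self):
        t = table_of({"cat": [0, 1, 0, 1], "x": [1.0, 2.0, 3.0, 4.0]},
                     kinds={"cat": CATEGORICAL, "x": CONTINUOUS})
        out = zscore(t)
        assert np.array_equal(out.data["cat"], [0, 1, 0, 1])


class TestUnivariateScreen:
    def test_identical_groups_yield_p_one_and_exclusion(self):
        t = table_of({"x": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        res = univariate_screen(t, [0, 0, 0, 1, 1, 1], alpha=0.05)
        assert res.pvalues["x"] == pytest.approx(1.0)
        assert res.selected == []

    def test_chi_square_2x2_matches_textbook_statistic(self):
        # contingency [[20,10],[10,20]]: chi2 = n(ad-bc)^2/(r1 r2 c1 c2)
        labels = np.repeat([0, 1], 30)
        x = np.concatenate([np.repeat([0, 1], [20, 10]),
                            np.repeat([0, 1], [10, 20])])
        t = table_of({"c": x}, kinds={"c": CATEGORICAL})
        res = univariate_screen(t, labels, alpha=0.05)
        from scipy.stats import chi2
        stat = 60 * (20 * 20 - 10 * 10) ** 2 / (30 * 30 * 30 * 30)
        assert stat == pytest.approx(6.667, abs=1e-3)
        assert res.pvalues["c"] == pytest.approx(chi2.sf(stat, 1), rel=1e-9)
        assert res.selected == ["c"]

    def test_strong_continuous_shift_detected(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])
        labels = np.repeat([0, 1], 50)
        res = univariate_screen(table_of({"x": x}), labels, alpha=0.05)
        # direct pooled-variance t statistic
        a, b = x[50:], x[:50]
        sp = np.sqrt((49 * a.var(ddof=1) + 49 * b.var(ddof=1)) / 98)
        tstat = (a.mean() - b.mean()) / (sp * np.sqrt(2 / 50))
        from scipy.stats import t as tdist
        assert res.pvalues["x"] == pytest.approx(2 * tdist.sf(abs(tstat), 98),
                                                 rel=1e-9)
        assert res.selected == ["x"]

    def test_single_class_labels_rejected(self):
        with pytest.raises(DomainError):
            univariate_screen(table_of({"x": [1.0, 2.0]}), [1, 1])

    def test_degenerate_contingency_skipped_with_warning(self):
        t = table_of({"c": [0, 0, 0, 0]}, kinds={"c": CATEGORICAL})
        with pytest.warns(UserWarning, match="degenerate"):
            res = univariate_screen(t, [0, 0, 1, 1])
        assert np.isnan(res.pvalues["c"])
        assert res.selected == []


class TestLasso:
    def test_infinite_penalty_gives_empty_support_and_mean_intercept(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = rng.normal(size=30)
        res = lasso_fit(X, y, 1e6)
        assert res.selected == []
        assert res.intercept == pytest.approx(y.mean(), abs=1e-12)

    @pytest.mark.parametrize("lam", [0.01, 0.1, 0.5])
    def test_single_predictor_matches_soft_threshold_oracle(self, lam):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std(ddof=1)
        y = 0.7 * x + rng.normal(0, 0.3, size=50)
        res = lasso_fit(x[:, None], y, lam)
        b0, beta = lasso_cd_oracle(x[:, None], y, lam)
        assert res.coef[0] == pytest.approx(beta[0], abs=1e-7)
        assert res.intercept == pytest.approx(b0, abs=1e-7)

    def test_multivariate_solution_matches_cd_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 5))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = X @ np.array([1.0, 0.0, -0.5, 0.0, 0.2]) + rng.normal(0, 0.2, 40)
        res = lasso_fit(X, y, 0.05)
        _, beta = lasso_cd_oracle(X, y, 0.05)
        assert np.allclose(res.coef, beta, atol=1e-6)

    def test_sparse_signal_recovery(self):
        rng = np.random.default_rng(8)
        n, p = 200, 12
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = 2.0 * X[:, 1] - 3.0 * X[:, 4] + rng.normal(0, 0.1, n)
        lam = select_lambda_cv(X, y, seed=0)
        res = lasso_fit(X, y, lam)
        assert {1, 4} <= set(res.selected)

    def test_support_monotone_on_orthonormal_design(self):
        # columns scaled so X^T X = M I: coefficients are soft thresholds
        rng = np.random.default_rng(9)
        M = 32
        A = rng.normal(size=(M, 3))
        A -= A.mean(axis=0)          # centered columns decouple the intercept
        Q, _ = np.linalg.qr(A)
        X = Q * np.sqrt(M)
        target = np.array([1.5, -0.8, 0.3])
        y = X @ target
        prev_support = None
        for lam in [0.1, 0.4, 1.0, 2.0]:
            res = lasso_fit(X, y, lam)
            closed = np.sign(X.T @ (y - y.mean()) / M) * np.maximum(
                np.abs(X.T @ (y - y.mean()) / M) - lam, 0.0)
            assert np.allclose(res.coef, closed, atol=1e-6)
            support = set(res.selected)
            if prev_support is not None:
                assert support <= prev_support
            prev_support = support

    def test_invalid_inputs_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(DomainError):
            lasso_fit(X, np.zeros(4), -1.0)
        with pytest.raises(DomainError):
            lasso_fit(X * np.nan, np.zeros(4), 0.1)


class TestSelectLambdaCV:
    def test_singleton_grid_returned_unchanged(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        assert select_lambda_cv(X, y, grid=[0.37]) == 0.37

    def test_matches_exhaustive_cv_oracle(self):
        from sklearn.linear_model import Lasso
        from sklearn.model_selection import KFold
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 4))
        y = X @ np.array([1.0, 0, 0, -0.5]) + rng.normal(0, 0.3, 40)
        grid = [0.01, 0.05, 0.2, 1.0]
        lam = select_lambda_cv(X, y, K=4, grid=grid, seed=3)
        # independent exhaustive loop
        means = []
        for g in grid:
            errs = []
            for tr, va in KFold(4, shuffle=True, random_state=3).split(X):
                m = Lasso(alpha=g, max_iter=50000, tol=1e-7).fit(X[tr], y[tr])
                errs.append(np.mean((y[va] - m.predict(X[va])) ** 2))
            means.append(np.mean(errs))
        assert lam == grid[int(np.argmin(means))]

    def test_default_grid_contains_0_002(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        assert 0.002 in default_lambda_grid(X, y)

    def test_too_many_folds_rejected(self):
        with pytest.raises(DomainError):
            select_lambda_cv(np.zeros((3, 2)), np.zeros(3), K=5, grid=[0.1])


class TestRadiomicsSpace:
    def test_reference_schema_has_758_features(self):
        names = enumerate_radiomics_space(RadiomicsSchema())
        assert len(names) == 758
        assert len(set(names)) == 758

    def test_shape_category_alone_counts_14(self):
        schema = RadiomicsSchema(firstorder=0, glcm=0, glrlm=0, glszm=0,
                                 ngtdm=0, gldm=0)
        assert len(enumerate_radiomics_space(schema)) == 14

    def test_eight_wavelet_subbands(self):
        bands = RadiomicsSchema().wavelet_subbands
        assert len(bands) == 8
        assert set(bands) == {"LLL", "LLH", "LHL", "LHH",
                              "HLL", "HLH", "HHL", "HHH"}

    @pytest.mark.parametrize("seed", range(5))
    def test_enumeration_matches_closed_form_count(self, seed):
        rng = np.random.default_rng(seed)
        schema = RadiomicsSchema(*rng.integers(0, 20, size=7))
        expected = schema.shape + 8 * (schema.firstorder + schema.texture_total)
        assert len(enumerate_radiomics_space(schema)) == expected

    def test_image_extraction_is_a_delegated_hook(self):
        with pytest.raises(NotImplementedError):
            extract_radiomics(np.zeros((4, 4, 4)), np.ones((4, 4, 4)))


class TestSelectionChain:
    @pytest.mark.parametrize("seed", range(5))
    def test_chain_recovers_dosimetrics_and_rejects_categoricals(self, seed):
        """Screen + lasso on a large synthetic cohort keeps every informative
        dose-volume column and never keeps a null categorical column."""
        cfg = CohortConfig(n_patients=4000, seed=seed)
        _, clinical, _, truth = generate_cohort(cfg, include_volumes=False)
        res = univariate_screen(clinical, truth.bag_labels, alpha=0.05)
        dosimetric = {"lung_v5", "lung_v10", "lung_v20", "lung_v30",
                      "lung_dmean"}
        assert dosimetric <= set(res.selected)
        continuous = [c for c in res.selected
                      if clinical.kind_of(c) == CONTINUOUS]
        z = zscore(clinical.select(continuous))
        lam = select_lambda_cv(z.values, truth.bag_labels, seed=seed)
        fit = lasso_fit(z.values, truth.bag_labels, lam, columns=z.columns)
        assert dosimetric <= set(fit.selected_columns)
        assert all(clinical.kind_of(c) == CONTINUOUS
                   for c in fit.selected_columns)
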