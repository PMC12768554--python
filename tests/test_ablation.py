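"""Linear and ordinal model fits, nested tests, and ablation machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronolex import (
    ablate_linear,
    ablate_ordinal,
    f_test_nested,
    fit_factorial_ordinal,
    fit_linear,
    fit_ordinal,
)
from chronolex.ablation import cell_design_row, factorial_design


def _decade_frame(rng, n=200, k=4):
    return pd.DataFrame(
        rng.normal(size=(n, k)), columns=[f"sim_{1900 + 10 * i}" for i in range(k)]
    )


class TestFitLinear:
    def test_exact_linear_relation(self, rng):
        X = _decade_frame(rng, n=50, k=3)
        y = 2.0 + X @ [1.0, -0.5, 0.25]
        fit = fit_linear(y, X)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), [2.0, 1.0, -0.5, 0.25], atol=1e-10
        )

    def test_matches_normal_equation_oracle(self, rng):
        X = _decade_frame(rng, n=200, k=3)
        y = rng.normal(size=200)
        fit = fit_linear(y, X)
        design = np.column_stack([np.ones(200), X.to_numpy()])
        oracle = np.linalg.pinv(design.T @ design) @ design.T @ y
        np.testing.assert_allclose(fit.coefficients.to_numpy(), oracle, atol=1e-8)

    def test_aic_identity(self, rng):
        X = _decade_frame(rng, n=100, k=2)
        fit = fit_linear(rng.normal(size=100), X)
        assert fit.aic == pytest.approx(2 * (fit.k_slopes + 2) - 2 * fit.loglik, abs=1e-8)

    def test_rank_deficiency_names_columns(self, rng):
        X = _decade_frame(rng, n=50, k=2)
        X["dup"] = X.iloc[:, 0] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(rng.normal(size=50), X)
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(rng.normal(size=50), np.zeros((50, 2)))


class TestFTest:
    def test_identical_fits_give_zero(self, rng):
        X = _decade_frame(rng, n=60, k=3)
        y = rng.normal(size=60)
        fit = fit_linear(y, X)
        f, p = f_test_nested(fit, fit, df_diff=1)
        assert f == 0.0 and p == 1.0

    def test_matches_rss_arithmetic_oracle(self, rng):
        X = _decade_frame(rng, n=10, k=2)
        y = rng.normal(size=10)
        full = fit_linear(y, X)
        reduced = fit_linear(y, X.iloc[:, :1])
        f, p = f_test_nested(full, reduced)
        f_oracle = ((reduced.rss - full.rss) / 1) / (full.rss / (10 - 2 - 1))
        assert f == pytest.approx(f_oracle, abs=1e-10)
        assert p == pytest.approx(stats.f.sf(f_oracle, 1, 7), abs=1e-12)

    def test_single_column_f_equals_t_squared(self, rng):
        import statsmodels.api as sm

        X = _decade_frame(rng, n=80, k=3)
        y = rng.normal(size=80)
        full = fit_linear(y, X)
        reduced = fit_linear(y, X.drop(columns=[X.columns[1]]))
        f, _ = f_test_nested(full, reduced)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert f == pytest.approx(ols.tvalues[X.columns[1]] ** 2, abs=1e-8)

    def test_non_nested_rejected(self, rng):
        X = _decade_frame(rng, n=50, k=2)
        y = rng.normal(size=50)
        a = fit_linear(y, X.iloc[:, :1])
        b = fit_linear(y, X.iloc[:, 1:])
        with pytest.raises(ValueError, match="nested"):
            f_test_nested(b, a)


class TestAblateLinear:
    def test_planted_signal_found(self):
        rng = np.random.default_rng(7)
        X = _decade_frame(rng, n=300, k=5)
        y = X["sim_1940"] + rng.normal(0, 0.01, size=300)
        results = ablate_linear(y, X, folds=5, seed=7)
        assert results[0].ablated == "none"
        assert results[0].delta_r2 == 0.0
        ranked = max(
            (r for r in results if r.ablated != "none"), key=lambda r: r.delta_r2
        )
        assert ranked.ablated == "sim_1940"
        assert ranked.p_value < 1e-6

    def test_seed_reproducibility(self, rng):
        X = _decade_frame(rng, n=120, k=3)
        y = rng.normal(size=120)
        a = ablate_linear(y, X, folds=4, seed=3)
        b = ablate_linear(y, X, folds=4, seed=3)
        for ra, rb in zip(a, b):
            assert ra.delta_r2 == rb.delta_r2
            assert ra.p_value == rb.p_value

    def test_training_loglik_nesting(self, rng):
        """The full model's in-sample log-likelihood dominates any ablation."""
        X = _decade_frame(rng, n=100, k=4)
        y = rng.normal(size=100)
        full = fit_linear(y, X)
        for col in X.columns:
            assert full.loglik >= fit_linear(y, X.drop(columns=[col])).loglik - 1e-10


def _simulate_ordinal(rng, betas, n, n_levels=7):
    X = rng.normal(size=(n, len(betas)))
    latent = X @ np.asarray(betas) + rng.logistic(size=n)
    cuts = np.quantile(latent, np.linspace(0, 1, n_levels + 1)[1:-1])
    return np.searchsorted(cuts, latent), pd.DataFrame(
        X, columns=[f"x{i}" for i in range(len(betas))]
    )


class TestFitOrdinal:
    def test_binary_collapse_matches_independent_logistic(self, rng):
        from sklearn.linear_model import LogisticRegression

        y, X = _simulate_ordinal(rng, [1.0, -0.7], n=3000, n_levels=2)
        fit = fit_ordinal(y, X)
        oracle = LogisticRegression(penalty=None, tol=1e-12, max_iter=5000)
        oracle.fit(X.to_numpy(), y)
        np.testing.assert_allclose(fit.betas.to_numpy(), oracle.coef_[0], atol=1e-6)

    def test_recovers_planted_slopes(self, rng):
        y, X = _simulate_ordinal(rng, [1.5, -0.5], n=8000)
        fit = fit_ordinal(y, X)
        assert fit.converged
        np.testing.assert_allclose(fit.betas.to_numpy(), [1.5, -0.5], atol=0.1)
        assert len(fit.thresholds) == 6
        assert np.all(np.diff(fit.thresholds) > 0)

    def test_probabilities_sum_to_one(self, rng):
        y, X = _simulate_ordinal(rng, [0.8], n=500)
        fit = fit_ordinal(y, X)
        np.testing.assert_allclose(fit.predict_proba(X).sum(axis=1), 1.0, atol=1e-10)

    def test_single_level_rejected(self, rng):
        X = pd.DataFrame({"x0": rng.normal(size=20)})
        with pytest.raises(ValueError, match="identical"):
            fit_ordinal(np.zeros(20, dtype=int), X)

    def test_bias_shrinks_with_n(self):
        errs = []
        for n in (500, 5000, 20000):
            r = np.random.default_rng(42)
            y, X = _simulate_ordinal(r, [1.2], n=n)
            errs.append(abs(float(fit_ordinal(y, X).betas.iloc[0]) - 1.2))
        assert errs[2] < errs[0]


class TestAblateOrdinal:
    def test_full_vs_full_is_zero_and_signal_detected(self):
        rng = np.random.default_rng(5)
        y, X = _simulate_ordinal(rng, [2.0, 0.0], n=2500)
        X.columns = ["strong", "null"]
        results = ablate_ordinal(y, X, folds=5, seed=5)
        none_row = results[0]
        assert none_row.ablated == "none" and none_row.elpd_diff == 0.0
        by_name = {r.ablated: r for r in results}
        strong = by_name["strong"]
        assert strong.elpd_diff < 0 and abs(strong.elpd_diff) > 2 * strong.elpd_se
        assert not strong.negligible
        assert by_name["null"].negligible

    def test_seed_reproducibility(self, rng):
        y, X = _simulate_ordinal(rng, [0.5], n=600)
        a = ablate_ordinal(y, X, folds=3, seed=9)
        b = ablate_ordinal(y, X, folds=3, seed=9)
        assert a[1].elpd_diff == b[1].elpd_diff


class TestFactorialOrdinal:
    def _simulate_factorial(self, rng, n_per_cell=400, interaction=0.0):
        rows = []
        effects = {"non_neighbor": 0.0, "n1950": 1.0, "n1990": 1.5}
        for age in ("YA", "OA"):
            for pair in ("non_neighbor", "n1950", "n1990"):
                for change in ("changed", "unchanged"):
                    latent_mean = (
                        effects[pair]
                        + (0.8 if change == "unchanged" else 0.0)
                        + (interaction if (age == "OA" and pair == "n1950") else 0.0)
                    )
                    latent = latent_mean + rng.logistic(size=n_per_cell)
                    ratings = np.clip(np.floor(latent + 2), 0, 6).astype(int)
                    for rtg in ratings:
                        rows.append(
                            {
                                "cohort": age,
                                "pair_type": pair,
                                "change_status": change,
                                "rating": rtg,
                            }
                        )
        return pd.DataFrame(rows)

    def test_reference_cell_design_row(self):
        row = cell_design_row("YA", "non_neighbor", "unchanged")
        # dummy-coded terms vanish; effect-coded terms sit at their low level
        assert row["pair_1950"] == 0 and row["pair_1990"] == 0
        assert row["age"] == -0.5 and row["change"] == -0.5
        assert row["age:pair_1950"] == 0 and row["pair_1990:change"] == 0

    def test_no_planted_interaction_estimated_near_zero(self, rng):
        df = self._simulate_factorial(rng, interaction=0.0)
        fit, table = fit_factorial_ordinal(df)
        se = np.sqrt(np.diag(fit.cov_betas))
        z = np.array(
            [fit.betas[name] / se[i] for i, name in enumerate(fit.betas.index) if ":" in name]
        )
        # no single interaction should stand out beyond sampling noise
        assert np.all(np.abs(z) < 3.5)
        assert np.mean(np.abs(z)) < 1.5

    def test_age_equal_gap_contrast_near_zero(self, rng):
        """Equal 1950s-1990s latent gaps across ages -> null age contrast."""
        df = self._simulate_factorial(rng)
        _, table = fit_factorial_ordinal(df)
        row = table[
            (table["term"] == "(1950s - 1990s): OA - YA")
            & (table["change"] == "changed")
        ].iloc[0]
        assert abs(row["estimate"]) <= 2.5 * row["se"]

    def test_missing_cell_listed(self, rng):
        df = self._simulate_factorial(rng, n_per_cell=30)
        df = df[~((df.cohort == "OA") & (df.pair_type == "n1950"))]
        with pytest.raises(ValueError, match="missing factorial cells"):
            fit_factorial_ordinal(df)

    def test_design_matrix_codes(self):
        df = pd.DataFrame(
            {
                "cohort": ["OA", "YA"],
                "pair_type": ["n1990", "non_neighbor"],
                "change_status": ["changed", "unchanged"],
            }
        )
        X = factorial_design(df)
        assert X.loc[0, "age"] == 0.5 and X.loc[0, "pair_1990"] == 1.0
        assert X.loc[0, "age:pair_1990:change"] == pytest.approx(0.25)
        assert X.loc[1].abs().sum() == pytest.approx(0.5 + 0.5 + 0.25)
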