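"""Correlation screen, OLS/elastic-net verification, contribution decomposition."""

import numpy as np
import pandas as pd
import pytest

from codoncontrib.association import (
    FactorContributionModel,
    contribution_report,
    correlation_screen,
    fit_ols,
)
from codoncontrib.mars import MarsRegression
from codoncontrib.penalized import fit_elastic_net, soft_threshold


def feature_frame(X: np.ndarray, names=None) -> pd.DataFrame:
    names = names or [f"codon:C{j:02d}" for j in range(X.shape[1])]
    return pd.DataFrame(X, columns=names, index=[f"g{i}" for i in range(len(X))])


class TestCorrelationScreen:
    def test_perfect_correlation(self, rng):
        x = rng.lognormal(0, 0.3, 50)
        frame = feature_frame(x[:, None], ["transcript_fc"])
        out = correlation_screen(frame, pd.Series(x, index=frame.index))
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p"] < 1e-12
        assert out.loc[0, "star"] == "**"

    def test_independent_features_stay_small(self, rng):
        n = 2000
        frame = feature_frame(rng.normal(size=(n, 5)))
        y = rng.lognormal(0, 0.5, n)
        out = correlation_screen(frame, pd.Series(y, index=frame.index))
        assert (out["r"].abs() < 0.08).all()
        assert (out["star"] == "").sum() >= 3

    def test_planted_correlation_recovered(self, rng):
        """Planted rho = 0.48 (the strength scale of interest) at n = 3000."""
        n, rho = 3000, 0.48
        z = rng.normal(size=n)
        y_log = rho * z + np.sqrt(1 - rho**2) * rng.normal(size=n)
        frame = feature_frame(z[:, None], ["codon:AAG"])
        out = correlation_screen(frame, pd.Series(np.exp(y_log), index=frame.index),
                                 log2_response=True)
        assert out.loc[0, "r"] == pytest.approx(rho, abs=0.05)

    def test_constant_feature_flagged(self, rng):
        X = np.column_stack([np.full(30, 0.5), rng.normal(size=30)])
        frame = feature_frame(X)
        out = correlation_screen(frame, pd.Series(rng.lognormal(0, 0.2, 30), index=frame.index))
        assert out.loc[0, "constant"]
        assert out.loc[0, "r"] == 0.0 and out.loc[0, "p"] == 1.0

    def test_misaligned_gene_sets_error(self, rng):
        frame = feature_frame(rng.normal(size=(10, 2)))
        bad = pd.Series(np.ones(10), index=[f"other{i}" for i in range(10)])
        with pytest.raises(ValueError, match="different genes"):
            correlation_screen(frame, bad)

    def test_star_thresholds_match_pvalues(self, rng):
        frame = feature_frame(rng.normal(size=(40, 8)))
        y = frame.iloc[:, 0] * 0.5 + rng.normal(0, 1, 40)
        out = correlation_screen(frame, pd.Series(np.exp(y), index=frame.index))
        for _, row in out.iterrows():
            expected = "**" if row.p < 0.01 else ("*" if row.p < 0.05 else "")
            assert row.star == expected


class TestOls:
    def test_noise_free_slope(self):
        x = np.linspace(0, 1, 20)
        out = fit_ols(x[:, None], 2 * x, ["x"])
        assert out.set_index("feature").loc["x", "estimate"] == pytest.approx(2.0, abs=1e-10)
        assert out.set_index("feature").loc["(intercept)", "estimate"] == pytest.approx(0.0, abs=1e-10)

    def test_orthonormal_design_closed_form(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(50, 3)))
        X = q - q.mean(axis=0)  # keep near-orthogonal, intercept handles means
        y = rng.normal(size=50)
        out = fit_ols(X, y).set_index("feature")
        # oracle: normal equations
        design = np.column_stack([np.ones(50), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.allclose(out["estimate"].to_numpy(), beta, atol=1e-8)

    def test_matches_normal_equations_on_random_design(self, rng):
        X = rng.normal(size=(80, 6))
        y = X @ rng.normal(size=6) + rng.normal(0, 0.5, 80)
        out = fit_ols(X, y).set_index("feature")
        design = np.column_stack([np.ones(80), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.allclose(out["estimate"].to_numpy(), beta, atol=1e-8)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, 2 * x, rng.normal(size=30)])
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(X, rng.normal(size=30), ["a", "a_twice", "b"])


class TestElasticNet:
    def test_zero_penalty_matches_ols(self, rng):
        X = rng.normal(size=(100, 4))
        y = X @ np.array([1.0, -0.5, 0.2, 0.0]) + rng.normal(0, 0.3, 100)
        res = fit_elastic_net(X, y, alpha=0.5, lambdas=np.array([0.0]), cv_folds=0,
                              tol=1e-12, max_iter=100000, obj_tol=0.0)
        design = np.column_stack([np.ones(100), X])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        assert np.allclose(res.coef, beta[1:], atol=1e-6)
        assert res.intercept == pytest.approx(beta[0], abs=1e-6)

    def test_large_penalty_shrinks_to_zero(self, rng):
        X = rng.normal(size=(60, 5))
        y = X[:, 0] + rng.normal(0, 0.1, 60)
        res = fit_elastic_net(X, y, alpha=0.5, lambdas=np.array([1e4]), cv_folds=0)
        assert np.allclose(res.coef, 0.0)

    def test_single_predictor_lasso_soft_threshold(self, rng):
        """Univariate lasso equals the closed-form S(x'y/n, lambda)."""
        n = 200
        x = rng.normal(size=n)
        y = 0.7 * x + rng.normal(0, 0.5, n)
        xs = (x - x.mean()) / x.std()
        yc = y - y.mean()
        for lam in (0.01, 0.1, 0.5):
            res = fit_elastic_net(x[:, None], y, alpha=1.0, lambdas=np.array([lam]), cv_folds=0)
            expect = soft_threshold(float(xs @ yc) / n, lam)
            assert res.coef_path[0, 0] == pytest.approx(expect, abs=1e-10)

    def test_matches_sklearn_on_fixed_lambda(self, rng):
        from sklearn.linear_model import ElasticNet

        X = rng.normal(size=(150, 10))
        y = X @ (rng.normal(size=10) * (rng.random(10) < 0.5)) + rng.normal(0, 0.5, 150)
        lam, mix = 0.07, 0.5
        res = fit_elastic_net(X, y, alpha=mix, lambdas=np.array([lam]), cv_folds=0,
                              tol=1e-10, obj_tol=0.0)
        Xs = (X - X.mean(0)) / X.std(0)
        sk = ElasticNet(alpha=lam, l1_ratio=mix, tol=1e-12, max_iter=100000)
        sk.fit(Xs, y - y.mean())
        assert np.allclose(res.coef_path[0], sk.coef_, atol=1e-8)

    def test_cv_selects_reasonable_lambda_and_is_seeded(self, rng):
        X = rng.normal(size=(300, 20))
        y = X[:, 0] - 0.5 * X[:, 1] + rng.normal(0, 0.5, 300)
        a = fit_elastic_net(X, y, seed=4, cv_folds=5)
        b = fit_elastic_net(X, y, seed=4, cv_folds=5)
        assert a.lambda_best == b.lambda_best
        assert np.array_equal(a.coef, b.coef)
        assert {0, 1} <= set(np.flatnonzero(a.coef))


class TestContributionReport:
    def _fit(self, rng, betas=(2.0, 0.0, 0.0)):
        X = rng.normal(size=(300, 3))
        y = X @ np.array(betas) + rng.normal(0, 1.6, 300)
        names = ["transcript_fc", "codon:AAG", "aa:K"]
        res = MarsRegression(y, X, feature_names=names, max_terms=11).fit()
        cats = {"transcript_fc": "transcript", "codon:AAG": "codon", "aa:K": "amino_acid"}
        return res, contribution_report(res, cats)

    def test_single_feature_gets_full_explained_share(self, rng):
        # one-column design: the lone feature carries the whole explained share
        x = rng.normal(size=(300, 1))
        y = 2.0 * x[:, 0] + rng.normal(0, 1.6, 300)
        res = MarsRegression(y, x, feature_names=["transcript_fc"], max_terms=9).fit()
        rep = contribution_report(res, {"transcript_fc": "transcript"})
        assert rep.features.loc[0, "feature"] == "transcript_fc"
        assert rep.features.loc[0, "contribution_pct"] == pytest.approx(
            res.rsquared * 100, abs=1e-6
        )
        assert rep.unexplained_pct == pytest.approx(100 - res.rsquared * 100)

    def test_mass_conservation(self, rng):
        res, rep = self._fit(rng, betas=(1.0, 0.8, 0.0))
        assert rep.features["contribution_pct"].sum() == pytest.approx(
            rep.total_explained_pct, abs=1e-9
        )
        assert rep.categories["contribution_pct"].sum() == pytest.approx(
            rep.total_explained_pct, abs=1e-9
        )
        assert rep.total_explained_pct + rep.unexplained_pct == pytest.approx(100.0)

    def test_unknown_category_raises(self, rng):
        X = rng.normal(size=(100, 1))
        y = X[:, 0]
        res = MarsRegression(y, X, feature_names=["mystery"], max_terms=5).fit()
        with pytest.raises(KeyError, match="mystery"):
            contribution_report(res, {})


class TestModelFacade:
    def test_planted_effects_recovered_end_to_end(self, rng):
        """Two planted effects dominate the contribution ranking; signs agree."""
        n = 1200
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        noise = rng.normal(0, 0.66, n)
        y_log2 = 0.5 * z1 + 0.4 * z2 + noise
        frame = pd.DataFrame(
            {
                "transcript_fc": 2.0**z1,
                "codon:AAG": 0.03 + 0.007 * z2,
                "codon:AAA": rng.normal(0.03, 0.007, n),
                "aa:K": rng.normal(0.06, 0.01, n),
                "gc:utr5": rng.normal(0.45, 0.05, n),
            },
            index=[f"g{i}" for i in range(n)],
        )
        response = pd.Series(2.0**y_log2, index=frame.index)
        model = FactorContributionModel(response, frame)
        res = model.fit(seed=3, cv_folds=5)
        top2 = res.contribution.top_features(2)
        assert set(top2) == {"transcript_fc", "codon:AAG"}
        assert res.verification.all_signs_agree
        agree = res.verification.agreement.set_index("feature")
        for f in ("transcript_fc", "codon:AAG"):
            assert agree.loc[f, "mars_sign"] == 1
        assert 35 <= res.contribution.total_explained_pct <= 65
        assert "Factor contribution analysis" in res.summary()

    def test_rejects_nonpositive_fold_changes(self, rng):
        frame = feature_frame(rng.normal(size=(20, 2)))
        with pytest.raises(ValueError, match="strictly positive"):
            FactorContributionModel(pd.Series(np.zeros(20), index=frame.index), frame)

    def test_write_outputs(self, rng, tmp_path):
        n = 300
        z = rng.normal(size=n)
        frame = pd.DataFrame(
            {"transcript_fc": 2.0**z, "codon:AAG": rng.normal(0.03, 0.01, n)},
            index=[f"g{i}" for i in range(n)],
        )
        y = pd.Series(2.0 ** (0.7 * z + rng.normal(0, 0.5, n)), index=frame.index)
        res = FactorContributionModel(y, frame).fit(cv_folds=3)
        written = res.write_outputs(tmp_path)
        assert all(p.exists() for p in written)
        assert (tmp_path / "mars_model.json").exists()
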