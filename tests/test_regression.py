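import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import clone

from crosswise import (
    CrosswiseCounts,
    CrosswiseLogisticRegression,
    ModelSpec,
    Term,
    estimate_prevalence,
    fit_crosswise_logistic,
    likelihood_profile,
    make_design,
)


def crosswise_answers(rng, eta, p):
    """Latent-model forward simulation used by the oracles below."""
    y = rng.random(len(eta)) < expit(eta)
    z = rng.random(len(eta)) < p
    return (y == z).astype(float)


@pytest.fixture(scope="module")
def toy():
    """Intercept + one binary covariate, n=200, p=0.24, fixed seed."""
    rng = np.random.default_rng(7)
    x = rng.binomial(1, 0.5, 200).astype(float)
    a = crosswise_answers(rng, -0.4 + 1.0 * x, 0.24)
    return x, a


class TestSolver:
    def test_intercept_only_matches_moment_estimator(self, design24):
        """With no covariates the MLE of sigmoid(b0) is the moment
        inversion of the A-proportion."""
        rng = np.random.default_rng(11)
        a = crosswise_answers(rng, np.full(2000, -0.3), 0.24)
        m = CrosswiseLogisticRegression(p=0.24).fit(np.empty((2000, 0)), a)
        counts = CrosswiseCounts(int(a.sum()), int(2000 - a.sum()))
        moment = estimate_prevalence(counts, design24)
        assert expit(m.intercept_) == pytest.approx(moment.pi_hat, abs=1e-8)

    @pytest.mark.parametrize("p", [0.24, 0.8])
    def test_loglik_at_start_is_n_log_half(self, toy, p):
        """beta=0 gives q=1/2 for every row regardless of p."""
        x, a = toy
        with pytest.warns(RuntimeWarning, match="did not converge"):
            m = CrosswiseLogisticRegression(p=p, max_iter=0).fit(x, a)
        assert m.loglik_ == pytest.approx(len(a) * np.log(0.5))
        assert not m.converged_

    def test_matches_dense_grid_search_oracle(self, toy):
        """Newton optimum agrees with brute-force maximisation over a
        0.01-step grid on [-4,4]^2 to within 0.02 per coordinate."""
        x, a = toy
        p = 0.24
        m = CrosswiseLogisticRegression(p=p).fit(x, a)
        n11 = ((x == 1) & (a == 1)).sum(); n10 = ((x == 1) & (a == 0)).sum()
        n01 = ((x == 0) & (a == 1)).sum(); n00 = ((x == 0) & (a == 0)).sum()
        grid = np.arange(-4.0, 4.0 + 1e-9, 0.01)
        b0, b1 = np.meshgrid(grid, grid, indexing="ij")
        q0 = (1 - p) + (2 * p - 1) * expit(b0)
        q1 = (1 - p) + (2 * p - 1) * expit(b0 + b1)
        ll = (n01 * np.log(q0) + n00 * np.log1p(-q0)
              + n11 * np.log(q1) + n10 * np.log1p(-q1))
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert m.intercept_ == pytest.approx(grid[i], abs=0.02)
        assert m.coef_[0] == pytest.approx(grid[j], abs=0.02)

    def test_reduces_to_ordinary_logistic_at_p_one(self):
        """p=1 observes the trait directly; coefficients must match a
        reference logistic regression to 1e-6."""
        rng = np.random.default_rng(42)
        X = np.column_stack([rng.binomial(1, 0.5, 300),
                             rng.normal(size=300)])
        a = crosswise_answers(rng, -0.3 + 0.8 * X[:, 0] - 0.5 * X[:, 1], 1.0)
        m = CrosswiseLogisticRegression(p=1.0).fit(X, a)
        ref = sm.Logit(a, sm.add_constant(X)).fit(disp=0)
        ours = np.concatenate([[m.intercept_], m.coef_])
        assert np.allclose(ours, ref.params, atol=1e-6)

    def test_relabel_invariance(self, toy):
        """Swapping A/B labels while replacing p by 1-p leaves the fit
        unchanged (the likelihood is identical)."""
        x, a = toy
        m1 = CrosswiseLogisticRegression(p=0.24).fit(x, a)
        m2 = CrosswiseLogisticRegression(p=0.76).fit(x, 1 - a)
        assert m2.intercept_ == pytest.approx(m1.intercept_, abs=1e-8)
        assert np.allclose(m1.coef_, m2.coef_, atol=1e-8)
        assert m2.loglik_ == pytest.approx(m1.loglik_, abs=1e-8)

    def test_score_vanishes_at_optimum(self, toy):
        x, a = toy
        m = CrosswiseLogisticRegression(p=0.24).fit(x, a)
        assert m.converged_
        assert np.max(np.abs(m.score_)) < 1e-6

    def test_ascent_from_flat_start_in_weak_design(self, toy):
        """Even at p=0.55, where the likelihood is nearly flat, accepted
        steps only ever increase it above the beta=0 value."""
        x, a = toy
        m = CrosswiseLogisticRegression(p=0.55).fit(x, a)
        assert m.loglik_ >= len(a) * np.log(0.5) - 1e-10

    def test_rank_deficiency_rejected(self, toy):
        x, a = toy
        X = np.column_stack([x, x])
        with pytest.raises(ValueError, match="rank deficient"):
            CrosswiseLogisticRegression(p=0.24).fit(X, a)

    def test_nonbinary_answers_rejected(self, toy):
        x, _ = toy
        with pytest.raises(ValueError, match="binary"):
            CrosswiseLogisticRegression(p=0.24).fit(x, np.full(len(x), 2))

    def test_sklearn_protocol_and_predictions(self, toy):
        x, a = toy
        m = CrosswiseLogisticRegression(p=0.24).fit(x, a)
        c = clone(m)
        assert c.get_params()["p"] == 0.24
        proba = m.predict_proba(np.array([[0.0], [1.0]]))
        assert proba.shape == (2, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        qa = m.predict_answer_proba(np.array([[0.0], [1.0]]))
        assert ((1 - 0.24) + (2 * 0.24 - 1) * proba[:, 1]
                == pytest.approx(qa))


class TestFormulaInterface:
    def test_listwise_deletion_and_or_table(self, fixture_survey, design24):
        survey, _ = fixture_survey
        spec = ModelSpec("answer", (Term("age", "18"), Term("sex", "girl")),
                         design24)
        fit = fit_crosswise_logistic(survey, spec)
        complete = survey[["answer", "age", "sex"]].dropna()
        assert fit.n_used == len(complete)
        # or_table is exp of beta and Wald limits, elementwise
        se = np.sqrt(np.diag(fit.cov.to_numpy()))
        z = 1.959963984540054
        for k, row in enumerate(fit.or_table.itertuples(), start=1):
            assert row.odds_ratio == pytest.approx(np.exp(fit.beta.iloc[k]))
            assert row.ci_low == pytest.approx(np.exp(fit.beta.iloc[k] - z * se[k]))
            assert row.ci_high == pytest.approx(np.exp(fit.beta.iloc[k] + z * se[k]))
        cov = fit.cov.to_numpy()
        assert np.allclose(cov, cov.T)
        assert (np.linalg.eigvalsh(cov) > -1e-10).all()

    def test_missing_reference_level(self, fixture_survey, design24):
        survey, _ = fixture_survey
        spec = ModelSpec("answer", (Term("age", "17"),), design24)
        with pytest.raises(ValueError, match="reference level"):
            fit_crosswise_logistic(survey, spec)

    def test_unknown_column(self, fixture_survey, design24):
        survey, _ = fixture_survey
        with pytest.raises(KeyError):
            fit_crosswise_logistic(
                survey, ModelSpec("answer", (Term("shoe_size"),), design24))

    def test_cluster_bootstrap_se_runs_seeded(self, fixture_survey, design24):
        survey, _ = fixture_survey
        spec = ModelSpec("answer", (Term("sex", "girl"),), design24)
        fit1 = fit_crosswise_logistic(survey, spec, cluster_col="cluster",
                                      n_boot=30, seed=5)
        fit2 = fit_crosswise_logistic(survey, spec, cluster_col="cluster",
                                      n_boot=30, seed=5)
        se1 = np.sqrt(np.diag(fit1.cov.to_numpy()))
        assert (se1 > 0).all() and np.isfinite(se1).all()
        assert np.allclose(fit1.cov.to_numpy(), fit2.cov.to_numpy())


@pytest.fixture(scope="module")
def fitted(design24):
    rng = np.random.default_rng(19)
    x = rng.binomial(1, 0.5, 1500).astype(float)
    a = crosswise_answers(rng, -0.4 + 1.0 * x, 0.24)
    data = pd.DataFrame({"answer": np.where(a == 1, "A", "B"),
                         "x": x.astype(int)})
    spec = ModelSpec("answer", (Term("x", "0"),), design24)
    return data, fit_crosswise_logistic(data, spec)


class TestLikelihoodProfile:
    def test_profile_peaks_at_the_mle(self, fitted):
        _, fit = fitted
        mle = float(fit.beta["x[1]"])
        grid = np.sort(np.concatenate([np.linspace(mle - 1.5, mle + 1.5, 13),
                                       [mle]]))
        prof = likelihood_profile(fit, "x[1]", grid)
        lls = prof["profile_loglik"].to_numpy()
        at_mle = lls[np.argmin(np.abs(prof["x[1]"].to_numpy() - mle))]
        assert at_mle == pytest.approx(fit.loglik, abs=1e-8)
        assert lls.max() <= fit.loglik + 1e-8
        # monotone decrease away from the MLE on both sides
        k = int(np.argmax(lls))
        assert (np.diff(lls[:k + 1]) >= -1e-9).all()
        assert (np.diff(lls[k:]) <= 1e-9).all()

    def test_grid_missing_mle_warns(self, fitted):
        _, fit = fitted
        with pytest.warns(RuntimeWarning, match="does not cover"):
            likelihood_profile(fit, "x[1]", np.linspace(5.0, 6.0, 3))

    def test_stronger_designs_give_sharper_profiles(self, design24):
        """The same latent data observed at p=0.9 yields a more curved
        profile than at p=0.6: information grows with |2p-1|."""
        rng = np.random.default_rng(23)
        n = 4000
        x = rng.binomial(1, 0.5, n).astype(float)
        y = (rng.random(n) < expit(-0.4 + 1.0 * x))
        drops = {}
        for p in (0.6, 0.9):
            z = rng.random(n) < p
            a = (y == z).astype(float)
            data = pd.DataFrame({"answer": np.where(a == 1, "A", "B"),
                                 "x": x.astype(int)})
            fit = fit_crosswise_logistic(
                data, ModelSpec("answer", (Term("x", "0"),), make_design(p)))
            mle = float(fit.beta["x[1]"])
            prof = likelihood_profile(fit, "x[1]",
                                      [mle - 0.5, mle, mle + 0.5])
            lls = prof["profile_loglik"].to_numpy()
            drops[p] = lls[1] - (lls[0] + lls[2]) / 2
        assert drops[0.9] > drops[0.6]
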