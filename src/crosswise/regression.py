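"""Crosswise logistic regression.

Logistic regression for a latent binary sensitive outcome y observed only
through the crosswise answer a (A=1 when the sensitive and innocuous answers
agree).  With innocuous prevalence p and linear predictor eta = x beta,

    Pr(a = 1 | x) = q(eta) = (1 - p) + (2p - 1) * sigmoid(eta),

and the log-likelihood is the Bernoulli likelihood in q.  Maximisation is by
Fisher scoring from beta = 0 with step-halving (the likelihood flattens as p
approaches 1/2, where the design carries no information); standard errors
come from the inverse observed information at the optimum.

At p = 1 the answer reveals y directly and the model reduces to ordinary
logistic regression; relabelling A/B while replacing p by 1 - p leaves the
likelihood invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .design import CrosswiseDesign

__all__ = [
    "Term",
    "ModelSpec",
    "RegressionFit",
    "CrosswiseLogisticRegression",
    "fit_crosswise_logistic",
    "likelihood_profile",
    "build_design_matrix",
]

_EPS = 1e-12  # clip for the answer probability q


def _loglik_parts(beta, X, a, p, offset=None):
    """Log-likelihood, score and the two information matrices at beta."""
    eta = X @ beta
    if offset is not None:
        eta = eta + offset
    s = 2.0 * p - 1.0
    sig = expit(eta)
    q = np.clip((1.0 - p) + s * sig, _EPS, 1.0 - _EPS)
    ll = float(np.sum(a * np.log(q) + (1 - a) * np.log1p(-q)))
    v = s * sig * (1.0 - sig)            # dq/deta
    w = v * (1.0 - 2.0 * sig)            # d2q/deta2
    resid = (a - q) / (q * (1.0 - q))
    grad = X.T @ (resid * v)
    fisher_w = v * v / (q * (1.0 - q))
    fisher = X.T @ (fisher_w[:, None] * X)
    # observed per-row curvature d2 log-lik / deta2
    h = a * (w * q - v * v) / q**2 + (1 - a) * (-w * (1.0 - q) - v * v) / (1.0 - q) ** 2
    hess = X.T @ (h[:, None] * X)
    return ll, grad, fisher, hess


def _loglik_only(beta, X, a, p, offset=None):
    eta = X @ beta
    if offset is not None:
        eta = eta + offset
    q = np.clip((1.0 - p) + (2.0 * p - 1.0) * expit(eta), _EPS, 1.0 - _EPS)
    return float(np.sum(a * np.log(q) + (1 - a) * np.log1p(-q)))


def _fisher_scoring(X, a, p, *, offset=None, max_iter=200, tol=1e-8,
                    max_halvings=40):
    """Maximise the crosswise log-likelihood; returns a result dict.

    Fisher-scoring steps with halving whenever a step would decrease the
    log-likelihood, so accepted iterations ascend monotonically.
    """
    n, k = X.shape
    if n < k:
        raise ValueError(f"n={n} rows for {k} parameters")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    beta = np.zeros(k)
    ll, grad, fisher, hess = _loglik_parts(beta, X, a, p, offset)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(fisher, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(fisher + 1e-8 * np.eye(k), grad)
        t = 1.0
        for _ in range(max_halvings):
            cand = beta + t * step
            ll_new = _loglik_only(cand, X, a, p, offset)
            if ll_new >= ll - 1e-13:
                break
            t *= 0.5
        else:
            break  # no ascent direction left; report non-convergence
        beta = beta + t * step
        ll, grad, fisher, hess = _loglik_parts(beta, X, a, p, offset)
    else:
        it = max_iter
    if not converged and np.max(np.abs(grad)) < tol:
        converged = True

    neg_hess = -hess
    cov = None
    try:
        # observed information; fall back to expected if not positive definite
        np.linalg.cholesky(neg_hess)
        cov = np.linalg.inv(neg_hess)
    except np.linalg.LinAlgError:
        try:
            cov = np.linalg.inv(fisher)
        except np.linalg.LinAlgError:
            cov = np.full((k, k), np.nan)
    return {"beta": beta, "cov": cov, "loglik": ll, "grad": grad,
            "converged": converged, "n_iter": it}


class CrosswiseLogisticRegression(BaseEstimator):
    """Logistic regression for a crosswise-observed binary outcome.

    scikit-learn-style estimator: ``fit(X, a)`` takes a numeric design
    matrix (without intercept column unless ``fit_intercept=False``) and the
    binary answer indicator a (1 = answer A).  ``predict_proba`` returns the
    latent sensitive-trait probability sigmoid(x beta); use
    :meth:`predict_answer_proba` for the observable A-probability.

    Parameters
    ----------
    p : float
        Known innocuous prevalence; must differ from 1/2.
    fit_intercept : bool, default True
    max_iter : int, default 200
    tol : float, default 1e-8
        Convergence tolerance on the maximum absolute score component.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
    intercept_ : float
    cov_ : ndarray
        Covariance of (intercept, coef) from inverse observed information.
    loglik_ : float
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, p: float = 0.24, fit_intercept: bool = True,
                 max_iter: int = 200, tol: float = 1e-8):
        self.p = p
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.tol = tol

    def _validate(self, X, a=None):
        CrosswiseDesign(p=self.p)  # validates p
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if a is None:
            return X
        a = np.asarray(a)
        if a.ndim != 1 or a.shape[0] != X.shape[0]:
            raise ValueError("X and a have incompatible shapes")
        uniq = np.unique(a)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError("a must be binary with 1 = answer A")
        return X, a.astype(float)

    def fit(self, X, a, offset=None):
        X, a = self._validate(X, a)
        if self.fit_intercept:
            Xd = np.column_stack([np.ones(X.shape[0]), X])
        else:
            Xd = X
        res = _fisher_scoring(Xd, a, self.p, offset=offset,
                              max_iter=self.max_iter, tol=self.tol)
        beta = res["beta"]
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = beta
        self.cov_ = res["cov"]
        self.loglik_ = res["loglik"]
        self.converged_ = res["converged"]
        self.n_iter_ = res["n_iter"]
        self.score_ = res["grad"]
        self.n_features_in_ = X.shape[1]
        if not self.converged_:
            warnings.warn("crosswise logistic fit did not converge; "
                          "partial result returned", RuntimeWarning)
        return self

    def decision_function(self, X):
        X = self._validate(X)
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        """Probability of the latent sensitive trait, columns (1-pi, pi)."""
        pi = expit(self.decision_function(X))
        return np.column_stack([1.0 - pi, pi])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)

    def predict_answer_proba(self, X):
        """Probability of observing answer A."""
        pi = expit(self.decision_function(X))
        return (1.0 - self.p) + (2.0 * self.p - 1.0) * pi


# ---------------------------------------------------------------------------
# Formula-level interface over respondent data frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """One model term: categorical (dummy-coded against ``reference``) or
    continuous (``reference=None``)."""

    name: str
    reference: str | None = None

    @property
    def is_categorical(self) -> bool:
        return self.reference is not None


@dataclass(frozen=True)
class ModelSpec:
    """Response column, model terms and the crosswise design."""

    response: str
    terms: tuple[Term, ...]
    design: CrosswiseDesign


@dataclass
class RegressionFit:
    """Result of a crosswise logistic fit on a respondent data frame."""

    beta: pd.Series
    cov: pd.DataFrame
    or_table: pd.DataFrame
    loglik: float
    converged: bool
    n_used: int
    iterations: int
    model: CrosswiseLogisticRegression = field(repr=False, default=None)
    X: np.ndarray = field(repr=False, default=None)
    a: np.ndarray = field(repr=False, default=None)


def build_design_matrix(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str], pd.DataFrame]:
    """Listwise-delete and dummy-code; returns (X, a, names, used rows).

    Categorical terms are coded against their declared reference level,
    which must appear in the data; the answer column accepts A/B
    case-insensitively with A mapped to 1.
    """
    cols = [spec.response] + [t.name for t in spec.terms]
    for c in cols:
        if c not in data.columns:
            raise KeyError(f"column {c!r} not in data")
    used = data[cols].dropna()
    ans = used[spec.response].astype(str).str.upper()
    if not ans.isin(["A", "B"]).all():
        bad = sorted(set(ans[~ans.isin(["A", "B"])]))
        raise ValueError(f"invalid answer tokens {bad}")
    a = (ans == "A").to_numpy(dtype=float)

    blocks: list[np.ndarray] = []
    names: list[str] = []
    for term in spec.terms:
        col = used[term.name]
        if term.is_categorical:
            cats = sorted(map(str, col.unique()))
            if str(term.reference) not in cats:
                raise ValueError(
                    f"reference level {term.reference!r} of {term.name!r} "
                    f"absent from data (levels: {cats})")
            svals = col.astype(str)
            for cat in cats:
                if cat == str(term.reference):
                    continue
                blocks.append((svals == cat).to_numpy(dtype=float))
                names.append(f"{term.name}[{cat}]")
        else:
            blocks.append(pd.to_numeric(col).to_numpy(dtype=float))
            names.append(term.name)
    X = np.column_stack(blocks) if blocks else np.empty((len(used), 0))
    return X, a, names, used


def fit_crosswise_logistic(
    data: pd.DataFrame,
    spec: ModelSpec,
    max_iter: int = 200,
    tol: float = 1e-8,
    cluster_col: str | None = None,
    n_boot: int = 999,
    seed: int = 0,
) -> RegressionFit:
    """Fit the crosswise logistic model on respondent-level data.

    Rows with a missing response or any missing model covariate are dropped
    (listwise deletion).  The OR table reports exp(beta), Wald confidence
    limits and two-sided normal p-values per non-intercept coefficient.
    With ``cluster_col`` set, coefficient standard errors are replaced by a
    seeded cluster bootstrap (resampling clusters with replacement).
    """
    X, a, names, used = build_design_matrix(data, spec)
    model = CrosswiseLogisticRegression(p=spec.design.p, max_iter=max_iter, tol=tol)
    model.fit(X, a)
    full_names = ["(intercept)"] + names
    beta = pd.Series(np.concatenate([[model.intercept_], model.coef_]),
                     index=full_names, name="beta")
    cov = pd.DataFrame(model.cov_, index=full_names, columns=full_names)

    if cluster_col is not None:
        cov = _cluster_bootstrap_cov(data, spec, cluster_col, n_boot, seed,
                                     full_names, max_iter, tol)

    se = np.sqrt(np.diag(cov.to_numpy()))
    z = norm.ppf(0.975)
    rows = []
    for j, name in enumerate(full_names):
        if name == "(intercept)":
            continue
        b, s = beta.iloc[j], se[j]
        wald = b / s if s > 0 else np.nan
        rows.append({
            "term": name,
            "odds_ratio": float(np.exp(b)),
            "ci_low": float(np.exp(b - z * s)),
            "ci_high": float(np.exp(b + z * s)),
            "p_value": float(2 * norm.sf(abs(wald))) if np.isfinite(wald) else np.nan,
        })
    or_table = pd.DataFrame(rows, columns=["term", "odds_ratio", "ci_low",
                                           "ci_high", "p_value"])
    return RegressionFit(beta=beta, cov=cov, or_table=or_table,
                         loglik=model.loglik_, converged=model.converged_,
                         n_used=len(used), iterations=model.n_iter_,
                         model=model, X=X, a=a)


def _cluster_bootstrap_cov(data, spec, cluster_col, n_boot, seed,
                           full_names, max_iter, tol) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    clusters = data[cluster_col].dropna().unique()
    draws = []
    for _ in range(n_boot):
        picked = rng.choice(clusters, size=len(clusters), replace=True)
        boot = pd.concat([data[data[cluster_col] == c] for c in picked],
                         ignore_index=True)
        try:
            X, a, _, _ = build_design_matrix(boot, spec)
            m = CrosswiseLogisticRegression(p=spec.design.p, max_iter=max_iter,
                                            tol=tol)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                m.fit(X, a)
            draws.append(np.concatenate([[m.intercept_], m.coef_]))
        except (ValueError, np.linalg.LinAlgError):
            continue
    draws = np.asarray(draws)
    if len(draws) < 2:
        raise ValueError("cluster bootstrap produced too few valid fits")
    return pd.DataFrame(np.cov(draws, rowvar=False), index=full_names,
                        columns=full_names)


def likelihood_profile(
    fit: RegressionFit,
    term: str,
    grid,
    p: float | None = None,
) -> pd.DataFrame:
    """Profile log-likelihood of one coefficient over a grid.

    At each grid value the term's coefficient is fixed (entering as an
    offset) and all other coefficients are re-maximised.  Warns when the
    grid does not bracket the MLE of the profiled coefficient.
    """
    if fit.model is None or fit.X is None:
        raise ValueError("fit carries no model/data; refit with fit_crosswise_logistic")
    names = list(fit.beta.index)
    if term not in names:
        raise KeyError(f"unknown term {term!r}; have {names}")
    j = names.index(term)
    mle = float(fit.beta.iloc[j])
    grid = np.asarray(grid, dtype=float)
    if mle < grid.min() or mle > grid.max():
        warnings.warn(f"profile grid [{grid.min():g}, {grid.max():g}] does not "
                      f"cover the MLE {mle:.4g} of {term!r}", RuntimeWarning)

    Xfull = np.column_stack([np.ones(len(fit.a)), fit.X])
    keep = [k for k in range(Xfull.shape[1]) if k != j]
    Xr = Xfull[:, keep]
    col = Xfull[:, j]
    pval = fit.model.p if p is None else p
    lls = []
    for g in grid:
        res = _fisher_scoring(Xr, fit.a, pval, offset=g * col,
                              max_iter=fit.model.max_iter, tol=fit.model.tol)
        lls.append(res["loglik"])
    return pd.DataFrame({term: grid, "profile_loglik": lls})
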