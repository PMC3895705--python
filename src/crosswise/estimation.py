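"""Prevalence estimation from crosswise answer counts.

The proportion of A ("my two answers agree") responses, lambda, relates to
the sensitive prevalence pi through lambda = (1-p) + (2p-1) pi, so the
moment estimator is

    pi_hat = (lambda_hat + p - 1) / (2p - 1),

with standard error SE(lambda_hat) / |2p - 1|.  With p < 1/2 the inversion
is order-reversing, so interval endpoints mapped from the lambda scale must
be swapped.  Estimates and bounds are clipped to [0, 1] with an explicit
flag rather than raising: sampling noise legitimately pushes lambda_hat
outside [min(p, 1-p), max(p, 1-p)] in small samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator
from statsmodels.stats.proportion import proportion_confint

from .design import CrosswiseDesign

__all__ = [
    "CrosswiseCounts",
    "PrevalenceEstimate",
    "GroupComparison",
    "PrevalenceEstimator",
    "estimate_lambda",
    "estimate_prevalence",
    "cluster_robust_se",
    "compare_groups",
    "counts_from_survey",
]


@dataclass(frozen=True)
class CrosswiseCounts:
    """Sufficient statistic for prevalence estimation: A and B counts.

    ``cluster_breakdown`` optionally carries per-cluster ``(n_A, n_B)``
    pairs for cluster-robust variance estimation; it must sum to the totals.
    """

    n_A: int
    n_B: int
    stratum: str | None = None
    cluster_breakdown: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_A < 0 or self.n_B < 0:
            raise ValueError("counts must be non-negative")
        if self.n < 1:
            raise ValueError("empty data: need at least one response")
        if self.cluster_breakdown is not None:
            a = sum(c[0] for c in self.cluster_breakdown)
            b = sum(c[1] for c in self.cluster_breakdown)
            if (a, b) != (self.n_A, self.n_B):
                raise ValueError("cluster breakdown does not sum to the totals")

    @property
    def n(self) -> int:
        return self.n_A + self.n_B


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Point and interval estimate of the sensitive prevalence."""

    lambda_hat: float
    pi_hat: float
    se: float
    ci_low: float
    ci_high: float
    level: float
    clipped: bool
    method: str
    n: int
    stratum: str | None = None
    design_effect: float | None = None

    def percent(self) -> tuple[int, int, int]:
        """(pi, low, high) as integer percents, rounding half away from zero."""
        return tuple(int(np.floor(100 * v + 0.5)) for v in
                     (self.pi_hat, self.ci_low, self.ci_high))


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample z comparison of independent prevalence estimates."""

    diff: float
    se: float
    z: float
    p_value: float
    ci_low: float
    ci_high: float
    level: float


def estimate_lambda(counts: CrosswiseCounts) -> tuple[float, float]:
    """A-proportion and its binomial standard error."""
    lam = counts.n_A / counts.n
    se = np.sqrt(lam * (1.0 - lam) / counts.n)
    return lam, float(se)


def _clip01(x: float) -> float:
    return min(1.0, max(0.0, x))


def estimate_prevalence(
    counts_or_lambda: CrosswiseCounts | float,
    design: CrosswiseDesign,
    level: float = 0.95,
    method: str = "wald",
    n: int | None = None,
) -> PrevalenceEstimate:
    """Estimate the sensitive prevalence from counts or a bare A-proportion.

    With a :class:`CrosswiseCounts` input the standard error and confidence
    interval are computed; with a bare ``lambda_hat`` (and no ``n``) only
    the point estimate is defined and SE/CI are NaN.  ``method`` is
    ``"wald"`` (normal interval on the pi scale, the default) or
    ``"wilson"`` (Wilson score interval for lambda mapped through the
    inversion, endpoint-swapped when p < 1/2).
    """
    if method not in ("wald", "wilson"):
        raise ValueError(f"unknown CI method {method!r}")
    stratum = None
    if isinstance(counts_or_lambda, CrosswiseCounts):
        counts = counts_or_lambda
        lam, lam_se = estimate_lambda(counts)
        n = counts.n
        stratum = counts.stratum
    else:
        lam = float(counts_or_lambda)
        if not (0.0 <= lam <= 1.0):
            raise ValueError("lambda_hat must lie in [0, 1]")
        counts = None
        if n is not None:
            lam_se = float(np.sqrt(lam * (1.0 - lam) / n))
        else:
            lam_se = float("nan")

    raw = design.pi_from_lambda(lam)
    pi_hat = _clip01(raw)
    se = lam_se / abs(design.slope)
    z = norm.ppf(0.5 + level / 2.0)

    if np.isnan(se):
        lo = hi = float("nan")
        clipped = pi_hat != raw
    elif method == "wald":
        lo_raw, hi_raw = raw - z * se, raw + z * se
        lo, hi = _clip01(lo_raw), _clip01(hi_raw)
        clipped = (pi_hat != raw) or (lo != lo_raw) or (hi != hi_raw)
    else:
        if counts is None:
            n_A = int(round(lam * n))
        else:
            n_A = counts.n_A
        lam_lo, lam_hi = proportion_confint(n_A, n, alpha=1.0 - level, method="wilson")
        end1 = design.pi_from_lambda(float(lam_lo))
        end2 = design.pi_from_lambda(float(lam_hi))
        lo_raw, hi_raw = (end2, end1) if design.slope < 0 else (end1, end2)
        lo, hi = _clip01(lo_raw), _clip01(hi_raw)
        clipped = (pi_hat != raw) or (lo != lo_raw) or (hi != hi_raw)

    return PrevalenceEstimate(
        lambda_hat=float(lam), pi_hat=float(pi_hat), se=float(se),
        ci_low=float(lo), ci_high=float(hi), level=level, clipped=bool(clipped),
        method=method, n=int(n) if n else 0, stratum=stratum,
    )


def cluster_robust_se(
    counts: CrosswiseCounts,
    design: CrosswiseDesign,
    level: float = 0.95,
) -> PrevalenceEstimate:
    """Prevalence estimate with a between-cluster variance for lambda_hat.

    Uses the ultimate-cluster (linearisation) estimator: with cluster totals
    t_c of A answers and sizes m_c,

        Var(lambda_hat) = k/(k-1) * sum_c (t_c - m_c lambda_hat)^2 / n^2,

    propagated through division by |2p-1|.  The result's ``design_effect``
    is the ratio of this variance to the binomial variance lambda(1-lambda)/n.
    """
    if counts.cluster_breakdown is None or len(counts.cluster_breakdown) < 2:
        raise ValueError("cluster-robust variance needs >= 2 clusters")
    k = len(counts.cluster_breakdown)
    t = np.array([c[0] for c in counts.cluster_breakdown], dtype=float)
    m = np.array([c[0] + c[1] for c in counts.cluster_breakdown], dtype=float)
    n = counts.n
    lam = counts.n_A / n
    var_lam = k / (k - 1) * float(np.sum((t - m * lam) ** 2)) / n**2
    var_binom = lam * (1.0 - lam) / n
    deff = var_lam / var_binom if var_binom > 0 else float("inf")

    raw = design.pi_from_lambda(lam)
    pi_hat = _clip01(raw)
    se = float(np.sqrt(var_lam)) / abs(design.slope)
    z = norm.ppf(0.5 + level / 2.0)
    lo_raw, hi_raw = raw - z * se, raw + z * se
    lo, hi = _clip01(lo_raw), _clip01(hi_raw)
    return PrevalenceEstimate(
        lambda_hat=float(lam), pi_hat=float(pi_hat), se=float(se),
        ci_low=float(lo), ci_high=float(hi), level=level,
        clipped=bool((pi_hat != raw) or (lo != lo_raw) or (hi != hi_raw)),
        method="wald-cluster", n=n, stratum=counts.stratum,
        design_effect=float(deff),
    )


def compare_groups(
    est1: PrevalenceEstimate, est2: PrevalenceEstimate, level: float = 0.95
) -> GroupComparison:
    """z test for a difference between two independent prevalence estimates."""
    se = float(np.sqrt(est1.se**2 + est2.se**2))
    if not np.isfinite(se) or se == 0.0:
        raise ValueError("degenerate data: combined standard error is zero")
    diff = est1.pi_hat - est2.pi_hat
    z = diff / se
    p = 2.0 * norm.sf(abs(z))
    zq = norm.ppf(0.5 + level / 2.0)
    return GroupComparison(diff=diff, se=se, z=float(z), p_value=float(p),
                           ci_low=diff - zq * se, ci_high=diff + zq * se,
                           level=level)


def counts_from_survey(
    survey: pd.DataFrame,
    by: str | None = None,
    answer_col: str = "answer",
    cluster_col: str = "cluster",
) -> CrosswiseCounts | dict[str, CrosswiseCounts]:
    """Aggregate a respondent-level survey into :class:`CrosswiseCounts`.

    With ``by`` set, returns one counts object per non-missing stratum of
    that covariate.  A cluster breakdown is attached when ``cluster_col``
    is present.
    """
    if answer_col not in survey.columns:
        raise KeyError(f"no answer column {answer_col!r} in survey")
    a = survey[answer_col].astype(str).str.upper()
    bad = ~a.isin(["A", "B"])
    if bad.any():
        raise ValueError(f"invalid answer tokens: {sorted(survey[answer_col][bad].unique())}")

    def _one(frame: pd.DataFrame, stratum: str | None) -> CrosswiseCounts:
        fa = frame[answer_col].astype(str).str.upper()
        breakdown = None
        if cluster_col in frame.columns:
            grouped = fa.groupby(frame[cluster_col])
            breakdown = tuple(
                (int((g == "A").sum()), int((g == "B").sum()))
                for _, g in grouped
            )
        return CrosswiseCounts(n_A=int((fa == "A").sum()), n_B=int((fa == "B").sum()),
                               stratum=stratum, cluster_breakdown=breakdown)

    if by is None:
        return _one(survey, None)
    if by not in survey.columns:
        raise KeyError(f"no stratification column {by!r} in survey")
    out: dict[str, CrosswiseCounts] = {}
    for value, frame in survey.dropna(subset=[by]).groupby(by, sort=True):
        out[str(value)] = _one(frame, str(value))
    return out


class PrevalenceEstimator(BaseEstimator):
    """Sensitive-prevalence estimator with a scikit-learn-style interface.

    Parameters
    ----------
    p : float
        Known innocuous-trait prevalence of the crosswise design.
    level : float, default 0.95
        Confidence level.
    method : {"wald", "wilson"}, default "wald"
        Interval construction; ignored when clusters are supplied (a
        cluster-robust Wald interval is then used).

    Attributes
    ----------
    lambda_hat_, pi_hat_, se_, ci_low_, ci_high_, clipped_, n_ :
        Components of the fitted estimate.
    estimate_ : PrevalenceEstimate
        The full result object.
    """

    def __init__(self, p: float = 0.24, level: float = 0.95, method: str = "wald"):
        self.p = p
        self.level = level
        self.method = method

    def fit(self, answers, clusters=None) -> "PrevalenceEstimator":
        """Fit from a vector of crosswise answers ('A'/'B' or 1/0)."""
        design = CrosswiseDesign(p=self.p)
        a = np.asarray(answers)
        if a.ndim != 1:
            a = a.ravel()
        if a.dtype.kind in "USO":
            upper = np.char.upper(a.astype(str))
            if not np.isin(upper, ["A", "B"]).all():
                raise ValueError("answers must be 'A' or 'B'")
            ind = upper == "A"
        else:
            ind = a.astype(bool)
        if clusters is not None:
            clusters = np.asarray(clusters).ravel()
            breakdown = tuple(
                (int(ind[clusters == c].sum()), int((~ind[clusters == c]).sum()))
                for c in np.unique(clusters)
            )
            counts = CrosswiseCounts(int(ind.sum()), int((~ind).sum()),
                                     cluster_breakdown=breakdown)
            self.estimate_ = cluster_robust_se(counts, design, level=self.level)
        else:
            counts = CrosswiseCounts(int(ind.sum()), int((~ind).sum()))
            self.estimate_ = estimate_prevalence(counts, design, level=self.level,
                                                 method=self.method)
        est = self.estimate_
        self.lambda_hat_, self.pi_hat_, self.se_ = est.lambda_hat, est.pi_hat, est.se
        self.ci_low_, self.ci_high_ = est.ci_low, est.ci_high
        self.clipped_, self.n_ = est.clipped, est.n
        return self
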