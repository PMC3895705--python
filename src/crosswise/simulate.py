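"""Synthetic crosswise-survey generator.

Generates respondent-level datasets with the statistical structure of a
cluster-sampled crosswise survey: categorical covariates drawn from declared
margins, a latent sensitive trait following a logistic model with a
cluster-level random intercept, an independent innocuous trait of known
prevalence, the crosswise answer A/B, and per-item missingness.

The survey table a downstream analyst sees never contains the latent traits;
they are returned in a separate truth table with the same row order, so tests
can verify the response mechanism and parameter recovery while inference code
only ever sees A/B answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq
from scipy.special import expit, logit

from .design import CrosswiseDesign

__all__ = [
    "CovariateSpec",
    "PopulationSpec",
    "simulate_survey",
    "study_fixture",
    "study_population_spec",
]

ANSWER_SAME = "A"
ANSWER_DIFFERENT = "B"

#: Cluster random-intercept SD (logit scale) of the canonical study fixture,
#: calibrated by Monte Carlo so that 75 clusters x 20 respondents yield an
#: empirical design effect of ~2 for the A-proportion.
STUDY_CLUSTER_SD = 1.12


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution and item non-response of one categorical covariate."""

    name: str
    categories: tuple[str, ...]
    probs: tuple[float, ...]
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.probs):
            raise ValueError(f"{self.name}: categories and probabilities differ in length")
        if any(q < 0 for q in self.probs) or abs(sum(self.probs) - 1.0) > 1e-12:
            raise ValueError(f"{self.name}: marginal probabilities must sum to 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"{self.name}: missing rate must lie in [0, 1)")


@dataclass(frozen=True)
class PopulationSpec:
    """Everything needed to simulate one crosswise survey.

    ``effects`` maps covariate name -> {category -> logit-scale coefficient};
    omitted categories (the reference levels) contribute 0.  ``intercept`` and
    the effects are conditional on the cluster random intercept, which is
    Normal(0, cluster_sd^2) on the logit scale.
    """

    n_clusters: int
    cluster_size: int
    design: CrosswiseDesign
    intercept: float
    covariates: tuple[CovariateSpec, ...] = ()
    effects: dict = field(default_factory=dict)
    cluster_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.cluster_size < 1:
            raise ValueError("need at least one cluster of at least one respondent")
        if self.cluster_sd < 0:
            raise ValueError("cluster_sd must be >= 0")
        names = {c.name for c in self.covariates}
        for key in self.effects:
            if key not in names:
                raise ValueError(f"effect declared for unknown covariate {key!r}")

    @property
    def n(self) -> int:
        return self.n_clusters * self.cluster_size


def simulate_survey(
    spec: PopulationSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one survey; returns ``(survey, truth)`` data frames.

    For each respondent the generator draws covariates from their margins,
    a cluster intercept u_c ~ Normal(0, cluster_sd^2), the latent sensitive
    trait y ~ Bernoulli(sigmoid(x beta + u_c)), and the innocuous trait
    z ~ Bernoulli(p) independent of everything else.  The recorded answer is
    A exactly when y == z.  Missingness is applied independently per
    covariate (missing completely at random), after the traits are drawn.

    ``survey`` holds cluster, answer, and covariates (missing as NaN);
    ``truth`` holds the hidden y, z, and the linear predictor, row-aligned
    with ``survey``.  Deterministic given ``spec.seed`` (or the ``rng``
    passed in).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n
    cluster_id = np.repeat(np.arange(spec.n_clusters), spec.cluster_size)

    eta = np.full(n, spec.intercept, dtype=float)
    columns: dict[str, np.ndarray] = {}
    for cov in spec.covariates:
        codes = rng.choice(len(cov.categories), size=n, p=np.asarray(cov.probs))
        values = np.asarray(cov.categories, dtype=object)[codes]
        columns[cov.name] = values
        for category, coef in spec.effects.get(cov.name, {}).items():
            eta += np.where(values == category, coef, 0.0)

    u = rng.normal(0.0, spec.cluster_sd, spec.n_clusters) if spec.cluster_sd > 0 \
        else np.zeros(spec.n_clusters)
    eta += u[cluster_id]

    y = rng.random(n) < expit(eta)
    z = rng.random(n) < spec.design.p
    answer = np.where(y == z, ANSWER_SAME, ANSWER_DIFFERENT)

    survey = pd.DataFrame({"cluster": cluster_id, "answer": answer})
    for cov in spec.covariates:
        values = columns[cov.name]
        if cov.missing_rate > 0:
            values = values.copy()
            values[rng.random(n) < cov.missing_rate] = np.nan
        survey[cov.name] = values

    truth = pd.DataFrame({
        "cluster": cluster_id,
        "y_sensitive": y.astype(int),
        "z_innocuous": z.astype(int),
        "eta": eta,
    })
    return survey, truth


# ---------------------------------------------------------------------------
# The canonical study fixture: 75 clusters x 20 university students,
# innocuous prevalence p = 0.24, overall sensitive prevalence 0.41,
# age-21-vs-18 odds ratio 3.7, covariate margins from the study's
# descriptive tables.
# ---------------------------------------------------------------------------

_STUDY_P = 0.24
_STUDY_PI = 0.41
_STUDY_AGE21_OR = 3.7
_AGES = ("18", "19", "20", "21", "22", "23", "24")
# 60.3% aged 18-21 spread uniformly over four years, the rest over 22-24.
_AGE_PROBS = (0.603 / 4,) * 4 + (0.397 / 3,) * 3

_GH_NODES, _GH_WEIGHTS = hermegauss(60)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _marginal_prob(eta: float, sigma: float) -> float:
    """E[sigmoid(eta + u)] for u ~ Normal(0, sigma^2), by Gauss-Hermite."""
    if sigma == 0.0:
        return float(expit(eta))
    return float(expit(eta + sigma * _GH_NODES) @ _GH_WEIGHTS)


def _conditional_eta(target: float, sigma: float) -> float:
    """Invert the marginalisation: eta with E[sigmoid(eta + u)] = target."""
    if sigma == 0.0:
        return float(logit(target))
    return brentq(lambda e: _marginal_prob(e, sigma) - target, -40.0, 40.0, xtol=1e-13)


def _study_age_margins() -> tuple[float, ...]:
    """Population prevalence per age group hitting the fixture's truths.

    Solves for the reference (age-18) prevalence pi_18 such that, with a
    population-averaged odds ratio of 3.7 for age 21 and no effect for the
    other ages, the overall prevalence is 0.41.
    """
    w = np.asarray(_AGE_PROBS)
    idx21 = _AGES.index("21")
    log_or = np.log(_STUDY_AGE21_OR)

    def overall(pi_ref: float) -> float:
        pis = np.full(len(_AGES), pi_ref)
        pis[idx21] = expit(logit(pi_ref) + log_or)
        return float(w @ pis) - _STUDY_PI

    pi_ref = brentq(overall, 1e-6, 1 - 1e-6, xtol=1e-13)
    pis = np.full(len(_AGES), pi_ref)
    pis[idx21] = expit(logit(pi_ref) + log_or)
    return tuple(float(v) for v in pis)


def study_population_spec(seed: int = 0, cluster_sd: float = STUDY_CLUSTER_SD) -> PopulationSpec:
    """The :class:`PopulationSpec` behind :func:`study_fixture`.

    Margins follow the study's descriptive tables: 63.2% girls among the
    1454 respondents with recorded sex (27 of ~1500 missing), 60.3% aged
    18-21, 91.5% urban, four religious-attendance levels, seven
    media-exposure categories, and a life-skills-course indicator.  The
    stated truths — overall prevalence 0.41 and an age-21-vs-18 odds ratio
    of 3.7 — are population-averaged; the conditional coefficients are
    recovered from them by integrating out the cluster intercept.
    """
    age_pis = _study_age_margins()
    eta_by_age = [_conditional_eta(pi_a, cluster_sd) for pi_a in age_pis]
    intercept = eta_by_age[0]
    age_effects = {age: eta - intercept
                   for age, eta in zip(_AGES[1:], eta_by_age[1:])}

    covariates = (
        CovariateSpec("sex", ("girl", "boy"), (919 / 1454, 535 / 1454),
                      missing_rate=27 / 1481),
        CovariateSpec("age", _AGES, _AGE_PROBS, missing_rate=1 - 1438 / 1500),
        CovariateSpec("residence", ("urban", "rural"), (0.915, 0.085),
                      missing_rate=1 - 1390 / 1500),
        CovariateSpec("religious_attendance",
                      ("never", "seldom", "sometimes", "often"),
                      (99 / 1443, 379 / 1443, 619 / 1443, 346 / 1443),
                      missing_rate=1 - 1443 / 1500),
        CovariateSpec("media",
                      ("book", "film", "picture", "satellite", "other",
                       "combination", "none"),
                      (73 / 1454, 450 / 1454, 109 / 1454, 145 / 1454,
                       11 / 1454, 378 / 1454, 288 / 1454),
                      missing_rate=1 - 1454 / 1500),
        CovariateSpec("life_skill_course", ("yes", "no"),
                      (525 / 1454, 929 / 1454), missing_rate=1 - 1454 / 1500),
    )
    return PopulationSpec(
        n_clusters=75, cluster_size=20,
        design=CrosswiseDesign(p=_STUDY_P,
                               sensitive_label="ever had sexual intercourse",
                               innocuous_label="friend or relative named Ali or Mohammad"),
        intercept=intercept,
        covariates=covariates,
        effects={"age": age_effects},
        cluster_sd=cluster_sd,
        seed=seed,
    )


def study_fixture(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the canonical 1500-respondent study fixture at ``seed``."""
    return simulate_survey(study_population_spec(seed=seed))
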