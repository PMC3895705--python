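"""Crosswise survey design and sample-size planning.

The crosswise design pairs a sensitive yes/no question with an unrelated
innocuous question whose population prevalence ``p`` is known (e.g. from a
name registry).  Respondents report only whether their two answers agree
(option A) or disagree (option B), so no individual answer is disclosed.
The probability of an A answer is

    lambda = pi * p + (1 - pi) * (1 - p) = (1 - p) + (2p - 1) * pi,

which identifies the sensitive prevalence ``pi`` whenever p != 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

from scipy.stats import norm

__all__ = [
    "CrosswiseDesign",
    "SamplePlan",
    "make_design",
    "plan_sample_size",
    "variance_inflation",
]

#: Designs with |p - 1/2| below this tolerance are rejected as
#: non-identifiable (the A-probability no longer depends on pi).
IDENTIFIABILITY_TOL = 1e-9


@dataclass(frozen=True)
class CrosswiseDesign:
    """The known innocuous prevalence and question-pair metadata.

    Parameters
    ----------
    p : float
        Population probability of "yes" to the innocuous question,
        in [0, 1] and bounded away from 1/2.
    sensitive_label, innocuous_label : str
        Human-readable descriptions of the two questions.
    """

    p: float
    sensitive_label: str = "sensitive attribute"
    innocuous_label: str = "innocuous attribute"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"innocuous prevalence p={self.p!r} outside [0, 1]")
        if abs(self.p - 0.5) < IDENTIFIABILITY_TOL:
            raise ValueError(
                "non-identifiable design: p = 1/2 makes the A-probability "
                "independent of the sensitive prevalence"
            )

    @property
    def slope(self) -> float:
        """2p - 1, the slope of lambda in pi (negative when p < 1/2)."""
        return 2.0 * self.p - 1.0

    def lambda_from_pi(self, pi: float) -> float:
        """Forward map: probability of an A answer at sensitive prevalence pi."""
        return (1.0 - self.p) + self.slope * pi

    def pi_from_lambda(self, lam: float) -> float:
        """Inverse map (moment estimator), unclipped."""
        return (lam + self.p - 1.0) / self.slope

    def to_config(self) -> dict:
        return {"p": self.p,
                "sensitive_label": self.sensitive_label,
                "innocuous_label": self.innocuous_label}

    @classmethod
    def from_config(cls, cfg: Mapping[str, object]) -> "CrosswiseDesign":
        return cls(p=float(cfg["p"]),
                   sensitive_label=str(cfg.get("sensitive_label", "sensitive attribute")),
                   innocuous_label=str(cfg.get("innocuous_label", "innocuous attribute")))


def make_design(p: float, labels: tuple[str, str] | None = None) -> CrosswiseDesign:
    """Construct a validated :class:`CrosswiseDesign`.

    ``labels`` is an optional ``(sensitive, innocuous)`` pair of question
    descriptions.
    """
    if labels is None:
        return CrosswiseDesign(p=p)
    sensitive, innocuous = labels
    return CrosswiseDesign(p=p, sensitive_label=sensitive, innocuous_label=innocuous)


@dataclass(frozen=True)
class SamplePlan:
    """A cluster-survey sample-size plan for estimating a proportion.

    ``n_base`` is the size implied by the precision requirement after the
    design-effect and response-rate adjustments; ``n_final`` additionally
    inflates for the extra variance of indirect (crosswise) questioning.
    """

    p0: float
    alpha: float
    d: float
    deff: float
    response_rate: float
    crosswise_inflation: float
    n_base: int
    n_final: int
    n_clusters: int | None = None
    cluster_size: int | None = None

    def __post_init__(self) -> None:
        if not (self.n_final >= self.n_base >= 1):
            raise ValueError("sample plan requires n_final >= n_base >= 1")
        if self.n_clusters is not None and self.cluster_size is not None:
            if self.n_clusters * self.cluster_size < self.n_final:
                raise ValueError("clusters do not cover the planned sample size")

    def to_config(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def plan_sample_size(
    p0: float,
    alpha: float = 0.05,
    d: float = 0.05,
    deff: float = 1.0,
    response_rate: float = 1.0,
    crosswise_inflation: float = 1.0,
    n_base: int | None = None,
    cluster_size: int | None = None,
) -> SamplePlan:
    """Plan the sample size for a cluster survey of a proportion.

    The base size is the single-proportion precision formula with a design
    effect and response-rate correction,

        n_base = ceil( z_{1-alpha/2}^2 * p0 (1 - p0) / d^2 * deff / response_rate ),

    and the final size inflates it for crosswise questioning,
    ``n_final = ceil(n_base * crosswise_inflation)``.  Rounding is upward at
    each stage.  Pass ``n_base`` explicitly to inflate an externally chosen
    base size instead of the formula's.  If ``cluster_size`` is given the
    plan allocates ``ceil(n_final / cluster_size)`` clusters.
    """
    if not (0.0 < p0 < 1.0):
        raise ValueError("planning prevalence p0 must lie in (0, 1)")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if d <= 0.0:
        raise ValueError("precision half-width d must be positive")
    if deff < 1.0:
        raise ValueError("design effect must be >= 1")
    if not (0.0 < response_rate <= 1.0):
        raise ValueError("response rate must lie in (0, 1]")
    if crosswise_inflation < 1.0:
        raise ValueError("crosswise inflation factor must be >= 1")

    if n_base is None:
        z = norm.ppf(1.0 - alpha / 2.0)
        n_raw = z * z * p0 * (1.0 - p0) / (d * d) * deff / response_rate
        n_base = math.ceil(n_raw)
    elif n_base < 1:
        raise ValueError("n_base must be >= 1")

    n_final = math.ceil(n_base * crosswise_inflation)
    n_clusters = None
    if cluster_size is not None:
        if cluster_size < 1:
            raise ValueError("cluster size must be >= 1")
        n_clusters = math.ceil(n_final / cluster_size)

    return SamplePlan(
        p0=p0, alpha=alpha, d=d, deff=deff, response_rate=response_rate,
        crosswise_inflation=crosswise_inflation, n_base=int(n_base),
        n_final=int(n_final), n_clusters=n_clusters, cluster_size=cluster_size,
    )


def variance_inflation(design: CrosswiseDesign, pi: float) -> float:
    """Variance of the crosswise estimator relative to direct questioning.

    For a simple random sample of size n the crosswise moment estimator has
    variance lambda(1-lambda) / (n (2p-1)^2) against pi(1-pi)/n for a direct
    question, so the ratio

        [lambda (1 - lambda) / (2p - 1)^2] / [pi (1 - pi)]

    quantifies the privacy premium.  It is >= 1 everywhere, equals 1 in the
    degenerate direct-questioning limits p in {0, 1}, and diverges as
    p -> 1/2.
    """
    if not (0.0 < pi < 1.0):
        raise ValueError("variance inflation requires 0 < pi < 1")
    lam = design.lambda_from_pi(pi)
    return (lam * (1.0 - lam) / design.slope**2) / (pi * (1.0 - pi))
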