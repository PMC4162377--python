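"""Two-parameter binary item response model and its factor-analytic form.

A binary item response is modelled on two equivalent metrics.

IRT metric
    P(y = 1 | eta) = F(a * (eta - b))
    with discrimination ``a``, difficulty ``b`` and latent ability ``eta``.

Factor metric
    The observed response is a dichotomisation of a continuous latent
    response variable ``y* = lambda * eta + epsilon``; the item scores 1
    when ``y*`` exceeds a threshold ``tau``.  Under a logit link the
    residual ``epsilon`` is standard logistic (variance pi^2/3); under a
    probit link it is standard normal (variance 1).  In both cases

        P(y = 1 | eta) = F(lambda * eta - tau)

    where ``F`` is the link's CDF, so the two metrics are connected by

        a = lambda,    b = tau / lambda.

The latent ability in group ``g`` is distributed N(alpha_g, psi_g); the
group mean and variance are carried by :class:`GroupDistribution`.

Everything in this module is pure computation on finite numbers: no
clipping or guarding is applied to the returned probabilities (likelihood
code does its own guarding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit, ndtr

__all__ = [
    "LINKS",
    "LOGIT_RESIDUAL_VARIANCE",
    "PROBIT_RESIDUAL_VARIANCE",
    "DomainError",
    "UndefinedDifficultyError",
    "ItemParamsFactor",
    "ItemParamsIRT",
    "GroupDistribution",
    "link_cdf",
    "item_response_prob",
    "threshold_model_prob",
    "factor_to_irt",
    "irt_to_factor",
]

#: Residual variance of the latent response variable, fixed by the link.
LOGIT_RESIDUAL_VARIANCE = math.pi ** 2 / 3
PROBIT_RESIDUAL_VARIANCE = 1.0

LINKS = ("logit", "probit")


class DomainError(ValueError):
    """Raised when an argument lies outside the model's domain."""


class UndefinedDifficultyError(DomainError):
    """Raised when a zero loading makes the IRT difficulty undefined."""


def _check_link(link: str) -> str:
    if link not in LINKS:
        raise DomainError(f"unknown link {link!r}; expected one of {LINKS}")
    return link


def _finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} must be finite, got {value!r}")
    return arr


def link_cdf(z, link: str = "logit"):
    """CDF of the link distribution (standard logistic or standard normal)."""
    _check_link(link)
    z = np.asarray(z, dtype=float)
    out = expit(z) if link == "logit" else ndtr(z)
    return float(out) if out.ndim == 0 else out


def item_response_prob(a, b, eta, link: str = "logit"):
    """P(y = 1 | eta) on the IRT metric: F(a * (eta - b)).

    Strictly increasing in ``eta`` when ``a > 0``; equals 0.5 at
    ``eta = b`` for every finite discrimination.
    """
    a = _finite("discrimination a", a)
    b = _finite("difficulty b", b)
    eta = _finite("ability eta", eta)
    return link_cdf(a * (eta - b), link)


def threshold_model_prob(lam, tau, eta, link: str = "logit"):
    """P(y = 1 | eta) on the factor metric: F(lambda * eta - tau).

    This is P(lambda*eta + epsilon > tau) with the link's standardized
    residual, and coincides with :func:`item_response_prob` evaluated at
    ``a = lambda, b = tau/lambda`` whenever ``lambda != 0``.
    """
    lam = _finite("loading lambda", lam)
    tau = _finite("threshold tau", tau)
    eta = _finite("ability eta", eta)
    return link_cdf(lam * eta - tau, link)


@dataclass(frozen=True)
class ItemParamsFactor:
    """Item parameters on the factor metric: loading and threshold.

    A loading of exactly zero is representable (optimizers may visit it)
    but is flagged via :attr:`degenerate`; converting it to the IRT metric
    raises, since the difficulty divides by the loading.
    """

    loading: float
    threshold: float
    link: str = "logit"
    item: Optional[str] = None
    group: Optional[str] = None

    def __post_init__(self):
        _finite("loading", self.loading)
        _finite("threshold", self.threshold)
        _check_link(self.link)

    @property
    def degenerate(self) -> bool:
        """True when the loading is exactly zero (IRT difficulty undefined)."""
        return self.loading == 0.0

    @property
    def residual_variance(self) -> float:
        return LOGIT_RESIDUAL_VARIANCE if self.link == "logit" else PROBIT_RESIDUAL_VARIANCE

    def prob(self, eta):
        return threshold_model_prob(self.loading, self.threshold, eta, self.link)


@dataclass(frozen=True)
class ItemParamsIRT:
    """Item parameters on the IRT metric: discrimination and difficulty."""

    discrimination: float
    difficulty: float
    link: str = "logit"
    item: Optional[str] = None
    group: Optional[str] = None

    def __post_init__(self):
        _finite("discrimination", self.discrimination)
        _finite("difficulty", self.difficulty)
        _check_link(self.link)

    def prob(self, eta):
        return item_response_prob(self.discrimination, self.difficulty, eta, self.link)


@dataclass(frozen=True)
class GroupDistribution:
    """Latent ability distribution N(mean, variance) of one group."""

    mean: float
    variance: float
    label: Optional[str] = None

    def __post_init__(self):
        _finite("mean", self.mean)
        _finite("variance", self.variance)
        if self.variance <= 0.0:
            raise DomainError(
                f"factor variance must be strictly positive, got {self.variance}"
            )


def factor_to_irt(params: ItemParamsFactor) -> ItemParamsIRT:
    """Convert factor-metric parameters to the IRT metric.

    ``a = lambda`` and ``b = tau / lambda``; raises
    :class:`UndefinedDifficultyError` for a zero loading.
    """
    if params.loading == 0.0:
        raise UndefinedDifficultyError(
            "difficulty b = tau/lambda is undefined for zero loading "
            f"(item={params.item!r}, group={params.group!r})"
        )
    return ItemParamsIRT(
        discrimination=params.loading,
        difficulty=params.threshold / params.loading,
        link=params.link,
        item=params.item,
        group=params.group,
    )


def irt_to_factor(params: ItemParamsIRT) -> ItemParamsFactor:
    """Convert IRT-metric parameters to the factor metric.

    ``lambda = a`` and ``tau = a * b``; a round trip with
    :func:`factor_to_irt` is the identity whenever ``a != 0``.
    """
    return ItemParamsFactor(
        loading=params.discrimination,
        threshold=params.discrimination * params.difficulty,
        link=params.link,
        item=params.item,
        group=params.group,
    )
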