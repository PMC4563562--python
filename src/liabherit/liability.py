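"""Liability-threshold scale transformations and familial recurrence risk.

A binary disease with lifetime risk K is modelled as the exceedance of
a standard-normal liability over ``t = Phi^-1(1 - K)``. Heritability
estimated on the observed 0/1 scale in an ascertained case-control
sample (case fraction P) converts to the liability scale as

    h2_liab = h2_obs * K^2 (1-K)^2 / (z^2 P (1-P)),

with ``z`` the normal density at the threshold. Under the additive
model, relatives of a case have liability correlated ``r = a * h2``
(``a`` = 0.5 for full siblings or parent-offspring), giving a
recurrence risk ratio ``lambda = P(l2 > t | l1 > t) / K`` from the
bivariate-normal tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .errors import InvalidInputError, NumericalError


@dataclass
class LiabilityContext:
    """Lifetime risk, sample case fraction, and derived threshold terms.

    ``t`` and ``z`` are always derived from K on access, never stored.
    """

    K: float
    P: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.K < 1.0:
            raise InvalidInputError("K must be in (0, 1)")
        if self.P is None:
            self.P = self.K
        if not 0.0 <= self.P <= 1.0:
            raise InvalidInputError("P must be in [0, 1]")

    @property
    def t(self) -> float:
        return float(stats.norm.ppf(1.0 - self.K))

    @property
    def z(self) -> float:
        return float(stats.norm.pdf(self.t))

    @property
    def obs_to_liab_factor(self) -> float:
        """Multiplier taking observed-scale h2 to the liability scale."""
        if self.P in (0.0, 1.0):
            raise InvalidInputError("P must be strictly inside (0, 1)")
        K, P, z = self.K, self.P, self.z
        return K**2 * (1.0 - K) ** 2 / (z**2 * P * (1.0 - P))


def obs_to_liability(h2_obs: float, ctx: LiabilityContext) -> float:
    """Observed-scale heritability to the liability scale.

    With P = K the factor reduces to the unascertained closed form
    ``K(1-K)/z^2``. The same factor applies to standard errors.
    """
    if not 0.0 <= h2_obs <= 1.0:
        raise InvalidInputError("h2_obs must be in [0, 1]")
    return h2_obs * ctx.obs_to_liab_factor


def liability_to_obs(h2_liab: float, ctx: LiabilityContext) -> float:
    """Inverse of :func:`obs_to_liability`."""
    return h2_liab / ctx.obs_to_liab_factor


def sibling_rr(
    h2_liab: float,
    ctx: LiabilityContext,
    relatedness_a: float = 0.5,
) -> float:
    """Recurrence risk ratio for a relative class under the liability model.

    ``lambda = P(l2 > t | l1 > t) / K`` with ``(l1, l2)`` standard
    bivariate normal of correlation ``r = relatedness_a * h2_liab``.
    The joint tail is evaluated by adaptive quadrature of the
    conditional normal tail over the proband's liability.
    """
    if not 0.0 <= h2_liab <= 1.0:
        raise InvalidInputError("h2_liab must be in [0, 1]")
    if not 0.0 < relatedness_a <= 1.0:
        raise InvalidInputError("relatedness_a must be in (0, 1]")
    r = relatedness_a * h2_liab
    K, t = ctx.K, ctx.t
    if r == 0.0:
        return 1.0
    if r >= 1.0:
        return 1.0 / K
    s = np.sqrt(1.0 - r * r)

    def integrand(x: float) -> float:
        return stats.norm.pdf(x) * stats.norm.sf((t - r * x) / s)

    joint, err = integrate.quad(integrand, t, np.inf, epsabs=1e-13, epsrel=1e-10)
    if not np.isfinite(joint) or (joint > 0 and err / joint > 1e-6):
        raise NumericalError(
            f"tail integration did not converge (value={joint!r}, abs err={err!r})"
        )
    return float(joint / (K * K))


def excess_familial_share(lambda_genetic: float, lambda_observed: float) -> float:
    """Share of the excess familial risk attributable to genetics.

    Default definition ``(lambda_genetic - 1) / (lambda_observed - 1)``
    (excess-risk ratio); other decompositions of familial risk exist
    and can give different shares, so outputs should be labelled with
    this definition.
    """
    if lambda_observed <= 1.0:
        raise InvalidInputError("lambda_observed must exceed 1")
    if lambda_genetic < 1.0:
        raise InvalidInputError("lambda_genetic must be >= 1")
    return (lambda_genetic - 1.0) / (lambda_observed - 1.0)
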