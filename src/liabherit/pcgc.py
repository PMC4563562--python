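"""Phenotype-correlation genotype-correlation (PCGC) regression.

A Haseman-Elston-type estimator: standardized phenotype products of
all sample pairs are regressed through the origin on the corresponding
GRM entries, and the slope is carried to the liability scale by the
same ascertainment constant as the observed-scale REML estimate. It
avoids the scale-conversion bias REML can incur on ascertained binary
traits, and serves here as the cross-check estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .grm import Grm
from .liability import LiabilityContext


@dataclass
class PcgcFit:
    """Origin regression of pairwise phenotype products on GRM entries."""

    slope: float
    h2_liab: float
    se: float
    n_pairs: int


def fit_pcgc(y: np.ndarray, grm: Grm, ctx: LiabilityContext) -> PcgcFit:
    """PCGC estimate of liability-scale heritability.

    ``y`` is standardized to ``(y - P)/sqrt(P(1-P))`` with P the sample
    case fraction; the slope over all off-diagonal pairs transforms by
    ``K^2(1-K)^2 / (z^2 P(1-P))``. The standard error is a
    delete-one-sample jackknife on the transformed estimate.
    """
    y = np.asarray(y).astype(float)
    n = y.size
    if grm.n != n:
        raise InvalidInputError("GRM not aligned with phenotype vector")
    P = float(y.mean())
    if P in (0.0, 1.0):
        raise InvalidInputError("phenotype is constant")
    ystar = (y - P) / np.sqrt(P * (1.0 - P))

    A = grm.values
    # off-diagonal sums via full-matrix identities
    Ay = A @ ystar
    full_num = float(ystar @ Ay) - float(np.diag(A) @ ystar**2)
    A2_rows = (A**2).sum(axis=1) - np.diag(A) ** 2
    full_den = float(A2_rows.sum())
    if full_den == 0.0:
        slope = 0.0
    else:
        slope = full_num / full_den

    factor = LiabilityContext(ctx.K, P).obs_to_liab_factor
    h2 = slope * factor

    # delete-one jackknife: remove sample i's row contributions
    num_i = ystar * (Ay - np.diag(A) * ystar)  # sum over j != i of y*i y*j Aij
    den_i = A2_rows
    theta = np.empty(n)
    for i in range(n):
        d = full_den - 2.0 * den_i[i]
        theta[i] = ((full_num - 2.0 * num_i[i]) / d if d != 0 else 0.0) * factor
    se = float(np.sqrt((n - 1) / n * np.sum((theta - theta.mean()) ** 2)))

    n_pairs = n * (n - 1) // 2
    return PcgcFit(float(slope), float(h2), se, n_pairs)
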