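"""Restricted maximum likelihood variance-component estimation (GREML).

Fits ``y ~ N(X beta, sum_c sigma2_c A_c + sigma2_e I)`` by
average-information (AI) REML with expectation-maximization fallback
steps, for one or many genetic relationship matrices. With a single
GRM the model is rotated into the GRM eigenbasis, where every
iteration costs O(n p^2) after one eigendecomposition; the multi-GRM
path uses dense Cholesky algebra. Standard errors come from the
inverse of the AI matrix at the optimum.

A binary 0/1 phenotype fitted this way yields an observed-scale
heritability; see :mod:`liabherit.liability` for conversion to the
liability scale with ascertainment correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .errors import InvalidInputError, NumericalError
from .grm import Grm

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class VarianceComponentFit:
    """REML estimates for one or more genetic variance components.

    ``sigma2`` holds the per-GRM components, ``sigma2_e`` the residual;
    ``se`` covers components then residual. ``h2_obs`` is per-component
    sigma2_c / total phenotypic variance, with delta-method SEs.
    """

    sigma2: np.ndarray
    sigma2_e: float
    se: np.ndarray
    loglik: float
    h2_obs: np.ndarray
    h2_obs_total: float
    h2_se: np.ndarray
    h2_total_se: float
    n_iter: int
    converged: bool
    identifiable: bool = True
    message: str = ""
    component_labels: list[str] = field(default_factory=list)
    ai_matrix: np.ndarray | None = None

    @property
    def phenotypic_variance(self) -> float:
        return float(self.sigma2.sum() + self.sigma2_e)


# ---------------------------------------------------------------------------
# REML statistics kernels
# ---------------------------------------------------------------------------


class _DenseKernel:
    """Loglik / score / AI statistics with explicit n x n covariances."""

    def __init__(self, y: np.ndarray, X: np.ndarray, mats: list[np.ndarray]):
        self.y, self.X, self.mats = y, X, mats
        self.n, self.p = X.shape

    def stats(self, sig: np.ndarray):
        V = sum(s * M for s, M in zip(sig, self.mats))
        try:
            c, low = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return None
        logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
        W = cho_solve((c, low), self.X)  # V^-1 X
        B = self.X.T @ W
        sgn, logdet_B = np.linalg.slogdet(B)
        if sgn <= 0:
            return None
        Binv = np.linalg.inv(B)
        Vy = cho_solve((c, low), self.y)
        Py = Vy - W @ (Binv @ (self.X.T @ Vy))

        k = len(self.mats)
        trPM = np.empty(k)
        q = []
        for ci, M in enumerate(self.mats):
            T = cho_solve((c, low), M)
            trPM[ci] = np.trace(T) - np.trace(Binv @ (W.T @ (M @ W)))
            q.append(M @ Py)
        yPMPy = np.array([Py @ qc for qc in q])

        Pq = []
        for qc in q:
            Vq = cho_solve((c, low), qc)
            Pq.append(Vq - W @ (Binv @ (self.X.T @ Vq)))
        AI = 0.5 * np.array([[q[a] @ Pq[b] for b in range(k)] for a in range(k)])
        AI = 0.5 * (AI + AI.T)

        yPy = float(self.y @ Py)
        ll = -0.5 * ((self.n - self.p) * _LOG2PI + logdet_V + logdet_B + yPy)
        score = -0.5 * (trPM - yPMPy)
        return ll, score, AI, trPM, yPMPy


class _EigenKernel:
    """Same statistics for diagonal covariances (single-GRM eigenbasis)."""

    def __init__(self, y: np.ndarray, X: np.ndarray, diags: list[np.ndarray]):
        self.y, self.X, self.diags = y, X, diags
        self.n, self.p = X.shape

    def stats(self, sig: np.ndarray):
        D = sum(s * d for s, d in zip(sig, self.diags))
        if np.any(D <= 0):
            return None
        Dinv = 1.0 / D
        W = self.X * Dinv[:, None]  # D^-1 X
        B = self.X.T @ W
        sgn, logdet_B = np.linalg.slogdet(B)
        if sgn <= 0:
            return None
        Binv = np.linalg.inv(B)

        def apply_P(v: np.ndarray) -> np.ndarray:
            return Dinv * v - W @ (Binv @ (W.T @ v))

        Py = apply_P(self.y)
        k = len(self.diags)
        trPM = np.empty(k)
        q = []
        for ci, d in enumerate(self.diags):
            trPM[ci] = np.sum(d * Dinv) - np.trace(Binv @ (W.T @ (d[:, None] * W)))
            q.append(d * Py)
        yPMPy = np.array([Py @ qc for qc in q])
        Pq = [apply_P(qc) for qc in q]
        AI = 0.5 * np.array([[q[a] @ Pq[b] for b in range(k)] for a in range(k)])
        AI = 0.5 * (AI + AI.T)

        ll = -0.5 * (
            (self.n - self.p) * _LOG2PI
            + float(np.sum(np.log(D)))
            + logdet_B
            + float(self.y @ Py)
        )
        score = -0.5 * (trPM - yPMPy)
        return ll, score, AI, trPM, yPMPy


# ---------------------------------------------------------------------------
# optimization loop
# ---------------------------------------------------------------------------


def _em_update(sig, trPM, yPMPy, n):
    return sig + sig**2 * (yPMPy - trPM) / n


def _run_reml(kernel, sig0, *, tol, max_iter, method, floor):
    sig = np.maximum(np.asarray(sig0, dtype=float), floor)
    res = kernel.stats(sig)
    if res is None:
        raise NumericalError("covariance matrix singular at starting values")
    ll, score, AI, trPM, yPMPy = res
    converged = False
    n_iter = 0
    message = ""
    for n_iter in range(1, max_iter + 1):
        if method == "em" or n_iter == 1:
            prop = _em_update(sig, trPM, yPMPy, kernel.n)
        else:
            # active-set AI step: components pinned at the floor whose
            # score still points below it stay fixed this iteration
            free = (sig > floor * (1 + 1e-6)) | (score > 0)
            prop = sig.copy()
            try:
                if free.any():
                    step = np.linalg.solve(AI[np.ix_(free, free)], score[free])
                    prop[free] = sig[free] + step
                else:
                    prop = _em_update(sig, trPM, yPMPy, kernel.n)
            except np.linalg.LinAlgError:
                prop = _em_update(sig, trPM, yPMPy, kernel.n)
        prop = np.maximum(prop, floor)

        # step-halve toward the current point if the step is invalid/worse
        accepted = None
        step = prop - sig
        for _ in range(12):
            cand = np.maximum(sig + step, floor)
            res = kernel.stats(cand)
            if res is not None and np.isfinite(res[0]) and res[0] >= ll - 1e-10:
                accepted = (cand, res)
                break
            step *= 0.5
        if accepted is None:
            # fall back to a damped EM step, which cannot diverge far
            cand = np.maximum(_em_update(sig, trPM, yPMPy, kernel.n), floor)
            res = kernel.stats(cand)
            if res is None:
                message = "no admissible step found"
                break
            accepted = (cand, res)

        new_sig, (new_ll, score, AI, trPM, yPMPy) = accepted
        delta = new_ll - ll
        sig, ll = new_sig, new_ll
        if abs(delta) < tol:
            converged = True
            break
    return sig, ll, AI, n_iter, converged, message


def _as_matrix(g) -> np.ndarray:
    return g.values if isinstance(g, Grm) else np.asarray(g, dtype=float)


def _labels(grms) -> list[str]:
    out = []
    for i, g in enumerate(grms):
        out.append(g.snp_subset if isinstance(g, Grm) else f"component{i + 1}")
    return out


def restricted_loglik(y, X, grms, sigma2, sigma2_e) -> float:
    """Restricted log-likelihood at fixed variance components.

    Direct definition: ``-1/2 [(n-p) log 2pi + log|V| + log|X'V^-1X| +
    y'Py]`` with ``V = sum_c sigma2_c A_c + sigma2_e I``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mats = [_as_matrix(g) for g in grms] + [np.eye(y.size)]
    kern = _DenseKernel(y, X, mats)
    res = kern.stats(np.append(np.asarray(sigma2, dtype=float), sigma2_e))
    if res is None:
        raise NumericalError("singular covariance at the requested parameters")
    return float(res[0])


def fit_reml(
    y,
    X=None,
    grms=(),
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
    method: str = "ai",
    diagonal_floor_frac: float = 1e-8,
    start: np.ndarray | None = None,
) -> VarianceComponentFit:
    """AI-REML fit of genetic variance components.

    Parameters
    ----------
    y
        Phenotype vector (quantitative, or 0/1 case-control entered
        directly on the observed scale).
    X
        Fixed-effect design including the intercept; default
        intercept-only.
    grms
        One or more :class:`~liabherit.grm.Grm` (or raw matrices) with
        sample order matching ``y``.
    method
        ``"ai"`` (AI updates with EM fallback, default) or ``"em"``.

    Non-convergence is reported via ``converged=False`` on the result,
    not an exception. A near-singular AI matrix (confounded
    components, e.g. an identity GRM) sets ``identifiable=False``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        raise InvalidInputError("X not aligned with y")
    grms = list(grms)
    if not grms:
        raise InvalidInputError("need at least one GRM")
    for g in grms:
        if isinstance(g, Grm) and g.n != n:
            raise InvalidInputError("GRM dimension does not match phenotype length")
    k = len(grms)
    vp = float(np.var(y))
    if vp == 0:
        raise InvalidInputError("phenotype has zero variance")
    floor = diagonal_floor_frac * vp
    sig0 = np.full(k + 1, vp / (k + 1)) if start is None else np.asarray(start, float)

    if k == 1:
        A = _as_matrix(grms[0])
        lam, U = np.linalg.eigh(A)
        kern = _EigenKernel(U.T @ y, U.T @ X, [lam, np.ones(n)])
    else:
        mats = [_as_matrix(g) for g in grms] + [np.eye(n)]
        kern = _DenseKernel(y, X, mats)

    sig, ll, AI, n_iter, converged, message = _run_reml(
        kern, sig0, tol=tol, max_iter=max_iter, method=method, floor=floor
    )

    identifiable = True
    try:
        cov = np.linalg.inv(AI)
        cond = np.linalg.cond(AI)
        if not np.isfinite(cond) or cond > 1e10:
            identifiable = False
            message = message or "AI matrix near-singular: components confounded"
    except np.linalg.LinAlgError:
        cov = np.full((k + 1, k + 1), np.nan)
        identifiable = False
        message = message or "AI matrix singular"
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    total = float(sig.sum())
    h2 = sig[:k] / total
    # delta method for h2_c = sigma_c / sum(sigma)
    h2_se = np.empty(k)
    for ci in range(k):
        grad = np.full(k + 1, -sig[ci] / total**2)
        grad[ci] += 1.0 / total
        h2_se[ci] = np.sqrt(max(0.0, grad @ cov @ grad))
    grad_tot = np.empty(k + 1)
    grad_tot[:k] = (total - sig[:k].sum()) / total**2
    grad_tot[k] = -sig[:k].sum() / total**2
    h2_total_se = float(np.sqrt(max(0.0, grad_tot @ cov @ grad_tot)))

    return VarianceComponentFit(
        sigma2=sig[:k].copy(),
        sigma2_e=float(sig[k]),
        se=se,
        loglik=float(ll),
        h2_obs=h2,
        h2_obs_total=float(h2.sum()),
        h2_se=h2_se,
        h2_total_se=h2_total_se,
        n_iter=n_iter,
        converged=converged,
        identifiable=identifiable,
        message=message,
        component_labels=_labels(grms),
        ai_matrix=AI,
    )


# ---------------------------------------------------------------------------
# joint per-chromosome fitting and per-SNP attribution
# ---------------------------------------------------------------------------


@dataclass
class JointChromosomeFit:
    """Simultaneous per-chromosome fit plus the whole-set single-GRM fit.

    The per-component total and the pooled single-GRM estimate need not
    agree exactly; both are reported, labelled.
    """

    joint: VarianceComponentFit
    whole: VarianceComponentFit

    @property
    def per_chromosome_h2(self) -> dict[str, float]:
        return dict(zip(self.joint.component_labels, self.joint.h2_obs))

    @property
    def total_h2_sum(self) -> float:
        return self.joint.h2_obs_total

    @property
    def total_h2_whole(self) -> float:
        return self.whole.h2_obs_total


def pool_grms(grms: list[Grm]) -> Grm:
    """SNP-count-weighted elementwise pool of per-chromosome GRMs.

    Equals the whole-set GRM computed from the union of SNPs (up to the
    diagonal convention), because each entry is a per-pair mean over
    its own SNP count.
    """
    num = sum(g.n_snps_pairwise * g.values for g in grms)
    den = sum(g.n_snps_pairwise for g in grms)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(den > 0, num / den, 0.0)
    return Grm(pooled, list(grms[0].sample_ids), den, "pooled")


def fit_joint_chromosomes(y, X, per_chr_grms, **opts) -> JointChromosomeFit:
    """Fit one variance component per chromosome, simultaneously.

    Also fits the pooled whole-set GRM as a single component for
    comparison with the per-chromosome total.
    """
    if len(per_chr_grms) < 2:
        raise InvalidInputError("need at least 2 per-chromosome GRMs")
    joint = fit_reml(y, X, per_chr_grms, **opts)
    whole = fit_reml(y, X, [pool_grms(per_chr_grms)], **opts)
    return JointChromosomeFit(joint, whole)


def _standardize_snp(dosage: np.ndarray) -> np.ndarray:
    x = np.asarray(dosage, dtype=float)
    mu = np.nanmean(x)
    x = np.where(np.isnan(x), mu, x)
    sd = x.std()
    if sd == 0:
        raise InvalidInputError("SNP covariate is monomorphic (zero variance)")
    return (x - mu) / sd


def per_snp_variance(
    y, X, per_chr_grms, snp_dosage, snp_chr: str, **opts
) -> float:
    """Variance attributed to one SNP by covariate-difference attribution.

    Fits the joint per-chromosome model with and without the SNP dosage
    appended to the fixed effects and returns the drop in that
    chromosome's observed-scale h2. ``snp_chr`` must match a component
    label (e.g. ``"chr3"``).
    """
    grms = list(per_chr_grms)
    labels = _labels(grms)
    if snp_chr not in labels:
        raise InvalidInputError(
            f"chromosome label {snp_chr!r} not among components {labels}"
        )
    ci = labels.index(snp_chr)
    y = np.asarray(y, dtype=float)
    if X is None:
        X = np.ones((y.size, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    z = _standardize_snp(snp_dosage)
    # drop the SNP column if it is already (collinearly) present in X
    resid = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
    if resid.std() < 1e-10:
        X_with = X
    else:
        X_with = np.column_stack([X, z])
    without = fit_reml(y, X, grms, **opts)
    with_ = fit_reml(y, X_with, grms, **opts)
    return float(without.h2_obs[ci] - with_.h2_obs[ci])


def per_snp_variance_batch(
    y, X, per_chr_grms, snp_dosages: np.ndarray, snp_chrs: list[str], **opts
) -> list[float]:
    """Covariate-difference attribution for a list of SNPs (columns)."""
    return [
        per_snp_variance(y, X, per_chr_grms, snp_dosages[:, j], snp_chrs[j], **opts)
        for j in range(len(snp_chrs))
    ]


def stratified_fit(
    y,
    subtype_labels,
    which: str,
    grm: Grm,
    X=None,
    **opts,
) -> VarianceComponentFit:
    """Single-GRM fit on cases of one subtype plus all controls.

    Cases of other subtypes (including unlabelled, e.g. mixed or
    indeterminate histology) are excluded; the GRM is subset to the
    retained samples.
    """
    y = np.asarray(y).astype(int)
    labels = np.asarray(subtype_labels, dtype=object)
    keep = (y == 0) | ((y == 1) & (labels == which))
    if not ((y == 1) & (labels == which)).any():
        raise InvalidInputError(f"no cases with subtype {which!r}")
    idx = np.flatnonzero(keep)
    sub = Grm(
        grm.values[np.ix_(idx, idx)],
        [grm.sample_ids[i] for i in idx],
        grm.n_snps_pairwise[np.ix_(idx, idx)],
        grm.snp_subset,
    )
    Xs = None if X is None else np.atleast_2d(np.asarray(X, dtype=float))[idx]
    return fit_reml(y[idx].astype(float), Xs, [sub], **opts)
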