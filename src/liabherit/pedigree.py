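"""Pedigrees, the numerator relationship matrix, and the Bayesian
liability-threshold animal model.

The population track of the package models a binary trait as a
thresholded latent liability ``l = X beta + u + e`` with ``u ~ N(0, A
sigma2_a)``, where ``A`` is the pedigree numerator relationship matrix,
and ``e ~ N(0, I)`` (probit residual fixed at 1 for identifiability).
``fit_threshold_animal_model`` samples the posterior by Gibbs sampling
with truncated-normal data augmentation; heritability per retained
round is ``h2 = sigma2_a / (sigma2_a + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    InvalidConfigError,
    InvalidInputError,
    NumericalError,
    PedigreeIntegrityError,
)

UNKNOWN = "0"


# ---------------------------------------------------------------------------
# Pedigree container
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """A set of individuals with parent references.

    ``table`` columns: ``id, father, mother, sex`` (sex 1 = male,
    2 = female, 0 = unknown), optional extras (``family``,
    ``generation`` ...). ``"0"`` (or None/NaN) marks an unknown parent.
    Construction validates referential integrity and acyclicity and
    stores a topological order (parents before offspring).
    """

    table: pd.DataFrame
    _order: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = self.table.copy().reset_index(drop=True)
        for col in ("id", "father", "mother"):
            if col not in t.columns:
                raise InvalidInputError(f"pedigree table lacks column {col!r}")
            t[col] = (
                t[col]
                .astype(object)
                .where(t[col].notna(), UNKNOWN)
                .astype(str)
            )
        if "sex" not in t.columns:
            t["sex"] = 0
        ids = t["id"].tolist()
        if len(set(ids)) != len(ids):
            raise PedigreeIntegrityError("duplicate individual ids in pedigree")
        self.table = t
        self._order = self._toposort()

    # -- helpers -----------------------------------------------------------

    def _index(self) -> dict[str, int]:
        return {iid: i for i, iid in enumerate(self.table["id"])}

    def parent_indices(self) -> np.ndarray:
        """``(n, 2)`` integer array of (father, mother) indices, -1 unknown."""
        idx = self._index()
        out = np.full((len(self.table), 2), -1, dtype=np.int64)
        for i, (f, m) in enumerate(zip(self.table["father"], self.table["mother"])):
            for k, parent in enumerate((f, m)):
                if parent != UNKNOWN:
                    if parent not in idx:
                        raise PedigreeIntegrityError(
                            f"parent {parent!r} of {self.table['id'][i]!r} "
                            "is not in the pedigree"
                        )
                    out[i, k] = idx[parent]
        return out

    def _toposort(self) -> np.ndarray:
        """Kahn topological order (parents first); raises on cycles."""
        parents = self.parent_indices()
        n = len(parents)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for i in range(n):
            for p in parents[i]:
                if p >= 0:
                    if p == i:
                        raise PedigreeIntegrityError(
                            f"{self.table['id'][i]!r} is its own parent"
                        )
                    children[p].append(i)
                    indeg[i] += 1
        queue = [i for i in range(n) if indeg[i] == 0]
        order = []
        while queue:
            i = queue.pop()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != n:
            raise PedigreeIntegrityError("cyclic parentage (individual is its own ancestor)")
        return np.asarray(order, dtype=np.int64)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def topological_order(self) -> np.ndarray:
        """Indices into ``table`` with every parent before its offspring."""
        return self._order.copy()

    def is_founder(self) -> np.ndarray:
        p = self.parent_indices()
        return (p[:, 0] < 0) & (p[:, 1] < 0)

    # -- IO ---------------------------------------------------------------

    @classmethod
    def read_tsv(cls, path) -> "Pedigree":
        """Read a LINKAGE-style TSV: id, father, mother, sex[, status...]."""
        t = pd.read_csv(path, sep="\t", dtype=str)
        if "sex" in t.columns:
            t["sex"] = pd.to_numeric(t["sex"], errors="coerce").fillna(0).astype(int)
        return cls(t)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Numerator relationship matrix
# ---------------------------------------------------------------------------


@dataclass
class Nrm:
    """Pedigree-expected additive relationship matrix (twice the kinship).

    ``values`` is ordered like ``ids`` (a topological order of the source
    pedigree); ``inbreeding`` holds F_i = A_ii - 1.
    """

    values: np.ndarray
    ids: list[str]

    @property
    def inbreeding(self) -> np.ndarray:
        return np.diag(self.values) - 1.0


def build_nrm(ped: Pedigree) -> Nrm:
    """Numerator relationship matrix by the tabular (Henderson) recursion.

    After sorting parents-before-offspring: ``A_ii = 1 + A_fm / 2`` and
    ``A_ij = (A_jf + A_jm) / 2`` for earlier j, with unknown parents
    contributing zero.
    """
    order = ped.topological_order()
    parents = ped.parent_indices()
    n = len(ped)
    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(n)
    A = np.zeros((n, n))
    for k, i in enumerate(order):
        f, m = parents[i]
        fp = pos[f] if f >= 0 else -1
        mp = pos[m] if m >= 0 else -1
        A[k, k] = 1.0 + (0.5 * A[fp, mp] if fp >= 0 and mp >= 0 else 0.0)
        if k:
            row = np.zeros(k)
            if fp >= 0:
                row += A[:k, fp]
            if mp >= 0:
                row += A[:k, mp]
            row *= 0.5
            A[k, :k] = row
            A[:k, k] = row
    ids = [ped.ids[i] for i in order]
    return Nrm(A, ids)


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficient F per individual, in ``ped.table`` order."""
    nrm = build_nrm(ped)
    pos = {iid: k for k, iid in enumerate(nrm.ids)}
    return np.array([nrm.values[pos[i], pos[i]] - 1.0 for i in ped.ids])


def nrm_inverse_sparse(ped: Pedigree):
    """Sparse inverse of the NRM by Henderson's rules.

    Returns ``(indptr, indices, data, order)`` in CSR layout over
    individuals in topological order; ``order`` maps CSR position ->
    row index of ``ped.table``. The Mendelian-sampling variance uses the
    exact parental inbreeding coefficients.
    """
    from scipy import sparse

    order = ped.topological_order()
    parents = ped.parent_indices()
    n = len(ped)
    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(n)
    F = inbreeding_coefficients(ped)

    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)
        if i != j:
            rows.append(j)
            cols.append(i)
            vals.append(v)

    for k, i in enumerate(order):
        f, m = parents[i]
        if f >= 0 and m >= 0:
            d = 0.5 - 0.25 * (F[f] + F[m])
        elif f >= 0 or m >= 0:
            known = f if f >= 0 else m
            d = 0.75 - 0.25 * F[known]
        else:
            d = 1.0
        alpha = 1.0 / d
        add(k, k, alpha)
        for p in (f, m):
            if p >= 0:
                add(k, pos[p], -0.5 * alpha)
        kp = [pos[p] for p in (f, m) if p >= 0]
        for a in range(len(kp)):
            for b in range(a, len(kp)):
                add(kp[a], kp[b], 0.25 * alpha)
    M = sparse.csr_matrix(
        (np.asarray(vals), (np.asarray(rows), np.asarray(cols))), shape=(n, n)
    )
    M.sum_duplicates()
    return M.indptr, M.indices.astype(np.int64), M.data, order


# ---------------------------------------------------------------------------
# Fixed-effect design
# ---------------------------------------------------------------------------


def fixed_effect_covariates(table: pd.DataFrame, names: list[str]) -> np.ndarray:
    """Design matrix from named covariate columns.

    Numeric columns are standardized to mean 0 / SD 1; categorical
    (object or category dtype) columns are one-hot encoded with the
    first level dropped. An intercept column of ones is always first.
    """
    cols = [np.ones(len(table))]
    for name in names:
        if name not in table.columns:
            raise InvalidInputError(f"covariate column {name!r} not found")
        col = table[name]
        if pd.api.types.is_numeric_dtype(col):
            v = col.to_numpy(dtype=float)
            sd = v.std()
            cols.append((v - v.mean()) / (sd if sd > 0 else 1.0))
        else:
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy())
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


@dataclass
class ChainConfig:
    """MCMC settings for the threshold animal model.

    Defaults follow registry-scale practice: 1.1M rounds, 100k burn-in,
    thinning 1,000 (1,000 retained samples); tests scale these down.
    ``prior_df``/``prior_scale`` parameterize the scaled-inverse-chi-square
    prior on the additive variance.
    """

    n_rounds: int = 1_100_000
    burn_in: int = 100_000
    thin: int = 1_000
    seed: int = 0
    prior_df: float = 1.0
    prior_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_rounds:
            raise InvalidConfigError("burn_in must be smaller than n_rounds")
        if self.thin < 1 or (self.n_rounds - self.burn_in) % self.thin:
            raise InvalidConfigError(
                "(n_rounds - burn_in) must be a positive multiple of thin"
            )
        if self.prior_scale <= 0 or self.prior_df <= 0:
            raise InvalidConfigError("prior_df and prior_scale must be positive")

    @property
    def n_samples(self) -> int:
        return (self.n_rounds - self.burn_in) // self.thin


@dataclass
class PosteriorChain:
    """Thinned posterior samples of sigma2_a and derived h2."""

    sigma2_a: np.ndarray
    h2: np.ndarray
    kept_rounds: np.ndarray
    config: ChainConfig

    def summary(self) -> dict:
        lo, hi = np.quantile(self.h2, [0.025, 0.975])
        return {
            "h2_mean": float(self.h2.mean()),
            "h2_ci95": (float(lo), float(hi)),
            "sigma2_a_mean": float(self.sigma2_a.mean()),
            "n_samples": int(self.h2.size),
            "ess": float(effective_sample_size(self.h2)),
            "geweke_z": float(geweke_z(self.h2)),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"round": self.kept_rounds, "sigma2_a": self.sigma2_a, "h2": self.h2}
        )


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the initial-positive-sequence autocorrelation sum."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or x.std() == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * x.var())
    s = 1.0
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k] if 2 * k < n else 0.0
        if pair <= 0:
            break
        s += 2.0 * pair
    return float(n / s)


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain means."""
    x = np.asarray(x, dtype=float)
    a = x[: max(2, int(first * x.size))]
    b = x[-max(2, int(last * x.size)) :]
    va = a.var(ddof=1) / effective_sample_size(a)
    vb = b.var(ddof=1) / effective_sample_size(b)
    denom = np.sqrt(va + vb)
    return float((a.mean() - b.mean()) / denom) if denom > 0 else 0.0


def fit_threshold_animal_model(
    ped: Pedigree,
    y: np.ndarray,
    X: np.ndarray | None,
    cfg: ChainConfig,
    observed: np.ndarray | None = None,
) -> PosteriorChain:
    """Posterior of the additive variance under the probit animal model.

    Gibbs sweep per round: (1) latent liabilities from truncated-normal
    full conditionals (side set by the binary response, threshold 0,
    intercept absorbing it); (2) fixed effects from their Gaussian full
    conditional (flat prior); (3) breeding values single-site from the
    mixed-model full conditional using the sparse NRM inverse; (4)
    sigma2_a from its scaled-inverse-chi-square full conditional.
    Residual variance is fixed at 1.

    Parameters
    ----------
    y
        Binary response (0/1) aligned to ``ped.table`` rows.
    X
        Fixed-effect design (with intercept); ``None`` for intercept-only.
    observed
        Optional boolean mask of individuals contributing a phenotype
        record; others are treated as relationship-only members.
    """
    from ._gibbs import run_gibbs

    n = len(ped)
    y = np.asarray(y, dtype=np.int8)
    if y.shape[0] != n:
        raise InvalidInputError("phenotype vector not aligned to pedigree")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] != n:
        raise InvalidInputError("covariate matrix not aligned to pedigree")
    if observed is None:
        observed = np.ones(n, dtype=bool)
    observed = np.asarray(observed, dtype=bool)
    if not observed.any():
        raise InvalidInputError("no observed phenotypes")

    indptr, indices, data, order = nrm_inverse_sparse(ped)
    # reorder everything into topological order used by the CSR matrix
    y_o = y[order]
    X_o = X[order]
    obs_o = observed[order].astype(np.int8)

    Xobs = X_o[obs_o.astype(bool)]
    XtX = Xobs.T @ Xobs
    try:
        XtX_inv = np.linalg.inv(XtX)
        L_beta = np.linalg.cholesky(XtX_inv)
    except np.linalg.LinAlgError as exc:  # rank-deficient design
        raise InvalidInputError("fixed-effect design is rank deficient") from exc

    sig, kept = run_gibbs(
        y_o,
        obs_o,
        X_o,
        XtX_inv,
        L_beta,
        indptr,
        indices,
        data,
        cfg.n_rounds,
        cfg.burn_in,
        cfg.thin,
        cfg.seed,
        cfg.prior_df,
        cfg.prior_scale,
        False,
    )
    if not np.all(np.isfinite(sig)):
        bad = int(kept[np.flatnonzero(~np.isfinite(sig))[0]])
        raise NumericalError(f"non-finite variance sample at round {bad}")
    h2 = sig / (sig + 1.0)
    return PosteriorChain(sig, h2, kept, cfg)


def sample_variance_prior(ped: Pedigree, cfg: ChainConfig) -> np.ndarray:
    """Draw sigma2_a with the data likelihood disabled.

    Alternates the breeding-value and variance full conditionals only,
    whose stationary distribution is the joint prior; the returned
    marginal should match scaled-inv-chi-square(prior_df, prior_scale).
    Used to validate the full-conditional wiring.
    """
    from ._gibbs import run_gibbs

    n = len(ped)
    indptr, indices, data, _ = nrm_inverse_sparse(ped)
    X = np.ones((n, 1))
    sig, _ = run_gibbs(
        np.zeros(n, dtype=np.int8),
        np.zeros(n, dtype=np.int8),
        X,
        np.eye(1),
        np.eye(1),
        indptr,
        indices,
        data,
        cfg.n_rounds,
        cfg.burn_in,
        cfg.thin,
        cfg.seed,
        cfg.prior_df,
        cfg.prior_scale,
        True,
    )
    return sig


def cohort_split_fit(
    ped: Pedigree,
    y: np.ndarray,
    era_labels: np.ndarray,
    cfg: ChainConfig,
    X: np.ndarray | None = None,
) -> dict:
    """Independent fits restricted to each era label.

    Mirrors a historical-vs-recent cohort comparison: each fit keeps the
    full pedigree for relationships but only individuals of that era
    contribute phenotype records. Returns the two chains plus whether
    their 95% credible intervals overlap.
    """
    labels = pd.Series(era_labels).astype(str).to_numpy()
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise InvalidInputError(f"expected exactly 2 era labels, got {uniq}")
    chains = {}
    for k, lab in enumerate(uniq):
        mask = labels == lab
        if not mask.any():
            raise InvalidInputError(f"era {lab!r} has no individuals")
        sub_cfg = ChainConfig(
            cfg.n_rounds, cfg.burn_in, cfg.thin, cfg.seed + k, cfg.prior_df, cfg.prior_scale
        )
        chains[lab] = fit_threshold_animal_model(ped, y, X, sub_cfg, observed=mask)
    (la, ca), (lb, cb) = chains.items()
    ia = ca.summary()["h2_ci95"]
    ib = cb.summary()["h2_ci95"]
    overlap = ia[0] <= ib[1] and ib[0] <= ia[1]
    return {"chains": chains, "ci_overlap": bool(overlap)}
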