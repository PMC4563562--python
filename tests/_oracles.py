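"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the REML
likelihood is evaluated from its dense matrix definition, kinship is
estimated by gene-dropping Monte Carlo, and the bivariate-normal tail
comes from scipy's multivariate normal CDF.
"""

import numpy as np
from numba import njit
from scipy import stats


def dense_restricted_loglik(y, X, V):
    """REML log-likelihood from the textbook matrix expression."""
    n, p = X.shape
    Vinv = np.linalg.inv(V)
    B = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(B) @ X.T @ Vinv
    _, ld_V = np.linalg.slogdet(V)
    _, ld_B = np.linalg.slogdet(B)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + ld_V + ld_B + y @ P @ y)


def bivariate_tail_rr(h2, K, a=0.5):
    """Recurrence risk ratio via scipy's bivariate normal CDF."""
    t = stats.norm.ppf(1 - K)
    r = a * h2
    joint = stats.multivariate_normal(cov=[[1, r], [r, 1]]).cdf([-t, -t])
    return joint / (K * K)


@njit(cache=True)
def _gene_drop_kinship(parents, order, n_drops, seed):
    """Monte Carlo kinship by dropping labelled founder alleles."""
    np.random.seed(seed)
    n = parents.shape[0]
    kin = np.zeros((n, n))
    alleles = np.zeros((n, 2), dtype=np.int64)
    for _ in range(n_drops):
        label = 0
        for k in range(n):
            i = order[k]
            for s in range(2):
                par = parents[i, s]
                if par < 0:
                    alleles[i, s] = label
                    label += 1
                else:
                    pick = 0 if np.random.random() < 0.5 else 1
                    alleles[i, s] = alleles[par, pick]
        for i in range(n):
            for j in range(i, n):
                m = 0
                for a in range(2):
                    for b in range(2):
                        if alleles[i, a] == alleles[j, b]:
                            m += 1
                kin[i, j] += 0.25 * m
    kin /= n_drops
    for i in range(n):
        for j in range(i + 1, n):
            kin[j, i] = kin[i, j]
    return kin


def gene_drop_kinship(ped, n_drops=20000, seed=0):
    """Kinship matrix (in ``ped.table`` order) by gene dropping."""
    parents = ped.parent_indices()
    order = ped.topological_order()
    return _gene_drop_kinship(parents, order, n_drops, seed)
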