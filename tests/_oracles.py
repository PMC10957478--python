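"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive quantities from first principles (explicit
loops, enumeration, quadrature) and stay independent of the package's
vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def ols_beta(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    return np.linalg.solve(X.T @ X, X.T @ y)


def one_way_cluster_cov(y, X, cluster_ids) -> np.ndarray:
    """Loop-over-clusters sandwich: bread @ sum_g s_g s_g' @ bread."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    beta = ols_beta(y, X)
    resid = y - X @ beta
    bread = np.linalg.inv(X.T @ X)
    k = X.shape[1]
    meat = np.zeros((k, k))
    ids = np.asarray(cluster_ids)
    for g in np.unique(ids):
        mask = ids == g
        s = X[mask].T @ resid[mask]
        meat += np.outer(s, s)
    return bread @ meat @ bread


def two_way_cluster_cov(y, X, case_ids, reader_ids) -> np.ndarray:
    """Inclusion-exclusion of one-way sandwiches; the pair dimension is
    the unique (case, reader) combination."""
    case_ids = np.asarray(case_ids)
    reader_ids = np.asarray(reader_ids)
    pairs = np.array([f"{c}|{r}" for c, r in zip(case_ids, reader_ids)])
    return (
        one_way_cluster_cov(y, X, case_ids)
        + one_way_cluster_cov(y, X, reader_ids)
        - one_way_cluster_cov(y, X, pairs)
    )


def auroc_pairs(scores, labels) -> float:
    """All-pairs Mann-Whitney probability with half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def bh_reject(p_values, q) -> np.ndarray:
    """Literal step-up definition: find the largest k with
    p_(k) <= q k / m and reject everything at or below p_(k)."""
    p = np.asarray(p_values, float)
    m = p.size
    sorted_p = np.sort(p)
    k_star = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= q * k / m:
            k_star = k
    if k_star == 0:
        return np.zeros(m, dtype=bool)
    return p <= sorted_p[k_star - 1]


def normal_normal_posterior_quadrature(mu_r, sigma_r, mu0, sigma0_sq, n_grid=40001):
    """Posterior mean/variance by dense-grid quadrature of
    prior x likelihood for the normal-normal model."""
    sd0 = np.sqrt(sigma0_sq)
    lo = min(mu0 - 10 * sd0, mu_r - 10 * max(sigma_r, 1e-12)) - 1.0
    hi = max(mu0 + 10 * sd0, mu_r + 10 * max(sigma_r, 1e-12)) + 1.0
    t = np.linspace(lo, hi, n_grid)
    log_post = -0.5 * ((t - mu0) ** 2) / sigma0_sq
    if sigma_r > 0:
        log_post = log_post - 0.5 * ((mu_r - t) ** 2) / sigma_r**2
    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    mean = float((w * t).sum())
    var = float((w * (t - mean) ** 2).sum())
    return mean, var
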