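"""SparCC-style compositional correlation inference.

Correlations between OTU abundances cannot be read off raw counts because
the data are compositional (reads per community sum to a fixed library
size).  The SparCC estimator works from log-ratio variances

    t_ij = var(log(x_i / x_j)),

which are invariant to the per-sample total.  Under the sparsity
assumption that most true (basis) correlations are weak, the basis
variances w_i solve the linear system

    sum_j t_ij = (D - 1) w_i + sum_{j != i} w_j,      i = 1..D,

and the basis correlations follow from

    rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)).

Strongly correlated pairs violate the sparsity assumption, so the
strongest pair above an exclusion threshold is removed from the system
and the variances re-solved, for a fixed number of iterations.

Pseudo p-values come from a permutation null: each OTU column is shuffled
independently across communities, the estimator re-run, and the two-sided
exceedance proportion reported.
"""

from __future__ import annotations

import numpy as np

from .data import OtuTable


def _logratio_variances(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """t_ij = var over communities of log(x_i/x_j), zeros shifted by a pseudocount."""
    L = np.log(counts + pseudocount)
    cov = np.cov(L, rowvar=False)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def _basis_correlations(T: np.ndarray, n_iter: int, threshold: float):
    """Solve for basis variances with iterative strong-pair exclusion."""
    D = T.shape[0]
    M = np.ones((D, D)) + np.eye(D) * (D - 2)
    t_sum = T.sum(axis=1)
    excluded = np.zeros((D, D), dtype=bool)

    def solve():
        w = np.linalg.solve(M, t_sum)
        w = np.clip(w, 1e-12, None)
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - T) / denom
        np.fill_diagonal(rho, 1.0)
        return w, np.clip(rho, -1.0, 1.0)

    w, rho = solve()
    for _ in range(n_iter):
        masked = np.where(excluded, 0.0, np.abs(rho))
        np.fill_diagonal(masked, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        M[i, j] -= 1.0
        M[j, i] -= 1.0
        t_sum[i] -= T[i, j]
        t_sum[j] -= T[i, j]
        if np.any(np.diag(M) < 1):
            break
        w, rho = solve()
    return rho


def sparcc_correlations(table: OtuTable | np.ndarray,
                        n_exclusion_iters: int = 10,
                        exclusion_threshold: float = 0.1,
                        n_bootstrap: int = 100,
                        seed: int = 0,
                        pseudocount: float = 1.0):
    """Basis correlation and pseudo p-value matrices for an OTU table.

    Returns ``(rho, pvals)`` as (D x D) arrays.  ``pvals`` are two-sided
    permutation exceedance proportions from ``n_bootstrap`` datasets with
    independently shuffled columns (add-one corrected so no p-value is
    exactly 0); pass ``n_bootstrap=0`` to skip them (pvals = NaN).
    """
    counts = table.counts.to_numpy(dtype=float) if isinstance(table, OtuTable) \
        else np.asarray(table, dtype=float)
    n, D = counts.shape
    if D < 4:
        raise ValueError("SparCC needs at least 4 OTUs (system underdetermined)")
    if n < 10:
        raise ValueError("SparCC needs at least 10 communities")
    T = _logratio_variances(counts, pseudocount)
    if not np.isfinite(T).all() or np.allclose(T[~np.eye(D, dtype=bool)], 0.0):
        raise ValueError("degenerate log-ratio variances")
    rho = _basis_correlations(T.copy(), n_exclusion_iters, exclusion_threshold)

    if n_bootstrap <= 0:
        return rho, np.full((D, D), np.nan)

    rng = np.random.default_rng(seed)
    exceed = np.zeros((D, D))
    for _ in range(n_bootstrap):
        perm = np.empty_like(counts)
        for j in range(D):
            perm[:, j] = counts[rng.permutation(n), j]
        T0 = _logratio_variances(perm, pseudocount)
        rho0 = _basis_correlations(T0, n_exclusion_iters, exclusion_threshold)
        exceed += np.abs(rho0) >= np.abs(rho)
    pvals = (exceed + 1.0) / (n_bootstrap + 1.0)
    np.fill_diagonal(pvals, 0.0)
    return rho, pvals
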