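"""Diversity and phylogenetic explanatory variables.

Three per-community metrics enter the analysis:

* Gini-Simpson diversity ``1 - sum(p_i^2)`` — the probability that two
  randomly drawn reads belong to different OTUs;
* Rao's quadratic entropy ``Q = sum_ij p_i p_j d_ij`` — the expected
  phylogenetic (cophenetic) distance between two random individuals,
  reducing to Gini-Simpson when all pairwise distances are 1;
* the abundance-weighted invader-community distance
  ``sum_i p_i d(invader, OTU_i)``.

Distances are path sums of branch lengths on the rooted 16S tree.  By
default cophenetic distances are normalised by their maximum before Rao's
Q is computed, bounding Q in [0, 1]; raw branch-length units are
available via ``normalize=False``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import TreeNode

from .data import OtuTable

_SUM_TOL = 1e-9


def _check_simplex(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty abundance vector")
    if (p < 0).any():
        raise ValueError("negative relative abundances")
    if abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"relative abundances sum to {p.sum()!r}, not 1")
    return p


def gini_simpson(p) -> float:
    """Gini-Simpson index 1 - sum(p_i^2) of a relative-abundance vector."""
    p = _check_simplex(p)
    return float(1.0 - np.dot(p, p))


def cophenetic_matrix(tree: TreeNode, tips: list[str]) -> pd.DataFrame:
    """Pairwise path-length (cophenetic) distances between named tips."""
    tip_names = {t.name for t in tree.tips()}
    unknown = [t for t in tips if t not in tip_names]
    if unknown:
        raise ValueError(f"tips not in tree: {unknown[:5]}")
    dm = tree.tip_tip_distances(endpoints=list(tips))
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).loc[tips, tips]


def rao_q(p, D, normalize: bool = True) -> float:
    """Rao's quadratic entropy sum_ij p_i p_j d_ij.

    With ``normalize`` the distances are divided by the maximum
    off-diagonal entry first (Q then lies in [0, 1] and equals
    Gini-Simpson when all off-diagonal distances are equal).
    """
    p = _check_simplex(p)
    D = np.asarray(D, dtype=float)
    if D.shape != (p.size, p.size):
        raise ValueError("p and D are not conformable")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if normalize:
        off = D[~np.eye(len(D), dtype=bool)]
        m = off.max() if off.size else 0.0
        if m > 0:
            D = D / m
    return float(p @ D @ p)


def invader_community_distance(p, d_inv) -> float:
    """Abundance-weighted mean phylogenetic distance invader -> community."""
    p = _check_simplex(p)
    d_inv = np.asarray(d_inv, dtype=float)
    if d_inv.shape != p.shape:
        raise ValueError("abundance and distance vectors differ in length")
    return float(p @ d_inv)


def diversity_table(table: OtuTable, tree: TreeNode, invaders: list[str],
                    normalize_rao: bool = True) -> pd.DataFrame:
    """Per-community Simpson, Rao's Q and invader distances.

    Returns a DataFrame indexed by community with columns ``simpson``,
    ``rao_q`` and ``invader_distance_<invader>`` for each invader tip.
    """
    rel = table.relative_abundances()
    otus = list(rel.columns)
    all_tips = otus + list(invaders)
    D_full = cophenetic_matrix(tree, all_tips)
    D = D_full.loc[otus, otus].to_numpy()
    if normalize_rao:
        off = D[~np.eye(len(D), dtype=bool)]
        m = off.max() if off.size else 0.0
        Dn = D / m if m > 0 else D
    else:
        Dn = D
    P = rel.to_numpy()
    simpson = 1.0 - np.einsum("ij,ij->i", P, P)
    rao = np.einsum("ij,jk,ik->i", P, Dn, P)
    out = pd.DataFrame({"simpson": simpson, "rao_q": rao}, index=rel.index)
    for inv in invaders:
        d_inv = D_full.loc[otus, inv].to_numpy()
        out[f"invader_distance_{inv}"] = P @ d_inv
    return out
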