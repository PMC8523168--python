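"""Dimensionality reductions of starting composition.

Seven reductions of the (communities x OTUs) count table are compared as
composition representations:

1-5. taxonomic aggregation at genus, family, order, class and phylum;
6.   principal coordinates (PCoA) of the Jensen-Shannon divergence
     matrix, keeping the first ``k`` axes;
7.   functional-group abundances from the signed SparCC co-occurrence
     network (see :mod:`invasim.netgroups`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data import OtuTable, TAXONOMIC_RANKS
from .netgroups import (build_signed_network, detect_functional_groups,
                        functional_group_abundances)
from .sparcc import sparcc_correlations

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


def aggregate_taxonomy(table: OtuTable, rank: str) -> pd.DataFrame:
    """Sum counts over OTUs sharing a label at ``rank``.

    Missing labels form an explicit "unclassified" column.  Row sums are
    conserved at every rank.
    """
    if rank not in TAXONOMIC_RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {TAXONOMIC_RANKS}")
    if table.taxonomy is None:
        raise ValueError("OTU table has no taxonomy")
    labels = table.taxonomy[rank].fillna(UNCLASSIFIED).replace("", UNCLASSIFIED)
    agg = table.counts.T.groupby(labels.to_numpy()).sum().T
    agg.columns.name = rank
    return agg


def jsd_matrix(rel_abund: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise Jensen-Shannon divergence (natural log, not its root).

    JSD(p, q) = H((p+q)/2) - (H(p) + H(q))/2, bounded by ln 2.
    """
    X = np.asarray(rel_abund, dtype=float)
    if not np.allclose(X.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows must sum to 1")
    # scipy's jensenshannon is the square root of the divergence
    D = squareform(pdist(X, metric="jensenshannon") ** 2)
    return D


def pcoa(distmat, k: int = 5):
    """Classical PCoA (Gower double-centering + eigendecomposition).

    Returns ``(coords, eigvals)`` where coords has one column per
    retained axis (eigenvectors scaled by sqrt(eigenvalue), descending
    eigenvalue order).  Negative eigenvalues — possible because the JS
    divergence is not Euclidean — are dropped with a logged warning; the
    sign of each axis is fixed so its largest-magnitude loading is
    positive.
    """
    index = distmat.index if isinstance(distmat, pd.DataFrame) else None
    D = np.asarray(distmat, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    if k > n - 1:
        raise ValueError("k must be <= n - 1")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_neg = int((eigvals < -1e-10 * max(1.0, abs(eigvals[0]))).sum())
    if n_neg:
        logger.warning("pcoa: dropping %d negative eigenvalues "
                       "(non-Euclidean divergence)", n_neg)
    pos = eigvals > max(1e-12, 1e-12 * abs(eigvals[0]))
    eigvals_pos = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(eigvals_pos)
    for j in range(coords.shape[1]):  # deterministic sign convention
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    coords = coords[:, :k]
    cols = [f"pco_{i + 1}" for i in range(coords.shape[1])]
    out = pd.DataFrame(coords, columns=cols, index=index)
    return out, eigvals


def jsd_pcoa(table: OtuTable, k: int = 5) -> pd.DataFrame:
    rel = table.relative_abundances()
    D = jsd_matrix(rel)
    coords, _ = pcoa(pd.DataFrame(D, index=rel.index, columns=rel.index), k=k)
    return coords


@dataclass
class ReductionSet:
    """Named collection of composition feature tables with provenance."""

    tables: dict[str, pd.DataFrame]
    metadata: dict[str, dict]

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]

    def n_features(self) -> dict[str, int]:
        return {name: t.shape[1] for name, t in self.tables.items()}


def run_all_reductions(table: OtuTable, k_pcoa: int = 5,
                       r_threshold: float = 0.2, p_threshold: float = 0.01,
                       min_group_size: int = 3,
                       merge_rules: dict[str, list[int]] | None = None,
                       n_bootstrap: int = 100, seed: int = 0) -> ReductionSet:
    """All seven composition reductions on one table.

    Returns feature tables keyed genus/family/order/class/phylum/
    jsd_pcoa/functional_groups, each carrying its feature count in the
    metadata.  The functional-group metadata also records the network
    partition for export.
    """
    tables: dict[str, pd.DataFrame] = {}
    metadata: dict[str, dict] = {}
    for rank in ("genus", "family", "order", "class", "phylum"):
        t = aggregate_taxonomy(table, rank)
        tables[rank] = t
        metadata[rank] = {"method": f"taxon:{rank}", "n_features": t.shape[1]}
    coords = jsd_pcoa(table, k=k_pcoa)
    tables["jsd_pcoa"] = coords
    metadata["jsd_pcoa"] = {"method": "jsd-pcoa", "n_features": coords.shape[1]}
    corr, pvals = sparcc_correlations(table, n_bootstrap=n_bootstrap, seed=seed)
    net = build_signed_network(corr, pvals, otu_ids=table.otu_ids,
                               r_threshold=r_threshold, p_threshold=p_threshold)
    part = detect_functional_groups(net)
    feats = functional_group_abundances(table, part, min_size=min_group_size,
                                        merge_rules=merge_rules)
    tables["functional_groups"] = feats
    metadata["functional_groups"] = {
        "method": "netgroups", "n_features": feats.shape[1],
        "n_groups_total": len(part.groups),
        "partition_density": part.partition_density,
        "partition": part.membership,
    }
    return ReductionSet(tables=tables, metadata=metadata)
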