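"""Signed co-occurrence network and functional-group detection.

Significant SparCC correlations define a network whose links are
aggregations (positive correlation) or segregations (negative).  OTUs
occupying the same position in this network — the same number and type of
links to the same neighbours — form a "functional group" and their mean
abundance becomes one composition feature.

Group detection clusters nodes by a typed-neighbour Jaccard similarity
(a shared neighbour counts only when both links to it carry the same
sign; a linked pair counts themselves as shared), using average-linkage
agglomerative clustering on 1 - similarity.  The dendrogram cut is chosen
to maximise the total partition density

    D = (2/M) * sum_c m_c (m_c - n_c + 1) / ((n_c - 2)(n_c - 1)),

summed over clusters with n_c >= 3 nodes and m_c internal edges, M being
the total edge count.  Ties on D are broken by partition stability (the
longest run of merge heights over which the partition persists), then by
fewest clusters, then lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data import OtuTable

AGGREGATION = "aggregation"
SEGREGATION = "segregation"


def build_signed_network(corr, pvals, otu_ids=None,
                         r_threshold: float = 0.2,
                         p_threshold: float = 0.01) -> nx.Graph:
    """Edges where |r| > r_threshold AND p < p_threshold (both strict).

    Nodes are all OTU ids (isolated nodes are kept so the partition can
    report them as unnetworked); edge attributes: r, p, type.
    """
    corr = np.asarray(corr, dtype=float)
    pvals = np.asarray(pvals, dtype=float)
    if corr.shape != pvals.shape or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation and p-value matrices must be square and conformable")
    D = corr.shape[0]
    if otu_ids is None:
        otu_ids = [f"OTU_{i:04d}" for i in range(D)]
    g = nx.Graph()
    g.add_nodes_from(otu_ids)
    iu = np.triu_indices(D, k=1)
    for i, j in zip(*iu):
        r, p = corr[i, j], pvals[i, j]
        if abs(r) > r_threshold and p < p_threshold:
            g.add_edge(otu_ids[i], otu_ids[j], r=float(r), p=float(p),
                       type=AGGREGATION if r > 0 else SEGREGATION)
    return g


@dataclass
class FunctionalGroupPartition:
    """OTU -> group assignment from the signed network.

    ``membership`` covers the networked (non-isolated) OTUs;
    ``partition_density`` is the objective value at the chosen cut.
    Retention (which groups become features) is decided later by
    :func:`functional_group_abundances`.
    """

    membership: dict[str, int]
    partition_density: float
    n_edges: int
    unnetworked: list[str] = field(default_factory=list)

    @property
    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for otu, gid in self.membership.items():
            out.setdefault(gid, []).append(otu)
        return {k: sorted(v) for k, v in sorted(out.items())}


def _typed_neighbour_similarity(g: nx.Graph, nodes: list[str]) -> np.ndarray:
    """Jaccard index over typed neighbour sets, inclusive of a linked pair."""
    sets = {v: {(u, g.edges[v, u]["type"]) for u in g.neighbors(v)} for v in nodes}
    n = len(nodes)
    S = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            va, vb = nodes[a], nodes[b]
            A, B = sets[va], sets[vb]
            if g.has_edge(va, vb):
                t = g.edges[va, vb]["type"]
                A = A | {(va, t)}
                B = B | {(vb, t)}
            union = len(A | B)
            S[a, b] = S[b, a] = (len(A & B) / union) if union else 0.0
    return S


def partition_density(g: nx.Graph, labels: dict[str, int]) -> float:
    """Total partition density of a node partition (clusters of < 3 nodes
    contribute nothing)."""
    M = g.number_of_edges()
    if M == 0:
        return 0.0
    clusters: dict[int, list[str]] = {}
    for v, c in labels.items():
        clusters.setdefault(c, []).append(v)
    total = 0.0
    for members in clusters.values():
        n_c = len(members)
        if n_c < 3:
            continue
        m_c = g.subgraph(members).number_of_edges()
        total += m_c * (m_c - n_c + 1) / ((n_c - 2) * (n_c - 1))
    return 2.0 * total / M


def detect_functional_groups(g: nx.Graph) -> FunctionalGroupPartition:
    """Partition the networked nodes into functional groups.

    Scans every partition in the average-linkage merge sequence and keeps
    the one maximising partition density (ties: most stable, then fewest
    clusters, then lexicographically smallest label vector).  Group ids
    are assigned in order of each group's smallest member id.  Raises on
    an empty (edgeless) network.
    """
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges")
    nodes = sorted(v for v in g.nodes if g.degree(v) > 0)
    unnetworked = sorted(v for v in g.nodes if g.degree(v) == 0)
    n = len(nodes)
    S = _typed_neighbour_similarity(g, nodes)
    dist = 1.0 - S
    np.fill_diagonal(dist, 0.0)
    if n == 1:  # pragma: no cover - an edge implies >= 2 nodes
        raise ValueError("network has fewer than 2 connected nodes")
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")

    # Walk the merge sequence, recording every intermediate partition, its
    # density and how long (in merge height) it persists.
    labels = np.arange(n)
    heights = [0.0] + [float(h) for h in Z[:, 2]]
    candidates = []  # (D, stability, n_clusters, canonical labels)

    def canonical(lab: np.ndarray) -> tuple[int, ...]:
        seen: dict[int, int] = {}
        out = []
        for x in lab:
            out.append(seen.setdefault(x, len(seen)))
        return tuple(out)

    def record(step: int, lab: np.ndarray):
        mapping = dict(zip(nodes, lab))
        dens = partition_density(g, mapping)
        gap = heights[step + 1] - heights[step] if step + 1 < len(heights) else 0.0
        candidates.append((dens, gap, len(set(lab)), canonical(lab)))

    record(0, labels)
    current = labels.copy()
    for step, (a, b, h, _) in enumerate(Z, start=1):
        # scipy assigns the merged cluster the id n - 1 + step
        current = np.where(np.isin(current, (int(a), int(b))), n - 1 + step, current)
        record(step, current)

    candidates.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))
    best = candidates[0]
    lab = best[3]
    # group ids ordered by smallest member node id
    first_member: dict[int, str] = {}
    for v, c in zip(nodes, lab):
        first_member.setdefault(c, v)
    order = sorted(first_member, key=lambda c: first_member[c])
    remap = {c: i for i, c in enumerate(order)}
    membership = {v: remap[c] for v, c in zip(nodes, lab)}
    return FunctionalGroupPartition(membership=membership,
                                    partition_density=float(best[0]),
                                    n_edges=g.number_of_edges(),
                                    unnetworked=unnetworked)


def functional_group_abundances(table: OtuTable,
                                partition: FunctionalGroupPartition,
                                min_size: int = 3,
                                merge_rules: dict[str, list[int]] | None = None
                                ) -> pd.DataFrame:
    """Group-abundance features: one column per retained group.

    A group is retained when it has at least ``min_size`` members;
    ``merge_rules`` may additionally coalesce named sets of small groups
    into extra retained features (the study applied one such rule to a
    set of sub-threshold Paenibacillus groups).  The feature value is the
    mean count across member OTUs per community; a final ``remainder``
    column is the mean count across all non-retained OTUs (including
    unnetworked ones), defined as 0 when that set is empty.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    merge_rules = merge_rules or {}
    counts = table.counts
    groups = partition.groups
    covered = set(partition.membership)
    features = {}
    merged_ids = {gid for ids in merge_rules.values() for gid in ids}
    retained_otus: set[str] = set()
    for gid, members in groups.items():
        members = [m for m in members if m in counts.columns]
        if len(members) >= min_size and gid not in merged_ids:
            features[f"group_{gid:02d}"] = counts[members].mean(axis=1)
            retained_otus.update(members)
    for name, gids in merge_rules.items():
        members = sorted(m for gid in gids for m in groups.get(gid, ())
                         if m in counts.columns)
        if members:
            features[name] = counts[members].mean(axis=1)
            retained_otus.update(members)
    rest = [c for c in counts.columns if c not in retained_otus]
    features["remainder"] = (counts[rest].mean(axis=1) if rest
                             else pd.Series(0.0, index=counts.index))
    return pd.DataFrame(features, index=counts.index)


def network_edge_table(g: nx.Graph) -> pd.DataFrame:
    """Edge list (source, target, r, p, type) for TSV export."""
    rows = [{"source": u, "target": v, **d} for u, v, d in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["source", "target", "r", "p", "type"])
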