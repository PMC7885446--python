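"""Median-joining haplotype networks and star-shape summaries.

A median-joining (MJ) network augments the ε-relaxed minimum spanning
network (MSN) over sampled haplotypes with inferred intermediate
haplotypes ("median vectors", Steiner points): for triplets of nodes
adjacent in the current network, the site-wise majority consensus is a
candidate node; candidates that reduce the total spanning cost are added
and the network is rebuilt until fixation.  Median vectors that end up
with degree < 3 are pruned.  A star-shaped network — one high-frequency
hub with many one-step derivatives — is the classic signature of a
recent rapid expansion.

Only variable alignment columns are carried as characters; constant
columns cannot affect any distance or median.  All tie-breaking is by
(weight, first-occurrence order), so construction is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .seq_io import HaplotypeTable

__all__ = [
    "hamming_matrix",
    "minimum_spanning_network",
    "median_joining",
    "star_summary",
    "network_cost",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1, "-": -1}


def _encode(seqs: list[str]) -> np.ndarray:
    out = np.empty((len(seqs), len(seqs[0])), dtype=np.int8)
    for i, s in enumerate(seqs):
        out[i] = [_CODE[c] for c in s]
    return out


def _pairwise(enc: np.ndarray) -> np.ndarray:
    n = enc.shape[0]
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = (enc[i] >= 0) & (enc[i + 1 :] >= 0)
        row = ((enc[i] != enc[i + 1 :]) & both).sum(axis=1)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return d


def hamming_matrix(table: HaplotypeTable) -> np.ndarray:
    """Symmetric pairwise-deletion Hamming distance matrix over haplotypes."""
    return _pairwise(_encode(table.sequences))


def minimum_spanning_network(
    enc: np.ndarray, epsilon: int = 0
) -> list[tuple[int, int, int]]:
    """Edges (i, j, weight) of the ε-relaxed minimum spanning network.

    An edge of weight d is kept iff its endpoints are not connected using
    only edges of weight < d − ε; ε = 0 gives the standard MSN (all
    minimal alternative connections retained), larger ε keeps additional
    slightly-suboptimal connections, so the ε = 0 network is a subgraph
    of every ε > 0 network.
    """
    n = enc.shape[0]
    dmat = _pairwise(enc)
    pairs = [(int(dmat[i, j]), i, j) for i in range(n) for j in range(i + 1, n)]
    pairs.sort()
    edges: list[tuple[int, int, int]] = []
    for d, i, j in pairs:
        # connectivity is judged on already-kept edges of weight < d - eps
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((a, b) for (a, b, w) in edges if w < d - epsilon)
        if not nx.has_path(g, i, j):
            edges.append((i, j, d))
    return edges


def network_cost(edges: list[tuple[int, int, int]], n: int) -> int:
    """Cost of the minimum spanning tree implied by a weighted edge list."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j, w in edges:
        g.add_edge(i, j, weight=w)
    if not nx.is_connected(g):
        raise ValueError("edge list does not connect all nodes")
    return int(
        sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))
    )


def _mst_cost(enc: np.ndarray) -> int:
    dmat = _pairwise(enc)
    g = nx.Graph()
    n = enc.shape[0]
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=int(dmat[i, j]))
    return int(
        sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))
    )


def _majority_median(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray | None:
    """Site-wise majority consensus of three encoded haplotypes.

    Ambiguous states are ignored site-wise (the unambiguous majority
    wins); a site where all three disagree has no majority and the
    triplet yields no median.
    """
    med = np.empty_like(a)
    for s in range(len(a)):
        states = [x for x in (a[s], b[s], c[s]) if x >= 0]
        if not states:
            med[s] = -1
            continue
        vals, cnt = np.unique(states, return_counts=True)
        if cnt.max() >= 2:
            med[s] = vals[np.argmax(cnt)]
        elif len(vals) == 1:
            med[s] = vals[0]
        else:
            return None
    return med


def median_joining(table: HaplotypeTable, epsilon: int = 0) -> nx.Graph:
    """Build a median-joining network for a haplotype table.

    Returns a :class:`networkx.Graph` whose nodes are haplotype labels
    ("H1".. for sampled haplotypes in first-occurrence order, "mv1".. for
    inferred median vectors) with attributes ``frequency``, ``is_median``
    and ``sequence`` (variable columns only); edges carry the number of
    substitutions as ``weight``.
    """
    seqs = table.sequences
    full = _encode(seqs)
    # keep only variable columns (sites with >= 2 unambiguous states)
    variable = []
    for j in range(full.shape[1]):
        col = full[:, j]
        if len(np.unique(col[col >= 0])) >= 2:
            variable.append(j)
    enc = full[:, variable] if variable else full[:, :0]
    n_sampled = len(seqs)
    if n_sampled == 1:
        g = nx.Graph()
        g.add_node(
            "H1", frequency=table.frequencies[0], is_median=False,
            sequence="",
        )
        return g

    nodes = [enc[i] for i in range(n_sampled)]
    n_medians = 0
    for _ in range(50):  # iterate to fixation; bound prevents runaway growth
        cur = np.vstack(nodes) if nodes[0].size else np.zeros((len(nodes), 0), np.int8)
        base_cost = _mst_cost(cur)
        msn = minimum_spanning_network(cur, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j, _w in msn:
            adj[i].add(j)
            adj[j].add(i)
        existing = {row.tobytes() for row in cur}
        # candidate medians from triplets adjacent in the current network
        candidates: list[np.ndarray] = []
        seen: set[bytes] = set()
        for v in range(len(nodes)):
            nbrs = sorted(adj[v])
            for ai in range(len(nbrs)):
                for bi in range(ai + 1, len(nbrs)):
                    med = _majority_median(
                        nodes[nbrs[ai]], nodes[v], nodes[nbrs[bi]]
                    )
                    if med is None:
                        continue
                    key = med.tobytes()
                    if key in existing or key in seen:
                        continue
                    seen.add(key)
                    candidates.append(med)
        best_gain = 0
        best_med: np.ndarray | None = None
        for med in candidates:
            cost = _mst_cost(np.vstack([cur, med]))
            gain = base_cost - cost
            if gain > best_gain:
                best_gain = gain
                best_med = med
        if best_med is None:
            break
        nodes.append(best_med)
        n_medians += 1

    # prune median vectors whose degree drops below 3, iteratively
    while True:
        cur = np.vstack(nodes)
        msn = minimum_spanning_network(cur, epsilon)
        deg = {i: 0 for i in range(len(nodes))}
        for i, j, _w in msn:
            deg[i] += 1
            deg[j] += 1
        removable = [
            i for i in range(n_sampled, len(nodes)) if deg[i] < 3
        ]
        if not removable:
            break
        drop = removable[0]
        nodes.pop(drop)

    cur = np.vstack(nodes)
    msn = minimum_spanning_network(cur, epsilon)
    g = nx.Graph()
    labels: list[str] = []
    for i in range(len(nodes)):
        if i < n_sampled:
            label = f"H{i + 1}"
            g.add_node(
                label,
                frequency=table.frequencies[i],
                is_median=False,
                sequence="".join("ACGTN"[min(v, 4)] for v in nodes[i]),
            )
        else:
            label = f"mv{i - n_sampled + 1}"
            g.add_node(
                label,
                frequency=0,
                is_median=True,
                sequence="".join("ACGTN"[min(v, 4)] for v in nodes[i]),
            )
        labels.append(label)
    for i, j, w in msn:
        g.add_edge(labels[i], labels[j], weight=w)
    return g


@dataclass(frozen=True)
class StarSummary:
    """Descriptive star-shape summary (no significance claim)."""

    hub: str
    hub_degree: int
    fraction_one_step: float


def star_summary(net: nx.Graph) -> StarSummary:
    """Identify the hub and how star-like the network is.

    Hub = the sampled (non-median) node of maximal degree; ties broken by
    higher frequency, then input order.  ``fraction_one_step`` is the
    fraction of the other sampled haplotypes adjacent to the hub.
    """
    sampled = [v for v, d in net.nodes(data=True) if not d.get("is_median")]
    if not sampled:
        raise ValueError("network has no sampled haplotypes")
    hub = max(
        sampled,
        key=lambda v: (
            net.degree(v),
            net.nodes[v].get("frequency", 0),
            -sampled.index(v),
        ),
    )
    others = [v for v in sampled if v != hub]
    if not others:
        return StarSummary(hub=hub, hub_degree=net.degree(hub), fraction_one_step=1.0)
    within = sum(1 for v in others if net.has_edge(hub, v))
    return StarSummary(
        hub=hub,
        hub_degree=int(net.degree(hub)),
        fraction_one_step=within / len(others),
    )


def write_network(net: nx.Graph, graphml_path=None, edges_tsv=None, nodes_tsv=None):
    """Export a network as GraphML and/or TSV edge and node tables."""
    if graphml_path is not None:
        nx.write_graphml(net, graphml_path)
    if edges_tsv is not None:
        with open(edges_tsv, "w", encoding="utf-8") as fh:
            fh.write("node1\tnode2\tweight\n")
            for u, v, w in net.edges(data="weight"):
                fh.write(f"{u}\t{v}\t{w}\n")
    if nodes_tsv is not None:
        with open(nodes_tsv, "w", encoding="utf-8") as fh:
            fh.write("node\tfrequency\tis_median\n")
            for v, d in net.nodes(data=True):
                fh.write(f"{v}\t{d.get('frequency', 0)}\t{int(bool(d.get('is_median')))}\n")
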