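"""Haplotype networks as minimum spanning networks (MSN).

The MSN over the complete Hamming-distance graph of haplotypes is the
union of all minimum spanning trees: an edge of weight w belongs to the
network iff its endpoints are still in different components of the graph
built from all strictly lighter edges.  With dense sampling this closely
approximates a median-joining network at homoplasy level 0, except that
no unsampled median (inferred ancestral) haplotypes are added — every
displayed node is an observed sequence.  Distances are computed on
scored positions only (columns free of N/gap across the haplotype set),
matching the masking used by the summary statistics.

Node weights follow either the number of individuals carrying the
haplotype or, after per-site deduplication, the number of distinct sites
at which it occurs (the circle-size convention that removes sample-size
bias across sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .popgen_core import HaplotypeTable


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph                    # nodes: haplotype indices; edge attr 'steps'
    weights: dict                      # node -> weight (individuals or sites)
    groups: dict | None = None         # node -> group label
    flags: list = field(default_factory=list)


class _DSU:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        self.parent[self.find(i)] = self.find(j)


def hamming_matrix(sequences: list) -> np.ndarray:
    """Pairwise Hamming distances over scored (N/gap-free) columns."""
    mat = np.frombuffer("".join(sequences).encode(), dtype="S1"
                        ).reshape(len(sequences), -1)
    scored = ~np.isin(mat, [b"N", b"-"]).any(axis=0)
    mat = mat[:, scored]
    k = len(sequences)
    d = np.zeros((k, k), dtype=int)
    for i in range(k):
        d[i, i + 1:] = (mat[i + 1:] != mat[i]).sum(axis=1)
    return d + d.T


def dedup_one_per_site(samples: pd.DataFrame,
                       sample_col: str = "sample_id",
                       site_col: str = "site_id",
                       hap_col: str = "haplotype") -> pd.DataFrame:
    """Retain at most one sample per (site, haplotype) pair.

    Idempotent; the first sample of each pair (in input order) is kept.
    """
    return samples.drop_duplicates(subset=[site_col, hap_col], keep="first")


def build_msn(haplotypes: HaplotypeTable, weight_by: str = "individuals"
              ) -> HaplotypeNetwork:
    """Minimum spanning network over haplotype Hamming distances.

    Kruskal with tie retention: every edge that appears in some minimum
    spanning tree is kept, so the result is connected and deterministic.
    ``weight_by`` is 'individuals' (haplotype counts) or 'sites'
    (distinct sites of occurrence).
    """
    k = haplotypes.k
    if k < 1:
        raise ValueError("need at least one haplotype")
    if weight_by == "individuals":
        weights = {i: int(c) for i, c in enumerate(haplotypes.counts)}
    elif weight_by == "sites":
        weights = {i: max(len(s), 1) for i, s in enumerate(haplotypes.sites)}
    else:
        raise ValueError(f"unknown weight mode {weight_by!r}")

    g = nx.Graph()
    g.add_nodes_from(range(k))
    if k == 1:
        return HaplotypeNetwork(g, weights)

    d = hamming_matrix(haplotypes.sequences)
    edges = [(int(d[i, j]), i, j) for i in range(k) for j in range(i + 1, k)]
    edges.sort()
    dsu = _DSU(k)
    pos = 0
    while pos < len(edges):
        w = edges[pos][0]
        batch = []
        while pos < len(edges) and edges[pos][0] == w:
            batch.append(edges[pos])
            pos += 1
        # keep every weight-w edge joining components of the lighter graph
        kept = [(i, j) for _, i, j in batch if dsu.find(i) != dsu.find(j)]
        for i, j in kept:
            g.add_edge(i, j, steps=w)
        for i, j in kept:
            dsu.union(i, j)
    flags = []
    if any(d[i, j] == 0 for i in range(k) for j in range(i + 1, k)):
        flags.append("zero-distance haplotype pair (distinct only at masked columns)")
    return HaplotypeNetwork(g, weights, flags=flags)


def assign_groups(network: HaplotypeNetwork, cut: float | None = None,
                  seeds: dict | None = None) -> dict:
    """Group labels per node, by edge cut or by nearest seed node.

    Exactly one of ``cut`` (remove edges with steps > cut, label connected
    components) and ``seeds`` (node -> label; nodes take the label of the
    nearest seed along network paths, ties to the lowest label) must be
    given.
    """
    if (cut is None) == (seeds is None):
        raise ValueError("specify exactly one of cut= or seeds=")
    g = network.graph
    if cut is not None:
        sub = nx.Graph()
        sub.add_nodes_from(g.nodes)
        sub.add_edges_from((u, v) for u, v, d in g.edges(data=True)
                           if d["steps"] <= cut)
        labels = {}
        comps = sorted(nx.connected_components(sub), key=min)
        for lab, comp in enumerate(comps):
            for node in comp:
                labels[node] = lab
        return labels
    best: dict = {}
    for label in sorted(set(seeds.values()), key=str):
        sources = [n for n, lab in seeds.items() if lab == label]
        dist = nx.multi_source_dijkstra_path_length(g, sources, weight="steps")
        for node, d in dist.items():
            if node not in best or d < best[node][0]:
                best[node] = (d, label)
    unreachable = set(g.nodes) - set(best)
    if unreachable:
        raise ValueError(f"nodes unreachable from any seed: {sorted(unreachable)}")
    return {node: lab for node, (d, lab) in best.items()}


# ---------------------------------------------------------------------------
# Exports


def write_edge_list(network: HaplotypeNetwork, path) -> None:
    rows = [{"from": u, "to": v, "steps": d["steps"],
             "weight_from": network.weights[u], "weight_to": network.weights[v]}
            for u, v, d in network.graph.edges(data=True)]
    pd.DataFrame(rows, columns=["from", "to", "steps", "weight_from",
                                "weight_to"]).to_csv(path, index=False)


def write_graphml(network: HaplotypeNetwork, path) -> None:
    g = network.graph.copy()
    for node in g.nodes:
        g.nodes[node]["weight"] = network.weights[node]
        if network.groups:
            g.nodes[node]["group"] = str(network.groups.get(node, ""))
    nx.write_graphml(g, path)


def write_nexus(haplotypes: HaplotypeTable, path) -> None:
    """NEXUS export of collapsed haplotypes (external network verification)."""
    seqs = haplotypes.sequences
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"DIMENSIONS NTAX={len(seqs)} NCHAR={len(seqs[0])};\n")
        fh.write("FORMAT DATATYPE=DNA MISSING=N GAP=-;\nMATRIX\n")
        for i, seq in enumerate(seqs):
            fh.write(f"hap{i}_{haplotypes.counts[i]} {seq}\n")
        fh.write(";\nEND;\n")
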