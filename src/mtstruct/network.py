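"""Minimum spanning networks over haplotypes; duplicate handling.

The MSN (epsilon = 0) is the union of all minimum spanning trees of the
complete haplotype graph weighted by nucleotide-difference counts,
obtained by Kruskal processing of equal-weight edge batches: within a
batch, every edge joining two still-separate components of the pre-batch
partition is kept. A positive epsilon additionally admits edges whose
weight exceeds the feasibility threshold by at most epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .diversity import pairwise_difference
from .seqio import SequenceDataset


@dataclass
class HaplotypeNode:
    label: str                 # lexicographically first member id
    sequence: str
    members: list[str] = field(default_factory=list)


@dataclass
class MSNGraph:
    nodes: list[HaplotypeNode]
    graph: nx.Graph            # node labels, edge attr "weight" = differences
    epsilon: float = 0.0

    @property
    def edges(self) -> list[tuple[str, str, int]]:
        return sorted((min(u, v), max(u, v), d["weight"])
                      for u, v, d in self.graph.edges(data=True))

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tdifferences\n")
            for u, v, w in self.edges:
                fh.write(f"{u}\t{v}\t{w}\n")

    def write_memberships(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node\tsample_id\n")
            for node in self.nodes:
                for m in node.members:
                    fh.write(f"{node.label}\t{m}\n")

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for node in self.nodes:
            g.nodes[node.label]["n_members"] = len(node.members)
            g.nodes[node.label]["members"] = ",".join(node.members)
        nx.write_graphml(g, str(path))


def collapse_haplotypes(records) -> list[HaplotypeNode]:
    """Group samples by exact sequence identity; node label is the
    lexicographically first member id."""
    by_seq: dict[str, list[str]] = {}
    for rec in records:
        by_seq.setdefault(rec.sequence.upper(), []).append(rec.sample_id)
    nodes = [HaplotypeNode(min(ids), seq, sorted(ids)) for seq, ids in by_seq.items()]
    return sorted(nodes, key=lambda n: n.label)


def build_msn(nodes, distance=None, epsilon: float = 0.0) -> MSNGraph:
    """Union-of-all-MSTs network. *distance* maps two nodes to their weight
    (defaults to the nucleotide-difference count under pairwise deletion)."""
    if distance is None:
        distance = lambda a, b: pairwise_difference(a.sequence, b.sequence)[0]
    g = nx.Graph()
    for node in nodes:
        g.add_node(node.label)
    if len(nodes) <= 1:
        return MSNGraph(list(nodes), g, epsilon)

    weighted = sorted(
        ((distance(a, b), a.label, b.label) for a, b in combinations(nodes, 2)),
        key=lambda e: (e[0], e[1], e[2]))
    uf = nx.utils.UnionFind(n.label for n in nodes)
    threshold = None  # weight of the batch that completes connectivity
    i = 0
    while i < len(weighted):
        w = weighted[i][0]
        if threshold is not None and w > threshold + epsilon:
            break
        batch = []
        while i < len(weighted) and weighted[i][0] == w:
            batch.append(weighted[i])
            i += 1
        # Admit every batch edge bridging the pre-batch partition: an edge
        # of weight w belongs to some MST iff its endpoints lie in distinct
        # components of the strictly-lighter subgraph.
        pre = {n.label: uf[n.label] for n in nodes}
        for w_, u, v in batch:
            if pre[u] != pre[v]:
                g.add_edge(u, v, weight=w_)
                uf.union(u, v)
        if threshold is None and len({uf[n.label] for n in nodes}) == 1:
            threshold = w
    if epsilon > 0 and threshold is not None:
        # Relaxation: additionally admit every edge within epsilon of the
        # connectivity threshold, whether or not it bridges components.
        for w, u, v in weighted:
            if w > threshold + epsilon:
                break
            if not g.has_edge(u, v):
                g.add_edge(u, v, weight=w)
    return MSNGraph(list(nodes), g, epsilon)


def find_pairs_at_distance(dataset: SequenceDataset, d: int) -> list[tuple[str, str]]:
    """All unordered sample pairs differing at exactly *d* jointly called
    positions."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    out = []
    for a, b in combinations(dataset.records, 2):
        diff, called = pairwise_difference(a.sequence, b.sequence)
        if called and diff == d:
            out.append(tuple(sorted((a.sample_id, b.sample_id))))
    return sorted(out)


def deduplicate(dataset: SequenceDataset) -> tuple[SequenceDataset, list[dict]]:
    """Remove potential maternal relatives: within each connected component
    of the identical-sequence (d = 0) pair graph, keep the lexicographically
    first sample id. Returns the reduced dataset and a removal log."""
    g = nx.Graph()
    g.add_nodes_from(r.sample_id for r in dataset.records)
    g.add_edges_from(find_pairs_at_distance(dataset, 0))
    removals = []
    keep = set()
    for comp in nx.connected_components(g):
        ordered = sorted(comp)
        keep.add(ordered[0])
        for sid in ordered[1:]:
            removals.append({"removed": sid, "kept": ordered[0],
                             "reason": "identical mtDNA sequence"})
    return dataset.subset(keep), sorted(removals, key=lambda r: r["removed"])
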