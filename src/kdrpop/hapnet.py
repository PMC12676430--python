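"""Median-joining haplotype networks.

The network combines a minimum spanning network (all links within ``epsilon``
of the minimal connection cost between components) with inferred median
(Steiner) vectors: for triplets of nodes with at least two of their three
links in the current network, the coordinate-wise majority consensus vector
is added, and the construction iterates to a fixed point. Obsolete medians
(multiplicity 0, degree <= 2, not on any shortest path between sampled
nodes) are then removed. All tie-breaking is by lexicographic vector order,
so the output is deterministic for a given input.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np


@dataclass
class HaplotypeNetwork:
    """Nodes are haplotype vectors (tuples); edge weights are Hamming
    distances. Median vectors carry multiplicity 0 and ``inferred=True``."""

    graph: nx.Graph
    epsilon: int

    @property
    def sampled_nodes(self) -> list[tuple]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if not d["inferred"])

    @property
    def median_nodes(self) -> list[tuple]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d["inferred"])

    def total_edge_weight(self) -> int:
        return sum(w for _, _, w in self.graph.edges(data="weight"))

    def connection_cost(self) -> int:
        """Weight of a minimum spanning tree over the final node set — the
        cost of connecting all sampled haplotypes through the network."""
        if self.graph.number_of_nodes() <= 1:
            return 0
        return int(sum(d["weight"] for _, _, d in
                       nx.minimum_spanning_edges(self.graph, data=True)))


def hamming(u: tuple, v: tuple) -> int:
    return sum(a != b for a, b in zip(u, v))


def collapse_haplotypes(haps: np.ndarray, annotations: dict[str, list] | None
                        = None) -> tuple[list[tuple], np.ndarray, list[dict]]:
    """Exact-match collapse of haplotype rows.

    Returns (unique vectors in lexicographic order, multiplicities, per-node
    annotation tallies). ``annotations`` maps an annotation name (e.g.
    "species", "group") to one value per input row.
    """
    haps = np.asarray(haps)
    rows = [tuple(int(x) for x in r) for r in haps]
    annotations = annotations or {}
    for key, vals in annotations.items():
        if len(vals) != len(rows):
            raise ValueError(f"annotation {key!r} length mismatch")
    uniq = sorted(set(rows))
    index = {h: i for i, h in enumerate(uniq)}
    mult = np.zeros(len(uniq), dtype=np.int64)
    tallies: list[dict] = [{k: {} for k in annotations} for _ in uniq]
    for r_i, h in enumerate(rows):
        i = index[h]
        mult[i] += 1
        for key, vals in annotations.items():
            v = str(vals[r_i])
            tallies[i][key][v] = tallies[i][key].get(v, 0) + 1
    return uniq, mult, tallies


def _minimum_spanning_network(nodes: list[tuple], epsilon: int) -> nx.Graph:
    """Kruskal-by-level MSN: at each ascending distance level, link all node
    pairs in different components; keep levels up to connection + epsilon."""
    G = nx.Graph()
    G.add_nodes_from(nodes)
    if len(nodes) <= 1:
        return G
    dist = {}
    for u, v in combinations(nodes, 2):
        dist.setdefault(hamming(u, v), []).append((u, v))
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n_comp = len(nodes)
    connect_level = None
    for w in sorted(dist):
        if connect_level is not None and w > connect_level + epsilon:
            break
        level_edges = [(u, v) for u, v in dist[w] if find(u) != find(v)]
        for u, v in level_edges:
            G.add_edge(u, v, weight=w)
        for u, v in level_edges:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
                n_comp -= 1
        if n_comp == 1 and connect_level is None:
            connect_level = w
    return G


def _majority_median(u: tuple, v: tuple, w: tuple) -> tuple:
    med = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            med.append(a)
        elif b == c:
            med.append(b)
        else:  # three distinct states: deterministic lexicographic tie-break
            med.append(min(a, b, c))
    return tuple(med)


def median_joining(haps, epsilon: int = 0, multiplicities=None,
                   tallies: list[dict] | None = None,
                   max_rounds: int = 25) -> HaplotypeNetwork:
    """Build the median-joining network of a set of unique haplotypes.

    ``haps`` is an (n, S) matrix or list of tuples (assumed unique);
    ``multiplicities`` and ``tallies`` (from :func:`collapse_haplotypes`)
    become node attributes for rendering.
    """
    sampled = [tuple(int(x) for x in r) for r in np.asarray(haps)]
    if len(set(sampled)) != len(sampled):
        raise ValueError("haplotypes must be unique; collapse first")
    if not sampled:
        raise ValueError("need at least one haplotype")
    if multiplicities is None:
        multiplicities = np.ones(len(sampled), dtype=np.int64)
    mult = {h: int(m) for h, m in zip(sampled, multiplicities)}
    tally = {h: (tallies[i] if tallies else {})
             for i, h in enumerate(sampled)}

    nodes = sorted(sampled)
    for _ in range(max_rounds):
        G = _minimum_spanning_network(nodes, epsilon)
        new = set()
        for u, v, w in combinations(nodes, 3):
            links = sum((G.has_edge(u, v), G.has_edge(u, w), G.has_edge(v, w)))
            if links >= 2:
                m = _majority_median(u, v, w)
                if m not in G:
                    new.add(m)
        if not new:
            break
        nodes = sorted(set(nodes) | new)

    sampled_set = set(sampled)
    G = _minimum_spanning_network(nodes, epsilon)
    G = _prune_obsolete_medians(G, sampled_set, epsilon)

    for n in G.nodes:
        G.nodes[n]["inferred"] = n not in sampled_set
        G.nodes[n]["multiplicity"] = mult.get(n, 0)
        G.nodes[n]["tallies"] = tally.get(n, {})
    return HaplotypeNetwork(graph=G, epsilon=epsilon)


def _on_some_shortest_path(G: nx.Graph, x, sampled: set) -> bool:
    dist_from_x = nx.single_source_dijkstra_path_length(G, x, weight="weight")
    for s, t in combinations(sorted(sampled), 2):
        if s == x or t == x:
            continue
        try:
            d_st = nx.dijkstra_path_length(G, s, t, weight="weight")
        except nx.NetworkXNoPath:
            continue
        if s in dist_from_x and t in dist_from_x and \
                dist_from_x[s] + dist_from_x[t] == d_st:
            return True
    return False


def _prune_obsolete_medians(G: nx.Graph, sampled: set, epsilon: int
                            ) -> nx.Graph:
    nodes = sorted(G.nodes)
    changed = True
    while changed:
        changed = False
        for x in sorted(n for n in nodes if n not in sampled):
            if G.degree(x) <= 2 and not _on_some_shortest_path(G, x, sampled):
                nodes = [n for n in nodes if n != x]
                G = _minimum_spanning_network(nodes, epsilon)
                changed = True
                break
    return G


def network_to_dot(net: HaplotypeNetwork, color_by: str | None = None,
                   palette: list[str] | None = None) -> str:
    """Deterministic DOT rendering: node size tracks multiplicity, inferred
    median vectors are drawn as small points, edges are labelled with their
    Hamming weight. Output is sorted so reruns are byte-identical."""
    palette = palette or ["#1b9e77", "#d95f02", "#7570b3", "#e7298a",
                          "#66a61e", "#e6ab02", "#a6761d", "#666666"]
    nodes = sorted(net.graph.nodes)
    if color_by is not None:
        keys = sorted({k for n in nodes for k in net.graph.nodes[n]["tallies"]})
        if color_by not in keys:
            raise KeyError(f"unknown annotation key {color_by!r}; "
                           f"available: {keys}")
        values = sorted({v for n in nodes
                         for v in net.graph.nodes[n]["tallies"]
                         .get(color_by, {})})
        color_of = {v: palette[i % len(palette)] for i, v in enumerate(values)}
    name = {n: f"h{i}" for i, n in enumerate(nodes)}
    lines = ["graph haplotype_network {", "  node [shape=circle];"]
    for n in nodes:
        d = net.graph.nodes[n]
        if d["inferred"]:
            attrs = ['label=""', "shape=point", "style=dashed"]
        else:
            attrs = [f'label="{d["multiplicity"]}"']
            w = 0.3 + 0.15 * np.sqrt(d["multiplicity"])
            attrs.append(f"width={w:.2f}")
            if color_by is not None:
                t = d["tallies"].get(color_by, {})
                if t:
                    major = max(sorted(t), key=lambda v: t[v])
                    attrs.append(f'fillcolor="{color_of[major]}"')
                    attrs.append("style=filled")
        lines.append(f"  {name[n]} [{', '.join(attrs)}];")
    for u, v in sorted(net.graph.edges):
        w = net.graph.edges[u, v]["weight"]
        a, b = sorted((name[u], name[v]))
        lines.append(f'  {a} -- {b} [label="{w}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def node_tallies_json(net: HaplotypeNetwork) -> list[dict]:
    """Per-node multiplicities and annotation tallies, ready for JSON."""
    out = []
    for i, n in enumerate(sorted(net.graph.nodes)):
        d = net.graph.nodes[n]
        out.append({
            "node": f"h{i}",
            "vector": list(n),
            "inferred": bool(d["inferred"]),
            "multiplicity": int(d["multiplicity"]),
            "tallies": d["tallies"],
        })
    return out
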