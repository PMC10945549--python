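"""Cytokine-centric kinase subnetworks on a reference interaction graph.

A reference network (e.g. KEGG-derived gene-gene edges) carries positive
edge weights where *higher weight means a less likely interaction*; inputs
scored as confidences must be inverted first (``invert_weights``). For each
cytokine, the subnetwork is the union of minimum-total-weight paths of at
most ``max_hops`` edges from each of its informative kinases to the
cytokine's gene (the anchor); all tied minimum-weight paths are kept so the
result is deterministic. A weight-threshold slider is emulated by
``prune_by_weight``: drop heavy edges, then drop nodes that lose their
connection to the anchor.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass
class CytokineSubnetwork:
    """Extracted neighborhood of one cytokine: anchor gene, member nodes,
    retained weighted edges, and per-kinase minimum path weights."""

    cytokine_id: str
    anchor: str
    graph: nx.Graph
    kinases: set[str] = field(default_factory=set)
    disconnected: set[str] = field(default_factory=set)
    path_weight: dict[str, float] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}


def load_reference_network(path, invert_weights: bool = False) -> nx.Graph:
    """Read a weighted edge list: 3-column TSV (node, node, weight) or SIF
    with the weight as the interaction field. Self-loops are rejected,
    duplicate edges collapse to the minimum weight, non-positive weights
    are a parse error carrying the line number. ``invert_weights`` maps a
    confidence score c to 1/c for inputs where higher means more likely."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 'node node weight' or SIF "
                    f"'node weight node', got {line!r}")
            # SIF puts the relation/weight in the middle column
            if _is_number(parts[1]) and not _is_number(parts[2]):
                a, w_str, b = parts[0], parts[1], parts[2]
            else:
                a, b, w_str = parts[0], parts[1], parts[2]
            try:
                w = float(w_str)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric weight {w_str!r}") from None
            if w <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive weight {w}")
            if invert_weights:
                w = 1.0 / w
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-loop on {a!r}")
            if g.has_edge(a, b):
                w = min(w, g[a][b]["weight"])
            g.add_edge(a, b, weight=w)
    return g


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_edge_list(g: nx.Graph, path) -> None:
    """Weighted 3-column TSV, edges in sorted order (round-trips through
    :func:`load_reference_network`)."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{b}\t{g[a][b]['weight']:.10g}\n")


def write_sif(g: nx.Graph, path) -> None:
    """SIF export with the edge weight as the interaction field
    (readable back by :func:`load_reference_network`)."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{g[a][b]['weight']:.10g}\t{b}\n")


def minimum_weight_paths(g: nx.Graph, source: str, target: str,
                         max_hops: int) -> tuple[float, list[list[str]]]:
    """All minimum-total-weight simple paths from source to target with at
    most ``max_hops`` edges.

    Hop-bounded Bellman-Ford-style sweep: best[h][v] is the least weight of
    any walk of exactly <= h edges to v; predecessors are kept for every
    tied optimum, and tied paths are all returned. Walks that revisit a
    node cannot beat the optimal simple path under positive weights.
    Returns (inf, []) when no qualifying path exists.
    """
    if source == target:
        return 0.0, [[source]]
    INF = float("inf")
    # best weight to each node using exactly k <= max_hops edges
    best = [{source: 0.0}]
    for _ in range(max_hops):
        prev, cur = best[-1], {}
        for u, du in prev.items():
            for v, attr in g[u].items():
                w = du + attr["weight"]
                if w < cur.get(v, INF):
                    cur[v] = w
        best.append(cur)
    opt = min((layer.get(target, INF) for layer in best), default=INF)
    if opt == INF:
        return INF, []
    # backtrack every tied path of every qualifying length
    paths: list[list[str]] = []

    def back(v: str, k: int, remaining: float, suffix: list[str]) -> None:
        if k == 0:
            if v == source and abs(remaining) <= 1e-9:
                paths.append([source] + suffix)
            return
        for u, attr in g[v].items():
            r = remaining - attr["weight"]
            if u in best[k - 1] and abs(best[k - 1][u] - r) <= 1e-9:
                back(u, k - 1, r, [v] + suffix)

    for k in range(1, max_hops + 1):
        if abs(best[k].get(target, INF) - opt) <= 1e-9:
            back(target, k, opt, [])
    # drop non-simple duplicates (possible only at weight ties through revisits)
    uniq = [p for p in paths if len(set(p)) == len(p)]
    dedup = []
    seen = set()
    for p in uniq:
        t = tuple(p)
        if t not in seen:
            seen.add(t)
            dedup.append(p)
    return opt, dedup


def extract_cytokine_network(net: nx.Graph, anchor: str, kinases,
                             max_hops: int = 2,
                             cytokine_id: str | None = None) -> CytokineSubnetwork:
    """Union of minimum-weight <= max_hops paths from each informative
    kinase to the cytokine's anchor gene. Kinases absent from the reference
    network are logged; kinases present but with no qualifying path are
    reported as disconnected."""
    if anchor not in net:
        raise KeyError(f"anchor node {anchor!r} not in reference network")
    kinases = set(kinases)
    absent = {k for k in kinases if k not in net}
    if absent:
        logger.warning("%d kinase(s) absent from reference network: %s",
                       len(absent), sorted(absent)[:5])
    sub = nx.Graph()
    sub.add_node(anchor)
    disconnected = set(absent)
    path_weight: dict[str, float] = {}
    for kin in sorted(kinases - absent):
        w, paths = minimum_weight_paths(net, kin, anchor, max_hops)
        if not paths:
            disconnected.add(kin)
            continue
        path_weight[kin] = w
        for p in paths:
            nx.add_path(sub, p)
    for a, b in sub.edges:
        sub[a][b]["weight"] = net[a][b]["weight"]
    return CytokineSubnetwork(
        cytokine_id=cytokine_id or anchor, anchor=anchor, graph=sub,
        kinases=kinases, disconnected=disconnected, path_weight=path_weight)


def prune_by_weight(sub: CytokineSubnetwork, threshold: float) -> CytokineSubnetwork:
    """Keep edges with weight <= threshold, then drop nodes no longer
    connected to the anchor. Idempotent; lower thresholds only remove."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    g = nx.Graph()
    g.add_node(sub.anchor)
    g.add_weighted_edges_from(
        (a, b, d["weight"]) for a, b, d in sub.graph.edges(data=True)
        if d["weight"] <= threshold)
    keep = (nx.node_connected_component(g, sub.anchor)
            if sub.anchor in g else {sub.anchor})
    g = g.subgraph(keep).copy()
    return CytokineSubnetwork(
        cytokine_id=sub.cytokine_id, anchor=sub.anchor, graph=g,
        kinases=sub.kinases,
        disconnected=sub.disconnected | {k for k in sub.path_weight
                                         if k not in g},
        path_weight={k: w for k, w in sub.path_weight.items() if k in g})


def subnetwork_to_json(sub: CytokineSubnetwork) -> dict:
    """Browser-renderable payload: nodes (with anchor/kinase flags) and
    weighted edges."""
    return {
        "cytokine": sub.cytokine_id,
        "anchor": sub.anchor,
        "nodes": [
            {"id": n, "is_anchor": n == sub.anchor,
             "is_kinase": n in sub.kinases}
            for n in sorted(sub.graph.nodes)
        ],
        "edges": [
            {"source": a, "target": b, "weight": sub.graph[a][b]["weight"]}
            for a, b in sorted(tuple(sorted(e)) for e in sub.graph.edges)
        ],
        "disconnected_kinases": sorted(sub.disconnected),
    }


def write_subnetwork(sub: CytokineSubnetwork, outdir,
                     formats: tuple[str, ...] = ("graphml", "json")) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    g = sub.graph.copy()
    for n in g.nodes:
        g.nodes[n]["is_anchor"] = n == sub.anchor
        g.nodes[n]["is_kinase"] = n in sub.kinases
    if "graphml" in formats:
        p = outdir / f"{sub.cytokine_id}_network.graphml"
        nx.write_graphml(g, p)
        paths.append(p)
    if "json" in formats:
        p = outdir / f"{sub.cytokine_id}_network.json"
        p.write_text(json.dumps(subnetwork_to_json(sub), indent=1))
        paths.append(p)
    return paths
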