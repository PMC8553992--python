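"""Signed correlation networks and their node metrics.

Edges are region pairs whose interregional Pearson correlation strictly
exceeds the threshold in absolute value (default |R| > 0.5), keeping the
correlation's sign as the edge weight. Two node metrics summarize each
region's role relative to a module partition:

* the modified within-module degree (mWMDz): the sum of absolute edge
  weights between a node and its module mates, divided by (module size - 1).
  It ranges 0 (no within-module edges) to 1 (|R| = 1 edges to every mate).
  Despite the historical name it is not a standardized z score — it is a
  weighted within-module connectivity fraction suited to small networks.
* the participation coefficient (PC): 1 - sum over modules s of
  (K_is / k_i)^2, where K_is counts the node's edges into module s and k_i
  its total degree. Edge *counts* are used here (both signs), not weights;
  0 means all edges stay in one module, values near 1 mean edges spread
  evenly over many modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .cluster import ModulePartition
from .coactivity import CorrelationMatrix
from .regions import RegionSet


@dataclass(frozen=True)
class SignedGraph:
    """Regions as nodes; undirected edges carrying signed Pearson weights."""

    nodes: RegionSet
    edges: dict[frozenset, float] = field(default_factory=dict)
    threshold: float = 0.5

    def __post_init__(self):
        for pair, w in self.edges.items():
            if len(pair) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(pair)}")
            a, b = sorted(pair)
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) references unknown region")
            if not abs(w) > self.threshold:
                raise ValueError(
                    f"edge ({a}, {b}) weight {w} does not exceed threshold "
                    f"{self.threshold} in absolute value"
                )
            if abs(w) > 1:
                raise ValueError(f"edge ({a}, {b}) weight {w} outside [-1, 1]")

    @classmethod
    def from_edges(cls, nodes, edge_list, threshold: float = 0.5) -> "SignedGraph":
        """Build from (region_a, region_b, weight) triples."""
        nodes = nodes if isinstance(nodes, RegionSet) else RegionSet(nodes)
        edges: dict[frozenset, float] = {}
        for a, b, w in edge_list:
            key = frozenset((a, b))
            if key in edges:
                raise ValueError(f"duplicate edge ({a}, {b})")
            edges[key] = float(w)
        return cls(nodes=nodes, edges=edges, threshold=threshold)

    def neighbors(self, node: str) -> list[tuple[str, float]]:
        out = []
        for pair, w in self.edges.items():
            if node in pair:
                (other,) = pair - {node}
                out.append((other, w))
        return out

    def degree(self, node: str) -> int:
        return sum(1 for pair in self.edges if node in pair)

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region_a": min(pair),
                "region_b": max(pair),
                "weight": w,
                "sign": "positive" if w > 0 else "negative",
            }
            for pair, w in self.edges.items()
        ]
        df = pd.DataFrame(rows, columns=["region_a", "region_b", "weight", "sign"])
        return df.sort_values(["region_a", "region_b"], ignore_index=True)


@dataclass(frozen=True)
class NodeMetrics:
    """Per-node table plus the per-module degree breakdown for audit."""

    table: pd.DataFrame  # region, module_id, within_degree, degree, mwmdz, pc
    per_module_degree: pd.DataFrame  # regions x module ids, edge counts


def threshold_edges(cm: CorrelationMatrix, threshold: float = 0.5) -> SignedGraph:
    """Keep region pairs with |R| strictly above the threshold, sign preserved.

    Pairs flagged missing in the correlation matrix (NaN sentinel) never
    become edges.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    R = cm.R
    names = list(R.columns)
    edges = []
    n_missing = 0
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = R.loc[a, b]
            if pd.isna(r):
                n_missing += 1
                continue
            if abs(r) > threshold:
                edges.append((a, b, float(r)))
    if n_missing:
        warnings.warn(
            f"{n_missing} region pair(s) had no valid correlation; no edge formed"
        )
    return SignedGraph.from_edges(cm.regions, edges, threshold=threshold)


def _check_same_regions(g: SignedGraph, p: ModulePartition) -> None:
    diff = set(g.nodes.names) ^ set(p.assignment)
    if diff:
        raise ValueError(f"graph and partition regions differ: {sorted(diff)}")


def mwmdz(g: SignedGraph, p: ModulePartition, node: str) -> float:
    """Modified within-module degree for one node.

    Sum of |weight| over edges to same-module nodes, divided by
    (module size - 1). A node alone in its module scores 0 by definition.
    """
    _check_same_regions(g, p)
    if node not in p.assignment:
        raise KeyError(node)
    module = p.assignment[node]
    size = p.module_sizes[module]
    if size == 1:
        return 0.0
    total = sum(
        abs(w) for other, w in g.neighbors(node) if p.assignment[other] == module
    )
    return total / (size - 1)


def participation_coefficient(g: SignedGraph, p: ModulePartition, node: str) -> float:
    """Participation coefficient for one node (edge counts, both signs).

    An isolated node (degree 0) returns 0 with a warning: it participates
    nowhere.
    """
    _check_same_regions(g, p)
    if node not in p.assignment:
        raise KeyError(node)
    k_i = g.degree(node)
    if k_i == 0:
        warnings.warn(f"node {node!r} has no edges; participation coefficient set to 0")
        return 0.0
    counts: dict[int, int] = {}
    for other, _w in g.neighbors(node):
        m = p.assignment[other]
        counts[m] = counts.get(m, 0) + 1
    return 1.0 - sum((k_is / k_i) ** 2 for k_is in counts.values())


def node_metrics_table(g: SignedGraph, p: ModulePartition) -> NodeMetrics:
    """mWMDz, PC, and degree breakdowns for every node."""
    _check_same_regions(g, p)
    modules = sorted(set(p.assignment.values()))
    rows = []
    breakdown = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # isolate warnings summarized below
        for node in g.nodes:
            module = p.assignment[node]
            neigh = g.neighbors(node)
            k_i = len(neigh)
            k_within = sum(1 for other, _ in neigh if p.assignment[other] == module)
            rows.append(
                {
                    "region": node,
                    "module_id": module,
                    "within_degree": k_within,
                    "degree": k_i,
                    "mwmdz": mwmdz(g, p, node),
                    "pc": participation_coefficient(g, p, node),
                }
            )
            counts = {m: 0 for m in modules}
            for other, _ in neigh:
                counts[p.assignment[other]] += 1
            breakdown.append(counts)
    isolated = [r["region"] for r in rows if r["degree"] == 0]
    if isolated:
        warnings.warn(f"isolated node(s) {isolated}: metrics set to 0")
    table = pd.DataFrame(rows)
    per_module = pd.DataFrame(breakdown, index=[r["region"] for r in rows])
    return NodeMetrics(table=table, per_module_degree=per_module)


def export_graph(g: SignedGraph, m: NodeMetrics, path, fmt: str = "graphml") -> Path:
    """Write the network with node and edge attributes.

    Nodes carry module_id, mwmdz and pc; edges carry the signed weight and
    a "positive"/"negative" sign attribute. Formats: graphml, gexf
    (both open directly in Gephi) or a plain edge list.
    """
    if fmt not in ("graphml", "gexf", "edgelist"):
        raise ValueError(f"unknown format {fmt!r}; choose graphml, gexf or edgelist")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    G = nx.Graph()
    meta = m.table.set_index("region")
    for node in g.nodes:
        G.add_node(
            node,
            module_id=int(meta.loc[node, "module_id"]),
            mwmdz=float(meta.loc[node, "mwmdz"]),
            pc=float(meta.loc[node, "pc"]),
        )
    for pair, w in sorted(g.edges.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(pair)
        G.add_edge(a, b, weight=float(w), sign="positive" if w > 0 else "negative")

    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "gexf":
        nx.write_gexf(G, path)
    else:
        nx.write_weighted_edgelist(G, path)
    return path
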