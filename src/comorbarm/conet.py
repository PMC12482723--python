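"""Per-timeframe diagnosis co-occurrence networks.

A node is a 3-character diagnosis code; its occurrence count is the number of
class transactions (patients) containing it, and its degree centrality is the
number of distinct diagnoses it co-occurs with.  An edge of weight ``w``
between two codes means ``w`` patients carried both diagnoses in that
timeframe — the within-class support of the code pair.  Graphs are exported
with these attributes (plus the occurrence share of the class denominator)
for downstream layout and rendering in Gephi.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .cohort import TransactionDB
from .errors import EmptyInputError, ParameterError, ValidationError


@dataclass
class CoNetwork:
    timeframe: str
    n_transactions: int
    occurrence: dict[str, int]
    edges: dict[tuple[str, str], int]
    degree: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.degree:
            deg = Counter()
            for a, b in self.edges:
                deg[a] += 1
                deg[b] += 1
            self.degree = {code: deg.get(code, 0) for code in self.occurrence}


@dataclass
class NodeSelection:
    """Nodes ordered by degree centrality, tie-extended at the cut rank."""

    nodes: list[str]


def build_network(db: TransactionDB, timeframe: str) -> CoNetwork:
    """Count node occurrences and pairwise co-occurrences in one class."""
    occurrence: Counter = Counter()
    edges: Counter = Counter()
    n = 0
    for t in db.transactions:
        if t.timeframe != timeframe:
            continue
        n += 1
        items = sorted(t.items)
        occurrence.update(items)
        edges.update(combinations(items, 2))
    return CoNetwork(
        timeframe=timeframe,
        n_transactions=n,
        occurrence=dict(occurrence),
        edges=dict(edges),
    )


def select_top_nodes(net: CoNetwork, k: int = 15) -> NodeSelection:
    """Top-k nodes by degree, keeping every node tied with the k-th degree.

    Ordering: degree descending, then occurrence descending, then code
    ascending.  Unlike the rule tables, the cut is extended through degree
    ties, so more than ``k`` nodes can be returned.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    ranked = sorted(
        net.occurrence,
        key=lambda c: (-net.degree[c], -net.occurrence[c], c),
    )
    if len(ranked) <= k:
        return NodeSelection(ranked)
    cut_degree = net.degree[ranked[k - 1]]
    selected = [c for i, c in enumerate(ranked) if i < k or net.degree[c] == cut_degree]
    return NodeSelection(selected)


def induced_subgraph(net: CoNetwork, selection: NodeSelection) -> CoNetwork:
    """Restrict nodes and edges to the selection; counts are unchanged."""
    keep = set(selection.nodes)
    foreign = keep - set(net.occurrence)
    if foreign:
        raise ValidationError(f"selection contains foreign nodes: {sorted(foreign)}")
    return CoNetwork(
        timeframe=net.timeframe,
        n_transactions=net.n_transactions,
        occurrence={c: n for c, n in net.occurrence.items() if c in keep},
        edges={
            pair: w
            for pair, w in net.edges.items()
            if pair[0] in keep and pair[1] in keep
        },
    )


def to_nx(net: CoNetwork) -> nx.Graph:
    # GEXF keeps only the graph name, so the class label and denominator are
    # encoded there as well as in the (GraphML-preserved) graph attributes
    g = nx.Graph(
        timeframe=net.timeframe,
        n_transactions=net.n_transactions,
        name=f"{net.timeframe}|n={net.n_transactions}",
    )
    for code, occ in sorted(net.occurrence.items()):
        share = occ / net.n_transactions if net.n_transactions else 0.0
        g.add_node(
            code,
            occurrence=occ,
            degree=net.degree[code],
            occurrence_share=round(share, 6),
        )
    for (a, b), w in sorted(net.edges.items()):
        g.add_edge(a, b, weight=w)
    return g


def from_nx(g: nx.Graph) -> CoNetwork:
    timeframe = g.graph.get("timeframe")
    n_transactions = g.graph.get("n_transactions")
    if (timeframe is None or n_transactions is None) and "|n=" in str(
        g.graph.get("name", "")
    ):
        timeframe, _, tail = str(g.graph["name"]).partition("|n=")
        n_transactions = int(tail)
    return CoNetwork(
        timeframe=timeframe or "",
        n_transactions=int(n_transactions or 0),
        occurrence={n: int(d["occurrence"]) for n, d in g.nodes(data=True)},
        edges={
            tuple(sorted((a, b))): int(d["weight"])
            for a, b, d in g.edges(data=True)
        },
    )


def export_graph(net: CoNetwork, path, fmt: str = "gexf") -> None:
    """Write the network as GEXF, GraphML or an edge CSV.

    Node attributes carry occurrence (the node-size source), degree and the
    occurrence share of the class denominator; edges carry raw co-occurrence
    weights.  GEXF and GraphML round-trip losslessly through
    :func:`read_graph`.
    """
    if not net.occurrence:
        raise EmptyInputError("refusing to export an empty network")
    fmt = fmt.lower()
    if fmt == "gexf":
        nx.write_gexf(to_nx(net), path)
    elif fmt == "graphml":
        nx.write_graphml(to_nx(net), path)
    elif fmt in ("csv", "edge-csv"):
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight"])
            for (a, b), w in sorted(net.edges.items()):
                writer.writerow([a, b, w])
    else:
        raise ParameterError(f"unknown export format {fmt!r}")


def read_graph(path, fmt: str = "gexf") -> CoNetwork:
    fmt = fmt.lower()
    if fmt == "gexf":
        return from_nx(nx.read_gexf(path))
    if fmt == "graphml":
        return from_nx(nx.read_graphml(path))
    raise ParameterError(f"unknown import format {fmt!r}")
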