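"""Co-prescription network and core-treatment identification.

The retained rules form an undirected simple graph: one node per CHM item
appearing in at least one retained rule (annotated with kind, prevalence
and degree), one edge per rule (annotated with support, reported confidence
and the co-prescription count). Degree — the number of retained rules a CHM
participates in — is the centrality the analysis reads off the network:
a high-degree, high-prevalence node sits at the center and anchors the
*core treatment*, together with the strongest retained edge.

The visual arrangement of any published figure is out of scope; the graph
is exported as GraphML and an edge-list TSV for downstream layout or
alternative centralities.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from ._util import pct
from .errors import ValidationError
from .mining import PairRule

__all__ = [
    "CoreTreatment", "build_network", "identify_core",
    "prevalent_unconnected", "write_graphml", "write_edgelist_tsv",
]


@dataclass(frozen=True)
class CoreTreatment:
    """The center of the network, made reproducible.

    ``core_nodes``: the items maximizing (degree, prevalence), ties broken
    by identifier — all tied maximizers, in id order.
    ``core_edge``: the retained rule maximizing (support, reported
    confidence), ties broken by pair id.
    """

    core_nodes: tuple[str, ...]
    core_edge: tuple[str, str]
    edge_support: float
    edge_confidence: float

    def to_dict(self) -> dict:
        return {"core_nodes": list(self.core_nodes),
                "core_edge": list(self.core_edge),
                "edge_support": self.edge_support,
                "edge_confidence": self.edge_confidence}


def build_network(rules: Sequence[PairRule],
                  item_counts: Mapping[str, int] | None = None,
                  n_total: int | None = None,
                  kinds: Mapping[str, str] | None = None) -> nx.Graph:
    """Build the undirected co-prescription graph from retained rules.

    Node attributes: ``kind`` (HF/SH/empty), ``prevalence`` (fraction of
    prescriptions containing the item, 0.0 when counts are not supplied),
    ``degree``. Edge attributes: ``support``, ``confidence``, ``n_ab``.
    An empty rule set yields an empty graph with a warning.
    """
    G = nx.Graph()
    if not rules:
        warnings.warn("building a network from an empty rule set",
                      stacklevel=2)
        return G
    item_counts = item_counts or {}
    kinds = kinds or {}
    for rule in rules:
        if rule.item_a == rule.item_b:
            raise ValidationError(f"self-loop rule on {rule.item_a}")
        G.add_edge(rule.item_a, rule.item_b, support=rule.support,
                   confidence=rule.reported_confidence, n_ab=rule.n_ab)
    n_total = n_total or (rules[0].n_total if rules else 0)
    for node in G.nodes:
        G.nodes[node]["kind"] = kinds.get(node, "")
        G.nodes[node]["prevalence"] = (
            item_counts.get(node, 0) / n_total if n_total else 0.0)
        G.nodes[node]["degree"] = G.degree[node]
    return G


def identify_core(G: nx.Graph) -> CoreTreatment:
    """Pick the core treatment deterministically.

    Invariant under node/edge insertion order. Raises ValidationError on an
    empty network (there is no core to identify).
    """
    if G.number_of_edges() == 0:
        raise ValidationError("cannot identify a core in an empty network")
    best_nodes = sorted(
        G.nodes,
        key=lambda v: (-G.degree[v], -G.nodes[v].get("prevalence", 0.0), v))
    top = best_nodes[0]
    top_key = (G.degree[top], G.nodes[top].get("prevalence", 0.0))
    core_nodes = tuple(sorted(
        v for v in G.nodes
        if (G.degree[v], G.nodes[v].get("prevalence", 0.0)) == top_key))

    def edge_key(e):
        a, b = sorted(e[:2])
        d = G.edges[e[0], e[1]]
        return (-d["support"], -d.get("confidence", 0.0), a, b)

    a, b = sorted(min(G.edges, key=edge_key)[:2])
    d = G.edges[a, b]
    return CoreTreatment(core_nodes=core_nodes, core_edge=(a, b),
                         edge_support=d["support"],
                         edge_confidence=d.get("confidence", 0.0))


def prevalent_unconnected(item_counts: Mapping[str, int], n_total: int,
                          G: nx.Graph, min_prevalence: float = 0.05
                          ) -> pd.DataFrame:
    """Items prevalent enough to matter yet absent from the network.

    CHM prescribed in >= ``min_prevalence`` of prescriptions but appearing
    in no retained rule — common items that attach to no stable partner
    (the classic example being a broadly-indicated formula prescribed on
    its own). Returned sorted by prevalence descending.
    """
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    rows = [(item, n, pct(n, n_total))
            for item, n in item_counts.items()
            if n / n_total >= min_prevalence and item not in G.nodes]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["item_id", "n", "prevalence_pct"])


def write_graphml(G: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(G, str(path))


def write_edgelist_tsv(G: nx.Graph, path: str | Path) -> None:
    rows = [{"item_a": min(a, b), "item_b": max(a, b), **d}
            for a, b, d in G.edges(data=True)]
    frame = pd.DataFrame(rows, columns=["item_a", "item_b", "support",
                                        "confidence", "n_ab"])
    frame = frame.sort_values(["item_a", "item_b"]).reset_index(drop=True)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
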