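"""Glycan co-occurrence networks.

Two compositions co-occur when they are both identified at the same
glycosylation site — (protein, Asn position) within a sample.  Each site
contributes each unordered pair at most once (set semantics: how many
glycopeptides at that site carry the pair is irrelevant), and edges observed
at fewer than ``min_weight`` sites are dropped, the default threshold being
three sites.
"""

from __future__ import annotations

from collections import defaultdict
from itertools import combinations

import networkx as nx
import pandas as pd

from .assembly import IntactGlycopeptide
from .glycans import classify, parse_composition

__all__ = ["cooccurrence", "cooccurrence_graph", "ego_network", "edge_table", "node_table"]


def cooccurrence(
    records: list[IntactGlycopeptide],
    min_weight: int = 3,
    pooled: bool = False,
) -> dict[str, list[tuple[str, str, int]]]:
    """Per-sample edge lists: (composition_a, composition_b, weight).

    Weight = number of sites where both compositions were identified.  With
    ``pooled`` a single network over all samples is returned under the key
    ``"pooled"`` (sites remain keyed by (protein, position) and are counted
    once per sample they appear in).
    """
    site_comps: dict[tuple, set[str]] = defaultdict(set)
    for r in records:
        sample = "pooled" if pooled else r.sample_id
        site_comps[(sample, r.sample_id, r.protein_id, r.site)].add(r.composition_key)
    weights: dict[str, dict[tuple[str, str], int]] = defaultdict(lambda: defaultdict(int))
    for r in records:
        weights["pooled" if pooled else r.sample_id]  # ensure every sample has an entry
    for (sample, _, _, _), comps in site_comps.items():
        for a, b in combinations(sorted(comps), 2):
            weights[sample][(a, b)] += 1
    return {
        sample: sorted(
            (a, b, w) for (a, b), w in pairs.items() if w >= min_weight
        )
        for sample, pairs in sorted(weights.items())
    }


def cooccurrence_graph(edges: list[tuple[str, str, int]]) -> nx.Graph:
    """Weighted undirected graph; nodes annotated with glycan class."""
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    for node in g.nodes:
        try:
            cls = classify(parse_composition(node.split(" [", 1)[0]))
            g.nodes[node]["glycan_class"] = cls.type_label
            g.nodes[node]["fucosylated"] = cls.fucosylated
            g.nodes[node]["sialylated"] = cls.sialylated
        except Exception:
            g.nodes[node]["glycan_class"] = "unknown"
    return g


def ego_network(edges: list[tuple[str, str, int]], center: str) -> nx.Graph:
    """Subgraph of edges incident to ``center``; empty when center is absent.

    Neighbor nodes carry their glycan class as an attribute (the quantity the
    published arc diagrams encode as edge colour).
    """
    g = cooccurrence_graph(edges)
    if center not in g:
        return nx.Graph()
    return g.subgraph([center, *g.neighbors(center)]).edge_subgraph(
        [(center, n) for n in g.neighbors(center)]
    ).copy()


def edge_table(per_sample_edges: dict[str, list[tuple[str, str, int]]]) -> pd.DataFrame:
    rows = [
        {"sample_id": sample, "comp_a": a, "comp_b": b, "weight": w}
        for sample, edges in per_sample_edges.items()
        for a, b, w in edges
    ]
    return pd.DataFrame(rows, columns=["sample_id", "comp_a", "comp_b", "weight"])


def node_table(per_sample_edges: dict[str, list[tuple[str, str, int]]]) -> pd.DataFrame:
    rows = []
    for sample, edges in per_sample_edges.items():
        g = cooccurrence_graph(edges)
        for node in sorted(g.nodes):
            rows.append(
                {
                    "sample_id": sample,
                    "composition": node,
                    "glycan_class": g.nodes[node].get("glycan_class", "unknown"),
                    "degree": g.degree(node),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "composition", "glycan_class", "degree"])
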