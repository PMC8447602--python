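"""Bait-prey interaction network assembly and known/novel annotation.

Significant interactor calls from every bait are merged into one undirected
graph: a prey pulled down by two baits appears once, with degree 2,
connecting the two pull-down experiments.  Prey nodes are annotated as
*known* (the bait-prey pair occurs in a user-supplied offline reference
list of published interactions) or *novel*; the list replaces any live
database query so builds stay hermetic.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = [
    "build_network",
    "read_known_pairs",
    "annotate_known",
    "write_edge_list",
    "write_graphml",
]


def build_network(calls: dict[str, pd.DataFrame]) -> nx.Graph:
    """Assemble the multi-bait network from per-bait call tables.

    ``calls`` maps bait_id to a call table carrying ``protein_id``,
    ``log2_difference``, ``q_value`` and ``significant``.  One node per
    distinct protein (role ``bait``, ``prey`` or ``both``), one edge per
    significant (bait, prey) pair; a bait recovered as its own prey yields
    a self-loop.  Node ordering is deterministic (baits in input order,
    then preys sorted).
    """
    g = nx.Graph()
    for bait_id in calls:
        g.add_node(bait_id, role="bait", novelty="bait")
    edges = []
    for bait_id, table in calls.items():
        sig = table[table["significant"]]
        for _, row in sig.iterrows():
            edges.append((bait_id, row["protein_id"],
                          float(row["log2_difference"]), float(row["q_value"])))
    for _, prey, _, _ in sorted(edges, key=lambda e: (e[1], e[0])):
        if prey not in g:
            g.add_node(prey, role="prey", novelty="novel")
        elif g.nodes[prey]["role"] == "bait":
            g.nodes[prey]["role"] = "both"
    for bait_id, prey, diff, q in edges:
        g.add_edge(bait_id, prey, bait_id=bait_id, prey_id=prey,
                   log2_difference=diff, q_value=q)
    return g


def read_known_pairs(path) -> set[frozenset]:
    """Parse an offline two-column TSV of unordered known-interaction pairs.

    Lines starting with '#' are comments.  A malformed row raises an error
    naming the line number.
    """
    pairs: set[frozenset] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"malformed known-pair row at line {lineno}: {line!r}")
            pairs.add(frozenset((fields[0], fields[1])))
    return pairs


def annotate_known(network: nx.Graph, known_pairs: set[frozenset]) -> nx.Graph:
    """Label prey nodes known/novel from the reference pair list.

    A prey is *known* iff its unordered (bait, prey) pair occurs in
    ``known_pairs`` for at least one bait that called it.  Matching is
    orientation-insensitive.  Topology is never altered; repeated
    annotation is idempotent.
    """
    for node, data in network.nodes(data=True):
        if data.get("novelty") == "bait":
            continue
        hit = any(frozenset((network.edges[e]["bait_id"], node)) in known_pairs
                  for e in network.edges(node))
        network.nodes[node]["novelty"] = "known" if hit else "novel"
    return network


def write_edge_list(network: nx.Graph, path) -> None:
    rows = [{"bait_id": d["bait_id"], "prey_id": d["prey_id"],
             "log2_difference": d["log2_difference"], "q_value": d["q_value"]}
            for _, _, d in network.edges(data=True)]
    pd.DataFrame(rows, columns=["bait_id", "prey_id", "log2_difference",
                                "q_value"]).sort_values(
        ["bait_id", "prey_id"]).to_csv(path, sep="\t", index=False)


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, path)
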