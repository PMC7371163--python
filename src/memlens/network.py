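"""Undirected protein-residue / lipid-molecule interaction networks.

Nodes are protein residues and individual lipid molecules; an undirected
edge joins a residue to a lipid molecule when their window-mean atom-pair
contact count reaches the inclusion threshold (default 1.0).  The graph is
bipartite by construction — there are no residue-residue or lipid-lipid
edges — and "clusters" are its connected components.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .errors import MemlensError

__all__ = [
    "InteractionNetwork",
    "residue_node",
    "lipid_node",
    "build_network",
    "components",
    "export_network",
    "read_graphml",
]


def residue_node(chain: str, residue_number: int) -> str:
    return f"res:{chain}:{residue_number}"


def lipid_node(species: str, molecule_id: int) -> str:
    return f"lip:{species}:{molecule_id}"


@dataclass
class InteractionNetwork:
    """Thin wrapper over a networkx Graph with bipartite conventions."""

    graph: nx.Graph

    @property
    def residue_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "residue"]

    @property
    def lipid_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "lipid"]

    def degree(self, node: str) -> int:
        return int(self.graph.degree[node])

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    edge_stats: pd.DataFrame,
    inclusion_threshold: float = 1.0,
    strict: bool = False,
) -> InteractionNetwork:
    """Build the interaction network from a per-(residue, lipid) edge table.

    *edge_stats* needs columns ``chain``, ``residue_number``, ``domain``,
    ``lipid_molecule``, ``species`` and ``mean_contacts`` (the output of
    :func:`memlens.statistics.pair_mean_contacts`).  An edge is created
    when ``mean_contacts >= inclusion_threshold`` (or strictly greater
    with *strict*); isolated nodes are not added, so every node in the
    graph carries at least one edge.
    """
    if inclusion_threshold < 0:
        raise MemlensError("inclusion_threshold must be non-negative")
    g = nx.Graph()
    for row in edge_stats.itertuples(index=False):
        w = float(row.mean_contacts)
        if (w > inclusion_threshold) if strict else (w >= inclusion_threshold):
            rnode = residue_node(str(row.chain), int(row.residue_number))
            lnode = lipid_node(str(row.species), int(row.lipid_molecule))
            g.add_node(
                rnode,
                kind="residue",
                chain=str(row.chain),
                residue_number=int(row.residue_number),
                domain=str(row.domain),
            )
            g.add_node(
                lnode,
                kind="lipid",
                species=str(row.species),
                molecule_id=int(row.lipid_molecule),
            )
            g.add_edge(rnode, lnode, weight=w)
    return InteractionNetwork(graph=g)


def components(network: InteractionNetwork) -> list[list[str]]:
    """Connected components (clusters), largest first.

    Deterministic order: node count descending, then the lexicographically
    smallest member node id; nodes within a component are sorted.
    """
    comps = [sorted(c) for c in nx.connected_components(network.graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def _annotate(network: InteractionNetwork) -> nx.Graph:
    g = network.graph.copy()
    for node in g.nodes:
        g.nodes[node]["degree"] = int(g.degree[node])
    for cid, comp in enumerate(components(network)):
        for node in comp:
            g.nodes[node]["component"] = cid
    return g


def export_network(
    network: InteractionNetwork, path: str | Path, format: str = "graphml"
) -> None:
    """Write the network as GraphML, SIF, or an edge-list CSV.

    GraphML carries node attributes (kind, chain/residue or species/
    molecule, degree, component id) and edge weights and loads directly
    into Cytoscape; SIF uses the interaction type ``contact``.
    """
    path = Path(path)
    fmt = format.lower()
    g = _annotate(network)
    if fmt == "graphml":
        nx.write_graphml(g, str(path))
    elif fmt == "sif":
        lines = [
            f"{u}\tcontact\t{v}"
            for u, v in sorted(map(lambda e: tuple(sorted(e)), g.edges))
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt in ("csv", "edge-csv"):
        rows = [
            {"source": u, "target": v, "weight": g.edges[u, v]["weight"]}
            for u, v in sorted(map(lambda e: tuple(sorted(e)), g.edges))
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            path, index=False
        )
    else:
        raise MemlensError(
            f"unknown network format {format!r}; use graphml, sif or csv"
        )


def read_graphml(path: str | Path) -> InteractionNetwork:
    """Load a GraphML file written by :func:`export_network`."""
    return InteractionNetwork(graph=nx.read_graphml(str(path)))
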