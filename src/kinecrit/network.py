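"""Graph views of a kinetic model and knockout-to-entity distances.

Two views are used. The metabolite-centric view is the bipartite
metabolite-reaction structure: metabolites participating in the deleted
reaction sit at distance 1; metabolites sharing a reaction with a
distance-k metabolite sit at distance k+1. The enzyme-centric view is a
directed graph with an edge from enzyme A to enzyme B whenever one of A's
products is one of B's substrates; distances from the deleted enzyme are
counted on this graph ignoring edge direction by default, because
influence in the kinetic equations also propagates against flux direction.

Distances are always computed on the original (intact) topology: they
measure how far from the deletion site an effect lands on the map, not the
connectivity of the residual network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .model import KineticModel

__all__ = ["DistanceMap", "metabolite_distances", "enzyme_graph", "enzyme_distances"]


@dataclass
class DistanceMap:
    """Distances of entities from a deleted enzyme.

    ``d`` maps entity id to a positive integer distance; entities that
    cannot be reached from the origin carry ``None`` (an explicit
    unreachable marker, never a fake large number).
    """

    origin: str
    entity_kind: str  # "metabolite" | "reaction"
    d: dict[str, int | None]

    def as_array(self, order: list[str]) -> np.ndarray:
        """Distances in a given entity order; unreachable become ``inf``."""
        return np.array(
            [np.inf if self.d.get(k) is None else float(self.d[k]) for k in order]
        )

    @property
    def reachable(self) -> dict[str, int]:
        return {k: v for k, v in self.d.items() if v is not None}


def _bipartite_graph(model: KineticModel, include_modifiers: bool) -> nx.Graph:
    g = nx.Graph()
    for m in model.metabolites:
        g.add_node(("m", m.id))
    for r in model.reactions:
        g.add_node(("r", r.id))
        linked = set(r.participant_ids)
        if include_modifiers:
            linked |= {mid for mid, _ in r.modifiers}
        for mid in linked:
            g.add_edge(("r", r.id), ("m", mid))
    return g


def metabolite_distances(
    model: KineticModel,
    enzyme_id: str,
    include_modifiers: bool = True,
) -> DistanceMap:
    """Breadth-first metabolite distances from a deleted reaction.

    ``include_modifiers`` counts regulatory (inhibitor/activator) edges as
    direct association, since they enter the rate laws like substrates do.
    """
    if enzyme_id not in model.rxn_by_id:
        raise LookupError(f"unknown enzyme/reaction id {enzyme_id!r}")
    g = _bipartite_graph(model, include_modifiers)
    lengths = nx.single_source_shortest_path_length(g, ("r", enzyme_id))
    d: dict[str, int | None] = {}
    for m in model.metabolites:
        bip = lengths.get(("m", m.id))
        # metabolite nodes are at odd bipartite depth: depth 1 -> distance 1,
        # depth 3 -> distance 2, ...
        d[m.id] = None if bip is None else (bip + 1) // 2
    return DistanceMap(origin=enzyme_id, entity_kind="metabolite", d=d)


def enzyme_graph(model: KineticModel) -> nx.DiGraph:
    """Directed reaction graph: A -> B if a product of A is a substrate of B."""
    g = nx.DiGraph()
    g.add_nodes_from(model.reaction_ids)
    producers: dict[str, set[str]] = {}
    for r in model.reactions:
        for mid, _ in r.products:
            producers.setdefault(mid, set()).add(r.id)
    for r in model.reactions:
        for mid, _ in r.substrates:
            for src in producers.get(mid, ()):  # noqa: B905
                if src != r.id:
                    g.add_edge(src, r.id)
    return g


def enzyme_distances(
    model: KineticModel,
    enzyme_id: str,
    directed: bool = False,
) -> DistanceMap:
    """BFS distances of every reaction from the deleted enzyme.

    Direction is ignored by default (see module docstring); set
    ``directed=True`` to count only along flux direction.
    """
    if enzyme_id not in model.rxn_by_id:
        raise LookupError(f"unknown enzyme/reaction id {enzyme_id!r}")
    g: nx.Graph | nx.DiGraph = enzyme_graph(model)
    if not directed:
        g = g.to_undirected()
    lengths = nx.single_source_shortest_path_length(g, enzyme_id)
    d: dict[str, int | None] = {}
    for rid in model.reaction_ids:
        if rid == enzyme_id:
            continue  # the origin carries no distance of its own
        d[rid] = lengths.get(rid)
    return DistanceMap(origin=enzyme_id, entity_kind="reaction", d=d)
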