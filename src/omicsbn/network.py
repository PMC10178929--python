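"""DAG structures over typed omics nodes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .datasets import GE, CandidateEdgeSet, LayerDefinition, Node
from .errors import ContractError


@dataclass
class NetworkStructure:
    """A directed acyclic graph over typed (GE/CNV/METH) nodes.

    Edges must be drawn from a :class:`CandidateEdgeSet`; layer fan-in
    limits are enforced by :meth:`validate` and by the sampler.
    """

    nodes: tuple[Node, ...]
    edges: set = field(default_factory=set)

    def __post_init__(self):
        self.edges = set(self.edges)
        self._layer = {n.id: n.layer for n in self.nodes}

    @classmethod
    def empty(cls, candidates: CandidateEdgeSet) -> "NetworkStructure":
        return cls(nodes=candidates.nodes, edges=set())

    def layer_of(self, node_id: str) -> str:
        return self._layer[node_id]

    def parents_of(self, node_id: str) -> frozenset[str]:
        return frozenset(u for u, v in self.edges if v == node_id)

    def children_of(self, node_id: str) -> frozenset[str]:
        return frozenset(v for u, v in self.edges if u == node_id)

    def copy(self) -> "NetworkStructure":
        return NetworkStructure(nodes=self.nodes, edges=set(self.edges))

    def add_edge(self, u: str, v: str) -> None:
        self.edges.add((u, v))

    def remove_edge(self, u: str, v: str) -> None:
        self.edges.discard((u, v))

    def reverse_edge(self, u: str, v: str) -> None:
        self.edges.discard((u, v))
        self.edges.add((v, u))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.id, layer=n.layer)
        g.add_edges_from(self.edges)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def fan_in_ok(self, layers: LayerDefinition) -> bool:
        for n in self.nodes:
            counts: dict[str, int] = {}
            for u in self.parents_of(n.id):
                counts[self._layer[u]] = counts.get(self._layer[u], 0) + 1
            for lay, c in counts.items():
                if lay not in layers.names or c > layers.fan_in(lay):
                    return False
        return True

    def validate(self, candidates: Optional[CandidateEdgeSet] = None,
                 layers: Optional[LayerDefinition] = None) -> "NetworkStructure":
        if candidates is not None:
            bad = self.edges - set(candidates.edges)
            if bad:
                raise ContractError(f"edges outside the candidate set: {sorted(bad)}")
        for u, v in self.edges:
            if self._layer[v] != GE:
                raise ContractError(f"non-GE node {v} cannot have parents ({u}->{v})")
        if not self.is_acyclic():
            raise ContractError("structure contains a directed cycle")
        if layers is not None and not self.fan_in_ok(layers):
            raise ContractError("structure violates a layer fan-in limit")
        return self

    def __eq__(self, other) -> bool:
        return (isinstance(other, NetworkStructure)
                and self.nodes == other.nodes and self.edges == other.edges)

    def __hash__(self):
        return hash((self.nodes, frozenset(self.edges)))
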