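"""The undirected Hamming-1 state transition graph over observed states.

Vertices are the distinct binarized expression states; two states are joined
iff they differ in exactly one gene, and the edge is labelled with that gene.
For each gene v, the boundary set N_v collects the states whose v-flip leaves
the observed state space; the synthesis threshold is applied against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .core import BinaryState, GeneSet, flip_bit, state_to_string
from .errors import InfeasibleError
from .expression_io import ClassSpec, ExpressionDataset


@dataclass(frozen=True)
class NodeInfo:
    multiplicity: int
    classes: tuple  # multiset of class labels as a sorted tuple


@dataclass
class StateGraph:
    genes: GeneSet
    nodes: dict  # BinaryState -> NodeInfo
    edges: set  # frozenset({s1, s2}) pairs; label derivable from the flip

    def edge_label(self, s1: BinaryState, s2: BinaryState) -> str:
        (i,) = [k for k in range(self.genes.n) if s1[k] != s2[k]]
        return self.genes.names[i]

    def neighbours(self, s: BinaryState):
        """(gene, neighbour) pairs present in the node set, in gene order."""
        out = []
        for i, g in enumerate(self.genes.names):
            t = flip_bit(s, i)
            if t in self.nodes:
                out.append((g, t))
        return out


@dataclass(frozen=True)
class BoundarySet:
    gene: str
    states: frozenset


def build_state_graph(ds: ExpressionDataset, spec: ClassSpec):
    """Deduplicate states, join Hamming-1 pairs, and map classes to I/F.

    Returns ``(graph, initial_states, target_states)``.  A state observed
    under both an initial and a target class belongs to both sets.
    """
    mult: dict = {}
    classes: dict = {}
    for c in ds.cells:
        mult[c.state] = mult.get(c.state, 0) + 1
        classes.setdefault(c.state, []).append(c.class_label)
    nodes = {s: NodeInfo(mult[s], tuple(sorted(classes[s]))) for s in mult}

    edges = set()
    for s in nodes:
        for i in range(ds.genes.n):
            t = flip_bit(s, i)
            if t in nodes:
                edges.add(frozenset((s, t)))
    g = StateGraph(genes=ds.genes, nodes=nodes, edges=edges)

    initial = {s for s, info in nodes.items() if set(info.classes) & spec.initial_classes}
    target = {s for s, info in nodes.items() if set(info.classes) & spec.target_classes}
    if not initial:
        raise InfeasibleError(f"no states in initial classes {sorted(spec.initial_classes)}")
    if not target:
        raise InfeasibleError(f"no states in target classes {sorted(spec.target_classes)}")
    return g, frozenset(initial), frozenset(target)


def boundary_states(g: StateGraph, gene: str) -> BoundarySet:
    """States without a gene-labelled edge: their flip is unobserved."""
    i = g.genes.index(gene)
    states = frozenset(s for s in g.nodes if flip_bit(s, i) not in g.nodes)
    return BoundarySet(gene=gene, states=states)


@dataclass
class GraphSummary:
    n_nodes: int
    n_edges: int
    class_node_counts: dict
    n_isolated: int
    n_components: int


def graph_summary(g: StateGraph) -> GraphSummary:
    nxg = to_networkx(g)
    class_counts: dict = {}
    for info in g.nodes.values():
        for label in set(info.classes):
            class_counts[label] = class_counts.get(label, 0) + 1
    return GraphSummary(
        n_nodes=len(g.nodes),
        n_edges=len(g.edges),
        class_node_counts=class_counts,
        n_isolated=sum(1 for s in g.nodes if not g.neighbours(s)),
        n_components=nx.number_connected_components(nxg),
    )


def to_networkx(g: StateGraph) -> nx.Graph:
    nxg = nx.Graph()
    for s, info in g.nodes.items():
        nxg.add_node(
            state_to_string(s),
            multiplicity=info.multiplicity,
            classes=",".join(info.classes),
        )
    for e in g.edges:
        s1, s2 = sorted(e)
        nxg.add_edge(state_to_string(s1), state_to_string(s2), gene=g.edge_label(s1, s2))
    return nxg


def write_edge_list(g: StateGraph, path) -> None:
    """Plain-text edge list: bitstring, bitstring, gene label per line."""
    with open(path, "w") as fh:
        for e in sorted(g.edges, key=sorted):
            s1, s2 = sorted(e)
            fh.write(f"{state_to_string(s1)}\t{state_to_string(s2)}\t{g.edge_label(s1, s2)}\n")


def write_graphml(g: StateGraph, path) -> None:
    nx.write_graphml(to_networkx(g), Path(path))
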