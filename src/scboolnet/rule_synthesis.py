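"""Three-phase synthesis of per-gene Boolean update rules.

Phase 1 orients the undirected Hamming-1 graph by keeping only edge
directions realisable by some function in the monotone activator/repressor
family (enumerative single-witness check).  Phase 2 finds, for every
(initial, final) state pair, the shortest directed path by BFS.  Phase 3
searches, gene by gene, for every update rule u = f1 AND NOT f2 within the
per-gene activator/repressor bounds that (condition 1) reproduces each
gene-labelled edge on the chosen paths and (condition 2) is self-consistent
on at least the threshold fraction of the gene's boundary set.

The phase-3 search is a pruned enumeration over candidate monotone
structures with bitmask evaluation; it returns the complete, semantically
deduplicated rule set for each gene.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path as _FsPath
from typing import Iterable, Optional

import pandas as pd

from .boolfunc import UpdateRule, enumerate_candidate_functions, rule_truth_key
from .core import BinaryState, GeneSet, flip_bit, state_to_string
from .errors import FormatError, InfeasibleError
from .state_graph import BoundarySet, StateGraph, boundary_states


@dataclass(frozen=True)
class GeneParameters:
    """Per-gene search bounds: a_i activators, r_i repressors, threshold %."""

    gene: str
    max_activators: int
    max_repressors: int
    threshold_percent: float

    def __post_init__(self):
        if self.max_activators < 1:
            raise ValueError(f"{self.gene}: at least one activator is required")
        if self.max_repressors < 0:
            raise ValueError(f"{self.gene}: repressor bound must be >= 0")
        if not 0 <= self.threshold_percent <= 100:
            raise ValueError(f"{self.gene}: threshold must be in [0, 100]")


#: Column headers of the parameters CSV (one row per gene).
PARAMETER_COLUMNS = ("Gene", "Number of activators", "Number of repressors", "Threshold %")


def read_parameters_csv(path) -> dict:
    """Load a per-gene parameter table (columns as in PARAMETER_COLUMNS)."""
    df = pd.read_csv(_FsPath(path), skipinitialspace=True)
    missing = [c for c in PARAMETER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing parameter column(s) {missing}")
    params = {}
    for _, row in df.iterrows():
        g = str(row["Gene"]).strip()
        params[g] = GeneParameters(
            gene=g,
            max_activators=int(row["Number of activators"]),
            max_repressors=int(row["Number of repressors"]),
            threshold_percent=float(row["Threshold %"]),
        )
    return params


def write_parameters_csv(params: dict, path) -> None:
    rows = [
        [p.gene, p.max_activators, p.max_repressors, p.threshold_percent]
        for p in params.values()
    ]
    pd.DataFrame(rows, columns=list(PARAMETER_COLUMNS)).to_csv(path, index=False)


@dataclass
class DirectedStateGraph:
    genes: GeneSet
    nodes: frozenset
    successors: dict  # BinaryState -> tuple of (gene, BinaryState), lex-sorted

    def edges(self):
        for s1, outs in self.successors.items():
            for gene, s2 in outs:
                yield (s1, s2, gene)


def orient_edges(g: StateGraph, params: dict) -> DirectedStateGraph:
    """Phase 1: keep a direction iff some in-family function realises it.

    For a 0->1 flip a monotone, constant-free f1 can fire only if some gene
    is ON in the source state.  For a 1->0 flip either a repressor may fire
    (needs r_v >= 1 and an ON gene — always present, the gene itself is ON)
    or f1 can evaluate false (needs an OFF gene in the source).
    """
    for gname in g.genes:
        if gname not in params:
            raise FormatError(f"no parameters given for gene {gname!r}")
    successors: dict = {}
    for s in g.nodes:
        any_on = any(s)
        any_off = not all(s)
        outs = []
        for gene, t in g.neighbours(s):
            i = g.genes.index(gene)
            if s[i] == 0:  # 0 -> 1: need a candidate activator ON
                keep = any_on
            else:  # 1 -> 0: repressor, or f1 false
                keep = (params[gene].max_repressors >= 1 and any_on) or any_off
            if keep:
                outs.append((gene, t))
        successors[s] = tuple(sorted(outs, key=lambda gt: gt[1]))
    return DirectedStateGraph(genes=g.genes, nodes=frozenset(g.nodes), successors=successors)


@dataclass(frozen=True)
class StatePath:
    """A shortest initial -> final path in the directed state graph."""

    states: tuple

    @property
    def initial(self) -> BinaryState:
        return self.states[0]

    @property
    def final(self) -> BinaryState:
        return self.states[-1]

    def edges(self, genes: GeneSet):
        for s1, s2 in zip(self.states, self.states[1:]):
            (i,) = [k for k in range(genes.n) if s1[k] != s2[k]]
            yield (s1, s2, genes.names[i])


@dataclass
class ReachabilityReport:
    unreachable_finals: tuple
    n_pairs_connected: int

    def ok(self) -> bool:
        return not self.unreachable_finals


def shortest_paths(G: DirectedStateGraph, initial: Iterable[BinaryState], final: Iterable[BinaryState]):
    """Phase 2: one shortest path per connected (i, f) pair.

    Deterministic tie-break: among equal-length paths the lexicographically
    smallest state sequence is returned (backward BFS distances + greedy
    lex-minimal forward walk).  Raises InfeasibleError if some final state
    is unreachable from every initial state.

    Returns ``(paths, report)``.
    """
    initial = sorted(set(initial))
    final = sorted(set(final))
    predecessors: dict = {s: [] for s in G.nodes}
    for s1, outs in G.successors.items():
        for _, s2 in outs:
            predecessors[s2].append(s1)

    paths = []
    unreachable = []
    n_pairs = 0
    for f in final:
        dist = {f: 0}
        queue = deque([f])
        while queue:
            cur = queue.popleft()
            for p in predecessors[cur]:
                if p not in dist:
                    dist[p] = dist[cur] + 1
                    queue.append(p)
        reached_from_any = False
        for i in initial:
            if i not in dist:
                continue
            reached_from_any = True
            n_pairs += 1
            states = [i]
            cur = i
            while cur != f:
                nxt = min(
                    s2 for _, s2 in G.successors[cur] if dist.get(s2, -1) == dist[cur] - 1
                )
                states.append(nxt)
                cur = nxt
            paths.append(StatePath(states=tuple(states)))
        if not reached_from_any:
            unreachable.append(f)

    report = ReachabilityReport(unreachable_finals=tuple(unreachable), n_pairs_connected=n_pairs)
    if unreachable:
        raise InfeasibleError(
            "final state(s) unreachable from every initial state: "
            + ", ".join(state_to_string(s) for s in unreachable)
            + " — loosen parameters or revisit class selection",
            report=report,
        )
    return paths, report


@dataclass
class SynthesisConstraint:
    """Everything phase 3 needs for one gene."""

    gene: str
    hard_points: dict  # BinaryState -> required output (0/1)
    boundary: BoundarySet
    min_self_consistent: int


def build_constraints(
    paths: list, g: StateGraph, gene: str, p: GeneParameters
) -> SynthesisConstraint:
    """Collect path hard points and the boundary self-consistency quota.

    Condition 1: each gene-labelled path edge (s1, s2) demands
    u(s1) = s2(gene).  Condition 2: u must agree with s(gene) on at least
    ceil(threshold% x |N_gene|) boundary states.
    """
    idx = g.genes.index(gene)
    hard_points: dict = {}
    for path in paths:
        for s1, s2, label in path.edges(g.genes):
            if label != gene:
                continue
            required = s2[idx]
            assert hard_points.get(s1, required) == required  # flip targets are unique
            hard_points[s1] = required
    boundary = boundary_states(g, gene)
    quota = math.ceil(p.threshold_percent * len(boundary.states) / 100.0 - 1e-9)
    return SynthesisConstraint(
        gene=gene,
        hard_points=hard_points,
        boundary=boundary,
        min_self_consistent=max(quota, 0),
    )


def _masks(formula, states, genes):
    """Evaluate a monotone formula over a state list as an int bitmask."""
    mask = 0
    idx = genes.index
    for k, s in enumerate(states):
        if any(all(s[idx(v)] for v in term) for term in formula.terms):
            mask |= 1 << k
    return mask


def synthesize_gene_rules(
    c: SynthesisConstraint, p: GeneParameters, genes: GeneSet
) -> list[UpdateRule]:
    """Phase 3 for one gene: the complete deduplicated compatible rule set.

    Enumerates candidate (f1, f2) structures within the bounds, prunes f1
    candidates that already violate a positive hard point, checks the
    remaining pairs against hard points and the boundary quota on bitmasks,
    and deduplicates semantically (truth-table key over essential
    variables).  An empty list means the parameters are too tight.
    """
    idx = genes.index(c.gene)
    states = sorted(set(c.hard_points) | set(c.boundary.states))
    pos = {s: k for k, s in enumerate(states)}

    hp1 = sum(1 << pos[s] for s, req in c.hard_points.items() if req == 1)
    hp0 = sum(1 << pos[s] for s, req in c.hard_points.items() if req == 0)
    boundary_mask = sum(1 << pos[s] for s in c.boundary.states)
    self_mask = sum(1 << pos[s] for s in c.boundary.states if s[idx] == 1)
    full = (1 << len(states)) - 1

    f1_candidates = []
    for f1 in enumerate_candidate_functions(genes, p.max_activators):
        m1 = _masks(f1, states, genes)
        if m1 & hp1 == hp1:  # f1 must hold at every positive hard point
            f1_candidates.append((f1, m1))

    f2_options = [(None, 0)]
    if p.max_repressors >= 1:
        for f2 in enumerate_candidate_functions(genes, p.max_repressors):
            f2_options.append((f2, _masks(f2, states, genes)))

    rules: list[UpdateRule] = []
    seen = set()
    for f1, m1 in f1_candidates:
        for f2, m2 in f2_options:
            u = m1 & ~m2 & full
            if u & hp1 != hp1 or u & hp0:
                continue
            agree = ~(u ^ self_mask) & boundary_mask
            if agree.bit_count() < c.min_self_consistent:
                continue
            rule = UpdateRule(gene=c.gene, activators=f1, repressors=f2)
            key = rule_truth_key(rule)
            if key in seen:
                continue
            seen.add(key)
            rules.append(rule)
    return rules


@dataclass
class RuleSet:
    """All compatible rules per gene, plus the paths that constrained them."""

    genes: GeneSet
    rules: dict  # gene -> list[UpdateRule]
    paths: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    @property
    def unresolved_genes(self) -> list:
        return [g for g in self.genes if not self.rules.get(g)]

    def n_rules(self, gene: str) -> int:
        return len(self.rules.get(gene, []))


def synthesize_all(
    g: StateGraph,
    initial: Iterable[BinaryState],
    final: Iterable[BinaryState],
    params: dict,
) -> RuleSet:
    """Run the full pipeline: orient, find paths, synthesize each gene."""
    directed = orient_edges(g, params)
    paths, _report = shortest_paths(directed, initial, final)
    rules: dict = {}
    for gene in g.genes:
        constraint = build_constraints(paths, g, gene, params[gene])
        rules[gene] = synthesize_gene_rules(constraint, params[gene], g.genes)
    return RuleSet(genes=g.genes, rules=rules, paths=paths, parameters=dict(params))
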