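"""Ground-truth networks and simulated class-labelled Boolean datasets.

The generator emulates the statistical structure the synthesis pipeline
assumes: cells are snapshots along asynchronous trajectories of a known
Boolean network, and the class label is a coarse time bucket of the walk
step (a crude pseudotime), since synthesis consumes only the initial and
final classes.  It produces the same CSV dialect the loader reads, so every
pipeline stage is testable without external data.
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass, field

from .boolfunc import MonotoneFormula, UpdateRule, _structures_exact, rule_truth_key
from .core import BinaryState, GeneSet
from .expression_io import Cell, ClassSpec, ExpressionDataset
from .model_analysis import CombinedModel, async_successors, model_from_rules, simulate_walk
from .rule_synthesis import GeneParameters, synthesize_all
from .state_graph import build_state_graph


@dataclass(frozen=True)
class GroundTruthNetwork:
    genes: GeneSet
    rules: dict  # gene -> UpdateRule (exactly one)
    initial_states: frozenset

    def to_model(self) -> CombinedModel:
        return model_from_rules(self.genes, self.rules)


def _sample_formula(rng: random.Random, names, k: int) -> MonotoneFormula:
    support = sorted(rng.sample(names, k))
    struct = rng.choice(_structures_exact(k))
    return MonotoneFormula(tuple(frozenset(support[i] for i in t) for t in struct))


def sample_network(
    n_genes: int,
    max_activators: int = 2,
    max_repressors: int = 1,
    seed: int = 0,
    n_initial_states: int = 2,
) -> GroundTruthNetwork:
    """Draw one update rule per gene within the given bounds, reproducibly.

    Degenerate draws whose rule is constant false (repressors swallowing the
    activators, e.g. f1 = A, f2 = A) are redrawn, so every gene can in
    principle switch on.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    rng = random.Random(seed)
    genes = GeneSet([f"G{i}" for i in range(n_genes)])
    rules = {}
    for g in genes:
        for _ in range(100):
            f1 = _sample_formula(rng, genes.names, rng.randint(1, max_activators))
            k_rep = rng.randint(0, max_repressors)
            f2 = _sample_formula(rng, genes.names, k_rep) if k_rep else None
            rule = UpdateRule(gene=g, activators=f1, repressors=f2)
            if any(rule_truth_key(rule)[1]):
                break
        rules[g] = rule
    initial = set()
    while len(initial) < n_initial_states:
        s = tuple(rng.randint(0, 1) for _ in range(n_genes))
        if any(s):
            initial.add(s)
    return GroundTruthNetwork(genes=genes, rules=rules, initial_states=frozenset(initial))


def generate_dataset(
    net: GroundTruthNetwork,
    n_cells: int = 200,
    n_classes: int = 3,
    walk_length: int = 20,
    seed: int = 0,
) -> ExpressionDataset:
    """Simulate asynchronous walks and label cells by walk-step bucket.

    Class labels are T0..T{n_classes-1}; the first bucket contains the walk
    starts (the network's initial states) and each walk's endpoint is
    assigned to the last bucket.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    model = net.to_model()
    rng = random.Random(seed)
    starts = sorted(net.initial_states)
    cells = []
    k = 0
    while len(cells) < n_cells:
        start = starts[rng.randrange(len(starts))]
        traj = simulate_walk(model, start, walk_length, seed=rng.randrange(2**31))
        for step, state in enumerate(traj):
            bucket = min(step * n_classes // max(walk_length, 1), n_classes - 1)
            if step == len(traj) - 1:
                bucket = n_classes - 1
            cells.append(Cell(cell_id=f"c{k}", class_label=f"T{bucket}", state=state))
            k += 1
    return ExpressionDataset(genes=net.genes, cells=cells[:n_cells])


def true_transition_closure(net: GroundTruthNetwork):
    """Exhaustive reachability from the initial states in the ground-truth
    asynchronous transition graph: (states, transitions)."""
    model = net.to_model()
    visited = set(net.initial_states)
    transitions = set()
    queue = deque(net.initial_states)
    while queue:
        s = queue.popleft()
        for _, t in async_successors(model, s):
            transitions.add((s, t))
            if t not in visited:
                visited.add(t)
                queue.append(t)
    return visited, transitions


@dataclass
class RecoveryReport:
    per_gene: dict  # gene -> bool (true rule among synthesized rules)
    coverage_complete: bool
    n_states: int
    n_transitions_true: int
    n_transitions_observed: int
    rule_counts: dict = field(default_factory=dict)

    @property
    def recovery_rate(self) -> float:
        return sum(self.per_gene.values()) / len(self.per_gene)


def recovery_experiment(
    n_genes: int,
    max_activators: int = 2,
    max_repressors: int = 1,
    seed: int = 0,
    synth_activators: int | None = None,
    synth_repressors: int | None = None,
) -> RecoveryReport:
    """Sample a network, observe walks to transition closure, re-synthesize
    at the true bounds and threshold 0%, and check per gene whether the true
    rule is among the compatible rules.

    Walking is bounded by 10 * 2**n_genes total steps; initial states are
    labelled T0, every visited state T1, and terminal states (stable states
    reached, else walk endpoints) T2.  Synthesis uses I = T0, F = T2.

    ``synth_activators`` / ``synth_repressors`` override the bounds used at
    synthesis time (default: the true bounds), e.g. to show that tightening
    below the truth loses the true rule.
    """
    if n_genes > 6:
        raise ValueError("recovery experiment supports n_genes <= 6")
    net = sample_network(n_genes, max_activators, max_repressors, seed=seed)
    model = net.to_model()
    _, true_transitions = true_transition_closure(net)

    rng = random.Random(seed + 1)
    starts = sorted(net.initial_states)
    budget = 10 * (1 << n_genes)
    visited = set(net.initial_states)
    observed = set()
    endpoints = set()
    steps_used = 0
    while steps_used < budget and observed != true_transitions:
        start = starts[rng.randrange(len(starts))]
        traj = simulate_walk(model, start, min(4 * n_genes, budget - steps_used), seed=rng.randrange(2**31))
        steps_used += len(traj) - 1
        for s1, s2 in zip(traj, traj[1:]):
            observed.add((s1, s2))
        visited.update(traj)
        endpoints.add(traj[-1])

    stable_visited = {s for s in visited if not async_successors(model, s)}
    finals = sorted(stable_visited) if stable_visited else sorted(endpoints)

    cells = []
    k = 0
    for s in sorted(visited):
        cells.append(Cell(cell_id=f"v{k}", class_label="T1", state=s))
        k += 1
    for s in sorted(net.initial_states & visited):
        cells.append(Cell(cell_id=f"i{k}", class_label="T0", state=s))
        k += 1
    for s in finals:
        cells.append(Cell(cell_id=f"f{k}", class_label="T2", state=s))
        k += 1
    ds = ExpressionDataset(genes=net.genes, cells=cells)

    spec = ClassSpec(initial_classes={"T0"}, target_classes={"T2"})
    graph, initial, final = build_state_graph(ds, spec)
    params = {
        g: GeneParameters(
            gene=g,
            max_activators=synth_activators if synth_activators is not None else max_activators,
            max_repressors=synth_repressors if synth_repressors is not None else max_repressors,
            threshold_percent=0.0,
        )
        for g in net.genes
    }
    rs = synthesize_all(graph, initial, final, params)

    per_gene = {}
    for g in net.genes:
        true_key = rule_truth_key(net.rules[g])
        per_gene[g] = any(rule_truth_key(r) == true_key for r in rs.rules[g])
    return RecoveryReport(
        per_gene=per_gene,
        coverage_complete=observed == true_transitions,
        n_states=len(visited),
        n_transitions_true=len(true_transitions),
        n_transitions_observed=len(observed),
        rule_counts={g: len(rs.rules[g]) for g in net.genes},
    )
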