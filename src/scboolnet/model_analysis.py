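"""Combined-model analysis: stable states, perturbations, async simulation.

When several compatible rules {f_i1, ..., f_in} survive for a gene x_i, the
combined network uses

    f'_i = (NOT x_i AND (f_i1 AND ... AND f_in)) OR (x_i AND (f_i1 OR ... OR f_in))

i.e. an OFF gene turns on only if every compatible rule agrees, while an ON
gene stays on if any rule keeps it on.  Every fixed point of any single-rule
sub-model is then also a fixed point of the combined model.

Stable states are the states fixed under every f'_i.  Enumeration uses a
backtracking constraint search with three-valued (Kleene) propagation and
solution recording, complete by construction; an exhaustive 2**n scan is
available as ``method='exhaustive'`` for independent verification (n <= 20).

Knockout / overexpression replaces the perturbed gene's update function by
the constant 0 / 1 (not a post-update clamp; identical for fixed points,
different in general for trajectories).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .boolfunc import UpdateRule, evaluate_rule
from .core import BinaryState, GeneSet, all_states, flip_bit
from .errors import CapabilityError, IncompleteModelError, UnknownGeneError

__all__ = [
    "CombinedModel",
    "Perturbation",
    "evaluate_rule",
    "combine_rules",
    "apply_perturbation",
    "find_stable_states",
    "async_successors",
    "simulate_walk",
    "write_stable_states_csv",
]


@dataclass(frozen=True)
class Perturbation:
    """Forced gene values: 0 = knockout, 1 = overexpression."""

    assignments: tuple  # tuple of (gene, value)

    def __init__(self, assignments):
        items = tuple(dict(assignments).items())
        for g, v in items:
            if v not in (0, 1):
                raise ValueError(f"perturbation value for {g!r} must be 0 or 1")
        object.__setattr__(self, "assignments", items)

    @classmethod
    def parse(cls, text: str) -> "Perturbation":
        """Parse 'GATA3=1,SOX2=0' syntax."""
        pairs = []
        for chunk in text.split(","):
            chunk = chunk.strip()
            if not chunk:
                continue
            gene, _, value = chunk.partition("=")
            pairs.append((gene.strip(), int(value)))
        return cls(pairs)


@dataclass
class CombinedModel:
    """Per-gene update: either a rule list (combined semantics) or a forced
    constant from a perturbation."""

    genes: GeneSet
    functions: dict  # gene -> ("rules", tuple[UpdateRule, ...]) | ("const", 0|1)

    def update(self, gene: str, state: BinaryState) -> int:
        kind, payload = self.functions[gene]
        if kind == "const":
            return payload
        x = state[self.genes.index(gene)]
        values = [evaluate_rule(r, state, self.genes) for r in payload]
        return int(any(values) if x else all(values))

    def update3(self, gene: str, bits: list) -> Optional[int]:
        """Three-valued update on a partial state (None = unknown)."""
        kind, payload = self.functions[gene]
        if kind == "const":
            return payload
        vals = [_rule3(r, bits, self.genes) for r in payload]
        conj = _kleene_all(vals)
        disj = _kleene_any(vals)
        x = bits[self.genes.index(gene)]
        if x == 0:
            return conj
        if x == 1:
            return disj
        if conj == disj:
            return conj
        return None


def _kleene_any(vals):
    if any(v == 1 for v in vals):
        return 1
    if all(v == 0 for v in vals):
        return 0
    return None


def _kleene_all(vals):
    if any(v == 0 for v in vals):
        return 0
    if all(v == 1 for v in vals):
        return 1
    return None


def _formula3(formula, bits, genes: GeneSet):
    idx = genes.index
    return _kleene_any(
        [_kleene_all([bits[idx(v)] for v in term]) for term in formula.terms]
    )


def _rule3(rule: UpdateRule, bits, genes: GeneSet):
    f1 = _formula3(rule.activators, bits, genes)
    if f1 == 0:
        return 0
    f2 = 0 if rule.repressors is None else _formula3(rule.repressors, bits, genes)
    if f2 == 1:
        return 0
    if f1 == 1 and f2 == 0:
        return 1
    return None


def combine_rules(rs) -> CombinedModel:
    """Merge a RuleSet into one executable network (all genes need >= 1 rule)."""
    missing = rs.unresolved_genes
    if missing:
        raise IncompleteModelError(
            "no compatible rule for gene(s) "
            + ", ".join(missing)
            + " — loosen their parameters (more inputs, lower threshold) and re-run",
            genes=missing,
        )
    functions = {g: ("rules", tuple(rs.rules[g])) for g in rs.genes}
    return CombinedModel(genes=rs.genes, functions=functions)


def model_from_rules(genes: GeneSet, rules: dict) -> CombinedModel:
    """Build a model with exactly one rule per gene (a sub-model selection)."""
    functions = {}
    for g in genes:
        r = rules[g]
        functions[g] = ("rules", (r,) if isinstance(r, UpdateRule) else tuple(r))
    return CombinedModel(genes=genes, functions=functions)


def apply_perturbation(m: CombinedModel, p: Perturbation) -> CombinedModel:
    functions = dict(m.functions)
    for gene, value in p.assignments:
        if gene not in m.genes:
            raise UnknownGeneError(f"unknown gene in perturbation: {gene!r}")
        functions[gene] = ("const", value)
    return CombinedModel(genes=m.genes, functions=functions)


def find_stable_states(
    m: CombinedModel,
    perturbation: Optional[Perturbation] = None,
    method: str = "search",
) -> list[BinaryState]:
    """All fixed points of the (optionally perturbed) model, lex-sorted.

    ``method='search'`` backtracks over partial assignments with Kleene
    propagation; ``method='exhaustive'`` filters all 2**n states (n <= 20).
    Both are complete; the latter exists as an independent cross-check.
    """
    if perturbation is not None:
        m = apply_perturbation(m, perturbation)
    n = m.genes.n
    if method == "exhaustive":
        if n > 20:
            raise CapabilityError("exhaustive scan supported for n <= 20 only")
        return [
            s
            for s in all_states(n)
            if all(m.update(g, s) == s[i] for i, g in enumerate(m.genes.names))
        ]
    if method != "search":
        raise ValueError(f"unknown method {method!r}")

    names = m.genes.names
    results: list[BinaryState] = []
    bits: list = [None] * n

    def consistent() -> bool:
        for i, g in enumerate(names):
            v = m.update3(g, bits)
            if v is not None and bits[i] is not None and v != bits[i]:
                return False
        return True

    def recurse(i: int) -> None:
        if not consistent():
            return
        if i == n:
            results.append(tuple(bits))
            return
        for v in (0, 1):
            bits[i] = v
            recurse(i + 1)
        bits[i] = None

    recurse(0)
    return results


def async_successors(m: CombinedModel, s: BinaryState) -> list:
    """One (gene, successor) per gene whose update disagrees with its bit;
    empty exactly when s is stable."""
    out = []
    for i, g in enumerate(m.genes.names):
        if m.update(g, s) != s[i]:
            out.append((g, flip_bit(s, i)))
    return out


def simulate_walk(
    m: CombinedModel, start: BinaryState, max_steps: int, seed: int
) -> list[BinaryState]:
    """Asynchronous random walk: pick uniformly among enabled single-gene
    flips; stop at a stable state.  Reproducible given the seed."""
    rng = random.Random(seed)
    trajectory = [start]
    current = start
    for _ in range(max_steps):
        succ = async_successors(m, current)
        if not succ:
            break
        _, current = rng.choice(succ)
        trajectory.append(current)
    return trajectory


def write_stable_states_csv(
    states: Iterable[BinaryState], genes: GeneSet, path, label: str = "wild_type"
) -> None:
    """Attractor table: one row per stable state, one 0/1 column per gene."""
    rows = [[label, i] + list(s) for i, s in enumerate(states)]
    df = pd.DataFrame(rows, columns=["condition", "attractor"] + list(genes.names))
    df.to_csv(path, index=False)
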