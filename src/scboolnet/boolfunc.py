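"""Monotone Boolean formulas and activator/repressor update rules.

Update rules take the restricted form

    u(s) = f1(s) AND NOT f2(s)

with ``f1`` (activators) and ``f2`` (repressors) monotone: built from AND/OR
only, no negation, no constants.  Every monotone non-constant function has a
unique minimal DNF whose terms are its minimal true points and form an
antichain under set inclusion; that antichain is the canonical form used
here, and every variable occurring in it is essential.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

from .core import BinaryState, GeneSet
from .errors import CapabilityError

#: Largest supported essential-variable count for exhaustive enumeration.
#: Dedekind's M(4) = 168 keeps this cheap; M(5) = 7581 would not be needed
#: by any realistic per-gene input bound.
MAX_ENUM_VARS = 4


@dataclass(frozen=True)
class MonotoneFormula:
    """OR of ANDs over gene names, stored as an antichain of terms.

    ``terms`` is a tuple of frozensets; each frozenset is one AND-term
    (a minimal true point).  Terms are kept sorted for determinism.
    """

    terms: tuple

    def __init__(self, terms: Iterable[Iterable[str]]):
        canon = []
        for t in terms:
            # a bare string is one gene name, not an iterable of names
            t = frozenset([t]) if isinstance(t, str) else frozenset(t)
            if not t:
                raise ValueError("empty term (constant true) not allowed")
            canon.append(t)
        if not canon:
            raise ValueError("empty formula (constant false) not allowed")
        # drop non-minimal terms, then sort for a stable representation
        minimal = [t for t in canon if not any(o < t for o in canon)]
        minimal = sorted(set(minimal), key=lambda t: (len(t), sorted(t)))
        for a, b in itertools.combinations(minimal, 2):
            if a <= b or b <= a:
                raise ValueError("terms must form an antichain")
        object.__setattr__(self, "terms", tuple(minimal))

    @property
    def variables(self) -> frozenset:
        return frozenset().union(*self.terms)

    def evaluate(self, state: BinaryState, genes: GeneSet) -> bool:
        idx = genes.index
        return any(all(state[idx(v)] for v in term) for term in self.terms)

    def __str__(self) -> str:
        parts = [" & ".join(sorted(t)) for t in self.terms]
        if len(parts) == 1:
            return parts[0]
        return " | ".join(f"({p})" if " & " in p else p for p in parts)


@dataclass(frozen=True)
class UpdateRule:
    """One gene's update function u = f1 AND NOT f2 (f2 optional)."""

    gene: str
    activators: MonotoneFormula
    repressors: Optional[MonotoneFormula] = None

    def evaluate(self, state: BinaryState, genes: GeneSet) -> bool:
        if not self.activators.evaluate(state, genes):
            return False
        if self.repressors is not None and self.repressors.evaluate(state, genes):
            return False
        return True

    @property
    def activator_variables(self) -> frozenset:
        return self.activators.variables

    @property
    def repressor_variables(self) -> frozenset:
        return self.repressors.variables if self.repressors is not None else frozenset()

    def __str__(self) -> str:
        if self.repressors is None:
            return f"{self.gene} := {self.activators}"
        rep = str(self.repressors)
        if self.repressors.terms and (len(self.repressors.terms) > 1 or len(rep.split()) > 1):
            rep = f"({rep})"
        return f"{self.gene} := ({self.activators}) & !{rep}"


def evaluate_rule(rule: UpdateRule, state: BinaryState, genes: GeneSet) -> bool:
    """Evaluate f1(s) AND NOT f2(s); an absent f2 contributes true."""
    return rule.evaluate(state, genes)


@lru_cache(maxsize=None)
def _structures_exact(k: int) -> tuple:
    """All monotone structures over variables 0..k-1 with every variable
    essential, as tuples of frozensets of positions.

    Enumerated as antichains of non-empty subsets whose union is the full
    variable set; each monotone function appears exactly once (minimal-DNF
    uniqueness).  Counts cross-check against Dedekind numbers:
    k=1 -> 1, k=2 -> 2, k=3 -> 9, k=4 -> 114.
    """
    if k > MAX_ENUM_VARS:
        raise CapabilityError(
            f"monotone enumeration supports at most {MAX_ENUM_VARS} variables, got {k}"
        )
    subsets = [frozenset(c) for r in range(1, k + 1) for c in itertools.combinations(range(k), r)]
    full = frozenset(range(k))
    out = []
    for r in range(1, len(subsets) + 1):
        for combo in itertools.combinations(subsets, r):
            if frozenset().union(*combo) != full:
                continue
            if any(a <= b or b <= a for a, b in itertools.combinations(combo, 2)):
                continue
            out.append(tuple(sorted(combo, key=lambda t: (len(t), sorted(t)))))
    out.sort(key=lambda terms: (len(terms), [(len(t), sorted(t)) for t in terms]))
    return tuple(out)


def enumerate_candidate_functions(genes: GeneSet, max_vars: int) -> list[MonotoneFormula]:
    """All non-constant monotone functions with at most ``max_vars`` essential
    variables drawn from ``genes``, each in canonical antichain form.

    Deterministic order: by support size, then support tuple (gene order),
    then structure.
    """
    if max_vars > MAX_ENUM_VARS:
        raise CapabilityError(
            f"at most {MAX_ENUM_VARS} variables supported, got {max_vars}"
        )
    result = []
    names = genes.names
    for k in range(1, min(max_vars, len(names)) + 1):
        structs = _structures_exact(k)
        for support in itertools.combinations(names, k):
            for struct in structs:
                result.append(
                    MonotoneFormula(tuple(frozenset(support[i] for i in t) for t in struct))
                )
    return result


def _truth_table(func, variables: Sequence[str]):
    """Truth table of ``func`` (mapping dict name->bit to bool) over the
    given variable order, as a tuple of 0/1 ints (lex order of assignments)."""
    m = len(variables)
    table = []
    for k in range(1 << m):
        assign = {v: (k >> (m - 1 - i)) & 1 for i, v in enumerate(variables)}
        table.append(1 if func(assign) else 0)
    return tuple(table)


def rule_truth_key(rule: UpdateRule):
    """Canonical semantic key for an update rule.

    Two rules are equivalent as Boolean functions over all states iff their
    keys are equal.  The key is the rule's truth table restricted to its
    essential variables (the function cannot depend on anything else).
    """

    def _f(assign):
        f1 = any(all(assign[v] for v in t) for t in rule.activators.terms)
        if not f1:
            return False
        if rule.repressors is not None and any(
            all(assign[v] for v in t) for t in rule.repressors.terms
        ):
            return False
        return True

    variables = sorted(rule.activator_variables | rule.repressor_variables)
    table = _truth_table(_f, variables)
    # strip inessential variables (possible through f1/f2 cancellation)
    changed = True
    while changed and variables:
        changed = False
        for i, v in enumerate(variables):
            m = len(variables)
            lo, hi = [], []
            for k, val in enumerate(table):
                if (k >> (m - 1 - i)) & 1:
                    hi.append(val)
                else:
                    lo.append(val)
            if lo == hi:
                variables = variables[:i] + variables[i + 1 :]
                table = tuple(lo)
                changed = True
                break
    return (tuple(variables), table)
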