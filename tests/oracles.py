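"""Independent brute-force oracles used to cross-check the implementation.

Everything here works on raw truth tables indexed by integers
(bit i of the index = gene i), deliberately sharing no code with the
package's antichain-based machinery.
"""

from functools import lru_cache


def state_index(state) -> int:
    k = 0
    for i, b in enumerate(state):
        k |= b << i
    return k


@lru_cache(maxsize=None)
def monotone_tables(n: int):
    """All non-constant monotone Boolean functions on n inputs as truth
    tables (tuples of length 2**n), via exhaustive filtering."""
    size = 1 << n
    tables = []
    for code in range(1 << size):
        bits = tuple((code >> k) & 1 for k in range(size))
        if all(b == 0 for b in bits) or all(b == 1 for b in bits):
            continue
        ok = True
        for k in range(size):
            for p in range(n):
                if not k & (1 << p) and bits[k] > bits[k | (1 << p)]:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            tables.append(bits)
    return tuple(tables)


def essential_count(table, n: int) -> int:
    count = 0
    for p in range(n):
        if any(table[k] != table[k ^ (1 << p)] for k in range(1 << n)):
            count += 1
    return count


def naive_gene_rules(n, hard_points, boundary, quota, max_act, max_rep):
    """Complete set of semantically distinct update functions u = f1 & ~f2
    compatible with the constraints, as a frozenset of full truth tables.

    hard_points: dict state-tuple -> required 0/1; boundary: iterable of
    (state-tuple, self_value) pairs; quota: minimum boundary agreements.
    """
    size = 1 << n
    f1s = [t for t in monotone_tables(n) if essential_count(t, n) <= max_act]
    f2s = [None]
    if max_rep >= 1:
        f2s += [t for t in monotone_tables(n) if essential_count(t, n) <= max_rep]
    results = set()
    for f1 in f1s:
        for f2 in f2s:
            u = tuple(
                f1[k] & (1 - (f2[k] if f2 is not None else 0)) for k in range(size)
            )
            if any(u[state_index(s)] != req for s, req in hard_points.items()):
                continue
            agree = sum(1 for s, v in boundary if u[state_index(s)] == v)
            if agree < quota:
                continue
            results.add(u)
    return frozenset(results)


def rule_full_table(rule, gene_names):
    """Full truth table of a package UpdateRule over all genes, computed by
    direct formula transcription (not via the package's evaluator)."""
    n = len(gene_names)
    pos = {g: i for i, g in enumerate(gene_names)}
    table = []
    for k in range(1 << n):
        s = {g: (k >> pos[g]) & 1 for g in gene_names}
        f1 = any(all(s[v] for v in t) for t in rule.activators.terms)
        f2 = rule.repressors is not None and any(
            all(s[v] for v in t) for t in rule.repressors.terms
        )
        table.append(1 if (f1 and not f2) else 0)
    return tuple(table)


def naive_stable_states(gene_names, rule_lists, forced=None):
    """Exhaustive fixed points of the combined network, transcribing the
    combining formula f' = (~x & AND rules) | (x & OR rules) directly."""
    forced = forced or {}
    n = len(gene_names)
    pos = {g: i for i, g in enumerate(gene_names)}
    stable = []
    for k in range(1 << n):
        state = tuple((k >> i) & 1 for i in range(n))
        s = {g: state[pos[g]] for g in gene_names}
        ok = True
        for g in gene_names:
            if g in forced:
                nxt = forced[g]
            else:
                vals = []
                for rule in rule_lists[g]:
                    f1 = any(all(s[v] for v in t) for t in rule.activators.terms)
                    f2 = rule.repressors is not None and any(
                        all(s[v] for v in t) for t in rule.repressors.terms
                    )
                    vals.append(1 if (f1 and not f2) else 0)
                x = s[g]
                nxt = ((1 - x) and min(vals)) or (x and max(vals))
            if nxt != s[g]:
                ok = False
                break
        if ok:
            stable.append(state)
    return sorted(stable)


def hamming_edges(states):
    """All unordered Hamming-1 pairs among the given states, by pairwise
    comparison (quadratic; independent of the flip-lookup construction)."""
    states = list(states)
    edges = set()
    for i, a in enumerate(states):
        for b in states[i + 1 :]:
            if sum(x != y for x, y in zip(a, b)) == 1:
                edges.add(frozenset((a, b)))
    return edges
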