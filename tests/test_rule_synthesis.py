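import random

import pytest

from instances import random_instance
from oracles import naive_gene_rules, rule_full_table
from scboolnet import (
    Cell,
    ClassSpec,
    ExpressionDataset,
    FormatError,
    GeneParameters,
    GeneSet,
    InfeasibleError,
    build_constraints,
    build_state_graph,
    evaluate_rule,
    orient_edges,
    read_parameters_csv,
    shortest_paths,
    state_from_string,
    synthesize_all,
    synthesize_gene_rules,
    write_parameters_csv,
)
from scboolnet.core import all_states


def directed_edge_set(G):
    return {(s1, s2, gene) for s1, s2, gene in G.edges()}


class TestOrientEdges:
    def params(self, genes, r=1):
        return {g: GeneParameters(g, 1, r, 0.0) for g in genes}

    def make_graph(self, states):
        genes = GeneSet(["A", "B", "C"])
        cells = [Cell(str(i), "x", state_from_string(s)) for i, s in enumerate(states)]
        g, _, _ = build_state_graph(ExpressionDataset(genes, cells), ClassSpec({"x"}, {"x"}))
        return g

    def test_turn_on_from_all_zero_is_pruned(self):
        g = self.make_graph(["000", "001"])
        G = orient_edges(g, self.params(g.genes))
        edges = directed_edge_set(G)
        assert ((0, 0, 0), (0, 0, 1), "C") not in edges  # no activator can be ON
        assert ((0, 0, 1), (0, 0, 0), "C") in edges  # A or B is OFF: f1 can be false

    def test_turn_off_from_all_ones_needs_a_repressor(self):
        g = self.make_graph(["111", "110"])
        no_rep = orient_edges(g, self.params(g.genes, r=0))
        assert ((1, 1, 1), (1, 1, 0), "C") not in directed_edge_set(no_rep)
        with_rep = orient_edges(g, self.params(g.genes, r=1))
        assert ((1, 1, 1), (1, 1, 0), "C") in directed_edge_set(with_rep)

    def test_turn_on_with_activator_present_is_retained(self):
        g = self.make_graph(["100", "110"])
        G = orient_edges(g, self.params(g.genes))
        assert ((1, 0, 0), (1, 1, 0), "B") in directed_edge_set(G)

    def test_missing_parameters_raise(self):
        g = self.make_graph(["100", "110"])
        with pytest.raises(FormatError, match="'C'"):
            orient_edges(g, {g_: GeneParameters(g_, 1, 1, 0.0) for g_ in ["A", "B"]})

    def test_pruning_is_sound_for_every_candidate_rule(self):
        """No pruned direction is realisable by any in-family function:
        exhaustively cross-checked on random graphs."""
        from scboolnet import enumerate_candidate_functions
        from scboolnet.boolfunc import UpdateRule

        rng = random.Random(3)
        for _ in range(10):
            pool = list(all_states(3))
            nodes = rng.sample(pool, rng.randint(2, 8))
            g = self.make_graph(["".join(map(str, s)) for s in nodes])
            r_bound = rng.randint(0, 2)
            params = {x: GeneParameters(x, 2, r_bound, 0.0) for x in g.genes}
            G = orient_edges(g, params)
            kept = directed_edge_set(G)
            f1s = enumerate_candidate_functions(g.genes, 2)
            f2s = [None] + (enumerate_candidate_functions(g.genes, r_bound) if r_bound else [])
            for s in g.nodes:
                for gene, t in g.neighbours(s):
                    i = g.genes.index(gene)
                    realizable = any(
                        evaluate_rule(UpdateRule(gene, f1, f2), s, g.genes) == t[i]
                        for f1 in f1s
                        for f2 in f2s
                    )
                    assert ((s, t, gene) in kept) == realizable


class TestShortestPaths:
    def chain_graph(self):
        genes = GeneSet(["A", "B", "C"])
        states = ["100", "110", "111", "011"]
        cells = [Cell(str(i), "x", state_from_string(s)) for i, s in enumerate(states)]
        g, _, _ = build_state_graph(ExpressionDataset(genes, cells), ClassSpec({"x"}, {"x"}))
        return g, orient_edges(g, {x: GeneParameters(x, 1, 1, 0.0) for x in genes})

    def test_chain_path(self):
        _, G = self.chain_graph()
        paths, report = shortest_paths(G, {(1, 0, 0)}, {(0, 1, 1)})
        assert len(paths) == 1
        assert paths[0].states == ((1, 0, 0), (1, 1, 0), (1, 1, 1), (0, 1, 1))
        assert report.ok()

    def test_identical_initial_and_final_gives_trivial_path(self):
        _, G = self.chain_graph()
        paths, _ = shortest_paths(G, {(1, 0, 0)}, {(1, 0, 0)})
        assert paths[0].states == ((1, 0, 0),)
        assert not list(paths[0].edges(G.genes))

    def test_lexicographic_tie_break(self):
        # diamond 100 -> {110, 101} -> 111: two equal-length routes
        genes = GeneSet(["A", "B", "C"])
        states = ["100", "110", "101", "111"]
        cells = [Cell(str(i), "x", state_from_string(s)) for i, s in enumerate(states)]
        g, _, _ = build_state_graph(ExpressionDataset(genes, cells), ClassSpec({"x"}, {"x"}))
        G = orient_edges(g, {x: GeneParameters(x, 1, 1, 0.0) for x in genes})
        paths, _ = shortest_paths(G, {(1, 0, 0)}, {(1, 1, 1)})
        # (100, 101, 111) beats (100, 110, 111) lexicographically
        assert paths[0].states == ((1, 0, 0), (1, 0, 1), (1, 1, 1))

    def test_unreachable_final_raises_with_report(self):
        genes = GeneSet(["A", "B", "C"])
        # 000 cannot be exited (no activator ON), so 111 is unreachable
        cells = [Cell("0", "x", (0, 0, 0)), Cell("1", "x", (1, 1, 1))]
        g, _, _ = build_state_graph(ExpressionDataset(genes, cells), ClassSpec({"x"}, {"x"}))
        G = orient_edges(g, {x: GeneParameters(x, 1, 1, 0.0) for x in genes})
        with pytest.raises(InfeasibleError, match="111") as exc:
            shortest_paths(G, {(0, 0, 0)}, {(1, 1, 1)})
        assert exc.value.report.unreachable_finals == ((1, 1, 1),)


class TestBuildConstraints:
    def test_toy_hard_points(self, toy_graph, toy_params):
        g, initial, final = toy_graph
        G = orient_edges(g, toy_params)
        paths, _ = shortest_paths(G, initial, final)
        cB = build_constraints(paths, g, "B", toy_params["B"])
        assert cB.hard_points == {(1, 0, 0): 1}
        cA = build_constraints(paths, g, "A", toy_params["A"])
        assert cA.hard_points == {(1, 1, 1): 0}

    @pytest.mark.parametrize("threshold,expected", [(100.0, 2), (50.0, 1), (0.0, 0), (75.0, 2), (25.0, 1)])
    def test_threshold_quota_is_ceiling_of_percentage(self, toy_graph, threshold, expected):
        g, initial, final = toy_graph
        p = GeneParameters("A", 1, 1, threshold)
        G = orient_edges(g, {**make_params(g.genes), "A": p})
        paths, _ = shortest_paths(G, initial, final)
        c = build_constraints(paths, g, "A", p)
        assert len(c.boundary.states) == 2
        assert c.min_self_consistent == expected


def make_params(genes, a=1, r=1, t=0.0):
    return {g: GeneParameters(g, a, r, t) for g in genes}


class TestToySynthesis:
    """The 4-state worked instance, pre-verified by brute force."""

    def test_full_rule_set(self, toy_ruleset):
        as_str = {g: [str(r) for r in rules] for g, rules in toy_ruleset.rules.items()}
        assert as_str == {
            "A": ["A := (A) & !C"],
            "B": ["B := A"],
            "C": ["C := B"],
        }
        assert toy_ruleset.unresolved_genes == []

    def test_gene_B_tightened_threshold_has_no_rule(self, toy_graph):
        g, initial, final = toy_graph
        params = make_params(g.genes, a=1, r=0, t=100.0)
        params["A"] = GeneParameters("A", 1, 1, 100.0)
        rs = synthesize_all(g, initial, final, params)
        assert rs.rules["B"] == []
        assert "B" in rs.unresolved_genes

    def test_gene_B_two_activators(self, toy_graph, toy_params):
        g, initial, final = toy_graph
        G = orient_edges(g, toy_params)
        paths, _ = shortest_paths(G, initial, final)
        p = GeneParameters("B", 2, 0, 100.0)
        rules = synthesize_gene_rules(build_constraints(paths, g, "B", p), p, g.genes)
        assert {str(r) for r in rules} == {"B := A | B", "B := A | C"}


class TestOracleEquivalence:
    def test_synthesis_matches_brute_force_on_random_instances(self):
        """The pruned structured search returns exactly the same rule sets
        (as Boolean functions) as naive enumeration over all monotone
        (f1, f2) truth-table pairs."""
        rng = random.Random(2024)
        checked = 0
        for _ in range(60):
            g, params, paths, constraints = random_instance(rng)
            n = g.genes.n
            for gene in g.genes:
                c = constraints[gene]
                p = params[gene]
                rules = synthesize_gene_rules(c, p, g.genes)
                got = {rule_full_table(r, g.genes.names) for r in rules}
                assert len(got) == len(rules), "duplicate rules returned"
                idx = g.genes.index(gene)
                expected = naive_gene_rules(
                    n,
                    c.hard_points,
                    [(s, s[idx]) for s in c.boundary.states],
                    c.min_self_consistent,
                    p.max_activators,
                    p.max_repressors,
                )
                assert got == set(expected)
                checked += 1
        assert checked >= 100

    def test_soundness_replay(self):
        """Every returned rule actually satisfies its hard points and
        boundary quota when re-evaluated from scratch."""
        rng = random.Random(99)
        for _ in range(20):
            g, params, paths, constraints = random_instance(rng)
            for gene in g.genes:
                c, p = constraints[gene], params[gene]
                idx = g.genes.index(gene)
                for rule in synthesize_gene_rules(c, p, g.genes):
                    assert len(rule.activator_variables) <= p.max_activators
                    assert len(rule.repressor_variables) <= p.max_repressors
                    for s, req in c.hard_points.items():
                        assert evaluate_rule(rule, s, g.genes) == req
                    agree = sum(
                        1
                        for s in c.boundary.states
                        if evaluate_rule(rule, s, g.genes) == s[idx]
                    )
                    assert agree >= c.min_self_consistent

    def test_loosening_parameters_grows_rule_set(self):
        """More activators/repressors or a lower threshold never removes a
        previously compatible rule."""
        rng = random.Random(5)
        for _ in range(15):
            g, params, paths, constraints = random_instance(rng)
            for gene in g.genes:
                p = params[gene]
                base = {
                    rule_full_table(r, g.genes.names)
                    for r in synthesize_gene_rules(constraints[gene], p, g.genes)
                }
                for looser in (
                    GeneParameters(gene, min(p.max_activators + 1, 4), p.max_repressors, p.threshold_percent),
                    GeneParameters(gene, p.max_activators, min(p.max_repressors + 1, 4), p.threshold_percent),
                    GeneParameters(gene, p.max_activators, p.max_repressors, 0.0),
                ):
                    c2 = build_constraints(paths, g, gene, looser)
                    got = {
                        rule_full_table(r, g.genes.names)
                        for r in synthesize_gene_rules(c2, looser, g.genes)
                    }
                    assert base <= got


class TestSynthesizeAll:
    def test_single_state_class_gives_empty_paths_and_threshold_only_rules(self):
        genes = GeneSet(["A", "B"])
        cells = [Cell("0", "x", (1, 0)), Cell("1", "x", (1, 0))]
        g, initial, final = build_state_graph(
            ExpressionDataset(genes, cells), ClassSpec({"x"}, {"x"})
        )
        rs = synthesize_all(g, initial, final, make_params(genes, t=0.0))
        assert all(len(p.states) == 1 for p in rs.paths)
        # unconstrained at threshold 0: the whole in-bounds family comes back
        from scboolnet import enumerate_candidate_functions

        n_family = len(enumerate_candidate_functions(genes, 1)) * (
            1 + len(enumerate_candidate_functions(genes, 1))
        )
        # family size minus semantic duplicates (X & !X == Y & !Y)
        assert rs.n_rules("A") == rs.n_rules("B") > 0
        assert rs.n_rules("A") <= n_family

    def test_unreachable_target_propagates(self):
        genes = GeneSet(["A", "B", "C"])
        cells = [Cell("0", "E3", (0, 0, 0)), Cell("1", "E7", (1, 1, 1))]
        g, initial, final = build_state_graph(
            ExpressionDataset(genes, cells), ClassSpec({"E3"}, {"E7"})
        )
        with pytest.raises(InfeasibleError):
            synthesize_all(g, initial, final, make_params(genes))


def test_parameters_csv_round_trip(tmp_path):
    params = {
        "NANOG": GeneParameters("NANOG", 1, 0, 70.0),
        "HAND1": GeneParameters("HAND1", 1, 2, 70.0),
    }
    path = tmp_path / "params.csv"
    write_parameters_csv(params, path)
    assert read_parameters_csv(path) == params


def test_parameters_csv_missing_column(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("Gene,Number of activators\nA,1\n")
    with pytest.raises(FormatError, match="Threshold"):
        read_parameters_csv(p)
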