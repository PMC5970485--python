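"""Random small synthesis instances for oracle-equivalence checks."""

from collections import deque
import random

from scboolnet import (
    Cell,
    ClassSpec,
    ExpressionDataset,
    GeneParameters,
    GeneSet,
    build_constraints,
    build_state_graph,
    orient_edges,
    shortest_paths,
)
from scboolnet.core import all_states


def random_instance(rng: random.Random):
    """A feasible random instance: graph over <= 16 observed states of
    n <= 4 genes, bounds <= 2, thresholds in {0, 50, 100}%.

    Returns (graph, params, paths, per-gene constraints).
    """
    n = rng.randint(2, 4)
    genes = GeneSet([chr(65 + i) for i in range(n)])
    universe = list(all_states(n))
    nodes = rng.sample(universe, rng.randint(2, min(16, len(universe))))
    cells = [
        Cell(cell_id=str(i), class_label="obs", state=s) for i, s in enumerate(nodes)
    ]
    ds = ExpressionDataset(genes=genes, cells=cells)
    g, _, _ = build_state_graph(ds, ClassSpec({"obs"}, {"obs"}))

    params = {
        gname: GeneParameters(
            gname,
            rng.randint(1, 2),
            rng.randint(0, 2),
            rng.choice([0.0, 50.0, 100.0]),
        )
        for gname in genes
    }
    directed = orient_edges(g, params)

    initial = set(rng.sample(nodes, rng.randint(1, 2)))
    reachable = set(initial)
    queue = deque(initial)
    while queue:
        s = queue.popleft()
        for _, t in directed.successors[s]:
            if t not in reachable:
                reachable.add(t)
                queue.append(t)
    final = set(rng.sample(sorted(reachable), rng.randint(1, min(2, len(reachable)))))

    paths, _ = shortest_paths(directed, initial, final)
    constraints = {
        gname: build_constraints(paths, g, gname, params[gname]) for gname in genes
    }
    return g, params, paths, constraints
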