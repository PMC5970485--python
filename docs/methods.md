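# Methods

## Model

scboolnet treats binarized single-cell expression profiles as states of an
asynchronous Boolean network over the measured genes. The modelling
assumptions are:

* each gene is on (1) or off (0); a cell is a state *s ∈ {0,1}ⁿ*;
* dynamics proceed by single-gene flips (asynchronous update), so all
  interleavings and rates are allowed;
* two observed states at Hamming distance 1 are candidate endpoints of one
  update event — the undirected state graph joins exactly those pairs and
  labels each edge with the differing gene;
* update functions have the activator/repressor form *u = f₁ ∧ ¬f₂* with
  *f₁*, *f₂* monotone (AND/OR, no negation, no constants). *f₁* is
  mandatory (at least one activator), *f₂* optional; repression dominates.
  A gene may regulate itself.

Monotone formulas are stored as antichains of minimal AND-terms (the
minimal true points), which is a canonical form: every monotone
non-constant function has exactly one, and every variable occurring in it
is essential.

## Synthesis procedure

**Phase 1 — orientation.** A directed edge *s₁ → s₂* flipping gene *v* is
kept iff some in-family function can realise it: a 0→1 flip needs at least
one gene ON in *s₁* (a monotone, constant-free *f₁* is false on the all-off
input); a 1→0 flip needs either an allowed repressor (*r_v ≥ 1*; *v* itself
is ON in *s₁*, so an ON witness always exists) or some gene OFF in *s₁* so
that *f₁* can evaluate false. This is deliberately the weakest sound
criterion — phase 3 constraints dominate, so sharper pruning would only be
an optimisation.

**Phase 2 — paths.** For every pair of an initial state *i* (from the
user-selected initial classes) and final state *f* (target classes), the
shortest directed path in the pruned graph is computed by BFS. If some
final state is unreachable from every initial state, synthesis aborts with
a reachability report. Determinism: among equal-length paths the
lexicographically smallest state sequence is returned, implemented as a
backward BFS distance labelling followed by a greedy lexicographic forward
walk. When a state is both initial and final, its path is trivial and
contributes no constraints. Paths are built per (i, f) pair, following the
procedure's printed definition, even though reachability alone would need
only one path per final state.

**Phase 3 — rule search.** Per gene *v* the constraints are
(1) *hard points*: for every *v*-labelled edge (s₁, s₂) on a chosen path,
*u(s₁) = s₂(v)*; (2) *boundary self-consistency*: with *N_v* the states
whose *v*-flip leaves the observed state space, *u(s) = s(v)* must hold on
at least ⌈t_v/100 · |N_v|⌉ states of *N_v*. The threshold is read as a
percentage of |N_v| (vacuous when *N_v* is empty). The search enumerates
candidate monotone structures within the bounds — supports of size ≤ a_v
(≤ r_v) times the exactly-*k*-essential-variable structures, of which there
are 1, 2, 9, 114 for k = 1..4 (Dedekind counts minus constants and
smaller-support functions) — pruning *f₁* candidates that violate a
positive hard point, evaluating pairs on bitmasks over the relevant states,
and deduplicating semantically by the truth table over essential variables.
The result is the complete deduplicated compatible set; an empty set means
the gene's parameters are too tight (the intended workflow is to start
loose — more inputs, lower threshold — and tighten per gene until each gene
has a rule). Enumeration is capped at 4 variables per formula; beyond that
the candidate space (Dedekind growth) stops being enumerable, and published
per-gene input bounds for this method do not exceed 3.

## Combined model and analysis

With compatible rules {f_i1 … f_in} for gene *x_i*, the combined update is
*f′ᵢ = (¬xᵢ ∧ (fᵢ₁ ∧ … ∧ fᵢₙ)) ∨ (xᵢ ∧ (fᵢ₁ ∨ … ∨ fᵢₙ))*: an OFF gene
turns on only with unanimous agreement, an ON gene persists if any rule
sustains it. Every fixed point of any single-rule selection is then a fixed
point of the combined model (verified mechanically in the tests). The
combining formula is implemented verbatim; the informal reading "the
combined network transitions if all sub-models do" is an approximation of
it.

Stable states (fixed points of all *f′ᵢ*) are enumerated by a backtracking
search over partial assignments: genes are assigned in order, each
partial assignment is propagated with three-valued (Kleene) evaluation of
every *f′ᵢ*, and branches whose determined update contradicts an assigned
bit are cut. The search is complete by construction; an exhaustive 2ⁿ scan
(n ≤ 20) is kept as an independently coded cross-check and both routes are
compared on hundreds of random models in the tests. Output is sorted
lexicographically. Complex (cyclic) attractors are out of scope; export to
SBML-qual allows external tools to find them.

Knockout / overexpression replaces the perturbed gene's update function by
the constant 0 / 1 — function replacement, not post-update clamping. The
two coincide exactly on fixed points; they differ for trajectories (a
clamped gene could still be chosen for a no-op update), which is why the
replacement semantics is used throughout, including simulation.

## Parameters

| parameter | unit | default | meaning |
|---|---|---|---|
| max activators *aᵢ* | count ≥ 1 | per gene, required | bound on *f₁*'s variables |
| max repressors *rᵢ* | count ≥ 0 | per gene, required | bound on *f₂*'s variables |
| threshold *tᵢ* | % of \|Nᵢ\| | per gene, required | minimum boundary self-consistency |
| limit of detection | expression units | 0 | binarization cut-off (value > limit → on); 0 is the read-count rule, qPCR data should use the experimentally determined limit |
| walk length | steps | 20 | synthetic trajectory length |
| classes | count | 3 | synthetic time buckets T0…T{k−1} |
| seed | int | 0 | all randomness (walk choice, network sampling) |

## Synthetic data generator

`sample_network` draws one rule per gene uniformly over supports and
exactly-*k* structures within the bounds (defaults 2 activators,
1 repressor — small in-degrees typical of curated Boolean GRN models),
redrawing the rare constant-false compositions, plus two random initial
states with ≥ 1 active gene. `generate_dataset` emits cells along seeded
asynchronous walks; the class label is the walk-step bucket, a crude
pseudotime standing in for experimental time points — sufficient because
synthesis consumes only the initial and final classes. The generator
reproduces exactly the Boolean layer the method consumes; it does not model
dropout, sequencing depth, doublets or binarization error, so passing tests
demonstrate correctness of the synthesis machinery on ideal data, not
robustness to real measurement noise.

`recovery_experiment` walks to transition closure (bounded by 10·2ⁿ steps),
labels initial states T0, all visited states T1 and terminal states T2,
re-synthesizes at the true bounds with threshold 0%, and reports per gene
whether the ground-truth rule is among the compatible set. **Known
limitation:** recovery is not guaranteed even at full transition coverage.
The chosen shortest paths live in the Hamming-1 graph of *observed* states,
and two observed states can be adjacent without the ground-truth network
ever taking that step; a path using such an edge imposes a hard point the
true rule violates. This is inherent to committing to one BFS path per
(i, f) pair — the underlying problem statement only asks that *some*
realisable path exist. The acceptance script therefore reports the measured
recovery rate rather than assuming 100%.

## Correlation baseline

Spearman correlation is computed as Pearson on rank-transformed columns
(identical by definition, and well-defined per pair when other genes are
constant; constant genes score 0 with a warning). Partial correlations come
from the precision matrix Ω of the rank correlation matrix,
ρᵢⱼ = −Ωᵢⱼ/√(ΩᵢᵢΩⱼⱼ): direct inversion when the matrix is well-conditioned
and cells outnumber genes, otherwise a Ledoit–Wolf shrinkage estimate
(scikit-learn). Correlations are computed on the binarized matrix — the
only data the tool holds — which is an assumption to keep in mind when
comparing against analyses run on continuous expression. Predicted directed
edges are matched to unordered pairs; self-loops have no undirected
counterpart and are excluded from the overlap count.

## Numerical and design choices

* State order is the lexicographic order of bit tuples everywhere
  (BFS tie-breaks, stable-state output, CSV rows), making every pipeline
  stage deterministic for a given seed.
* The threshold quota uses ⌈t·|N|/100 − ε⌉ with ε = 10⁻⁹ so that exact
  percentages (50% of 2, 100% of k) are not tipped by floating-point
  representation.
* Rule equivalence is decided by truth tables restricted to essential
  variables (≤ 8 after an activator/repressor union), never by 2ⁿ tables,
  so deduplication stays exact at any gene count.
* Constraint searches are pruned enumerations with bitmask evaluation
  rather than calls into an external satisfiability solver; at the bounds
  this method operates under (≤ 4 inputs per formula) the candidate space
  is small enough that complete enumeration is exact and fast, and the test
  suite verifies completeness against naive brute force over all monotone
  truth-table pairs.
* SBML Level 3 qual documents are written and parsed directly (lxml): one
  qualitative species per gene (maxLevel 1), one transition per gene whose
  level-1 function term encodes the update function in MathML
  (`eq(ci, 1)` atoms under and/or/not). Gene names are sanitised to valid
  SIds with originals preserved in `qual:name`; round-trips are verified by
  truth-table equality.
* Degenerate inputs: datasets with one state synthesize against an empty
  path set (threshold-only constraints); constant genes are flagged as
  unlearnable at validation; an all-pruned directed graph is legal and
  surfaces as unreachable finals.

## Problem sizes

Default verification sizes — 200 random instances for each oracle
equivalence, 50 rule sets for conservation, recovery at 3–5 genes with 5
replicates, an 8-gene/400-cell end-to-end run — keep the full suite and the
acceptance script in the seconds-to-minutes range while exercising every
code path; all scale linearly with the counts if deeper sampling is wanted.
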