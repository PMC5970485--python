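# scboolnet

Reconstruction and analysis of **executable asynchronous Boolean network
models** from binarized single-cell gene expression time courses.

Single-cell qPCR or RNA-seq snapshots taken across a developmental time
course can be read as states of an asynchronous Boolean network: each gene
is on (reads detected / above the limit of detection) or off, and each cell
is one Boolean state *s = (x₁, …, xₙ)*. scboolnet searches for the logical
update rules that drive transitions from early cell states towards late
cell states, producing a mechanistic, executable model rather than a mere
correlation network — the model can be run forward, its stable states
(interpreted as mature cell types) enumerated, and in-silico knockouts or
overexpressions applied. It is aimed at computational biologists studying
differentiation, development or reprogramming with class-labelled
(time-point-labelled) single-cell data.

## Method

1. **State graph.** Distinct observed states become vertices; two states
   are joined iff they differ in exactly one gene *v*, and the edge is
   labelled *v*.
2. **Edge orientation.** Update functions are restricted to the form
   *u = f₁ ∧ ¬f₂* with *f₁* (activators) and *f₂* (repressors) monotone
   (AND/OR only, no negation, no constants), bounded per gene by *aᵢ*
   activators and *rᵢ* repressors. Each edge direction is kept only if some
   function in this family can realise the flip.
3. **Paths.** For every (initial, final) state pair — selected through the
   dataset's Class labels — a shortest directed path is found by BFS, with a
   deterministic lexicographic tie-break.
4. **Rule search.** Per gene, the complete set of in-bounds functions is
   found such that (a) every gene-labelled edge on the chosen paths is
   reproduced, and (b) the function is self-consistent (*uᵢ(s) = s(vᵢ)*) on
   at least *tᵢ*% of the gene's boundary set *Nᵢ* — the states whose
   gene-*i* flip leaves the observed state space.
5. **Combined model & analysis.** All compatible rules per gene *xᵢ* merge
   into *f′ᵢ = (¬xᵢ ∧ (fᵢ₁ ∧ … ∧ fᵢₙ)) ∨ (xᵢ ∧ (fᵢ₁ ∨ … ∨ fᵢₙ))*; fixed
   points of every single-rule sub-model are preserved. Stable states are
   enumerated by a complete backtracking search; knockout/overexpression
   replaces a gene's function by the constant 0/1.

Models export to SBML Level 3 qual (for GINsim, BoolNet, …), a lossless
JSON document, and a signed interaction edge list; a (partial) correlation
baseline quantifies which predicted links carry no marginal correlation
signal. A synthetic-data module generates ground-truth networks and
simulated class-labelled datasets for end-to-end validation.

## Worked example

`examples/toy_states.csv` holds four observed states of genes A, B, C along
the chain 100 → 110 → 111 → 011, with 100 labelled class `E3` (early) and
011 labelled `E7` (late); `examples/toy_parameters.csv` bounds the search
(A: 1 activator/1 repressor/100%, B: 1/0/50%, C: 1/0/100%).

```sh
$ scboolnet synthesize --input examples/toy_states.csv \
    --parameters examples/toy_parameters.csv \
    --initial E3 --target E7 --out out/
INFO scboolnet: state graph: 4 states, 3 edges, 1 components
rules per gene: A=1, B=1, C=1

$ cat out/rules.txt
# A: 1 compatible rule(s)
A := (A) & !C
# B: 1 compatible rule(s)
B := A
# C: 1 compatible rule(s)
C := B
```

Exactly one rule survives per gene: A maintains itself until repressed by
C, B is activated by A, and C by B — the unique in-bounds logic that
reproduces the observed progression. Analysing the model:

```sh
$ scboolnet analyze --model out/model.json --perturb A=1 --out out/attractors.csv
wild_type: 1 stable state(s)
A=1: 1 stable state(s)

$ cat out/attractors.csv
condition,attractor,A,B,C
wild_type,0,0,0,0
A=1,0,1,1,1
```

The wild-type network has a single stable state with all genes off (the
cascade decays once A shuts down), while forcing A on (overexpression)
drives the system to the all-on state. `scboolnet simulate` generates
synthetic datasets from random ground-truth networks, and
`scboolnet compare` ranks gene pairs by Spearman or partial correlation and
reports which predicted directed edges fall outside the top-k pairs.

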