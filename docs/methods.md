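# Methods

## Scope and model class

`boolmerge` operates on Boolean logical models of gene regulation: each
node holds 0/1 and is updated by a propositional rule over other nodes,
restricted to NOT/AND/OR (precedence `!` > `&` > `|`, left-associative).
Constants `0`/`1` are part of the grammar so clamped (mutated) nodes are
expressible. Multi-valued and probabilistic logics are out of scope;
reading an SBML-qual species with `maxLevel > 1` raises rather than
silently binarizing, because binarization changes dynamics and belongs to
the curator.

Nodes without a rule are *external inputs*. Inputs hold their value under
both update schemes; exhaustive attractor enumeration therefore yields
attractors per input combination automatically, and each attractor is
labeled with its input context. Identifiers are case-sensitive; matching
across models happens only after harmonization.

## Harmonization

Symbol mapping is offline-first: a curated TSV table (alias → approved
symbol, optional HGNC id, provenance in {alias, previous, ortholog,
manual}) is the source of truth, matching the semi-automated curation this
step requires in practice. Renaming rewrites all rules consistently and
is idempotent. Two distinct nodes mapping to one approved symbol raise a
collision error instead of silently merging — that decision belongs to the
curator. Cross-species models are reconciled through `ortholog` rows of
the same table; nodes with no standard nomenclature (fusion proteins,
complexes) pass through unmapped and are flagged in the report.

Interaction graphs can be translated into rules by the inhibitor-dominant
template: each target gets `(OR of activators) & !(OR of inhibitors)`.
This translation is exact for the template class and inverts
`interaction_graph` on it; dual-signed edges cannot be expressed by the
template and raise.

## Merge semantics

For a node shared by several models, the merged rule is, per configured
strategy (default plus per-node overrides):

- OR: ⋁_j f^{M_j} (pointwise max),
- AND: ⋀_j f^{M_j} (pointwise min),
- IW: 0 on any state where a pooled inhibitor is ON, else the OR
  combination; closed form ¬(⋁ I) ∧ f^OR.

Decisions taken where the semantics were genuinely open:

- **"Active inhibitor" is read state-wise over the pooled inhibitor set**:
  I is the union over all source rules of the target's inhibitory
  regulators, and IW evaluates to 0 exactly on states where some member of
  I is ON. This makes f^IW a well-defined Boolean function and agrees with
  the inhibitor-dominant graph-translation template.
- **Inhibitor detection is semantic by default** (exhaustive flip test over
  the rule's regulators, cap 16): syntactic negation can both over- and
  under-report inhibition after rule simplification (e.g. `!(!A)`); the
  negation-parity fallback is available for larger rules and as an
  explicit configuration.
- **Dual-signed regulators count as inhibitors under IW**, with a warning —
  the conservative reading of inhibition dominance.
- **Input-vs-regulated conflicts resolve to the regulated rules**: a model
  that leaves a node unregulated is treated as silent about it, not as
  asserting constancy. The merge report records this per node.
- n-ary merging is supported; all three combiners are associative and
  commutative in the model list up to logical equivalence.

A consequence worth stating explicitly: the pointwise chain
f^AND ≤ f^IW ≤ f^OR does **not** hold for general rules. f^IW ≤ f^OR
always holds (IW only zeroes OR states), but a source rule can evaluate to
1 on a state where an inhibitor pooled from another source rule is active
(e.g. rules `A | !B` and `A` at A=1, B=1: both ON, yet B ∈ I forces
IW to 0 while AND is 1). The chain does hold for rules in
activator/inhibitor template form, where a rule can never be ON while one
of its own inhibitors is active. The test suite asserts the two valid
inequalities as properties and documents the general-case violation.

## Dynamics

States are encoded as integers (bit *i* = value of the *i*-th node in
lexicographic order). Rules are compiled to per-node truth tables over
their regulators, so full-state-space sweeps are vectorized.

- Synchronous attractors: cycles of the deterministic map, found by
  iterating every state with path coloring.
- Asynchronous attractors: terminal strongly connected components of the
  state-transition graph (one unstable node flipped per transition),
  computed via graph condensation (networkx). A singleton terminal SCC is
  a fixed point; fixed points coincide across schemes since both solve
  f(x) = x.

Exact enumeration is capped at 22 nodes (~4M states). Beyond the cap an
explicit sampling mode runs random restarts — trajectory cycling for the
synchronous map; random walks plus a bounded forward closure whose
terminal SCCs are provably true attractors for the asynchronous scheme —
and flags results `complete=False`. Attractors are returned in canonical
order (smallest encoded state first) and labeled `<prefix><index>`, with
the tabular export labeling states `<prefix><index>.<j>`.

Activation frequency supports two weightings: `uniform_attractor` (mean
per attractor, then mean over attractors; the default, so a large cyclic
attractor does not dominate) and `uniform_state` (mean over the multiset
of all attractor states). The choice is recorded by the caller's output.

## Evaluation

Attractor *patterns* are per-gene mean activations over an attractor's
states; distance between patterns is the mean absolute difference over
shared genes (normalized Hamming distance on fixed points, in [0, 1]).
Patterns are clustered agglomeratively with average linkage on the
pairwise distance matrix (scipy), flat clusters cut at a distance
threshold.

The network score evaluates phenotype expressions (proliferation,
apoptosis, differentiation — kept as expressions over model nodes rather
than extra nodes, so the dynamics are unchanged) on each attractor state
as proliferation − apoptosis − differentiation ∈ [−2, 1], averages within
attractors and then across them; a per-attractor mode is exposed because
averaging over attractors is itself a modeling choice. Cohort scoring
clamps each distinct mutation profile (GoF → constant 1, LoF → constant
0), recomputes attractors, and weights by patient count; unknown genes are
dropped with a warning and counted, since real cohorts always carry
mutations outside any model. Correlation against outcome variables is
Pearson or Spearman (scipy), with integer patient-count weights handled by
frequency expansion.

## Synthetic data

The generator emulates the merging setting itself: pairs of
self-contained models with complementary node coverage and a configurable
shared-regulator core. Rules are random OR-of-ANDs over at most
`k_regulators` regulators (defaults: 10 nodes, k = 3, one input), with
literal polarity drawn by `activation_bias` (default 0.7, biased toward
activation as regulatory rules typically are, while leaving inhibitors
common enough to exercise IW and sign inference). Shared nodes are
regulated by shared nodes only so each model validates on its own; a
`divergence` fraction of shared nodes get independent rules in the second
model, recorded as ground truth in a sidecar JSON. All randomness flows
through numpy's PCG64 via `default_rng(seed)`, so outputs are
byte-identical across platforms for a given seed. A drawn self-identity
rule is normalized to an input, matching the rule-file convention.

What the generator does not emulate: scale-free topology, biologically
calibrated rule distributions, canalizing structure, or the curation noise
of real published models (inconsistent naming is exercised separately
through the mapping-table tests). Passing tests therefore demonstrate the
correctness of the composition and dynamics machinery, not biological
fidelity of any particular merged model.

## Numerical and engineering choices

- Exhaustive caps: 16 regulators for sign inference, 20 variables for
  equivalence checks, 22 nodes for exact attractor enumeration; each
  raises a specific error that names the sampling/syntactic alternative.
- Serialization emits minimal parentheses under the fixed precedence;
  parse(serialize(e)) is logically equivalent to e (property-tested).
- SBML-qual dialect: Level 3 Version 1 + qual version 1, Boolean species,
  one transition per regulated species, default term for the OFF case and
  a single ON function term in MathML and/or/not over `species = 1`
  equality tests — the smallest dialect common qualitative-modeling tools
  emit. CV-term annotations (`bqbiol:*`/`bqmodel:*`) survive round trips;
  unrecognized annotation payloads are carried opaquely.
- Verification problem sizes: the formula oracle sweeps 500 seeded pairs
  (nodes ≤ 10 per model) and the attractor oracle 200 seeded models in the
  test suite (150 and 100 in the faster acceptance script), exhaustively
  per model — sizes chosen to cover every rule shape the generator
  produces many times over while the whole suite stays in seconds.

## Known limitations

- Exact asynchronous analysis materializes the full state-transition
  graph; the 22-node cap is a memory/time guard, and sampling mode above
  it cannot certify completeness of the attractor list.
- The IW inhibitor pool treats inhibition globally per target; no
  per-source-model scoping is offered.
- Phenotype expressions are logical only; arithmetic phenotype functions
  are not supported.
- Survival modeling (hazard ratios) and raw expression-data processing are
  outside the package; only the score-vs-outcome correlation interface is
  provided.
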