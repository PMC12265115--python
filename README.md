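# boolmerge

Merge independently published Boolean gene-regulatory-network (GRN) models
into a single executable model, and evaluate the result by attractor
analysis, attractor-pattern clustering, mutation clamping and a
phenotype-based network score.

Published logical GRN models each cover one slice of a biological system —
a differentiation pathway here, a tumor-suppressor circuit there — under
their own gene-naming conventions. `boolmerge` is for systems biologists
who want to combine such models: it harmonizes node symbols against a
curated mapping table (including mouse-to-human ortholog reconciliation),
detects the overlap between models, composes the rules of shared nodes by
one of three deterministic strategies, and provides the dynamics and
scoring machinery to check that the merged model retains the behavior of
its sources.

## The rule-composition strategies

Each node *i* of a Boolean model holds 0/1 and is updated by a logical rule
*f_i* over its regulators, written with `!` (NOT), `&` (AND), `|` (OR).
Given *n* harmonized source models with rules *f_i^{M_j}* for a shared
node, the merged rule is one of:

- **OR** — ⋁_j *f_i^{M_j}*: the node activates if *any* source model
  predicts activation (inclusive; independent activation by multiple
  transcription factors).
- **AND** — ⋀_j *f_i^{M_j}*: the node activates only if *every* source
  model predicts activation (stringent; cooperative control).
- **Inhibitor Wins (IW)** — 0 on any state where some inhibitory regulator
  pooled from the source rules is ON, otherwise the OR combination; in
  closed form ¬(⋁ I) ∧ ⋁_j *f_i^{M_j}* with I the pooled inhibitor set.
  Inhibitors are found semantically by exhaustive flip test (a regulator
  whose activation can only turn the target off), with a syntactic
  negation-parity fallback for large rules.

The strategy is configurable per node. Long-term behavior is read from
attractors: fixed points and cyclic attractors under synchronous update
(cycles of the deterministic map) or asynchronous update (terminal
strongly connected components of the state-transition graph). Clinical
readouts use phenotype expressions and the network score
*proliferation − apoptosis − differentiation*, averaged over attractor
states, with mutation profiles applied by clamping (gain of function → 1,
loss of function → 0).

## Worked example

Merge two toy hematopoiesis models that share the antagonistic pair
GATA1/PU1 under Inhibitor Wins, then enumerate asynchronous attractors:

```python
import boolmerge as bm

erythroid = bm.LogicalModel.from_rules(
    {"GATA1": "GATA1 & !PU1", "PU1": "PU1 & !GATA1", "KLF1": "GATA1"},
    model_id="erythroid",
)
myeloid = bm.LogicalModel.from_rules(
    {"PU1": None, "CEBPA": "PU1 & !GATA1", "GATA1": "GATA1 & !CEBPA"},
    model_id="myeloid",
)
merged, report = bm.merge_models([erythroid, myeloid], bm.MergeConfig("IW"))
print(report.to_string(index=False))
attrs = bm.attractors(merged, scheme="asynchronous", label_prefix="M")
print(bm.attractors_to_frame(attrs).to_string(index=False))
```

which prints

```
 node           sources strategy inhibitors_used
CEBPA           myeloid   single
GATA1 erythroid;myeloid       IW       CEBPA,PU1
 KLF1         erythroid   single
  PU1 erythroid;myeloid   single
label state        kind       scheme  complete  CEBPA  GATA1  KLF1  PU1
   M1  M1.1 fixed_point asynchronous      True      0      0     0    0
   M2  M2.1 fixed_point asynchronous      True      0      1     1    0
   M3  M3.1 fixed_point asynchronous      True      1      0     0    1
```

GATA1 is shared by both models, so its merged rule pools the inhibitors
CEBPA and PU1 (`!(CEBPA | PU1) & (...)`); PU1 is an unregulated input in
the myeloid model, so the erythroid rule carries over unchanged
(`single`). The three fixed points are the expected cell states: all-off,
an erythroid-like state (GATA1/KLF1 on) and a myeloid-like state
(PU1/CEBPA on), with the mutual GATA1–PU1 antagonism keeping the lineages
exclusive.

The same pipeline is available from a shell:

```sh
boolmerge synth --out-dir fixtures --pair --overlap 3 --seed 5
boolmerge merge fixtures/synthA.bnet fixtures/synthB.bnet -o merged.bnet --strategy IW
boolmerge attractors merged.bnet --scheme async -o attractors.csv
```

plus `convert` (SBML-qual ↔ bnet), `annotate` (symbol harmonization with a
TSV mapping table) and `score` (cohort network scores from a mutation
table, optionally correlated against an outcome column).

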