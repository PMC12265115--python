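"""State-space dynamics of Boolean models.

States are total 0/1 assignments; the canonical encoding packs them into an
integer with bit *i* holding the value of the *i*-th node in lexicographic
node order.  Two update schemes are supported:

* synchronous — all nodes updated at once; a deterministic map whose
  attractors are the cycles of the functional graph;
* asynchronous — one unstable node flipped at a time; a nondeterministic
  state-transition graph (STG) whose attractors are the terminal strongly
  connected components.

Fixed points coincide under both schemes (solutions of ``f(x) = x``).
Input nodes hold their value under both schemes, so exhaustive enumeration
automatically yields attractors per input combination; each attractor is
labeled with its input context.

Exact analysis enumerates all ``2^n`` states and is capped (default 22
nodes); beyond that an explicit sampling mode estimates the attractor set
from random restarts and flags completeness as unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .logic import Const, evaluate, variables
from .model import GOF, LOF, LogicalModel, MutationProfile, NodeSpec

__all__ = [
    "Attractor",
    "StateSpaceCapError",
    "encode_state",
    "decode_state",
    "sync_step",
    "async_successors",
    "attractors",
    "activation_frequency",
    "clamp",
    "attractors_to_frame",
]

DEFAULT_EXHAUSTIVE_CAP = 22

SYNC = "synchronous"
ASYNC = "asynchronous"


class StateSpaceCapError(ValueError):
    """Exact enumeration requested beyond the exhaustive node cap."""


@dataclass
class Attractor:
    """A fixed point or cyclic attractor under one update scheme."""

    kind: str  # "fixed_point" | "cyclic"
    scheme: str  # "synchronous" | "asynchronous"
    states: tuple[dict[str, int], ...]
    label: str = ""
    input_context: dict[str, int] = field(default_factory=dict)
    complete: bool = True  # False when found by sampling

    @property
    def is_fixed_point(self) -> bool:
        return self.kind == "fixed_point"

    def __len__(self) -> int:
        return len(self.states)

    def mean_activation(self) -> dict[str, float]:
        """Per-gene mean value over the attractor's states (its pattern)."""
        genes = self.states[0].keys()
        n = len(self.states)
        return {
            g: sum(s[g] for s in self.states) / n for g in genes
        }


# ---------------------------------------------------------------------------
# state encoding and compiled update tables


def encode_state(state: Mapping[str, int], order: Sequence[str]) -> int:
    """Pack a state dict into an integer (bit i = value of order[i])."""
    code = 0
    for i, name in enumerate(order):
        if state[name]:
            code |= 1 << i
    return code


def decode_state(code: int, order: Sequence[str]) -> dict[str, int]:
    return {name: (code >> i) & 1 for i, name in enumerate(order)}


class _Compiled:
    """Per-node truth tables over regulator indices, for fast stepping."""

    def __init__(self, model: LogicalModel) -> None:
        self.order: list[str] = model.sorted_ids()
        index = {name: i for i, name in enumerate(self.order)}
        self.n = len(self.order)
        self.regs: list[tuple[int, ...]] = []
        self.tables: list[np.ndarray] = []
        self.input_idx: list[int] = []
        for i, name in enumerate(self.order):
            node = model[name]
            if node.rule is None:
                self.input_idx.append(i)
                self.regs.append((i,))
                self.tables.append(np.array([0, 1], dtype=np.uint8))
                continue
            reg_names = sorted(variables(node.rule), key=index.__getitem__)
            table = np.empty(1 << len(reg_names), dtype=np.uint8)
            for bits in range(1 << len(reg_names)):
                assignment = {
                    reg_names[j]: (bits >> j) & 1
                    for j in range(len(reg_names))
                }
                table[bits] = evaluate(node.rule, assignment)
            self.regs.append(tuple(index[r] for r in reg_names))
            self.tables.append(table)

    def node_value(self, i: int, code: int) -> int:
        regs = self.regs[i]
        idx = 0
        for j, r in enumerate(regs):
            idx |= ((code >> r) & 1) << j
        return int(self.tables[i][idx])

    def sync_next(self, code: int) -> int:
        out = 0
        for i in range(self.n):
            if self.node_value(i, code):
                out |= 1 << i
        return out

    def unstable_nodes(self, code: int) -> list[int]:
        return [
            i
            for i in range(self.n)
            if self.node_value(i, code) != ((code >> i) & 1)
        ]

    # vectorized full enumeration ------------------------------------------

    def sync_next_all(self) -> np.ndarray:
        """next-state code for every state 0..2^n-1 (synchronous map)."""
        states = np.arange(1 << self.n, dtype=np.int64)
        nxt = np.zeros_like(states)
        for i in range(self.n):
            idx = np.zeros_like(states)
            for j, r in enumerate(self.regs[i]):
                idx |= ((states >> r) & 1) << j
            nxt |= self.tables[i][idx].astype(np.int64) << i
        return nxt

    def node_values_all(self) -> np.ndarray:
        """(n, 2^n) matrix of f_i(x) for every node and state."""
        states = np.arange(1 << self.n, dtype=np.int64)
        out = np.empty((self.n, states.size), dtype=np.uint8)
        for i in range(self.n):
            idx = np.zeros_like(states)
            for j, r in enumerate(self.regs[i]):
                idx |= ((states >> r) & 1) << j
            out[i] = self.tables[i][idx]
        return out


def sync_step(model: LogicalModel, state: Mapping[str, int]) -> dict[str, int]:
    """One synchronous update: every regulated node re-evaluated, inputs
    held."""
    out = dict(state)
    for node in model:
        if node.rule is not None:
            out[node.node_id] = evaluate(node.rule, state)
    return out


def async_successors(
    model: LogicalModel, state: Mapping[str, int]
) -> list[dict[str, int]]:
    """Asynchronous successors: one per unstable node, flipping only it.

    Empty list iff ``state`` is a fixed point.
    """
    succs = []
    for node in model:
        if node.rule is None:
            continue
        val = evaluate(node.rule, state)
        if val != state[node.node_id]:
            s = dict(state)
            s[node.node_id] = val
            succs.append(s)
    return succs


# ---------------------------------------------------------------------------
# attractor detection


def attractors(
    model: LogicalModel,
    scheme: str = ASYNC,
    cap: int = DEFAULT_EXHAUSTIVE_CAP,
    mode: str = "exact",
    n_samples: int = 200,
    max_steps: int = 2000,
    closure_limit: int = 20000,
    seed: int | None = None,
    label_prefix: str | None = None,
) -> list[Attractor]:
    """All attractors of ``model`` under the given update scheme.

    Exact mode (default) enumerates every state: synchronous attractors are
    the cycles of the deterministic map, asynchronous attractors the
    terminal SCCs of the full STG.  Above ``cap`` nodes exact mode raises
    :class:`StateSpaceCapError`; ``mode="sample"`` then explores from
    ``n_samples`` random initial states and returns attractors flagged
    ``complete=False``.

    Attractors are returned in canonical order (smallest encoded state
    first) and labeled ``<prefix><index>`` (prefix defaults to the first
    letter of the model id, uppercased).
    """
    if scheme not in (SYNC, ASYNC):
        raise ValueError(f"unknown scheme {scheme!r}")
    comp = _Compiled(model)
    if mode == "exact":
        if comp.n > cap:
            raise StateSpaceCapError(
                f"{comp.n} nodes exceed the exhaustive cap {cap}; "
                "request mode='sample' explicitly"
            )
        if scheme == SYNC:
            raw = _sync_attractors_exact(comp)
        else:
            raw = _async_attractors_exact(comp)
        complete = True
    elif mode == "sample":
        rng = np.random.default_rng(seed)
        if scheme == SYNC:
            raw = _sync_attractors_sampled(comp, rng, n_samples, max_steps)
        else:
            raw = _async_attractors_sampled(
                comp, rng, n_samples, max_steps, closure_limit
            )
        complete = False
    else:
        raise ValueError(f"unknown mode {mode!r}")

    raw = sorted(set(frozenset(states) for states in raw), key=min)
    prefix = label_prefix
    if prefix is None:
        prefix = (model.model_id[:1] or "A").upper()
    input_idx = comp.input_idx
    out = []
    for k, states in enumerate(raw, start=1):
        codes = sorted(states)
        dicts = tuple(decode_state(c, comp.order) for c in codes)
        if len(codes) == 1:
            if scheme == SYNC:
                fixed = comp.sync_next(codes[0]) == codes[0]
            else:
                fixed = not comp.unstable_nodes(codes[0])
        else:
            fixed = False
        ctx = {
            comp.order[i]: (codes[0] >> i) & 1 for i in input_idx
        }
        out.append(
            Attractor(
                kind="fixed_point" if fixed else "cyclic",
                scheme=scheme,
                states=dicts,
                label=f"{prefix}{k}",
                input_context=ctx,
                complete=complete,
            )
        )
    return out


def _sync_attractors_exact(comp: _Compiled) -> list[set[int]]:
    nxt = comp.sync_next_all()
    n_states = nxt.size
    color = np.zeros(n_states, dtype=np.uint8)  # 0 new, 1 done
    cycles: list[set[int]] = []
    for s in range(n_states):
        if color[s]:
            continue
        path: list[int] = []
        pos: dict[int, int] = {}
        cur = s
        while color[cur] == 0 and cur not in pos:
            pos[cur] = len(path)
            path.append(cur)
            cur = int(nxt[cur])
        if color[cur] == 0:
            cycles.append(set(path[pos[cur]:]))
        for p in path:
            color[p] = 1
    return cycles


def _async_edges(comp: _Compiled) -> tuple[np.ndarray, np.ndarray]:
    states = np.arange(1 << comp.n, dtype=np.int64)
    values = comp.node_values_all()
    srcs = []
    dsts = []
    for i in range(comp.n):
        cur = (states >> i) & 1
        unstable = values[i] != cur
        src = states[unstable]
        srcs.append(src)
        dsts.append(src ^ (1 << i))
    return np.concatenate(srcs), np.concatenate(dsts)


def _async_attractors_exact(comp: _Compiled) -> list[set[int]]:
    src, dst = _async_edges(comp)
    g = nx.DiGraph()
    g.add_nodes_from(range(1 << comp.n))
    g.add_edges_from(zip(src.tolist(), dst.tolist()))
    cond = nx.condensation(g)
    out = []
    for c, data in cond.nodes(data=True):
        if cond.out_degree(c) == 0:
            out.append(set(data["members"]))
    return out


def _sync_attractors_sampled(
    comp: _Compiled, rng: np.random.Generator, n_samples: int, max_steps: int
) -> list[set[int]]:
    n_states = 1 << comp.n
    found: set[frozenset[int]] = set()
    for _ in range(n_samples):
        cur = int(rng.integers(n_states))
        pos: dict[int, int] = {}
        path: list[int] = []
        for _ in range(max_steps):
            if cur in pos:
                found.add(frozenset(path[pos[cur]:]))
                break
            pos[cur] = len(path)
            path.append(cur)
            cur = comp.sync_next(cur)
    return [set(s) for s in found]


def _async_attractors_sampled(
    comp: _Compiled,
    rng: np.random.Generator,
    n_samples: int,
    max_steps: int,
    closure_limit: int,
) -> list[set[int]]:
    n_states = 1 << comp.n
    found: set[frozenset[int]] = set()
    for _ in range(n_samples):
        cur = int(rng.integers(n_states))
        for _ in range(max_steps):
            unstable = comp.unstable_nodes(cur)
            if not unstable:
                break
            i = unstable[int(rng.integers(len(unstable)))]
            cur ^= 1 << i
        # bounded forward closure from the walk endpoint; if it closes, its
        # terminal SCCs are true attractors of the full STG
        closure = {cur}
        frontier = [cur]
        closed = True
        while frontier:
            nxt_frontier = []
            for s in frontier:
                for i in comp.unstable_nodes(s):
                    t = s ^ (1 << i)
                    if t not in closure:
                        closure.add(t)
                        nxt_frontier.append(t)
            frontier = nxt_frontier
            if len(closure) > closure_limit:
                closed = False
                break
        if not closed:
            continue
        g = nx.DiGraph()
        g.add_nodes_from(closure)
        for s in closure:
            for i in comp.unstable_nodes(s):
                g.add_edge(s, s ^ (1 << i))
        cond = nx.condensation(g)
        for c, data in cond.nodes(data=True):
            if cond.out_degree(c) == 0:
                found.add(frozenset(data["members"]))
    return [set(s) for s in found]


# ---------------------------------------------------------------------------
# derived quantities


def activation_frequency(
    attrs: Sequence[Attractor], weighting: str = "uniform_attractor"
) -> dict[str, float]:
    """Mean activation of each node over the attractor set.

    ``uniform_attractor`` averages each attractor's per-gene mean and then
    averages over attractors (every attractor counts once regardless of
    size); ``uniform_state`` averages over the multiset of all attractor
    states.
    """
    if not attrs:
        raise ValueError("activation_frequency requires at least one attractor")
    if weighting not in ("uniform_attractor", "uniform_state"):
        raise ValueError(f"unknown weighting {weighting!r}")
    genes = list(attrs[0].states[0].keys())
    if weighting == "uniform_attractor":
        acc = {g: 0.0 for g in genes}
        for a in attrs:
            pat = a.mean_activation()
            for g in genes:
                acc[g] += pat[g]
        return {g: acc[g] / len(attrs) for g in genes}
    total = 0
    acc = {g: 0.0 for g in genes}
    for a in attrs:
        for s in a.states:
            total += 1
            for g in genes:
                acc[g] += s[g]
    return {g: acc[g] / total for g in genes}


def clamp(model: LogicalModel, profile: MutationProfile) -> LogicalModel:
    """Personalize a model with a mutation profile.

    Gain-of-function genes get the constant-1 rule, loss-of-function
    constant-0; everything else is untouched.  Unknown genes raise.
    """
    missing = sorted(g for g in profile.effects if g not in model)
    if missing:
        raise KeyError(
            f"mutation profile names genes absent from the model: {missing}"
        )
    out = model.copy()
    for gene, eff in profile.effects.items():
        out[gene].rule = Const(1 if eff == GOF else 0)
    return out


def attractors_to_frame(attrs: Sequence[Attractor]) -> pd.DataFrame:
    """Tabular attractor view: one row per attractor state.

    Columns: label, state, kind, scheme, complete, input context
    (``input:<gene>``), then one 0/1 column per gene.
    """
    rows = []
    for a in attrs:
        for j, s in enumerate(a.states, start=1):
            row: dict[str, object] = {
                "label": a.label,
                "state": f"{a.label}.{j}",
                "kind": a.kind,
                "scheme": a.scheme,
                "complete": a.complete,
            }
            for g, v in a.input_context.items():
                row[f"input:{g}"] = v
            row.update(s)
            rows.append(row)
    return pd.DataFrame(rows)
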