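"""Seeded random Boolean networks and overlapping model pairs.

The generator emulates the merging setting of two independently published
gene-regulatory models: complementary node coverage with a handful of
shared regulators.  Rules are random OR-of-ANDs over up to ``k_regulators``
regulators with literal polarity drawn by ``activation_bias``, which
exercises all three merge strategies and sign inference nontrivially.
Shared nodes of a pair are regulated by shared nodes only, so each model
remains self-contained; a ``divergence`` fraction of shared nodes get
independent rules in the second model, and the generator records which, as
ground truth for merge tests.

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64),
so a seed pins the model byte-for-byte across platforms.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from typing import Union

import numpy as np

from .logic import BoolExpr, Var, conj, disj, negate, to_text
from .model import LogicalModel, NodeSpec

__all__ = ["SynthParams", "random_model", "overlapping_pair", "write_ground_truth"]

PathLike = Union[str, os.PathLike]


@dataclass
class SynthParams:
    """Knobs of the random-model generator.

    ``n_nodes`` — model size; ``k_regulators`` — max in-degree per rule;
    ``activation_bias`` — probability a literal is positive (1.0 yields a
    network without inhibitors); ``overlap`` — shared-node count for the
    pair generator; ``divergence`` — probability a shared node's rule
    differs between the pair; ``n_inputs`` — unregulated nodes.
    """

    n_nodes: int = 10
    k_regulators: int = 3
    activation_bias: float = 0.7
    seed: int = 0
    overlap: int = 3
    divergence: float = 0.0
    n_inputs: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.k_regulators <= self.n_nodes:
            raise ValueError("need 1 <= k_regulators <= n_nodes")
        if not 0 <= self.overlap <= self.n_nodes:
            raise ValueError("overlap must be within [0, n_nodes]")
        for p_name in ("activation_bias", "divergence"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{p_name} must be in [0, 1]")
        if not 0 <= self.n_inputs < self.n_nodes:
            raise ValueError("need 0 <= n_inputs < n_nodes")


def _random_rule(
    rng: np.random.Generator,
    pool: list[str],
    k: int,
    bias: float,
) -> BoolExpr:
    """Random OR-of-ANDs over <= k regulators drawn from ``pool``."""
    k_eff = int(rng.integers(1, min(k, len(pool)) + 1))
    regs = rng.choice(pool, size=k_eff, replace=False).tolist()
    n_clauses = int(rng.integers(1, min(2, k_eff) + 1))
    # split regulators over clauses; every chosen regulator appears once
    rng.shuffle(regs)
    bounds = sorted(
        rng.choice(range(1, k_eff), size=n_clauses - 1, replace=False)
    ) if n_clauses > 1 else []
    clauses = []
    prev = 0
    for b in list(bounds) + [k_eff]:
        lits = []
        for r in regs[prev:b]:
            lit: BoolExpr = Var(r)
            if rng.random() >= bias:
                lit = negate(lit)
            lits.append(lit)
        clauses.append(conj(lits))
        prev = b
    return disj(clauses)


def random_model(params: SynthParams, model_id: str = "synthetic") -> LogicalModel:
    """Seeded random Boolean network; same params give an identical model."""
    rng = np.random.default_rng(params.seed)
    names = [f"G{i:03d}" for i in range(1, params.n_nodes + 1)]
    input_names = set(
        rng.choice(names, size=params.n_inputs, replace=False).tolist()
    )
    nodes = []
    for name in names:
        if name in input_names:
            nodes.append(NodeSpec(name, None))
        else:
            rule = _random_rule(
                rng, names, params.k_regulators, params.activation_bias
            )
            # a drawn self-identity rule is an input by convention
            nodes.append(NodeSpec(name, None if rule == Var(name) else rule))
    model = LogicalModel(
        nodes,
        model_id=model_id,
        source={"generator": "boolmerge.synth", "rng": "PCG64",
                "seed": str(params.seed)},
    )
    assert not model.validate()
    return model


def overlapping_pair(
    params: SynthParams,
) -> tuple[LogicalModel, LogicalModel, set[str]]:
    """Two models sharing exactly ``params.overlap`` node symbols.

    Shared nodes are regulated by shared nodes only (each model stays
    self-contained); with ``divergence=0`` the shared rules are identical
    in both models.  Ground truth (which shared nodes diverge) is stored in
    each model's ``source['diverged']``.
    """
    rng = np.random.default_rng(params.seed)
    n_shared = params.overlap
    n_own = params.n_nodes - n_shared
    shared = [f"S{i:03d}" for i in range(1, n_shared + 1)]
    own_a = [f"A{i:03d}" for i in range(1, n_own + 1)]
    own_b = [f"B{i:03d}" for i in range(1, n_own + 1)]

    def build(own: list[str], shared_rules: dict[str, BoolExpr | None]):
        names = shared + own
        nodes = [
            NodeSpec(
                s,
                None if shared_rules[s] == Var(s) else shared_rules[s],
            )
            for s in shared
        ]
        n_inputs = min(params.n_inputs, len(own))
        inputs = set(
            rng.choice(own, size=n_inputs, replace=False).tolist()
        ) if own else set()
        for name in own:
            if name in inputs:
                nodes.append(NodeSpec(name, None))
            else:
                rule = _random_rule(
                    rng, names, params.k_regulators, params.activation_bias,
                )
                nodes.append(
                    NodeSpec(name, None if rule == Var(name) else rule)
                )
        return nodes

    def shared_rule() -> BoolExpr | None:
        if not shared:
            return None
        return _random_rule(
            rng, shared, min(params.k_regulators, len(shared)),
            params.activation_bias,
        )

    rules_a = {s: shared_rule() for s in shared}
    diverged = [s for s in shared if rng.random() < params.divergence]
    rules_b = dict(rules_a)
    for s in diverged:
        rules_b[s] = shared_rule()

    meta = {"generator": "boolmerge.synth", "rng": "PCG64",
            "seed": str(params.seed), "diverged": json.dumps(diverged)}
    a = LogicalModel(build(own_a, rules_a), model_id="synthA", source=dict(meta))
    b = LogicalModel(build(own_b, rules_b), model_id="synthB", source=dict(meta))
    assert not a.validate() and not b.validate()
    return a, b, set(shared)


def write_ground_truth(
    model_or_pair, params: SynthParams, path: PathLike
) -> None:
    """Sidecar JSON with generator params and per-model ground truth."""
    payload: dict = {"params": asdict(params), "rng": "PCG64"}
    if isinstance(model_or_pair, LogicalModel):
        payload["models"] = [_truth(model_or_pair)]
    else:
        a, b, shared = model_or_pair
        payload["models"] = [_truth(a), _truth(b)]
        payload["shared"] = sorted(shared)
        payload["diverged"] = json.loads(a.source.get("diverged", "[]"))
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def _truth(model: LogicalModel) -> dict:
    return {
        "model_id": model.model_id,
        "rules": {
            nid: (None if n.rule is None else to_text(n.rule))
            for nid, n in model.nodes.items()
        },
        "inputs": model.input_ids(),
    }
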