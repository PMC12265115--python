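"""Compose harmonized logical models into one merged model.

Three deterministic rule-combination strategies are offered for nodes
shared between models, each with a different biological reading:

* ``OR`` — a node activates if any source model predicts activation
  (inclusive; multiple transcription factors can independently activate).
* ``AND`` — a node activates only if every source model predicts activation
  (stringent; cooperative control).
* ``IW`` (Inhibitor Wins) — any active inhibitory regulator from any source
  rule forces the node off; otherwise the OR-combination applies.  Closed
  form: ``!(OR of pooled inhibitors) & (OR of source rules)``.

The inhibitor set for IW is pooled across *all* source rules of the node.
Inhibitors are detected semantically (exhaustive flip test) by default or
syntactically (negation parity) for large rules.  Dual-signed regulators
are conservatively treated as inhibitors, with a warning.

A strategy can be overridden per node; nodes present in a single model keep
their rule untouched, and a node that is an input in some models but
regulated in at least one takes the combination of the regulated rules only
(absence of a rule is absence of knowledge, not a constant).
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import pandas as pd

from .logic import (
    BoolExpr,
    SIGN_DUAL,
    SIGN_INHIBITOR,
    Var,
    conj,
    disj,
    infer_signs,
    negate,
    syntactic_signs,
)
from .model import LogicalModel, NodeSpec

__all__ = [
    "MergeConfig",
    "MergeConfigError",
    "merge_models",
    "combine_or",
    "combine_and",
    "combine_iw",
    "pooled_inhibitors",
]

STRATEGIES = ("OR", "AND", "IW")
PathLike = Union[str, os.PathLike]


class MergeConfigError(ValueError):
    pass


@dataclass
class MergeConfig:
    """Default strategy plus per-node overrides.

    JSON form::

        {"default": "OR",
         "per_node": {"TP53": "IW"},
         "inhibitor_detection": "semantic"}
    """

    default_strategy: str = "OR"
    per_node: dict[str, str] = field(default_factory=dict)
    inhibitor_detection: str = "semantic"

    def __post_init__(self) -> None:
        if self.default_strategy not in STRATEGIES:
            raise MergeConfigError(
                f"unknown strategy {self.default_strategy!r}; "
                f"choose one of {STRATEGIES}"
            )
        for node, strat in self.per_node.items():
            if strat not in STRATEGIES:
                raise MergeConfigError(
                    f"unknown strategy {strat!r} for node {node!r}"
                )
        if self.inhibitor_detection not in ("semantic", "syntactic"):
            raise MergeConfigError(
                "inhibitor_detection must be 'semantic' or 'syntactic'"
            )

    def strategy_for(self, node: str) -> str:
        return self.per_node.get(node, self.default_strategy)

    @classmethod
    def from_json(cls, path: PathLike) -> "MergeConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            default_strategy=payload.get("default", "OR"),
            per_node=dict(payload.get("per_node", {})),
            inhibitor_detection=payload.get("inhibitor_detection", "semantic"),
        )

    def to_json(self, path: PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "default": self.default_strategy,
                    "per_node": self.per_node,
                    "inhibitor_detection": self.inhibitor_detection,
                },
                fh,
                indent=2,
            )


def combine_or(rules: Sequence[BoolExpr]) -> BoolExpr:
    """Disjunction of source rules: pointwise max."""
    if not rules:
        raise ValueError("combine_or requires at least one rule")
    return disj(rules)


def combine_and(rules: Sequence[BoolExpr]) -> BoolExpr:
    """Conjunction of source rules: pointwise min."""
    if not rules:
        raise ValueError("combine_and requires at least one rule")
    return conj(rules)


def pooled_inhibitors(
    rules: Sequence[BoolExpr],
    target: str,
    detection: str = "semantic",
    cap: int = 16,
) -> set[str]:
    """Union over source rules of the target's inhibitory regulators.

    Dual-signed regulators count as inhibitors (inhibition dominates) and
    trigger a warning.
    """
    inhibitors: set[str] = set()
    for rule in rules:
        if detection == "semantic":
            infs = infer_signs(rule, target, cap=cap)
        else:
            infs = syntactic_signs(rule, target)
        for inf in infs:
            if inf.sign == SIGN_INHIBITOR:
                inhibitors.add(inf.regulator)
            elif inf.sign == SIGN_DUAL:
                warnings.warn(
                    f"regulator {inf.regulator!r} of {target!r} is "
                    "dual-signed; treated as inhibitor under Inhibitor Wins",
                    stacklevel=2,
                )
                inhibitors.add(inf.regulator)
    return inhibitors


def combine_iw(
    rules: Sequence[BoolExpr],
    target: str = "node",
    detection: str = "semantic",
    cap: int = 16,
) -> BoolExpr:
    """Inhibitor-Wins combination.

    The result is 0 on any state where some pooled inhibitor is ON, and the
    OR-combination elsewhere: ``!(i1 | i2 | ...) & (f1 | f2 | ...)``.
    """
    if not rules:
        raise ValueError("combine_iw requires at least one rule")
    inhibitors = pooled_inhibitors(rules, target, detection=detection, cap=cap)
    combined = combine_or(rules)
    if not inhibitors:
        return combined
    guard = negate(disj(Var(i) for i in sorted(inhibitors)))
    return conj([guard, combined])


def merge_models(
    models: Sequence[LogicalModel],
    config: MergeConfig | None = None,
    model_id: str = "merged",
) -> tuple[LogicalModel, pd.DataFrame]:
    """Merge two or more harmonized models into one.

    The merged node set is the union of all source node sets.  Per node:

    * present in one model only -> rule carried over unchanged;
    * input everywhere -> stays an input;
    * regulated in >= 1 model -> the configured combination of the
      *regulated* source rules.

    Returns the merged model and a provenance report with one row per node
    (``node``, ``sources``, ``strategy``, ``inhibitors_used``).
    """
    if len(models) < 2:
        raise ValueError("merging requires at least two models")
    config = config or MergeConfig()
    all_symbols: set[str] = set()
    for m in models:
        all_symbols |= set(m.node_ids())
    unknown = [n for n in config.per_node if n not in all_symbols]
    if unknown:
        raise MergeConfigError(
            f"per_node strategy for nodes absent from every model: {unknown}"
        )

    nodes: list[NodeSpec] = []
    rows = []
    for sym in sorted(all_symbols):
        present = [m for m in models if sym in m]
        rules = [m[sym].rule for m in present if m[sym].rule is not None]
        sources = ";".join(m.model_id for m in present)
        annotations: dict[str, list[str]] = {}
        for m in present:
            for k, v in m[sym].annotations.items():
                bucket = annotations.setdefault(k, [])
                bucket.extend(u for u in v if u not in bucket)
        inhibitors_used = ""
        if not rules:
            rule: BoolExpr | None = None
            strategy = "input"
        elif len(rules) == 1:
            rule = rules[0]
            strategy = "single"
        else:
            strategy = config.strategy_for(sym)
            if strategy == "OR":
                rule = combine_or(rules)
            elif strategy == "AND":
                rule = combine_and(rules)
            else:
                pooled = pooled_inhibitors(
                    rules, sym, detection=config.inhibitor_detection
                )
                rule = combine_iw(
                    rules, sym, detection=config.inhibitor_detection
                )
                inhibitors_used = ",".join(sorted(pooled))
        nodes.append(NodeSpec(sym, rule, annotations=annotations))
        rows.append((sym, sources, strategy, inhibitors_used))

    merged = LogicalModel(
        nodes,
        model_id=model_id,
        species=models[0].species,
        source={"merged_from": ";".join(m.model_id for m in models)},
    )
    report = pd.DataFrame(
        rows, columns=["node", "sources", "strategy", "inhibitors_used"]
    )
    return merged, report
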