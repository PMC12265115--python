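"""Logical-model container: nodes, rules, annotations, provenance.

A :class:`LogicalModel` is a named collection of nodes, each carrying a
Boolean update rule over other nodes of the same model.  Nodes without a
rule are *inputs*: they hold their value under both update schemes unless
clamped or enumerated over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .logic import (
    BoolExpr,
    SignedInfluence,
    SIGN_NONE,
    Var,
    infer_signs,
    parse_rule,
    substitute,
    to_text,
    variables,
)

__all__ = [
    "NodeSpec",
    "LogicalModel",
    "MutationProfile",
    "validate",
]

GOF = "GoF"
LOF = "LoF"


@dataclass
class NodeSpec:
    """One node of a logical model.

    ``rule is None`` marks an external input.  ``annotations`` maps a
    qualifier/namespace (e.g. ``bqbiol:is``, ``hgnc``) to identifier
    strings; unknown annotation payloads are carried through opaquely.
    """

    node_id: str
    rule: BoolExpr | None = None
    display_symbol: str | None = None
    annotations: dict[str, list[str]] = field(default_factory=dict)
    evidence: str | None = None

    def __post_init__(self) -> None:
        if self.display_symbol is None:
            self.display_symbol = self.node_id

    @property
    def is_input(self) -> bool:
        return self.rule is None

    def copy(self) -> "NodeSpec":
        return NodeSpec(
            self.node_id,
            self.rule,
            self.display_symbol,
            {k: list(v) for k, v in self.annotations.items()},
            self.evidence,
        )


class LogicalModel:
    """Ordered collection of :class:`NodeSpec` with provenance metadata.

    Node order is preserved as given (file order); iteration and
    serialization helpers expose a lexicographic order where determinism
    matters.
    """

    def __init__(
        self,
        nodes: Iterable[NodeSpec],
        model_id: str = "model",
        species: str = "",
        source: Mapping[str, str] | None = None,
    ) -> None:
        self.model_id = model_id
        self.species = species
        self.source = dict(source or {})
        self.nodes: dict[str, NodeSpec] = {}
        # duplicates kept aside (first occurrence wins) so validate() can
        # report them as diagnostics instead of failing construction
        self._duplicate_ids: list[str] = []
        for n in nodes:
            if n.node_id in self.nodes:
                self._duplicate_ids.append(n.node_id)
            else:
                self.nodes[n.node_id] = n

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_rules(
        cls,
        rules: Mapping[str, str | BoolExpr | None],
        model_id: str = "model",
        species: str = "",
        source: Mapping[str, str] | None = None,
    ) -> "LogicalModel":
        """Build a model from ``{node_id: rule-text | BoolExpr | None}``.

        ``None`` (or the node's own name as rule text) marks an input.
        """
        nodes = []
        for nid, rule in rules.items():
            if rule is None:
                expr: BoolExpr | None = None
            elif isinstance(rule, str):
                expr = parse_rule(rule)
            else:
                expr = rule
            if expr is not None and expr == Var(nid):
                expr = None  # self-identity convention marks an input
            nodes.append(NodeSpec(nid, expr))
        return cls(nodes, model_id=model_id, species=species, source=source)

    def copy(self, model_id: str | None = None) -> "LogicalModel":
        return LogicalModel(
            (n.copy() for n in self.nodes.values()),
            model_id=model_id or self.model_id,
            species=self.species,
            source=dict(self.source),
        )

    # -- basic accessors -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[NodeSpec]:
        return iter(self.nodes.values())

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def __getitem__(self, node_id: str) -> NodeSpec:
        return self.nodes[node_id]

    def __repr__(self) -> str:
        return (
            f"LogicalModel({self.model_id!r}, {len(self.nodes)} nodes, "
            f"{len(self.input_ids())} inputs)"
        )

    def node_ids(self) -> list[str]:
        """Node identifiers in stored order."""
        return list(self.nodes)

    def sorted_ids(self) -> list[str]:
        return sorted(self.nodes)

    def input_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes.values() if n.is_input]

    def symbols(self) -> set[str]:
        return {n.display_symbol for n in self.nodes.values()}

    def rules_text(self) -> dict[str, str | None]:
        return {
            nid: (None if n.rule is None else to_text(n.rule))
            for nid, n in self.nodes.items()
        }

    # -- analysis ------------------------------------------------------------

    def validate(self) -> list[str]:
        return validate(self)

    def interaction_graph(self, cap: int = 16) -> list[SignedInfluence]:
        """Signed regulatory edges, inferred semantically per node rule.

        Regulators with no semantic influence (sign ``none``) are omitted.
        Deterministic order: target then regulator, lexicographic.
        """
        edges: list[SignedInfluence] = []
        for nid in sorted(self.nodes):
            node = self.nodes[nid]
            if node.rule is None:
                continue
            for inf in infer_signs(node.rule, nid, cap=cap):
                if inf.sign != SIGN_NONE:
                    edges.append(inf)
        edges.sort(key=lambda e: (e.target, e.regulator))
        return edges

    def rename_nodes(self, renames: Mapping[str, str]) -> "LogicalModel":
        """Return a copy with node ids, symbols and rules renamed."""
        nodes = []
        for n in self.nodes.values():
            new = n.copy()
            if n.node_id in renames:
                new.node_id = renames[n.node_id]
                new.display_symbol = renames[n.node_id]
            if new.rule is not None:
                new.rule = substitute(new.rule, renames)
            nodes.append(new)
        return LogicalModel(
            nodes, model_id=self.model_id, species=self.species,
            source=dict(self.source),
        )


def validate(model: LogicalModel) -> list[str]:
    """Diagnostics for model invariants; empty list means valid.

    Checks: at least one node, no duplicate node ids, and no rule
    referencing an absent node.
    """
    diags: list[str] = []
    if len(model.nodes) == 0:
        diags.append("model has no nodes")
    for dup in model._duplicate_ids:
        diags.append(f"duplicate node id {dup!r}")
    for nid, node in model.nodes.items():
        if node.rule is None:
            continue
        for ref in sorted(variables(node.rule)):
            if ref not in model.nodes:
                diags.append(
                    f"node {nid!r}: rule references absent node {ref!r}"
                )
    return diags


@dataclass
class MutationProfile:
    """Per-gene clamping effects: gain of function (``GoF``) forces a gene
    ON, loss of function (``LoF``) forces it OFF."""

    effects: dict[str, str] = field(default_factory=dict)
    profile_id: str = ""

    def __post_init__(self) -> None:
        for gene, eff in self.effects.items():
            if eff not in (GOF, LOF):
                raise ValueError(
                    f"effect for {gene!r} must be {GOF!r} or {LOF!r}, "
                    f"got {eff!r}"
                )

    def key(self) -> tuple[tuple[str, str], ...]:
        """Canonical hashable identity (gene order ignored)."""
        return tuple(sorted(self.effects.items()))

    def __len__(self) -> int:
        return len(self.effects)
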