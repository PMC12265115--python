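"""Gene-symbol harmonization: mapping tables, overlap detection, and
translation of signed interaction graphs into rules.

Symbol mapping is offline-first: a curated TSV table (alias -> approved
HGNC symbol) is the source of truth.  Cross-species models (e.g. mouse
hematopoiesis networks) are reconciled to human symbols through ``ortholog``
rows of the same table.  The mapping step is semi-automated by design —
collisions (two distinct nodes mapping to one approved symbol) raise and
require manual resolution, and fusion proteins or complexes with no
standard nomenclature pass through unmapped with a warning in the report.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import pandas as pd

from .logic import (
    SignedInfluence,
    SIGN_ACTIVATOR,
    SIGN_DUAL,
    SIGN_INHIBITOR,
    Var,
    conj,
    disj,
    negate,
)
from .model import LogicalModel, NodeSpec

__all__ = [
    "MappingTable",
    "MappingCollisionError",
    "apply_mapping",
    "find_overlap",
    "graph_to_rules",
]

PathLike = Union[str, os.PathLike]

_SOURCES = {"alias", "previous", "ortholog", "manual"}


class MappingCollisionError(ValueError):
    """Two distinct nodes would map to the same approved symbol."""


@dataclass
class MappingTable:
    """Alias -> approved-symbol table with optional HGNC ids.

    TSV columns: ``alias``, ``approved``, ``hgnc_id`` (optional), ``source``
    (one of alias/previous/ortholog/manual).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"alias", "approved"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"mapping table missing columns: {sorted(missing)}")
        if "hgnc_id" not in self.frame.columns:
            self.frame["hgnc_id"] = ""
        if "source" not in self.frame.columns:
            self.frame["source"] = "manual"
        if self.frame["alias"].duplicated().any():
            dups = sorted(
                self.frame.loc[self.frame["alias"].duplicated(), "alias"]
            )
            raise ValueError(f"duplicate aliases in mapping table: {dups}")
        if (self.frame["approved"].astype(str).str.len() == 0).any():
            raise ValueError("mapping table has empty approved symbols")
        bad = set(self.frame["source"]) - _SOURCES
        if bad:
            raise ValueError(f"unknown mapping sources: {sorted(bad)}")

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[str, str] | tuple[str, str, str, str]]
    ) -> "MappingTable":
        records = []
        for row in rows:
            if len(row) == 2:
                alias, approved = row
                records.append((alias, approved, "", "manual"))
            else:
                records.append(tuple(row))
        return cls(
            pd.DataFrame(
                records, columns=["alias", "approved", "hgnc_id", "source"]
            )
        )

    @classmethod
    def from_tsv(cls, path: PathLike) -> "MappingTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str).fillna(""))

    def to_tsv(self, path: PathLike) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def lookup(self) -> dict[str, tuple[str, str, str]]:
        return {
            r.alias: (r.approved, r.hgnc_id, r.source)
            for r in self.frame.itertuples()
        }

    def __len__(self) -> int:
        return len(self.frame)


def apply_mapping(
    model: LogicalModel, table: MappingTable
) -> tuple[LogicalModel, pd.DataFrame]:
    """Rename every node whose symbol matches a table alias to its approved
    symbol, rewriting all rules consistently.

    Returns the renamed model and a per-node report (``node``, ``mapped_to``,
    ``status`` in {mapped, exact, unmapped}, ``source``).  Raises
    :class:`MappingCollisionError` if two distinct nodes would collapse to
    one symbol — that merge decision belongs to the curator, never to the
    renamer.
    """
    lut = table.lookup()
    approved_set = set(table.frame["approved"])
    renames: dict[str, str] = {}
    rows = []
    for nid in model.node_ids():
        if nid in lut:
            approved, hgnc_id, src = lut[nid]
            if approved != nid:
                renames[nid] = approved
            rows.append((nid, approved, "mapped", src))
        elif nid in approved_set:
            rows.append((nid, nid, "exact", ""))
        else:
            rows.append((nid, "", "unmapped", ""))

    # collision check: final symbol space must stay injective
    final: dict[str, str] = {}
    for nid in model.node_ids():
        tgt = renames.get(nid, nid)
        if tgt in final:
            raise MappingCollisionError(
                f"nodes {final[tgt]!r} and {nid!r} both map to {tgt!r}; "
                "resolve manually in the mapping table"
            )
        final[tgt] = nid

    renamed = model.rename_nodes(renames)
    for nid in model.node_ids():
        if nid in lut:
            approved, hgnc_id, src = lut[nid]
            if hgnc_id:
                node = renamed[renames.get(nid, nid)]
                node.annotations.setdefault("bqbiol:is", [])
                uri = f"https://identifiers.org/hgnc/{hgnc_id}"
                if uri not in node.annotations["bqbiol:is"]:
                    node.annotations["bqbiol:is"].append(uri)
    report = pd.DataFrame(
        rows, columns=["node", "mapped_to", "status", "source"]
    )
    return renamed, report


def find_overlap(a: LogicalModel, b: LogicalModel) -> set[str]:
    """Shared node symbols of two harmonized models (exact intersection)."""
    return a.symbols() & b.symbols()


def graph_to_rules(
    edges: Sequence[SignedInfluence], model_id: str = "translated"
) -> LogicalModel:
    """Translate a signed interaction graph into a logical model under the
    inhibitor-dominant template.

    Each target's rule is ``(OR of activators) & !(OR of inhibitors)``;
    targets with only inhibitors get ``!(OR of inhibitors)``.  Nodes that
    appear only as regulators become inputs.  Dual-signed edges cannot be
    expressed by this template and raise ``ValueError``.
    """
    activators: dict[str, list[str]] = {}
    inhibitors: dict[str, list[str]] = {}
    all_nodes: set[str] = set()
    for e in edges:
        all_nodes.add(e.regulator)
        all_nodes.add(e.target)
        if e.sign == SIGN_ACTIVATOR:
            activators.setdefault(e.target, []).append(e.regulator)
        elif e.sign == SIGN_INHIBITOR:
            inhibitors.setdefault(e.target, []).append(e.regulator)
        elif e.sign == SIGN_DUAL:
            raise ValueError(
                f"dual-signed edge {e.regulator}->{e.target} cannot be "
                "expressed by the activator/inhibitor template"
            )
        # sign 'none' edges carry no influence and are dropped

    nodes = []
    for nid in sorted(all_nodes):
        acts = sorted(set(activators.get(nid, [])))
        inhs = sorted(set(inhibitors.get(nid, [])))
        if not acts and not inhs:
            nodes.append(NodeSpec(nid, None))
            continue
        parts = []
        if acts:
            parts.append(disj(Var(a) for a in acts))
        if inhs:
            parts.append(negate(disj(Var(i) for i in inhs)))
        nodes.append(NodeSpec(nid, conj(parts)))
    return LogicalModel(nodes, model_id=model_id)
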