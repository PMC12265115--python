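"""Plain-text Boolean rule files ("bnet" style).

One line per node: ``target, factors`` where *factors* is a rule in the
package grammar (``!``/``&``/``|``).  A header line ``targets, factors`` is
tolerated.  The format has no input keyword, so an input node is written by
the self-identity convention ``A, A``.
"""

from __future__ import annotations

import os
from typing import Union

from .logic import RuleSyntaxError, Var, parse_rule, to_text
from .model import LogicalModel, NodeSpec

__all__ = ["read_bnet", "write_bnet"]

PathLike = Union[str, os.PathLike]


class BnetSyntaxError(ValueError):
    def __init__(self, message: str, line_no: int) -> None:
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def read_bnet(path: PathLike, model_id: str | None = None) -> LogicalModel:
    """Read a bnet-style rule file into a :class:`LogicalModel`."""
    nodes: list[NodeSpec] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "," not in line:
                raise BnetSyntaxError(
                    "expected 'target, factors'", line_no
                )
            target, factors = line.split(",", 1)
            target = target.strip()
            factors = factors.strip()
            if target.lower() == "targets" and factors.lower() == "factors":
                continue  # header
            if not target:
                raise BnetSyntaxError("empty target", line_no)
            try:
                expr = parse_rule(factors)
            except RuleSyntaxError as e:
                raise BnetSyntaxError(str(e), line_no) from e
            if expr == Var(target):
                # self-identity marks an external input
                nodes.append(NodeSpec(target, None))
            else:
                nodes.append(NodeSpec(target, expr))
    if model_id is None:
        model_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return LogicalModel(nodes, model_id=model_id)


def write_bnet(model: LogicalModel, path: PathLike) -> None:
    """Write ``model`` as a bnet-style rule file (lexicographic node order)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("targets, factors\n")
        for nid in model.sorted_ids():
            node = model[nid]
            rule = nid if node.rule is None else to_text(node.rule)
            fh.write(f"{nid}, {rule}\n")
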