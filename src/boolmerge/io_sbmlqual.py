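"""SBML-qual reading and writing (Level 3 Version 1, qual version 1).

The dialect is deliberately the smallest one every major qualitative-model
tool emits: Boolean species only (``maxLevel="1"``), one transition per
regulated species with a default term for the OFF case and a single
function term for the ON case, and transition logic expressed in MathML
``and``/``or``/``not`` over equality tests ``species = 1``.

Species with ``maxLevel > 1`` are rejected explicitly — multi-valued models
must be booleanised upstream; silent binarization would change dynamics.

Node annotations are carried as RDF CV terms (``bqbiol:is`` etc.) on the
qualitative species; qualifiers we do not model are preserved opaquely.
"""

from __future__ import annotations

import os
from typing import Union

from lxml import etree

from .logic import (
    And,
    BoolExpr,
    Const,
    Not,
    Or,
    Var,
    conj,
    disj,
    infer_signs,
    SupportCapError,
    syntactic_signs,
    SIGN_ACTIVATOR,
    SIGN_INHIBITOR,
    variables,
)
from .model import LogicalModel, NodeSpec

__all__ = ["read_sbmlqual", "write_sbmlqual", "SbmlQualError"]

PathLike = Union[str, os.PathLike]

NS_SBML = "http://www.sbml.org/sbml/level3/version1/core"
NS_QUAL = "http://www.sbml.org/sbml/level3/version1/qual/version1"
NS_MATH = "http://www.w3.org/1998/Math/MathML"
NS_RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
NS_BQBIOL = "http://biomodels.net/biology-qualifiers/"
NS_BQMODEL = "http://biomodels.net/model-qualifiers/"

NSMAP = {None: NS_SBML, "qual": NS_QUAL}


class SbmlQualError(ValueError):
    """Unreadable or unsupported SBML-qual content."""


def _q(tag: str) -> str:
    return f"{{{NS_QUAL}}}{tag}"


def _m(tag: str) -> str:
    return f"{{{NS_MATH}}}{tag}"


# ---------------------------------------------------------------------------
# MathML <-> BoolExpr


def _expr_to_mathml(expr: BoolExpr, parent: etree._Element) -> None:
    if isinstance(expr, Var):
        apply = etree.SubElement(parent, _m("apply"))
        etree.SubElement(apply, _m("eq"))
        ci = etree.SubElement(apply, _m("ci"))
        ci.text = f" {expr.name} "
        cn = etree.SubElement(apply, _m("cn"))
        cn.set("type", "integer")
        cn.text = " 1 "
    elif isinstance(expr, Const):
        etree.SubElement(parent, _m("true" if expr.value else "false"))
    elif isinstance(expr, Not):
        apply = etree.SubElement(parent, _m("apply"))
        etree.SubElement(apply, _m("not"))
        _expr_to_mathml(expr.child, apply)
    elif isinstance(expr, (And, Or)):
        apply = etree.SubElement(parent, _m("apply"))
        etree.SubElement(apply, _m("and" if isinstance(expr, And) else "or"))
        for c in expr.children:
            _expr_to_mathml(c, apply)
    else:  # pragma: no cover
        raise TypeError(f"not a BoolExpr: {expr!r}")


def _strip(text: str | None) -> str:
    return (text or "").strip()


def _mathml_to_expr(el: etree._Element) -> BoolExpr:
    tag = etree.QName(el).localname
    if tag == "math":
        children = [c for c in el if isinstance(c.tag, str)]
        if len(children) != 1:
            raise SbmlQualError("math element must have exactly one child")
        return _mathml_to_expr(children[0])
    if tag == "ci":
        return Var(_strip(el.text))
    if tag == "true":
        return Const(1)
    if tag == "false":
        return Const(0)
    if tag == "cn":
        v = _strip(el.text)
        if v not in ("0", "1"):
            raise SbmlQualError(f"non-Boolean constant {v!r}")
        return Const(int(v))
    if tag != "apply":
        raise SbmlQualError(f"unsupported MathML element <{tag}>")
    children = [c for c in el if isinstance(c.tag, str)]
    op = etree.QName(children[0]).localname
    args = children[1:]
    if op == "eq":
        if len(args) != 2:
            raise SbmlQualError("eq requires two arguments")
        ci, cn = args
        if etree.QName(ci).localname != "ci":
            ci, cn = cn, ci
        name = _strip(ci.text)
        level = _strip(cn.text)
        if level == "1":
            return Var(name)
        if level == "0":
            return Not(Var(name))
        raise SbmlQualError(
            f"equality test against level {level!r} for {name!r}: "
            "only Boolean levels 0/1 are supported"
        )
    if op == "not":
        if len(args) != 1:
            raise SbmlQualError("not requires one argument")
        inner = _mathml_to_expr(args[0])
        return Not(inner) if not isinstance(inner, Not) else inner.child
    if op == "and":
        return conj(_mathml_to_expr(a) for a in args)
    if op == "or":
        return disj(_mathml_to_expr(a) for a in args)
    raise SbmlQualError(f"unsupported MathML operator <{op}>")


# ---------------------------------------------------------------------------
# annotations


def _write_annotation(node: NodeSpec, species_el: etree._Element) -> None:
    cv_terms = {
        k: v for k, v in node.annotations.items()
        if k.startswith(("bqbiol:", "bqmodel:")) and v
    }
    opaque = node.annotations.get("_opaque", [])
    if not cv_terms and not opaque:
        return
    ann = etree.SubElement(species_el, f"{{{NS_SBML}}}annotation")
    if cv_terms:
        rdf = etree.SubElement(
            ann, f"{{{NS_RDF}}}RDF",
            nsmap={"rdf": NS_RDF, "bqbiol": NS_BQBIOL, "bqmodel": NS_BQMODEL},
        )
        desc = etree.SubElement(rdf, f"{{{NS_RDF}}}Description")
        desc.set(f"{{{NS_RDF}}}about", f"#{node.node_id}")
        for qualifier in sorted(cv_terms):
            prefix, local = qualifier.split(":", 1)
            ns = NS_BQBIOL if prefix == "bqbiol" else NS_BQMODEL
            qel = etree.SubElement(desc, f"{{{ns}}}{local}")
            bag = etree.SubElement(qel, f"{{{NS_RDF}}}Bag")
            for uri in cv_terms[qualifier]:
                li = etree.SubElement(bag, f"{{{NS_RDF}}}li")
                li.set(f"{{{NS_RDF}}}resource", uri)
    for blob in opaque:
        try:
            ann.append(etree.fromstring(blob))
        except etree.XMLSyntaxError:
            pass


def _read_annotation(species_el: etree._Element) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    ann = species_el.find(f"{{{NS_SBML}}}annotation")
    if ann is None:
        return out
    for child in ann:
        if not isinstance(child.tag, str):
            continue
        if etree.QName(child).namespace == NS_RDF:
            for desc in child.iter(f"{{{NS_RDF}}}Description"):
                for qel in desc:
                    if not isinstance(qel.tag, str):
                        continue
                    qns = etree.QName(qel).namespace
                    if qns == NS_BQBIOL:
                        key = "bqbiol:" + etree.QName(qel).localname
                    elif qns == NS_BQMODEL:
                        key = "bqmodel:" + etree.QName(qel).localname
                    else:
                        continue
                    uris = [
                        li.get(f"{{{NS_RDF}}}resource", "")
                        for li in qel.iter(f"{{{NS_RDF}}}li")
                    ]
                    out.setdefault(key, []).extend(u for u in uris if u)
        else:
            out.setdefault("_opaque", []).append(
                etree.tostring(child, encoding="unicode")
            )
    return out


# ---------------------------------------------------------------------------
# public API


def write_sbmlqual(model: LogicalModel, path: PathLike) -> None:
    """Write ``model`` as SBML L3V1 + qual v1 (deterministic element order)."""
    sbml = etree.Element(
        f"{{{NS_SBML}}}sbml", nsmap=NSMAP
    )
    sbml.set("level", "3")
    sbml.set("version", "1")
    sbml.set(_q("required"), "true")
    mdl = etree.SubElement(sbml, f"{{{NS_SBML}}}model")
    mdl.set("id", _sanitize_id(model.model_id))
    if model.source:
        mdl.set("name", model.source.get("title", model.model_id))
    comps = etree.SubElement(mdl, f"{{{NS_SBML}}}listOfCompartments")
    comp = etree.SubElement(comps, f"{{{NS_SBML}}}compartment")
    comp.set("id", "default")
    comp.set("constant", "true")

    species_list = etree.SubElement(mdl, _q("listOfQualitativeSpecies"))
    for nid in model.sorted_ids():
        node = model[nid]
        sp = etree.SubElement(species_list, _q("qualitativeSpecies"))
        sp.set(_q("id"), nid)
        if node.display_symbol and node.display_symbol != nid:
            sp.set(_q("name"), node.display_symbol)
        sp.set(_q("compartment"), "default")
        sp.set(_q("constant"), "true" if node.is_input else "false")
        sp.set(_q("maxLevel"), "1")
        _write_annotation(node, sp)

    transitions = etree.SubElement(mdl, _q("listOfTransitions"))
    for nid in model.sorted_ids():
        node = model[nid]
        if node.rule is None:
            continue
        tr = etree.SubElement(transitions, _q("transition"))
        tr.set(_q("id"), f"tr_{nid}")
        regs = sorted(variables(node.rule))
        if regs:
            inputs = etree.SubElement(tr, _q("listOfInputs"))
            signs = _regulator_signs(node.rule, nid)
            for reg in regs:
                inp = etree.SubElement(inputs, _q("input"))
                inp.set(_q("id"), f"tr_{nid}_in_{reg}")
                inp.set(_q("qualitativeSpecies"), reg)
                inp.set(_q("transitionEffect"), "none")
                inp.set(_q("sign"), signs.get(reg, "unknown"))
        outputs = etree.SubElement(tr, _q("listOfOutputs"))
        out = etree.SubElement(outputs, _q("output"))
        out.set(_q("qualitativeSpecies"), nid)
        out.set(_q("transitionEffect"), "assignmentLevel")
        terms = etree.SubElement(tr, _q("listOfFunctionTerms"))
        default = etree.SubElement(terms, _q("defaultTerm"))
        default.set(_q("resultLevel"), "0")
        fterm = etree.SubElement(terms, _q("functionTerm"))
        fterm.set(_q("resultLevel"), "1")
        math = etree.SubElement(fterm, _m("math"), nsmap={None: NS_MATH})
        _expr_to_mathml(node.rule, math)

    tree = etree.ElementTree(sbml)
    tree.write(
        os.fspath(path), xml_declaration=True, encoding="UTF-8",
        pretty_print=True,
    )


def _regulator_signs(rule: BoolExpr, target: str) -> dict[str, str]:
    mapping = {
        SIGN_ACTIVATOR: "positive",
        SIGN_INHIBITOR: "negative",
        "dual": "dual",
        "none": "unknown",
    }
    try:
        infs = infer_signs(rule, target)
    except SupportCapError:
        infs = syntactic_signs(rule, target)
    return {i.regulator: mapping[i.sign] for i in infs}


def _sanitize_id(raw: str) -> str:
    cleaned = "".join(c if c.isalnum() or c == "_" else "_" for c in raw)
    if not cleaned or not (cleaned[0].isalpha() or cleaned[0] == "_"):
        cleaned = "m_" + cleaned
    return cleaned


def read_sbmlqual(path: PathLike) -> LogicalModel:
    """Read an SBML L3 qual document into a :class:`LogicalModel`.

    Species with no transition (or marked constant) become inputs.  Raises
    :class:`SbmlQualError` for ``maxLevel > 1`` species, naming them.
    """
    try:
        tree = etree.parse(os.fspath(path))
    except etree.XMLSyntaxError as e:
        raise SbmlQualError(f"XML parse error: {e}") from e
    root = tree.getroot()
    mdl = root.find(f"{{{NS_SBML}}}model")
    if mdl is None:
        raise SbmlQualError("no <model> element")

    nodes: dict[str, NodeSpec] = {}
    names: dict[str, str] = {}
    sp_list = mdl.find(_q("listOfQualitativeSpecies"))
    if sp_list is None:
        raise SbmlQualError("no qualitative species list (not an SBML-qual file?)")
    for sp in sp_list.findall(_q("qualitativeSpecies")):
        sid = sp.get(_q("id"))
        if sid is None:
            raise SbmlQualError("qualitativeSpecies without id")
        max_level = sp.get(_q("maxLevel"))
        if max_level is not None and int(max_level) > 1:
            raise SbmlQualError(
                f"species {sid!r} has maxLevel={max_level}; only Boolean "
                "models are supported — booleanise the model first"
            )
        name = sp.get(_q("name"))
        if name:
            names[sid] = name
        nodes[sid] = NodeSpec(
            sid,
            None,
            display_symbol=name or sid,
            annotations=_read_annotation(sp),
        )

    tr_list = mdl.find(_q("listOfTransitions"))
    seen_outputs: set[str] = set()
    if tr_list is not None:
        for tr in tr_list.findall(_q("transition")):
            outputs = tr.find(_q("listOfOutputs"))
            if outputs is None:
                raise SbmlQualError("transition without outputs")
            for out in outputs.findall(_q("output")):
                target = out.get(_q("qualitativeSpecies"))
                if target not in nodes:
                    raise SbmlQualError(
                        f"transition output names unknown species {target!r}"
                    )
                if target in seen_outputs:
                    raise SbmlQualError(
                        f"species {target!r} is the output of more than one "
                        "transition"
                    )
                seen_outputs.add(target)
                nodes[target].rule = _transition_rule(tr, target)

    return LogicalModel(
        nodes.values(),
        model_id=mdl.get("id", "model"),
    )


def _transition_rule(tr: etree._Element, target: str) -> BoolExpr:
    terms = tr.find(_q("listOfFunctionTerms"))
    if terms is None:
        raise SbmlQualError(f"transition for {target!r} has no function terms")
    on_terms: list[BoolExpr] = []
    default_level = 0
    default = terms.find(_q("defaultTerm"))
    if default is not None:
        default_level = int(default.get(_q("resultLevel"), "0"))
    for ft in terms.findall(_q("functionTerm")):
        level = int(ft.get(_q("resultLevel"), "0"))
        math = ft.find(_m("math"))
        if math is None:
            raise SbmlQualError(
                f"function term for {target!r} has no math"
            )
        expr = _mathml_to_expr(math)
        if level == 1:
            on_terms.append(expr)
        elif level != 0:
            raise SbmlQualError(
                f"function term for {target!r} has non-Boolean "
                f"resultLevel={level}"
            )
    if default_level == 1:
        if not on_terms:
            return Const(1)
        # ON unless some explicit level-0 term fires; level-0 terms with
        # default 1 are not emitted by this writer but read conservatively:
        # the ON region is everything outside the level-0 terms.
        raise SbmlQualError(
            f"transition for {target!r} mixes defaultTerm level 1 with "
            "function terms; unsupported dialect"
        )
    if not on_terms:
        return Const(0)
    return disj(on_terms)
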