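"""Export of synthesized models: SBML Level 3 qual, native JSON, edge TSV.

SBML-qual is the interchange path into GINsim, BoolNet and similar logical
modelling tools: one qualitative species per gene (max level 1) and one
transition per gene whose level-1 function term carries the update function
as MathML.  The native JSON document is the lossless round-trip format and
keeps every alternative rule per gene plus provenance.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Optional, Union

from lxml import etree

from .boolfunc import MonotoneFormula, UpdateRule
from .core import BinaryState, GeneSet
from .errors import ModelDocumentError
from .model_analysis import CombinedModel
from .rule_synthesis import RuleSet

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
_NSMAP = {None: SBML_NS, "qual": QUAL_NS}


def _q(tag: str) -> str:
    return f"{{{QUAL_NS}}}{tag}"


def _m(tag: str) -> str:
    return f"{{{MATHML_NS}}}{tag}"


# ---------------------------------------------------------------------------
# Boolean expression trees (nested tuples) shared by writer and reader
#   ("var", gene) ("not", e) ("and", [e...]) ("or", [e...]) ("const", 0|1)
# ---------------------------------------------------------------------------

def rule_expression(rule: UpdateRule):
    def formula_expr(f: MonotoneFormula):
        terms = [
            ("and", [("var", v) for v in sorted(t)]) if len(t) > 1 else ("var", next(iter(t)))
            for t in f.terms
        ]
        return terms[0] if len(terms) == 1 else ("or", terms)

    f1 = formula_expr(rule.activators)
    if rule.repressors is None:
        return f1
    return ("and", [f1, ("not", formula_expr(rule.repressors))])


def combined_expression(m: CombinedModel, gene: str):
    kind, payload = m.functions[gene]
    if kind == "const":
        return ("const", payload)
    exprs = [rule_expression(r) for r in payload]
    if len(exprs) == 1:
        return exprs[0]
    x = ("var", gene)
    return (
        "or",
        [("and", [("not", x), ("and", exprs)]), ("and", [x, ("or", exprs)])],
    )


def evaluate_expression(expr, state: BinaryState, genes: GeneSet) -> int:
    op = expr[0]
    if op == "var":
        return state[genes.index(expr[1])]
    if op == "const":
        return expr[1]
    if op == "not":
        return 1 - evaluate_expression(expr[1], state, genes)
    if op == "and":
        return int(all(evaluate_expression(e, state, genes) for e in expr[1]))
    if op == "or":
        return int(any(evaluate_expression(e, state, genes) for e in expr[1]))
    raise ValueError(f"unknown expression node {op!r}")


def expression_variables(expr) -> set:
    op = expr[0]
    if op == "var":
        return {expr[1]}
    if op == "const":
        return set()
    if op == "not":
        return expression_variables(expr[1])
    return set().union(*(expression_variables(e) for e in expr[1]))


# ---------------------------------------------------------------------------
# SBML Level 3 + qual
# ---------------------------------------------------------------------------

def _sanitize_ids(names) -> dict:
    """Map gene names to valid, unique SBML SIds; originals go in qual:name."""
    mapping = {}
    used = set()
    for name in names:
        sid = re.sub(r"[^A-Za-z0-9_]", "_", name)
        if not re.match(r"[A-Za-z_]", sid):
            sid = "g_" + sid
        base, k = sid, 1
        while sid in used:
            k += 1
            sid = f"{base}_{k}"
        used.add(sid)
        mapping[name] = sid
    return mapping


def _mathml(expr, sid: dict, parent) -> None:
    op = expr[0]
    if op == "var":
        apply = etree.SubElement(parent, _m("apply"))
        etree.SubElement(apply, _m("eq"))
        etree.SubElement(apply, _m("ci")).text = f" {sid[expr[1]]} "
        cn = etree.SubElement(apply, _m("cn"))
        cn.set("type", "integer")
        cn.text = " 1 "
        return
    if op == "const":
        etree.SubElement(parent, _m("true" if expr[1] else "false"))
        return
    apply = etree.SubElement(parent, _m("apply"))
    if op == "not":
        etree.SubElement(apply, _m("not"))
        _mathml(expr[1], sid, apply)
        return
    etree.SubElement(apply, _m(op))  # 'and' / 'or'
    for e in expr[1]:
        _mathml(e, sid, apply)


def write_sbml_qual(model: Union[CombinedModel, dict], path, genes: Optional[GeneSet] = None) -> None:
    """Write one transition per gene with its update function as MathML.

    ``model`` is either a CombinedModel or a dict mapping each gene to a
    single UpdateRule (a sub-model selection); the latter needs ``genes``.
    """
    if isinstance(model, CombinedModel):
        gene_set = model.genes
        expr_of = {g: combined_expression(model, g) for g in gene_set}
    else:
        if genes is None:
            raise ValueError("a gene set is required with a rule-dict selection")
        gene_set = genes
        expr_of = {g: rule_expression(model[g]) for g in gene_set}

    sid = _sanitize_ids(gene_set.names)
    sbml = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=_NSMAP)
    sbml.set("level", "3")
    sbml.set("version", "1")
    sbml.set(_q("required"), "true")
    model_el = etree.SubElement(sbml, f"{{{SBML_NS}}}model")
    model_el.set("id", "boolean_network")

    species_list = etree.SubElement(model_el, _q("listOfQualitativeSpecies"))
    for g in gene_set:
        sp = etree.SubElement(species_list, _q("qualitativeSpecies"))
        sp.set(_q("id"), sid[g])
        sp.set(_q("name"), g)
        sp.set(_q("compartment"), "default")
        sp.set(_q("constant"), "false")
        sp.set(_q("maxLevel"), "1")

    transitions = etree.SubElement(model_el, _q("listOfTransitions"))
    for g in gene_set:
        expr = expr_of[g]
        tr = etree.SubElement(transitions, _q("transition"))
        tr.set(_q("id"), f"tr_{sid[g]}")
        inputs_el = etree.SubElement(tr, _q("listOfInputs"))
        for v in sorted(expression_variables(expr), key=gene_set.index):
            inp = etree.SubElement(inputs_el, _q("input"))
            inp.set(_q("id"), f"tr_{sid[g]}_in_{sid[v]}")
            inp.set(_q("qualitativeSpecies"), sid[v])
            inp.set(_q("transitionEffect"), "none")
        outputs_el = etree.SubElement(tr, _q("listOfOutputs"))
        out = etree.SubElement(outputs_el, _q("output"))
        out.set(_q("qualitativeSpecies"), sid[g])
        out.set(_q("transitionEffect"), "assignmentLevel")
        terms = etree.SubElement(tr, _q("listOfFunctionTerms"))
        default = etree.SubElement(terms, _q("defaultTerm"))
        default.set(_q("resultLevel"), "0")
        fterm = etree.SubElement(terms, _q("functionTerm"))
        fterm.set(_q("resultLevel"), "1")
        math = etree.SubElement(fterm, _m("math"))
        _mathml(expr, sid, math)

    etree.ElementTree(sbml).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _parse_mathml(el, name_of: dict):
    tag = etree.QName(el).localname
    if tag == "math":
        children = list(el)
        if len(children) != 1:
            raise ModelDocumentError("math element must have exactly one child")
        return _parse_mathml(children[0], name_of)
    if tag == "true":
        return ("const", 1)
    if tag == "false":
        return ("const", 0)
    if tag != "apply":
        raise ModelDocumentError(f"unsupported MathML element <{tag}>")
    children = list(el)
    op = etree.QName(children[0]).localname
    args = children[1:]
    if op == "eq":
        ci = next(c for c in args if etree.QName(c).localname == "ci")
        cn = next(c for c in args if etree.QName(c).localname == "cn")
        var = ("var", name_of[ci.text.strip()])
        return var if int(cn.text.strip()) == 1 else ("not", var)
    if op == "not":
        return ("not", _parse_mathml(args[0], name_of))
    if op in ("and", "or"):
        return (op, [_parse_mathml(a, name_of) for a in args])
    raise ModelDocumentError(f"unsupported MathML operator <{op}>")


@dataclass
class QualModel:
    """Result of reading an SBML-qual file: per-gene expression trees."""

    genes: GeneSet
    expressions: dict  # gene name -> expression tree

    def evaluate(self, gene: str, state: BinaryState) -> int:
        return evaluate_expression(self.expressions[gene], state, self.genes)


def read_sbml_qual(path) -> QualModel:
    tree = etree.parse(str(path))
    root = tree.getroot()
    species = root.findall(f".//{_q('qualitativeSpecies')}")
    if not species:
        raise ModelDocumentError("no qualitative species found")
    name_of = {}
    names = []
    for sp in species:
        sid = sp.get(_q("id"))
        name = sp.get(_q("name")) or sid
        name_of[sid] = name
        names.append(name)
    genes = GeneSet(names)

    expressions = {}
    for tr in root.findall(f".//{_q('transition')}"):
        out = tr.find(f".//{_q('output')}")
        gene = name_of[out.get(_q("qualitativeSpecies"))]
        fterm = next(
            (
                t
                for t in tr.findall(f".//{_q('functionTerm')}")
                if t.get(_q("resultLevel")) == "1"
            ),
            None,
        )
        if fterm is None:
            expressions[gene] = ("const", 0)
            continue
        math = fterm.find(_m("math"))
        expressions[gene] = _parse_mathml(math, name_of)
    missing = [g for g in names if g not in expressions]
    if missing:
        raise ModelDocumentError(f"no transition for gene(s) {missing}")
    return QualModel(genes=genes, expressions=expressions)


# ---------------------------------------------------------------------------
# Native JSON model document
# ---------------------------------------------------------------------------

FORMAT_NAME = "scboolnet-model"
FORMAT_VERSION = 1


@dataclass
class ModelDocument:
    genes: GeneSet
    rules: dict  # gene -> list[UpdateRule]
    provenance: dict = field(default_factory=dict)

    def to_ruleset(self) -> RuleSet:
        return RuleSet(genes=self.genes, rules=dict(self.rules))


def _rule_to_json(rule: UpdateRule) -> dict:
    return {
        "activators": [sorted(t) for t in rule.activators.terms],
        "repressors": None
        if rule.repressors is None
        else [sorted(t) for t in rule.repressors.terms],
    }


def _rule_from_json(gene: str, obj: dict, where: str) -> UpdateRule:
    if "activators" not in obj:
        raise ModelDocumentError(f"{where}: missing field 'activators'", field="activators")
    reps = obj.get("repressors")
    return UpdateRule(
        gene=gene,
        activators=MonotoneFormula([frozenset(t) for t in obj["activators"]]),
        repressors=None if reps is None else MonotoneFormula([frozenset(t) for t in reps]),
    )


def write_model_json(rs: Union[RuleSet, ModelDocument], path, provenance: Optional[dict] = None) -> None:
    if isinstance(rs, ModelDocument):
        doc_prov = dict(rs.provenance)
        genes, rules = rs.genes, rs.rules
    else:
        doc_prov = {}
        genes, rules = rs.genes, rs.rules
        if getattr(rs, "parameters", None):
            doc_prov["parameters"] = {
                g: {
                    "max_activators": p.max_activators,
                    "max_repressors": p.max_repressors,
                    "threshold_percent": p.threshold_percent,
                }
                for g, p in rs.parameters.items()
            }
    if provenance:
        doc_prov.update(provenance)
    payload = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "genes": list(genes.names),
        "rules": {g: [_rule_to_json(r) for r in rules.get(g, [])] for g in genes},
        "provenance": doc_prov,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_model_json(path) -> ModelDocument:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelDocumentError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    for required in ("format", "version", "genes", "rules"):
        if required not in payload:
            raise ModelDocumentError(
                f"{path}: missing required field {required!r}", field=required
            )
    if payload["format"] != FORMAT_NAME:
        raise ModelDocumentError(
            f"{path}: unexpected format {payload['format']!r}", field="format"
        )
    genes = GeneSet(payload["genes"])
    rules = {}
    for g in genes:
        entries = payload["rules"].get(g, [])
        rules[g] = [
            _rule_from_json(g, obj, f"{path}: rules[{g!r}][{i}]")
            for i, obj in enumerate(entries)
        ]
    return ModelDocument(genes=genes, rules=rules, provenance=payload.get("provenance", {}))


# ---------------------------------------------------------------------------
# Signed interaction edge list
# ---------------------------------------------------------------------------

def network_edges(rs: Union[RuleSet, ModelDocument]) -> list:
    """Deduplicated (source, target, sign, rule_index) records: a '+' edge
    g -> t when g is an activator of some rule of t, '-' when a repressor."""
    edges = []
    seen = set()
    for target in rs.genes:
        for i, rule in enumerate(rs.rules.get(target, [])):
            for src in sorted(rule.activator_variables, key=rs.genes.index):
                if (src, target, "+") not in seen:
                    seen.add((src, target, "+"))
                    edges.append((src, target, "+", i))
            for src in sorted(rule.repressor_variables, key=rs.genes.index):
                if (src, target, "-") not in seen:
                    seen.add((src, target, "-"))
                    edges.append((src, target, "-", i))
    return edges


def write_network_edges(rs: Union[RuleSet, ModelDocument], path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tsign\trule_index\n")
        for src, tgt, sign, i in network_edges(rs):
            fh.write(f"{src}\t{tgt}\t{sign}\t{i}\n")
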