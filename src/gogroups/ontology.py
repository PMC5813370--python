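"""Ontology data model, parsers, merging and EL normalization.

The in-memory model is deliberately small: named classes, object
properties, and the three EL class constructors (named class, intersection,
existential restriction).  Everything outside the EL profile — disjunction,
negation, universal restriction, inverse properties, cardinality — is
rejected at parse time (or ignored with a warning where a real ontology is
known to carry a handful of harmless axioms, e.g. InverseObjectProperties).

Two input syntaxes are supported:

* obographs JSON (``nodes`` / ``edges`` / ``logicalDefinitionAxioms`` /
  ``propertyChainAxioms``), the format the Gene Ontology publishes;
* a small OWL functional-syntax subset, convenient for hand-written
  fixtures, covering Declaration, SubClassOf, EquivalentClasses,
  ObjectIntersectionOf, ObjectSomeValuesFrom, SubObjectPropertyOf,
  ObjectPropertyChain, TransitiveObjectProperty and
  ReflexiveObjectProperty.

``normalize`` rewrites an ontology into the four EL normal forms over named
classes (A ⊑ B; A1 ⊓ A2 ⊑ B; A ⊑ ∃R.B; ∃R.A ⊑ B) plus property axioms,
introducing deterministic fresh names with the reserved prefix ``X:``.
Entailments over the original signature are preserved.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace

logger = logging.getLogger("gogroups")

#: reserved prefix for fresh classes introduced during normalization
FRESH_PREFIX = "X"

_CURIE_RE = re.compile(r"^[A-Za-z_][\w.-]*:[\w.-]+$")


class OntologyError(Exception):
    """Base error for ontology parsing and construction."""


class ParseError(OntologyError):
    pass


class ProfileViolationError(OntologyError):
    """Input uses a construct outside the supported EL subset."""


class ReferentialError(OntologyError):
    """An axiom refers to an undeclared class or property."""


class MergeConflictError(OntologyError):
    pass


def normalize_curie(ident: str) -> str:
    """Normalize an identifier to ``PREFIX:local`` CURIE form.

    Accepts OBO-style IRIs (``http://purl.obolibrary.org/obo/GO_0038171``)
    and underscore CURIEs (``GO_0038171``); both normalize to
    ``GO:0038171``.  Identifiers already in colon form pass through.
    """
    if ident.startswith("http://") or ident.startswith("https://"):
        ident = ident.rsplit("/", 1)[-1].rsplit("#", 1)[-1]
    if ":" not in ident and "_" in ident:
        prefix, local = ident.split("_", 1)
        # only OBO-style ids (numeric local part) use underscore as the
        # prefix separator; relation names like has_participant do not
        if local and local[0].isdigit():
            ident = f"{prefix}:{local}"
    return ident


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassRef:
    """A named class identified by a CURIE."""

    id: str
    label: str | None = None
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not _CURIE_RE.match(self.id):
            raise OntologyError(f"class id is not a CURIE: {self.id!r}")

    @property
    def namespace(self) -> str:
        return self.id.split(":", 1)[0]


@dataclass(frozen=True)
class PropertyRef:
    """An object property; transitive/reflexive flags are independent."""

    id: str
    label: str | None = None
    transitive: bool = False
    reflexive: bool = False


@dataclass(frozen=True)
class Named:
    ref: ClassRef

    @property
    def id(self) -> str:
        return self.ref.id


@dataclass(frozen=True)
class And:
    conjuncts: tuple  # of ClassExpr, length >= 2

    def __post_init__(self) -> None:
        if len(self.conjuncts) < 2:
            raise OntologyError("And requires at least two conjuncts")


@dataclass(frozen=True)
class Some:
    property: PropertyRef
    filler: "ClassExpr"


ClassExpr = Named | And | Some


@dataclass(frozen=True)
class SubClassOf:
    sub: ClassExpr
    sup: ClassExpr


@dataclass(frozen=True)
class EquivalentClasses:
    exprs: tuple  # of ClassExpr, length >= 2

    def __post_init__(self) -> None:
        if len(self.exprs) < 2:
            raise OntologyError("EquivalentClasses requires at least two expressions")


@dataclass(frozen=True)
class SubPropertyOf:
    sub: PropertyRef
    sup: PropertyRef


@dataclass(frozen=True)
class PropertyChain:
    """``first ∘ second ⊑ sup``."""

    first: PropertyRef
    second: PropertyRef
    sup: PropertyRef


Axiom = SubClassOf | EquivalentClasses | SubPropertyOf | PropertyChain


def _expr_key(expr: ClassExpr) -> tuple:
    """Canonical sort/identity key for a class expression."""
    if isinstance(expr, Named):
        return ("n", expr.id)
    if isinstance(expr, Some):
        return ("s", expr.property.id, _expr_key(expr.filler))
    return ("a", tuple(sorted(_expr_key(c) for c in expr.conjuncts)))


def canonicalize_expr(expr: ClassExpr) -> ClassExpr:
    """Sort conjuncts lexicographically (recursively) for axiom identity."""
    if isinstance(expr, Named):
        return expr
    if isinstance(expr, Some):
        return Some(expr.property, canonicalize_expr(expr.filler))
    conj = tuple(
        sorted((canonicalize_expr(c) for c in expr.conjuncts), key=_expr_key)
    )
    return And(conj)


def _axiom_key(ax: Axiom) -> tuple:
    if isinstance(ax, SubClassOf):
        return ("sc", _expr_key(ax.sub), _expr_key(ax.sup))
    if isinstance(ax, EquivalentClasses):
        return ("eq", tuple(sorted(_expr_key(e) for e in ax.exprs)))
    if isinstance(ax, SubPropertyOf):
        return ("sp", ax.sub.id, ax.sup.id)
    return ("pc", ax.first.id, ax.second.id, ax.sup.id)


class Ontology:
    """A set of class/property declarations plus a list of EL axioms."""

    def __init__(self) -> None:
        self.classes: dict[str, ClassRef] = {}
        self.properties: dict[str, PropertyRef] = {}
        self.axioms: list[Axiom] = []
        self._axiom_keys: set[tuple] = set()

    # -- construction -------------------------------------------------

    def add_class(self, ref: ClassRef) -> ClassRef:
        existing = self.classes.get(ref.id)
        if existing is None:
            self.classes[ref.id] = ref
            return ref
        # first label wins; obsolete flag is sticky
        merged = existing
        if existing.label is None and ref.label is not None:
            merged = replace(merged, label=ref.label)
        elif ref.label is not None and existing.label != ref.label:
            logger.warning(
                "conflicting labels for %s: keeping %r, ignoring %r",
                ref.id, existing.label, ref.label,
            )
        if ref.obsolete and not existing.obsolete:
            merged = replace(merged, obsolete=True)
        self.classes[ref.id] = merged
        return merged

    def add_property(self, ref: PropertyRef) -> PropertyRef:
        existing = self.properties.get(ref.id)
        if existing is None:
            self.properties[ref.id] = ref
            return ref
        if (existing.transitive, existing.reflexive) != (ref.transitive, ref.reflexive):
            merged = replace(
                existing,
                transitive=existing.transitive or ref.transitive,
                reflexive=existing.reflexive or ref.reflexive,
            )
            self.properties[ref.id] = merged
            return merged
        if existing.label is None and ref.label is not None:
            self.properties[ref.id] = replace(existing, label=ref.label)
        return self.properties[ref.id]

    def add_axiom(self, ax: Axiom) -> None:
        if isinstance(ax, SubClassOf):
            ax = SubClassOf(canonicalize_expr(ax.sub), canonicalize_expr(ax.sup))
        elif isinstance(ax, EquivalentClasses):
            ax = EquivalentClasses(
                tuple(sorted((canonicalize_expr(e) for e in ax.exprs), key=_expr_key))
            )
        key = _axiom_key(ax)
        if key in self._axiom_keys:
            return
        self._axiom_keys.add(key)
        self.axioms.append(ax)

    # -- queries ------------------------------------------------------

    def check_referential_closure(self) -> None:
        """Raise ReferentialError if any axiom refers to an undeclared id."""

        def walk(expr: ClassExpr) -> None:
            if isinstance(expr, Named):
                if expr.id not in self.classes:
                    raise ReferentialError(f"undeclared class {expr.id}")
            elif isinstance(expr, And):
                for c in expr.conjuncts:
                    walk(c)
            else:
                if expr.property.id not in self.properties:
                    raise ReferentialError(f"undeclared property {expr.property.id}")
                walk(expr.filler)

        for ax in self.axioms:
            if isinstance(ax, SubClassOf):
                walk(ax.sub)
                walk(ax.sup)
            elif isinstance(ax, EquivalentClasses):
                for e in ax.exprs:
                    walk(e)
            elif isinstance(ax, SubPropertyOf):
                for p in (ax.sub, ax.sup):
                    if p.id not in self.properties:
                        raise ReferentialError(f"undeclared property {p.id}")
            else:
                for p in (ax.first, ax.second, ax.sup):
                    if p.id not in self.properties:
                        raise ReferentialError(f"undeclared property {p.id}")

    def copy(self) -> "Ontology":
        out = Ontology()
        out.classes = dict(self.classes)
        out.properties = dict(self.properties)
        out.axioms = list(self.axioms)
        out._axiom_keys = set(self._axiom_keys)
        return out


# ---------------------------------------------------------------------------
# obographs JSON parsing
# ---------------------------------------------------------------------------

_NON_EL_EDGE_HINTS = ("unionOf", "complementOf", "allValuesFrom", "inverseOf")


def parse_obograph(text: str) -> Ontology:
    """Parse an obographs JSON document into an :class:`Ontology`.

    CLASS nodes become class declarations (``deprecated`` → obsolete);
    PROPERTY nodes become object properties; ``is_a`` edges become
    SubClassOf between named classes; any other edge with predicate P
    becomes ``sub ⊑ ∃P.obj``; logical definitions become
    EquivalentClasses of the defined class with the genus/restriction
    intersection; ``propertyChainAxioms`` become PropertyChain entries.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}") from exc

    graphs = doc.get("graphs", [doc])
    ont = Ontology()
    prop_ids: set[str] = set()

    for graph in graphs:
        for node in graph.get("nodes", []):
            if "id" not in node:
                raise ParseError(f"node without id field: {node!r}")
            nid = normalize_curie(node["id"])
            ntype = node.get("type", "CLASS")
            label = node.get("lbl")
            meta = node.get("meta") or {}
            deprecated = bool(meta.get("deprecated", False))
            if ntype == "PROPERTY":
                prop_ids.add(nid)
                ont.add_property(PropertyRef(nid, label=label))
            elif ntype == "CLASS":
                ont.add_class(ClassRef(nid, label=label, obsolete=deprecated))
            # INDIVIDUAL nodes are outside scope and skipped

    def class_expr(ident: str) -> Named:
        cid = normalize_curie(ident)
        if cid not in ont.classes:
            raise ReferentialError(f"edge references undeclared node {cid}")
        return Named(ont.classes[cid])

    def prop_ref(ident: str) -> PropertyRef:
        pid = normalize_curie(ident)
        if pid not in ont.properties:
            ont.add_property(PropertyRef(pid))
        return ont.properties[pid]

    for graph in graphs:
        for edge in graph.get("edges", []):
            pred = edge.get("pred", "is_a")
            if any(h in pred for h in _NON_EL_EDGE_HINTS):
                raise ProfileViolationError(f"non-EL edge predicate: {pred}")
            sub_id = normalize_curie(edge["sub"])
            obj_id = normalize_curie(edge["obj"])
            if pred == "subPropertyOf" and sub_id in ont.properties:
                ont.add_axiom(SubPropertyOf(prop_ref(sub_id), prop_ref(obj_id)))
                continue
            sub = class_expr(edge["sub"])
            obj = class_expr(edge["obj"])
            if pred in ("is_a", "subClassOf"):
                ont.add_axiom(SubClassOf(sub, obj))
            else:
                ont.add_axiom(SubClassOf(sub, Some(prop_ref(pred), obj)))

        for lda in graph.get("logicalDefinitionAxioms", []):
            defined = class_expr(lda["definedClassId"])
            parts: list[ClassExpr] = [class_expr(g) for g in lda.get("genusIds", [])]
            for restr in lda.get("restrictions", []) or []:
                parts.append(
                    Some(prop_ref(restr["propertyId"]), class_expr(restr["fillerId"]))
                )
            if not parts:
                continue
            other = parts[0] if len(parts) == 1 else And(tuple(parts))
            ont.add_axiom(EquivalentClasses((defined, other)))

        for pca in graph.get("propertyChainAxioms", []):
            chain = [prop_ref(p) for p in pca["chainPredicateIds"]]
            sup = prop_ref(pca["predicateId"])
            if len(chain) != 2:
                raise ProfileViolationError(
                    f"only binary property chains supported, got {len(chain)}"
                )
            ont.add_axiom(PropertyChain(chain[0], chain[1], sup))

    return ont


def serialize_obograph(ont: Ontology) -> str:
    """Serialize to obographs JSON (best effort, for fixture export).

    Handles named-to-named subsumptions (``is_a`` edges), existential
    restrictions with named fillers (property edges), logical definitions
    of the genus+restrictions shape, subPropertyOf edges and property
    chains.  Transitive/reflexive flags have no obographs slot here; the
    functional-syntax dump is the lossless serialization, and a warning is
    logged when flags are dropped.
    """
    nodes, edges, ldas, pcas = [], [], [], []
    for cid in sorted(ont.classes):
        ref = ont.classes[cid]
        node = {"id": cid, "type": "CLASS"}
        if ref.label:
            node["lbl"] = ref.label
        if ref.obsolete:
            node["meta"] = {"deprecated": True}
        nodes.append(node)
    for pid in sorted(ont.properties):
        prop = ont.properties[pid]
        node = {"id": pid, "type": "PROPERTY"}
        if prop.label:
            node["lbl"] = prop.label
        nodes.append(node)
        if prop.transitive or prop.reflexive:
            logger.warning(
                "obographs export drops transitive/reflexive flag on %s", pid
            )

    def as_restriction(expr: ClassExpr):
        if isinstance(expr, Some) and isinstance(expr.filler, Named):
            return {"propertyId": expr.property.id, "fillerId": expr.filler.id}
        return None

    for ax in ont.axioms:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Named):
            if isinstance(ax.sup, Named):
                edges.append({"sub": ax.sub.id, "pred": "is_a", "obj": ax.sup.id})
                continue
            if isinstance(ax.sup, Some) and isinstance(ax.sup.filler, Named):
                edges.append(
                    {"sub": ax.sub.id, "pred": ax.sup.property.id, "obj": ax.sup.filler.id}
                )
                continue
            if isinstance(ax.sup, And):
                simple = True
                for conj in ax.sup.conjuncts:
                    if not (isinstance(conj, Named) or as_restriction(conj)):
                        simple = False
                if simple:
                    for conj in ax.sup.conjuncts:
                        if isinstance(conj, Named):
                            edges.append({"sub": ax.sub.id, "pred": "is_a", "obj": conj.id})
                        else:
                            edges.append(
                                {
                                    "sub": ax.sub.id,
                                    "pred": conj.property.id,
                                    "obj": conj.filler.id,
                                }
                            )
                    continue
        if isinstance(ax, EquivalentClasses) and len(ax.exprs) == 2:
            named = [e for e in ax.exprs if isinstance(e, Named)]
            other = [e for e in ax.exprs if not isinstance(e, Named)]
            if len(named) == 1 and len(other) == 1 and isinstance(other[0], And):
                genus, restrictions, ok = [], [], True
                for conj in other[0].conjuncts:
                    if isinstance(conj, Named):
                        genus.append(conj.id)
                    else:
                        restr = as_restriction(conj)
                        if restr is None:
                            ok = False
                            break
                        restrictions.append(restr)
                if ok:
                    ldas.append(
                        {
                            "definedClassId": named[0].id,
                            "genusIds": genus,
                            "restrictions": restrictions,
                        }
                    )
                    continue
        if isinstance(ax, SubPropertyOf):
            edges.append({"sub": ax.sub.id, "pred": "subPropertyOf", "obj": ax.sup.id})
            continue
        if isinstance(ax, PropertyChain):
            pcas.append(
                {
                    "predicateId": ax.sup.id,
                    "chainPredicateIds": [ax.first.id, ax.second.id],
                }
            )
            continue
        raise OntologyError(f"axiom not representable in obographs export: {ax}")
    graph = {
        "nodes": nodes,
        "edges": edges,
        "logicalDefinitionAxioms": ldas,
        "propertyChainAxioms": pcas,
    }
    return json.dumps({"graphs": [graph]}, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Functional-syntax subset
# ---------------------------------------------------------------------------

_SUPPORTED_HEADS = {
    "Declaration", "Class", "ObjectProperty",
    "SubClassOf", "EquivalentClasses",
    "ObjectIntersectionOf", "ObjectSomeValuesFrom",
    "SubObjectPropertyOf", "ObjectPropertyChain",
    "TransitiveObjectProperty", "ReflexiveObjectProperty",
    "AnnotationAssertion",
}

_TOKEN_RE = re.compile(r"\(|\)|\"(?:[^\"\\]|\\.)*\"|[^\s()]+")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0]
        for match in _TOKEN_RE.finditer(stripped):
            tokens.append((match.group(0), lineno))
    return tokens


def _parse_sexprs(tokens: list[tuple[str, int]]):
    """Parse a flat token stream into nested (head, args) s-expressions."""
    pos = 0

    def parse_one():
        nonlocal pos
        tok, lineno = tokens[pos]
        if tok == ")":
            raise ParseError(f"unexpected ')' at line {lineno}")
        pos += 1
        if pos < len(tokens) and tokens[pos][0] == "(":
            pos += 1  # consume '('
            args = []
            while True:
                if pos >= len(tokens):
                    raise ParseError(f"unbalanced parentheses (opened near line {lineno})")
                if tokens[pos][0] == ")":
                    pos += 1
                    return (tok, args, lineno)
                args.append(parse_one())
        return tok

    exprs = []
    while pos < len(tokens):
        tok, lineno = tokens[pos]
        if tok == ")":
            raise ParseError(f"unbalanced parentheses at line {lineno}")
        exprs.append(parse_one())
        if isinstance(exprs[-1], str):
            raise ParseError(f"bare token {exprs[-1]!r} at top level, line {lineno}")
    return exprs


def _strip_name(name: str) -> str:
    if name.startswith(":"):
        name = name[1:]
    return normalize_curie(name.strip("<>"))


def _class_name(name: str) -> str:
    name = _strip_name(name)
    # class ids must be CURIEs; bare local names get a default prefix
    return name if ":" in name else f"LOCAL:{name}"


def parse_functional_subset(text: str) -> Ontology:
    """Parse the supported OWL functional-syntax subset.

    Any construct outside the subset (e.g. ``ObjectUnionOf``,
    ``InverseObjectProperties``, ``ObjectAllValuesFrom``) raises
    :class:`ProfileViolationError`.
    """
    exprs = _parse_sexprs(_tokenize(text))
    ont = Ontology()
    pending: list[tuple] = []

    def check_head(head: str, lineno: int) -> None:
        if head not in _SUPPORTED_HEADS:
            raise ProfileViolationError(
                f"unsupported construct {head} at line {lineno}"
            )

    # first pass: declarations, so expressions can resolve refs
    for node in exprs:
        head, args, lineno = node
        if head == "Ontology":
            pending.extend(a for a in args if not isinstance(a, str))
            continue
        pending.append(node)

    def get_class(name: str) -> ClassRef:
        cid = _class_name(name)
        if cid not in ont.classes:
            ont.add_class(ClassRef(cid))
        return ont.classes[cid]

    def get_prop(name: str) -> PropertyRef:
        pid = _strip_name(name)
        if pid not in ont.properties:
            ont.add_property(PropertyRef(pid))
        return ont.properties[pid]

    for node in pending:
        head, args, lineno = node
        check_head(head, lineno)
        if head == "Declaration":
            inner = args[0]
            if isinstance(inner, str):
                raise ParseError(f"malformed Declaration at line {lineno}")
            ihead, iargs, _ = inner
            check_head(ihead, lineno)
            if ihead == "Class":
                get_class(iargs[0])
            elif ihead == "ObjectProperty":
                get_prop(iargs[0])
            else:
                raise ProfileViolationError(
                    f"unsupported declaration {ihead} at line {lineno}"
                )

    def to_expr(node) -> ClassExpr:
        if isinstance(node, str):
            return Named(get_class(node))
        head, args, lineno = node
        check_head(head, lineno)
        if head == "ObjectIntersectionOf":
            return And(tuple(to_expr(a) for a in args))
        if head == "ObjectSomeValuesFrom":
            return Some(get_prop(args[0]), to_expr(args[1]))
        raise ProfileViolationError(f"unsupported class constructor {head} at line {lineno}")

    for node in pending:
        head, args, lineno = node
        if head == "Declaration":
            continue
        check_head(head, lineno)
        if head == "SubClassOf":
            ont.add_axiom(SubClassOf(to_expr(args[0]), to_expr(args[1])))
        elif head == "EquivalentClasses":
            ont.add_axiom(EquivalentClasses(tuple(to_expr(a) for a in args)))
        elif head == "SubObjectPropertyOf":
            first = args[0]
            if isinstance(first, tuple) and first[0] == "ObjectPropertyChain":
                chain = [get_prop(a) for a in first[1]]
                if len(chain) != 2:
                    raise ProfileViolationError(
                        f"only binary property chains supported (line {lineno})"
                    )
                ont.add_axiom(PropertyChain(chain[0], chain[1], get_prop(args[1])))
            else:
                ont.add_axiom(SubPropertyOf(get_prop(args[0]), get_prop(args[1])))
        elif head == "TransitiveObjectProperty":
            pid = _strip_name(args[0])
            base = ont.properties.get(pid, PropertyRef(pid))
            ont.properties[pid] = replace(base, transitive=True)
        elif head == "ReflexiveObjectProperty":
            pid = _strip_name(args[0])
            base = ont.properties.get(pid, PropertyRef(pid))
            ont.properties[pid] = replace(base, reflexive=True)
        elif head == "AnnotationAssertion":
            # only rdfs:label annotations are interpreted
            if len(args) == 3 and str(args[0]).endswith("label"):
                cid = _class_name(args[1])
                pid = _strip_name(args[1])
                label = str(args[2]).strip('"')
                if cid in ont.classes:
                    ont.add_class(ClassRef(cid, label=label))
                elif pid in ont.properties:
                    ont.properties[pid] = replace(ont.properties[pid], label=label)
    return ont


def serialize_functional(ont: Ontology) -> str:
    """Canonical functional-syntax-subset dump (round-trips by parse)."""
    lines = []
    for cid in sorted(ont.classes):
        lines.append(f"Declaration(Class({cid}))")
    for pid in sorted(ont.properties):
        lines.append(f"Declaration(ObjectProperty({pid}))")
    for pid in sorted(ont.properties):
        p = ont.properties[pid]
        if p.transitive:
            lines.append(f"TransitiveObjectProperty({pid})")
        if p.reflexive:
            lines.append(f"ReflexiveObjectProperty({pid})")
    for cid in sorted(ont.classes):
        label = ont.classes[cid].label
        if label:
            escaped = label.replace('"', '\\"')
            lines.append(f'AnnotationAssertion(rdfs:label {cid} "{escaped}")')
    for pid in sorted(ont.properties):
        label = ont.properties[pid].label
        if label:
            escaped = label.replace('"', '\\"')
            lines.append(f'AnnotationAssertion(rdfs:label {pid} "{escaped}")')

    def dump(expr: ClassExpr) -> str:
        if isinstance(expr, Named):
            return expr.id
        if isinstance(expr, Some):
            return f"ObjectSomeValuesFrom({expr.property.id} {dump(expr.filler)})"
        return "ObjectIntersectionOf(" + " ".join(dump(c) for c in expr.conjuncts) + ")"

    ax_lines = []
    for ax in ont.axioms:
        if isinstance(ax, SubClassOf):
            ax_lines.append(f"SubClassOf({dump(ax.sub)} {dump(ax.sup)})")
        elif isinstance(ax, EquivalentClasses):
            ax_lines.append("EquivalentClasses(" + " ".join(dump(e) for e in ax.exprs) + ")")
        elif isinstance(ax, SubPropertyOf):
            ax_lines.append(f"SubObjectPropertyOf({ax.sub.id} {ax.sup.id})")
        else:
            ax_lines.append(
                f"SubObjectPropertyOf(ObjectPropertyChain({ax.first.id} {ax.second.id}) {ax.sup.id})"
            )
    lines.extend(sorted(ax_lines))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


def merge_ontologies(parts: list[Ontology]) -> Ontology:
    """Union of classes, properties and axioms.

    Duplicate declarations collapse; conflicting class labels resolve to
    the first occurrence with a logged warning.  The same property id
    declared with different transitive/reflexive flags across parts is a
    :class:`MergeConflictError`.
    """
    if not parts:
        raise OntologyError("merge_ontologies requires at least one part")
    out = Ontology()
    for part in parts:
        for ref in part.classes.values():
            out.add_class(ref)
        for prop in part.properties.values():
            existing = out.properties.get(prop.id)
            if existing is not None and (
                existing.transitive != prop.transitive
                or existing.reflexive != prop.reflexive
            ):
                raise MergeConflictError(
                    f"conflicting property characteristics for {prop.id}"
                )
            out.add_property(prop)
        for ax in part.axioms:
            out.add_axiom(ax)
    return out


# ---------------------------------------------------------------------------
# EL normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizedAxioms:
    """EL axioms reduced to four normal forms over named classes.

    nf1: (A, B) for A ⊑ B
    nf2: (A1, A2, B) for A1 ⊓ A2 ⊑ B
    nf3: (A, R, B) for A ⊑ ∃R.B
    nf4: (R, A, B) for ∃R.A ⊑ B
    """

    nf1: set = field(default_factory=set)
    nf2: set = field(default_factory=set)
    nf3: set = field(default_factory=set)
    nf4: set = field(default_factory=set)
    sub_properties: set = field(default_factory=set)   # (sub, sup) ids
    chains: set = field(default_factory=set)           # (r1, r2, sup) ids
    reflexive_properties: set = field(default_factory=set)
    classes: set = field(default_factory=set)          # all named ids incl. fresh
    fresh_classes: set = field(default_factory=set)

    @property
    def original_classes(self) -> set:
        return self.classes - self.fresh_classes


def normalize(ont: Ontology) -> NormalizedAxioms:
    """Decompose every axiom into NF1–NF4 with deterministic fresh names.

    EquivalentClasses become pairwise mutual SubClassOf; a transitive
    property R is compiled to the chain R ∘ R ⊑ R; fresh names take the
    reserved ``X:`` prefix numbered in input order, so the same input
    yields the same output.
    """
    nx = NormalizedAxioms()
    nx.classes.update(ont.classes)
    counter = [0]

    def fresh() -> str:
        counter[0] += 1
        name = f"{FRESH_PREFIX}:{counter[0]:04d}"
        nx.fresh_classes.add(name)
        nx.classes.add(name)
        return name

    def norm_sub(expr: ClassExpr) -> str:
        """Name the expression on a subclass (left) position."""
        if isinstance(expr, Named):
            return expr.id
        if isinstance(expr, And):
            names = [norm_sub(c) for c in expr.conjuncts]
            acc = names[0]
            for nxt in names[1:]:
                f = fresh()
                nx.nf2.add((acc, nxt, f))
                acc = f
            return acc
        f_filler = norm_sub(expr.filler)
        f = fresh()
        nx.nf4.add((expr.property.id, f_filler, f))
        return f

    def norm_sup(a: str, expr: ClassExpr) -> None:
        """Emit axioms for ``a ⊑ expr``."""
        if isinstance(expr, Named):
            nx.nf1.add((a, expr.id))
            return
        if isinstance(expr, And):
            for c in expr.conjuncts:
                norm_sup(a, c)
            return
        if isinstance(expr.filler, Named):
            nx.nf3.add((a, expr.property.id, expr.filler.id))
            return
        b = fresh()
        nx.nf3.add((a, expr.property.id, b))
        norm_sup(b, expr.filler)

    def handle_subclassof(sub: ClassExpr, sup: ClassExpr) -> None:
        a = sub.id if isinstance(sub, Named) else norm_sub(sub)
        norm_sup(a, sup)

    for ax in ont.axioms:
        if isinstance(ax, SubClassOf):
            handle_subclassof(ax.sub, ax.sup)
        elif isinstance(ax, EquivalentClasses):
            exprs = list(ax.exprs)
            for i, e1 in enumerate(exprs):
                for e2 in exprs[i + 1:]:
                    handle_subclassof(e1, e2)
                    handle_subclassof(e2, e1)
        elif isinstance(ax, SubPropertyOf):
            nx.sub_properties.add((ax.sub.id, ax.sup.id))
        else:
            nx.chains.add((ax.first.id, ax.second.id, ax.sup.id))

    for prop in ont.properties.values():
        if prop.transitive:
            nx.chains.add((prop.id, prop.id, prop.id))
        if prop.reflexive:
            nx.reflexive_properties.add(prop.id)
    return nx
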