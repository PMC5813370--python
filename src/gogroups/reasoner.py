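"""EL completion-rule saturation, classification and DL queries.

The saturation computes the least fixpoint of the standard EL completion
rules over normalized axioms:

* (init) C ⊑ C for every named class C
* (R1) C ⊑ A, A ⊑ B            ⇒ C ⊑ B
* (R2) C ⊑ A1, C ⊑ A2, A1⊓A2⊑B ⇒ C ⊑ B
* (R3) C ⊑ A, A ⊑ ∃R.B         ⇒ link(C, R, B)
* (R4) link(C,R,D), D ⊑ A, ∃R.A⊑B ⇒ C ⊑ B
* (R5) link(C,R,D), R ⊑ S      ⇒ link(C, S, D)
* (R6) link(C,R1,D), link(D,R2,E), R1∘R2⊑S ⇒ link(C, S, E)
* (R7) reflexive R             ⇒ link(C, R, C) for every class C

``saturate`` is the production implementation (worklist with indexes, the
same architecture ELK-style reasoners use); ``naive_closure`` recomputes
the identical fixpoint by brute-force repeated passes with no worklist and
no indexing, and exists purely as an independent oracle for testing.

``query`` answers a DL query for an arbitrary EL class expression by
extending the ontology with a fresh query class equivalent to the
expression, saturating, and reading off equivalent and strictly subsumed
named classes.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .ontology import (
    And,
    ClassExpr,
    ClassRef,
    EquivalentClasses,
    FRESH_PREFIX,
    Named,
    NormalizedAxioms,
    Ontology,
    ReferentialError,
    normalize,
)


@dataclass
class Saturation:
    """Entailed subsumptions and role links over named classes.

    ``subsumptions`` maps each class id to the set of ids subsuming it
    (always including itself); ``links`` holds entailed role assertions
    ``(source, property, target)`` closed under the property hierarchy,
    chains and reflexivity.
    """

    subsumptions: dict = field(default_factory=dict)
    links: set = field(default_factory=set)

    def is_subsumed(self, sub: str, sup: str) -> bool:
        return sup in self.subsumptions.get(sub, ())


def _super_properties(nx: NormalizedAxioms) -> dict:
    """Reflexive-transitive closure of the declared property hierarchy."""
    props: set[str] = set()
    for s, p in nx.sub_properties:
        props.update((s, p))
    for r1, r2, s in nx.chains:
        props.update((r1, r2, s))
    props.update(nx.reflexive_properties)
    for _, r, _ in nx.nf3:
        props.add(r)
    for r, _, _ in nx.nf4:
        props.add(r)

    supers = {p: {p} for p in props}
    direct: dict[str, set[str]] = {}
    for s, p in nx.sub_properties:
        direct.setdefault(s, set()).add(p)
    changed = True
    while changed:
        changed = False
        for p in props:
            new = set()
            for q in supers[p]:
                new |= direct.get(q, set())
            if not new <= supers[p]:
                supers[p] |= new
                changed = True
    return supers


def saturate(nx: NormalizedAxioms) -> Saturation:
    """Worklist saturation with indexes keyed on class and (property, class)."""
    supers = _super_properties(nx)

    nf1_by_sub: dict[str, list[str]] = {}
    for a, b in nx.nf1:
        nf1_by_sub.setdefault(a, []).append(b)
    nf2_by_conj: dict[str, list[tuple[str, str]]] = {}
    for a1, a2, b in nx.nf2:
        nf2_by_conj.setdefault(a1, []).append((a2, b))
        if a1 != a2:
            nf2_by_conj.setdefault(a2, []).append((a1, b))
    nf3_by_sub: dict[str, list[tuple[str, str]]] = {}
    for a, r, b in nx.nf3:
        nf3_by_sub.setdefault(a, []).append((r, b))
    nf4_by_prop_filler: dict[tuple[str, str], list[str]] = {}
    for r, a, b in nx.nf4:
        nf4_by_prop_filler.setdefault((r, a), []).append(b)
    chains_by_first: dict[str, list[tuple[str, str]]] = {}
    chains_by_second: dict[str, list[tuple[str, str]]] = {}
    for r1, r2, s in nx.chains:
        chains_by_first.setdefault(r1, []).append((r2, s))
        chains_by_second.setdefault(r2, []).append((r1, s))

    subs: dict[str, set[str]] = {c: set() for c in nx.classes}
    links: set[tuple[str, str, str]] = set()
    links_out: dict[str, set[tuple[str, str]]] = {}
    links_in: dict[str, set[tuple[str, str]]] = {}

    queue: deque = deque()

    def push_sub(c: str, a: str) -> None:
        if a not in subs[c]:
            subs[c].add(a)
            queue.append(("s", c, a))

    def push_link(c: str, r: str, d: str) -> None:
        # close under the property hierarchy at insertion (rule R5)
        for s in supers.get(r, (r,)):
            triple = (c, s, d)
            if triple not in links:
                links.add(triple)
                links_out.setdefault(c, set()).add((s, d))
                links_in.setdefault(d, set()).add((s, c))
                queue.append(("l", c, s, d))

    for c in nx.classes:
        push_sub(c, c)
        for r in nx.reflexive_properties:
            push_link(c, r, c)

    while queue:
        item = queue.popleft()
        if item[0] == "s":
            _, c, a = item
            for b in nf1_by_sub.get(a, ()):          # R1
                push_sub(c, b)
            for a2, b in nf2_by_conj.get(a, ()):     # R2
                if a2 in subs[c]:
                    push_sub(c, b)
            for r, b in nf3_by_sub.get(a, ()):       # R3
                push_link(c, r, b)
            # R4 with new subsumption D ⊑ A: incoming links to D=c
            for r, e in links_in.get(c, set()).copy():
                for b in nf4_by_prop_filler.get((r, a), ()):
                    push_sub(e, b)
        else:
            _, c, r, d = item
            for a in subs[d].copy():                 # R4
                for b in nf4_by_prop_filler.get((r, a), ()):
                    push_sub(c, b)
            for r2, s in chains_by_first.get(r, ()): # R6 (new link is left)
                for r2b, e in links_out.get(d, set()).copy():
                    if r2b == r2:
                        push_link(c, s, e)
            for r1, s in chains_by_second.get(r, ()):  # R6 (new link is right)
                for r1b, b in links_in.get(c, set()).copy():
                    if r1b == r1:
                        push_link(b, s, d)

    return Saturation(subsumptions=subs, links=links)


def naive_closure(nx: NormalizedAxioms) -> Saturation:
    """Brute-force fixpoint oracle: repeated full passes, no indexing.

    Intended for small inputs only; must agree exactly with ``saturate``.
    """
    subs: dict[str, set[str]] = {c: {c} for c in nx.classes}
    links: set[tuple[str, str, str]] = set()
    for c in nx.classes:
        for r in nx.reflexive_properties:
            links.add((c, r, c))

    changed = True
    while changed:
        changed = False
        for c in nx.classes:
            for a in list(subs[c]):
                for a1, b in nx.nf1:
                    if a1 == a and b not in subs[c]:
                        subs[c].add(b)
                        changed = True
                for a1, a2, b in nx.nf2:
                    if a1 == a and a2 in subs[c] and b not in subs[c]:
                        subs[c].add(b)
                        changed = True
                for a1, r, b in nx.nf3:
                    if a1 == a and (c, r, b) not in links:
                        links.add((c, r, b))
                        changed = True
        for (c, r, d) in list(links):
            for rr, a, b in nx.nf4:
                if rr == r and a in subs[d] and b not in subs[c]:
                    subs[c].add(b)
                    changed = True
            for sub_p, sup_p in nx.sub_properties:
                if sub_p == r and (c, sup_p, d) not in links:
                    links.add((c, sup_p, d))
                    changed = True
        for (c, r1, d) in list(links):
            for (d2, r2, e) in list(links):
                if d2 != d:
                    continue
                for c1, c2, s in nx.chains:
                    if c1 == r1 and c2 == r2 and (c, s, e) not in links:
                        links.add((c, s, e))
                        changed = True
    return Saturation(subsumptions=subs, links=links)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


@dataclass
class Taxonomy:
    """Equivalence groups plus direct subsumption edges between groups."""

    groups: list            # list of sorted tuples of class ids
    group_of: dict          # class id -> group index
    direct_edges: set       # (sub group index, sup group index)


def classify(sat: Saturation) -> Taxonomy:
    """Group mutually subsumed classes and transitively reduce the rest."""
    ids = sorted(sat.subsumptions)
    group_key: dict[str, tuple] = {}
    for c in ids:
        equiv = tuple(sorted(d for d in sat.subsumptions[c] if sat.is_subsumed(d, c)))
        group_key[c] = equiv
    groups = sorted(set(group_key.values()))
    group_of = {c: groups.index(group_key[c]) for c in ids}

    def strict_supers(gi: int) -> set[int]:
        rep = groups[gi][0]
        return {
            group_of[s]
            for s in sat.subsumptions[rep]
            if group_of[s] != gi
        }

    direct = set()
    for gi in range(len(groups)):
        ups = strict_supers(gi)
        for gj in ups:
            # gj is direct iff no intermediate group strictly between
            if not any(gj in strict_supers(gk) for gk in ups if gk != gj):
                direct.add((gi, gj))
    return Taxonomy(groups=[tuple(g) for g in groups], group_of=group_of, direct_edges=direct)


# ---------------------------------------------------------------------------
# DL queries
# ---------------------------------------------------------------------------

QUERY_CLASS_ID = f"{FRESH_PREFIX}:query"


@dataclass
class QueryResult:
    """Named classes equivalent to and strictly subsumed by a query expression.

    ``obsolete`` retains ids of obsolete classes that would otherwise have
    been answers; they are excluded from ``equivalents``/``descendants``.
    """

    query_expr: ClassExpr
    equivalents: list
    descendants: list
    obsolete: list = field(default_factory=list)

    @property
    def all_ids(self) -> set:
        return {c.id for c in self.equivalents} | {c.id for c in self.descendants}


def _check_signature(ont: Ontology, expr: ClassExpr) -> None:
    if isinstance(expr, Named):
        if expr.id not in ont.classes:
            raise ReferentialError(f"query references undeclared class {expr.id}")
    elif isinstance(expr, And):
        for c in expr.conjuncts:
            _check_signature(ont, c)
    else:
        if expr.property.id not in ont.properties:
            raise ReferentialError(
                f"query references undeclared property {expr.property.id}"
            )
        _check_signature(ont, expr.filler)


def _result_from_saturation(
    ont: Ontology,
    sat: Saturation,
    qid: str,
    expr: ClassExpr,
    result_prefixes: set[str] | None,
) -> QueryResult:
    prefixes = result_prefixes if result_prefixes is not None else {"GO"}
    equivalents, descendants, obsolete = [], [], []
    for cid, sups in sat.subsumptions.items():
        if qid not in sups or cid == qid:
            continue
        if cid.split(":", 1)[0] == FRESH_PREFIX:
            continue
        ref = ont.classes.get(cid)
        if ref is None or ref.namespace not in prefixes:
            continue
        if ref.obsolete:
            obsolete.append(cid)
            continue
        if sat.is_subsumed(qid, cid):
            equivalents.append(ref)
        else:
            descendants.append(ref)
    equivalents.sort(key=lambda r: r.id)
    descendants.sort(key=lambda r: r.id)
    obsolete.sort()
    return QueryResult(
        query_expr=expr,
        equivalents=equivalents,
        descendants=descendants,
        obsolete=obsolete,
    )


def query_all(
    ont: Ontology,
    exprs: dict,
    result_prefixes: set[str] | None = None,
    saturator=saturate,
) -> dict:
    """Answer several DL queries over one shared saturation.

    ``exprs`` maps a caller-chosen key to a ClassExpr; one fresh query
    class per expression is added, the extended ontology is normalized and
    saturated once, and per-key results are read off.  Fresh names never
    leak into results.
    """
    extended = ont.copy()
    qids = {}
    for i, (key, expr) in enumerate(exprs.items(), start=1):
        _check_signature(ont, expr)
        qid = f"{QUERY_CLASS_ID}{i:04d}"
        qids[key] = qid
        extended.add_class(ClassRef(qid))
        extended.add_axiom(EquivalentClasses((Named(extended.classes[qid]), expr)))
    nx = normalize(extended)
    sat = saturator(nx)
    return {
        key: _result_from_saturation(ont, sat, qids[key], exprs[key], result_prefixes)
        for key in exprs
    }


def query(
    ont: Ontology,
    expr: ClassExpr,
    result_prefixes: set[str] | None = None,
    saturator=saturate,
) -> QueryResult:
    """Answer a single DL query (equivalent + subsumed named classes)."""
    return query_all(ont, {"q": expr}, result_prefixes, saturator)["q"]
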