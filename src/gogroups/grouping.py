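"""Bespoke grouping object properties and query descriptions.

OWL 2 EL has no disjunction, so a query like "processes in which a
chemical participates OR that regulate such a process" cannot be written
directly.  The workaround is a *grouping property*: a high-level object
property with the individual routes as subproperties, plus property-chain
axioms for composed routes (e.g. ``regulates ∘ has_participant``).  An
existential restriction over the grouping property then answers the
disjunctive question in one EL query.  Making the grouping property
reflexive additionally makes the filler class (and its subclasses) answer
its own query — used for structure patterns like "a synapse OR part of a
synapse".

Grouping specs are data, not code: presets ship as packaged JSON and users
can load their own spec files, so new query patterns need no code change.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

from .ontology import (
    Axiom,
    ClassRef,
    Ontology,
    OntologyError,
    PropertyChain,
    PropertyRef,
    SubPropertyOf,
)

logger = logging.getLogger("gogroups")


@dataclass(frozen=True)
class GroupingSpec:
    """Declarative definition of one grouping property.

    ``chains`` lists (r1, r2) pairs; each induces an intermediate property
    named ``<r1>_o_<r2>`` defined by the chain r1 ∘ r2 and placed under
    the grouping property.  ``description_template`` must contain the
    ``{filler}`` placeholder; it may repeat (one slot per disjunct of the
    emulated OR), and every occurrence receives the same filler label.
    """

    name: str
    subproperties: tuple = ()
    chains: tuple = ()          # of (r1, r2) id pairs
    reflexive: bool = False
    description_template: str = ""

    def __post_init__(self) -> None:
        if self.description_template and "{filler}" not in self.description_template:
            raise OntologyError(
                f"grouping spec {self.name}: template lacks {{filler}} placeholder"
            )
        if self.name in self.subproperties:
            raise OntologyError(
                f"grouping spec {self.name}: name collides with a member property"
            )


def chain_property_id(r1: str, r2: str) -> str:
    local = f"{r1.split(':', 1)[-1]}_o_{r2.split(':', 1)[-1]}"
    return local if ":" not in r1 else f"{r1.split(':', 1)[0]}:{local}"


def make_grouping_property(spec: GroupingSpec) -> tuple[list[PropertyRef], list[Axiom]]:
    """Emit the declarations and axioms realizing one grouping property.

    Returns ``(properties, axioms)``: the grouping property itself (with
    its reflexive flag), one intermediate property per chain, one
    SubPropertyOf per subproperty and per intermediate, and one
    PropertyChain per chain.
    """
    grouping = PropertyRef(spec.name, reflexive=spec.reflexive)
    properties = [grouping]
    axioms: list[Axiom] = []
    for pid in spec.subproperties:
        axioms.append(SubPropertyOf(PropertyRef(pid), grouping))
    for r1, r2 in spec.chains:
        inter = PropertyRef(chain_property_id(r1, r2))
        properties.append(inter)
        axioms.append(PropertyChain(PropertyRef(r1), PropertyRef(r2), inter))
        axioms.append(SubPropertyOf(inter, grouping))
    return properties, axioms


# -- presets ----------------------------------------------------------------

#: base relations the presets build on (mirrors the GO relation hierarchy
#: for regulation direction)
BASE_PROPERTY_HIERARCHY = (
    ("positively_regulates", "regulates"),
    ("negatively_regulates", "regulates"),
)

BASE_PROPERTIES = (
    "part_of",
    "has_participant",
    "occurs_in",
    "regulates",
    "positively_regulates",
    "negatively_regulates",
    "results_in_development_of",
    "results_in_organization_of",
)


def load_grouping_specs(text: str) -> list[GroupingSpec]:
    """Load grouping specs from a JSON document (list of objects)."""
    raw = json.loads(text)
    specs = []
    for item in raw:
        specs.append(
            GroupingSpec(
                name=item["name"],
                subproperties=tuple(item.get("subproperties", ())),
                chains=tuple(tuple(c) for c in item.get("chains", ())),
                reflexive=bool(item.get("reflexive", False)),
                description_template=item.get("description_template", ""),
            )
        )
    return specs


def standard_grouping_specs() -> list[GroupingSpec]:
    """The grouping-property presets shipped with the package."""
    text = resources.files("gogroups").joinpath("data/grouping_presets.json").read_text()
    return load_grouping_specs(text)


def standard_grouping_axioms() -> tuple[list[PropertyRef], list[Axiom]]:
    """Declarations + axioms for all presets plus the base hierarchy.

    Deterministic: applying twice yields an identical axiom multiset.
    """
    properties = [PropertyRef(p) for p in BASE_PROPERTIES]
    axioms: list[Axiom] = [
        SubPropertyOf(PropertyRef(s), PropertyRef(p)) for s, p in BASE_PROPERTY_HIERARCHY
    ]
    for spec in standard_grouping_specs():
        props, axs = make_grouping_property(spec)
        properties.extend(props)
        axioms.extend(axs)
    return properties, axioms


def grouping_ontology() -> Ontology:
    """The presets as a standalone ontology, ready for merging."""
    ont = Ontology()
    properties, axioms = standard_grouping_axioms()
    for p in properties:
        ont.add_property(p)
    for ax in axioms:
        ont.add_property(ax.sub if isinstance(ax, SubPropertyOf) else ax.first)
        if isinstance(ax, PropertyChain):
            ont.add_property(ax.second)
            ont.add_property(ax.sup)
        else:
            ont.add_property(ax.sup)
        ont.add_axiom(ax)
    return ont


def apply_groupings(ont: Ontology) -> Ontology:
    """Return a copy of ``ont`` extended with the preset grouping axioms.

    Unlike a strict merge, property characteristic flags are OR-combined:
    serializations that cannot carry transitive/reflexive flags (obographs)
    would otherwise conflict with the presets on re-import.
    """
    out = ont.copy()
    properties, axioms = standard_grouping_axioms()
    for prop in properties:
        out.add_property(prop)
    for ax in axioms:
        if isinstance(ax, SubPropertyOf):
            out.add_property(ax.sub)
            out.add_property(ax.sup)
        else:
            out.add_property(ax.first)
            out.add_property(ax.second)
            out.add_property(ax.sup)
        out.add_axiom(ax)
    return out


def describe_query(spec: GroupingSpec, filler: ClassRef) -> str:
    """Instantiate the spec's template with the filler's label.

    Falls back to the CURIE with a logged warning when the label is
    missing.
    """
    label = filler.label
    if not label:
        logger.warning("filler %s has no label; using its CURIE in description", filler.id)
        label = filler.id
    return spec.description_template.replace("{filler}", label)
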