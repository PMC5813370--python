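"""Deterministic fixtures: toy ontologies, random EL ontologies, and
synthetic expression data with planted tissue signatures.

Everything here is generated in memory from a seed so the full pipeline —
parsing, reasoning, mapping, gene-set construction, enrichment — is
testable without downloading any real ontology or expression resource.
The toy ontologies reuse real GO/ChEBI identifiers for traceability but
make no claim of fidelity to the real ontologies.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import ExpressionMatrix
from .grouping import grouping_ontology
from .mapping import CombinedMapping
from .ontology import (
    And,
    ClassRef,
    EquivalentClasses,
    Named,
    Ontology,
    PropertyChain,
    PropertyRef,
    Some,
    SubClassOf,
    SubPropertyOf,
    merge_ontologies,
)

# ---------------------------------------------------------------------------
# Toy cannabinoid ontology (worked mapping example)
# ---------------------------------------------------------------------------

CANNABINOID_FILLER = "CHEBI:67194"

#: the five GO classes the cannabinoid mapping query must return
CANNABINOID_GO_IDS = (
    "GO:0004949",  # cannabinoid receptor activity
    "GO:0038171",  # cannabinoid signaling pathway
    "GO:0071926",  # endocannabinoid signaling pathway
    "GO:1901696",  # cannabinoid biosynthetic process
    "GO:2000124",  # regulation of endocannabinoid signaling pathway
)

#: the subset present in the manual mapping (auto finds three more)
CANNABINOID_MANUAL_IDS = ("GO:0038171", "GO:2000124")

_CANNABINOID_LABELS = {
    "GO:0004949": "cannabinoid receptor activity",
    "GO:0038171": "cannabinoid signaling pathway",
    "GO:0071926": "endocannabinoid signaling pathway",
    "GO:1901696": "cannabinoid biosynthetic process",
    "GO:2000124": "regulation of endocannabinoid signaling pathway",
    "CHEBI:67194": "cannabinoid",
    "CHEBI:67197": "endocannabinoid",
}


def toy_cannabinoid_ontology() -> Ontology:
    """Tiny ontology reproducing the cannabinoid mapping worked example.

    The query ``participant_OR_reg_participant some cannabinoid`` must
    return exactly the five GO classes: four via direct participation
    (one of them through a subclass filler) and the regulation class only
    via the ``regulates ∘ has_participant`` chain.  Grouping-property
    presets are merged in.
    """
    ont = Ontology()
    for cid, label in _CANNABINOID_LABELS.items():
        ont.add_class(ClassRef(cid, label=label))
    has_part = PropertyRef("has_participant")
    regulates = PropertyRef("regulates")
    ont.add_property(has_part)
    ont.add_property(regulates)

    def cl(cid: str) -> Named:
        return Named(ont.classes[cid])

    ont.add_axiom(SubClassOf(cl("CHEBI:67197"), cl("CHEBI:67194")))
    ont.add_axiom(SubClassOf(cl("GO:0038171"), Some(has_part, cl("CHEBI:67194"))))
    ont.add_axiom(
        SubClassOf(
            cl("GO:0071926"),
            And((cl("GO:0038171"), Some(has_part, cl("CHEBI:67197")))),
        )
    )
    ont.add_axiom(SubClassOf(cl("GO:2000124"), Some(regulates, cl("GO:0071926"))))
    ont.add_axiom(SubClassOf(cl("GO:0004949"), Some(has_part, cl("CHEBI:67194"))))
    ont.add_axiom(SubClassOf(cl("GO:1901696"), Some(has_part, cl("CHEBI:67194"))))
    return merge_ontologies([ont, grouping_ontology()])


def cannabinoid_manual_mapping() -> dict[str, set[str]]:
    return {"cannabinoid": set(CANNABINOID_MANUAL_IDS)}


def cannabinoid_mapping_table() -> str:
    return (
        "term\tproperty\tfiller\n"
        f"cannabinoid\tparticipant_OR_reg_participant\t{CANNABINOID_FILLER}\n"
    )


# ---------------------------------------------------------------------------
# Toy cell/anatomy pattern ontology (T-cell and synapse patterns)
# ---------------------------------------------------------------------------

T_CELL = "CL:0000084"
SYNAPSE = "GO:0045202"

#: witness classes for the four cell-grouping routes of the T-cell pattern
T_CELL_WITNESSES = {
    "part_of": "GO:0042101",                  # T cell receptor complex
    "has_participant": "GO:0070489",          # T cell aggregation
    "occurs_in": "GO:0002456",                # T cell mediated immunity
    "results_in_development_of": "GO:0030217",  # T cell differentiation
}

#: synapse-pattern answers: the filler itself, a subclass of it, a part,
#: an organization process and a participating process
SYNAPSE_WITNESSES = {
    "self": "GO:0045202",
    "subclass": "GO:0060076",                 # excitatory synapse
    "part_of": "GO:0014069",                  # postsynaptic density
    "results_in_organization_of": "GO:0050808",  # synapse organization
    "has_participant": "GO:0099536",          # synaptic signaling
}

_PATTERN_LABELS = {
    T_CELL: "T cell",
    SYNAPSE: "synapse",
    "GO:0042101": "T cell receptor complex",
    "GO:0070489": "T cell aggregation",
    "GO:0002456": "T cell mediated immunity",
    "GO:0030217": "T cell differentiation",
    "GO:0060076": "excitatory synapse",
    "GO:0014069": "postsynaptic density",
    "GO:0050808": "synapse organization",
    "GO:0099536": "synaptic signaling",
}


def toy_pattern_ontology() -> Ontology:
    """Fixture exercising the cell-grouping and reflexive structure
    patterns: each route of each grouping property has one witness class."""
    ont = Ontology()
    for cid, label in _PATTERN_LABELS.items():
        ont.add_class(ClassRef(cid, label=label))
    for pid in (
        "part_of", "has_participant", "occurs_in",
        "results_in_development_of", "results_in_organization_of",
    ):
        ont.add_property(PropertyRef(pid))

    def cl(cid: str) -> Named:
        return Named(ont.classes[cid])

    for route, go_id in T_CELL_WITNESSES.items():
        ont.add_axiom(SubClassOf(cl(go_id), Some(PropertyRef(route), cl(T_CELL))))
    for route, go_id in SYNAPSE_WITNESSES.items():
        if route == "self":
            continue
        if route == "subclass":
            ont.add_axiom(SubClassOf(cl(go_id), cl(SYNAPSE)))
            continue
        ont.add_axiom(SubClassOf(cl(go_id), Some(PropertyRef(route), cl(SYNAPSE))))
    return merge_ontologies([ont, grouping_ontology()])


# ---------------------------------------------------------------------------
# Random EL ontologies (oracle-equivalence testing)
# ---------------------------------------------------------------------------


def random_el_ontology(
    seed: int,
    n_classes: int = 15,
    n_props: int = 3,
    density: float = 2.0,
) -> Ontology:
    """Seeded random EL ontology covering every axiom kind.

    ``density`` scales the number of class axioms (≈ density · n_classes).
    Properties are randomly flagged transitive/reflexive; the axiom mix
    covers plain subsumptions, existential restrictions on both sides,
    conjunctions, equivalences, property hierarchy and chains.
    """
    rng = random.Random(seed)
    ont = Ontology()
    class_ids = [f"RND:C{i:03d}" for i in range(n_classes)]
    prop_ids = [f"RND:p{i}" for i in range(n_props)]
    for cid in class_ids:
        ont.add_class(ClassRef(cid))
    for pid in prop_ids:
        ont.add_property(
            PropertyRef(
                pid,
                transitive=rng.random() < 0.25,
                reflexive=rng.random() < 0.15,
            )
        )

    def rand_class() -> Named:
        return Named(ont.classes[rng.choice(class_ids)])

    def rand_prop() -> PropertyRef:
        return ont.properties[rng.choice(prop_ids)]

    n_axioms = int(density * n_classes)
    if n_axioms == 0:  # declarations only
        return ont
    for _ in range(n_axioms):
        kind = rng.random()
        if kind < 0.30:
            ont.add_axiom(SubClassOf(rand_class(), rand_class()))
        elif kind < 0.50:
            ont.add_axiom(SubClassOf(rand_class(), Some(rand_prop(), rand_class())))
        elif kind < 0.65:
            ont.add_axiom(SubClassOf(Some(rand_prop(), rand_class()), rand_class()))
        elif kind < 0.80:
            ont.add_axiom(
                SubClassOf(And((rand_class(), rand_class())), rand_class())
            )
        elif kind < 0.90:
            ont.add_axiom(
                EquivalentClasses(
                    (rand_class(), And((rand_class(), Some(rand_prop(), rand_class()))))
                )
            )
        else:
            ont.add_axiom(SubClassOf(rand_class(), And((rand_class(), rand_class()))))
    # property axioms: a couple of subproperty and chain axioms
    for _ in range(rng.randint(0, 2)):
        ont.add_axiom(SubPropertyOf(rand_prop(), rand_prop()))
    for _ in range(rng.randint(0, 2)):
        ont.add_axiom(PropertyChain(rand_prop(), rand_prop(), rand_prop()))
    return ont


# ---------------------------------------------------------------------------
# Synthetic expression with planted signatures
# ---------------------------------------------------------------------------


@dataclass
class PlantedTruth:
    """Ground truth for a synthetic expression matrix.

    ``signature_genes`` assigns disjoint gene sets to conditions; those
    genes are shifted up by ``effect_size`` baseline standard deviations
    in their own condition's samples.
    """

    signature_genes: dict            # condition -> set of genes
    effect_size: float = 2.0
    baseline_log_mean: float = 1.0
    baseline_log_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        seen: set = set()
        for genes in self.signature_genes.values():
            if seen & set(genes):
                raise ValueError("signature sets must be disjoint across conditions")
            seen |= set(genes)


def default_truth(
    conditions=("liver", "brain", "blood", "muscle", "skin"),
    genes_per_condition: int = 20,
    effect_size: float = 2.0,
    seed: int = 0,
) -> PlantedTruth:
    """Planted truth with ``genes_per_condition`` signature genes per
    condition, named ``g_<condition>_<i>``."""
    return PlantedTruth(
        signature_genes={
            c: {f"g_{c}_{i:03d}" for i in range(genes_per_condition)}
            for c in conditions
        },
        effect_size=effect_size,
        seed=seed,
    )


def synthetic_expression(
    truth: PlantedTruth,
    n_genes: int = 300,
    samples_per_condition: int = 3,
) -> ExpressionMatrix:
    """Log-normal baseline expression with planted signature shifts.

    Baseline values are LogNormal(baseline_log_mean, baseline_log_sigma);
    each signature gene gains ``effect_size`` baseline standard deviations
    in its own condition's samples.  Values are non-negative; the same
    truth (incl. seed) regenerates the identical matrix.
    """
    conditions = list(truth.signature_genes)
    sig_genes = [g for c in conditions for g in sorted(truth.signature_genes[c])]
    n_background = n_genes - len(sig_genes)
    if n_background < 0:
        raise ValueError("n_genes smaller than the number of signature genes")
    genes = sig_genes + [f"g_bg_{i:04d}" for i in range(n_background)]

    rng = np.random.default_rng(truth.seed)
    samples, sample_conditions = [], {}
    for cond in conditions:
        for k in range(samples_per_condition):
            name = f"{cond}_s{k}"
            samples.append(name)
            sample_conditions[name] = cond

    mu, sigma = truth.baseline_log_mean, truth.baseline_log_sigma
    base = rng.lognormal(mean=mu, sigma=sigma, size=(len(genes), len(samples)))
    # analytic SD of the baseline log-normal
    sd = float(np.sqrt((np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)))
    data = pd.DataFrame(base, index=genes, columns=samples)
    for cond in conditions:
        cols = [s for s in samples if sample_conditions[s] == cond]
        rows = sorted(truth.signature_genes[cond])
        data.loc[rows, cols] += truth.effect_size * sd
    return ExpressionMatrix(data=data, sample_conditions=sample_conditions)


def condition_go_id(condition: str, conditions: list) -> str:
    return f"GO:9{conditions.index(condition):06d}"


def synthetic_annotations(
    truth: PlantedTruth, n_distractors: int = 50
) -> tuple[dict[str, set[str]], CombinedMapping]:
    """Annotations + combined mapping tying planted genes to toy GO ids.

    Each signature gene is annotated to its condition's GO id; distractor
    (background) genes go to an unrelated id.  The combined mapping maps
    one vocabulary term per condition to that condition's GO id, so the
    derived ``<condition> rcv`` set equals the planted signature set.
    """
    conditions = list(truth.signature_genes)
    annotations: dict[str, set[str]] = {}
    pairs = []
    for cond in conditions:
        go_id = condition_go_id(cond, conditions)
        pairs.append((cond, go_id, "auto"))
        for gene in sorted(truth.signature_genes[cond]):
            annotations.setdefault(gene, set()).add(go_id)
    for i in range(n_distractors):
        annotations.setdefault(f"g_bg_{i:04d}", set()).add("GO:8000001")
    return annotations, CombinedMapping(pairs=pairs)


def annotations_tsv(annotations: dict[str, set[str]]) -> str:
    lines = [
        f"{gene}\t{go}"
        for gene in sorted(annotations)
        for go in sorted(annotations[gene])
    ]
    return "\n".join(lines) + "\n" if lines else ""


def expression_tsv(m: ExpressionMatrix) -> str:
    return m.data.to_csv(sep="\t", index_label="gene", float_format="%.6f")
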