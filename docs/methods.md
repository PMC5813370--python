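# Methods

## Problem

Gene-set enrichment tools need sets of Gene Ontology (GO) classes that
group genes in biologically meaningful ways. Many useful groupings —
"all processes involving a cannabinoid", "anything that is part of, occurs
in, or develops into a T cell" — cut across the GO's subclass hierarchy
and cannot be read off the graph structure. They can, however, be written
as description-logic class expressions over the richly axiomatised GO
(with its ChEBI/CL/Uberon imports) and answered by an OWL reasoner: the
answer to a query expression is the set of named classes equivalent to or
subsumed by it. `gogroups` implements this end to end: an OWL 2 EL
reasoner, a vocabulary-to-GO mapping pipeline driven by a TSV of query
specifications, and rank-based over-representation analysis using the
resulting gene sets.

## EL reasoning

Queries are restricted to the OWL 2 EL profile (conjunction and
existential restriction only; no disjunction, negation, universal
restriction or inverses), for which classification is polynomial.

**Normalization.** Every axiom is decomposed into four normal forms over
named classes — A ⊑ B; A₁ ⊓ A₂ ⊑ B; A ⊑ ∃R.B; ∃R.A ⊑ B — introducing
fresh names with the reserved prefix `X:` (numbered in input order, so
identical inputs yield identical outputs). EquivalentClasses axioms become
pairwise mutual subsumptions; a transitive property R is compiled to the
chain R ∘ R ⊑ R so the rule engine needs a single chain rule. The
transformation is a conservative extension: entailments over the original
signature are preserved, which the test suite verifies against a
brute-force oracle on small random ontologies.

**Saturation.** The reasoner computes the least fixpoint of the standard
EL completion rules (initialisation C ⊑ C; the four normal-form rules;
property-hierarchy propagation of role links; binary chain composition;
reflexive-property self-links) with a worklist and indexes keyed on class
and (property, class) — the architecture ELK-class reasoners use. The
property hierarchy is closed reflexively-transitively up front, and every
inserted role link is expanded over its super-properties at insertion
time, which subsumes the hierarchy rule. Reflexive self-links are
materialised for every declared class rather than lazily; at the scales
this package targets the cost is irrelevant, and it keeps the correctness
argument simple. This is the package's hot spot if it is ever pointed at a
full GO release.

**Oracle.** `naive_closure` recomputes the identical fixpoint by repeated
full passes over all rules with plain sets — no worklist, no indexing. It
exists only as an independent correctness oracle; the suite checks exact
equality of subsumptions and links on hundreds of seeded random ontologies
covering every axiom kind, plus chains, transitivity and reflexivity.

**Queries.** A DL query adds a fresh class Q with Q ≡ expression,
re-normalizes, saturates, and reads off equivalents (mutual subsumption
with Q) and descendants (strict subsumption). Results are filtered to a
configurable namespace prefix set (default `{"GO"}`) and to non-obsolete
classes; obsolete answers are retained in a side list because the mapping
pipeline reports them in its "is obsolete" column. Batched execution
(`query_all`, used by the mapping pipeline) adds all query classes before
a single saturation; per-query answers cannot cross-contaminate because
each fresh query class is constrained only by its own equivalence axiom,
which the suite checks by comparing batched against one-by-one runs.

## Grouping properties: emulating disjunction in EL

EL lacks OR, so disjunctive groupings are emulated with a *grouping
property*: a high-level object property g with one subproperty per
disjunct, plus, for composed routes such as "regulates a process in which
X participates", an intermediate property defined by a property chain
(`regulates ∘ has_participant ⊑ regulates_o_has_participant ⊑ g`).
A query ∃g.F then returns the union of the route-wise answers, which the
suite verifies route by route. Marking g reflexive additionally makes F
and its subclasses answer the query (every class links to itself), which
expresses patterns like "a synapse OR part of a synapse OR ...".

Grouping specs are data, not code: presets ship as packaged JSON
(participation-or-regulated-participation; occurs-in-or-participation; a
reflexive structure pattern; a four-route cell pattern), users load their
own from the same JSON shape, and each spec carries a one-slot description
template (`{filler}`) used to generate human-readable query descriptions.
The template placeholder may repeat — a disjunctive description naturally
mentions the filler once per disjunct. `regulates` is given
`positively_regulates`/`negatively_regulates` subproperties in the
presets, mirroring the GO relation hierarchy so direction-specific
regulation classes are captured by the chain route.

## Mapping pipeline

The mapping table is a TSV `term → grouping property → single filler
class`. All queries run over one shared saturation; per-term results are
compared with an optional manual mapping into a table with columns
`GO name, GO ID, manual, auto, checked, black listed, is obsolete`.
Review is file-based: a blacklist TSV of (term, GO id) pairs removes
rejected classes. The combined output keeps every automated,
non-blacklisted, non-obsolete pair, optionally retaining manual-only pairs
with distinct provenance; manual ids absent from the ontology are flagged
obsolete rather than treated as errors. Terms with empty automated results
are reported in `unmapped.tsv`. Truly disjunctive terms can union the
results of several EL queries (`union_mappings`).

## Over-representation analysis

**Gene sets.** For each mapped term, the gene set is the union of genes
*directly* annotated to the term's mapped GO ids (no propagation over the
ontology — the query's answer set already contains all descendant
classes). Names carry the ` rcv` suffix. Tissue signatures (` ts` suffix)
come from the Gini coefficient of each gene's per-condition mean
expression profile, G = Σᵢⱼ|vᵢ−vⱼ|/(2n²v̄) (population form, bounded by
(n−1)/n): genes with G strictly above 0.7 are assigned to their argmax
condition (ties to the first condition, with a warning), and per-dataset
signatures merge by union.

**Scoring.** For each condition, genes are ranked by mean expression
across that condition's samples (mid-ranks for ties, rank 1 = highest).
Each gene set is scored against the background with a two-sided Wilcoxon
rank-sum test restricted to the universe. Following the source
vocabulary's convention the universe defaults to the union of genes over
the whole gene-set collection, not all measured genes (configurable by
passing an explicit universe). The exact null distribution is used when
the smaller group has ≤ 8 members, there are no ties, and the restricted
universe has ≤ 500 genes (beyond that the exact enumeration buys nothing
over the approximation and costs combinatorially); otherwise a
tie-corrected normal approximation with continuity correction. The
enrichment score is −log10 p; the signed Z is the tie-corrected rank-sum
deviate, positive when the set sits at high expression. The choice of a
two-sided test with signed Z reflects that both over- and
under-representation are of interest; one-sided p-values can be recovered
from (z, p). Degenerate input (all expression values equal) yields
p = 1, score = 0, z = 0.

**Presentation.** The matrix of Z-scores is ordered by agglomerative
hierarchical clustering on euclidean distance (average linkage by
default; single/complete selectable), with missing cells imputed as 0 —
neutral under the null — for clustering only. Ordered Z and score
matrices are written as fixed-format TSVs; an optional heat map is
cosmetic and untested. Jaccard indices compare gene sets pairwise.

## Synthetic data

The generators stand in for the real resources (GO releases, GTEx/array
atlases, NCBI annotations), which are deliberately out of scope.

* `toy_cannabinoid_ontology` reproduces the worked mapping example: five
  GO classes answer ∃participant_OR_reg_participant.cannabinoid — four by
  participation (one through a subclass filler, endocannabinoid ⊑
  cannabinoid) and the regulation class only through the chain. A manual
  mapping of two of the five makes the automated-minus-manual difference
  exactly three.
* `toy_pattern_ontology` gives each route of the cell pattern and the
  reflexive structure pattern exactly one witness class, so deleting one
  route axiom removes exactly one answer.
* `random_el_ontology(seed, n_classes, n_props, density)` samples every
  axiom kind (≈ density·n_classes class axioms, default density 2.0, plus
  a few property axioms and random transitive/reflexive flags). Sizes stay
  small (≤ 25 classes) so the unindexed oracle remains tractable.
* `synthetic_expression` draws log-normal baseline values (log-mean 1,
  log-sd 1 — RPKM-like positivity and right skew) for a default of 300
  genes, 5 conditions × 3 samples, and shifts each planted signature gene
  up by `effect_size` (default 2) baseline standard deviations in its own
  condition. `synthetic_annotations` annotates signature genes to one toy
  GO id per condition so the derived ` rcv` set equals the planted set.

What the fixtures do *not* emulate: the scale and tangledness of a real
GO release (tens of thousands of classes, deep existential nesting),
correlated gene-gene expression structure, batch effects, or dropout.
Passing tests therefore demonstrate algorithmic correctness and
statistical calibration at desk scale, not performance or robustness on
production transcriptomes.

## Numerical and design choices

* Fresh normalization names: reserved prefix `X:`, sequential in input
  order — reproducible saturations, diffable outputs.
* CURIE handling: IRIs and underscore forms normalize to `PREFIX:local`,
  but only when the local part is numeric (OBO style); relation names
  like `has_participant` are left intact.
* Obographs export cannot carry transitive/reflexive flags, so the
  functional-syntax dump is the lossless serialization; loading an
  ontology through the CLI re-applies the preset grouping axioms with
  OR-combined flags to avoid spurious conflicts.
* Inverse-property and disjointness axioms are outside the EL subset used
  here; parsers reject non-EL class constructs outright.
* Conjuncts are ordered lexicographically before axiom deduplication.
* All randomness is seed-parameterised; every generator regenerates
  byte-identical output for the same seed.

## Known limitations

* The reasoner materialises reflexive links for all classes and is tuned
  for fixture-to-moderate scale, not a full GO-with-imports release.
* Only binary property chains are supported (longer chains can be folded
  by the caller).
* GAF parsing keeps all evidence codes by default (an IEA-exclusion flag
  is the obvious extension) and uses only gene symbol + GO id columns.
* The heat-map rendering is cosmetic and intentionally untested.
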