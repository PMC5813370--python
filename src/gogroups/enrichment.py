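"""Gene sets, Gini tissue signatures, Wilcoxon enrichment, clustering.

The statistical core: for each gene set and each condition (tissue or
cell type), genes are ranked by the condition's mean expression and the
set's ranks are compared with the background by a two-sided Wilcoxon
rank-sum (Mann–Whitney) test.  The enrichment score is −log10(p); the
signed Z-score (tie-corrected rank-sum normal deviate) gives direction —
positive means the set sits at high expression.  Per the source
vocabulary's convention, the universe defaults to the union of genes over
the whole gene-set collection rather than all measured genes.

Tissue signatures come from the Gini coefficient of each gene's
per-condition mean expression profile: genes with Gini > 0.7 (strict) are
assigned to their argmax condition, and per-dataset signatures are merged
non-redundantly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

logger = logging.getLogger("gogroups")

#: largest total sample size for which the exact Wilcoxon null is enumerated
EXACT_MAX_N = 500


class EnrichmentError(Exception):
    pass


class ScoringError(EnrichmentError):
    """A gene set / condition pair violates the scoring preconditions."""


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass
class ExpressionMatrix:
    """Genes × samples of non-negative RPKM-like values.

    ``sample_conditions`` maps sample → condition; identity when samples
    are already per-condition aggregates.
    """

    data: pd.DataFrame  # index = genes, columns = samples
    sample_conditions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise EnrichmentError("duplicate gene ids in expression matrix")
        if (self.data.to_numpy() < 0).any():
            raise EnrichmentError("negative expression values")
        if not self.sample_conditions:
            self.sample_conditions = {c: c for c in self.data.columns}

    @property
    def genes(self) -> list:
        return list(self.data.index)

    @property
    def conditions(self) -> list:
        seen = []
        for s in self.data.columns:
            c = self.sample_conditions[s]
            if c not in seen:
                seen.append(c)
        return seen

    def condition_means(self) -> pd.DataFrame:
        """Per-condition mean across samples (genes × conditions)."""
        cond = pd.Series({s: self.sample_conditions[s] for s in self.data.columns})
        means = self.data.T.groupby(cond).mean().T
        return means[self.conditions]


@dataclass
class GeneVector:
    """Genes ranked by a condition's mean expression (rank 1 = highest)."""

    condition: str
    means: pd.Series          # index = genes
    ranks: pd.Series          # mid-ranks, 1 = highest mean

    @property
    def genes(self) -> set:
        return set(self.means.index)


@dataclass
class EnrichmentCell:
    set_name: str
    condition: str
    p_value: float
    score: float
    z: float


# ---------------------------------------------------------------------------
# Annotations and gene sets
# ---------------------------------------------------------------------------


def parse_annotations(text: str) -> dict[str, set[str]]:
    """Parse GAF 2.x or two-column ``gene<TAB>go_id`` TSV into gene → GO ids.

    Only direct annotations are kept; GAF lines with a NOT qualifier are
    dropped; malformed lines are skipped with a logged count.
    """
    annotations: dict[str, set[str]] = {}
    skipped = 0
    for line in text.splitlines():
        if not line.strip() or line.startswith("!"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 15:  # GAF
            qualifier = parts[3]
            if "NOT" in qualifier.split("|"):
                continue
            gene, go_id = parts[2] or parts[1], parts[4]
            if not gene or not go_id:
                skipped += 1
                continue
        elif len(parts) == 2:
            gene, go_id = parts
            if not gene or not go_id:
                skipped += 1
                continue
        else:
            skipped += 1
            continue
        annotations.setdefault(gene, set()).add(go_id)
    if skipped:
        logger.warning("parse_annotations: skipped %d malformed lines", skipped)
    if not annotations:
        raise EnrichmentError("no usable annotation lines")
    return annotations


def build_gene_sets(annotations: dict[str, set[str]], combined) -> list[GeneSet]:
    """One gene set per mapped vocabulary term: union of genes directly
    annotated to the term's mapped GO ids; suffix ``ʼ rcvʼ``; empty sets
    dropped with a warning.  No propagation over the ontology — the mapped
    id set already contains all descendants by construction of the query.
    """
    by_go: dict[str, set[str]] = {}
    for gene, gos in annotations.items():
        for go in gos:
            by_go.setdefault(go, set()).add(gene)
    sets = []
    for term in combined.terms:
        genes: set[str] = set()
        for go in combined.ids_for(term):
            genes |= by_go.get(go, set())
        if not genes:
            logger.warning("term %r has no annotated genes; dropping set", term)
            continue
        sets.append(GeneSet(name=f"{term} rcv", genes=frozenset(genes)))
    return sets


# ---------------------------------------------------------------------------
# Gini tissue signatures
# ---------------------------------------------------------------------------


def gini_coefficient(v) -> float:
    """Population Gini index G = Σ_i Σ_j |v_i − v_j| / (2 n² v̄).

    Bounded by (n−1)/n; 0 for a uniform vector.  All-zero input is an
    error (the caller must exclude unexpressed genes).
    """
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise EnrichmentError("gini_coefficient needs a 1-d vector of length >= 2")
    if (arr < 0).any():
        raise EnrichmentError("gini_coefficient requires non-negative values")
    total = arr.sum()
    if total == 0:
        raise EnrichmentError("gini_coefficient undefined for all-zero vector")
    n = arr.size
    sorted_arr = np.sort(arr)
    # pairwise-sum identity: Σ_i Σ_j |vi−vj| = 2 Σ_i (2i−n−1) v_(i)
    weighted = (2 * np.arange(1, n + 1) - n - 1) @ sorted_arr
    return float(weighted / (n * total))


def select_tissue_enriched(
    m: ExpressionMatrix, threshold: float = 0.7
) -> dict[str, set[str]]:
    """Genes with Gini of per-condition means strictly above ``threshold``,
    assigned to their argmax condition (ties → first condition, warned)."""
    means = m.condition_means()
    out: dict[str, set[str]] = {c: set() for c in means.columns}
    values = means.to_numpy()
    for i, gene in enumerate(means.index):
        row = values[i]
        if row.sum() == 0:
            continue
        if gini_coefficient(row) <= threshold:
            continue
        top = row.max()
        winners = np.flatnonzero(row == top)
        if winners.size > 1:
            logger.warning(
                "gene %s ties on argmax across %d conditions; using first", gene, winners.size
            )
        out[means.columns[winners[0]]].add(gene)
    return out


def merge_signatures(per_dataset: list[dict[str, set[str]]]) -> dict[str, GeneSet]:
    """Non-redundant per-condition union across datasets; names ``<cond> ts``."""
    merged: dict[str, set[str]] = {}
    for dataset in per_dataset:
        for cond, genes in dataset.items():
            merged.setdefault(cond, set()).update(genes)
    return {
        cond: GeneSet(name=f"{cond} ts", genes=frozenset(genes))
        for cond, genes in merged.items()
    }


# ---------------------------------------------------------------------------
# Rank vectors and Wilcoxon scoring
# ---------------------------------------------------------------------------


def build_gene_vector(m: ExpressionMatrix, condition: str) -> GeneVector:
    """Per-gene mean over the condition's samples, mid-ranked (1 = highest)."""
    samples = [s for s in m.data.columns if m.sample_conditions[s] == condition]
    if not samples:
        raise EnrichmentError(f"unknown condition {condition!r}")
    means = m.data[samples].mean(axis=1)
    ranks = pd.Series(
        stats.rankdata(-means.to_numpy(), method="average"), index=means.index
    )
    return GeneVector(condition=condition, means=means, ranks=ranks)


def _exact_two_sided_p(in_values: np.ndarray, out_values: np.ndarray) -> float:
    res = stats.mannwhitneyu(
        in_values, out_values, alternative="two-sided", method="exact"
    )
    return float(res.pvalue)


def enrichment_score(
    gene_set: GeneSet, vec: GeneVector, universe: set[str]
) -> EnrichmentCell:
    """Two-sided Wilcoxon rank-sum of in-set vs out-of-set expression.

    The test runs on the universe restricted to the vector's genes; the
    exact null is enumerated when the smaller group has ≤ 8 members, there
    are no ties and the restricted universe is small (≤ ``EXACT_MAX_N``);
    otherwise the tie-corrected normal approximation with continuity
    correction is used.  z > 0 means the set's genes sit at higher
    expression than the background.
    """
    domain = sorted(universe & vec.genes)
    in_genes = sorted(gene_set.genes & set(domain))
    out_genes = [g for g in domain if g not in gene_set.genes]
    if not in_genes or not out_genes:
        raise ScoringError(
            f"set {gene_set.name!r} in condition {vec.condition!r}: "
            f"needs ≥1 in-set and ≥1 background gene within the universe"
        )
    values = vec.means.loc[domain].to_numpy(dtype=float)
    # rank within the restricted domain, high expression = high rank value
    ranks = stats.rankdata(values, method="average")
    in_mask = np.asarray([g in gene_set.genes for g in domain])
    n1, n2 = int(in_mask.sum()), int((~in_mask).sum())
    n = n1 + n2

    w = float(ranks[in_mask].sum())
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))) if n > 1 else 0.0
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)

    if var_w <= 0:  # all values identical: no rank separation
        return EnrichmentCell(gene_set.name, vec.condition, p_value=1.0, score=0.0, z=0.0)

    z = (w - mean_w) / math.sqrt(var_w)
    has_ties = bool((tie_counts > 1).any())
    if min(n1, n2) <= 8 and not has_ties and n <= EXACT_MAX_N:
        p = _exact_two_sided_p(values[in_mask], values[~in_mask])
    else:
        # continuity-corrected two-sided normal p
        z_cc = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
        p = float(2 * stats.norm.sf(max(z_cc, 0.0)))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return EnrichmentCell(
        gene_set.name, vec.condition, p_value=p, score=-math.log10(p), z=z
    )


def enrichment_matrix(
    collection: list[GeneSet],
    vectors: list[GeneVector],
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Score every (set, condition) pair; cells failing preconditions are
    missing (NaN) with a warning.  Returns a DataFrame of EnrichmentCell
    objects (or NaN), rows = set names, columns = conditions.

    The default universe is the union of genes over the collection.
    """
    if universe is None:
        universe = set().union(*(s.genes for s in collection)) if collection else set()
    cells = {}
    for gene_set in collection:
        row = {}
        for vec in vectors:
            try:
                row[vec.condition] = enrichment_score(gene_set, vec, universe)
            except ScoringError as exc:
                logger.warning("missing cell: %s", exc)
                row[vec.condition] = np.nan
        cells[gene_set.name] = row
    return pd.DataFrame.from_dict(cells, orient="index")[
        [v.condition for v in vectors]
    ]


def matrix_values(cells: pd.DataFrame, attr: str) -> pd.DataFrame:
    """Extract a numeric matrix (``z``, ``score`` or ``p_value``) from a
    matrix of EnrichmentCells; missing cells become NaN."""
    return cells.map(lambda c: getattr(c, attr) if isinstance(c, EnrichmentCell) else np.nan)


# ---------------------------------------------------------------------------
# Jaccard and clustering
# ---------------------------------------------------------------------------


def jaccard_index(a: GeneSet, b: GeneSet) -> float:
    """|A∩B| / |A∪B|; error when both sets are empty."""
    union = a.genes | b.genes
    if not union:
        raise EnrichmentError("jaccard_index undefined for two empty sets")
    return len(a.genes & b.genes) / len(union)


def cluster_order(z: pd.DataFrame, axis: str = "both", method: str = "average"):
    """Leaf order(s) from hierarchical clustering on euclidean distance.

    ``axis`` is ``rows``, ``columns`` or ``both``; missing values are
    imputed as 0 (neutral under the null) with a warning.  Returns a
    permutation array, or a (rows, columns) tuple for ``both``.
    """
    mat = z.to_numpy(dtype=float)
    if mat.size == 0:
        raise EnrichmentError("cannot cluster an empty matrix")
    if np.isnan(mat).any():
        logger.warning("cluster_order: imputing missing Z values as 0")
        mat = np.nan_to_num(mat, nan=0.0)

    def order(m: np.ndarray) -> np.ndarray:
        if m.shape[0] < 2:
            return np.arange(m.shape[0])
        return leaves_list(linkage(m, method=method, metric="euclidean"))

    if axis == "rows":
        return order(mat)
    if axis == "columns":
        return order(mat.T)
    if axis == "both":
        return order(mat), order(mat.T)
    raise ValueError(f"axis must be rows|columns|both, got {axis!r}")


def write_matrix(
    cells: pd.DataFrame,
    row_order,
    col_order,
    path,
    heatmap: bool = False,
) -> None:
    """Write ordered Z and score matrices as fixed-format TSVs.

    ``path`` is a stem: writes ``<stem>.z.tsv`` and ``<stem>.score.tsv``
    (6 decimal places, bit-exact on read-back); with ``heatmap=True`` also
    a cosmetic ``<stem>.png``.
    """
    if cells.size == 0:
        raise EnrichmentError("cannot write an empty matrix")
    path = Path(path)
    zmat = matrix_values(cells, "z").iloc[row_order, col_order]
    smat = matrix_values(cells, "score").iloc[row_order, col_order]
    zmat.to_csv(path.with_suffix(".z.tsv"), sep="\t", float_format="%.6f")
    smat.to_csv(path.with_suffix(".score.tsv"), sep="\t", float_format="%.6f")
    if heatmap:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(max(4, zmat.shape[1] * 0.5), max(3, zmat.shape[0] * 0.4)))
        im = ax.imshow(zmat.to_numpy(), cmap="RdBu_r", aspect="auto")
        ax.set_xticks(range(zmat.shape[1]), zmat.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(zmat.shape[0]), zmat.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="Z")
        fig.tight_layout()
        fig.savefig(path.with_suffix(".png"), dpi=120)
        plt.close(fig)


def write_gmt(sets: list[GeneSet], path, descriptions: dict | None = None) -> None:
    """GMT-style TSV: ``name<TAB>description<TAB>gene...`` per line."""
    descriptions = descriptions or {}
    lines = []
    for s in sorted(sets, key=lambda s: s.name):
        genes = "\t".join(sorted(s.genes))
        lines.append(f"{s.name}\t{descriptions.get(s.name, '')}\t{genes}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(text: str) -> list[GeneSet]:
    sets = []
    for line in text.splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise EnrichmentError(f"malformed GMT line: {line[:80]!r}")
        sets.append(GeneSet(name=parts[0], genes=frozenset(parts[2:])))
    return sets
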