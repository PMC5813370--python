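"""TSV-driven mapping workflow: vocabulary term → GO term set.

Each line of the mapping table maps one vocabulary term to an EL mapping
query ``grouping_property some filler``.  Queries run over one shared
saturation, automated results are compared row-by-row against a manual
mapping, a blacklist removes rejected pairs, and the surviving pairs form
a combined mapping table that downstream gene-set construction consumes.

The curator review loop is reduced to file inputs: a blacklist TSV of
(term, go_id) pairs stands in for per-class rejection, and the emitted
per-term results TSV (columns ``GO name, GO ID, manual, auto, checked,
black listed, is obsolete``) is the reviewable artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .grouping import GroupingSpec, describe_query
from .ontology import ClassRef, Named, Ontology, PropertyRef, Some
from .reasoner import QueryResult, query_all

logger = logging.getLogger("gogroups")

RESULT_COLUMNS = (
    "GO name", "GO ID", "manual", "auto", "checked", "black listed", "is obsolete",
)


class MappingError(Exception):
    pass


@dataclass(frozen=True)
class MappingRecord:
    """One vocabulary term mapped to a single-filler EL query."""

    term: str
    grouping_property: str
    filler: str
    description: str = ""


@dataclass
class MappingResultRow:
    go_id: str
    go_name: str
    manual: int
    auto: int
    checked: int = 0
    blacklisted: int = 0
    is_obsolete: int = 0


@dataclass
class MappingResult:
    """Per-term comparison of manual vs automated GO term sets."""

    term: str
    rows: list = field(default_factory=list)  # of MappingResultRow, sorted by go_id

    @property
    def auto_ids(self) -> set:
        return {r.go_id for r in self.rows if r.auto}

    @property
    def manual_ids(self) -> set:
        return {r.go_id for r in self.rows if r.manual}

    @property
    def auto_only_ids(self) -> set:
        return {r.go_id for r in self.rows if r.auto and not r.manual}

    @property
    def manual_only_ids(self) -> set:
        return {r.go_id for r in self.rows if r.manual and not r.auto}


@dataclass
class CombinedMapping:
    """Reviewed (term, go_id) pairs with provenance ``auto`` or
    ``manual-retained``; never contains blacklisted or obsolete entries."""

    pairs: list = field(default_factory=list)  # of (term, go_id, provenance)

    def ids_for(self, term: str) -> set:
        return {g for t, g, _ in self.pairs if t == term}

    @property
    def terms(self) -> list:
        return sorted({t for t, _, _ in self.pairs})


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def parse_mapping_table(
    tsv: str, specs: dict[str, GroupingSpec] | None = None, ont: Ontology | None = None
) -> list[MappingRecord]:
    """Parse the ``term<TAB>property<TAB>filler`` mapping table.

    Duplicate terms, wrong column counts and (when an ontology is given)
    unresolvable filler ids are errors naming the offending line.  When a
    term's property names a known :class:`GroupingSpec`, its human-readable
    description is generated from the spec template.
    """
    specs = specs or {}
    records: list[MappingRecord] = []
    seen: set[str] = set()
    lines = tsv.splitlines()
    if not lines:
        return records
    start = 1 if lines[0].lower().startswith("term") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise MappingError(f"line {lineno}: expected 3 columns, got {len(parts)}")
        term, prop, filler = (p.strip() for p in parts)
        if term in seen:
            raise MappingError(f"line {lineno}: duplicate term {term!r}")
        seen.add(term)
        if ont is not None and filler not in ont.classes:
            raise MappingError(f"line {lineno}: unresolvable filler id {filler!r}")
        description = ""
        if prop in specs:
            filler_ref = (
                ont.classes[filler] if ont is not None and filler in ont.classes
                else ClassRef(filler)
            )
            description = describe_query(specs[prop], filler_ref)
        records.append(MappingRecord(term, prop, filler, description))
    return records


def parse_pair_table(tsv: str) -> dict[str, set[str]]:
    """Parse a two-column ``term<TAB>go_id`` table (manual or blacklist)."""
    out: dict[str, set[str]] = {}
    lines = tsv.splitlines()
    start = 1 if lines and lines[0].lower().startswith("term") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise MappingError(f"line {lineno}: expected 2 columns, got {len(parts)}")
        term, go_id = (p.strip() for p in parts)
        out.setdefault(term, set()).add(go_id)
    return out


# ---------------------------------------------------------------------------
# Query execution
# ---------------------------------------------------------------------------


def run_mappings(
    ont: Ontology,
    records: list[MappingRecord],
    result_prefixes: set[str] | None = None,
    saturator=None,
) -> dict[str, QueryResult]:
    """Run every mapping query over one shared saturation.

    The ontology must already include the grouping-property axioms.  All
    query classes are added in one batch so classification happens once.
    """
    exprs = {}
    for rec in records:
        prop = ont.properties.get(rec.grouping_property)
        if prop is None:
            prop = PropertyRef(rec.grouping_property)
        filler = ont.classes.get(rec.filler)
        if filler is None:
            raise MappingError(f"term {rec.term!r}: filler {rec.filler} not in ontology")
        exprs[rec.term] = Some(prop, Named(filler))
    kwargs = {"saturator": saturator} if saturator is not None else {}
    return query_all(ont, exprs, result_prefixes, **kwargs)


def union_mappings(results: list[QueryResult]) -> set[ClassRef]:
    """Set union of equivalents ∪ descendants across query results.

    Supports vocabulary terms defined as the union of several EL queries
    (the workaround for truly disjunctive terms such as metabolism =
    participation ∪ transport).
    """
    out: set[ClassRef] = set()
    for res in results:
        out |= set(res.equivalents)
        out |= set(res.descendants)
    return out


# ---------------------------------------------------------------------------
# Comparison, blacklist, combined table
# ---------------------------------------------------------------------------


def compare_mappings(
    term: str,
    auto: set[ClassRef],
    manual: set[str],
    blacklist: set[str],
    ont: Ontology,
) -> MappingResult:
    """Build the per-term comparison table of automated vs manual mappings.

    Manual ids absent from the ontology (typically ids obsoleted since the
    manual mapping was made) are flagged obsolete with a warning rather
    than rejected.
    """
    auto_ids = {c.id: c for c in auto}
    rows = []
    for go_id in sorted(auto_ids.keys() | manual):
        ref = ont.classes.get(go_id)
        if ref is None:
            logger.warning(
                "term %r: manual id %s not in ontology; flagging obsolete", term, go_id
            )
            obsolete = 1
            name = ""
        else:
            obsolete = int(ref.obsolete)
            name = ref.label or ""
        rows.append(
            MappingResultRow(
                go_id=go_id,
                go_name=name,
                manual=int(go_id in manual),
                auto=int(go_id in auto_ids),
                blacklisted=int(go_id in blacklist),
                is_obsolete=obsolete,
            )
        )
    return MappingResult(term=term, rows=rows)


def emit_combined_mapping(
    results: list[MappingResult], keep_manual_only: bool = True
) -> CombinedMapping:
    """Combine reviewed per-term tables into the final mapping table.

    Keeps every automated, non-blacklisted, non-obsolete pair; manual-only
    pairs are retained (provenance ``manual-retained``) iff
    ``keep_manual_only``; obsolete ids are always excluded.
    """
    pairs = []
    for res in sorted(results, key=lambda r: r.term):
        for row in sorted(res.rows, key=lambda r: r.go_id):
            if row.blacklisted or row.is_obsolete:
                continue
            if row.auto:
                pairs.append((res.term, row.go_id, "auto"))
            elif row.manual and keep_manual_only:
                pairs.append((res.term, row.go_id, "manual-retained"))
    combined = CombinedMapping(pairs=pairs)
    assert not any(
        row.blacklisted and (res.term, row.go_id) in {(t, g) for t, g, _ in pairs}
        for res in results for row in res.rows
    )
    return combined


# ---------------------------------------------------------------------------
# File outputs
# ---------------------------------------------------------------------------


def write_result_tsv(result: MappingResult, path: Path) -> None:
    lines = ["\t".join(RESULT_COLUMNS)]
    for row in result.rows:
        lines.append(
            "\t".join(
                [
                    row.go_name,
                    row.go_id,
                    str(row.manual),
                    str(row.auto),
                    str(row.checked),
                    str(row.blacklisted),
                    str(row.is_obsolete),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_pipeline_outputs(
    results: list[MappingResult],
    combined: CombinedMapping,
    unmapped: list[str],
    outdir: Path,
) -> None:
    """Emit per-term tables, combined mapping, summary and unmapped list."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for res in results:
        safe = res.term.replace("/", "_").replace(" ", "_")
        write_result_tsv(res, outdir / f"{safe}.tsv")
    lines = ["term\tgo_id\tprovenance"]
    lines += [f"{t}\t{g}\t{p}" for t, g, p in combined.pairs]
    (outdir / "combined_mapping.tsv").write_text("\n".join(lines) + "\n")
    summary = ["term\tn_auto\tn_manual\tn_auto_only\tn_manual_only"]
    for res in sorted(results, key=lambda r: r.term):
        summary.append(
            f"{res.term}\t{len(res.auto_ids)}\t{len(res.manual_ids)}"
            f"\t{len(res.auto_only_ids)}\t{len(res.manual_only_ids)}"
        )
    (outdir / "summary.tsv").write_text("\n".join(summary) + "\n")
    (outdir / "unmapped.tsv").write_text(
        "term\n" + "".join(f"{t}\n" for t in sorted(unmapped))
    )


def run_pipeline(
    ont: Ontology,
    records: list[MappingRecord],
    manual: dict[str, set[str]] | None = None,
    blacklist: dict[str, set[str]] | None = None,
    result_prefixes: set[str] | None = None,
    keep_manual_only: bool = True,
) -> tuple[list[MappingResult], CombinedMapping, list[str]]:
    """End-to-end mapping run: queries → comparison → combined table.

    Returns (per-term results, combined mapping, unmapped term names);
    a term is unmapped when its automated result is empty.
    """
    manual = manual or {}
    blacklist = blacklist or {}
    query_results = run_mappings(ont, records, result_prefixes)
    results, unmapped = [], []
    for rec in records:
        qres = query_results[rec.term]
        auto = union_mappings([qres])
        if not auto:
            unmapped.append(rec.term)
        results.append(
            compare_mappings(
                rec.term,
                auto,
                manual.get(rec.term, set()),
                blacklist.get(rec.term, set()),
                ont,
            )
        )
    combined = emit_combined_mapping(results, keep_manual_only=keep_manual_only)
    return results, combined, unmapped
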