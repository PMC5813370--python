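"""Gene sets, Gini signatures, Wilcoxon scoring, Jaccard and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gogroups import (
    CombinedMapping,
    EnrichmentError,
    ExpressionMatrix,
    GeneSet,
    ScoringError,
    build_gene_sets,
    build_gene_vector,
    cluster_order,
    enrichment_matrix,
    enrichment_score,
    gini_coefficient,
    jaccard_index,
    matrix_values,
    merge_signatures,
    parse_annotations,
    read_gmt,
    select_tissue_enriched,
    write_gmt,
    write_matrix,
)


def _matrix(values: dict, samples=None) -> ExpressionMatrix:
    data = pd.DataFrame(values).T
    if samples:
        data.columns = list(samples)
        return ExpressionMatrix(data=data, sample_conditions=dict(samples.items()) if isinstance(samples, dict) else {})
    data.columns = [f"c{i}" for i in range(data.shape[1])]
    return ExpressionMatrix(data=data)


class TestParseAnnotations:
    def test_two_column_tsv(self):
        out = parse_annotations("g1\tGO:1\ng1\tGO:2\ng2\tGO:1\n")
        assert out == {"g1": {"GO:1", "GO:2"}, "g2": {"GO:1"}}

    def test_gaf_not_qualifier_dropped(self):
        cols = [""] * 17
        cols[1], cols[2], cols[4] = "P1", "g1", "GO:1"
        keep = "\t".join(cols)
        cols2 = list(cols)
        cols2[3] = "NOT|involved_in"
        drop = "\t".join(cols2)
        out = parse_annotations("!gaf-version: 2.2\n" + keep + "\n" + drop + "\n")
        assert out == {"g1": {"GO:1"}}

    def test_duplicates_collapse(self):
        assert parse_annotations("g\tGO:1\ng\tGO:1\n") == {"g": {"GO:1"}}

    def test_zero_usable_lines_is_error(self):
        with pytest.raises(EnrichmentError):
            parse_annotations("malformed\n")


class TestBuildGeneSets:
    def test_union_of_direct_annotations(self):
        annotations = {"g1": {"GO:A1"}, "g2": {"GO:B1"}, "g3": {"GO:C1"}}
        combined = CombinedMapping(
            pairs=[("term", "GO:A1", "auto"), ("term", "GO:B1", "auto")]
        )
        sets = build_gene_sets(annotations, combined)
        assert sets == [GeneSet("term rcv", frozenset({"g1", "g2"}))]

    def test_descendant_annotation_outside_mapped_set_excluded(self):
        annotations = {"g": {"GO:child"}}
        combined = CombinedMapping(pairs=[("term", "GO:parent", "auto")])
        assert build_gene_sets(annotations, combined) == []

    def test_empty_set_dropped_with_warning(self, caplog):
        combined = CombinedMapping(pairs=[("term", "GO:none", "auto")])
        with caplog.at_level("WARNING", logger="gogroups"):
            sets = build_gene_sets({"g": {"GO:other"}}, combined)
        assert sets == [] and any("no annotated genes" in r.message for r in caplog.records)


class TestGini:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ((1, 1, 1, 1), 0.0),
            ((1, 0, 0, 0, 0), 0.8),
            ((2, 1, 1, 0), 0.375),
        ],
    )
    def test_worked_values(self, vec, expected):
        assert gini_coefficient(vec) == pytest.approx(expected)

    def test_matches_pairwise_definition(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.gamma(2.0, 1.0, size=rng.integers(2, 12))
            n, mean = v.size, v.mean()
            brute = sum(abs(a - b) for a in v for b in v) / (2 * n * n * mean)
            assert gini_coefficient(v) == pytest.approx(brute)

    def test_scale_invariance_and_bound(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            v = rng.gamma(1.0, 1.0, size=8) + 1e-9
            g = gini_coefficient(v)
            assert gini_coefficient(3.7 * v) == pytest.approx(g)
            assert 0 <= g <= 7 / 8

    def test_all_zero_is_error(self):
        with pytest.raises(EnrichmentError):
            gini_coefficient([0, 0, 0])

    @settings(derandomize=True, max_examples=50)
    @given(
        v=st.lists(
            st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=30,
        ).filter(lambda v: sum(v) > 0),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_property_scale_invariant_and_bounded(self, v, scale):
        g = gini_coefficient(v)
        n = len(v)
        assert 0.0 <= g <= (n - 1) / n + 1e-12
        assert gini_coefficient([scale * x for x in v]) == pytest.approx(g, abs=1e-9)


class TestSelectTissueEnriched:
    def test_one_hot_gene_assigned_to_its_tissue(self):
        m = _matrix({"hot": [0, 0, 5, 0, 0], "flat": [1, 1, 1, 1, 1]})
        out = select_tissue_enriched(m)
        assert out["c2"] == {"hot"}
        assert all("flat" not in genes for genes in out.values())

    def test_threshold_is_strict(self):
        # gini of a one-hot length-4 vector is exactly 0.75 > 0.7;
        # construct a gene with gini exactly 0.7 via threshold override
        m = _matrix({"hot": [0, 0, 5, 0]})
        assert select_tissue_enriched(m, threshold=0.75)["c2"] == set()
        assert select_tissue_enriched(m, threshold=0.7)["c2"] == {"hot"}

    def test_all_zero_gene_skipped(self):
        m = _matrix({"zero": [0, 0, 0, 0], "hot": [9, 0, 0, 0]})
        out = select_tissue_enriched(m)
        assert out["c0"] == {"hot"}

    def test_argmax_tie_takes_first_condition(self, caplog):
        m = _matrix({"twin": [5, 5, 0, 0, 0, 0, 0, 0, 0, 0]})
        with caplog.at_level("WARNING", logger="gogroups"):
            out = select_tissue_enriched(m)
        assert out["c0"] == {"twin"} and out["c1"] == set()
        assert any("ties" in r.message for r in caplog.records)


class TestMergeSignatures:
    def test_union_identity_and_carry_through(self):
        merged = merge_signatures(
            [{"liver": {"a", "b"}}, {"liver": {"b", "c"}, "brain": {"d"}}]
        )
        assert merged["liver"].genes == {"a", "b", "c"}
        assert merged["liver"].name == "liver ts"
        assert merged["brain"].genes == {"d"}


class TestGeneVector:
    def test_mean_over_condition_samples(self):
        data = pd.DataFrame({"s1": [2.0], "s2": [4.0]}, index=["g"])
        m = ExpressionMatrix(data=data, sample_conditions={"s1": "liver", "s2": "liver"})
        vec = build_gene_vector(m, "liver")
        assert vec.means["g"] == 3.0

    def test_rank_one_is_highest_and_ties_midranked(self):
        data = pd.DataFrame({"c": [10.0, 5.0, 5.0, 1.0]}, index=list("abcd"))
        vec = build_gene_vector(ExpressionMatrix(data=data), "c")
        assert vec.ranks["a"] == 1.0
        assert vec.ranks["b"] == vec.ranks["c"] == 2.5
        assert vec.ranks["d"] == 4.0

    def test_unknown_condition_raises(self):
        m = _matrix({"g": [1, 2]})
        with pytest.raises(EnrichmentError):
            build_gene_vector(m, "nope")


def brute_force_two_sided_p(values, in_genes_count):
    """Enumerate every assignment of the in-set positions: the oracle for
    the exact rank-sum p (no ties)."""
    n = len(values)
    ranks = stats.rankdata(values)
    observed = None
    sums = []
    for combo in itertools.combinations(range(n), in_genes_count):
        sums.append(sum(ranks[list(combo)]))
    observed = sum(ranks[: in_genes_count])  # caller puts in-set first
    mean = in_genes_count * (n + 1) / 2
    extreme = sum(1 for s in sums if abs(s - mean) >= abs(observed - mean) - 1e-12)
    return extreme / len(sums)


class TestEnrichmentScore:
    def _vector(self, values, genes):
        data = pd.DataFrame({"c": values}, index=genes)
        return build_gene_vector(ExpressionMatrix(data=data), "c")

    def test_exact_worked_example(self):
        """Top 3 of 6 distinct values: exact two-sided p = 2/20 = 0.1."""
        genes = [f"g{i}" for i in range(1, 7)]
        vec = self._vector([6, 5, 4, 3, 2, 1], genes)
        cell = enrichment_score(GeneSet("top", {"g1", "g2", "g3"}), vec, set(genes))
        assert cell.p_value == pytest.approx(0.1)
        assert cell.score == pytest.approx(1.0)
        assert cell.z > 0
        assert cell.p_value == pytest.approx(
            brute_force_two_sided_p([6, 5, 4, 3, 2, 1], 3)
        )

    def test_all_equal_values_give_null_cell(self):
        genes = list("abcdef")
        vec = self._vector([2.0] * 6, genes)
        cell = enrichment_score(GeneSet("s", {"a", "b"}), vec, set(genes))
        assert (cell.p_value, cell.score, cell.z) == (1.0, 0.0, 0.0)

    def test_complement_flips_z_keeps_p(self):
        genes = [f"g{i}" for i in range(8)]
        values = [8, 7, 6, 5, 4, 3, 2, 1]
        vec = self._vector(values, genes)
        a = enrichment_score(GeneSet("a", set(genes[:3])), vec, set(genes))
        b = enrichment_score(GeneSet("b", set(genes[3:])), vec, set(genes))
        assert a.p_value == pytest.approx(b.p_value)
        assert a.z == pytest.approx(-b.z)

    def test_empty_intersection_raises(self):
        genes = list("abc")
        vec = self._vector([3, 2, 1], genes)
        with pytest.raises(ScoringError):
            enrichment_score(GeneSet("s", {"zz"}), vec, set(genes))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_mannwhitneyu(self, seed):
        """Cross-check p against scipy on random tie-free data, exact and
        asymptotic branches."""
        rng = np.random.default_rng(seed)
        n = 40
        genes = [f"g{i}" for i in range(n)]
        values = rng.permutation(n) + 1.0
        vec = self._vector(values, genes)
        in_genes = set(rng.choice(genes, size=6, replace=False))
        cell = enrichment_score(GeneSet("s", in_genes), vec, set(genes))
        x = [values[genes.index(g)] for g in in_genes]
        y = [values[i] for i, g in enumerate(genes) if g not in in_genes]
        expected = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert cell.p_value == pytest.approx(float(expected.pvalue))

    def test_exact_close_to_normal_approximation(self):
        """Tie-free, small-group inputs: |p_exact − p_normal| < 0.05."""
        from gogroups import enrichment as enr

        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(12, 30))
            genes = [f"g{i}" for i in range(n)]
            values = rng.permutation(n) + 1.0
            vec = self._vector(values, genes)
            k = int(rng.integers(2, 8))
            in_genes = set(rng.choice(genes, size=k, replace=False))
            exact = enrichment_score(GeneSet("s", in_genes), vec, set(genes)).p_value
            old = enr.EXACT_MAX_N
            enr.EXACT_MAX_N = 0  # force the asymptotic branch
            try:
                approx = enrichment_score(GeneSet("s", in_genes), vec, set(genes)).p_value
            finally:
                enr.EXACT_MAX_N = old
            assert abs(exact - approx) < 0.05

    def test_direction_monotone_in_expression(self):
        """Raising in-set expression never decreases z."""
        genes = [f"g{i}" for i in range(12)]
        rng = np.random.default_rng(4)
        base = rng.permutation(12) + 1.0
        in_genes = set(genes[:4])
        z_prev = None
        for bump in (0.0, 5.0, 50.0):
            values = base.copy()
            for i, g in enumerate(genes):
                if g in in_genes:
                    values[i] += bump
            vec = self._vector(values, genes)
            z = enrichment_score(GeneSet("s", in_genes), vec, set(genes)).z
            if z_prev is not None:
                assert z >= z_prev - 1e-12
            z_prev = z


class TestEnrichmentMatrix:
    def test_cross_product_shape(self):
        genes = [f"g{i}" for i in range(10)]
        data = pd.DataFrame(
            np.random.default_rng(0).lognormal(size=(10, 3)),
            index=genes,
            columns=["c1", "c2", "c3"],
        )
        m = ExpressionMatrix(data=data)
        vectors = [build_gene_vector(m, c) for c in m.conditions]
        sets = [GeneSet("a", set(genes[:4])), GeneSet("b", set(genes[4:]))]
        cells = enrichment_matrix(sets, vectors)
        assert cells.shape == (2, 3)

    def test_set_outside_universe_gives_missing_row(self, caplog):
        genes = [f"g{i}" for i in range(6)]
        data = pd.DataFrame({"c": range(6)}, index=genes, dtype=float)
        m = ExpressionMatrix(data=data)
        vectors = [build_gene_vector(m, "c")]
        sets = [GeneSet("in", set(genes[:3])), GeneSet("out", {"other1", "other2"})]
        with caplog.at_level("WARNING", logger="gogroups"):
            cells = enrichment_matrix(sets, vectors, universe=set(genes))
        assert matrix_values(cells, "z").loc["out"].isna().all()
        assert any("missing cell" in r.message for r in caplog.records)

    def test_default_universe_is_collection_union(self):
        genes = [f"g{i}" for i in range(8)]
        data = pd.DataFrame({"c": range(8)}, index=genes, dtype=float)
        m = ExpressionMatrix(data=data)
        vectors = [build_gene_vector(m, "c")]
        sets = [GeneSet("a", set(genes[:2])), GeneSet("b", set(genes[2:4]))]
        cells = enrichment_matrix(sets, vectors)
        explicit = enrichment_matrix(sets, vectors, universe=set(genes[:4]))
        assert (
            matrix_values(cells, "p_value").to_numpy()
            == matrix_values(explicit, "p_value").to_numpy()
        ).all()


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
            ({"a"}, {"a"}, 1.0),
            ({"a"}, {"b"}, 0.0),
        ],
    )
    def test_worked_values(self, a, b, expected):
        assert jaccard_index(GeneSet("x", a), GeneSet("y", b)) == expected

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(20)]
        for _ in range(20):
            a = GeneSet("a", set(rng.choice(universe, 6)))
            b = GeneSet("b", set(rng.choice(universe, 6)))
            j = jaccard_index(a, b)
            assert j == jaccard_index(b, a)
            assert 0 <= j <= 1
            assert (j == 1.0) == (a.genes == b.genes)

    def test_both_empty_is_error(self):
        with pytest.raises(EnrichmentError):
            jaccard_index(GeneSet("a", set()), GeneSet("b", set()))

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.frozensets(st.integers(0, 15), max_size=10),
        b=st.frozensets(st.integers(0, 15), max_size=10),
    )
    def test_property_symmetry_bounds_identity(self, a, b):
        if not (a | b):
            return
        j = jaccard_index(GeneSet("a", a), GeneSet("b", b))
        assert j == jaccard_index(GeneSet("b", b), GeneSet("a", a))
        assert 0.0 <= j <= 1.0
        assert (j == 1.0) == (a == b)


class TestClusterOrder:
    def test_identical_rows_adjacent(self):
        z = pd.DataFrame(
            [[0.0, 0.0], [9.0, 9.0], [0.0, 0.0]], index=["a", "b", "c"]
        )
        order = list(cluster_order(z, axis="rows"))
        assert abs(order.index(0) - order.index(2)) == 1

    def test_single_row_identity(self):
        z = pd.DataFrame([[1.0, 2.0]])
        assert list(cluster_order(z, axis="rows")) == [0]

    def test_outgroup_last_joined(self):
        z = pd.DataFrame([[0.0], [1.0], [10.0]])
        order = list(cluster_order(z, axis="rows"))
        assert {order[0], order[1]} == {0, 1} or {order[1], order[2]} == {0, 1}

    def test_nan_imputed_as_zero(self, caplog):
        z = pd.DataFrame([[np.nan, 1.0], [0.0, 1.0]])
        with caplog.at_level("WARNING", logger="gogroups"):
            cluster_order(z, axis="rows")
        assert any("imputing" in r.message for r in caplog.records)


class TestWriteMatrix:
    def _cells(self):
        genes = [f"g{i}" for i in range(12)]
        data = pd.DataFrame(
            np.random.default_rng(1).lognormal(size=(12, 2)),
            index=genes,
            columns=["c1", "c2"],
        )
        m = ExpressionMatrix(data=data)
        vectors = [build_gene_vector(m, c) for c in m.conditions]
        sets = [GeneSet("a", set(genes[:5])), GeneSet("b", set(genes[5:]))]
        return enrichment_matrix(sets, vectors)

    def test_tsv_roundtrip_bit_exact(self, tmp_path):
        cells = self._cells()
        write_matrix(cells, [0, 1], [0, 1], tmp_path / "m")
        text1 = (tmp_path / "m.z.tsv").read_text()
        write_matrix(cells, [0, 1], [0, 1], tmp_path / "m2")
        assert text1 == (tmp_path / "m2.z.tsv").read_text()
        back = pd.read_csv(tmp_path / "m.z.tsv", sep="\t", index_col=0)
        assert back.shape == (2, 2)

    def test_permutation_moves_rows_only(self, tmp_path):
        cells = self._cells()
        write_matrix(cells, [1, 0], [0, 1], tmp_path / "m")
        back = pd.read_csv(tmp_path / "m.z.tsv", sep="\t", index_col=0)
        assert list(back.index) == ["b", "a"]

    def test_empty_matrix_is_error(self, tmp_path):
        with pytest.raises(EnrichmentError):
            write_matrix(pd.DataFrame(), [], [], tmp_path / "m")


class TestGmt:
    def test_roundtrip(self, tmp_path):
        sets = [GeneSet("a rcv", {"g1", "g2"}), GeneSet("b ts", {"g3"})]
        write_gmt(sets, tmp_path / "sets.gmt", descriptions={"a rcv": "desc"})
        back = read_gmt((tmp_path / "sets.gmt").read_text())
        assert {s.name: s.genes for s in back} == {s.name: s.genes for s in sets}
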