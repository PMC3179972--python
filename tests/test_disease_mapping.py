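import io
from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from orthomerge.disease_mapping import (
    DiseaseRecord,
    GeneLiteratureMesh,
    MeshLookup,
    assign_category,
    category_summary,
    join_disease_orthologs,
    read_gwas_records,
    read_mesh_lookup,
    read_omim_records,
    shared_disease_categories,
    simplify_term,
)
from orthomerge.integration import OrthologPair, integrate


@pytest.fixture(scope="module")
def lookup():
    entry = io.StringIO(
        "breast cancer\tbreast neoplasms\tC04\n"
        "breast tumor\tbreast neoplasms\tC04\n"
        "alcohol sensitivity\talcohol-induced disorders\tC18\n"
    )
    cs = io.StringIO("Neuro\tC10\n")
    manual = io.StringIO("weird rare disorder\tC16\n")
    return read_mesh_lookup(entry, cs, manual)


class TestSimplifyTerm:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Breast cancer", "breast cancer"),
            ("Diabetes mellitus, susceptibility to", "diabetes mellitus"),
            ("  Eye   color ", "eye color"),
            ("Deafness, autosomal recessive", "deafness"),
            ("Anemia [hemolytic]", "anemia"),
        ],
    )
    def test_examples(self, raw, expected):
        assert simplify_term(raw) == expected

    @given(st.text(max_size=60))
    def test_idempotent_and_deterministic(self, raw):
        once = simplify_term(raw)
        assert simplify_term(once) == once
        assert simplify_term(raw) == once


class TestAssignCategory:
    def test_entry_term_routes_to_mesh_category(self, lookup):
        rec = DiseaseRecord("GWAS", "Breast Cancer")
        cats, route = assign_category(rec, lookup)
        assert route == "entry_term"
        assert {c.code for c in cats} == {"C04"}

    def test_trait_keyword_routes_to_y02(self, lookup):
        cats, route = assign_category(DiseaseRecord("GWAS", "hair color"), lookup)
        assert route == "y02_rule"
        assert {c.code for c in cats} == {"Y02"}

    def test_risk_factor_keyword_routes_to_y01(self, lookup):
        cats, route = assign_category(DiseaseRecord("GWAS", "HDL cholesterol"), lookup)
        assert route == "y01_rule"
        assert {c.code for c in cats} == {"Y01"}

    def test_cs_heading_takes_precedence(self, lookup):
        rec = DiseaseRecord("OMIM_phenotype", "Breast cancer", 600001, "Neuro")
        cats, route = assign_category(rec, lookup)
        assert route == "cs_heading"
        assert {c.code for c in cats} == {"C10"}

    def test_manual_override_used_when_lookup_fails(self, lookup):
        cats, route = assign_category(
            DiseaseRecord("OMIM_gene_locus", "Weird rare disorder", 600002), lookup
        )
        assert route == "manual_override"
        assert {c.code for c in cats} == {"C16"}

    def test_unmapped_is_reported_not_guessed(self, lookup):
        cats, route = assign_category(DiseaseRecord("GWAS", "zzq finding"), lookup)
        assert route == "unmapped" and cats == set()

    def test_deterministic_and_idempotent(self, lookup):
        rec = DiseaseRecord("GWAS", "breast tumor")
        assert assign_category(rec, lookup) == assign_category(rec, lookup)


class TestFixtureRouting:
    def test_every_record_maps_by_exactly_its_planted_route(self, disease_fixture):
        lookup = read_mesh_lookup(
            io.StringIO(disease_fixture.entry_term_text),
            io.StringIO(disease_fixture.cs_heading_text),
            io.StringIO(disease_fixture.manual_override_text),
        )
        records = read_omim_records(io.StringIO(disease_fixture.omim_text))
        records += read_gwas_records(io.StringIO(disease_fixture.gwas_text))
        assert len(records) == len(disease_fixture.planted_records)
        route_counts = Counter()
        for rec, planted in zip(records, disease_fixture.planted_records):
            cats, route = assign_category(rec, lookup)
            route_counts[route] += 1
            assert route == planted.route
            if planted.category_code is None:
                assert cats == set()
            else:
                assert planted.category_code in {c.code for c in cats}
        assert sum(route_counts.values()) == len(records)


def small_pairs():
    return [
        OrthologPair(1, 101, frozenset("abcd")),
        OrthologPair(1, 102, frozenset("wxyz")),
        OrthologPair(1, 103, frozenset("ab")),
        OrthologPair(2, 104, frozenset("a")),
    ]


class TestJoin:
    def test_omim_id_query_returns_each_predicted_ortholog(self, lookup):
        rec = DiseaseRecord("OMIM_phenotype", "acute alcohol sensitivity", 610251, None, {1})
        rows = join_disease_orthologs([rec], small_pairs(), lookup, omim_ids={610251})
        assert [r.target_gene for r in rows] == [101, 102, 103]

    def test_term_query_without_match_is_empty(self, lookup):
        rec = DiseaseRecord("GWAS", "breast cancer", None, None, {1})
        assert join_disease_orthologs([rec], small_pairs(), lookup, term_query="kidney") == []

    def test_best_match_keeps_tied_top_candidates(self, lookup):
        rec = DiseaseRecord("GWAS", "breast cancer", None, None, {1})
        rows = join_disease_orthologs([rec], small_pairs(), lookup, filter_mode="best_match")
        assert sorted(r.target_gene for r in rows) == [101, 102]

    def test_filter_monotonicity(self, lookup, world, tool_pair_sets, disease_fixture):
        integrated = integrate(tool_pair_sets)
        records = read_omim_records(io.StringIO(disease_fixture.omim_text))
        fx_lookup = read_mesh_lookup(
            io.StringIO(disease_fixture.entry_term_text),
            io.StringIO(disease_fixture.cs_heading_text),
            io.StringIO(disease_fixture.manual_override_text),
        )

        def row_keys(mode):
            rows = join_disease_orthologs(records, integrated, fx_lookup, filter_mode=mode)
            return {(r.human_gene, r.target_gene) for r in rows if r.target_gene}

        none, ge2, ge3 = row_keys("none"), row_keys("score_ge2"), row_keys("score_ge3")
        assert ge3 <= ge2 <= none

    def test_gene_without_ortholog_gets_explicit_row(self, lookup):
        rec = DiseaseRecord("GWAS", "breast cancer", None, None, {42})
        (row,) = join_disease_orthologs([rec], small_pairs(), lookup)
        assert row.target_gene is None and row.simple_score is None

    def test_unknown_filter_and_category_rejected(self, lookup):
        with pytest.raises(ValueError):
            join_disease_orthologs([], small_pairs(), lookup, filter_mode="bogus")
        with pytest.raises(KeyError, match="valid"):
            join_disease_orthologs([], small_pairs(), lookup, category_query="C99")

    def test_summary_recomputes_from_rows(self, lookup):
        recs = [
            DiseaseRecord("GWAS", "breast cancer", None, None, {1, 2}),
            DiseaseRecord("GWAS", "breast tumor", None, None, {1}),
        ]
        rows = join_disease_orthologs(recs, small_pairs(), lookup)
        summary = category_summary(rows)
        assert summary["C04"]["n_terms"] == 2
        assert summary["C04"]["n_human_genes"] == 2
        assert summary["C04"]["n_target_genes"] == len(
            {r.target_gene for r in rows if r.target_gene}
        )


class TestSharedCategories:
    def test_common_category_is_shared(self):
        lit = GeneLiteratureMesh({1: {"C04"}, 2: {"C04", "C10"}})
        assert shared_disease_categories(1, {2}, lit) == {"C04"}

    def test_disjoint_sets_share_nothing(self):
        lit = GeneLiteratureMesh({1: {"C04"}, 2: {"C10"}})
        assert shared_disease_categories(1, {2}, lit) == set()

    def test_absent_genes_treated_as_empty(self):
        lit = GeneLiteratureMesh({})
        assert shared_disease_categories(1, {2, 3}, lit) == set()

    def test_planted_sharing_recovered_exactly(self, world, disease_fixture):
        lit = GeneLiteratureMesh.read(io.StringIO(disease_fixture.literature_text))
        humans_of_fly = {}
        for a, b in world.truth.truth_pairs:
            humans_of_fly.setdefault(b, set()).add(a)
        recovered = {
            b for b, hs in humans_of_fly.items() if shared_disease_categories(b, hs, lit)
        }
        assert recovered == disease_fixture.shared_fly_genes
        assert not recovered & disease_fixture.unshared_fly_genes
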