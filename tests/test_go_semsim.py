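import math

import pytest

from orthomerge.go_semsim import (
    GoAnnotationSet,
    GoDag,
    NotComputable,
    compute_ic,
    compute_tool_weights,
    filter_by_evidence,
    gene_pair_similarity,
    term_similarity,
    tool_mean_similarity,
    weighted_score,
)
from orthomerge.integration import OrthologPair

from .oracles import oracle_bma, oracle_ic, oracle_lin

ROOT = "GO:0003674"


def chain_dag():
    # root -> t1 -> t2, plus a second branch root -> u1
    return GoDag({ROOT: set(), "t1": {ROOT}, "t2": {"t1"}, "u1": {ROOT}})


def ann(mapping, subset="MF1"):
    return GoAnnotationSet({g: set(ts) for g, ts in mapping.items()}, subset)


class TestEvidenceFiltering:
    def test_iea_only_gene_dropped_from_mf2(self):
        out = filter_by_evidence(ann({1: {("t1", "IEA")}}), "MF2")
        assert 1 not in out.genes()

    def test_ida_gene_survives_all_subsets(self):
        a = ann({1: {("t1", "IDA")}})
        for subset in ("MF1", "MF2", "MF3"):
            assert 1 in filter_by_evidence(a, subset).genes()

    def test_tas_survives_mf2_not_mf3(self):
        a = ann({1: {("t1", "TAS")}})
        assert 1 in filter_by_evidence(a, "MF2").genes()
        assert 1 not in filter_by_evidence(a, "MF3").genes()

    def test_mf1_is_identity(self):
        a = ann({1: {("t1", "IEA"), ("t2", "IDA")}})
        assert filter_by_evidence(a, "MF1").assignments == a.assignments

    def test_unknown_subset_rejected(self):
        with pytest.raises(ValueError, match="unknown subset"):
            filter_by_evidence(ann({}), "MF9")

    def test_subsets_are_nested(self, annotations):
        mf2 = filter_by_evidence(annotations, "MF2")
        mf3 = filter_by_evidence(annotations, "MF3")
        assert mf3.genes() <= mf2.genes() <= annotations.genes()


class TestInformationContent:
    def test_root_and_universal_terms_have_zero_ic(self):
        dag = chain_dag()
        ic = compute_ic(ann({1: {("t2", "IDA")}, 2: {("t1", "IDA")}}), dag)
        assert ic[ROOT] == 0.0
        assert ic["t1"] == 0.0  # both annotations fall under t1

    def test_chain_counts_by_hand(self):
        dag = chain_dag()
        ic = compute_ic(ann({1: {("t2", "IDA")}, 2: {("t1", "IDA")}}), dag)
        assert ic["t2"] == pytest.approx(-math.log(0.5))

    def test_unannotated_terms_excluded(self):
        dag = chain_dag()
        ic = compute_ic(ann({1: {("t2", "IDA")}}), dag)
        assert "u1" not in ic

    def test_empty_corpus_not_computable(self):
        with pytest.raises(NotComputable):
            compute_ic(ann({}), chain_dag())

    def test_ic_non_decreasing_parent_to_child(self, dag, annotations, term_ic):
        for term, parents in dag.parents.items():
            if term not in term_ic:
                continue
            for p in parents:
                if p in term_ic:
                    assert term_ic[term] >= term_ic[p] - 1e-12


class TestTermSimilarity:
    def test_identical_informative_terms_score_one(self):
        dag = chain_dag()
        ic = compute_ic(ann({1: {("t2", "IDA")}, 2: {("u1", "IDA")}}), dag)
        assert term_similarity("t2", "t2", dag, ic) == 1.0

    def test_terms_sharing_only_root_score_zero(self):
        dag = chain_dag()
        ic = compute_ic(ann({1: {("t2", "IDA")}, 2: {("u1", "IDA")}}), dag)
        assert term_similarity("t2", "u1", dag, ic) == 0.0

    def test_absent_term_raises(self):
        dag = chain_dag()
        ic = compute_ic(ann({1: {("t2", "IDA")}}), dag)
        with pytest.raises(KeyError):
            term_similarity("nope", "t2", dag, ic)

    def test_symmetry_and_bounds_on_fixture(self, dag, term_ic):
        terms = sorted(term_ic.ic)[:12]
        for t1 in terms:
            for t2 in terms:
                s = term_similarity(t1, t2, dag, term_ic)
                assert 0.0 <= s <= 1.0
                assert s == term_similarity(t2, t1, dag, term_ic)

    def test_matches_bruteforce_on_fixture(self, dag, annotations, term_ic):
        assignments = {g: annotations.terms_for(g) for g in sorted(annotations.genes())[:40]}
        oracle, total = oracle_ic(assignments, dag.parents)
        sub_ic = compute_ic(
            GoAnnotationSet({g: {(t, "IDA") for t in ts} for g, ts in assignments.items()}),
            dag,
        )
        terms = sorted(oracle)
        for t in terms:
            assert sub_ic[t] == pytest.approx(oracle[t], abs=1e-12)
        for t1 in terms[::3]:
            for t2 in terms[::4]:
                assert term_similarity(t1, t2, dag, sub_ic) == pytest.approx(
                    oracle_lin(t1, t2, dag.parents, oracle), abs=1e-12
                )


class TestGenePairSimilarity:
    def test_identical_term_sets_score_one(self, dag, term_ic):
        terms = {t for t in term_ic.ic if term_ic[t] > 0}
        some = set(sorted(terms)[:3])
        assert gene_pair_similarity(some, some, dag, term_ic) == pytest.approx(1.0)

    def test_singletons_reduce_to_term_similarity(self, dag, term_ic):
        t1, t2 = sorted(t for t in term_ic.ic if term_ic[t] > 0)[:2]
        assert gene_pair_similarity({t1}, {t2}, dag, term_ic) == pytest.approx(
            term_similarity(t1, t2, dag, term_ic)
        )

    def test_empty_side_not_computable(self, dag, term_ic):
        assert gene_pair_similarity(set(), {"GO:0003674"}, dag, term_ic) is None

    def test_matches_bruteforce_bma(self, dag, annotations, term_ic):
        genes = sorted(g for g in annotations.genes() if annotations.terms_for(g))
        oracle_ic_map = {t: term_ic[t] for t in term_ic.ic}
        for ga, gb in zip(genes[:20], genes[20:40]):
            got = gene_pair_similarity(
                annotations.terms_for(ga), annotations.terms_for(gb), dag, term_ic
            )
            want = oracle_bma(
                annotations.terms_for(ga), annotations.terms_for(gb), dag.parents, oracle_ic_map
            )
            assert got == pytest.approx(want, abs=1e-9)


class TestToolWeights:
    def test_weights_from_means_by_hand(self):
        tw = compute_tool_weights({"a": 0.6, "b": 0.7, "c": 0.8})
        assert tw["a"] == pytest.approx(0.6 / 0.7)
        assert tw["b"] == pytest.approx(1.0)
        assert tw["c"] == pytest.approx(0.8 / 0.7)

    def test_printed_extremes_reproduce_published_weight_range(self):
        # nine mean similarities spanning 0.612..0.691 with median 0.678
        means = [0.612, 0.640, 0.655, 0.668, 0.678, 0.682, 0.685, 0.688, 0.691]
        tw = compute_tool_weights(dict(zip("abcdefghi", means)))
        assert min(tw.weight.values()) == pytest.approx(0.612 / 0.678, abs=1e-9)
        assert max(tw.weight.values()) == pytest.approx(0.691 / 0.678, abs=1e-9)
        assert round(min(tw.weight.values()), 3) == 0.903
        assert round(max(tw.weight.values()), 3) == 1.019

    def test_single_tool_weight_is_one(self):
        assert compute_tool_weights({"only": 0.42})["only"] == 1.0

    def test_all_missing_not_computable(self):
        with pytest.raises(NotComputable):
            compute_tool_weights({"a": None})

    def test_scale_invariance_and_unit_median(self):
        import statistics

        means = {"a": 0.5, "b": 0.61, "c": 0.66, "d": 0.72}
        w1 = compute_tool_weights(means)
        w2 = compute_tool_weights({t: 3.7 * s for t, s in means.items()})
        assert statistics.median(w1.weight.values()) == pytest.approx(1.0, abs=1e-9)
        for t in means:
            assert w1[t] == pytest.approx(w2[t], abs=1e-12)


class TestWeightedScore:
    def test_sum_of_supporting_weights(self):
        from orthomerge.go_semsim import ToolWeights

        pair = OrthologPair(1, 2, frozenset({"a", "b"}))
        assert weighted_score(pair, ToolWeights({"a": 1.0, "b": 0.9})) == pytest.approx(1.9)

    def test_unit_weights_recover_simple_score(self):
        from orthomerge.go_semsim import ToolWeights

        pair = OrthologPair(1, 2, frozenset({"a", "b", "c"}))
        assert weighted_score(pair, ToolWeights({t: 1.0 for t in "abc"})) == pair.simple_score

    def test_missing_weight_raises(self):
        from orthomerge.go_semsim import ToolWeights

        with pytest.raises(KeyError):
            weighted_score(OrthologPair(1, 2, frozenset({"a"})), ToolWeights({}))

    def test_bounded_by_score_times_extreme_weights(self, tool_pair_sets, dag, annotations, term_ic):
        from orthomerge.go_semsim import ToolWeights
        from orthomerge.integration import integrate

        sims = {}
        for t in tool_pair_sets:
            sims[t.tool_name] = tool_mean_similarity(t, annotations, dag, term_ic).mean_sim
        tw = compute_tool_weights(sims)
        lo, hi = min(tw.weight.values()), max(tw.weight.values())
        for p in integrate(tool_pair_sets):
            w = weighted_score(p, tw)
            assert p.simple_score * lo - 1e-9 <= w <= p.simple_score * hi + 1e-9


class TestToolMeanSimilarity:
    def test_identical_annotations_mean_one(self, dag, term_ic):
        from orthomerge.id_mapping import GenePair
        from orthomerge.integration import ToolPairSet

        informative = sorted(t for t in term_ic.ic if term_ic[t] > 0)[:2]
        annotations = GoAnnotationSet(
            {1: {(t, "IDA") for t in informative}, 2: {(t, "IDA") for t in informative}}
        )
        tps = ToolPairSet("t", ("human", "fly"), {GenePair(1, 2)})
        ts = tool_mean_similarity(tps, annotations, dag, term_ic)
        assert ts.mean_sim == pytest.approx(1.0)
        assert ts.n_pairs == 1

    def test_no_annotated_pairs_not_computable(self, dag, term_ic):
        from orthomerge.id_mapping import GenePair
        from orthomerge.integration import ToolPairSet

        tps = ToolPairSet("t", ("human", "fly"), {GenePair(999999, 999998)})
        with pytest.raises(NotComputable):
            tool_mean_similarity(tps, GoAnnotationSet({}), dag, term_ic)
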