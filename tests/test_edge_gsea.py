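import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from subpathx import edge_gsea
from subpathx.data_io import PathwayEdgeSets


def ranked_from_scores(score_map):
    """Build a RankedEdgeList from {edge_id: score} via the public API."""
    return edge_gsea.rank_edges(pd.Series(score_map), sample_id="S")


def enumeration_oracle(scores, hit, exponent):
    """Independent step-by-step running-sum enumeration (plain Python)."""
    n = len(scores)
    k = sum(hit)
    wsum = sum(abs(s) ** exponent for s, h in zip(scores, hit) if h)
    running, total = [], 0.0
    for s, h in zip(scores, hit):
        if h:
            total += (abs(s) ** exponent / wsum) if wsum else 1.0 / k
        else:
            total -= 1.0 / (n - k)
        running.append(total)
    peak = max(range(n), key=lambda i: (abs(running[i]), -i))
    return running[peak], peak + 1, running


E1, E2, E3, E4 = ("A", "E1"), ("A", "E2"), ("A", "E3"), ("A", "E4")
FOUR = {"A|E1": 4.0, "A|E2": 3.0, "A|E3": 2.0, "A|E4": 1.0}


class TestRankEdges:
    def test_descending_with_ties_by_id(self):
        r = ranked_from_scores({"A|B": 1.0, "A|C": 1.0, "X|Y": 4.0, "M|N": 2.0})
        assert r.edges == [("X", "Y"), ("M", "N"), ("A", "B"), ("A", "C")]

    def test_all_equal_scores_fully_lexicographic(self):
        r = ranked_from_scores({"C|D": 0.0, "A|B": 0.0, "B|C": 0.0})
        assert r.edges == [("A", "B"), ("B", "C"), ("C", "D")]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            edge_gsea.rank_edges(pd.Series(dtype=float))


class TestEnrichmentScore:
    def test_single_top_hit(self):
        es, peak, _ = edge_gsea.enrichment_score(ranked_from_scores(FOUR), {E1})
        assert es == pytest.approx(1.0)
        assert peak == 1

    def test_single_bottom_hit(self):
        es, peak, _ = edge_gsea.enrichment_score(ranked_from_scores(FOUR), {E4})
        assert es == pytest.approx(-1.0)
        assert peak == 3

    def test_top_and_bottom_hit(self):
        es, peak, run = edge_gsea.enrichment_score(ranked_from_scores(FOUR), {E1, E4})
        assert es == pytest.approx(0.8)
        assert peak == 1
        assert run == pytest.approx([0.8, 0.3, -0.2, 0.0])

    def test_prefix_and_suffix_sets_saturate(self):
        rng = np.random.default_rng(3)
        for exponent in (0.0, 1.0, 2.0):
            scores = np.sort(rng.normal(size=12))[::-1]
            ranked = ranked_from_scores(
                {f"A|E{i:02d}": s for i, s in enumerate(scores)}
            )
            top = set(ranked.edges[:4])
            bottom = set(ranked.edges[-4:])
            assert edge_gsea.enrichment_score(ranked, top, exponent)[0] == pytest.approx(1.0)
            assert edge_gsea.enrichment_score(ranked, bottom, exponent)[0] == pytest.approx(-1.0)

    def test_exponent_zero_is_classical_ks(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(5, 30)
            scores = rng.normal(size=n)
            ranked = ranked_from_scores({f"A|E{i:02d}": s for i, s in enumerate(scores)})
            k = int(rng.integers(1, n))
            hit_set = set(rng.choice(len(ranked.edges), k, replace=False))
            eset = {ranked.edges[i] for i in hit_set}
            es, _, _ = edge_gsea.enrichment_score(ranked, eset, exponent=0.0)
            # classical two-sample KS between hit ranks and miss ranks
            hits = np.array([e in eset for e in ranked.edges])
            diff = np.cumsum(hits / k - (~hits) / (n - k))
            expected = diff[np.argmax(np.abs(diff))]
            assert es == pytest.approx(expected, abs=1e-12)

    def test_reversal_negates_unweighted_es(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=10)
        fwd = ranked_from_scores({f"A|E{i:02d}": s for i, s in enumerate(scores)})
        rev = edge_gsea.RankedEdgeList(
            sample_id="S", edges=fwd.edges[::-1], scores=fwd.scores[::-1]
        )
        eset = set(fwd.edges[:3]) | {fwd.edges[7]}
        es_f, _, _ = edge_gsea.enrichment_score(fwd, eset, exponent=0.0)
        es_r, _, _ = edge_gsea.enrichment_score(rev, eset, exponent=0.0)
        assert es_f == pytest.approx(-es_r, abs=1e-12)

    def test_exhaustive_small_lists(self):
        rng = np.random.default_rng(11)
        for n in (2, 4, 6, 8):
            scores = rng.normal(size=n)
            ranked = ranked_from_scores({f"A|E{i}": s for i, s in enumerate(scores)})
            for r in range(1, n):
                for combo in itertools.combinations(range(n), r):
                    hit = [i in combo for i in range(n)]
                    eset = {ranked.edges[i] for i in combo}
                    es, peak, run = edge_gsea.enrichment_score(ranked, eset)
                    oes, opeak, orun = enumeration_oracle(ranked.scores, hit, 1.0)
                    assert es == pytest.approx(oes, abs=1e-12)
                    assert peak == opeak
                    assert run == pytest.approx(orun, abs=1e-12)


class TestPermutationPvalue:
    def test_deterministic_given_seed(self):
        ranked = ranked_from_scores(
            {f"A|E{i:03d}": s for i, s in enumerate(np.random.default_rng(1).normal(size=50))}
        )
        eset = set(ranked.edges[:6])
        p1 = edge_gsea.permutation_pvalue(ranked, eset, n_perm=200, seed=42)
        p2 = edge_gsea.permutation_pvalue(ranked, eset, n_perm=200, seed=42)
        assert p1 == p2

    def test_addone_bounds(self):
        ranked = ranked_from_scores(
            {f"A|E{i:03d}": s for i, s in enumerate(np.random.default_rng(2).normal(size=40))}
        )
        eset = set(ranked.edges[10:16])
        p = edge_gsea.permutation_pvalue(ranked, eset, n_perm=199, seed=0)
        assert 1 / 200 <= p <= 1.0

    def test_top_block_reaches_floor(self):
        scores = {f"A|E{i:04d}": float(1000 - i) for i in range(1000)}
        ranked = ranked_from_scores(scores)
        eset = set(ranked.edges[:10])
        p = edge_gsea.permutation_pvalue(ranked, eset, n_perm=999, seed=7)
        assert p == pytest.approx(1 / 1000)

    def test_vectorized_null_matches_direct_es(self):
        # the permutation null's candidate-point shortcut must agree with
        # full running-sum evaluation on the same random sets
        rng = np.random.default_rng(5)
        scores = rng.normal(size=30)
        ranked = ranked_from_scores({f"A|E{i:02d}": s for i, s in enumerate(scores)})
        from subpathx.edge_gsea import _null_es_abs

        k = 7
        null = _null_es_abs(ranked.scores, k, 50, np.random.default_rng(9), 1.0)
        rng2 = np.random.default_rng(9)
        u = rng2.random((50, 30))
        pos = np.sort(np.argpartition(u, k - 1, axis=1)[:, :k], axis=1)
        for row, p_row in enumerate(pos):
            eset = {ranked.edges[i] for i in p_row}
            es, _, _ = edge_gsea.enrichment_score(ranked, eset)
            assert null[row] == pytest.approx(abs(es), abs=1e-12)


class TestFdrAdjust:
    def test_step_up_hand_example(self):
        q = edge_gsea.fdr_adjust([0.01, 0.02, 0.03])
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert edge_gsea.fdr_adjust([0.2]) == pytest.approx([0.2])
        assert edge_gsea.fdr_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=12))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_order_invariant_and_matches_hand_stepup(self, pvals):
        p = np.array(pvals)
        m = len(p)
        order = np.argsort(p, kind="stable")
        ranked_q = p[order] * m / np.arange(1, m + 1)
        stepup = np.minimum.accumulate(ranked_q[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepup, 1.0)
        assert edge_gsea.fdr_adjust(p) == pytest.approx(expected, abs=1e-12)
        perm = np.random.default_rng(0).permutation(m)
        assert edge_gsea.fdr_adjust(p[perm]) == pytest.approx(expected[perm], abs=1e-12)


class TestLeadingEdge:
    def test_positive_es_takes_members_before_peak(self):
        ranked = ranked_from_scores(FOUR)
        es, peak, _ = edge_gsea.enrichment_score(ranked, {E1, E2})
        assert es == pytest.approx(1.0) and peak == 2
        assert edge_gsea.leading_edge(ranked, {E1, E2}, es, peak) == [E1, E2]

    def test_negative_es_takes_members_after_peak(self):
        ranked = ranked_from_scores(FOUR)
        es, peak, _ = edge_gsea.enrichment_score(ranked, {E4})
        assert edge_gsea.leading_edge(ranked, {E4}, es, peak) == [E4]

    def test_mixed_set_keeps_only_top_side(self):
        ranked = ranked_from_scores(FOUR)
        es, peak, _ = edge_gsea.enrichment_score(ranked, {E1, E4})
        assert edge_gsea.leading_edge(ranked, {E1, E4}, es, peak) == [E1]


class TestExtractSubpathways:
    def _enrichment(self, rows, cores):
        table = pd.DataFrame(
            rows, columns=["pathway_id", "es", "peak", "p", "q", "n_core", "direction"]
        )
        return edge_gsea.SampleEnrichment(sample_id="S", table=table, core_edges=cores)

    def test_nothing_significant_gives_empty_list(self):
        enr = self._enrichment([("P1", 0.5, 3, 0.5, 0.5, 2, "up")], {"P1": [E1, E2]})
        assert edge_gsea.extract_subpathways(enr) == []

    def test_shared_edge_stays_per_pathway(self):
        enr = self._enrichment(
            [("P1", 0.9, 1, 0.001, 0.002, 1, "up"), ("P2", 0.8, 2, 0.001, 0.002, 2, "up")],
            {"P1": [E1], "P2": [E1, E2]},
        )
        sps = edge_gsea.extract_subpathways(enr)
        assert {sp.pathway_id: sp.edges for sp in sps} == {
            "P1": {E1},
            "P2": {E1, E2},
        }
        assert all(sp.nodes == {g for e in sp.edges for g in e} for sp in sps)

    def test_min_edges_filter(self):
        enr = self._enrichment([("P1", 0.9, 1, 0.001, 0.002, 1, "up")], {"P1": [E1]})
        assert edge_gsea.extract_subpathways(enr, min_edges=2) == []


def test_analyze_sample_skips_small_sets(small_cohort, caplog):
    import subpathx as sx

    stats = sx.compute_reference_stats(small_cohort.expression, small_cohort.pathways)
    esm = sx.compute_edge_score_matrix(small_cohort.expression, stats)
    sample = esm.scores.columns[0]
    pathways = PathwayEdgeSets(
        pathways=dict(
            small_cohort.pathways.pathways,
            TINY={next(iter(small_cohort.pathways.pathways["PW01"]))},
        )
    )
    enr = edge_gsea.analyze_sample(
        esm.scores[sample], pathways, sample_id=sample, n_perm=100, seed=0
    )
    assert "TINY" not in set(enr.table["pathway_id"])
    assert set(enr.table["pathway_id"]) == {"PW01", "PW02", "PW03", "PW04"}
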