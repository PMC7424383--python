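"""Pair scoring (overlap, co-expression, regulation similarity) and network."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cerna_prognost import (
    ExpressionMatrix,
    InteractionDB,
    RunConfig,
    build_network,
    coexpression,
    extract_triplets,
    hypergeom_tail,
    regsim_from_correlations,
    regulation_similarity,
    score_pairs,
    shared_mirna_test,
)
from cerna_prognost.cerna import CeRNAPair, candidate_pairs
from cerna_prognost.errors import EmptyNetworkError, ScoringError, ValidationError


def enumeration_tail(N, K, n, k):
    """Oracle: P(overlap >= k) by exhaustive enumeration of all n-draws."""
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        hits += len(marked & set(draw)) >= k
    return hits / total


def _db(rows):
    return InteractionDB(
        pd.DataFrame(rows, columns=["mirna", "target", "target_class"])
    )


def _expr(values, ids, rna_class, scale="logCPM"):
    values = pd.DataFrame(values, index=ids,
                          columns=[f"T{i}" for i in range(len(values[0]))])
    group = pd.Series(["tumor"] * values.shape[1], index=values.columns)
    return ExpressionMatrix(values=values, rna_class=rna_class, group=group,
                            scale=scale)


class TestSharedMirnaTest:
    def test_worked_example_matches_enumeration(self):
        # N=10, K=4, n=5, k=3 -> (C(4,3)C(6,2)+C(4,4)C(6,1))/C(10,5) = 66/252
        p = hypergeom_tail(10, 4, 5, 3)
        assert abs(p - 66 / 252) < 1e-12
        assert abs(p - enumeration_tail(10, 4, 5, 3)) < 1e-12

    def test_saturated_overlap_is_certain(self):
        assert hypergeom_tail(6, 6, 6, 6) == pytest.approx(1.0)

    def test_small_universe_enumeration_equivalence(self):
        for N in (4, 6, 8):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeom_tail(N, K, n, k) == pytest.approx(
                            enumeration_tail(N, K, n, k), abs=1e-12
                        )

    def test_on_interaction_db(self):
        rows = [("m1", "L1", "lncRNA"), ("m2", "L1", "lncRNA"),
                ("m1", "G1", "mRNA"), ("m3", "G1", "mRNA")]
        db = _db(rows)
        shared, p = shared_mirna_test("L1", "G1", db, {"m1", "m2", "m3"})
        assert shared == {"m1"}
        # N=3, K=2, n=2, k=1: P(X>=1) = 1 - C(1,2)/C(3,2) -> 1.0
        assert p == pytest.approx(1.0)

    def test_zero_overlap_not_scored(self):
        rows = [("m1", "L1", "lncRNA"), ("m2", "G1", "mRNA")]
        shared, p = shared_mirna_test("L1", "G1", _db(rows), {"m1", "m2"})
        assert shared == set() and p is None


class TestCoexpression:
    def test_perfect_linear(self):
        x = np.arange(10, dtype=float)
        lnc = _expr([list(x)], ["L1"], "lncRNA")
        mrna = _expr([list(2 * x + 1)], ["G1"], "mRNA")
        r, p = coexpression("L1", "G1", lnc, mrna)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_anticorrelated(self):
        x = np.arange(10, dtype=float)
        lnc = _expr([list(x)], ["L1"], "lncRNA")
        mrna = _expr([list(-x)], ["G1"], "mRNA")
        r, _ = coexpression("L1", "G1", lnc, mrna)
        assert r == pytest.approx(-1.0)

    def test_p_value_calibration(self):
        """|r| exceeds the p<0.05 critical value (~0.197 at n=100) ~5% of the time."""
        rng = np.random.default_rng(1234)
        crit = 0.197
        hits = sum(
            abs(np.corrcoef(rng.normal(size=100), rng.normal(size=100))[0, 1]) > crit
            for _ in range(1000)
        )
        assert 0.03 < hits / 1000 < 0.07

    def test_constant_vector_rejected(self):
        lnc = _expr([[1.0] * 5], ["L1"], "lncRNA")
        mrna = _expr([[1.0, 2.0, 3.0, 2.0, 1.0]], ["G1"], "mRNA")
        with pytest.raises(ValidationError):
            coexpression("L1", "G1", lnc, mrna)


class TestRegulationSimilarity:
    def test_identical_profiles_score_one(self):
        assert regsim_from_correlations([(0.4, 0.4), (-0.2, -0.2)]) == 1.0

    def test_opposite_single_mirna_scores_zero(self):
        assert regsim_from_correlations([(0.4, -0.4)]) == 0.0

    def test_hand_computed_m2_example(self):
        # terms: (0.8/0.8)^2 = 1 and 0^2 = 0 -> 1 - (1+0)/2 = 0.5
        val = regsim_from_correlations([(0.4, -0.4), (0.3, 0.3)])
        assert val == pytest.approx(0.5)

    def test_zero_zero_term_counts_as_zero_distance(self):
        assert regsim_from_correlations([(0.0, 0.0)]) == 1.0

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(
            st.tuples(
                st.floats(-1, 1, allow_nan=False),
                st.floats(-1, 1, allow_nan=False),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_bounds_and_permutation_invariance(self, pairs):
        v = regsim_from_correlations(pairs)
        assert 0.0 <= v <= 1.0
        assert regsim_from_correlations(pairs[::-1]) == pytest.approx(v)

    def test_matrix_version_identity_case(self):
        rng = np.random.default_rng(5)
        mirv = rng.normal(size=12)
        target = rng.normal(size=12)
        lnc = _expr([list(target)], ["L1"], "lncRNA")
        mrna = _expr([list(target)], ["G1"], "mRNA")  # identical profiles
        mir = _expr([list(mirv)], ["m1"], "miRNA")
        v = regulation_similarity({"m1"}, "L1", "G1", mir, lnc, mrna)
        assert v == pytest.approx(1.0)

    def test_empty_mirna_set_rejected(self):
        with pytest.raises(ScoringError):
            regsim_from_correlations([])


class TestNetwork:
    def _pair(self, lnc, mrna, mirs, passes=True):
        return CeRNAPair(lnc, mrna, tuple(mirs), 0.01, 0.8, 0.001, 0.9, passes)

    def test_single_pair_three_mirnas(self):
        net = build_network([self._pair("L1", "G1", ["m1", "m2", "m3"])])
        assert len(net.nodes) == 5
        assert net.n_edges == 6
        for m in ("m1", "m2", "m3"):
            assert net.degree(m) == 2

    def test_star_hub(self):
        pairs = [self._pair("L1", f"G{i}", ["m1"]) for i in range(9)]
        net = build_network(pairs, RunConfig(hub_k=3))
        assert net.degree("m1") == 10
        assert net.hubs[0] == "m1"

    def test_shared_edge_stored_once(self):
        pairs = [self._pair("L1", "G1", ["m1"]), self._pair("L1", "G2", ["m1"])]
        net = build_network(pairs)
        assert net.n_edges == 3  # m1-L1 deduplicated

    def test_degree_sum_is_twice_edges(self, cohort_logcpm):
        logcpm, db, _clin, _truth = cohort_logcpm
        pairs = score_pairs(db, db.mirna_ids, logcpm["lncRNA"],
                            logcpm["mRNA"], logcpm["miRNA"])
        net = build_network(pairs)
        assert sum(net.degree(n) for n in net.nodes) == 2 * net.n_edges

    def test_bipartite_by_construction(self, cohort_logcpm):
        logcpm, db, _clin, _truth = cohort_logcpm
        pairs = score_pairs(db, db.mirna_ids, logcpm["lncRNA"],
                            logcpm["mRNA"], logcpm["miRNA"])
        net = build_network(pairs)
        for u, v, _d in net.graph.edges(data=True):
            classes = {net.graph.nodes[u]["rna_class"],
                       net.graph.nodes[v]["rna_class"]}
            assert "miRNA" in classes

    def test_no_passing_pairs_rejected(self):
        with pytest.raises(EmptyNetworkError):
            build_network([self._pair("L1", "G1", ["m1"], passes=False)])


class TestTriplets:
    def test_planted_triplets_recovered_end_to_end(self, cohort_logcpm):
        logcpm, db, _clin, truth = cohort_logcpm
        pairs = score_pairs(db, db.mirna_ids, logcpm["lncRNA"],
                            logcpm["mRNA"], logcpm["miRNA"])
        net = build_network(pairs)
        triplets = {(t.lncrna_id, t.mirna_id, t.mrna_id)
                    for t in extract_triplets(net, pairs)}
        for planted in truth.planted_triplets:
            assert planted in triplets

    def test_hub_restriction_excludes_non_hub_members(self):
        pairs = [
            CeRNAPair("L1", "G1", ("m1",), 0.01, 0.9, 1e-4, 0.9, True),
            CeRNAPair("L2", "G2", ("m2",), 0.01, 0.9, 1e-4, 0.9, True),
        ]
        net = build_network(pairs, RunConfig(hub_k=3))  # only one full triplet fits
        trip = extract_triplets(net, pairs)
        flags = {(t.lncrna_id, t.in_hub_subnetwork) for t in trip}
        assert sum(f for _l, f in flags) <= 1
        # unrestricted list still contains both
        assert {t.lncrna_id for t in trip} == {"L1", "L2"}

    def test_candidate_pairs_require_shared_mirna(self):
        rows = [("m1", "L1", "lncRNA"), ("m1", "G1", "mRNA"),
                ("m2", "L2", "lncRNA"), ("m3", "G2", "mRNA")]
        assert candidate_pairs(_db(rows)) == [("L1", "G1")]
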