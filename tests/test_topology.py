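"""Degree, cardinality and pattern detectors against the brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kgtopo import (
    aggregate_by_relation,
    counterpart_in_train,
    detect_edge_patterns,
    edge_cardinality,
    metapath_composition_counts,
    pattern_summary,
    triple_degrees,
    triple_topology,
)

from conftest import make_graph, oracle_topology, random_graph

DEGREE_COLS = ["deg_h", "deg_t", "deg_r_h", "deg_r_t"]
FLAG_COLS = ["is_symmetric", "has_inference", "has_inverse", "has_composition",
             "n_comp_intermediates", "n_comp_relpairs"]


class TestDegrees:
    def test_degree_toy_values(self, degree_toy):
        # frozen from the nested-loop oracle
        expect = oracle_topology(degree_toy.triples)
        assert [e["deg_h"] for e in expect] == [2, 2, 1, 2]
        assert [e["deg_r_h"] for e in expect] == [2, 2, 1, 1]
        assert [e["deg_t"] for e in expect] == [2, 1, 2, 2]
        assert [e["deg_r_t"] for e in expect] == [2, 1, 2, 1]
        got = triple_degrees(degree_toy)
        for col in DEGREE_COLS:
            assert got[col].tolist() == [e[col] for e in expect]

    def test_singleton_graph_all_ones(self):
        got = triple_degrees(make_graph([(0, 0, 1)]))
        assert got[DEGREE_COLS].to_numpy().tolist() == [[1, 1, 1, 1]]

    def test_degrees_monotone_under_edge_addition(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            g = random_graph(rng, max_triples=60)
            base = triple_degrees(g)[DEGREE_COLS].to_numpy()
            extra = None
            for _ in range(50):
                cand = rng.integers(0, [g.n_entities, g.n_relations, g.n_entities])
                if not (g.triples == cand).all(axis=1).any():
                    extra = cand
                    break
            if extra is None:
                continue
            bigger = make_graph(np.vstack([g.triples, extra]),
                                n_entities=g.n_entities, n_relations=g.n_relations)
            after = triple_degrees(bigger, g.triples)[DEGREE_COLS].to_numpy()
            assert (after >= base).all()


class TestCardinality:
    @pytest.mark.parametrize(
        "dh,dt,expected",
        [(1, 1, "1:1"), (2, 1, "1:M"), (1, 3, "M:1"), (2, 3, "M:M")],
    )
    def test_class_table(self, dh, dt, expected):
        assert edge_cardinality(dh, dt) == expected

    def test_invalid_degree_errors(self):
        with pytest.raises(ValueError):
            edge_cardinality(0, 1)

    def test_fractions_sum_to_one(self):
        g = random_graph(np.random.default_rng(2), max_triples=150)
        s = pattern_summary(g)
        assert sum(s.cardinality_fractions.values()) == pytest.approx(1.0)


class TestPatternFlags:
    def test_symmetric_pair(self):
        pat = detect_edge_patterns(make_graph([(0, 0, 1), (1, 0, 0)]))
        assert pat["is_symmetric"].all()
        assert not pat[["has_inference", "has_inverse", "has_composition"]].any().any()

    def test_inference_and_inverse(self):
        inf = detect_edge_patterns(make_graph([(0, 0, 1), (0, 1, 1)]))
        assert inf["has_inference"].all() and not inf["has_inverse"].any()
        inv = detect_edge_patterns(make_graph([(0, 0, 1), (1, 1, 0)]))
        assert inv["has_inverse"].all() and not inv["has_inference"].any()

    def test_composition_toy(self, composition_toy):
        pat = detect_edge_patterns(composition_toy)
        # only the direct edge A->B composes, via one intermediate and one rel pair
        assert pat["has_composition"].tolist() == [False, False, True]
        assert pat["n_comp_intermediates"].tolist() == [0, 0, 1]
        assert pat["n_comp_relpairs"].tolist() == [0, 0, 1]
        assert not pat[["is_symmetric", "has_inference", "has_inverse"]].any().any()

    def test_self_loop_is_not_symmetric(self):
        pat = detect_edge_patterns(make_graph([(0, 0, 0)]))
        assert not pat["is_symmetric"].any()

    def test_self_loop_cannot_be_composition_intermediate(self):
        # h->h loop plus h->t must not count n = h as an intermediate
        pat = detect_edge_patterns(make_graph([(0, 0, 0), (0, 0, 1), (1, 1, 1)]))
        assert not pat["has_composition"].any()

    def test_oracle_equivalence_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            g = random_graph(rng)
            topo = triple_topology(g)
            expect = pd.DataFrame(oracle_topology(g.triples))
            for col in DEGREE_COLS + FLAG_COLS:
                assert topo[col].tolist() == expect[col].tolist(), col

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 2), st.integers(0, 5)),
                    min_size=1, max_size=40))
    def test_oracle_equivalence_hypothesis(self, triples):
        g = make_graph(np.unique(np.asarray(triples), axis=0),
                       n_entities=6, n_relations=3)
        topo = triple_topology(g)
        expect = pd.DataFrame(oracle_topology(g.triples))
        for col in DEGREE_COLS + FLAG_COLS:
            assert topo[col].tolist() == expect[col].tolist(), col

    def test_symmetry_of_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            g = random_graph(rng, max_triples=120)
            pat = detect_edge_patterns(g)
            flags = {(h, r, t): s for (h, r, t), s in
                     zip(map(tuple, g.triples), pat["is_symmetric"])}
            for (h, r, t), s in flags.items():
                if (t, r, h) in flags:
                    assert flags[(t, r, h)] == s or h == t

    def test_reversal_duality_inverse_vs_inference(self):
        # an inverse counterpart of (h,r,t) in G is an inference counterpart
        # of (h,r,t) in the edge-reversed graph: (t,r',h) in G <=> (h,r',t)
        # in rev(G)
        rng = np.random.default_rng(8)
        for _ in range(10):
            g = random_graph(rng, max_triples=120)
            rev = make_graph(g.triples[:, [2, 1, 0]],
                             n_entities=g.n_entities, n_relations=g.n_relations)
            inv_fwd = detect_edge_patterns(g)["has_inverse"].tolist()
            inf_on_rev = detect_edge_patterns(g, pattern_graph=rev)["has_inference"].tolist()
            assert inv_fwd == inf_on_rev

    def test_flags_invariant_under_id_relabelling(self):
        rng = np.random.default_rng(9)
        g = random_graph(rng, max_triples=120)
        pe = rng.permutation(g.n_entities)
        pr = rng.permutation(g.n_relations)
        relab = np.stack([pe[g.triples[:, 0]], pr[g.triples[:, 1]], pe[g.triples[:, 2]]], axis=1)
        g2 = make_graph(relab, n_entities=g.n_entities, n_relations=g.n_relations)
        a = detect_edge_patterns(g)
        b = detect_edge_patterns(g2)
        for col in FLAG_COLS:
            assert a[col].tolist() == b[col].tolist()

    def test_pattern_graph_scope(self):
        # classify test triples against a larger pattern graph
        g = make_graph([(0, 0, 1)], n_entities=3, n_relations=2)
        pg = make_graph([(0, 0, 1), (1, 1, 0)], n_entities=3, n_relations=2)
        pat = detect_edge_patterns(g, pattern_graph=pg)
        assert pat["has_inverse"].tolist() == [True]


class TestSummaries:
    def test_single_edge_all_none(self):
        s = pattern_summary(make_graph([(0, 0, 1)]))
        assert s.none_fraction == 1.0
        assert all(v == 0.0 for v in s.pattern_fractions.values())

    def test_composition_toy_fractions(self, composition_toy):
        s = pattern_summary(composition_toy)
        assert s.pattern_fractions["has_composition"] == pytest.approx(1 / 3)
        assert s.none_fraction == pytest.approx(2 / 3)

    def test_empty_graph_errors(self):
        g = make_graph([(0, 0, 1)]).subgraph(np.array([False]))
        with pytest.raises(ValueError):
            pattern_summary(g)

    def test_aggregate_by_relation_labels(self):
        g = make_graph([(0, 0, 1), (1, 0, 0), (2, 1, 3), (3, 1, 2), (4, 1, 5), (5, 2, 6)])
        topo = triple_topology(g)
        agg = aggregate_by_relation(topo, majority_threshold=0.9)
        by_rel = agg.set_index("relation")["predominant"]
        assert by_rel[0] == "symmetric"  # all of r0's triples are symmetric
        assert by_rel[1] == "mixed"  # 2 of 3 symmetric -> below 0.9
        assert by_rel[2] == "mixed"

    def test_aggregate_threshold_validation(self):
        g = make_graph([(0, 0, 1)])
        with pytest.raises(ValueError):
            aggregate_by_relation(triple_topology(g), majority_threshold=0.3)


class TestMetapaths:
    def test_two_intermediate_types(self):
        # (A, rx, B) via N1 (gene) and N2 (drug) with distinct rel pairs
        types = ["unknown", "gene", "drug", "unknown"]
        g = make_graph(
            [(0, 0, 3), (0, 1, 1), (1, 2, 3), (0, 3, 2), (2, 4, 3)],
            types=types, n_relations=5,
        )
        mp = metapath_composition_counts(g, focus_relation=0)
        per_type = mp.groupby("intermediate_type")["n_paths"].sum()
        assert per_type.to_dict() == {"gene": 1, "drug": 1}
        assert len(mp[["r1", "r2"]].drop_duplicates()) == 2

    def test_no_composition_gives_empty_frame(self):
        g = make_graph([(0, 0, 1)], types=["gene", "gene"])
        assert metapath_composition_counts(g, 0).empty

    def test_missing_types_error(self):
        g = make_graph([(0, 0, 1)])
        with pytest.raises(ValueError, match="type"):
            metapath_composition_counts(g, 0)

    def test_path_instance_vs_intermediate_counts(self):
        # two parallel relations on the first hop -> 2 paths, 1 intermediate
        g = make_graph([(0, 0, 2), (0, 1, 1), (0, 2, 1), (1, 0, 2)],
                       types=["a", "b", "a"], n_relations=3)
        mp = metapath_composition_counts(g, 0)
        assert mp["n_paths"].sum() == 2
        assert mp["n_intermediates"].max() == 1


class TestCounterpartInTrain:
    def test_flags(self):
        train = make_graph([(1, 0, 0), (0, 1, 1), (2, 2, 0)], n_entities=4, n_relations=4)
        test = np.array([(0, 0, 1), (0, 3, 2), (3, 0, 3)])
        flags = counterpart_in_train(test, train)
        assert flags["sym_in_train"].tolist() == [True, False, False]
        assert flags["inf_in_train"].tolist() == [True, False, False]
        assert flags["inv_in_train"].tolist() == [False, True, False]

    def test_overlap_errors(self):
        train = make_graph([(0, 0, 1)])
        with pytest.raises(ValueError, match="overlap"):
            counterpart_in_train(np.array([(0, 0, 1)]), train)
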