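"""Stratified metrics, pattern effects, counterpart contrast, case study."""

import numpy as np
import pandas as pd
import pytest

from kgtopo import (
    RankingResult,
    case_study,
    counterpart_contrast,
    default_degree_bins,
    pattern_effect,
    ranking_metrics,
    restricted_candidates,
    stratify,
    triple_topology,
)
from kgtopo.analysis import degree_bin_labels
from kgtopo.graph import encode_triples

from conftest import make_graph


def results_for(topo: pd.DataFrame, ranks) -> list[RankingResult]:
    return [
        RankingResult(int(h), int(r), int(t), float(rank), 100, int(t))
        for (h, r, t), rank in zip(
            topo[["head", "relation", "tail"]].itertuples(index=False), ranks
        )
    ]


@pytest.fixture
def toy_topo():
    g = make_graph(
        [(0, 0, 1), (1, 0, 0), (2, 0, 3), (0, 1, 3), (4, 1, 3), (2, 1, 0), (3, 0, 4)]
    )
    return g, triple_topology(g)


class TestBins:
    def test_power_of_two_edges(self):
        assert default_degree_bins(10).tolist() == [1, 2, 4, 8, 16]

    def test_labels_partition_degrees(self):
        edges = default_degree_bins(20)
        vals = np.arange(1, 21)
        labels = degree_bin_labels(vals, edges)
        # every degree lands in exactly one bin; bin of 1 is the singleton {1}
        assert labels[0] == "1"
        assert set(labels) == {"1", "2-3", "4-7", "8-15", "16-31"}

    def test_zero_degree_handled(self):
        labels = degree_bin_labels(np.array([0, 1]), default_degree_bins(4))
        assert labels[0] == "0"


class TestStratify:
    def test_group_mrr_arithmetic(self, toy_topo):
        g, topo = toy_topo
        # symmetric triples rank 1; everything else rank 2 or 4
        ranks = [1 if s else r for s, r in zip(topo["is_symmetric"], [0, 0, 2, 4, 2, 4, 2])]
        res = results_for(topo, ranks)
        out = stratify(res, topo, schema="is_symmetric")
        by_flag = out.set_index("is_symmetric")
        assert by_flag.loc[True, "mrr"] == pytest.approx(1.0)
        assert by_flag.loc[True, "count"] == 2

    def test_cardinality_single_group_equals_global(self):
        g = make_graph([(0, 0, 1), (0, 0, 2), (3, 0, 1), (3, 0, 2)])
        topo = triple_topology(g)
        assert (topo["cardinality"] == "M:M").all()
        res = results_for(topo, [1, 2, 3, 4])
        out = stratify(res, topo, schema="cardinality")
        assert len(out) == 1
        assert out["mrr"][0] == pytest.approx(ranking_metrics(res)["mrr"])

    def test_counts_partition_and_mrr_reconstructs(self, toy_topo):
        g, topo = toy_topo
        rng = np.random.default_rng(0)
        res = results_for(topo, rng.integers(1, 30, len(topo)))
        total = ranking_metrics(res)
        for schema in ("degree", "cardinality", "is_symmetric"):
            out = stratify(res, topo, schema=schema)
            assert out["count"].sum() == len(topo)
            recon = (out["count"] * out["mrr"]).sum() / out["count"].sum()
            assert recon == pytest.approx(total["mrr"], abs=1e-12)

    def test_misaligned_inputs_error(self, toy_topo):
        g, topo = toy_topo
        res = results_for(topo, np.ones(len(topo)))
        with pytest.raises(ValueError, match="aligned"):
            stratify(res[:-1], topo, schema="cardinality")

    def test_unknown_schema_errors(self, toy_topo):
        g, topo = toy_topo
        res = results_for(topo, np.ones(len(topo)))
        with pytest.raises(ValueError, match="schema"):
            stratify(res, topo, schema="astrology")


class TestPatternEffect:
    def test_constructed_delta(self, toy_topo):
        g, topo = toy_topo
        flag = topo["is_symmetric"].to_numpy()
        ranks = np.where(flag, 1.0, 2.0)
        res = results_for(topo, ranks)
        out = pattern_effect(res, topo, "is_symmetric")
        populated = out.dropna(subset=["delta_mrr"])
        assert np.allclose(populated["delta_mrr"], 0.5)
        assert populated["n_with"].sum() == int(flag.sum())

    def test_identical_distributions_zero_delta(self, toy_topo):
        g, topo = toy_topo
        res = results_for(topo, np.full(len(topo), 3.0))
        out = pattern_effect(res, topo, "has_inference")
        populated = out.dropna(subset=["delta_mrr"])
        assert (populated["delta_mrr"].abs() < 1e-15).all()

    def test_empty_side_marked_undefined(self, toy_topo):
        g, topo = toy_topo
        res = results_for(topo, np.ones(len(topo)))
        out = pattern_effect(res, topo, "has_inverse")
        empties = out[(out["n_with"] == 0) | (out["n_without"] == 0)]
        assert empties["delta_mrr"].isna().all()

    def test_unknown_flag_errors(self, toy_topo):
        g, topo = toy_topo
        with pytest.raises(ValueError):
            pattern_effect(results_for(topo, np.ones(len(topo))), topo, "has_vibes")


class TestCounterpartContrast:
    def test_groups_and_counts(self, toy_topo):
        g, topo = toy_topo
        flags = pd.DataFrame(
            {
                "head": topo["head"], "relation": topo["relation"], "tail": topo["tail"],
                "sym_in_train": [True, True, False, False, False, False, False],
                "inv_in_train": [False] * 7,
                "inf_in_train": [False] * 7,
            }
        )
        ranks = [1, 1, 4, 4, 4, 4, 4]
        out = counterpart_contrast(results_for(topo, ranks), flags)
        sym = out[out["pattern"] == "sym_in_train"].set_index("counterpart_in_train")
        assert sym.loc[True, "count"] == 2 and sym.loc[True, "mrr"] == pytest.approx(1.0)
        assert sym.loc[False, "mrr"] == pytest.approx(0.25)
        inv = out[out["pattern"] == "inv_in_train"].set_index("counterpart_in_train")
        assert inv.loc[True, "count"] == 0 and np.isnan(inv.loc[True, "mrr"])


def _case_study_graphs():
    base = [(f"a{i}", "treats", f"X{i % 4}") for i in range(40)]
    extra = [(f"a{i}", "binds", f"Y{i % 3}") for i in range(10)]
    g1_rows = base + extra
    g2_rows = base + extra + [(f"b{i}", "treats", f"X{i % 4}") for i in range(25)]
    def build(rows):
        from kgtopo.graph import Vocab, KnowledgeGraph
        ev, rv = Vocab(), Vocab()
        trips = np.asarray([(ev.add(h), rv.add(r), ev.add(t)) for h, r, t in rows])
        return KnowledgeGraph(trips, ev, rv)
    return build(g1_rows), build(g2_rows)


class TestCaseStudy:
    def test_shared_extraction_and_leakage(self):
        g1, g2 = _case_study_graphs()
        bundle = case_study(g1, g2, "treats", test_fraction=0.10, seed=3)
        assert len(bundle.test_labels) == 4  # 10% of 40 shared triples
        # no test triple appears in either training graph
        for train, ids in ((bundle.train_1, bundle.test_ids_1),
                           (bundle.train_2, bundle.test_ids_2)):
            keys = set(encode_triples(train.triples, train.n_entities,
                                      train.n_relations).tolist())
            gone = set(encode_triples(ids, train.n_entities, train.n_relations).tolist())
            assert not keys & gone
        assert g1.n_triples - bundle.train_1.n_triples == 4
        assert g2.n_triples - bundle.train_2.n_triples == 4

    def test_candidates_are_shared_tails(self):
        g1, g2 = _case_study_graphs()
        bundle = case_study(g1, g2, "treats", seed=3)
        labels1 = {g1.entities.labels[c] for c in bundle.candidates_1}
        labels2 = {g2.entities.labels[c] for c in bundle.candidates_2}
        assert labels1 == labels2 == {"X0", "X1", "X2", "X3"}

    def test_seed_determinism(self):
        g1, g2 = _case_study_graphs()
        a = case_study(g1, g2, "treats", seed=9)
        b = case_study(g1, g2, "treats", seed=9)
        assert a.test_labels == b.test_labels

    def test_missing_relation_errors(self):
        g1, g2 = _case_study_graphs()
        with pytest.raises(ValueError):
            case_study(g1, g2, "cures")
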