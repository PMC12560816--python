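"""Stratified accuracy analyses and the cross-graph case-study protocol.

Link-prediction accuracy is strongly confounded by entity degree: tails with
many incoming edges are easy to predict, heads with many outgoing edges of
the query relation are hard (the graph is incomplete, so unfiltered correct
answers crowd out the expected one). The analyses here therefore slice
ranking results by degree bins, cardinality class, pattern flags and
counterpart-in-train flags, so the effect of each topological property can
be read off within strata of comparable degree.

The case study compares two graphs that share triples of a relation (e.g. a
graph and its superset built by augmenting it from extra sources): a common
10% test sample of the shared triples is held out of both graphs, and both
arms are evaluated against the same restricted candidate set, making the
MRRs directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import RankingResult, ranking_metrics, restricted_candidates, results_frame
from .graph import KnowledgeGraph, Vocab, encode_triples
from .topology import PATTERNS


def default_degree_bins(max_degree: int) -> np.ndarray:
    """Power-of-two bin edges: {1}, {2,3}, {4..7}, ... up to max_degree."""
    edges = [1]
    while edges[-1] <= max_degree:
        edges.append(edges[-1] * 2)
    return np.asarray(edges)


def degree_bin_labels(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bin label for each degree value (degree 0 maps to '0')."""
    idx = np.digitize(values, edges, right=False) - 1
    labels = np.empty(len(values), dtype=object)
    for i, v in zip(range(len(values)), values):
        if idx[i] < 0:
            labels[i] = "0"
        else:
            lo = edges[idx[i]]
            hi = edges[idx[i] + 1] - 1 if idx[i] + 1 < len(edges) else None
            labels[i] = f"{lo}" if hi == lo else (f"{lo}-{hi}" if hi else f">={lo}")
    return labels


def _check_aligned(results_df: pd.DataFrame, topo: pd.DataFrame) -> None:
    if len(results_df) != len(topo) or not (
        (results_df[["head", "relation", "tail"]].to_numpy()
         == topo[["head", "relation", "tail"]].to_numpy()).all()
    ):
        raise ValueError("results and topology tables are not aligned on the same triples")


def stratify(
    results: list[RankingResult] | pd.DataFrame,
    topo: pd.DataFrame,
    schema: str,
    bins: np.ndarray | None = None,
    ks=(1, 3, 10),
) -> pd.DataFrame:
    """Per-group ranking metrics under a grouping schema.

    Schemas: ``"degree"`` (head-bin x tail-bin on the same-relation
    degrees), ``"cardinality"``, any pattern flag name (groups flag
    true/false), or any counterpart flag column present in ``topo``.
    Group metrics are exactly :func:`ranking_metrics` restricted to the
    group; empty groups are omitted (their count is zero by construction).
    """
    rdf = results if isinstance(results, pd.DataFrame) else results_frame(results)
    _check_aligned(rdf, topo)
    df = rdf.copy()
    if schema == "degree":
        edges = bins if bins is not None else default_degree_bins(
            int(max(topo["deg_r_h"].max(), topo["deg_r_t"].max()))
        )
        df["head_bin"] = degree_bin_labels(topo["deg_r_h"].to_numpy(), edges)
        df["tail_bin"] = degree_bin_labels(topo["deg_r_t"].to_numpy(), edges)
        keys = ["head_bin", "tail_bin"]
    elif schema == "cardinality":
        df["cardinality"] = topo["cardinality"].to_numpy()
        keys = ["cardinality"]
    elif schema in topo.columns:
        df[schema] = topo[schema].to_numpy()
        keys = [schema]
    else:
        raise ValueError(f"unknown grouping schema {schema!r}")
    rows = []
    for key, grp in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        m = ranking_metrics(grp, ks=ks)
        rows.append({**dict(zip(keys, key)), "count": len(grp), **{k: v for k, v in m.items() if k != "n"}})
    return pd.DataFrame(rows)


def pattern_effect(
    results: list[RankingResult] | pd.DataFrame,
    topo: pd.DataFrame,
    pattern: str = "has_composition",
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """MRR difference (with-pattern minus without) per degree-bin cell.

    Cells where either side is empty carry NaN deltas. A positive delta in
    the low-degree cells is the signature of a pattern the models exploit.
    """
    if pattern not in PATTERNS and pattern not in topo.columns:
        raise ValueError(f"unknown pattern flag {pattern!r}")
    rdf = results if isinstance(results, pd.DataFrame) else results_frame(results)
    _check_aligned(rdf, topo)
    edges = bins if bins is not None else default_degree_bins(
        int(max(topo["deg_r_h"].max(), topo["deg_r_t"].max()))
    )
    hb = degree_bin_labels(topo["deg_r_h"].to_numpy(), edges)
    tb = degree_bin_labels(topo["deg_r_t"].to_numpy(), edges)
    flag = topo[pattern].to_numpy().astype(bool)
    inv_rank = 1.0 / rdf["rank"].to_numpy()
    rows = []
    for h_bin in pd.unique(hb):
        for t_bin in pd.unique(tb):
            cell = (hb == h_bin) & (tb == t_bin)
            if not cell.any():
                continue
            w, wo = cell & flag, cell & ~flag
            mrr_w = float(inv_rank[w].mean()) if w.any() else np.nan
            mrr_wo = float(inv_rank[wo].mean()) if wo.any() else np.nan
            rows.append(
                {
                    "head_bin": h_bin,
                    "tail_bin": t_bin,
                    "n_with": int(w.sum()),
                    "n_without": int(wo.sum()),
                    "mrr_with": mrr_w,
                    "mrr_without": mrr_wo,
                    "delta_mrr": mrr_w - mrr_wo,
                }
            )
    return pd.DataFrame(rows)


def counterpart_contrast(
    results: list[RankingResult] | pd.DataFrame,
    counterpart_flags: pd.DataFrame,
    ks=(1, 3, 10),
) -> pd.DataFrame:
    """Metrics for counterpart-in-train vs not, per pattern.

    For each of the symmetric / inverse / inference flags, reports metrics
    over the triples whose counterpart was visible during training and over
    those without one. Empty groups are reported with count 0 and NaN
    metrics.
    """
    rdf = results if isinstance(results, pd.DataFrame) else results_frame(results)
    _check_aligned(rdf, counterpart_flags)
    rows = []
    for flag in ("sym_in_train", "inv_in_train", "inf_in_train"):
        vals = counterpart_flags[flag].to_numpy().astype(bool)
        for present in (True, False):
            grp = rdf[vals == present]
            row = {"pattern": flag, "counterpart_in_train": present, "count": len(grp)}
            if len(grp):
                row.update({k: v for k, v in ranking_metrics(grp, ks=ks).items() if k != "n"})
            else:
                row.update({"mrr": np.nan, **{f"hits@{k}": np.nan for k in ks}})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-graph case study
# ---------------------------------------------------------------------------


@dataclass
class CaseStudyBundle:
    """Paired experiment inputs for one relation shared by two graphs.

    ``test_labels`` are the held-out shared triples as label tuples;
    ``test_ids_1`` / ``test_ids_2`` are the same triples in each graph's id
    space, ``candidates_1`` / ``candidates_2`` the common candidate tails in
    each id space. ``train_1`` / ``train_2`` are the graphs with the test
    triples removed.
    """

    relation_label: str
    train_1: KnowledgeGraph
    train_2: KnowledgeGraph
    test_labels: list[tuple[str, str, str]]
    test_ids_1: np.ndarray
    test_ids_2: np.ndarray
    candidates_1: np.ndarray
    candidates_2: np.ndarray


def _labels_to_ids(labels, entities: Vocab, relations: Vocab) -> np.ndarray:
    return np.asarray(
        [(entities[h], relations[r], entities[t]) for h, r, t in labels], dtype=np.int64
    ).reshape(-1, 3)


def case_study(
    g1: KnowledgeGraph,
    g2: KnowledgeGraph,
    relation: str,
    test_fraction: float = 0.10,
    seed: int = 0,
) -> CaseStudyBundle:
    """Build the paired experiment for a relation shared by two graphs.

    Shared triples are found by exact label match of head, relation and tail
    (appropriate when one graph is constructed as a superset of the other).
    A seeded ``test_fraction`` sample of them becomes the common test set,
    removed from both training graphs; the candidate set is the distinct
    tails of all shared triples of the relation.
    """
    if relation not in g1.relations or relation not in g2.relations:
        raise ValueError(f"relation {relation!r} missing from one of the graphs")
    set1 = {lab for lab in g1.triple_labels() if lab[1] == relation}
    set2 = {lab for lab in g2.triple_labels() if lab[1] == relation}
    shared = sorted(set1 & set2)
    if not shared:
        raise ValueError(f"no shared triples for relation {relation!r}")
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_fraction * len(shared))))
    test_idx = rng.choice(len(shared), size=n_test, replace=False)
    test_labels = [shared[i] for i in sorted(test_idx)]

    ids1 = _labels_to_ids(test_labels, g1.entities, g1.relations)
    ids2 = _labels_to_ids(test_labels, g2.entities, g2.relations)

    def drop(g: KnowledgeGraph, ids: np.ndarray) -> KnowledgeGraph:
        keys = encode_triples(g.triples, g.n_entities, g.n_relations)
        gone = set(encode_triples(ids, g.n_entities, g.n_relations).tolist())
        return g.subgraph(~np.isin(keys, list(gone)))

    shared_ids1 = _labels_to_ids(shared, g1.entities, g1.relations)
    shared_ids2 = _labels_to_ids(shared, g2.entities, g2.relations)
    r1, r2 = g1.relations[relation], g2.relations[relation]
    return CaseStudyBundle(
        relation_label=relation,
        train_1=drop(g1, ids1),
        train_2=drop(g2, ids2),
        test_labels=test_labels,
        test_ids_1=ids1,
        test_ids_2=ids2,
        candidates_1=restricted_candidates(shared_ids1, r1),
        candidates_2=restricted_candidates(shared_ids2, r2),
    )
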