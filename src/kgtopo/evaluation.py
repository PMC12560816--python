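"""Filtered tail-prediction ranking and its summary metrics.

The evaluation protocol: for each test triple (h, r, t), score the query
(h, r, ?) against a candidate set (all entities by default), mask out the
scores of other tails t' known to be true — i.e. (h, r, t') present in the
filter graph — and record the rank of the true tail among the remaining
candidates. Ties are resolved by the mean-rank rule by default (the rank is
averaged over the tied block), which is unbiased between the optimistic and
pessimistic conventions.

Metrics: MRR (mean reciprocal rank), Hits@K (fraction of queries with rank
<= K), and the demixing rate — the fraction of queries whose top-ranked
prediction has the entity type the relation is supposed to target, a basic
sanity check on whether a model has learned the graph's type schema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import KnowledgeGraph


@dataclass
class RankingResult:
    """Outcome of one filtered (h, r, ?) query."""

    head: int
    relation: int
    tail: int
    rank: float  # >= 1; fractional under the mean-rank tie rule
    n_candidates: int  # candidates remaining after masking
    top_entity: int  # best-ranked candidate (the prediction)

    @property
    def query(self) -> tuple[int, int]:
        return (self.head, self.relation)


def results_frame(results: list[RankingResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def _true_tails_index(filter_graph: KnowledgeGraph):
    """(h, r) -> sorted array of known-true tails."""
    T = filter_graph.triples
    keys = T[:, 0] * filter_graph.n_relations + T[:, 1]
    order = np.argsort(keys, kind="stable")
    sk, tails = keys[order], T[order, 2]
    uniq, starts = np.unique(sk, return_index=True)
    bounds = np.append(starts, len(sk))

    def lookup(h: int, r: int) -> np.ndarray:
        k = h * filter_graph.n_relations + r
        i = np.searchsorted(uniq, k)
        if i == len(uniq) or uniq[i] != k:
            return np.empty(0, dtype=np.int64)
        return tails[bounds[i] : bounds[i + 1]]

    return lookup


def _rank_with_ties(scores: np.ndarray, true_idx: int, tie_rule: str) -> float:
    s_true = scores[true_idx]
    higher = int((scores > s_true).sum())
    tied = int((scores == s_true).sum())  # includes the true tail itself
    if tie_rule == "optimistic":
        return float(higher + 1)
    if tie_rule == "pessimistic":
        return float(higher + tied)
    return higher + (tied + 1) / 2.0  # mean rank over the tied block


def filtered_tail_ranks(
    model,
    test_triples: np.ndarray,
    filter_graph: KnowledgeGraph | None,
    candidates: np.ndarray | None = None,
    tie_rule: str = "mean",
) -> list[RankingResult]:
    """Rank the true tail of each test triple among candidate entities.

    ``model`` is anything with a ``score_tails(h, r, candidates)`` method.
    ``filter_graph`` supplies the triples whose tails are masked (use the
    union of all splits for the standard filtered protocol; ``None`` gives
    unfiltered ranks). The true tail itself is never masked. A candidate set
    that excludes a query's true tail raises a ``ValueError`` for that query.
    """
    if tie_rule not in ("mean", "optimistic", "pessimistic"):
        raise ValueError("tie_rule must be mean, optimistic or pessimistic")
    test = np.asarray(test_triples, dtype=np.int64).reshape(-1, 3)
    lookup = _true_tails_index(filter_graph) if filter_graph is not None else None
    results: list[RankingResult] = []
    for h, r, t in test:
        cand = (np.arange(model.n_entities) if candidates is None
                else np.asarray(candidates, dtype=np.int64))
        where_true = np.flatnonzero(cand == t)
        if len(where_true) == 0:
            raise ValueError(f"candidate set excludes the true tail of ({h}, {r}, {t})")
        if lookup is not None:
            known = lookup(int(h), int(r))
            mask = ~np.isin(cand, known) | (cand == t)
            cand = cand[mask]
        scores = model.score_tails(int(h), int(r), cand)
        true_idx = int(np.flatnonzero(cand == t)[0])
        rank = _rank_with_ties(scores, true_idx, tie_rule)
        results.append(
            RankingResult(int(h), int(r), int(t), rank, len(cand), int(cand[np.argmax(scores)]))
        )
    return results


def ranking_metrics(results: list[RankingResult] | pd.DataFrame, ks=(1, 3, 10)) -> dict[str, float]:
    """MRR and Hits@K over a set of ranking results."""
    ranks = (results["rank"].to_numpy() if isinstance(results, pd.DataFrame)
             else np.array([r.rank for r in results]))
    if len(ranks) == 0:
        raise ValueError("no ranking results")
    out = {"mrr": float((1.0 / ranks).mean()), "n": int(len(ranks))}
    for k in ks:
        out[f"hits@{k}"] = float((ranks <= k).mean())
    return out


def demixing_rate(
    results: list[RankingResult],
    entity_types: np.ndarray,
    target_type: str,
) -> float:
    """Fraction of queries whose top-1 prediction has the target entity type."""
    if entity_types is None:
        raise ValueError("entity types are required for demixing")
    if not results:
        raise ValueError("no ranking results")
    hits = sum(1 for r in results if str(entity_types[r.top_entity]) == target_type)
    return hits / len(results)


def restricted_candidates(shared_triples: np.ndarray, relation: int) -> np.ndarray:
    """Distinct tail entities of a relation's shared triples.

    Used by the cross-graph case study: evaluating both graphs against this
    common candidate set makes their MRRs directly comparable.
    """
    shared = np.asarray(shared_triples, dtype=np.int64).reshape(-1, 3)
    tails = np.unique(shared[shared[:, 1] == relation, 2])
    if len(tails) == 0:
        raise ValueError(f"no shared triples for relation {relation}")
    return tails


def expected_random_mrr(n_candidates: int) -> float:
    """Expected MRR of a uniformly random ranking over n candidates.

    The true tail's rank is uniform on 1..n, so E[1/rank] = H_n / n with
    H_n the n-th harmonic number.
    """
    return float(np.sum(1.0 / np.arange(1, n_candidates + 1)) / n_candidates)


def prediction_export(
    model,
    test_triples: np.ndarray,
    graph: KnowledgeGraph,
    filter_graph: KnowledgeGraph | None = None,
    top_n: int = 10,
) -> pd.DataFrame:
    """Top-N ranked entity labels with scores for each test query."""
    test = np.asarray(test_triples, dtype=np.int64).reshape(-1, 3)
    lookup = _true_tails_index(filter_graph) if filter_graph is not None else None
    rows = []
    labels = graph.entities.labels
    rels = graph.relations.labels
    for h, r, t in test:
        cand = np.arange(model.n_entities)
        if lookup is not None:
            known = lookup(int(h), int(r))
            cand = cand[~np.isin(cand, known) | (cand == t)]
        scores = model.score_tails(int(h), int(r), cand)
        top = np.argsort(-scores, kind="stable")[:top_n]
        for j, i in enumerate(top, start=1):
            rows.append(
                {
                    "head": labels[h],
                    "relation": rels[r],
                    "true_tail": labels[t],
                    "rank": j,
                    "prediction": labels[cand[i]],
                    "score": float(scores[i]),
                }
            )
    return pd.DataFrame(rows)
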