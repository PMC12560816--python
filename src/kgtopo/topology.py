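"""Per-triple topological statistics for multi-relational graphs.

For a triple (h, r, t) in a graph G the quantities computed here are

* ``deg_h``   — head out-degree: number of distinct tails reachable from h
  under any relation; ``deg_r_h`` restricts to relation r.
* ``deg_t``   — tail in-degree: number of distinct heads pointing to t under
  any relation; ``deg_r_t`` restricts to relation r.
* edge cardinality — 1:1 / 1:M / M:1 / M:M from whether the same-relation
  degrees equal or exceed 1.
* four edge patterns:
  - symmetric:   h != t and (t, r, h) in G,
  - inference:   some r' != r with (h, r', t) in G,
  - inverse:     some r' != r with (t, r', h) in G,
  - composition: a directed 2-path h -> n -> t with n not in {h, t}.

All quantities are defined per triple, not per relation type: a relation may
contain a mix of, say, symmetric and asymmetric triples, and averaging over
the relation would wash the signal out. Detection is sparse (per-relation
boolean adjacency, matrix products for 2-paths) and is verified against a
brute-force enumeration oracle in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .graph import KnowledgeGraph, encode_triples

CARDINALITIES = ("1:1", "1:M", "M:1", "M:M")
PATTERNS = ("is_symmetric", "has_inference", "has_inverse", "has_composition")


def _pair_keys(heads: np.ndarray, tails: np.ndarray, n_entities: int) -> np.ndarray:
    return heads.astype(np.int64) * n_entities + tails.astype(np.int64)


def _member(keys: np.ndarray, universe_sorted: np.ndarray) -> np.ndarray:
    """Boolean membership of ``keys`` in a sorted key array."""
    pos = np.searchsorted(universe_sorted, keys)
    pos_c = np.minimum(pos, len(universe_sorted) - 1)
    return (pos < len(universe_sorted)) & (universe_sorted[pos_c] == keys)


def _count_map(keys: np.ndarray):
    """Sorted unique keys and their multiplicities, for vectorised lookup."""
    uniq, counts = np.unique(keys, return_counts=True)

    def lookup(q: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(uniq, q)
        pos_c = np.minimum(pos, len(uniq) - 1) if len(uniq) else np.zeros_like(pos)
        found = (pos < len(uniq)) & (uniq[pos_c] == q) if len(uniq) else np.zeros(len(q), bool)
        out = np.zeros(len(q), dtype=np.int64)
        out[found] = counts[pos_c[found]]
        return out

    return lookup


def _any_rel_adjacency(triples: np.ndarray, n_entities: int) -> sparse.csr_matrix:
    """Binary adjacency over distinct (h, t) pairs, any relation."""
    pairs = np.unique(_pair_keys(triples[:, 0], triples[:, 2], n_entities))
    rows, cols = pairs // n_entities, pairs % n_entities
    return sparse.csr_matrix(
        (np.ones(len(pairs), dtype=np.int64), (rows, cols)),
        shape=(n_entities, n_entities),
    )


# ---------------------------------------------------------------------------
# Degrees and cardinality
# ---------------------------------------------------------------------------


def triple_degrees(g: KnowledgeGraph, triples: np.ndarray | None = None) -> pd.DataFrame:
    """The four degree quantities for each triple, measured on graph *g*.

    ``triples`` defaults to the graph's own triples; passing, say, test
    triples with a training graph measures the degrees the model actually
    saw. Degrees count distinct neighbouring entities, not edges.
    """
    if g.n_triples == 0:
        raise ValueError("graph is empty")
    T = g.triples
    q = T if triples is None else np.asarray(triples, dtype=np.int64).reshape(-1, 3)
    n_e, n_r = g.n_entities, g.n_relations

    A = _any_rel_adjacency(T, n_e)
    out_deg = np.asarray(A.sum(axis=1)).ravel()
    in_deg = np.asarray(A.sum(axis=0)).ravel()
    # same-relation degrees: distinct tails per (h, r), distinct heads per (r, t)
    hr = _count_map(T[:, 0] * n_r + T[:, 1])
    rt = _count_map(T[:, 2] * n_r + T[:, 1])
    return pd.DataFrame(
        {
            "head": q[:, 0],
            "relation": q[:, 1],
            "tail": q[:, 2],
            "deg_h": out_deg[q[:, 0]],
            "deg_t": in_deg[q[:, 2]],
            "deg_r_h": hr(q[:, 0] * n_r + q[:, 1]),
            "deg_r_t": rt(q[:, 2] * n_r + q[:, 1]),
        }
    )


def edge_cardinality(deg_r_h, deg_r_t):
    """Cardinality class from the same-relation degrees.

    (1,1) -> 1:1; (>1,1) -> 1:M; (1,>1) -> M:1; (>1,>1) -> M:M. The class
    is written tail:head, so 1:M means the head fans out to many tails each
    of which has a single same-relation in-edge.
    """
    h = np.asarray(deg_r_h)
    t = np.asarray(deg_r_t)
    scalar = h.ndim == 0
    h, t = np.atleast_1d(h), np.atleast_1d(t)
    if (h < 1).any() or (t < 1).any():
        raise ValueError("degrees must be >= 1 for triples present in the graph")
    out = np.where(h == 1, np.where(t == 1, "1:1", "M:1"), np.where(t == 1, "1:M", "M:M"))
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# Edge patterns
# ---------------------------------------------------------------------------


def detect_edge_patterns(
    g: KnowledgeGraph,
    pattern_graph: KnowledgeGraph | None = None,
    relation_pairs: bool = True,
) -> pd.DataFrame:
    """Pattern flags and composition counts for every triple of *g*.

    Counterpart edges and 2-paths are sought in ``pattern_graph`` (default:
    *g* itself; pass the training graph to restrict to what a model saw).
    Columns: the four boolean flags, ``n_comp_intermediates`` (distinct
    intermediate entities n), and ``n_comp_relpairs`` (distinct (r1, r2)
    pairs over all h->n->t paths; skipped when ``relation_pairs=False``).
    """
    if g.n_triples == 0:
        raise ValueError("graph is empty")
    pg = pattern_graph if pattern_graph is not None else g
    q, T = g.triples, pg.triples
    n_e, n_r = pg.n_entities, pg.n_relations

    trip_keys = np.sort(encode_triples(T, n_e, n_r))
    pair_count = _count_map(_pair_keys(T[:, 0], T[:, 2], n_e))

    h, r, t = q[:, 0], q[:, 1], q[:, 2]
    fwd_in_pg = _member(encode_triples(q, n_e, n_r), trip_keys)
    rev_same = _member(encode_triples(q[:, [2, 1, 0]], n_e, n_r), trip_keys)

    is_symmetric = (h != t) & rev_same
    has_inference = (pair_count(_pair_keys(h, t, n_e)) - fwd_in_pg.astype(int)) >= 1
    has_inverse = (pair_count(_pair_keys(t, h, n_e)) - rev_same.astype(int)) >= 1

    # distinct intermediates: (A @ A)[h, t] counts n with h->n and n->t,
    # then remove the disallowed n = h (needs a self-loop at h plus h->t)
    # and n = t (h->t plus a self-loop at t)
    A = _any_rel_adjacency(T, n_e)
    A2 = (A @ A).tocsr()
    n_int = np.asarray(A2[h, t]).ravel().astype(np.int64)
    loop = np.zeros(n_e, dtype=np.int64)
    loop_ids = T[T[:, 0] == T[:, 2], 0]
    loop[loop_ids] = 1
    direct = np.asarray(A[h, t]).ravel().astype(np.int64)
    n_int -= direct * (loop[h] + loop[t])
    # for a self-loop query (h == t) the two corrections collapse into one
    selfq = h == t
    if selfq.any():
        n_int[selfq] = np.asarray(A2[h[selfq], t[selfq]]).ravel() - loop[h[selfq]]

    out = pd.DataFrame(
        {
            "head": h,
            "relation": r,
            "tail": t,
            "is_symmetric": is_symmetric,
            "has_inference": has_inference,
            "has_inverse": has_inverse,
            "has_composition": n_int >= 1,
            "n_comp_intermediates": n_int,
        }
    )
    if relation_pairs:
        out["n_comp_relpairs"] = _composition_relpair_counts(q, T, n_e, n_r, A)
    return out


def _pair_relation_index(T: np.ndarray, n_e: int):
    """Sorted (pair_key -> slice of relations) index over the triples."""
    keys = _pair_keys(T[:, 0], T[:, 2], n_e)
    order = np.argsort(keys, kind="stable")
    sk, rels = keys[order], T[order, 1]
    starts = np.searchsorted(sk, np.unique(sk))
    uniq = sk[starts]
    bounds = np.append(starts, len(sk))
    return uniq, bounds, rels


def _composition_relpair_counts(q, T, n_e, n_r, A: sparse.csr_matrix) -> np.ndarray:
    """Distinct (r1, r2) pairs over 2-paths h->n->t, per query triple."""
    uniq, bounds, rels = _pair_relation_index(T, n_e)

    def pair_rels(a: int, b: int) -> np.ndarray:
        k = a * n_e + b
        i = np.searchsorted(uniq, k)
        if i == len(uniq) or uniq[i] != k:
            return np.empty(0, dtype=np.int64)
        return rels[bounds[i] : bounds[i + 1]]

    Acsr = A.tocsr()
    Acsc = A.tocsc()
    counts = np.zeros(len(q), dtype=np.int64)
    for i, (h, _, t) in enumerate(q):
        outs = Acsr.indices[Acsr.indptr[h] : Acsr.indptr[h + 1]]
        ins = Acsc.indices[Acsc.indptr[t] : Acsc.indptr[t + 1]]
        mids = np.intersect1d(outs, ins, assume_unique=True)
        mids = mids[(mids != h) & (mids != t)]
        if len(mids) == 0:
            continue
        pairs: set[tuple[int, int]] = set()
        for n in mids:
            r1s, r2s = pair_rels(h, n), pair_rels(n, t)
            pairs.update((int(r1), int(r2)) for r1 in r1s for r2 in r2s)
        counts[i] = len(pairs)
    return counts


def triple_topology(
    g: KnowledgeGraph,
    pattern_graph: KnowledgeGraph | None = None,
    relation_pairs: bool = True,
) -> pd.DataFrame:
    """Full per-triple record: degrees, cardinality class and pattern flags."""
    deg = triple_degrees(pattern_graph if pattern_graph is not None else g, g.triples)
    pat = detect_edge_patterns(g, pattern_graph, relation_pairs=relation_pairs)
    out = deg.copy()
    # degrees measured on an external graph (e.g. test triples against train)
    # can be 0; classify cardinality as if the query edge itself were present
    out["cardinality"] = edge_cardinality(
        np.maximum(deg["deg_r_h"].to_numpy(), 1), np.maximum(deg["deg_r_t"].to_numpy(), 1)
    )
    for col in pat.columns[3:]:
        out[col] = pat[col].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass
class PatternSummary:
    """Census of pattern and cardinality fractions over a triple set.

    Pattern fractions can sum above 1 (one triple may satisfy several
    patterns); cardinality fractions sum to 1. ``none`` is the fraction of
    triples with none of the four patterns.
    """

    n_triples: int
    pattern_fractions: dict[str, float]
    none_fraction: float
    cardinality_fractions: dict[str, float]
    pattern_counts: dict[str, int] = field(default_factory=dict)

    def to_frame(self, decimals: int = 3) -> pd.DataFrame:
        row = {k.replace("is_", "").replace("has_", ""): round(v, decimals)
               for k, v in self.pattern_fractions.items()}
        row["none"] = round(self.none_fraction, decimals)
        row.update({c: round(self.cardinality_fractions.get(c, 0.0), decimals)
                    for c in CARDINALITIES})
        row["n_triples"] = self.n_triples
        return pd.DataFrame([row])


def pattern_summary(g: KnowledgeGraph, pattern_graph: KnowledgeGraph | None = None) -> PatternSummary:
    """Fractions of triples with each pattern and cardinality class."""
    topo = triple_topology(g, pattern_graph, relation_pairs=False)
    n = len(topo)
    fracs = {p: float(topo[p].mean()) for p in PATTERNS}
    counts = {p: int(topo[p].sum()) for p in PATTERNS}
    none = float((~topo[list(PATTERNS)].any(axis=1)).mean())
    card = topo["cardinality"].value_counts(normalize=True).to_dict()
    return PatternSummary(n, fracs, none, {c: float(card.get(c, 0.0)) for c in CARDINALITIES}, counts)


def aggregate_by_relation(topo: pd.DataFrame, majority_threshold: float = 0.95) -> pd.DataFrame:
    """Per-relation pattern fractions and a predominant-pattern label.

    The label is the pattern whose fraction exceeds ``majority_threshold``
    (the highest such fraction if several patterns co-occur above it), else
    ``"mixed"``. Relation-level labels lose information — the per-triple
    table is the primary product — but they allow comparison with studies
    that classify whole relation types.
    """
    if not 0.5 < majority_threshold <= 1:
        raise ValueError("majority_threshold must lie in (0.5, 1]")
    rows = []
    for rel, grp in topo.groupby("relation"):
        fr = {p: float(grp[p].mean()) for p in PATTERNS}
        above = {p: v for p, v in fr.items() if v > majority_threshold}
        label = max(above, key=above.get).replace("is_", "").replace("has_", "") if above else "mixed"
        rows.append({"relation": rel, "n_triples": len(grp), **fr, "predominant": label})
    return pd.DataFrame(rows)


def metapath_composition_counts(g: KnowledgeGraph, focus_relation: int) -> pd.DataFrame:
    """Composition path census for the triples of one relation.

    For every triple (h, focus, t) that has composition, enumerate the
    2-paths h -> n -> t and accumulate, per intermediate entity type and per
    relation pair (r1, r2): the number of path instances and the number of
    distinct intermediates. Rows: (intermediate_type, r1, r2, n_paths,
    n_intermediates).
    """
    if g.entity_types is None:
        raise ValueError("entity types are required; load a type file first")
    T = g.triples
    n_e = g.n_entities
    A = _any_rel_adjacency(T, n_e)
    uniq, bounds, rels = _pair_relation_index(T, n_e)

    def pair_rels(a, b):
        k = a * n_e + b
        i = np.searchsorted(uniq, k)
        if i == len(uniq) or uniq[i] != k:
            return np.empty(0, dtype=np.int64)
        return rels[bounds[i] : bounds[i + 1]]

    Acsr, Acsc = A.tocsr(), A.tocsc()
    acc: dict[tuple[str, int, int], list[int]] = {}
    for h, _, t in T[T[:, 1] == focus_relation]:
        outs = Acsr.indices[Acsr.indptr[h] : Acsr.indptr[h + 1]]
        ins = Acsc.indices[Acsc.indptr[t] : Acsc.indptr[t + 1]]
        mids = np.intersect1d(outs, ins, assume_unique=True)
        for n in mids[(mids != h) & (mids != t)]:
            typ = str(g.entity_types[n])
            for r1 in pair_rels(h, n):
                for r2 in pair_rels(n, t):
                    key = (typ, int(r1), int(r2))
                    if key in acc:
                        acc[key][0] += 1
                        acc[key][1].add(int(n))  # type: ignore[union-attr]
                    else:
                        acc[key] = [1, {int(n)}]  # type: ignore[list-item]
    rows = [
        {"intermediate_type": typ, "r1": r1, "r2": r2, "n_paths": c, "n_intermediates": len(ns)}
        for (typ, r1, r2), (c, ns) in acc.items()
    ]
    cols = ["intermediate_type", "r1", "r2", "n_paths", "n_intermediates"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols).sort_values("n_paths", ascending=False, ignore_index=True)


def counterpart_in_train(test_triples: np.ndarray, train: KnowledgeGraph) -> pd.DataFrame:
    """Whether each test triple's pattern counterpart was seen in training.

    ``sym_in_train``: (t, r, h) in train; ``inv_in_train``: some r' != r with
    (t, r', h) in train; ``inf_in_train``: some r' != r with (h, r', t) in
    train. Counterparts visible during training make the prediction easier —
    a leakage-like effect that analyses must separate out.
    """
    q = np.asarray(test_triples, dtype=np.int64).reshape(-1, 3)
    n_e, n_r = train.n_entities, train.n_relations
    T = train.triples
    keys = np.sort(encode_triples(T, n_e, n_r))
    if _member(encode_triples(q, n_e, n_r), keys).any():
        raise ValueError("test triples overlap the training graph")
    pair_count = _count_map(_pair_keys(T[:, 0], T[:, 2], n_e))
    h, r, t = q[:, 0], q[:, 1], q[:, 2]
    rev_same = _member(encode_triples(q[:, [2, 1, 0]], n_e, n_r), keys)
    return pd.DataFrame(
        {
            "head": h,
            "relation": r,
            "tail": t,
            "sym_in_train": (h != t) & rev_same,
            "inv_in_train": (pair_count(_pair_keys(t, h, n_e)) - rev_same.astype(int)) >= 1,
            "inf_in_train": pair_count(_pair_keys(h, t, n_e)) >= 1,
        }
    )
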