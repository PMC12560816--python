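"""Shared fixtures and the brute-force topology oracle.

The oracle applies the degree / cardinality / pattern definitions literally
with nested loops over the triple list. It is deliberately independent of
the sparse implementation so the two can be compared on random graphs.
"""

from __future__ import annotations

import numpy as np
import pytest

from kgtopo.graph import KnowledgeGraph, Vocab


def make_graph(triples, n_entities=None, n_relations=None, types=None) -> KnowledgeGraph:
    """Build a KnowledgeGraph from integer triple tuples."""
    triples = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
    n_e = n_entities or int(triples[:, [0, 2]].max()) + 1
    n_r = n_relations or int(triples[:, 1].max()) + 1
    ev, rv = Vocab(), Vocab()
    for i in range(n_e):
        ev.add(f"E{i}")
    for i in range(n_r):
        rv.add(f"r{i}")
    tarr = None
    if types is not None:
        tarr = np.asarray(types, dtype=object)
    return KnowledgeGraph(triples, ev, rv, entity_types=tarr)


def random_graph(rng: np.random.Generator, max_entities=15, max_relations=4,
                 max_triples=200, self_loops=True) -> KnowledgeGraph:
    n_e = int(rng.integers(2, max_entities + 1))
    n_r = int(rng.integers(1, max_relations + 1))
    n = int(rng.integers(1, max_triples + 1))
    h = rng.integers(0, n_e, n)
    r = rng.integers(0, n_r, n)
    t = rng.integers(0, n_e, n)
    trip = np.unique(np.stack([h, r, t], axis=1), axis=0)
    if not self_loops:
        trip = trip[trip[:, 0] != trip[:, 2]]
        if len(trip) == 0:
            trip = np.array([[0, 0, 1]])
    return make_graph(trip, n_entities=n_e, n_relations=n_r)


def oracle_topology(triples, pattern_triples=None) -> list[dict]:
    """Literal nested-loop evaluation of the degree and pattern definitions."""
    q = [tuple(map(int, x)) for x in np.asarray(triples).reshape(-1, 3)]
    G = q if pattern_triples is None else [tuple(map(int, x))
                                           for x in np.asarray(pattern_triples).reshape(-1, 3)]
    Gset = set(G)
    out = []
    for h, r, t in q:
        deg_h = len({t2 for (h2, _, t2) in G if h2 == h})
        deg_t = len({h2 for (h2, _, t2) in G if t2 == t})
        deg_r_h = len({t2 for (h2, r2, t2) in G if h2 == h and r2 == r})
        deg_r_t = len({h2 for (h2, r2, t2) in G if t2 == t and r2 == r})
        is_symmetric = h != t and (t, r, h) in Gset
        has_inference = any(r2 != r for (h2, r2, t2) in G if h2 == h and t2 == t)
        has_inverse = any(r2 != r for (h2, r2, t2) in G if h2 == t and t2 == h)
        mids, relpairs = set(), set()
        for (a, r1, n) in G:
            if a != h or n == h or n == t:
                continue
            for (n2, r2, b) in G:
                if n2 == n and b == t:
                    mids.add(n)
                    relpairs.add((r1, r2))
        out.append(
            dict(
                head=h, relation=r, tail=t,
                deg_h=deg_h, deg_t=deg_t, deg_r_h=deg_r_h, deg_r_t=deg_r_t,
                is_symmetric=is_symmetric, has_inference=has_inference,
                has_inverse=has_inverse, has_composition=len(mids) > 0,
                n_comp_intermediates=len(mids), n_comp_relpairs=len(relpairs),
            )
        )
    return out


@pytest.fixture
def degree_toy() -> KnowledgeGraph:
    """G = {(A,r1,B), (A,r1,C), (D,r1,B), (A,r2,B)} with A,B,C,D = 0..3."""
    return make_graph([(0, 0, 1), (0, 0, 2), (3, 0, 1), (0, 1, 1)])


@pytest.fixture
def composition_toy() -> KnowledgeGraph:
    """A -r1-> N -r2-> B alongside the direct edge A -r3-> B."""
    return make_graph([(0, 0, 1), (1, 1, 2), (0, 2, 2)])
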