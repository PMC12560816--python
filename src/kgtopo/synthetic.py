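"""Synthetic multi-relational graphs with planted, ledgered edge patterns.

The generator emulates the structure of biomedical knowledge graphs at small
scale: several entity types (gene/drug/disease-like blocks), a heavy-tailed
degree distribution, and controllable frequencies of the four edge patterns
(symmetric, inverse, inference, composition). Every planted pattern instance
is recorded in a ledger of the concrete triples involved, so detectors and
downstream analyses can be validated against known ground truth.

Planting adds counterpart edges to independently sampled base edges rather
than rewiring, so base-edge statistics stay interpretable. Inverse and
inference counterparts draw fresh relation ids from a reserved pool (an
inverse under the same relation would be symmetry). In ``clean_mode`` any
edge whose insertion would create a pattern instance beyond the ones being
planted is rejected and resampled, so detector output equals the ledger
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import SPLITS, KnowledgeGraph, Vocab, _largest_remainder_sizes


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic graph.

    ``degree_skew`` is the exponent of the power-law endpoint weights
    (0 = uniform; around 0.8 gives the mild hub structure typical of curated
    biomedical graphs). Planting rates are per base edge. ``entity_types``
    maps type name to its proportion of entities (contiguous id blocks).
    ``n_extra_relations`` is the reserved pool for inverse/inference
    counterpart relations.
    """

    n_entities: int = 300
    n_relations: int = 4
    n_base_edges: int = 800
    degree_skew: float = 0.8
    p_sym: float = 0.0
    p_inv: float = 0.0
    p_inf: float = 0.0
    p_comp: float = 0.0
    entity_types: dict[str, float] = field(
        default_factory=lambda: {"gene": 0.5, "drug": 0.3, "disease": 0.2}
    )
    n_extra_relations: int = 4
    clean_mode: bool = False
    max_retries: int = 100
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_sym", "p_inv", "p_inf", "p_comp"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.entity_types.values()) - 1.0) > 1e-9:
            raise ValueError("entity type proportions must sum to 1")
        if self.n_base_edges > self.n_entities * (self.n_entities - 1) * self.n_relations:
            raise ValueError("more base edges requested than distinct triples exist")
        if (self.p_inv or self.p_inf) and self.n_extra_relations < 1:
            raise ValueError("inverse/inference planting needs a reserved relation pool")


@dataclass
class SyntheticLedger:
    """Ground-truth planted instances, as the concrete triples involved."""

    symmetric: list[tuple[tuple, tuple]] = field(default_factory=list)
    inverse: list[tuple[tuple, tuple]] = field(default_factory=list)
    inference: list[tuple[tuple, tuple]] = field(default_factory=list)
    composition: list[tuple[tuple, tuple, tuple]] = field(default_factory=list)

    def all_triples(self) -> set[tuple]:
        out: set[tuple] = set()
        for group in (self.symmetric, self.inverse, self.inference, self.composition):
            for inst in group:
                out.update(inst)
        return out

    def expected_flags(self) -> dict[str, set[tuple]]:
        """Triples that each detector flag must fire on, implied by the ledger."""
        flags: dict[str, set[tuple]] = {
            "is_symmetric": set(),
            "has_inverse": set(),
            "has_inference": set(),
            "has_composition": set(),
        }
        for a, b in self.symmetric:
            flags["is_symmetric"].update((a, b))
        for a, b in self.inverse:
            flags["has_inverse"].update((a, b))
        for a, b in self.inference:
            flags["has_inference"].update((a, b))
        for base, _, _ in self.composition:
            flags["has_composition"].add(base)
        return flags


class _GraphState:
    """Incremental edge store with the lookups clean-mode validation needs."""

    def __init__(self) -> None:
        self.triples: list[tuple[int, int, int]] = []
        self.tripleset: set[tuple[int, int, int]] = set()
        self.pair_rels: dict[tuple[int, int], set[int]] = {}
        self.out_nbrs: dict[int, set[int]] = {}
        self.in_nbrs: dict[int, set[int]] = {}

    def has_pair(self, a: int, b: int) -> bool:
        return (a, b) in self.pair_rels

    def add(self, h: int, r: int, t: int) -> None:
        self.triples.append((h, r, t))
        self.tripleset.add((h, r, t))
        self.pair_rels.setdefault((h, t), set()).add(r)
        self.out_nbrs.setdefault(h, set()).add(t)
        self.in_nbrs.setdefault(t, set()).add(h)

    def new_patterns(self, h: int, r: int, t: int) -> set[str]:
        """Pattern kinds that inserting (h, r, t) would create or extend."""
        created: set[str] = set()
        rels_rev = self.pair_rels.get((t, h), set())
        rels_fwd = self.pair_rels.get((h, t), set())
        if h != t and r in rels_rev:
            created.add("sym")
        if rels_fwd - {r}:
            created.add("inf")
        if rels_rev - {r}:
            created.add("inv")
        # composition: the new edge as the direct edge of an existing 2-path,
        # or as a path edge completing a 2-path alongside an existing direct edge
        mids = self.out_nbrs.get(h, set()) & self.in_nbrs.get(t, set())
        if mids - {h, t}:
            created.add("comp")
        for x in self.in_nbrs.get(h, set()):
            if x != h and x != t and h != x and self.has_pair(x, t) and h != t:
                created.add("comp_other")
        for y in self.out_nbrs.get(t, set()):
            if y != t and y != h and self.has_pair(h, y) and t != h:
                created.add("comp_other")
        return created


def _endpoint_weights(n: int, skew: float, rng: np.random.Generator) -> np.ndarray:
    ranks = rng.permutation(n) + 1.0
    w = ranks ** (-skew)
    return w / w.sum()


def generate(config: SyntheticConfig) -> tuple[KnowledgeGraph, SyntheticLedger]:
    """Generate a graph and the ledger of its planted pattern instances.

    Base edges (h != t) are sampled without replacement with power-law
    endpoint weights; each base edge independently receives a symmetric,
    inverse, inference and/or composition counterpart with the configured
    rates. Same seed, same output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_e, n_rb = config.n_entities, config.n_relations
    state = _GraphState()
    ledger = SyntheticLedger()

    head_w = _endpoint_weights(n_e, config.degree_skew, rng)
    tail_w = _endpoint_weights(n_e, config.degree_skew, rng)
    clean = config.clean_mode

    def try_add(h, r, t, allowed: set[str]) -> bool:
        if (h, r, t) in state.tripleset:
            return False
        if clean and not state.new_patterns(h, r, t) <= allowed:
            return False
        state.add(h, r, t)
        return True

    def sample_base() -> tuple[int, int, int]:
        for _ in range(config.max_retries):
            h = int(rng.choice(n_e, p=head_w))
            t = int(rng.choice(n_e, p=tail_w))
            r = int(rng.integers(n_rb))
            if h == t:
                continue
            if try_add(h, r, t, allowed=set()):
                return h, r, t
        raise RuntimeError(
            "could not place a base edge within the retry budget; "
            "the configuration is too dense for clean_mode"
        )

    reserved = list(range(n_rb, n_rb + config.n_extra_relations))

    for _ in range(config.n_base_edges):
        h, r, t = sample_base()
        base = (h, r, t)
        if rng.random() < config.p_sym:
            if try_add(t, r, h, allowed={"sym"}):
                ledger.symmetric.append((base, (t, r, h)))
        if rng.random() < config.p_inv:
            for _ in range(config.max_retries):
                rp = int(rng.choice(reserved))
                if try_add(t, rp, h, allowed={"inv"}):
                    ledger.inverse.append((base, (t, rp, h)))
                    break
        if rng.random() < config.p_inf:
            for _ in range(config.max_retries):
                rp = int(rng.choice(reserved))
                if try_add(h, rp, t, allowed={"inf"}):
                    ledger.inference.append((base, (h, rp, t)))
                    break
        if rng.random() < config.p_comp:
            for _ in range(config.max_retries):
                n = int(rng.integers(n_e))
                if n == h or n == t:
                    continue
                r1, r2 = int(rng.integers(n_rb)), int(rng.integers(n_rb))
                e1, e2 = (h, r1, n), (n, r2, t)
                if e1 in state.tripleset or e2 in state.tripleset:
                    continue
                if clean and not _comp_plant_ok(state, base, e1, e2):
                    continue
                if not clean:
                    state.add(*e1)
                    state.add(*e2)
                ledger.composition.append((base, e1, e2))
                break
            # on retry exhaustion the counterpart is simply not planted;
            # realized rates are validated statistically, not per edge

    triples = np.asarray(state.triples, dtype=np.int64)
    entities = Vocab()
    for i in range(n_e):
        entities.add(f"E{i:05d}")
    relations = Vocab()
    for r in range(n_rb):
        relations.add(f"rel{r}")
    for r in reserved:
        relations.add(f"xrel{r - n_rb}")

    sizes = _largest_remainder_sizes(n_e, tuple(config.entity_types.values()))  # type: ignore[arg-type]
    types = np.empty(n_e, dtype=object)
    start = 0
    for (name, _), k in zip(config.entity_types.items(), sizes):
        types[start : start + k] = name
        start += k
    g = KnowledgeGraph(triples, entities, relations, entity_types=types)
    return g, ledger


def _comp_plant_ok(state: _GraphState, base, e1, e2) -> bool:
    """Clean-mode check: planting the path e1, e2 creates exactly one
    composition instance, on the base edge, and nothing else.

    Adds e1 and e2 to the state when the check passes. Requires the base
    edge to be the only direct edge on its (h, t) pair — otherwise every
    co-located inference edge would silently gain an un-ledgered
    composition flag.
    """
    h, r, t = base
    n = e1[2]
    if state.pair_rels.get((h, t), set()) != {r}:
        return False
    if state.new_patterns(*e1):
        return False
    state.add(*e1)
    ok = (
        not (state.pair_rels.get((n, t), set()))  # e2 duplicates no pair -> no inf
        and not (state.pair_rels.get((t, n), set()))  # no inv/sym with reverse pair
        and not ((state.out_nbrs.get(n, set()) & state.in_nbrs.get(t, set())) - {n, t})
        # backward completions: direct (x, ., t) gaining comp via x -> n -> t
        and {x for x in state.in_nbrs.get(n, set()) if x not in (n, t) and state.has_pair(x, t)}
        == {h}
        # forward completions: direct (n, ., y) gaining comp via n -> t -> y
        and not {y for y in state.out_nbrs.get(t, set()) if y != t and state.has_pair(n, y)}
    )
    if not ok:
        _rollback(state, e1)
        return False
    state.add(*e2)
    return True


def _rollback(state: _GraphState, triple: tuple[int, int, int]) -> None:
    h, r, t = triple
    state.triples.remove(triple)
    state.tripleset.remove(triple)
    rels = state.pair_rels[(h, t)]
    rels.discard(r)
    if not rels:
        del state.pair_rels[(h, t)]
        state.out_nbrs[h].discard(t)
        state.in_nbrs[t].discard(h)


# ---------------------------------------------------------------------------
# Counterpart-aware splitting
# ---------------------------------------------------------------------------


def controlled_split(
    g: KnowledgeGraph,
    ledger: SyntheticLedger,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    counterpart_policy: str = "in_train",
) -> KnowledgeGraph:
    """Split so planted counterparts land in a controlled split.

    ``in_train``: whenever one member of a planted symmetric/inverse/
    inference pair is tagged valid/test, the other member is forced into
    train — the leakage-like condition under which such test triples become
    easy. ``held_out``: whenever one member is in test, so is the other —
    the model never sees the counterpart. Split sizes stay within +-2 of the
    rounded fractions, rebalanced using unconstrained triples.
    """
    if counterpart_policy not in ("in_train", "held_out"):
        raise ValueError("counterpart_policy must be 'in_train' or 'held_out'")
    rng = np.random.default_rng(seed)
    n = g.n_triples
    sizes = dict(zip(SPLITS, _largest_remainder_sizes(n, fractions)))
    trip_list = [tuple(t) for t in g.triples.tolist()]
    index = {t: i for i, t in enumerate(trip_list)}
    partners: dict[int, set[int]] = {}
    for group in (ledger.symmetric, ledger.inverse, ledger.inference):
        for a, b in group:
            i, j = index[a], index[b]
            partners.setdefault(i, set()).add(j)
            partners.setdefault(j, set()).add(i)
    split = np.full(n, "train", dtype=object)

    if counterpart_policy == "in_train":
        # expose at most one member of any planted pair to valid/test; every
        # partner of an exposed triple then stays in train
        exposed: set[int] = set()
        need = {"test": sizes["test"], "valid": sizes["valid"]}
        for i in rng.permutation(n):
            if partners.get(i, set()) & exposed:
                continue
            if need["test"] > 0:
                split[i], _ = "test", exposed.add(i)
                need["test"] -= 1
            elif need["valid"] > 0:
                split[i], _ = "valid", exposed.add(i)
                need["valid"] -= 1
            else:
                break
        if need["test"] + need["valid"] > 2:
            raise RuntimeError(
                "in_train policy unsatisfiable: too few triples outside planted pairs"
            )
    else:
        # test is closed under partnership: add whole pair-components
        comp = _pair_components(n, partners)
        comps = list(comp.values())
        order = rng.permutation(len(comps))
        n_test = 0
        for ci in order:
            members = comps[ci]
            if n_test + len(members) <= sizes["test"] + 2 and n_test < sizes["test"]:
                for i in members:
                    split[i] = "test"
                n_test += len(members)
        if abs(n_test - sizes["test"]) > 2:
            raise RuntimeError("held_out policy cannot match the test fraction within +-2")
        rest = np.flatnonzero(split == "train")
        pick = rng.permutation(len(rest))[: sizes["valid"]]
        split[rest[pick]] = "valid"
    return g.with_split(split)


def _pair_components(n: int, partners: dict[int, set[int]]) -> dict[int, list[int]]:
    """Connected components of the planted-pair graph (singletons included)."""
    root = list(range(n))

    def find(x: int) -> int:
        while root[x] != x:
            root[x] = root[root[x]]
            x = root[x]
        return x

    for i, js in partners.items():
        for j in js:
            ri, rj = find(i), find(j)
            if ri != rj:
                root[ri] = rj
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return comps
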