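"""Data model and I/O for directed multi-relational knowledge graphs.

A knowledge graph is a set of triples (head, relation, tail) over integer-encoded
entity and relation vocabularies. Triples are stored as an ``(n, 3)`` integer
array; optional per-triple split tags (train/valid/test) and per-entity type
labels (gene, drug, disease, ...) support the evaluation and analysis layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

SPLITS = ("train", "valid", "test")


class TripleParseError(ValueError):
    """A line of a triple file could not be parsed."""


@dataclass
class Vocab:
    """Bijection between string labels and contiguous integer ids (0..n-1)."""

    labels: list[str] = field(default_factory=list)
    index: dict[str, int] = field(default_factory=dict)

    def add(self, label: str) -> int:
        """Return the id of *label*, creating a new id on first appearance."""
        i = self.index.get(label)
        if i is None:
            i = len(self.labels)
            self.index[label] = i
            self.labels.append(label)
        return i

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> int:
        return self.index[label]

    def __contains__(self, label: str) -> bool:
        return label in self.index


@dataclass
class KnowledgeGraph:
    """Integer-encoded triple set with vocabularies, optional types and splits.

    Invariants: all ids lie in range, there are no duplicate (h, r, t) rows,
    and split tags (when present) partition the triples.
    """

    triples: np.ndarray
    entities: Vocab
    relations: Vocab
    entity_types: np.ndarray | None = None  # per entity id, dtype object (str)
    split: np.ndarray | None = None  # per triple, values in SPLITS

    def __post_init__(self) -> None:
        self.triples = np.asarray(self.triples, dtype=np.int64).reshape(-1, 3)
        self.validate()

    # -- basic properties ---------------------------------------------------

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_relations(self) -> int:
        return len(self.relations)

    @property
    def n_triples(self) -> int:
        return len(self.triples)

    def validate(self) -> None:
        t = self.triples
        if t.size:
            if t[:, [0, 2]].min() < 0 or t[:, [0, 2]].max() >= self.n_entities:
                raise ValueError("entity id out of range")
            if t[:, 1].min() < 0 or t[:, 1].max() >= self.n_relations:
                raise ValueError("relation id out of range")
            if len(np.unique(encode_triples(t, self.n_entities, self.n_relations))) != len(t):
                raise ValueError("duplicate triples")
        if self.split is not None:
            if len(self.split) != len(t):
                raise ValueError("split tags must align with triples")
            bad = set(np.unique(self.split)) - set(SPLITS)
            if bad:
                raise ValueError(f"unknown split tags: {bad}")
        if self.entity_types is not None and len(self.entity_types) != self.n_entities:
            raise ValueError("entity_types must have one entry per entity")

    # -- convenience --------------------------------------------------------

    def split_triples(self, tag: str) -> np.ndarray:
        """Triples carrying the given split tag."""
        if self.split is None:
            raise ValueError("graph has no split tags")
        return self.triples[self.split == tag]

    def subgraph(self, mask: np.ndarray) -> "KnowledgeGraph":
        """Graph over the same vocabularies containing only the masked triples."""
        return KnowledgeGraph(
            self.triples[mask],
            self.entities,
            self.relations,
            self.entity_types,
            self.split[mask] if self.split is not None else None,
        )

    def with_split(self, split: np.ndarray) -> "KnowledgeGraph":
        return KnowledgeGraph(self.triples, self.entities, self.relations, self.entity_types, split)

    def triple_labels(self) -> list[tuple[str, str, str]]:
        e, r = self.entities.labels, self.relations.labels
        return [(e[h], r[rel], e[t]) for h, rel, t in self.triples]


def encode_triples(triples: np.ndarray, n_entities: int, n_relations: int) -> np.ndarray:
    """Collision-free int64 key for each (h, r, t) row."""
    t = np.asarray(triples, dtype=np.int64)
    return (t[:, 0] * n_relations + t[:, 1]) * n_entities + t[:, 2]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _parse_lines(path: Path, delimiter: str | None, header: bool):
    with open(path) as fh:
        lines = fh.read().splitlines()
    if header and lines:
        lines = lines[1:]
    rows = []
    for lineno, line in enumerate(lines, start=2 if header else 1):
        if not line.strip():
            continue
        fields = line.split(delimiter) if delimiter else line.split()
        fields = [f for f in fields if f != ""]
        if len(fields) < 3:
            raise TripleParseError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
        rows.append(fields[:3])
    return rows


def load_triples(
    path: str | Path,
    delimiter: str | None = None,
    header: bool = False,
    sorted_vocab: bool = False,
    entities: Vocab | None = None,
    relations: Vocab | None = None,
) -> KnowledgeGraph:
    """Load a delimited triple file (one ``head relation tail`` per line).

    Vocabulary ids are assigned in first-appearance order (or sorted label
    order with ``sorted_vocab=True``). Duplicate lines collapse to a single
    triple; the number of collapsed duplicates is logged. ``entities`` /
    ``relations`` allow loading several files (e.g. pre-split benchmarks)
    against shared vocabularies.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = _parse_lines(path, delimiter, header)
    if not rows:
        raise TripleParseError(f"{path}: no triples found")

    ev = entities if entities is not None else Vocab()
    rv = relations if relations is not None else Vocab()
    if sorted_vocab and entities is None and relations is None:
        for lab in sorted({h for h, _, _ in rows} | {t for _, _, t in rows}):
            ev.add(lab)
        for lab in sorted({r for _, r, _ in rows}):
            rv.add(lab)

    triples = np.empty((len(rows), 3), dtype=np.int64)
    for i, (h, r, t) in enumerate(rows):
        triples[i] = ev.add(h), rv.add(r), ev.add(t)

    keys = encode_triples(triples, len(ev), len(rv))
    _, first = np.unique(keys, return_index=True)
    if len(first) < len(triples):
        logger.info("%s: collapsed %d duplicate triples", path, len(triples) - len(first))
        triples = triples[np.sort(first)]
    return KnowledgeGraph(triples, ev, rv)


def load_split_files(
    train: str | Path,
    valid: str | Path | None = None,
    test: str | Path | None = None,
    **kwargs,
) -> KnowledgeGraph:
    """Load pre-split benchmark files into one split-tagged graph."""
    ev, rv = Vocab(), Vocab()
    parts, tags = [], []
    for tag, p in zip(SPLITS, (train, valid, test)):
        if p is None:
            continue
        g = load_triples(p, entities=ev, relations=rv, **kwargs)
        parts.append(g.triples)
        tags.append(np.full(len(g.triples), tag, dtype=object))
    triples = np.vstack(parts)
    split = np.concatenate(tags)
    # drop duplicates across files, keeping the earliest (train-first) copy
    keys = encode_triples(triples, len(ev), len(rv))
    _, first = np.unique(keys, return_index=True)
    if len(first) < len(triples):
        logger.info("collapsed %d duplicate triples across splits", len(triples) - len(first))
        order = np.sort(first)
        triples, split = triples[order], split[order]
    return KnowledgeGraph(triples, ev, rv, split=split)


def load_entity_types(g: KnowledgeGraph, path: str | Path, delimiter: str | None = None) -> None:
    """Attach entity types from a two-column file (entity label, type label).

    Entities absent from the file receive type ``"unknown"``.
    """
    types = np.full(g.n_entities, "unknown", dtype=object)
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            if len(fields) < 2:
                raise TripleParseError(f"{path}: type lines need 2 fields")
            label, typ = fields[0], fields[1]
            if label in g.entities:
                types[g.entities[label]] = typ
    g.entity_types = types


def write_triples(g: KnowledgeGraph, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for h, r, t in g.triple_labels():
            fh.write(f"{h}{delimiter}{r}{delimiter}{t}\n")


def write_vocab(vocab: Vocab, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for i, lab in enumerate(vocab.labels):
            fh.write(f"{lab}{delimiter}{i}\n")


def write_entity_types(g: KnowledgeGraph, path: str | Path, delimiter: str = "\t") -> None:
    if g.entity_types is None:
        raise ValueError("graph has no entity types")
    with open(path, "w") as fh:
        for lab, typ in zip(g.entities.labels, g.entity_types):
            fh.write(f"{lab}{delimiter}{typ}\n")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def remove_reverse_duplicates(g: KnowledgeGraph) -> KnowledgeGraph:
    """Drop the later member of every reverse pair {(h,r,t), (t,r,h)}, h != t.

    Some benchmark graphs materialise every triple in both directions; keeping
    both would make every edge trivially symmetric and leak reverse copies
    across train/test splits. Self-loops and pairs under different relations
    are untouched. Keep-first is deterministic in input order.
    """
    n_e, n_r = g.n_entities, g.n_relations
    fwd = encode_triples(g.triples, n_e, n_r)
    rev = encode_triples(g.triples[:, [2, 1, 0]], n_e, n_r)
    order = np.argsort(fwd, kind="stable")
    sorted_fwd = fwd[order]
    # a triple is dropped iff its reverse exists AND the reverse came earlier
    pos = np.searchsorted(sorted_fwd, rev)
    has_rev = (pos < len(sorted_fwd)) & (sorted_fwd[np.minimum(pos, len(sorted_fwd) - 1)] == rev)
    rev_index = np.full(len(g.triples), -1, dtype=np.int64)
    rev_index[has_rev] = order[np.minimum(pos, len(sorted_fwd) - 1)][has_rev]
    idx = np.arange(len(g.triples))
    not_self = g.triples[:, 0] != g.triples[:, 2]
    drop = has_rev & not_self & (rev_index < idx)
    keep = ~drop
    if drop.any():
        logger.info("removed %d reverse-duplicate triples", int(drop.sum()))
    return g.subgraph(keep)


def _largest_remainder_sizes(n: int, fractions: tuple[float, float, float]) -> list[int]:
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(x)) for x in raw]
    for i in sorted(range(3), key=lambda i: raw[i] - sizes[i], reverse=True)[: n - sum(sizes)]:
        sizes[i] += 1
    return sizes


def assign_splits(
    g: KnowledgeGraph,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    guarantee_train_coverage: bool = False,
) -> KnowledgeGraph:
    """Randomly tag triples as train/valid/test.

    Split sizes follow largest-remainder rounding of the fractions. With
    ``guarantee_train_coverage``, any valid/test triple whose head, tail or
    relation never occurs in train is swapped into train (against a random
    train triple whose removal keeps coverage), so the embedding layer never
    meets an unseen id at evaluation time.
    """
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    n = g.n_triples
    sizes = _largest_remainder_sizes(n, fractions)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    split = np.empty(n, dtype=object)
    split[perm[: sizes[0]]] = "train"
    split[perm[sizes[0] : sizes[0] + sizes[1]]] = "valid"
    split[perm[sizes[0] + sizes[1] :]] = "test"

    if guarantee_train_coverage:
        moved = 0
        for _ in range(n):  # each pass fixes at least one violation
            train_mask = split == "train"
            tr = g.triples[train_mask]
            seen_e = np.zeros(g.n_entities, dtype=bool)
            seen_r = np.zeros(g.n_relations, dtype=bool)
            if len(tr):
                seen_e[tr[:, 0]] = seen_e[tr[:, 2]] = True
                seen_r[tr[:, 1]] = True
            bad = np.flatnonzero(
                ~train_mask
                & (~seen_e[g.triples[:, 0]] | ~seen_e[g.triples[:, 2]] | ~seen_r[g.triples[:, 1]])
            )
            if len(bad) == 0:
                break
            i = bad[0]
            donors = np.flatnonzero(train_mask)
            split[i], split[donors[rng.integers(len(donors))]] = "train", split[i]
            moved += 1
        if moved:
            logger.info("moved %d triples into train to guarantee coverage", moved)
    return g.with_split(split)
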