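# kgtopo

Per-triple topological analysis and shallow embedding models for
multi-relational knowledge graphs, aimed at the biomedical setting where
graphs mix genes, drugs, diseases and pathways and where link-prediction
accuracy depends strongly on local graph structure.

Knowledge-graph completion — answering queries (h, r, ?) over triples
(head, relation, tail) — is widely used for drug repurposing and
target-discovery work. Whether a knowledge-graph-embedding (KGE) model gets
a particular triple right turns out to depend less on the relation type as
a whole and more on the *local topology of the individual triple*: the
degrees of its endpoints, its edge cardinality, and whether it participates
in symmetric, inverse, inference or composition patterns. `kgtopo` measures
those per-triple properties exactly, trains the standard shallow KGE models
(TransE, DistMult, RotatE, TripleRE), evaluates them with the filtered
tail-ranking protocol, and provides the stratified analyses that connect
topology to accuracy — plus a synthetic-graph generator that *plants*
pattern instances with a ground-truth ledger, so every stage is testable
without external data.

## Definitions at a glance

For a triple (h, r, t) in graph G:

* deg(h) = |{t' : ∃r' (h, r', t') ∈ G}| (distinct tails), deg(t)
  analogously; deg_r(·) restricts to relation r.
* cardinality: (deg_r(h), deg_r(t)) = (1,1) → 1:1, (>1,1) → 1:M,
  (1,>1) → M:1, (>1,>1) → M:M.
* symmetric: h ≠ t and (t, r, h) ∈ G; inference: (h, r', t) ∈ G for some
  r' ≠ r; inverse: (t, r', h) ∈ G for some r' ≠ r; composition: a directed
  2-path h → n → t with n ∉ {h, t}.
* filtered rank: rank of t among candidates after masking other tails known
  true; MRR = mean(1/rank); Hits@K = fraction(rank ≤ K).

## Worked example

Train DistMult and TransE on a synthetic relation that is 100% symmetric,
with every test triple's reverse counterpart placed in the training split
(`examples/03_train_and_evaluate.py`):

```text
2000 triples, all symmetric; 200 test queries, counterparts in train
random-ranking baseline MRR = 0.0209

distmult  MRR=0.519  Hits@1=0.360  Hits@10=0.865
transe    MRR=0.052  Hits@1=0.000  Hits@10=0.140
```

DistMult scores are symmetric by construction, so the reverse edge seen in
training pins the answer (MRR 25× the random baseline). TransE cannot
represent a symmetric relation at all — no non-zero translation satisfies
both directions — and stays near the baseline. Flipping the split policy so
counterparts are *held out* drops DistMult to MRR ≈ 0.02: the advantage was
the counterpart, not the relation. These two contrasts are the package's
core acceptance experiments.

The other example scripts cover the per-triple census
(`01_topology_census.py`), ledger-exact pattern planting
(`02_synthetic_ledger.py`), degree-stratified and counterpart-contrast
analysis (`04_stratified_analysis.py`) and the paired cross-graph case
study with a common test set and candidate pool (`05_case_study.py`).

A thin CLI mirrors the library for shell use:

```bash
kgt load --triples graph.tsv --out g/
kgt topology --graph g/ --out report.csv --by-relation
kgt generate --config cfg.txt --seed 7 --out syn/
kgt train --graph syn/ --model distmult --dim 64 --out model/
kgt evaluate --model model/ --graph syn/ --out results.csv
```

## Layout

```
src/kgtopo/        graph.py (data model, I/O, preprocessing, splits)
                   topology.py (degrees, cardinality, patterns, censuses)
                   synthetic.py (planted-pattern generator, controlled splits)
                   models.py (TransE/DistMult/RotatE/TripleRE + training)
                   evaluation.py (filtered ranking, MRR/Hits@K, demixing)
                   analysis.py (stratification, contrasts, case study)
                   cli.py (the `kgt` command)
examples/          one narrative script per capability
docs/methods.md    models, assumptions, parameter choices, limitations
tests/             pytest suite incl. brute-force oracles
```
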