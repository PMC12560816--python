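# Methods

## Scope and model of the data

`kgtopo` operates on directed multi-relational graphs: finite sets of triples
(h, r, t) over integer-encoded entity and relation vocabularies, optionally
with per-entity type labels (gene, drug, disease, ...) and per-triple split
tags. The package treats topological properties as attributes of *individual
triples*, not of whole relation types. This matters because real biomedical
graphs mix, within one relation, triples that are symmetric and triples that
are not, triples embedded in dense neighbourhoods and isolated ones; any
relation-level label is a lossy average, and correlating such averages with
model accuracy washes out the signal that is visible at the triple level.

## Per-triple topology

For a triple (h, r, t) in graph G:

* **head out-degree** deg(h) = |{t' : ∃r' (h, r', t') ∈ G}| — distinct
  tails, not edge counts; **tail in-degree** deg(t) analogously;
* **same-relation degrees** deg_r(h), deg_r(t) restrict to relation r;
* **edge cardinality** classifies (deg_r(h), deg_r(t)): (1,1) → 1:1,
  (>1,1) → 1:M, (1,>1) → M:1, (>1,>1) → M:M. The class is written
  tail:head — for a 1:M edge the head fans out to several tails, each with a
  single same-relation in-edge;
* **symmetric**: h ≠ t and (t, r, h) ∈ G;
* **inference**: ∃r' ≠ r with (h, r', t) ∈ G;
* **inverse**: ∃r' ≠ r with (t, r', h) ∈ G;
* **composition**: ∃ n ∉ {h, t} and relations r1, r2 with (h, r1, n) and
  (n, r2, t) ∈ G. Only directed 2-paths h → n → t count; r1 and r2 may
  equal r or each other — only the intermediate entity is constrained.
  Self-loops at h or t therefore never create a composition.

A triple may satisfy several patterns at once, or none; censuses report the
fraction per pattern (which may sum above 1), the none-of-the-four fraction,
and cardinality fractions (which sum to 1). Fractions are displayed to 3
decimals; raw counts are always retained.

The sparse implementation uses per-pair relation multiplicities (sorted
integer keys), membership tests on encoded triples, and the boolean
any-relation adjacency A: the number of distinct composition intermediates
is (A·A)[h, t] minus corrections for n = h and n = t when self-loops exist.
Distinct relation pairs per composed triple are enumerated from the out/in
adjacency lists. Every quantity is verified, element for element, against a
brute-force nested-loop evaluation of the definitions on random graphs
(property test over 100 graphs of up to 200 triples, plus a
hypothesis-driven variant).

Two graph scopes are exposed explicitly. A census defaults to the graph the
triples came from (all splits merged). Analyses of test triples pass the
training graph as `pattern_graph`, so counterpart flags and degrees measure
what the model actually saw. Degrees measured against an external graph can
be 0; for cardinality classification (which needs degrees ≥ 1) the query
edge is treated as if present, i.e. degrees are clipped at 1, while the raw
value (including 0) feeds the degree bins.

A useful identity, exploited in the tests: an inverse counterpart of a triple
in G is exactly an inference counterpart of the same (un-reversed) triple in
the edge-reversed graph. Note that reversing the query triple *as well*
collapses the identity to a tautology, so the duality must be checked with
the query fixed.

## Reverse-duplicate removal

Some benchmark graphs materialise every edge in both directions. Keeping
both makes every triple trivially symmetric and leaks the reverse copy of
each test triple into training. `remove_reverse_duplicates` drops the later
member (in input order) of every {(h, r, t), (t, r, h)} pair with h ≠ t;
self-loops and pairs under different relations are untouched. Keep-first is
a convention — nothing in the data prefers one direction — chosen because it
is deterministic and independent of dataset version. The operation is
idempotent, and afterwards the symmetric fraction of the h ≠ t triples is
exactly zero.

## Synthetic graphs with ledgered patterns

The generator emulates the structural features that drive the analyses —
multiple entity types, heavy-tailed degrees, controllable pattern
frequencies — at a scale where everything can be validated exactly.

* **Base edges** (h ≠ t) are sampled without replacement; head and tail are
  drawn with weights ∝ rank^(−s) over a random entity ranking. The default
  skew s = 0.8 gives mild hubs, qualitatively similar to curated biomedical
  graphs; s = 0 is uniform. The hub statistic that grows monotonically with
  s is the per-entity max/median out-degree (the per-triple analogue is
  size-biased: hubs inflate the median as well).
* **Planting**: each base edge independently receives, with rates p_sym,
  p_inv, p_inf, p_comp, a symmetric counterpart (t, r, h), an inverse
  counterpart (t, r', h), an inference counterpart (h, r', t), and/or a
  composition path (h, r1, n), (n, r2, t) with a fresh intermediate.
  Inverse/inference counterparts draw r' from a reserved relation pool —
  an "inverse" under the same relation would be symmetry. Planting adds
  edges rather than rewiring, so base-edge statistics stay interpretable.
  Every planted instance is recorded in a ledger of concrete triples.
* **clean_mode**: every insertion is validated against the current graph;
  an edge that would create any pattern instance beyond the one being
  planted is rejected and resampled (up to `max_retries`, default 100, after
  which that counterpart is skipped; base-edge starvation raises an error).
  Composition planting additionally requires the base edge to be the only
  direct edge on its (h, t) pair, otherwise a co-located inference edge
  would silently gain an un-ledgered composition flag. In clean mode the
  detector output equals the ledger *exactly* — this is the ground truth
  for the recovery tests. Cross-pattern rejections make realized planting
  rates slightly lower than nominal in clean mode; the binomial
  concentration of planted counts is therefore checked in noisy mode, where
  only duplicate collisions (rare) interfere.
* **Types** are assigned to contiguous id blocks with configurable
  proportions (default gene 0.5 / drug 0.3 / disease 0.2).

What the generator does **not** emulate: the joint degree–pattern
distribution of any real graph, relation-specific type constraints at
Hetionet-like scale, or realistic incompleteness. Tests passing on these
graphs establish correctness of the machinery and the direction of the
topology–accuracy effects under controlled conditions, not effect sizes on
real data. One consequence worth stating plainly: planted composition paths
use *fresh random* intermediates, so — unlike real biomedical compositions,
which encode genuine regularities (a drug and a disease sharing a gene) —
they carry little signal a model can transfer to the held-out direct edge.
The composition-effect delta measured on these graphs is therefore small
and close to zero, and the acceptance report treats it as a sign-level,
stochastic quantity. The counterpart-based effects (symmetry, inverse,
inference), by contrast, are large and stable, because the planted
counterpart is directly informative about the held-out edge.

### Counterpart-controlled splits

`controlled_split` produces the two study conditions for leakage-like
analysis. Under `in_train`, at most one member of any planted
symmetric/inverse/inference pair is exposed to valid/test, so every exposed
triple has its counterpart in training. Under `held_out`, the test set is
closed under pair-partnership (whole union-find components of the pair graph
are assigned), so no test triple's counterpart is seen in training. Split
sizes follow largest-remainder rounding and are met within ±2 triples; an
unsatisfiable request (e.g. a test fraction larger than the exposable set)
raises.

## Embedding models

Four shallow scorers, all mapping a triple to a real score (higher = more
plausible):

| model    | score | notes |
|----------|-------|-------|
| TransE   | −‖e_h + e_r − e_t‖_p | cannot represent symmetry (needs e_r = 0) |
| DistMult | Σ_i e_h,i · e_r,i · e_t,i | symmetric by construction |
| RotatE   | −Σ_j \|e_h,j · e_r,j − e_t,j\| | complex embeddings; relations are unit-modulus rotations |
| TripleRE | −‖e_h ∘ r_head − e_t ∘ r_tail + r_mid‖_p | three relation parts |

DistMult's symmetry is exact to the last bit: the product is evaluated as
(e_h ∘ e_t) ∘ e_r, so swapping h and t does not even change rounding.
RotatE relations are parameterised by phase vectors, so the unit-modulus
constraint holds by construction at every step; the distance is the sum of
component-wise complex moduli, which keeps distances on the scale of the
margin at the default initialisation.

Training is mini-batch gradient descent with closed-form gradients (these
scorers are compositions of elementwise products and p-norms; no autodiff
framework is needed). Defaults: self-adversarial negative sampling — K
uniform corruptions per positive (default 64; head or tail side chosen per
negative), reweighted by a softmax of their own scores at temperature 1.0,
with loss softplus(−(γ + s_pos)) + Σ_k w_k softplus(γ + s_neg,k) — margin
γ = 9, Adagrad at learning rate 0.05, batch 256. A margin-ranking loss and
plain SGD are available for parity with older setups. Initialisation:
uniform ±γ/d for the distance models, N(0, 0.1²) for DistMult, phases
uniform in [0, 2π). All randomness flows from one seed; identical seeds give
bit-identical runs. A non-finite loss aborts with a diagnostic rather than
silently producing NaN embeddings. No early stopping: the epoch budget is
explicit.

These hyperparameters are the package's own defaults, chosen so that the
qualitative model-behaviour laws are observable on synthetic graphs of a few
thousand triples within seconds; users fitting real graphs should treat
them as starting points.

## Evaluation protocol

Tail prediction only: for each test triple (h, r, t) the query (h, r, ?) is
scored against a candidate set (all entities by default), the scores of
other tails known true in the *filter graph* are masked (the true tail is
exempt from masking), and the rank of t among the survivors is recorded.
The filter graph should be the union of all splits — the standard filtered
protocol. Head prediction is the same computation on the edge-reversed
graph, not a separate code path.

Ties take the mean rank over the tied block (unbiased between the
optimistic and pessimistic conventions, both of which are available for
cross-library comparison). Metrics: MRR = mean(1/rank), Hits@K =
fraction(rank ≤ K). With untrained random embeddings the rank is uniform on
{1..n}, so the expected MRR is H_n/n (harmonic number over n candidates) —
used as the random baseline and as a distributional test of the ranking
code. A candidate set that omits a query's true tail is an error, not a
silent skip.

**Demixing** is operationalized as the fraction of queries whose top-ranked
(filtered) prediction carries the target entity type. This is one concrete
choice among several plausible ones; reports should flag it as such.

**Restricted-candidate evaluation** scores queries against the distinct
tails of a relation's shared triples — the device that makes cross-graph
comparisons fair, since both arms face the same candidates.

## Stratified analyses

`stratify` computes per-group metrics under a grouping schema: head-bin ×
tail-bin on same-relation degrees (bins default to powers of two — {1},
{2,3}, {4..7}, ... — configurable), cardinality class, any pattern flag, or
any counterpart flag. Groups partition the test triples, so count-weighted
group MRRs reconstruct the global MRR to numerical identity (asserted to
1e-12). `pattern_effect` reports the per-cell MRR difference with-pattern
minus without (NaN where a side is empty); `counterpart_contrast` compares
the counterpart-in-train group against the rest per pattern. Degrees of
test triples are measured on the training graph by default — what the model
saw — with the full-graph option for census parity.

## Cross-graph case study

When one graph is (approximately) a subset of another, triples shared by
both — matched by exact entity/relation labels — support a paired
experiment: a seeded 10% sample of the shared triples of one relation
becomes a common test set, removed from both training graphs; both arms are
evaluated against the common restricted candidate set. The bundle carries
both training graphs, the test set in both id spaces, and the candidates;
leakage (a test triple surviving in a training graph) is structurally
impossible and asserted in tests. Embedding size is an explicit parameter
of whatever models are trained on the bundle; fuzzy entity alignment is out
of scope.

## Numerical and degenerate-input choices

* Vocabulary ids in first-appearance order (sorted mode available);
  duplicate input lines collapse with a logged count.
* Largest-remainder rounding for split sizes; split assignment, generation,
  sampling and training are all deterministic functions of their seeds.
* p-norm subgradient at kinks is taken as 0 (sign(0) = 0); norm
  denominators are floored at 1e-12.
* Empty graphs are errors for censuses and training; empty groups in
  stratified tables carry counts of 0 and no metric value; relations with
  no triples are omitted from per-relation aggregation.
* `aggregate_by_relation` labels a relation by the pattern whose triple
  fraction exceeds the threshold (default 0.95, must be > 0.5); if several
  patterns co-occur above it, the largest fraction wins; otherwise "mixed".

## Problem sizes used in the shipped experiments

The acceptance script and test-suite experiments run on synthetic graphs of
300 entities / 2000 triples (model-behaviour and counterpart-contrast
experiments, embedding dim 64, 20 epochs, 32 negatives), 90–150 entities
for detector-exactness checks, and 100 random graphs of ≤ 200 triples for
oracle equivalence. These sizes were chosen as the smallest at which the
qualitative effects are stable across seeds; all of them are parameters,
and every experiment scales to larger graphs unchanged.

## Known limitations

* Composition detection is limited to directed 2-paths; longer or
  undirected metapaths are out of scope.
* The trainer materialises dense gradient buffers per batch, which is
  simple and exact but wasteful for very large vocabularies; real-scale
  training would shard or sparsify the update.
* Demixing is a top-1 type-match rate; other definitions (type-restricted
  MRR, rank-weighted type purity) are not implemented.
* No convolutional or GNN scorers; no AUROC / triple-classification
  evaluation; no statistical machinery beyond counts and deltas.
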