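"""Train two embedding models on an all-symmetric relation and compare.

TransE cannot represent symmetric relations (it would need a zero relation
vector), while DistMult is symmetric by construction. With every test
triple's reverse counterpart visible in training, the gap is dramatic.
"""

from kgtopo import (
    ModelConfig,
    SyntheticConfig,
    controlled_split,
    expected_random_mrr,
    filtered_tail_ranks,
    generate,
    ranking_metrics,
    train,
)

g, ledger = generate(SyntheticConfig(n_entities=300, n_relations=1,
                                     n_base_edges=1000, p_sym=1.0,
                                     clean_mode=True, seed=3))
gs = controlled_split(g, ledger, (0.8, 0.1, 0.1), seed=3, counterpart_policy="in_train")
test = gs.split_triples("test")
print(f"{g.n_triples} triples, all symmetric; {len(test)} test queries, "
      f"counterparts in train")
print(f"random-ranking baseline MRR = {expected_random_mrr(g.n_entities):.4f}\n")

for scoring in ("distmult", "transe"):
    model = train(gs, ModelConfig(scoring=scoring, embedding_dim=64, epochs=20,
                                  num_negatives=32, seed=1))
    res = filtered_tail_ranks(model, test, gs)
    m = ranking_metrics(res)
    print(f"{scoring:9s} MRR={m['mrr']:.3f}  Hits@1={m['hits@1']:.3f}  "
          f"Hits@10={m['hits@10']:.3f}")

print()
print("DistMult ranks the known-reverse tail near the top (MRR far above the"
      " random baseline); TransE stays near the baseline because no non-zero"
      " translation satisfies both directions of a symmetric edge.")
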