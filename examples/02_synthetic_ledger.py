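"""Generate a synthetic graph with planted patterns and verify the ledger.

In clean mode the generator guarantees that the pattern detector finds
exactly the planted instances — the ground truth for all downstream tests.
"""

import numpy as np

from kgtopo import SyntheticConfig, detect_edge_patterns, generate, pattern_summary

cfg = SyntheticConfig(
    n_entities=200, n_relations=3, n_base_edges=500,
    p_sym=0.2, p_inv=0.1, p_inf=0.1, p_comp=0.2,
    clean_mode=True, seed=7,
)
g, ledger = generate(cfg)
print(f"graph: {g.n_triples} triples, {g.n_entities} entities, {g.n_relations} relations")
print(f"planted: {len(ledger.symmetric)} symmetric pairs, {len(ledger.inverse)} inverse,"
      f" {len(ledger.inference)} inference, {len(ledger.composition)} composition paths")

pat = detect_edge_patterns(g)
trips = [tuple(x) for x in g.triples.tolist()]
expected = ledger.expected_flags()
for flag, want in expected.items():
    got = {trips[i] for i in np.flatnonzero(pat[flag].to_numpy())}
    print(f"{flag:16s} detector={len(got):4d} ledger={len(want):4d} exact={got == want}")

print()
print(pattern_summary(g).to_frame().to_string(index=False))
print()
print("'exact=True' on every line means the detector flags coincide with the"
      " planted ground truth — no accidental pattern instances slipped in.")
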