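"""Enumerate predicted DDI pairs from a knowledge base and grade potency.

Substrates and inhibitors of a shared CYP enzyme are paired; pair potency
combines one drug's metabolism extent with the other's inhibition potency
(Ki bins: <10 uM strong, 10-100 moderate, >100 weak).
"""

import cypddi

kb, _ = cypddi.generate_knowledge_base(n_drugs=12, seed=4)
pairs = cypddi.predict_pairs(kb)
print(f"knowledge base: {kb['drug'].nunique()} drugs, {len(kb)} enzyme roles")
print(f"predicted directional pairs: {len(pairs)}")

for pair in pairs[:5]:
    potency = cypddi.predict_pair_potency(pair, kb)
    print(f"  {pair.substrate_drug} (substrate) x {pair.inhibitor_drug} "
          f"(inhibitor) via {','.join(sorted(pair.enzymes))}: {potency} DDI")
# "strong" means a major metabolism route of one drug meets strong (Ki<10 uM)
# inhibition by the other on the same enzyme.

print("\nKi potency bins:", [(ki, cypddi.classify_potency(ki)) for ki in (5, 50, 150)])
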