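"""Null-model assembly partitioning: βNTI + Raup–Crick on two contrasting
regimes — strong homogeneous selection vs near-panmictic neutrality."""

import numpy as np

from benthicom import (
    beta_nti,
    classify_processes,
    raup_crick_bray,
    simulate_metacommunity,
    simulate_neutral_communities,
    simulate_selection_regime,
    simulate_tree,
)

tree = simulate_tree(150, seed=7)
meta = simulate_metacommunity(150, sigma=1.0, seed=8)

for name, table in [
    ("homogeneous selection",
     simulate_selection_regime(tree, 12, 1000, seed=9, meta=meta)),
    ("neutral (m = 0.9)",
     simulate_neutral_communities(meta, 0.9, 1000, 12, seed=9,
                                  taxon_ids=tree.tip_labels)),
]:
    bnti = beta_nti(table, tree, n_null=199, seed=10)
    rc = raup_crick_bray(table, n_null=199, seed=11)
    cls = classify_processes(bnti, rc)
    z = bnti.bnti.values.to_numpy()[np.triu_indices(12, 1)]
    print(f"{name}: median bNTI = {np.nanmedian(z):+.2f}")
    print("  process fractions:",
          {k: round(v, 2) for k, v in cls.fractions.items() if v > 0})

print("\nbNTI < -2 marks less phylogenetic turnover than the taxa-shuffle "
      "null expects\n(homogeneous selection); pairs within +-2 fall to the "
      "Raup-Crick rules, where\n|RC| <= 0.95 is drift. The selection regime "
      "is built so filtered taxa form a\nclade, which is exactly the signal "
      "bNTI detects.")
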