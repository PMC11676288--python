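"""Sediment nitrogen chemistry: derived pools, group comparison, db-RDA,
and boosted-tree relative influence."""

from benthicom import (
    SimulationConfig,
    abt_influence,
    bray_curtis,
    community_response,
    compare_chemistry,
    db_rda,
    simulate_dataset,
)

dataset = simulate_dataset(SimulationConfig(seed=42))
env = dataset["metadata"].frame
table = dataset["tables"]["bacteria"]

print("chemistry group comparison (rank-sum, exact at n = 6 per group):")
chem = compare_chemistry(env)
print(chem.loc[["FA", "EN", "ammonia", "ON"]].round(4))

dist = bray_curtis(table)
variables = ["FA", "ammonia", "nitrate", "nitrite", "ON"]
rda = db_rda(dist, env, variables, n_permutations=999, seed=0)
print(f"\ndb-RDA: constrained inertia = {rda.constrained_proportion:.1%}, "
      f"pseudo-F = {rda.f_statistic:.2f}, p = {rda.p_value:.3f}")

abt = abt_influence(community_response(dist), env, variables, seed=0)
print("ABT relative influence (%):")
print(abt.influence.round(1).sort_values(ascending=False).to_string())

print("\nEN = ammonia + nitrate + nitrite and ON = TN - EN - FA hold "
      "exactly by\nconstruction. The treatment group carries configured FA "
      "and ammonia offsets,\nso FA/EN/ammonia are higher and ON lower in "
      "BG. db-RDA asks how much of the\ncommunity's Bray-Curtis structure "
      "chemistry explains; ABT ranks the predictors.")
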