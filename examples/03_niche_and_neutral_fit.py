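"""Levins niche breadth, generalist/specialist classification, and the
Sloan neutral-model fit that quantifies dispersal."""

from benthicom import (
    SimulationConfig,
    classify_generalists,
    fit_neutral_model,
    levins_breadth,
    simulate_dataset,
)

dataset = simulate_dataset(SimulationConfig(seed=42, migration_m=0.3))
table = dataset["tables"]["protist"]

breadth = levins_breadth(table)
print(f"community habitat niche breadth (mean over samples): "
      f"{breadth.b_community.mean():.2f} (max possible = {table.n_samples})")

cls = classify_generalists(table, n_null=1000, ci=0.95, seed=0)
print("classification fractions:",
      {k: round(v, 3) for k, v in cls.fractions.items()})

fit = fit_neutral_model(table)
print(f"Sloan neutral fit: m = {fit.m:.3f}, Nt = {fit.nt}, "
      f"R^2 = {fit.r_squared:.3f}")
print("\nLevins B = 1/sum(P^2) rises from 1 (one sample) to N (even "
      "spread); generalists\nexceed the 95% resampling-null band, "
      "specialists fall below it. The fitted\nmigration rate m estimates "
      "dispersal: the generator drew these samples with a\nconcentration "
      "equivalent near m = 0.3, and smaller m means stronger dispersal "
      "limitation.")
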