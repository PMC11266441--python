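"""Generate a synthetic multi-environment maize trial study.

Builds a compact three-year study (parent x tester hybrids, RCBD yield
trials, weather/soil/EC/coordinate layers) and prints its dimensions and the
realized phenotype decomposition.
"""

import numpy as np

from metboost import SimConfig, generate_study

cfg = SimConfig(
    seed=7,
    n_parents=30,
    n_markers=500,
    n_environments_per_year=(2, 4, 4),
    field_rows=12,
    field_cols=12,
    env_hybrid_frac=0.5,
)
study = generate_study(cfg)

print(f"hybrids: {len(study.population.hybrids)} "
      f"(testers: {sorted(set(study.population.tester_of.values()))})")
print(f"environments: {len(study.envs)} over years {cfg.years}")
print(f"plots: {len(study.plot_table)}  "
      f"mean yield {study.plot_table['Yield_Mg_ha'].mean():.2f} Mg/ha")
print(f"weather records: {len(study.weather)} (30-min steps)")
print(f"EC matrix: {study.ecs.shape}")

# the stored truth decomposes every plot exactly
truth = study.truth.plot_effects
for col in ("g_add", "env", "gxe", "resid"):
    print(f"  realized var({col}): {np.var(truth[col]):.3f}")
# Yields decompose as intercept + genetics + environment + GxE + field
# effects + residual; the realized variances above should sit near the
# configured components (0.30 additive, 2.0 environment, 0.2 GxE, 1.0 residual).
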