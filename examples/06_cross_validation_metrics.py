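"""Stage 6: cross-validation schemes and evaluation metrics.

Builds the three CV plans on one study, reports the tester-overlap signature
that distinguishes them, and compares two models with the dependent
overlapping-correlation (Meng) test.
"""

import numpy as np

from metboost import SimConfig, generate_study
from metboost import evaluation as ev
from metboost.trials import plot_mean_blues

study = generate_study(SimConfig(seed=5))  # default-size study, 755 hybrids
blues = plot_mean_blues(study.plot_table)
tester_of = study.population.tester_of

for scheme in ("CV2", "CV1", "CV0"):
    plan = ev.SPLITTERS[scheme](blues, seed=5)
    fracs = [len(tr) / (len(tr) + len(va)) for tr, va in plan.assignments.values()]
    overlap = ev.tester_overlap(plan, tester_of)
    print(f"{scheme}: train fraction {100 * np.mean(fracs):.1f}%  "
          f"tester overlap {100 * overlap:.1f}%")
# CV2 holds out combinations (all testers stay shared, overlap 100%); CV1
# holds out new hybrids (rare testers can drop out of validation); CV0
# predicts a new year from earlier ones (year-1-only testers lower the
# overlap further) — the sparse-testing difficulty gradient.

# Meng test: is one model's accuracy significantly higher than another's?
rng = np.random.default_rng(0)
obs = rng.normal(size=300)
pred_a = obs + rng.normal(0, 0.8, 300)   # weaker model
pred_b = obs + rng.normal(0, 0.5, 300)   # stronger model
r1 = np.corrcoef(obs, pred_a)[0, 1]
r2 = np.corrcoef(obs, pred_b)[0, 1]
r12 = np.corrcoef(pred_a, pred_b)[0, 1]
z, p = ev.meng_test(r1, r2, r12, 300)
print(f"\nMeng test: r1={r1:.3f} vs r2={r2:.3f} (r12={r12:.3f}) "
      f"-> z={z:.2f}, p={p:.2g}")
# Both correlations share the observed vector, so the test accounts for
# their dependence; Bonferroni is applied across all model pairs in a study.
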