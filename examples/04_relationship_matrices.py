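"""Stage 3: marker QC and genomic relationship matrices.

Runs the fixed QC order (individuals -> MAF filter -> LD pruning) and builds
the VanRaden additive and zero-centered dominance relationship matrices.
"""

import numpy as np

from metboost import SimConfig, generate_study
from metboost import genetics as gen

study = generate_study(SimConfig(seed=7, n_parents=30, n_markers=1000,
                                 n_environments_per_year=(2, 4, 4),
                                 field_rows=12, field_cols=12,
                                 env_hybrid_frac=0.5))
m = gen.from_population(study.population)
m = gen.filter_individuals(m, sorted(study.plot_table["Hybrid"].unique()))
print(f"phenotyped hybrids: {m.n_hybrids}, markers: {m.n_markers}")
m = gen.filter_maf(m, threshold=0.01)
print(f"after MAF >= 0.01: {m.n_markers} markers")
m = gen.ld_prune(m, window=100, step=20, r2=0.9)
print(f"after LD pruning (r2 > 0.9): {m.n_markers} markers")

A = gen.grm_additive(m)
D = gen.grm_dominance(m)
print(f"A: {A.matrix.shape}, diagonal mean {np.diag(A.matrix).mean():.3f}")
print(f"D: {D.matrix.shape}, diagonal mean {np.diag(D.matrix).mean():.3f}")

tester = study.population.pedigree.set_index("Hybrid").loc[m.hybrids, "Tester"]
same = tester.to_numpy()[:, None] == tester.to_numpy()[None, :]
off = ~np.eye(m.n_hybrids, dtype=bool)
Am = A.matrix.to_numpy()
print(f"mean A, same tester: {Am[same & off].mean():.3f}; "
      f"different tester: {Am[~same & off].mean():.3f}")
# Half-sib families (shared tester) are visibly more related — the structure
# a population PCA picks up as tester clusters.
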