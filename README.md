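# metboost

Machine-learning genomic prediction for maize multi-environment trials (MET).

Breeding programs evaluate hundreds of parent × tester hybrids across dozens of
location-years, but can never test every hybrid everywhere: genotype-by-environment
interaction (GEI) makes performance rank-shift across environments, and the
practical question is how well untested combinations — new hybrids, new
environments, or whole new years — can be predicted from what was tested.
`metboost` implements a complete workflow for this problem: it characterizes
environments with engineered features (envirotyping), characterizes hybrids
with genomic relationship matrices, combines the two either additively (G+E)
or multiplicatively through a Kronecker construction (GEI), and fits
gradient-boosted regression trees to predict hybrid grain yield (Mg/ha)
under three sparse-testing cross-validation schemes. A first-class synthetic
data generator emulates the shape of a Genomes-to-Fields-style study so the
whole pipeline is testable without any external download.

## The model at the core

**Stage 1 — trial models.** Each environment (location × year) is analysed with
the mixed model

```
y_ijklm = mu + H_i + R_j + b(R)_jk + r_l + c_m + e_ijklm
```

with fixed hybrid `H` and replicate `R` effects and random block-within-replicate
`b(R) ~ N(0, s2_b)`, row `r ~ N(0, s2_r)`, column `c ~ N(0, s2_c)` and residual
terms, fitted by average-information REML. The hybrid BLUEs form the response
table for all predictions; per-trial quality is summarized by
`CV% = 100·sqrt(s2_e)/mean(fitted)` and the generalized heritability
`H2 = 1 − V̄(Δ)/(2·s2_g)` (Cullis), where `V̄(Δ)` is the mean pairwise
prediction error variance of hybrid BLUPs from a random-hybrid refit.

**Stage 2 — envirotyping.** 90 features per environment in six categories:
63 weather aggregates (4 variables × 4 season groups × {mean, max, min, sd},
minus one degenerate cell), 15 SVD scores of 765 crop-model environmental
covariates, 6 lagged-yield summaries of the previous year at the same field
location, 3 soil assays, 2 floor-binned coordinates (`x' = floor(x/s)·s`,
s = 1.2° latitude / 3.6° longitude), and 1 management flag.

**Stage 3 — genetics.** Fixed QC order (keep phenotyped individuals → MAF ≥ 0.01
→ LD pruning at r² > 0.9, window 100, step 20), then the VanRaden additive
GRM `A = ZZ'/(2Σp(1−p))` and the zero-centered dominance GRM
`D = WW'/Σ(2pq)²`.

**Stages 4–6 — inputs, learner, evaluation.** Four input constructions (E,
G, G+E, GEI) share one BLUE table; the GEI construction is the Kronecker
product `X = E ⊗ G` whose top-k SVD scores are computed in factorized form
`SVD(E ⊗ G) = (U_E ⊗ U_G)(S_E ⊗ S_G)(V_E ⊗ V_G)'` without materializing the
(nq × mq) product. LightGBM regresses the BLUEs on the scores plus a
categorical field location. Evaluation covers CV2 (hold out 20% of
environment×hybrid combinations), CV1 (hold out 20% of final-year hybrids),
and CV0 (predict the final year from earlier years, topped up to an 80:20
train:validation ratio), with Pearson accuracy, the top-20% Coincidence
Index `(B−R)/(T−R)`, the Jaccard tester overlap between training and
validation populations, and Meng's z-test for comparing dependent
overlapping correlations (Bonferroni-corrected).

## Worked example

`examples/` holds one short script per capability. Running
`python examples/05_model_inputs_gbm.py` (a 155-hybrid, 12-environment
synthetic study) prints:

```
G(A)    k=100  mean CV2 accuracy r = 0.059
G(A)+E  k=100  mean CV2 accuracy r = 0.729
G(A)EI  k=100  mean CV2 accuracy r = 0.523
```

Genetics alone barely predicts sparse-testing yield because environments
differ far more than hybrids; adding the 90 environmental features (G+E)
lifts accuracy dramatically, and the multiplicative Kronecker input carries
the same information less parsimoniously — the workflow's central
qualitative finding. `python examples/06_cross_validation_metrics.py` (755
hybrids, 30 environments) shows the scheme signature:

```
CV2: train fraction 80.0%  tester overlap 100.0%
CV1: train fraction 88.9%  tester overlap 92.0%
CV0: train fraction 80.8%  tester overlap 78.0%
```

CV2 shares all testers between training and validation; CV1 can lose rare
testers from validation; CV0 additionally trains on year-1-only testers —
the genetic-relatedness gradient that makes CV0 the hardest scheme.

An end-to-end run (simulate → BLUEs → envirotype → genetics → inputs → fit →
evaluate, with per-stage provenance and resumability) is available both as a
library call (`metboost.pipeline.run`) and as a thin CLI:

```bash
metboost run-all --config config.yaml
```

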