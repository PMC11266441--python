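# Methods

This note records the models, the synthetic-data design, the numerical
choices, and the limitations of `metboost`, in enough detail to judge what a
passing test suite does and does not demonstrate.

## Single-trial mixed models

Each environment is fitted with fixed hybrid and replicate effects and
independent random block-within-replicate, row, and column effects. Variance
components are estimated by REML using average-information (AI) updates after
a three-step EM warm start. Numerical policy:

* convergence when the largest relative parameter change falls below 1e-6,
  capped at 200 iterations (non-convergence is flagged on the result, never
  raised);
* every AI step is step-halved (up to 8 times) against the REML
  log-likelihood so iterations are monotone, with the EM direction as a
  fallback when the AI direction fails to ascend;
* variances are floored at 1e-10; a component collapsing below 1e-8 × var(y)
  is pinned at the boundary (active set) — without pinning, Newton-like steps
  shrink a null component geometrically forever. A pinned component whose
  score (likelihood gradient) is positive at convergence is released once,
  guarding against premature pinning by a joint clipped step;
* plots are sorted canonically (replicate, row, column, hybrid) before any
  design matrix is built, so estimates are exactly invariant to input order;
* a rank check on the fixed design (pivoted QR) raises an estimability error
  naming the aliased columns; hybrids with no observed plots are dropped with
  a warning; a saturated design (one plot per hybrid, no residual degrees of
  freedom) short-circuits to the exact OLS solution;
* components fixed at exactly zero remove their random term, making the
  zero-variance limit literally an OLS fit — the basis of the OLS-equivalence
  tests.

BLUEs are reported as intercept + hybrid effect + mean replicate effect (the
hybrid's expected yield at the average replicate). The random-hybrid refit
supplies the genetic variance and `V̄(Δ)`, computed from the hybrid block of
the inverted mixed-model-equation coefficient matrix as the mean over hybrid
pairs of `PEV_ii + PEV_jj − 2·PEV_ij`. The coefficient of variation uses the
residual variance — the symbol collision in the source formula (σ²_r named
"residual") is resolved per its prose. `H²` is clamped to [0, 1] with a
warning; zero genetic variance yields `H² = 0` with a degenerate flag.

## Envirotyping

The 63-feature weather block is a declared reconstruction: 4 variables
(rainfall, solar radiation, humidity, temperature) × 4 season groups
(meteorological spring / summer / fall intersected with the trial window,
plus the full season) × 4 statistics (mean, max, min, sample SD), minus the
rainfall/full-season/minimum cell, which is almost surely zero. The exact
recipe used in the original study is in a supplementary table we do not
consume; the manifest (name → category, units) makes any discrepancy a
one-line change. Lagged-yield statistics default to mean, min, p25, p50,
p75, max of the previous year's plot yields at the same field location;
first-year environments have all six features missing (they stay as NaN —
the tree learner handles missing values natively). EC compression is an
uncentered truncated SVD (centering is a toggle), with explained variance
measured on the uncentered sum of squares. Coordinate binning is a true
floor (toward −∞); a tolerant floor (1e-9) makes binning idempotent despite
float division. An empty aggregation window produces missing features with a
warning rather than an error.

## Genetic stage

QC order is fixed: individuals → MAF → LD pruning. MAF uses non-missing
dosages; the filter keeps markers with MAF ≥ threshold. LD pruning follows
indep-pairwise semantics on dosage correlations (phased haplotypes do not
exist here): within each sliding window the currently worst pair above r² is
broken by removing the member with the higher mean r² to the window's other
survivors, ties by position (later marker removed); the window then slides
by the step. Missing dosages are mean-imputed per marker before GRM
construction; allele frequencies come from the filtered individual set. The
dominance coding is zero-centered in the alt-allele convention (dosage 0 →
−2p², 1 → 2pq, 2 → −2q²), which gives E[w] = 0 and a unit diagonal in
expectation under Hardy-Weinberg equilibrium.

## Model inputs

All four constructions share one BLUE table and carry the field location
(environment name minus the year) as a categorical column. SVDs are
uncentered and unscaled (raw concatenation), with a standardization toggle
deliberately left off by default; signs follow a fixed convention (largest
right-singular-vector loading positive). The GEI scores use the Kronecker
SVD identity — singular values are all products s_a·t_b of the factor
singular values, and the score of (environment i, hybrid j) on component
(a, b) is `U_E[i,a]·U_G[j,b]·s_a·t_b` — so the (nq × mq) product matrix is
never materialized; a materializing oracle exists behind a size cap for
testing. Ties among singular-value products are broken by stable flat-index
order. When k exceeds the available rank it is reduced with a warning.
Missing feature cells entering an SVD (lagged-yield gaps) are column-mean
imputed for the decomposition only.

## Learner

LightGBM regression with the library's defaults (100 trees, learning rate
0.1, 31 leaves, min 20 records per leaf) — the method prescribes no tuned
values, so the configuration exposes everything and fixes nothing beyond the
seed. Tests and the pipeline run single-threaded deterministic mode;
identical inputs and seed give identical predictions. The categorical
vocabulary is the union of the training and validation levels so encoding is
consistent across the split.

## Cross-validation schemes

CV2 partitions the last two years' environment×hybrid combinations into five
folds per repetition (ten repetitions). CV1 partitions the final-year hybrid
set; a held-out hybrid's records leave training entirely. CV0 samples 20% of
the final-year hybrids that have at least one earlier-year record (the
scheme predicts *known* hybrids in a new year; on the emulated design
essentially all final-year hybrids qualify), takes their earlier records
into training, and adds the earlier records of a 60% sample of the remaining
earlier-year hybrids. Non-sampled hybrids' earlier records stay in training
under CV1 (only sampled hybrids are removed).

The 60% top-up reproduces an ~80:20 record ratio by arithmetic, not by
tuning: with earlier-to-final record mass m = n_12/n_3 and fraction f of
earlier records belonging to final-year hybrids, the expected training mass
is m·(0.6 + 0.08·f); the default study design (below) has m ≈ 1.25 and
f ≈ 0.9, giving ≈ 80.7% training.

## Metrics

The Coincidence Index selects T = ceil(0.2·N) from each ranking (ties broken
by a stable sort on id) and uses R = 0.2·T, the expected overlap when both
rankings select the same fraction at random; CI = (B−R)/(T−R). The tester
overlap is the Jaccard index of the training and validation tester sets,
averaged over all fold×repetition cells. Model comparisons pool each model's
predictions over cells, compute the two accuracy correlations and the
intercorrelation of the prediction vectors, and apply the
Meng–Rosenthal–Rubin z-test (Fisher transforms; f = (1−r12)/(2(1−r̄²))
capped at 1; h = (1−f·r̄²)/(1−r̄²)), Bonferroni-corrected over all model
pairs within a scheme.

## Synthetic study design

The generator emulates the *shape* of a three-year MET study, not maize
biology. Defaults (all configurable):

* **Population.** 150 parents; year 1 uses two testers, years 2–3 share four
  (one carried over), plus one minor tester crossed to 5 dedicated parents
  in years 2–3 (~1% of hybrids, mirroring the small "other tester" share of
  the emulated population). Parents are fully inbred; testers may be
  heterozygous. Allele frequencies are drawn uniformly on the configured MAF
  range and realized by exact-count assignment (round(q·N) carrier lines,
  randomly placed; tester alleles exact-counted per tester group) so the
  hybrid-panel MAF stays within the configured band — i.i.d. draws across a
  handful of tester lines would quantize the tester-side frequency far
  outside it. 5% of markers are exact duplicates of their left neighbour,
  giving the LD-pruning stage a known target.
* **Trials.** Environments per year default to (6, 12, 12): the first year
  is smaller, consistent with its half-size hybrid panel, and this ratio is
  what places the CV0 recipe at the 80:20 ratio derived above. Each
  environment evaluates a random 35% of its year's panel (incomplete
  overlap) in a 2-replicate RCBD: replicates occupy side-by-side column
  bands on a 24×20 field grid, blocks are the rows within a band.
* **Phenotypes.** Plot yield = 10 Mg/ha intercept + additive value (i.i.d.
  normal marker effects rescaled to exactly v_g_add = 0.30 across the
  panel) + dominance value (centered heterozygosity codes, v_g_dom = 0.05)
  + environment effect (latent index z_e, v_env = 2.0) + G×E deviation
  (v_gxe = 0.20, half of it the product of a marker-determined plasticity
  score with z_e so the interaction is learnable, half unstructured) + block
  (0.05) / row (0.03) / column (0.03) effects + residual (1.0). These
  values put the emulated trial statistics in the neighbourhood of the
  study the package targets (CV% ≈ 10, H² ≈ 0.4–0.5). The full per-plot
  decomposition is stored as ground truth and reproduces every yield
  exactly.
* **Environment layers.** Weather is a 30-minute series over a configurable
  season window (default April 15 – September 30; the real windows are not
  published) with diurnal structure and means tied to z_e; the 765-column EC
  matrix is rank-10 signal (leading factor z_e) plus 0.001-SD noise, so 15
  components capture ≥ 99% of its variance; coordinates are regional centers
  snapped to the midpoint of their (1.2°, 3.6°) bin and jittered by ±0.25°,
  so nearby trials provably share a bin; history is the realized plot yields
  of the previous year at the same location (first-year locations have
  none). Missing-data injection (plots, weather gaps) is off by default.

What the generator does **not** emulate: real maize LD structure and allele
frequency spectra, weather climatology, crop-model mechanics, spatial field
trend beyond i.i.d. row/column effects, or realistic tester-by-year entry
decisions. Passing tests therefore demonstrate that the *pipeline machinery*
is correct and that its qualitative behaviour (G+E ≥ G under G×E; the
CV2/CV1/CV0 overlap gradient; the 80:20 CV0 arithmetic) emerges under
controlled conditions — not that the package would reach any particular
accuracy on real data.

## Problem sizes used in the checks

The test suite runs the full workflow at compact scales chosen as the
smallest sizes at which the checked quantities are stable: a 205-hybrid /
12-environment study for the pipeline-level properties and the G+E vs G
comparison (10 repetitions × 5 folds), the default 755-hybrid /
30-environment study for the CV-scheme and tester-overlap properties, 200
replicate 100-hybrid trials for REML recovery, and 1000 replicates for the
Meng-test null. The acceptance script uses the default study with all 30
trials fitted by REML.

## Known limitations

* The AI-REML works on the observation-level covariance (n × n); trials
  beyond a few thousand plots would want a sparse MME-based implementation.
* `V̄(Δ)` uses the full hybrid PEV block; memory grows with the square of
  the hybrid count per trial.
* The factor-analytic multiplicative mixed model often used as a baseline
  for MET analysis is out of scope; comparisons here are among the package's
  own model family.
* CV0's "additional 60%" is resampled independently per fold, so a hybrid's
  earlier records may appear in several folds' training sets (the validation
  contract is unaffected).
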