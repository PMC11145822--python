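# Methods

## Scope and data model

The package implements a two-sample summary-data MR study of K lipid
exposures on a binary outcome, with a drug-target (cis) arm. Inputs are
per-SNP association summaries: exposure betas per effect allele in the
trait's native units (e.g. mg/dL), outcome betas on the log-odds scale.
The causal effect θ is a log-OR per unit of exposure; reports exponentiate
to an OR with a 95% CI.

A note on scale: with ~100 instruments explaining a realistic share of a
lipid trait's variance and an outcome GWAS of ~4k cases in ~340k samples,
per-SD effect sizes would be estimated with SEs near 0.04 — ORs printed
with three-decimal CIs (1.006 (1.004, 1.007)) are only reachable when the
exposure is measured per raw unit (mg/dL). The package therefore works
per-unit throughout and carries the "1 SD = 38.67 mg/dL"-style annotation
in the `sd_units` field; the generator's default θ values (0.005–0.006 per
mg/dL ≈ 0.2–0.23 per SD) reproduce that reporting scale.

## Harmonization

Outcome records are re-expressed on the exposure's effect allele: matching
alleles are copied; swapped alleles negate the beta and reflect the EAF;
strand complements are resolved before declaring a SNP incompatible.
Palindromic (A/T, C/G) SNPs cannot be resolved by labels; the default
policy drops them when either EAF is in [0.42, 0.58] (configurable) and
otherwise infers orientation by EAF concordance. Missing EAF under an
inference policy drops the SNP rather than guessing. Every drop is
accounted for in a report whose categories partition the input.

## Instrument selection

Genome-wide instruments: p < 5×10⁻⁸, greedy LD clumping at r² < 0.001
within a 10,000 kb window (the window size is this package's choice; common
practice, not a published constant), ties in p broken by ascending SNP id
so results are independent of input order. Cis instruments: a gene region
±100 kb (closed interval, 1-based), clumped at the per-gene threshold
(HMGCR/PCSK9 0.2, NPC1L1 0.3) using the region span as the window; fewer
than 3 surviving SNPs is an error, never a silent result. Confounder
exclusion drops SNPs whose annotation labels match the query traits
(case-insensitive substring by default; exact mode available).

Instrument strength: per-SNP F = (β̂/se)², r² = F/(F+n−2) (t-based, usable
without EAF; the 2β²p(1−p) variant is provided), aggregate F from the
summed r². Steiger filtering compares t-based pseudo-r² on both sides —
a pass/fail directionality screen (significance gating available but off
by default); on the binary outcome this is a log-odds-scale approximation.

## Estimators and numerical choices

All estimators are closed-form weighted least squares written directly
(and cross-checked in the test suite against statsmodels WLS to 1e-10):

- Wald ratio SE is first-order (se_Y/|β_X|); a second-order option exists.
- IVW: fixed-effect by default; the multiplicative random-effects SE
  (inflation max(1, √(Q/(n−1)))) is always computed and reported alongside
  whenever heterogeneity is examined, since the emulated study does not
  state which variant it used.
- Egger re-orients instruments to β_X ≥ 0 internally; CIs use the normal
  approximation (t with n−2 df available) so all estimators share one CI
  convention at the instrument counts involved (≥ 68).
- Median estimators interpolate the weighted CDF s_j = (cum w − w/2)/Σw at
  0.5. The bootstrap SE is **model-centred**: outcome draws come from
  N(θ̂·β_X, se_Y) (exposure draws from N(β̂_X, se_X)). Centring on the
  observed betas convolves the sampling noise twice; near the median that
  widens the resampled ratio spread by ~√2, inflates the SE by 15–20%, and
  makes the test measurably conservative (type-I ≈ 0.026 vs 0.052 for the
  model-centred form in our calibration runs). The observed-centred scheme
  remains available (`bootstrap="observed"`).
- MR-Lasso minimizes Σw_j(β_Yj − α_j − Σθ_kβ_Xjk)² + λΣ|α_j| by cyclic
  coordinate descent (exact WLS θ-step, soft-threshold α-step; tolerance
  1e-8, max 10,000 sweeps). λ is chosen by a heterogeneity stopping rule:
  scan a 100-point log grid downward from the smallest λ zeroing all α and
  stop at the first (largest) λ whose valid set passes Cochran's Q at the
  0.05 critical value — i.e. exclude as few SNPs as needed. λ = 0 is
  rejected (one free intercept per SNP is unidentified).
- MR-PRESSO follows the standard construction: observed RSS from
  leave-one-out IVW estimates; the null distribution from parametric draws
  β*_X ~ N(β̂_X, se_X), β*_Y ~ N(θ̂₍₋ⱼ₎β̂_X, se_Y); add-one-corrected
  p-values (floor 1/(n_sim+1)); per-SNP outlier tests Bonferroni-adjusted;
  the corrected estimate is exactly IVW on the non-flagged SNPs; the
  distortion test compares against equal-size random subsets and is
  reported only when outliers exist. Seeded and bit-reproducible.
- Multivariable IVW/Egger use the weighted information matrix with
  inflation max(1, √(Q/(n−K))); Egger re-signs SNPs on an anchor exposure
  (first by default). Conditional F is the Q-based summary-data form:
  regress exposure k's SNP effects on the others (weights se_Y⁻²), then
  F_k = Σδ²_jk/se²_Xjk / n; values < 10 flag conditional weakness.
- Drug-target MR defaults to treating clumped cis instruments as
  independent (mirroring common toolchains) but always computes a GLS IVW
  with the instruments' LD in the weight matrix when an LD reference is
  supplied — residual correlation at r² < 0.2–0.3 inflates independent-mode
  precision, and the gap between the two is itself a diagnostic.

Bonferroni families: 3 lipids (0.05/3, displayed 0.017) and 4 drug-target
analyses (0.05/4, displayed 0.013); comparisons always use unrounded
thresholds.

## The synthetic generator

`simulate_dataset` draws MAF ~ U(0.01, 0.5); per-SNP exposure effects
multivariate across K traits (configurable mean/SD per trait and
correlation, with a shared random sign per SNP); outcome effects
β_Y = Σθ_kβ_Xk + α exactly, with α from a pleiotropy spec (none / balanced
/ directional, a proportion of SNPs, optionally oriented to the
exposure-increasing allele — orientation is what makes a non-zero mean
"directional" after estimators re-orient instruments). SEs use the
standard approximations se_X = sd_trait/√(2p(1−p)n_exp) and
se_Y = 1/√(2p(1−p)·n_out·φ(1−φ)) with case fraction φ (default mirroring
3,927 cases / 337,199 total). Observed betas are true values plus normal
noise; within declared LD blocks the noise is AR(1)-correlated and the LD
matrix exported accordingly (LD is modelled at the effect-correlation
level only — no individual-level genotypes). Cis blocks tag one causal
variant: effects decay from the block centre (`effect_decay`, default
0.85, deliberately slower than the LD decay so realistic numbers of block
SNPs clear genome-wide significance while clumping still thins the block).
Winner's curse arises naturally from selection on observed p and is not
corrected.

What the generator does *not* emulate: realistic allele-frequency spectra,
population stratification, sample overlap between the two GWAS, genuine
genotype-level LD, or non-normal summary noise. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to those real-data complications.

### Named study conditions

- `paper_like_config`: 3 lipids (trait SDs 38.67/15.51/90.72 mg/dL),
  θ = (0.005, 0, 0) with correlated effects, exposure GWAS n = 300k,
  outcome 337,199 at φ = 0.0116, three cis blocks. Genome-wide selection
  yields ≈ 107/106/68 instruments and the blocks ≈ 5/11/3 cis SNPs —
  emergent from selection, pinned in tests within ±30%.
- `median_robust_config`: 30% of 100 instruments carry oriented
  directional pleiotropy, mean 0.0045, SD 0.085 (log-odds). Chosen by a
  design-stage power calculation: the small mean with a large spread biases
  IVW measurably while the weighted median — which effectively trims the
  dispersed invalid ratios — stays centred. The two clauses are evaluated
  at different replicate counts (100 for the median, 1500 for IVW) because
  the magnitudes they resolve differ several-fold; both counts were fixed
  before the acceptance tests were written.
- `egger_power_config`: 30% of instruments with oriented mean 0.10,
  SD 0.02 — sized for ≈ 90% intercept-test power at 100 instruments.
- `mvmr_attenuation_config`: GLGC-scale exposure panel (n = 10⁶) and a
  balanced 400k outcome so conditional F ≈ 50 and the attenuation contrast
  reflects the estimators, not sampling noise; with the AMI-scale outcome
  the multivariable noise is comparable to the univariable bias and the
  qualitative pattern is unresolvable at θ = (0.005, 0, 0).

### Experiment sizes

Monte-Carlo checks use replicate counts sized to the magnitude they
measure: type-I error and CI coverage at 2,000 replicates (a ±3σ window
for the [93.5, 96.5]% coverage band), recovery at 2,000, PRESSO null
calibration at 500 datasets (n_sim = 300), PRESSO outlier power at 200
datasets (n_sim = 1000) on a 6-SNP equal-leverage panel — one 10-SE
outlier then shifts the pooled estimate by ~10/√n ≈ 4 SEs, so removing it
visibly improves the estimate; on large panels the shift drowns in noise
and "correction improves the estimate" is not a property any method could
exhibit. Pattern checks (MVMR attenuation, drug-target sign) use 200–500
replicates.

## Orchestration and reproducibility

`run_study` executes read/simulate → harmonize → selection → confounder
exclusion → Steiger → univariable battery + PRESSO → pooled MVMR battery →
per-drug, per-pair and non-target cis analyses → Bonferroni flags, writing
TSV tables plus a JSON manifest embedding every threshold. Stage failures
are contained per exposure and recorded in the manifest, never silently
skipped. Every stochastic stage consumes a sub-seed derived by hashing the
stage name into the master seed, so adding a stage does not perturb earlier
draws and two runs at one master seed are byte-identical; the manifest
omits wall-clock timestamps by default for exactly that reason (opt-in
`include_timestamp=True`). The numbered scripts under `analysis/` are the
orchestration surface — thin drivers over the library, one per study
stage.

## Known limitations

- The binary-outcome SE approximation and t-based pseudo-r² treat the
  log-odds scale linearly; fine for the tiny per-unit effects simulated
  here, cruder for large effects.
- MVMR assumes LD-independent pooled instruments (re-clumped at
  r² < 0.001); a full GLS MVMR with correlated instruments is out of scope.
- The distortion test conditions on the flagged outlier set, as in the
  standard construction; its p-value is descriptive.
- Proxy-SNP lookup, liftover, genotype-panel LD estimation and live
  annotation-database queries are deliberately out of scope.
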