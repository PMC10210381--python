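# Methods

## The causal model

`coagmr` implements two-sample summary-data Mendelian randomization: genetic
variants G₁…G_k serve as instruments for a continuous exposure X (here,
circulating coagulation-factor levels standardized to unit variance), and
their associations with a binary outcome Y (endometriosis case status) are
combined into an estimate of the causal log odds ratio θ per SD of exposure.
The identifying assumptions are the usual three: each instrument is robustly
associated with X; instruments are independent of confounders of X→Y; and
instruments affect Y only through X (no horizontal pleiotropy). The
estimators differ in how they relax the third assumption:

* **Wald ratio** per SNP: β̂ⱼ = β̂_out,j / β̂_exp,j, with first-order delta
  SE se_out,j / |β̂_exp,j|. The exposure-side noise term of the second-order
  expansion is omitted; this is the conventional choice and makes the IVW
  weighted mean of ratios algebraically identical to the zero-intercept
  weighted regression of β̂_out on β̂_exp with weights 1/se_out² (the two
  closed forms are cross-checked to 1×10⁻¹⁰ at run time).
* **Fixed-effects IVW** assumes all instruments valid and homogeneous.
* **Multiplicative random-effects IVW** keeps the IVW point estimate and
  inflates the SE by √max(1, Q/(k−1)); the floor at 1 means the
  random-effects interval is never narrower than the fixed-effects one, and
  the point estimate never moves — the pattern expected of this estimator
  (same OR, wider CI under heterogeneity). It is added to the result set
  exactly when the IVW Cochran's Q p-value is below α.
* **MR-Egger** regresses β̂_out on β̂_exp with a free intercept after
  orienting every SNP to β̂_exp ≥ 0. Under InSIDE (instrument strength
  independent of direct effects), the slope is a consistent causal estimate
  and the intercept estimates the mean directional pleiotropic effect.
  Parameter SEs are scaled by max(1, √(Q_egger/(k−2))) by default (the flag
  is recorded in run metadata).
* **Weighted median** returns the value at cumulative normalized weight 0.5
  of the ordered Wald ratios (linear interpolation between bracketing
  ratios, weights 1/se(β̂ⱼ)²), consistent while valid instruments carry more
  than half the weight. Its SE comes from a parametric bootstrap (default
  1000 replicates) that perturbs per-SNP exposure and outcome betas by
  their SEs; the bootstrap is always seeded, so results are bit-reproducible.

P-values for IVW/Egger/WM use the normal reference (not t), standard for
summary-data MR at these instrument counts; the 95% CI multiplier is fixed
at z = 1.959964. ORs are exp-transformed betas and CI bounds.

### Sensitivity analyses

* **Cochran's Q** on the Wald ratios around the IVW estimate (df = k−1) and
  around the Egger fit (df = k−2), upper chi-square tail.
* **Leave-one-out**: fixed-effects IVW re-estimated k times with each SNP
  removed, to expose single influential instruments.
* **Steiger directionality**: per-SNP variance explained is computed from
  summary data as r² = z²/(z² + n − 2) on each side; the inferred direction
  is exposure→outcome when Σr²_exp > Σr²_out, with a two-sided z test on
  the difference of summed Fisher-transformed correlations
  (variance 1/(n−3) per SNP). For the binary outcome the z-based r² is used
  directly rather than a liability-scale conversion; the choice is recorded
  in output metadata.
* **Multiple testing**: Bonferroni, p_adj = min(1, m·p), with the family
  defined as the exposures tested against one outcome cohort (default
  m = 11). This ×m arithmetic reproduces published adjusted values at their
  printed precision (1.25×10⁻⁴ → 1.375×10⁻³, printed 1.38×10⁻³;
  5.31×10⁻⁴ → 5.841×10⁻³, printed 5.8×10⁻³).

### Instrument selection

Selection filters candidate SNPs at P < 5×10⁻⁷ (strict inequality), then
applies greedy clumping: repeatedly index on the lowest-p remaining SNP and
discard SNPs on the same chromosome within ±10 Mb whose r² with the index
exceeds 0.1 (strict). Ties on p break deterministically by (chromosome,
position, id). SNPs absent from the LD matrix are treated as independent
and logged. Instruments missing from the outcome may be replaced by the
highest-r² proxy above r² = 0.8 (ties: smallest distance, then id), with the
proxy's alleles re-expressed in the target's through the proxy table's
allele map. Both the per-SNP F = z² (which drives the F > 10 screen) and the
multi-instrument F = R²(n−k−1)/(k(1−R²)) are reported, since either
convention appears in applied work; per-SNP r² uses z²/(z²+n−2), which is
robust to unknown trait scaling.

### Harmonization

Non-palindromic SNP pairs are aligned by exact match, allele swap (outcome
beta negated, eaf mirrored), strand complement (A↔T, C↔G; no sign change),
or swap-plus-complement. For palindromic SNPs the allele labels cannot
distinguish swap from strand flip, so orientation is decided by
effect-allele frequency: both frequencies must lie outside the ambiguity
band |eaf − 0.5| ≤ 0.08 (band configurable; which side's frequency is
required is a config switch, default both), and disagreement across the 0.5
mirror triggers a sign flip. Palindromes with a missing frequency on either
side are always dropped — strictly safer than guessing. Indels and
multi-allelic sites are rejected at read time. Every SNP's fate (kept with
action, proxied, dropped with reason) is recorded, and kept + dropped
always equals the input count.

### Meta-analysis

Outcome cohorts are combined SNP by SNP before MR with the fixed-effect,
standard-error-weighted scheme (wᵢ = 1/seᵢ², β_meta = Σwᵢβᵢ/Σwᵢ,
se_meta = (Σwᵢ)^(−1/2)) after re-expressing cohort B on cohort A's effect
alleles with the same logic as exposure–outcome harmonization. The
SE-weighted scheme (rather than sample-size z-weighting) is used because
the MR stage needs combined betas and SEs on the log-odds scale. No
between-cohort heterogeneity model is applied at the SNP level; heterogeneity
is assessed downstream at the MR stage.

### Power

Analytic power for a two-sided test of a log-OR β₁ against a binary outcome
with case fraction φ = ratio/(1+ratio):
power = Φ(|β₁|·√(n·R²·φ(1−φ)) − z₁₋α/₂), returning α/2 at β₁ = 0 and
monotone in n, R² and |β₁|. The same variance model underlies the
generator's outcome SEs, so analytic and simulated power agree by
construction when instruments are strong; the acceptance script verifies
this agreement within Monte-Carlo error across low/moderate/high-power
scenarios.

## The synthetic-data generator

Simulation is at summary level: no individual genotypes are drawn. For k
instruments with MAF pⱼ ~ U(maf_range) (default 0.05–0.5):

* per-SNP explained-variance shares are r²ⱼ = R²·uⱼ²/Σuⱼ² with
  uⱼ ~ U(0.7, 1.3), and true effects bⱼ = √(r²ⱼ/(2pⱼ(1−pⱼ))) on the
  unit-variance exposure scale, so Σ 2pⱼ(1−pⱼ)bⱼ² = R² exactly;
* effect alleles are coded exposure-increasing (bⱼ > 0), the convention
  used when reporting instruments; this also gives directional pleiotropy a
  well-defined sign under the Egger orientation step;
* exposure SEs are √((1−R²)/(2pⱼ(1−pⱼ)n_exp)); observed betas add
  N(0, se²) noise (suppressible for exact-limit tests, with reported SEs
  unchanged);
* outcome effects follow γⱼ = θbⱼ + αⱼ with pleiotropy
  αⱼ ~ N(pleio_mean, pleio_sd²) drawn independently of bⱼ, so InSIDE holds
  by construction and pleio_mean = 0 gives balanced pleiotropy; binary-trait
  SEs are 1/√(2pⱼ(1−pⱼ)·n·φ(1−φ));
* optional background null SNPs (true effect 0) exercise the significance
  screen; optional palindromic allele draws exercise strand handling; the
  two-cohort generator scrambles the second cohort's alleles with a
  recorded swap/strand-flip key so alignment can be verified bit for bit.

Defaults mirror the motivating study: 3–13 instruments with per-SNP F well
above 10, exposure GWAS of ~20 000, outcome cohorts shaped 8288:68 969
(FinnGen) and 4354:217 500 (UK Biobank). Per-exposure R² values are not
published in the main text of the motivating study, so default scenarios
use R² ∈ {0.01, 0.02, 0.05} as a fixture choice. All randomness flows
through one seeded `numpy` Generator; identical truth (including seed)
reproduces output bit-identically.

What the generator does **not** emulate: realistic LD-block structure
(instruments are placed > 10 Mb apart; LD enters only through explicit
matrices in clumping tests), imputation noise, exposure–outcome sample
overlap, population stratification, and individual-level nonlinearity of
the logistic model (outcome SEs use the large-sample score approximation).
Passing tests therefore validate the statistical machinery, not robustness
to those real-data complications.

## Validation scenarios and problem sizes

The acceptance script and the statistical test suite use: null calibration
at θ = 0, k = 10, 2000 replicates; recovery at θ = ln 0.42, k = 13,
R² = 0.02, n_exp = 20 000, FinnGen-shaped outcome, 500 replicates; Egger
discrimination at pleio_mean = 0.01 with k = 13, R² = 0.05,
n_exp = 50 000, 500 replicates; and power agreement at three effect sizes
spanning power ≈ 0.2/0.8/0.99, 2000 replicates each. The Egger scenario
deliberately uses stronger instruments than the recovery scenario because
MR-Egger is only approximately unbiased when instrument-strength spread is
large relative to exposure-side noise (high I²_GX); at mean F ≈ 30,
regression dilution visibly attenuates the Egger slope and leaks into the
intercept.

## Known limitations

* **First-order Wald SEs undercover at moderate instrument strength.** The
  IVW 95% CI attains nominal coverage when exposure effects are precisely
  estimated (measured 95.1% with exposure noise suppressed) but erodes to
  ~90–92% at mean per-SNP F ≈ 30 (e.g. R² = 0.02 over 13 instruments at
  n_exp = 20 000), driven by weak-instrument attenuation of the point
  estimate (~2% toward the null) plus ratio-denominator noise absent from
  the first-order SE. This is a documented property of the standard
  estimator, retained deliberately for exact equivalence with the weighted
  zero-intercept regression form.
* The weighted-median "valid majority" consistency guarantee is asymptotic;
  with noisy ratios and a large invalid minority the finite-sample estimate
  shifts toward the invalid side.
* MR-PRESSO-style outlier correction, mode-based estimators, multivariable
  MR and bi-directional MR are out of scope (the motivating design lacks
  genome-wide exposure data for the reverse direction).
* Strict "every per-SNP F > 10" is a typical-case property of the default
  generator settings, not a sure invariant: observed F = z² fluctuates
  around its expectation, so extreme draws can dip below 10.
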