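# Methods

## Setting and notation

`mrkit` works entirely at the summary level.  For variant j the exposure
GWAS reports an effect β̂ₓⱼ (SD units of a standardized quantitative trait
per effect allele) with standard error σₓⱼ, and the outcome GWAS reports
β̂ᵧⱼ (log-odds for a binary outcome) with σᵧⱼ.  Exposure and outcome
cohorts are assumed non-overlapping (two-sample design), so the two noise
components are independent.  The target parameter θ is the effect of one SD
of exposure on the log-odds of the outcome.

## Instrument selection

Selection applies, in order: (1) genome-wide significance, P < 5×10⁻⁸
strict; (2) greedy LD clumping at r² < 0.01 within a 10,000 kb window —
candidates are ranked by ascending p-value, each index SNP removes
remaining same-chromosome SNPs within half the window either side whose r²
with it is at or above threshold, so every retained pair is below
threshold; (3) MAF ≥ 1% (boundary kept — the exclusion rule is MAF < 1%);
(4) outcome matching, substituting a proxy with r² > 0.8 (strict) when the
SNP is absent from the outcome file.  The order is fixed; a commutation
test confirms that swapping the clump and MAF steps changes nothing when no
SNP is affected by both.

LD is an explicit input (square or long-format r² table) rather than a
bundled reference panel; pairs absent from the table count as r² = 0.
Because an r² matrix carries no sign information, a proxy is accepted only
when its outcome EAF is orientation-consistent with the requested SNP's
exposure EAF (|difference| < 0.2, logged); proxies are a different locus,
so letter-based allele matching does not apply to them and that EAF gate is
their orientation rule.

Instrument strength uses the standardized-trait approximation
R²ⱼ = 2β̂ₓⱼ²·EAFⱼ(1−EAFⱼ) and F = R²(n−k−1)/(k(1−R²)).  The reported
`mean_f` averages per-SNP F values (k = 1); the joint F from the summed R²
is reported alongside.  Sets with mean F ≤ 10 carry a weak-instrument
warning but are not refused.

## Harmonization

The outcome record is rewritten onto the exposure's effect-allele frame:
swapped alleles negate β̂ᵧ and complement the EAF; alleles that match only
after strand complementing are complemented first; anything else is dropped
as unconcordant.  Palindromic variants (A/T, C/G) cannot be oriented from
alleles alone.  The default policy excludes them — the conservative choice.
The `infer_by_eaf` policy orients them by allele-frequency agreement,
dropping the variant when either trait's EAF falls in the ambiguity band
(default 0.42–0.58, common practice).  Harmonization is idempotent, and all
downstream estimates are invariant (to 1e-12) under any consistent allele
recoding of the input files; both properties are tested.

## Univariable estimators

* **Wald ratio** θ̂ⱼ = β̂ᵧⱼ/β̂ₓⱼ with first-order delta SE σᵧⱼ/|β̂ₓⱼ|.
  The exposure-side noise is ignored, standard with strong instruments
  (F ≫ 10); this is the main reason several interval procedures below run
  slightly conservative.
* **IVW**: inverse-variance weighted mean of the ratios, wⱼ = β̂ₓⱼ²/σᵧⱼ²,
  algebraically the weighted least-squares slope of β̂ᵧ on β̂ₓ through the
  origin.  Cochran's Q = Σwⱼ(θ̂ⱼ−θ̂)² on J−1 df measures heterogeneity.
  The default variant is multiplicative random effects — SE inflated by
  max(1, √(Q/(J−1))) — because real instrument sets are typically
  heterogeneous; the fixed-effect variant is a flag away.  Normal reference
  for p-values.
* **MR-Egger**: each SNP oriented so β̂ₓⱼ ≥ 0, then weighted regression of
  β̂ᵧ on β̂ₓ with a free intercept.  The intercept estimates average
  directional pleiotropy (consistent under InSIDE — instrument strength
  independent of direct effects); the slope is the causal estimate.  Both
  use t(J−2) references and the same max(1, √(Q/(J−2))) SE floor.
* **Weighted median**: weighted 50th percentile of the ratios with linear
  interpolation across cumulative weights (knot j at cumulative weight
  minus wⱼ/2); consistent when valid instruments hold a weight majority.
* **Weighted mode**: peak of a weighted Gaussian kernel density over the
  ratios on a 512-point grid spanning the ratios ± 3 bandwidths (ties take
  the lowest grid point); bandwidth is a modified Silverman rule,
  0.9·min(weighted sd, weighted MAD/0.6745)·J^(−1/5), times a
  user-scalable factor.  Consistent when the largest group of instruments
  shares the true ratio.
* Median and mode SEs come from a parametric bootstrap: resample
  θⱼ* ~ N(θ̂ⱼ, se(θ̂ⱼ)²), re-estimate, take the SD over 1000 draws
  (default) under an explicit seed.

Odds-ratio reporting is exp(β) with CI exp(β ± 1.96·SE) throughout.

## MR-PRESSO

The global test forms, for each SNP, the leave-one-out IVW slope θ̂₋ⱼ and
the weighted residual sum of squares RSS = Σⱼ(β̂ᵧⱼ−θ̂₋ⱼβ̂ₓⱼ)²/σᵧⱼ²; its
null distribution is simulated by redrawing both axes
(β̂ₓⱼ* ~ N(β̂ₓⱼ, σₓⱼ²), β̂ᵧⱼ* ~ N(θ̂₋ⱼβ̂ₓⱼ, σᵧⱼ²)) and recomputing RSS
identically.  Per-SNP residual contributions give two-sided empirical
outlier p-values, Bonferroni-corrected across SNPs (α = 0.05 default); the
corrected estimate is an IVW refit on the outlier-free subset, bit-exact
against calling the IVW routine directly.  The distortion test compares the
raw-versus-corrected contrast with the same contrast under random removal
of equally many SNPs.

Empirical p-values are floored at 1/(n_sim+1), so the smallest achievable
Bonferroni-corrected outlier p is J/(n_sim+1): with the default n_sim =
1000, detection at α = 0.05 requires J < 50·(α/0.05).  Raise `n_sim` for
larger instrument sets.

## Multivariable MR

The joint design takes the union of each exposure's instruments, re-clumps
jointly (index SNP = smallest p across exposures, preventing
double-counting of correlated instruments contributed by different
exposures), drops SNPs missing from any trait (complete-case — imputing
absent effects at zero would bias that exposure toward the null), and
aligns every trait to the first exposure's allele frame.  Estimation is
weighted multivariable regression of β̂ᵧ on the K exposure columns, no
intercept, weights 1/σᵧⱼ², covariance inflated by max(1, Q/(J−K)), t(J−K)
p-values; K = 1 reduces exactly to fixed-effect IVW.  A per-exposure
conditional instrument-strength proxy (mean weighted chi-square of each
exposure's effects after projecting out the other columns) is reported
descriptively, with no threshold enforced.  Covariate traits (lifestyle
risk factors) extend K through the identical machinery.

## Study pipeline and FDR

`run_univariable` executes the exposures × outcomes grid, runs the enabled
estimators plus diagnostics per pair, and applies Benjamini–Hochberg FDR
within each (outcome, method) family across exposures — matching the usual
forest-plot layout where each method column carries its own FDR; a pooled
family is available by flag.  The MR-PRESSO global p is a diagnostic, not
an effect test, and stays outside the FDR families.  Pair-level failures
(e.g. zero surviving instruments) flag a row and the study continues.  All
randomness derives from one master seed through
`numpy.random.SeedSequence(master, spawn_key=(exposure, outcome, task))`;
reruns are byte-identical, and output tables use fixed 10-significant-digit
formatting to keep that true.

## Synthetic data

The generator emulates summary-level inputs directly, with no
genotype-level simulation: per-SNP exposure effects γⱼ from a configurable
distribution, pleiotropic outcome components αⱼ ~ N(μ_α, σ_α²) (sd
multiplied by `outlier_scale` for a chosen fraction of SNPs), true outcome
effects Γⱼ = θγⱼ + αⱼ on the log-odds scale, and independent Gaussian
noise at the analytic standard errors σₓⱼ = 1/√(2nₓ·EAFⱼ(1−EAFⱼ)) and
σᵧⱼ = 1/√(2·EAFⱼ(1−EAFⱼ)·n_eff) with n_eff the case-control effective
sample size.  Defaults represent a well-powered study: 100 SNPs, exposure
n = 100,000, 20,000 cases / 20,000 controls, EAF uniform on (0.05, 0.95),
20% palindromic allele pairs to exercise harmonization.  Outcome effects
are generated directly on the log-odds scale rather than through a
liability model so that the simulated θ is interpretable as a log-OR, the
scale on which two-sample MR reports.

The default instrument-effect distribution is signed-uniform, |γ| ~
U(0.02, 0.06) with random sign: variants used as instruments have cleared
a genome-wide significance filter, so their effects are bounded away from
zero, and this default mimics that post-selection property without
simulating the selection itself.  Two consequences matter for
interpretation: effects with random signs make *balanced* instrument sets,
so scenarios that need directional bias in IVW (Egger's raison d'être, the
valid-majority median scenario) must use a same-sign distribution
(`("uniform", low, high)`); and with all effects well away from zero the
Wald-ratio delta SEs are accurate.  Block-LD fixtures place `ld_block_size`
SNPs per block sharing one underlying effect (±2% jitter), constant
within-block r², zero between blocks.  MVMR scenarios draw per-SNP effect
vectors multivariate normal with a user correlation matrix; exposure GWAS
noise is independent across exposures (separate cohorts), so the designed
correlation lives in the true effects.

What the generator does *not* emulate: LD-induced correlation between
instrument effect estimates, winner's curse, allele-frequency differences
between cohorts, sample overlap, or liability-scale attenuation.  Passing
tests therefore demonstrate correctness of the estimators under the stated
sampling model, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

- Strict inequalities follow the selection rules exactly: P < 5×10⁻⁸,
  proxy r² > 0.8; MAF keeps the ≥ 1% boundary.
- Clump ties (equal p) break by snp_id; proxy ties by smaller p then
  snp_id; mode ties take the lowest grid point.
- All-identical ratios give Q = 0, p = 1, and a zero kernel bandwidth, in
  which case the common ratio is returned directly.
- β̂ₓ = 0 makes a Wald ratio undefined and is a domain error; empirical
  p-values are floored at 1/(n_sim+1); reported p-values are clipped into
  (0, 1].
- LD matrices are symmetrized after an asymmetry check at 1e-8 and must
  carry a unit diagonal.
- MVMR refuses rank-deficient designs, naming near-perfectly collinear
  exposure pairs.

## Calibration properties and known limitations

Under the null (θ = 0, no pleiotropy, 100 SNPs, defaults above) the Q
test, the Egger intercept test and the MR-PRESSO global test all reject at
5% within Monte-Carlo error, and IVW/Egger 95% CIs cover the null at 95%.
The parametric-bootstrap SEs of the weighted median and especially the
weighted mode run conservative: the bootstrap SD exceeds the estimators'
true sampling SD by ~10–15% (median, null coverage ≈ 97%) and more for the
mode (null coverage ≈ 99%), a known property of bootstrap-SE mode
estimation — their intervals are honest but wide, and their p-values
understate significance rather than overstating it.

Other limitations: first-order Wald SEs ignore exposure-side noise (fine at
mean F ≫ 10, anticonservative for weak instruments); MR-Egger shows its
usual finite-sample attenuation when instrument strengths vary little; the
MVMR conditional-strength statistic is descriptive, not the formal
conditional F; no Steiger directionality filtering, radial MR, or
simple/penalized mode variants; indels and multi-allelic sites are
rejected at parse time; positions are opaque coordinates — no genome-build
awareness or liftover.
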