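# Methods

## The analysis

`neuromr` estimates the causal effect of a brain-imaging exposure (a
white-matter DTI parameter or a regional gray-matter volume, measured per
standard deviation) on the risk of a neuropsychiatric disorder, using only
GWAS summary statistics from two non-overlapping samples.  For each
exposure–outcome pair:

1. **Instruments.** SNPs with exposure p < 5×10⁻⁸ are retained; greedy
   clumping keeps the best SNP and removes every other significant SNP with
   r² ≥ 0.001 to a kept SNP.  When SNP positions are supplied the clump is
   restricted to a 10,000-kb window (a convention; the r² cutoff is the
   binding rule, and without positions the window is ignored).  Exposures
   with no surviving SNP are recorded as "no strong instrument" and
   excluded, never silently dropped.
2. **Harmonization.** Outcome records are aligned to the exposure's effect
   allele: direct matches kept, swapped alleles negate the outcome beta,
   strand complements are resolved, irreconcilable pairs dropped and
   counted.  Palindromic (A/T, C/G) SNPs are kept under a forward-strand
   assumption rather than excluded — the analysis choice this pipeline
   standardizes on, since most disorder GWAS ship without allele
   frequencies that would allow a frequency check.  Duplicate SNP ids keep
   the smallest-p row.  P-values of exactly 0 are floored at the smallest
   positive normal double (`MIN_PVALUE`) before any quantile transform.
3. **Estimation.** The primary estimator is IVW for pairs with ≥ 2
   instruments and the Wald ratio for single-instrument pairs.  Wald-ratio
   standard errors use the first-order delta method se_out/|β_exp|
   (a second-order variant is a flag), so IVW is identical to a
   zero-intercept weighted regression of outcome on exposure betas with
   weights 1/se_out².  IVW uses multiplicative random effects with the
   residual scale floored at 1 — the de-facto default of the standard
   two-sample-MR tooling — with fixed effects behind a flag.  MR-Egger
   orients SNPs to positive exposure effects, fits a free intercept, scales
   both standard errors by max(1, √(Q′/(k−2))) and uses t references with
   k−2 df.  The weighted median interpolates the inverse-variance-weighted
   ratio percentile at 0.5; the weighted mode maximizes a weighted normal-
   kernel density with bandwidth φ·0.9·min(sd, mad)·k^(−1/5), φ = 1 by
   default.  Both get parametric-bootstrap standard errors (per-SNP betas
   resampled from their sampling distributions, 1000 draws, seeded); the
   mode uses the robust MAD spread of the bootstrap distribution, its
   source construction.  For single-instrument findings the SMR statistic
   T = z_x²z_y²/(z_x²+z_y²) (χ²₁) tests the effect accounting for noise on
   both sides, and HEIDI tests whether companion SNPs in LD with the top
   SNP (exposure p < 1.6×10⁻³, r² to the top SNP in [0.05, 0.9], at most
   20 — the defaults of the originating tool) share its ratio, via
   d′V⁻¹d with the delta-method covariance under LD, referred to χ² with
   one df per companion.  Weighted mode is computed on request but excluded
   from the default report profile, matching the study convention of
   reporting IVW/Egger/weighted-median columns.
4. **Sensitivity.** Cochran's Q uses modified second-order weights
   β_exp²/(se_out² + β̂²se_exp²) iteratively re-evaluated at the pooled
   estimate (the first-order form is a flag — the exact recipe is not
   canonical, so both are available and the choice is logged); Rucker's Q′
   is the weighted residual sum around the Egger line, always ≤ the
   first-order Q.  MR-PRESSO simulates outcome betas from the
   leave-one-out no-pleiotropy model (2500 draws by default, seeded),
   compares weighted leave-one-out residual sums, flags per-SNP outliers by
   Bonferroni-corrected exceedance p < 0.05, re-estimates IVW without them,
   and reports a distortion p against random same-size removals.
   Exceedance p-values are floored at 1/n_sim, never 0.  Leave-one-out IVW
   and a funnel table (ratio vs precision) round out the battery.
   Reverse-direction MR swaps the roles (disorder → imaging trait); a
   reverse IVW p > 0.05 is recorded as supporting the forward direction.
5. **Instrument strength and power.** Per-SNP variance explained is
   R² = 2·EAF(1−EAF)β² / (2·EAF(1−EAF)(β² + N·se²)); the EAF factor
   cancels, and the equivalent β²/(β²+N·se²) form is the fallback when EAF
   is unreported (flagged in the report).  F = R²(N−2)/(1−R²).  Study power
   for a binary outcome uses the published two-sample-MR calculator's
   closed form: with case fraction K and assumed OR per exposure SD,
   b = K·(OR/(1+K(OR−1)) − 1), v = (K(1−K) − b²)/(N·R²), and power is the
   noncentral-χ²₁ tail beyond the α critical value at noncentrality b²/v.
   The linearization is most accurate near balanced case-control designs;
   the pinning simulation-oracle test therefore uses K = 0.5.  Defaults
   OR = 1.3, α = 0.05; R² = 0 returns α exactly.
6. **Pooled inflation ("general causal contribution").** Primary p-values
   of all analyzable pairs (IVW and Wald-ratio pairs by default; an
   IVW-only flag exists) are pooled overall and per disorder.  λ is the
   slope of a through-origin regression of sorted observed χ²₁ quantiles on
   expected order statistics at (i−½)/n, with a 95% CI from the slope's
   standard error and no trimming (a trim fraction is exposed in config).
   Uniformity is tested by a two-sided KS test.  Because λ over a few
   hundred p-values is noisy, a permutation test shuffles the assignment of
   outcome records to instrument SNPs within every pair (breaking the
   instrument–outcome linkage while preserving marginals; a global
   across-pair shuffle is a flag — the within-pair form is this package's
   documented choice since "shuffling SNP labels" admits several readings),
   recomputes all IVW p-values, λ and the KS statistic, and reports
   add-one permutation p's with minimum 1/(B+1), B = 1000 by default.
   Pooling is re-run after removing pairs with Cochran p < 0.05 and after
   substituting outlier-corrected p-values.  Significance tiers per pair:
   nominal p < 0.05; single-disease p < 0.05/#exposures of the class;
   study-wide p < 0.05/#pairs of the class, with the denominator switchable
   between enumerated and actually-tested pair counts (both conventions are
   in circulation; neither is privileged).  The MR-tier × heterogeneity-tier
   cross-tabulation is emitted with row-normalized proportions.

The statsmodels-style surface — `MendelianRandomization(...).fit()` →
`MRResults` with `params`, `bse`, `conf_int()`, `summary()`, and
`sensitivity()` — wraps the same estimator functions the pipeline uses; the
pipeline applied to one pair is exactly the composition of the module
functions (tested).

## The synthetic-data generator

The generator emulates the statistical structure of the real inputs — a
UK-Biobank-scale continuous imaging GWAS (N = 17,706 DTI / 19,629 ROI)
against consortium-scale binary disorder GWAS — without individual-level
genotypes.  Per SNP with MAF drawn uniformly from (0.05, 0.5):
se_exp = 1/√(2·MAF(1−MAF)·N_exp) (standardized-trait approximation), and
binary outcomes additionally divide by √(K(1−K)), so the printed R²/F
formulas approximately recover simulation truth (tested).  True exposure
effects come from a null-plus-large-effect mixture: 1.5× the requested
instrument count of SNPs get effects N(0, τ²) with τ solved by root-finding
so the *expected* number of genome-wide-significant SNPs equals the request
— simpler than genome-scale realism and sufficient for every downstream
contract.  Horizontal pleiotropy is configurable: balanced (zero-mean),
directional (mean-shifted relative to the instrument's orientation, the
form that biases IVW but not the median), or InSIDE-violating (correlated
with instrument strength); a `pleiotropy_fraction` limits it to a subset of
SNPs.  Outliers add a fixed shift to the strongest instruments'  outcome
effects.  Optional outcome-specific loci give the disorder its own genetic
architecture (so reverse MR has genuine instruments), with an optional
reverse-causality effect.  Optional LD blocks share MAF within a block,
propagate causal effects to linked SNPs through the correlation matrix, and
correlate the sampling noise.  Outcome tables randomize allele orientation
(swaps, strand complements on non-palindromic SNPs) so harmonization is
exercised on every run.  p = two-sided normal tail of β/se exactly, and a
fixed seed determines every byte.

The full-study generator enumerates 110 DTI (22 tracts × 5 parameters,
labelled) and 101 ROI exposures against 12 disorders, each exposure owning
a disjoint SNP panel; a configurable fraction of pairs is causal (default
effect magnitude 0.15, chosen so pooled inflation lands in the λ ≈ 1.2–2.6
range a modest true-effect fraction produces rather than saturating the
tail-sensitive λ regression), and instrument-free exposures are generated
at the per-class rates of the real study (67/1320 DTI pairs, 239/1212 ROI
pairs discarded).

What the generator does *not* emulate: genome-scale LD and allele-frequency
spectra, sample overlap between cohorts, population stratification, winner's
curse from discovery–replication asymmetries, and case-control ascertainment
beyond the K(1−K) variance scaling.  Passing tests therefore validate the
estimators and the pipeline's contracts, not the field realism of any
particular dataset.

## Numerical choices and test conditions

* Test problem sizes: estimator recovery uses 30 instruments at
  N = 5×10⁴ per side, 200 seeds per effect size (0, 0.3, −0.48);
  calibration of the Egger-intercept/Cochran-Q/MR-PRESSO null rejection
  uses 100 instruments over 2000 seeds with PRESSO reduced to 500
  simulations.  The many-instrument calibration regime is deliberate: with
  the residual scale floored at 1, the Egger-intercept t test is
  conservative at small k (analytically ≈ 0.016 at k = 10, ≈ 0.034 at
  k = 30) and approaches its nominal level only with many instruments, so
  the nominal-rate check is run where the asymptotic reference applies.
* The 40%-invalid-instrument robustness scenario uses directional
  pleiotropy sd 0.03 with a 200,000-sample outcome GWAS: the weighted
  median's contamination bias shrinks with the ratio sampling noise, while
  IVW's pleiotropy bias does not, which is exactly the contrast the
  scenario demonstrates.
* Weighted-mode KDE: 512-point grid padded by three bandwidths but capped
  at the data span, so extreme bandwidths retain argmax resolution (the
  φ → ∞ limit then approaches the weighted mean as it should).  Its
  bootstrap-MAD confidence intervals are mildly conservative (measured
  coverage ≈ 0.97 where IVW and the weighted median sit at ≈ 0.96);
  coverage assertions therefore target the normal-theory estimators.
* Degenerate inputs: β_exp = 0 raises an undefined-ratio error; < 2/3/4
  instruments raise typed insufficient-instrument errors or return
  not-evaluable statuses (PRESSO, HEIDI, reverse MR) rather than p-values;
  empty harmonized pairs exclude the pair with a reason code.
* Per-stage seeds derive from the global seed by a blake2s hash of
  "(seed)/stage/exposure/outcome", so any stage re-runs reproducibly in
  isolation; identical seeds yield byte-identical result files.

## Known limitations

* The HEIDI statistic uses the plain d′V⁻¹d χ² form with a pseudo-inverse;
  the originating tool's saddlepoint-flavoured approximation may differ in
  the extreme tails.
* Reverse MR performs no Steiger filtering (out of scope), so a very strong
  forward effect whose instruments reach genome-wide significance in the
  outcome GWAS can masquerade as a reverse signal — in simulations this is
  avoided by giving outcomes their own loci, as real disorders have.
* The power formula inherits the linear-probability approximation of its
  source calculator; away from balanced case fractions it can differ from a
  logistic-model simulation by several percentage points of power.
* λ by through-origin order-statistic regression is dominated by the
  largest quantiles; with strong true effects mixed in, λ is an index of
  tail enrichment, not a calibration factor.
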