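# Methods

`mrforge` implements the full inferential pipeline of a two-sample Mendelian
randomization (MR) study of binary traits at consortium scale: instrument
selection from GWAS summary statistics, five univariable causal estimators
with a variant-count dispatch rule, a battery of pleiotropy /
reverse-causation / collider-bias sensitivity procedures, multivariable IVW,
and approximate-Bayes-factor (ABF) colocalization. A summary-statistics
simulator with known ground truth makes every stage testable without access
to restricted GWAS data.

## Model and assumptions

For variant *j*, let γ̂ⱼ (SE σ_xⱼ) be its estimated per-allele effect on the
exposure and Γ̂ⱼ (SE σ_yⱼ) on the outcome, both on the log-odds scale for
binary traits. Under the instrumental-variable assumptions (relevance,
independence, exclusion restriction), each valid instrument identifies the
same causal effect θ = Γⱼ/γⱼ. All estimators operate on summary statistics
only and assume the NOME approximation (σ_xⱼ negligible relative to |γⱼ|,
i.e. strong instruments), two independent samples, and effects harmonized to
a common effect allele.

## Estimators

* **Wald ratio** (1 variant): θ̂ = Γ̂/γ̂, SE |σ_y/γ̂| (first-order delta
  method; within 10% of the second-order SE for instrument F > 100).
* **IVW** (≥ 2): origin-constrained weighted least squares of Γ̂ on γ̂ with
  weights 1/σ_yⱼ². *Fixed effects* uses the WLS SE; *multiplicative random
  effects* inflates it by max(1, √(Q/(L−1))) with Q Cochran's statistic —
  the inflation never shrinks the fixed SE.
* **MR-Egger** (≥ 3): WLS with an intercept after orienting all γ̂ⱼ ≥ 0;
  the intercept estimates the mean directional pleiotropic effect, and both
  SEs carry the max(1, √(Q/(L−2))) inflation. Valid under InSIDE
  (pleiotropy independent of instrument strength).
* **Weighted median** (≥ 3): the 0.5 point of the weighted empirical
  quantile function of the ratio estimates θ̂ⱼ = Γ̂ⱼ/γ̂ⱼ with weights
  γ̂ⱼ²/σ_yⱼ², interpolated linearly at cumulative coordinates
  Sⱼ = (Σ_{k≤j}w_k − wⱼ/2). Consistent when > 50% of weight is valid.
* **Weighted mode** (≥ 3): argmax of a weighted normal-kernel density over
  the ratios, bandwidth φ·0.9·min(sd, IQR/1.349)·L^(−1/5) on the weighted
  ratio sample (φ = 1 by default), evaluated on a 512-point grid spanning
  the ratio range ± 3 bandwidths. Consistent when the largest weight share
  is valid (ZEMPA).

**Dispatch rule**: 1 variant → Wald ratio; 2–3 → fixed-effects IVW; > 3 →
multiplicative-random-effects IVW.

**Bootstrap SEs.** Median and mode SEs come from a parametric bootstrap
resampling (γ̂ⱼ, Γ̂ⱼ) from N(β̂, se) (default 5,000 replicates, mandatory
seed). The mode uses the normalized MAD of the bootstrap draws — bootstrap
modes occasionally jump between density bumps, making the SD unstable. A
calibration caveat: for these non-smooth statistics the bootstrap spread
conditions on already-noisy centers, so the resulting CIs are conservative.
At L = 35 with strong instruments, measured 95% CI coverage under the null
is ≈ 0.95 for Wald/IVW/Egger, ≈ 0.97 for the weighted median, and ≈ 0.99
for the weighted mode. This mirrors the behavior of the estimators'
reference implementations; interpret mode CIs as conservative.

## Instrument selection

Significance filtering (default p ≤ 5×10⁻⁸) is followed by greedy LD
clumping: rank by p-value (ties broken by chrom, pos, variant id, making
output order-invariant), accept the best remaining variant, and discard
weaker variants on the same chromosome within the window (default 10 Mb)
with r² at or above the threshold (default 0.001). Variants missing from
the LD matrix are treated as uncorrelated, with a warning. Instrument
strength is reported as per-variant F = (β̂/se)² and its arithmetic mean.

Gene-specific cis instruments restrict to gene body ± 200 kb (or the gene
body alone in intragenic-only mode) and fall back through p-value tiers
5×10⁻⁸ → 5×10⁻⁶ → 5×10⁻⁴, using the first tier that leaves at least one
clumped variant; a gene with none at the most lenient tier returns a typed
no-instrument outcome. Genes whose instruments contain identical variant
sets are merged into loci.

## Harmonization

Exposure and outcome records are intersected on variant id; outcome effects
whose allele pair is the swap (or reverse-complement swap) of the
exposure's are sign-flipped with eaf → 1 − eaf. Palindromic pairs (A/T,
C/G) cannot be strand-resolved from alleles alone, so they are retained
only when the effect-allele frequency is outside (0.42, 0.58) on both
traits and the minor allele lies on the same side; otherwise they are
dropped and counted. Harmonization is idempotent and conserves variants
(retained + dropped-palindromic + dropped-incompatible = intersection).

## Sensitivity procedures

* **Steiger filtering** removes variants explaining more outcome than
  exposure variance, using r² ≈ z²/(z² + n − 2) per trait on the observed
  scale (no prevalence input required); a variant is kept iff
  r²_exposure > r²_outcome.
* **Collider-slope correction.** A progression GWAS run conditional on an
  index event induces spurious effects b·δⱼ in variants with incidence
  effects δⱼ. Among incidence-associated variants, a two-component mixture
  is fitted to paired effects (b_I, b_P): the incidence-only component has
  b_I ~ N(0, s²) and b_P | b_I ~ N(b·b_I, τ²); the other component is a
  free bivariate normal. EM runs from a deterministic initialization plus
  three seeded random restarts, keeping the best log-likelihood (the
  likelihood surface can hold a second, inferior optimum where the free
  component absorbs the null cluster). Effects enter unoriented: the model
  is invariant under joint sign flips, and forcing b_I ≥ 0 would break the
  zero-mean marginal of the constrained component. Corrected effects are
  β_adj = β_P − b̂·β_I with se_adj = √(se_P² + b̂²·se_I²).
* **Sensitivity grid** re-runs selection + harmonization + dispatch over
  p ∈ {5×10⁻⁴, 5×10⁻⁶, 5×10⁻⁸, 5×10⁻¹⁰} × r² ∈ {10⁻⁴, 10⁻³, 10⁻², 10⁻¹};
  cells with no instruments are empty, not failures.
* **Robustness checklist** — six named criteria: (1) Egger intercept
  p ≥ 0.05 (or < 0.05 together with a significant causal slope) and all
  three pleiotropy-robust estimators sharing the primary sign;
  (2)/(3) directional consistency along the r² and p grid axes (the other
  axis held at the primary threshold); (4) collider-corrected estimate
  directionally consistent; (5) Steiger-filtered estimate consistent or
  nothing removed; (6) no significant positive reverse association.
  Missing inputs yield "not-evaluated", never a silent pass. Note that at
  a true effect of 0.19 the Egger slope (SE ≈ 0.12) flips sign by chance
  in ≈ 6% of replicates, so criterion 1 is expected to pass in roughly
  90–95% of end-to-end runs, not always.
* **Reverse MR** swaps trait roles and retries thresholds 5×10⁻⁸ then
  5×10⁻⁶; no instruments at either gives a typed not-evaluable outcome.
* **Sample-overlap diagnostic**: effective size N_eff =
  4·n_case·n_control/(n_case + n_control) per cohort; overlap fraction is
  the shared effective size over the smaller cohort's.

## Multivariable MR

Direct effects are estimated by origin-constrained WLS of outcome effects
on the matrix of exposure effects (weights 1/σ_y²), with SEs inflated by
max(1, √(Q/(L−k))). Instruments are the union of variants genome-wide
significant for either exposure, jointly clumped on the smaller p-value.
Exactly collinear exposures (including an all-zero column) raise an error
naming the condition number (limit 10⁸). The per-exposure conditional-F
diagnostic is a regression heuristic — the mean squared standardized
residual of each exposure's effects after projecting out the others — not
the Sanderson–Windmeijer statistic.

## Colocalization

Per-variant evidence is the Wakefield log-ABF, 0.5·(log(1 − r) + r·z²) with
shrinkage r = W/(W + se²); the prior effect SD √W defaults to 0.2 for both
quantitative and case-control traits. Hypothesis sums H0..H4 follow the
single-causal-variant enumeration (H3 via S1·S2 − S12) and are evaluated
entirely in log space with signed log-sum-exp, so |z| beyond 40 cannot
overflow. Per-variant priors default to p1 = p2 = 10⁻⁴, p12 = 10⁻⁵. The
conditional colocalization probability is PP(H4)/(PP(H3) + PP(H4)),
returning a typed not-evaluable outcome when the denominator is zero.

## Synthetic data generator

The generator works directly on the summary-statistic scale. Defaults are
the study conditions: θ = 0.19 (ln 1.21), L = 35 instruments, an exposure
GWAS of 21,021 cases / 391,160 controls and an outcome GWAS of 3,018 cases
/ 994,582 controls, MAF ~ U(0.05, 0.5), true instrument effects
γ ~ N(0, 0.125²) resampled until they clear genome-wide significance at the
exposure sample size (giving mean F near the ~115 reported for such panels),
and mild balanced pleiotropy (SD 0.005 on the outcome log-odds scale,
roughly a sixth of the outcome sampling SE). Directional pleiotropy is
defined on the exposure-increasing allele (its mean carries sign(γ));
InSIDE holds unless an α–γ correlation is requested. Standard errors use
the binary-trait approximation se ≈ √(n/(2·maf·(1 − maf)·n_case·n_control)),
stated openly as an approximation. Each instrument leads an AR(1) LD block
(ρ = 0.9) of null companions whose marginal z-scores are the causal z
attenuated by the signed correlation; further background variants are
independent nulls, and two optional outcome-specific variants (with an
optional reverse effect on the exposure) make reverse MR evaluable.
Sample overlap can be emulated by correlating the two noise draws.

Regional pairs for colocalization draw marginal z-scores from the standard
model z ~ N(Rμ, R) over an AR(1) LD matrix, with one causal variant per
trait (shared index or two far-separated indices) and betas z·se at the
analytic SE for a configurable regional sample size (default n = 50,000,
MAF 0.3). Unit-SE regions are deliberately not used: at realistic prior
scales (√W = 0.2) a unit-SE region makes every ABF ≈ 1 and colocalization
uninformative, which does not emulate real regional data.

What the simulator does *not* emulate: realistic human LD maps, allele
frequency spectra coupled to effect sizes, ancestry structure, imputation
error, or correlated sampling noise within LD blocks (observed noise is
drawn independently per variant in the GWAS-pair generator). Passing tests
therefore demonstrate correctness and calibration of the inference
machinery under the stated statistical model, not robustness to every
artifact of real GWAS data.

## Numerical choices and edge cases

* P-values are two-sided normal except Q (χ²); they are floored at the
  smallest positive double rather than returned as 0.
* The weighted-mode bandwidth falls back to the positive member of
  {sd, IQR/1.349} when one is zero; if both are zero the ratio with the
  largest weight is returned directly.
* Clumping ties on p-value break by (chrom, pos, variant_id).
* EM variances are floored at 10⁻¹²; the free component's covariance gets a
  10⁻¹⁰ ridge. Non-convergence within `max_iter` returns the last iterate
  flagged `converged=False`.
* All simulation entry points require a seed; replicate seeds are spawned
  via `numpy.random.SeedSequence` and kept below 2³¹.

## Problem sizes used in tests

The test suite runs the statistical checks at 1,000 replicates for CI
calibration, 2,000 for the Egger intercept type-I error, 500 for parameter
recovery, 100 end-to-end replicates for the checklist rate and the
collider correction, and 200 seeds per colocalization scenario, with
bootstrap SEs at 400 replicates inside simulation loops (5,000 remains the
default for single analyses; at 400 the SE estimation noise is ~4%, which
does not move coverage materially). These sizes were chosen to keep Monte
Carlo error well below the tolerances being asserted.
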