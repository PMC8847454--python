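# Methods

## Statistical model

`tsmr` implements summary-data two-sample Mendelian randomization. For
each of J independent instruments (clumped, genome-wide-significant
variants), the exposure study supplies γ̂ⱼ with standard error σ_Xj and
the outcome study supplies Γ̂ⱼ with σ_Yj, both expressed for a common
effect allele after harmonization. The working model is

  γ̂ⱼ ~ N(γⱼ, σ²_Xj),  Γ̂ⱼ ~ N(θ γⱼ + αⱼ, σ²_Yj),  errors independent,

with θ the causal effect (log-odds of the binary outcome per 1 SD of
genetically predicted exposure) and αⱼ a direct, exposure-bypassing
effect that is zero for a valid instrument. The two samples are assumed
non-overlapping, instruments mutually independent (LD clumping is an
upstream responsibility; the package refuses duplicate variant ids
rather than deduplicating), and the exposure–outcome relation linear.

### Estimators

* **Wald ratio.** β̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order delta-method SE
  σ_Yj/|γ̂ⱼ|. Exposure-side noise is ignored in the SE; this is the
  standard choice when instruments are strong (F ≫ 10; the studies this
  package targets have F in the hundreds to thousands) and makes IVW
  algebraically identical to weighted least squares of Γ̂ on γ̂ through
  the origin with weights σ_Yj⁻², which the test suite exploits as an
  independent oracle. γ̂ⱼ = 0 is a distinct, typed error
  (`InvalidInstrumentError`), not a floating-point accident.
* **Fixed-effect IVW** (primary): weighted mean of ratios with weights
  wⱼ = γ̂ⱼ²/σ²_Yj, SE (Σwⱼ)^(−1/2). A multiplicative random-effects
  variant (SE inflated by √max(1, Q/(J−1))) is available behind a flag
  but is not the default.
* **Simple / weighted median.** Point estimates use the midpoint
  convention (even J) and, for the weighted median, linear interpolation
  of the sorted ratios against cumulative-weight midpoints
  sⱼ = Σᵢ≤ⱼw′ᵢ − w′ⱼ/2 at s = 0.5, clamped to the extreme ratios when
  0.5 falls outside [s₁, s_J]. SEs come from a parametric bootstrap:
  γ̂ⱼ* ~ N(γ̂ⱼ, σ²_Xj), Γ̂ⱼ* ~ N(Γ̂ⱼ, σ²_Yj) drawn independently
  (two-sample design), the estimator recomputed per replicate, SE = SD
  across replicates. B = 10,000 by default for a single analysis; the
  seed is mandatory wherever a bootstrap method is selected.
* **MR-Egger.** Weighted regression of Γ̂ on γ̂ with free intercept,
  weights σ_Yj⁻², after orienting all γ̂ⱼ ≥ 0. The intercept estimates
  the mean directional pleiotropic effect (InSIDE: direct effects
  independent of instrument strength); its two-sided test is the
  directional-pleiotropy diagnostic. Coefficient SEs carry the
  conventional multiplicative residual scale max(1, σ̂), where σ̂² is
  the weighted residual mean square on J − 2 degrees of freedom. The
  I²GX statistic (Q_GX − (J−1))/Q_GX, with Q_GX the σ_Xj⁻²-weighted
  heterogeneity of the γ̂ⱼ, quantifies regression dilution: values near
  1 mean exposure effects are precise enough for Egger to be reliable.

All p-values are two-sided normal and all intervals are ±1.96 SE; no
t-reference and no multiple-testing adjustment. Odds ratios are
exp-transforms of the log-scale fields, which are always retained.

### Conservativeness of the median bootstrap

Centering the bootstrap at the observed (γ̂ⱼ, Γ̂ⱼ) — the standard
procedure — double-counts sampling scatter for median-type estimators
when all instruments are valid and strong: the observed ratios already
scatter around θ purely by noise, and the bootstrap adds fresh noise of
the same magnitude on top of those scattered centers. At the default
study scale (J = 139, samples in the 10⁵–10⁶ range) the bootstrap SE
runs ~15–20% above the empirical sampling SD, so median CIs over-cover
(~97–98%) and the median tests reject a true null at ~2–3% rather than
5%. IVW and Egger, being linear in Γ̂, are unaffected. This is a
property of the procedure, not a defect of the implementation; users
needing exact calibration for medians should interpret their CIs as
conservative.

## Harmonization rules

Matching is by variant id (an optional two-column query→proxy table,
pre-computed externally, is applied to the outcome before matching; no
LD reference is ever queried). For each exposure variant found in the
outcome: identical allele orientation copies the betas; swapped alleles
negate the outcome beta and reflect its EAF; a strand complement is
tried before declaring an irreconcilable `allele mismatch`. Palindromic
variants cannot be resolved by allele codes; under the default `strict`
policy they are dropped when either study's EAF is missing or within
0.08 of 0.5, and otherwise oriented by whether the two frequencies fall
on the same side of 0.5 (`drop` drops them unconditionally). The 0.08
window is the conventional ambiguity guard; it is configurable.

Finally every instrument is oriented so γ̂ⱼ ≥ 0 by flipping both betas
(and allele labels/frequencies) together. Egger requires this
convention; all other estimators' point estimates are provably invariant
to it, which the property tests assert. Harmonization is idempotent,
and |instruments| + |dropped| always equals the number of exposure
variants.

## Instrument strength

F = R²(N − 1 − K) / ((1 − R²)K) for K instruments jointly explaining R²
of the exposure in a discovery GWAS of N individuals. The published
headline F values for this kind of analysis are sensitive to which N a
consortium reports (effective vs maximum sample size), so the function
takes N explicitly and makes no attempt to guess it.

## Synthetic-data generator

The generator emulates exactly the regime the estimators assume: MAFs
pⱼ ~ U(0.05, 0.5); true γⱼ drawn half-normal and rescaled so
Σ 2pⱼ(1−pⱼ)γⱼ² equals the target R² exactly; per-variant SEs
σ = [2p(1−p)n]^(−1/2) (the linear approximation for log-odds effects,
avoiding individual-level simulation); independent Gaussian noise in the
two samples; p-values floored at 10⁻³⁰⁰ so extreme associations stay
representable in (0, 1]. Defaults are the European-scale study
conditions: J = 139, n_exposure = 659,316, n_outcome = 80,610,
R² = 0.196, θ = log 0.96.

Pleiotropy is a two-component mixture: with probability π an instrument
receives αⱼ ~ N(μ_α, σ_α²), drawn independently of γⱼ when InSIDE is
imposed (with a γ-linked term added when it is not). Truth effects are
oriented so γⱼ ≥ 0 with the effect allele defined as the
exposure-increasing allele, and directional pleiotropy is defined in
that orientation — the only convention under which "directional" is
meaningful, since a sign-symmetric allele labelling followed by the
γ̂ ≥ 0 convention would cancel any mean direct effect. The calibration
scenarios used in the acceptance tests put μ_α = 0.02, σ_α = 0.01
(directional) and μ_α = 0, σ_α = 0.03 (balanced) with π = 0.3; these
make the per-instrument direct effects several times larger than the
causal signal θγⱼ ≈ 0.0025, i.e. strong but not absurd contamination.

Emitted tables randomly scramble which allele is labelled "effect" in
each study and the outcome's strand (non-palindromic pairs only, unless
palindromic labels are explicitly enabled for harmonization stress
tests), so harmonizing the generator's output is a genuine round trip;
tests assert it recovers the unscrambled effects bit-exactly.

What the generator does **not** emulate: LD between instruments, sample
overlap between the two studies, winner's-curse bias in instrument
selection, allele-frequency differences between studies, MAF-dependent
effect-size architecture, and the exact binomial sampling of a
case-control outcome. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
those real-data complications.

`recovery_experiment` repeats the draw n_reps times (child seeds
spawned from the config seed, fully deterministic) and reports mean
bias, RMSE, empirical SE, mean model SE, 95% CI coverage and rejection
rates per method, plus the Egger intercept test's rejection rate. It
uses B = 200 bootstrap replicates for median SEs — an SE estimated with
~5% relative error, ample for aggregate calibration summaries — while
single analyses keep B = 10,000.

## Meta-analysis

Study effects enter as ratio-scale estimates with symmetric 95% CIs;
the log SE is (log U − log L)/(2·1.96). Fixed-effect pooling uses
weights se⁻²; DerSimonian–Laird pooling uses
τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)) with Q computed under fixed
weights, then weights (se² + τ²)⁻¹. The random model is the default for
forest-plot-style subgroup summaries of heterogeneous cohorts; a
single-study subgroup falls back to fixed with a warning. Q ≤ k−1
truncates τ² to zero, making random and fixed coincide.

## Numerical and degenerate-input choices

* Strict inequality p < threshold for instrument selection.
* Duplicate variant ids are a hard error everywhere (they signal an
  upstream clumping failure, and silent deduplication would bias
  weights).
* Medians require ≥ 3 instruments; Egger additionally requires nonzero
  variance in γ̂ (otherwise the slope is unidentifiable) and reports
  I²GX = −∞ when Q_GX = 0.
* Even-J medians use the midpoint of the two central ratios.
* The weighted-median bootstrap recomputes the weights γ̂ⱼ*²/σ²_Yj per
  replicate, so weight uncertainty propagates into the SE.
* Result tables contain no timestamps; reruns with identical config and
  seed are byte-identical (timestamps live only in the run log).

## Problem sizes

The test suite's Monte-Carlo checks use 120–1000 replicates at the
full J = 139 study scale (the per-replicate cost is small because all
kernels are vectorized); the acceptance script uses 300–500 replicates.
These sizes put Monte-Carlo error comfortably below the tolerances being
asserted while keeping a full run in the seconds-to-minutes range.

## Known limitations

* No LD-aware operations: clumping, proxy discovery and liftover are
  out of scope by design; proxies must be supplied pre-computed.
* The reverse-direction mode reuses the same machinery with roles
  swapped and warns below 4 usable instruments; it does not implement
  Steiger filtering or other directionality tests.
* No MR-PRESSO, mode-based or multivariable estimators; no nonlinear
  exposure–outcome models.
* Median CIs are conservative in the strong-instrument regime (see
  above).
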