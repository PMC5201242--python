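# Methods

This note records the statistical model behind `prs2d`, the numerical choices
made where the construction was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Model and estimators

Throughout, genotypes are standardized to mean 0, variance 1 and marginal
GWAS effects β̂_m are on that scale with standard deviation σ̂_m; for binary
traits β̂_m is a marginal log-odds ratio and is treated identically
downstream (the observational-scale R² is then a squared point-biserial
correlation). Selection at a two-sided P-value threshold α is identical to
the event |β̂_m| > λ(α) with λ(α) = Φ⁻¹(1 − α/2)·σ̂_m; the package uses the
strict inequality P < α everywhere, so the boundary |β̂| = λ is excluded —
ties occur with probability zero and the choice only matters for synthetic
edge cases.

**Conditional-likelihood MLE.** The corrected weight maximizes the density
of β̂ ~ N(β, σ̂²) conditional on selection,

    φ((β̂ − β)/σ̂)/σ̂ / [Φ(β/σ̂ − λ/σ̂) + Φ(−β/σ̂ − λ/σ̂)],

over unrestricted real β. The selection indicator is placed on the
*estimate* (the record was selected because |β̂| ≥ λ), not on the parameter;
conditioning on the estimate keeps the likelihood well defined and matches
the conditional-likelihood construction of Zhong and Prentice for
significance-selected GWAS estimates. By the symmetry of φ and Φ the
maximizer shares β̂'s sign, and the selection-probability denominator grows
with |β|, so the maximizer lies in [0, |β̂|]; the implementation folds the
problem onto that interval, localizes the mode with a 64-point grid and
refines by golden-section search to 1e-10. The denominator is evaluated on
the log scale with `log_ndtr` so λ/σ̂ up to ~40 does not underflow.

**Shrinkage behavior (what corrections can and cannot do).** Numerical
study of the two operators shows: the conditional MLE removes most of the
selection bias when the true effect is at or below λ and mildly overcorrects
around 1.5λ, and it reduces mean absolute bias over the range 0.5λ–2λ; the
soft threshold subtracts λ outright, so it only reduces estimation bias well
below the threshold (β ≲ 0.5λ) and over-shrinks clearly detected effects.
Its value for PRS is as a prediction shrinkage, not as an unbiased
estimator; consistent with that, the score-calibration test uses the MLE,
which pulls the calibration slope of the uncorrected PRS (≈ 0.65 in the test
scenario, inflated-weight overdispersion) back toward 1, while the lasso
overshoots past 1.

**Expected predictive correlation.** For independent SNPs with M₁/M₂ causal
and M₃/M₄ null SNPs in the HP/LP sets, E(PCC) is the ratio of
Σ M_g ∫ β·E[β̂·1_sel]·f(β) dβ over the causal groups to the square root of
Σ M_g ∫ E[β̂²·1_sel]·f(β) dβ + M₃·α₁·ν(0) + M₄·α₂·ν(0), where
E[β̂·1_sel] and E[β̂²·1_sel] come from closed-form two-sided truncated-normal
moments, ν(0) is the null conditional second moment, and f is the causal
effect distribution πN(0, σ₁²) + (1 − π)N(0, σ₂²) shared by HP and LP causal
SNPs. The sampling SD of β̂ is taken as 1/√N (marginal-regression
asymptotics with unit-variance y and g; the small per-SNP effect makes the
residual-variance correction negligible). Integrals use probabilists'
Gauss–Hermite quadrature with 128 nodes per mixture component; doubling the
nodes moves E(PCC) by < 1e-6 at the default architectures.

**PCC → AUC.** The exact published mapping is not reproduced in the source
material, so the package adopts the liability-threshold construction: score
s ~ N(0, ρ²) with ρ = PCC, residual liability N(0, 1 − ρ²), disease iff
liability exceeds Φ⁻¹(1 − K) at prevalence K, and AUC = P(s_case > s_ctrl)
by deterministic trapezoid integration (4,001 nodes over ±8ρ). The mapping
is validated against liability Monte Carlo to ±0.002; figure-level AUC
curves are therefore reproduced qualitatively, not digit for digit.

**Improvement tests.** K-fold improvement uses T = δ̄/√(s²/K) with the
(K−1)-denominator variance and a one-sided t tail on K−1 degrees of freedom
(the alternative "the new method predicts better" is directional; sidedness
is this package's choice). With a single independent validation set, the
bootstrap test resamples individuals, estimates the SD of ΔR² over 1,000
replicates by default, and reports the one-sided normal tail of
ΔR²_obs/sd_boot; the normal-approximation form (rather than percentile
intervals) is this package's choice of variance-based construction.

## Synthetic-data generator

The generator defines the study conditions used by the tests:

* **Genotypes.** Blockwise Gaussian copula: latent AR(1) normals
  (within-block correlation ρ, default 0.9; block sizes geometric with mean
  5) thresholded into {0,1,2} at Hardy–Weinberg proportions for MAF ~
  U(0.05, 0.5). Blocks are < 500 kb wide (1 kb SNP spacing) and ≥ 1.2 Mb
  apart on 22 chromosomes, so clumping windows never span blocks. This
  surrogate preserves the features the methods are sensitive to — local r²
  for clumping, LD-partner counts, residual weak LD between clump survivors
  in long blocks — but not real allele-frequency spectra, LD decay shapes,
  or population structure.
* **Causal set.** One causal SNP per block ("causal SNPs in linkage
  equilibrium" made exact); the published pipeline's choice of causal SNPs
  from a pruned set is not specified in detail, and one-per-block is this
  package's operationalization.
* **Effects and trait.** β ~ πN(0, σ₁²) + (1 − π)N(0, σ₂²) with π = 0.1,
  σ₁² = h₁²/(|C|π), σ₂² = h₂²/(|C|(1 − π)), defaults h₁² = 0.1, h₂² = 0.4;
  y = Σβg + N(0, 1 − h₁² − h₂²), giving Var(y) ≈ 1.
* **HP sets.** Exactly round(Δ·|C|·|S₁|/M) causal members, so the realized
  enrichment fold matches the requested Δ up to rounding. With
  `hp_ld_bias > 0`, HP members — causal and null alike — are sampled with
  weight exp(bias · block-size rank), concentrating the set in large
  high-LD blocks the way conserved-region SNP sets concentrate in strong-LD
  regions. The bias is applied to causal members too (not only null ones)
  because that is what produces the documented LD penalty: a causal HP SNP
  in a large block is sometimes out-competed in the clump by a correlated
  non-HP tag, moving its signal to the LP side and diluting the effective
  HP enrichment. Default bias 4 in the CR-mimicking experiments.
* **Seeds.** One master seed spawns named substreams (genotypes,
  assignment, effects, noise, validation), so each component is
  independently reproducible and replicate seeds are derived as
  SeedSequence([base, replicate]).

## Problem sizes

The experiment suite runs at a reduced desk scale chosen as this package's
default study condition: M = 10,000 SNPs, 10,000 discovery + 2,000
validation samples, 1,000 causal SNPs, HP size 2,000, 20 replicates — the
heritability, mixture weight, enrichment folds and h²-per-SNP ratios of the
full-scale design are preserved while a full replicated study runs in
minutes. The analytic-theory checks run at the full published architecture
(M = 53,163, 5,000 causal, HP 5,000, N up to 100,000), which the
independent-SNP shortcut (β̂ ~ N(β, 1/N) plus fresh iid validation
genotypes) makes cheap. The acceptance script measures the
variance-component constants at 5,000 causal SNPs and 10,000 individuals
over 20 replicates.

## Degenerate inputs and tie-breaks

Monomorphic SNPs are excluded from LD computation, receive zero weight in
scores, and get p = 1 in GWAS scans. Constant score vectors return R² = 0
and AUC = 0.5 by convention; perfectly separating scores give Nagelkerke R²
via the log-likelihood supremum (0). Clumping breaks P-value ties by
(chromosome, position, SNP id), making the output invariant to input row
order. Underflowed or inconsistent P-values are recomputed from z = β̂/σ̂ on
the log scale (floor 1e-300) rather than dropped, so λ(α) mappings never see
p = 0. Threshold grids are searched with a stable first-maximum argmax, so
tuning surfaces and optima are bit-reproducible.

## Known limitations

* LD is piecewise (block-diagonal); there is no inter-block LD and no decay
  tail beyond the block, so clumping is easier than on real data.
* The theory module assumes fully independent SNPs and equal effect-size
  distributions in HP and LP sets; it is a calibration target for the
  simulator, not a model of clumped real genomes.
* Binary-trait support treats log-odds weights like linear effects; no
  covariates, no absolute-risk calibration, no cross-study meta-analysis.
* The conditional MLE is computed per SNP; joint selection across correlated
  SNPs (which survives weakly even after clumping) is ignored, exactly as in
  the marginal construction it implements.
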