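# prs2d — annotation-informed polygenic risk scores with winner's curse correction

`prs2d` builds polygenic risk scores (PRS) from GWAS summary statistics for
researchers who want to squeeze more prediction out of a fixed discovery
sample by (a) treating functionally annotated SNPs differently from the rest
of the genome and (b) correcting the upward bias that significance-based SNP
selection induces in effect estimates.

## The methods

**1D PRS.** After LD-clumping to M roughly independent SNPs, the standard
score for individual *i* is

    PRS_i(α) = Σ_m β̂_m · I(P_m < α) · g_im

with standardized genotypes g, marginal effect estimates β̂ and a single
P-value threshold α tuned on validation data.

**2D PRS.** Given a partition of the clumped SNPs into a "high-prior" set S₁
(nominated by eQTL, conserved-region, cis-regulatory or pleiotropy evidence —
consumed here as a plain SNP-id list) and the "low-prior" remainder S₂, the
score uses one threshold per group:

    PRS_i(α₁, α₂) = Σ_{m∈S₁} β̂_m I(P_m < α₁) g_im + Σ_{m∈S₂} β̂_m I(P_m < α₂) g_im

When S₁ is enriched for causal SNPs the optimal α₁ is more liberal than α₂.

**Winner's curse correction.** Selection at threshold α is the event
|β̂_m| > λ(α) = Φ⁻¹(1 − α/2)·σ̂_m. Two weight corrections are applied
simultaneously with selection:

* *lasso*: the soft threshold sign(β̂)(|β̂| − λ(α))·I(|β̂| > λ(α)), i.e. the
  coordinate solution of the L1-penalized regression under an orthonormal
  design;
* *mle*: the maximizer of the likelihood of β̂ ~ N(β, σ̂²) conditional on
  |β̂| > λ(α) (a Zhong–Prentice-type conditional MLE).

**Theory.** For independent SNPs and a Gaussian-mixture effect-size
distribution, `prs2d.theory` evaluates the expected predictive correlation
E(PCC(α₁, α₂)) analytically (two-sided truncated-normal moments, detection
power and Gauss–Hermite quadrature over the mixture), maps PCC to AUC through
a liability-threshold model, and grid-searches the optimal thresholds.

**Simulator.** `prs2d.simulate` generates LD-blocked genotype panels
(blockwise AR(1) Gaussian copula), causal sets in linkage equilibrium (one
causal SNP per block), mixture effect sizes with π = 0.1 and variance
components h₁² = 0.1, h₂² = 0.4 scaled to a unit-variance trait, HP sets with
controllable enrichment fold Δ, and marginal GWAS scans — so every method is
testable end to end without external data.

## Worked example

```python
import numpy as np
from prs2d import SimConfig, ld_clump
from prs2d.simulate import (assign_causal_and_hp, draw_effect_sizes,
                            marginal_gwas, simulate_genotype_panel, simulate_trait)
from prs2d.scoring import ThresholdGridSearch

cfg = SimConfig(n_samples=6_000, m_snps=4_000, n_causal=400, hp_size=800,
                delta=4.0, seed=11)
panel = simulate_genotype_panel(cfg)
causal, partition = assign_causal_and_hp(cfg, panel)
effects = draw_effect_sizes(cfg, causal)
y = simulate_trait(panel, effects, cfg)

disc = panel.subset_samples(np.arange(5_000))
valid = panel.subset_samples(np.arange(5_000, 6_000))
summary = marginal_gwas(disc, y[:5_000])
clumped = ld_clump(summary, disc)
print(f"{len(clumped)} SNPs retained after clumping")

one_d = ThresholdGridSearch(summary, clumped, method="lasso").fit(valid, y[5_000:])
two_d = ThresholdGridSearch(summary, clumped, hp_ids=partition.hp,
                            method="lasso").fit(valid, y[5_000:])
print(f"1D lasso PRS: R2 = {one_d.best_score_:.3f} at alpha = {one_d.best_alpha1_:g}")
print(f"2D lasso PRS: R2 = {two_d.best_score_:.3f} at (alpha1, alpha2) = "
      f"({two_d.best_alpha1_:g}, {two_d.best_alpha2_:g})")
```

Output:

```
921 SNPs retained after clumping
1D lasso PRS: R2 = 0.436 at alpha = 0.2
2D lasso PRS: R2 = 0.460 at (alpha1, alpha2) = (0.5, 0.1)
```

The trait has heritability 0.5 spread over 400 causal SNPs; the HP set holds
four times its random share of causal SNPs (Δ = 4), so the tuned 2D score
admits HP SNPs at a liberal threshold (α₁ = 0.5) while holding the rest of
the genome to α₂ = 0.1, improving validation R² from 0.436 to 0.460.

`ThresholdGridSearch` and `PRSScorer` follow scikit-learn's estimator
conventions (`get_params`/`set_params`, fitted attributes with trailing
underscores, `fit`/`transform`/`score`), so they compose with sklearn
pipelines and model selection; thin module-level functions
(`build_prs_model`, `score_samples`, `optimize_thresholds`, …) expose the
same machinery functionally, and the `prs2d` command line wraps it for shell
use (`prs2d simulate|clump|correct|score|tune|theory|run-sim|evaluate`).

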