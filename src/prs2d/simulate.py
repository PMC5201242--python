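"""Forward simulation of GWAS data with blockwise LD.

The generator emulates the study design used throughout the package's tests:

1. Genotypes come from a blockwise Gaussian copula: within a block, latent
   normals follow an AR(1) with correlation ``within_block_rho`` and are
   thresholded into {0,1,2} dosages at Hardy-Weinberg proportions for MAFs
   drawn uniformly from ``maf_range``; blocks are mutually independent, less
   than 500 kb wide and more than 1 Mb apart.
2. The causal set has one SNP per block (causal SNPs in linkage
   equilibrium); a high-prior (HP) set of ``hp_size`` SNPs contains exactly
   round(delta * n_causal * hp_size / m_snps) causal members, giving
   enrichment fold delta.  With ``hp_ld_bias > 0`` HP membership (causal and
   null alike) is tilted toward large high-LD blocks, mimicking
   annotation-derived SNP sets that sit in strong-LD regions.
3. Effects of causal SNPs are drawn from pi N(0, sigma1^2) + (1-pi) N(0,
   sigma2^2) with sigma1^2 = h1_sq/(n_causal pi) and sigma2^2 =
   h2_sq/(n_causal (1-pi)), so the two components contribute h1_sq and h2_sq
   of the unit trait variance; defaults pi = 0.1, h1_sq = 0.1, h2_sq = 0.4.
4. The trait is y = sum_t beta_t g_t (standardized g) + N(0, 1 - h1_sq -
   h2_sq) noise, and a marginal GWAS scan produces summary statistics.

A direct summary-statistic simulator (beta_hat ~ N(beta, 1/N) per independent
SNP) supports checks of the analytic theory without genotype generation.

All draws descend from a single master seed through named substreams, so
panels, effects and noise are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import special

from .ld import GenotypePanel
from .sumstats import SnpPartition, SummaryTable, _normal_sf_two_sided
from .theory import ArchitectureSpec

__all__ = [
    "SimConfig",
    "simulate_genotype_panel",
    "assign_causal_and_hp",
    "draw_effect_sizes",
    "simulate_trait",
    "marginal_gwas",
    "simulate_summary_direct",
    "simulate_independent_panel",
    "variance_components_replicate",
]

_SUBSTREAMS = {"genotypes": 0, "assignment": 1, "effects": 2, "noise": 3, "validation": 4}
#: allele pairs used for simulated SNPs (none strand-ambiguous)
_ALLELE_PAIRS = np.array([("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")])


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated GWAS scenario.

    Defaults are the reduced desk scale used by the package's experiment
    suite: 10,000 SNPs in AR(1) blocks of mean size 5, 12,000 samples
    (intended as a 10,000-sample discovery and 2,000-sample validation
    split), 1,000 causal SNPs explaining half of the unit trait variance
    through the two-component mixture, and a 2,000-SNP HP set.
    """

    n_samples: int = 12_000
    m_snps: int = 10_000
    block_size_mean: int = 5
    within_block_rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 1_000
    pi: float = 0.1
    h1_sq: float = 0.1
    h2_sq: float = 0.4
    hp_size: int = 2_000
    delta: float = 1.0
    hp_ld_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise SimConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.within_block_rho < 1:
            raise SimConfigError("within_block_rho must lie in [0, 1)")
        if not 0 < self.pi < 1:
            raise SimConfigError("pi must lie in (0, 1)")
        if self.h1_sq + self.h2_sq >= 1:
            raise SimConfigError("h1_sq + h2_sq must be < 1")
        if self.hp_ld_bias < 0:
            raise SimConfigError("hp_ld_bias must be >= 0")
        if self.hp_overlap > min(self.hp_size, self.n_causal):
            raise SimConfigError(
                f"delta={self.delta} infeasible: needs overlap {self.hp_overlap} "
                f"> min(hp_size, n_causal)"
            )

    @property
    def hp_overlap(self) -> int:
        """Causal members of the HP set: round(delta |C| |S1| / M)."""
        return int(round(self.delta * self.n_causal * self.hp_size / self.m_snps))

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream generator; independent across stream names."""
        children = np.random.SeedSequence(self.seed).spawn(len(_SUBSTREAMS))
        return np.random.default_rng(children[_SUBSTREAMS[stream]])

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _block_sizes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Geometric block sizes around the mean, truncated to sum to m_snps."""
    if config.block_size_mean <= 1:
        return np.ones(config.m_snps, dtype=int)
    draw = rng.geometric(1.0 / config.block_size_mean, size=2 * config.m_snps)
    draw = np.minimum(draw, 400)  # keep blocks < 500 kb at 1 kb spacing
    cum = np.cumsum(draw)
    k = int(np.searchsorted(cum, config.m_snps)) + 1
    sizes = draw[:k].copy()
    sizes[-1] -= int(cum[k - 1] - config.m_snps)
    if sizes[-1] == 0:
        sizes = sizes[:-1]
    return sizes


def _snp_map(config: SimConfig, sizes: np.ndarray, maf: np.ndarray,
             rng: np.random.Generator) -> pd.DataFrame:
    n_blocks = len(sizes)
    block_of = np.repeat(np.arange(n_blocks), sizes)
    # blocks distributed round-robin over 22 chromosomes, >= 1.2 Mb apart
    chrom_of_block = np.arange(n_blocks) % 22 + 1
    start = np.zeros(n_blocks, dtype=np.int64)
    next_pos = np.ones(23, dtype=np.int64)
    for b in range(n_blocks):
        c = chrom_of_block[b]
        start[b] = next_pos[c]
        next_pos[c] = start[b] + (sizes[b] - 1) * 1_000 + 1_200_000
    offset = np.concatenate([np.arange(s) for s in sizes]) * 1_000
    pairs = _ALLELE_PAIRS[rng.integers(0, len(_ALLELE_PAIRS), config.m_snps)]
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(config.m_snps)],
            "chrom": chrom_of_block[block_of].astype(str),
            "pos": start[block_of] + offset,
            "counted_allele": pairs[:, 0],
            "other_allele": pairs[:, 1],
            "block": block_of,
            "maf_target": maf,
        }
    )


def simulate_genotype_panel(config: SimConfig) -> GenotypePanel:
    """Blockwise AR(1) Gaussian-copula genotypes; deterministic given seed."""
    rng = config.rng("genotypes")
    sizes = _block_sizes(config, rng)
    maf = rng.uniform(*config.maf_range, size=config.m_snps)
    snp_map = _snp_map(config, sizes, maf, rng)

    n, m = config.n_samples, config.m_snps
    # SNP-major latent matrix: the AR(1) recursion then walks contiguous rows
    z = rng.standard_normal((m, n), dtype=np.float32)
    rho = np.float32(config.within_block_rho)
    if rho > 0:
        innov = np.float32(np.sqrt(1.0 - config.within_block_rho**2))
        starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
        offset = np.arange(m) - np.repeat(starts, sizes)
        # all rows at in-block offset k depend only on rows at offset k-1,
        # so each step of the recursion is one vectorized update
        for k in range(1, int(offset.max()) + 1):
            rows = np.nonzero(offset == k)[0]
            z[rows] = rho * z[rows - 1] + innov * z[rows]
    # Hardy-Weinberg thresholds on the latent scale
    z0 = special.ndtri((1.0 - maf) ** 2).astype(np.float32)[:, None]
    z1 = special.ndtri(1.0 - maf**2).astype(np.float32)[:, None]
    dosages = (z > z0).astype(np.int8)
    dosages += z > z1
    dosages = np.ascontiguousarray(dosages.T)
    sample_ids = [f"sample{i:05d}" for i in range(n)]
    return GenotypePanel(dosages, snp_map, sample_ids)


def _block_rank_score(snp_map: pd.DataFrame) -> np.ndarray:
    """Per-block score in [0, 1]: normalized rank of block size.

    Blocks with a constant within-block correlation differ in LD only through
    size, so size rank orders blocks by LD-partner counts.
    """
    sizes = snp_map.groupby("block").size()
    rank = sizes.rank(method="average").to_numpy()
    return (rank - 1) / max(len(rank) - 1, 1)


def assign_causal_and_hp(
    config: SimConfig, panel: GenotypePanel
) -> tuple[list[str], SnpPartition]:
    """Pick the causal set (one SNP per block) and a delta-enriched HP set.

    The HP set has exactly ``config.hp_overlap`` causal members.  With
    ``hp_ld_bias > 0``, HP members (both causal and null) are sampled with
    weight exp(bias * block-size rank score), concentrating the HP set in
    large high-LD blocks the way conserved-region SNP sets concentrate in
    strong-LD regions.
    """
    rng = config.rng("assignment")
    snp_map = panel.snp_map
    if "block" not in snp_map.columns:
        raise SimConfigError("panel lacks simulator block metadata")
    blocks = snp_map["block"].to_numpy()
    n_blocks = blocks.max() + 1
    if config.n_causal > n_blocks:
        raise SimConfigError(
            f"n_causal={config.n_causal} exceeds number of blocks ({n_blocks})"
        )
    snp_ids = snp_map["snp_id"].to_numpy()
    score_block = _block_rank_score(snp_map)

    causal_blocks = rng.choice(n_blocks, size=config.n_causal, replace=False)
    causal_idx = np.empty(config.n_causal, dtype=int)
    block_members = pd.Series(np.arange(len(blocks))).groupby(blocks).apply(np.asarray)
    for i, b in enumerate(causal_blocks):
        members = block_members[b]
        causal_idx[i] = members[rng.integers(len(members))]
    causal_ids = [str(s) for s in snp_ids[causal_idx]]

    def weighted_sample(idx: np.ndarray, size: int) -> np.ndarray:
        if size == 0:
            return np.empty(0, dtype=int)
        w = np.exp(config.hp_ld_bias * score_block[blocks[idx]])
        return rng.choice(idx, size=size, replace=False, p=w / w.sum())

    n_overlap = config.hp_overlap
    hp_causal = weighted_sample(causal_idx, n_overlap)
    non_causal = np.setdiff1d(np.arange(len(snp_ids)), causal_idx, assume_unique=False)
    hp_null = weighted_sample(non_causal, config.hp_size - n_overlap)
    hp_ids = frozenset(str(s) for s in snp_ids[np.concatenate([hp_causal, hp_null])])
    partition = SnpPartition(frozenset(str(s) for s in snp_ids), hp_ids)
    return causal_ids, partition


def draw_effect_sizes(config: SimConfig, causal_ids: Iterable[str]) -> pd.DataFrame:
    """Mixture effects for causal SNPs: columns snp_id, beta, component.

    Component 1 (probability pi) has variance h1_sq/(n_causal pi), component 2
    h2_sq/(n_causal (1-pi)), so expected contributions are h1_sq and h2_sq.
    """
    rng = config.rng("effects")
    causal_ids = list(causal_ids)
    k = len(causal_ids)
    sigma1 = np.sqrt(config.h1_sq / (config.n_causal * config.pi))
    sigma2 = np.sqrt(config.h2_sq / (config.n_causal * (1.0 - config.pi)))
    component = np.where(rng.random(k) < config.pi, 1, 2)
    raw = rng.standard_normal(k)
    beta = raw * np.where(component == 1, sigma1, sigma2)
    return pd.DataFrame({"snp_id": causal_ids, "beta": beta, "component": component})


def simulate_trait(
    panel: GenotypePanel, betas: Mapping[str, float] | pd.DataFrame, config: SimConfig
) -> np.ndarray:
    """y = sum_t beta_t g_t (standardized g) + N(0, 1 - h1_sq - h2_sq)."""
    if isinstance(betas, pd.DataFrame):
        betas = dict(zip(betas["snp_id"], betas["beta"]))
    rng = config.rng("noise")
    ids = list(betas.keys())
    cols = np.array([panel.column(s) for s in ids])
    g = panel.standardized(cols)
    w = np.array([betas[s] for s in ids])
    noise_sd = np.sqrt(1.0 - config.h1_sq - config.h2_sq)
    return g @ w + rng.normal(0.0, noise_sd, size=panel.n_samples)


def marginal_gwas(panel: GenotypePanel, y: np.ndarray, *, chunk: int = 2_000) -> SummaryTable:
    """Per-SNP simple linear regression of y on standardized dosage.

    Returns a SummaryTable on the standardized-genotype scale with normal
    two-sided P-values (sample sizes here make t vs normal immaterial).
    Monomorphic SNPs get beta 0 with a huge se (never selected).
    """
    y = np.asarray(y, dtype=np.float64)
    n = panel.n_samples
    if len(y) != n:
        raise ValueError("phenotype length != panel samples")
    yc = y - y.mean()
    syy = float(yc @ yc)
    m = panel.m_snps
    beta = np.empty(m)
    se = np.empty(m)
    integer_fast_path = np.issubdtype(panel.dosages.dtype, np.integer)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        if integer_fast_path:
            # yc sums to 0, so yc @ g_std = (yc @ g) / sd: one matmul, no centering
            g = panel.dosages[:, lo:hi].astype(np.float32)
            sd = np.sqrt(np.maximum((g * g).mean(axis=0) - g.mean(axis=0) ** 2, 0.0))
            sd = np.where(sd > 0, sd, np.inf)
            b = (yc.astype(np.float32) @ g).astype(np.float64) / (n * sd)
        else:
            g = panel.standardized(np.arange(lo, hi))
            b = (yc @ g) / n  # Sxx = n under ddof-0 standardization
        rss = np.maximum(syy - n * b**2, 0.0)
        beta[lo:hi] = b
        se[lo:hi] = np.sqrt(rss / max(n - 2, 1) / n)
    poly = panel.polymorphic_mask()
    beta[~poly] = 0.0
    se[~poly] = np.inf
    se = np.where(se > 0, se, np.inf)
    z = np.where(np.isfinite(se), beta / se, 0.0)
    p = _normal_sf_two_sided(z)
    p[~poly] = 1.0
    df = pd.DataFrame(
        {
            "snp_id": panel.snp_map["snp_id"],
            "chrom": panel.snp_map["chrom"].astype(str),
            "pos": panel.snp_map["pos"],
            "effect_allele": panel.snp_map["counted_allele"],
            "other_allele": panel.snp_map["other_allele"],
            "beta": beta,
            "se": np.where(np.isfinite(se), se, 1e6),
            "p": p,
            "z": z,
            "eaf": panel.column_means() / 2.0,
            "n": n,
        }
    )
    return SummaryTable(df, trait_type="quantitative", standardized=True)


# ---------------------------------------------------------------------------
# independent-SNP shortcuts for theory validation and variance decomposition


def simulate_independent_panel(
    m_snps: int,
    n_samples: int,
    rng: np.random.Generator,
    maf_range: tuple[float, float] = (0.05, 0.5),
    prefix: str = "isnp",
    snp_ids: Iterable[str] | None = None,
) -> GenotypePanel:
    """Panel of mutually independent Hardy-Weinberg SNPs (no LD).

    Passing ``snp_ids`` names the columns (e.g. to pair the panel with a
    directly simulated SummaryTable); those SNPs get A/G alleles matching
    :func:`simulate_summary_direct`.
    """
    maf = rng.uniform(*maf_range, size=m_snps)
    dosages = np.empty((n_samples, m_snps), dtype=np.int8)
    chunk = max(1, int(2e7) // max(n_samples, 1))
    for lo in range(0, m_snps, chunk):
        hi = min(lo + chunk, m_snps)
        f = maf[lo:hi]
        u1 = rng.random((n_samples, hi - lo))
        u2 = rng.random((n_samples, hi - lo))
        dosages[:, lo:hi] = (u1 < f).astype(np.int8) + (u2 < f)
    if snp_ids is not None:
        snp_ids = list(snp_ids)
        if len(snp_ids) != m_snps:
            raise ValueError("snp_ids length != m_snps")
        pairs = np.broadcast_to(np.array([["A", "G"]]), (m_snps, 2))
    else:
        snp_ids = [f"{prefix}{i:06d}" for i in range(m_snps)]
        pairs = _ALLELE_PAIRS[rng.integers(0, len(_ALLELE_PAIRS), m_snps)]
    snp_map = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": np.arange(m_snps, dtype=np.int64) * 2_000_000 + 1,
            "counted_allele": pairs[:, 0],
            "other_allele": pairs[:, 1],
            "maf_target": maf,
        }
    )
    return GenotypePanel(dosages, snp_map)


def simulate_summary_direct(
    arch: ArchitectureSpec, seed: int
) -> tuple[SummaryTable, pd.DataFrame, SnpPartition]:
    """Draw beta_hat ~ N(beta, 1/N) for every SNP of an architecture.

    Returns the discovery SummaryTable (se = 1/sqrt(N)), a truth frame with
    columns snp_id, beta, group (hp/lp), causal flag and mixture component,
    and the HP/LP partition.  Validation against the analytic theory then
    scores fresh independent genotypes with these summary statistics.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    counts = {"hp_causal": arch.m1, "lp_causal": arch.m2, "hp_null": arch.m3, "lp_null": arch.m4}
    rows = []
    for group, k in counts.items():
        rows.append(
            pd.DataFrame(
                {
                    "snp_id": [f"{group}_{i:06d}" for i in range(k)],
                    "group": "hp" if group.startswith("hp") else "lp",
                    "causal": group.endswith("causal"),
                }
            )
        )
    truth = pd.concat(rows, ignore_index=True)
    m = len(truth)
    beta = np.zeros(m)
    causal = truth["causal"].to_numpy()
    k = int(causal.sum())
    component = np.zeros(m, dtype=int)
    comp_causal = np.where(rng.random(k) < arch.pi, 1, 2)
    sd = np.where(comp_causal == 1, np.sqrt(arch.sigma1_sq), np.sqrt(arch.sigma2_sq))
    beta[causal] = rng.standard_normal(k) * sd
    component[causal] = comp_causal
    truth["beta"] = beta
    truth["component"] = component

    se = arch.se
    beta_hat = beta + rng.normal(0.0, se, size=m)
    z = beta_hat / se
    df = pd.DataFrame(
        {
            "snp_id": truth["snp_id"],
            "chrom": "1",
            "pos": np.arange(m, dtype=np.int64) * 2_000_000 + 1,
            "effect_allele": "A",
            "other_allele": "G",
            "beta": beta_hat,
            "se": se,
            "p": _normal_sf_two_sided(z),
            "z": z,
            "n": arch.n_discovery,
        }
    )
    table = SummaryTable(df, trait_type="quantitative", standardized=True)
    partition = SnpPartition.from_hp(truth["snp_id"], truth.loc[truth["group"] == "hp", "snp_id"])
    return table, truth, partition


def variance_components_replicate(
    n_causal: int,
    pi: float,
    h1_sq: float,
    h2_sq: float,
    n_samples: int,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """One replicate of the trait-variance decomposition check.

    Draws mixture effects for ``n_causal`` independent standardized SNPs,
    simulates the unit-variance trait, and returns the empirical variances of
    the component-1 genetic sub-score, the component-2 sub-score, and the
    trait itself (expected h1_sq, h2_sq and 1).
    """
    sigma1 = np.sqrt(h1_sq / (n_causal * pi))
    sigma2 = np.sqrt(h2_sq / (n_causal * (1.0 - pi)))
    component = np.where(rng.random(n_causal) < pi, 1, 2)
    beta = rng.standard_normal(n_causal) * np.where(component == 1, sigma1, sigma2)
    maf = rng.uniform(0.05, 0.5, size=n_causal)
    g = (rng.random((n_samples, n_causal)) < maf).astype(np.float64)
    g += rng.random((n_samples, n_causal)) < maf
    g -= g.mean(axis=0)
    sd = g.std(axis=0)
    g /= np.where(sd > 0, sd, 1.0)
    score1 = g[:, component == 1] @ beta[component == 1]
    score2 = g[:, component == 2] @ beta[component == 2]
    eps = rng.normal(0.0, np.sqrt(1.0 - h1_sq - h2_sq), size=n_samples)
    y = score1 + score2 + eps
    return float(score1.var()), float(score2.var()), float(y.var())
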