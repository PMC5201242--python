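import numpy as np
import pandas as pd
import pytest

from prs2d.ld import GenotypePanel
from prs2d.simulate import (
    SimConfig,
    assign_causal_and_hp,
    draw_effect_sizes,
    marginal_gwas,
    simulate_genotype_panel,
    simulate_trait,
)
from prs2d.sumstats import SummaryTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_config():
    """Small LD-blocked scenario shared across tests (deterministic)."""
    return SimConfig(
        n_samples=1_500,
        m_snps=600,
        block_size_mean=5,
        within_block_rho=0.9,
        n_causal=60,
        hp_size=120,
        delta=4.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_genotype_panel(small_config)


@pytest.fixture(scope="session")
def small_scenario(small_config, small_panel):
    """(panel, causal_ids, partition, effects, y, summary) for the small scenario."""
    causal_ids, partition = assign_causal_and_hp(small_config, small_panel)
    effects = draw_effect_sizes(small_config, causal_ids)
    y = simulate_trait(small_panel, effects, small_config)
    summary = marginal_gwas(small_panel, y)
    return small_panel, causal_ids, partition, effects, y, summary


def make_panel(dosages, chrom=None, pos=None, counted=None, other=None):
    """Hand-built panel from a dosage matrix (columns = SNPs)."""
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "counted_allele": counted if counted is not None else ["A"] * m,
            "other_allele": other if other is not None else ["G"] * m,
        }
    )
    return GenotypePanel(dosages, snp_map)


def make_summary(
    snp_ids, betas, ses, ps=None, chrom=None, pos=None, effect=None, other=None, **kwargs
):
    """Hand-built summary table; p defaults to the normal two-sided value."""
    from prs2d.sumstats import _normal_sf_two_sided

    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    z = betas / ses
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom if chrom is not None else ["1"] * len(snp_ids),
            "pos": pos if pos is not None else (np.arange(len(snp_ids)) + 1) * 1000,
            "effect_allele": effect if effect is not None else ["A"] * len(snp_ids),
            "other_allele": other if other is not None else ["G"] * len(snp_ids),
            "beta": betas,
            "se": ses,
            "p": ps if ps is not None else _normal_sf_two_sided(z),
            "z": z,
        }
    )
    return SummaryTable(df, **kwargs)
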