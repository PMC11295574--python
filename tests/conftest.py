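import numpy as np
import pandas as pd
import pytest

from celliability.synthetic import (
    SimConfig,
    gen_counts,
    gen_gene_models,
    gen_panel_and_sumstats,
    gen_rare_variants,
)

# Study conditions for the shared planted-effect bundle: a scaled-down
# cortex-like study (6 cell populations x 60 nuclei, 300 genes, 4000
# SNPs in 40 LD blocks, 200 panel individuals) with a strong planted
# GWAS enrichment in the markers of the first cell population.
PLANTED = dict(
    n_genes=300, n_snps=4000, n_ld_blocks=40, panel_n=200,
    n_cell_types=6, cells_per_type=60, planted_set_effect=3.0,
    marker_fraction=0.08,
)


@pytest.fixture(scope="session")
def sim_bundle():
    cfg = SimConfig(seed=7, **PLANTED)
    genes = gen_gene_models(cfg)
    counts, ann, truth = gen_counts(cfg, genes)
    panel, sumstats = gen_panel_and_sumstats(cfg, genes, truth)
    return dict(
        cfg=cfg, genes=genes, counts=counts, ann=ann, truth=truth,
        panel=panel, sumstats=sumstats,
    )


@pytest.fixture(scope="session")
def rare_bundle():
    cfg = SimConfig(
        seed=11, n_genes=120, n_cell_types=4, cells_per_type=40,
        n_cases=600, n_controls=600, planted_burden_or=1.0,
    )
    genes = gen_gene_models(cfg)
    _, _, truth = gen_counts(cfg, genes)
    vt = gen_rare_variants(cfg, genes, truth)
    return dict(cfg=cfg, genes=genes, truth=truth, vt=vt)


@pytest.fixture()
def toy_spec():
    """3-gene x 3-cell-type specificity matrix with known values."""
    return pd.DataFrame(
        {
            "A": [1.0, 1 / 3, 0.5],
            "B": [0.0, 1 / 3, 0.25],
            "C": [0.0, 1 / 3, 0.25],
        },
        index=["g_only_A", "g_flat", "g_211"],
    )


def binomial_bounds(n: int, p: float = 0.05, conf: float = 0.99) -> tuple[float, float]:
    """Normal-approximation bounds on an empirical rejection rate."""
    from scipy import stats

    z = stats.norm.isf((1 - conf) / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half
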