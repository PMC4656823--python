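import numpy as np
import pandas as pd
import pytest

from transfermap import synth
from transfermap.core import DosageMatrix, make_variant_table, stage_rng


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    return synth.simulate_panel(
        n_blocks=2,
        snps_per_block=5,
        n_haplotypes=200,
        within_block_ld=1.0,
        maf_range=(0.2, 0.45),
        seed=7,
    )


@pytest.fixture
def small_cohort(small_panel):
    dm = synth.simulate_genotypes(small_panel, 100, seed=8)
    covs = synth.draw_covariates(stage_rng(9, "cov"), 100)
    covs.insert(0, "status", (stage_rng(9, "status").random(100) < 0.5).astype(int))
    covs.insert(0, "sample_id", dm.sample_ids)
    return dm, covs


def make_dm(g, ids=None, imputed=None, imp_r2=None, pos=None):
    """Wrap a raw genotype array into a DosageMatrix with stub metadata."""
    g = np.asarray(g, dtype=float)
    n, m = g.shape
    variants = make_variant_table(
        ids or [f"v{j}" for j in range(m)],
        "1",
        pos if pos is not None else 1_000_000 + np.arange(m) * 1_000,
        ["A"] * m,
        ["G"] * m,
        imputed,
        imp_r2,
    )
    return DosageMatrix(g, [f"S{i:04d}" for i in range(n)], variants)


@pytest.fixture
def make_dosage_matrix():
    return make_dm
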