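"""Shared independent oracles for two-locus LD tests."""

import numpy as np

from transfermap.core import stage_rng
from transfermap.ld import _loglik


def grid_loglik_max(counts):
    """Best log-likelihood over p_AB on a 0.001 grid with margins fixed
    at the observed allele frequencies (independent oracle)."""
    n = counts.sum()
    pA = (2 * counts[2, :].sum() + counts[1, :].sum()) / (2 * n)
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)
    best = -np.inf
    for pAB in np.arange(lo, hi + 1e-12, 0.001):
        f = np.array([pAB, pA - pAB, pB - pAB, 1 - pA - pB + pAB])
        if f.min() < -1e-12:
            continue
        best = max(best, _loglik(counts, np.clip(f, 0, 1)))
    return best


def random_genotype_pair(seed, n=60):
    """Unphased genotypes at two loci drawn from a random haplotype law."""
    rng = stage_rng(seed, "pair")
    pA, pB = rng.uniform(0.2, 0.8, 2)
    d = rng.uniform(-0.5, 0.5) * min(pA * (1 - pB), (1 - pA) * pB)
    f = np.clip(
        [pA * pB + d, pA * (1 - pB) - d, (1 - pA) * pB - d, (1 - pA) * (1 - pB) + d],
        1e-6,
        1,
    )
    f = np.asarray(f) / np.sum(f)
    haps = rng.choice(4, size=(n, 2), p=f)  # codes: 0=AB 1=Ab 2=aB 3=ab
    g1 = (haps < 2).sum(axis=1).astype(float)
    g2 = ((haps == 0) | (haps == 2)).sum(axis=1).astype(float)
    return g1, g2
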