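"""Pairwise LD, haplotype blocks, and the effective number of tests.

Two-locus haplotype frequencies are estimated from unphased hard calls
by EM over the double-heterozygote phase ambiguity; |D'| gets a 90%
profile-likelihood interval on a 0.001 grid; blocks follow the
confidence-interval dialect of Gabriel-style block finding (strong pair:
CI low >= 0.70 and CI high >= 0.98; recombination: CI high < 0.90; a
block's outermost pair must be strong and >= 95% of informative pairs
strong); the effective number of tests is (sum lambda)^2 / sum lambda^2
over the eigenvalues of the SNP correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import InvalidParameterError

EM_TOL = 1e-10
EM_MAX_ITER = 1000

STRONG_CI_LOW = 0.70
STRONG_CI_HIGH = 0.98
RECOMB_CI_HIGH = 0.90
STRONG_FRACTION = 0.95
CI_GRID_STEP = 0.001
CI_CHI2_CUT = float(stats.chi2.ppf(0.90, 1)) / 2.0
DEFAULT_MAX_PAIR_DISTANCE_BP = 500_000


@dataclass
class PairLD:
    id_a: str
    id_b: str
    freqs: tuple  # (p_AB, p_Ab, p_aB, p_ab)
    d_prime: float
    r2: float
    ci_low: float
    ci_high: float
    classification: str  # strong_ld | recombination | uninformative


@dataclass
class LDBlock:
    chrom: str
    start_bp: int  # 1-based, closed
    end_bp: int
    members: list  # variant ids in position order

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class NeffResult:
    k: int
    eigenvalues: np.ndarray
    n_eff: float


def _genotype_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 joint genotype count table, missing dropped pairwise."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(g1) | np.isnan(g2))
    t = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            t[a, b] = np.sum((g1[ok] == a) & (g2[ok] == b))
    return t


def _cell_probs(f: np.ndarray) -> np.ndarray:
    """Genotype cell probabilities (3x3, indices = A1 counts) under random mating."""
    pAB, pAb, paB, pab = f
    t = np.empty((3, 3))
    t[2, 2] = pAB**2
    t[2, 1] = 2 * pAB * pAb
    t[2, 0] = pAb**2
    t[1, 2] = 2 * pAB * paB
    t[1, 1] = 2 * pAB * pab + 2 * pAb * paB
    t[1, 0] = 2 * pAb * pab
    t[0, 2] = paB**2
    t[0, 1] = 2 * paB * pab
    t[0, 0] = pab**2
    return t


def _loglik(counts: np.ndarray, f: np.ndarray) -> float:
    probs = _cell_probs(np.asarray(f, dtype=float))
    with np.errstate(divide="ignore"):
        lp = np.log(probs)
    mask = counts > 0
    if np.any(np.isneginf(lp[mask])):
        return -np.inf
    return float(np.sum(counts[mask] * lp[mask]))


def two_locus_em(g1, g2, *, return_loglik: bool = False):
    """ML haplotype frequencies (p_AB, p_Ab, p_aB, p_ab) for two loci.

    EM over phase of double heterozygotes; converges when no frequency
    moves more than 1e-10.  The symmetric all-double-het case is broken
    toward the coupling solution (p_AB >= p_Ab) by the initializer.
    The log-likelihood is asserted non-decreasing across iterations.
    """
    counts = _genotype_counts(g1, g2)
    n = counts.sum()
    if n == 0:
        raise InvalidParameterError("no complete genotype pairs")
    pA = float((2 * counts[2, :].sum() + counts[1, :].sum()) / (2 * n))
    pB = float((2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n))
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise InvalidParameterError("monomorphic locus: haplotype phase uninformative")

    # known haplotype contributions from the eight unambiguous cells
    def known(c):
        kAB = 2 * c[2, 2] + c[2, 1] + c[1, 2]
        kAb = 2 * c[2, 0] + c[2, 1] + c[1, 0]
        kaB = 2 * c[0, 2] + c[0, 1] + c[1, 2]
        kab = 2 * c[0, 0] + c[0, 1] + c[1, 0]
        return np.array([kAB, kAb, kaB, kab], dtype=float)

    k = known(counts)
    n_dh = counts[1, 1]
    d0 = 0.01 * min(pA * (1 - pB), (1 - pA) * pB)  # coupling-biased start
    f = np.array(
        [pA * pB + d0, pA * (1 - pB) - d0, (1 - pA) * pB - d0, (1 - pA) * (1 - pB) + d0]
    )
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    ll_prev = -np.inf
    for _ in range(EM_MAX_ITER):
        denom = f[0] * f[3] + f[1] * f[2]
        t = 0.5 if denom == 0 else f[0] * f[3] / denom
        new = k + n_dh * np.array([t, 1 - t, 1 - t, t])
        new /= 2 * n
        ll = _loglik(counts, new)
        if ll < ll_prev - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        moved = np.max(np.abs(new - f))
        f = new
        ll_prev = ll
        if moved < EM_TOL:
            break
    if return_loglik:
        return f, ll_prev
    return f


def ld_stats(f) -> tuple:
    """(|D'|, r2) from haplotype frequencies."""
    pAB, pAb, paB, pab = f
    pA = pAB + pAb
    pB = pAB + paB
    denom = pA * (1 - pA) * pB * (1 - pB)
    d = pAB - pA * pB
    if denom <= 0:
        return 0.0, 0.0
    r2 = d * d / denom
    dmax = min(pA * (1 - pB), (1 - pA) * pB) if d > 0 else min(pA * pB, (1 - pA) * (1 - pB))
    dprime = 0.0 if dmax == 0 else abs(d) / dmax
    return float(min(dprime, 1.0)), float(min(r2, 1.0))


def _freqs_at_dprime(pA: float, pB: float, dprime: np.ndarray, sign: int) -> np.ndarray:
    """Haplotype-frequency rows for a grid of |D'| values at fixed margins."""
    if sign > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d = sign * dprime * dmax
    f = np.empty((dprime.size, 4))
    f[:, 0] = pA * pB + d
    f[:, 1] = pA * (1 - pB) - d
    f[:, 2] = (1 - pA) * pB - d
    f[:, 3] = (1 - pA) * (1 - pB) + d
    return np.clip(f, 0.0, 1.0)


def _loglik_grid(counts: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Vectorized log-likelihood for an array of frequency rows (g, 4)."""
    pAB, pAb, paB, pab = f[:, 0], f[:, 1], f[:, 2], f[:, 3]
    cells = np.empty((f.shape[0], 9))
    cells[:, 0] = pab**2
    cells[:, 1] = 2 * paB * pab
    cells[:, 2] = paB**2
    cells[:, 3] = 2 * pAb * pab
    cells[:, 4] = 2 * pAB * pab + 2 * pAb * paB
    cells[:, 5] = 2 * pAB * paB
    cells[:, 6] = pAb**2
    cells[:, 7] = 2 * pAB * pAb
    cells[:, 8] = pAB**2
    cvec = counts.reshape(-1)  # row-major over (g1, g2) in 0..2
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.log(cells)
        ll = np.where(cvec[None, :] > 0, cvec[None, :] * lp, 0.0)
    ll[np.isnan(ll)] = -np.inf
    return ll.sum(axis=1)


def dprime_ci(g1, g2) -> tuple:
    """90% profile-likelihood confidence bounds on |D'|.

    Allele frequencies are held at their observed (ML) values -- allele
    counts are fully observed from genotypes -- and the likelihood is
    profiled over the sign of D on a 0.001 grid of |D'|.
    """
    counts = _genotype_counts(g1, g2)
    n = counts.sum()
    if n < 10:
        raise InvalidParameterError("need at least 10 samples for a |D'| interval")
    pA = float((2 * counts[2, :].sum() + counts[1, :].sum()) / (2 * n))
    pB = float((2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n))
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise InvalidParameterError("monomorphic locus: |D'| undefined")
    grid = np.arange(0.0, 1.0 + CI_GRID_STEP / 2, CI_GRID_STEP)
    ll = np.maximum(
        _loglik_grid(counts, _freqs_at_dprime(pA, pB, grid, +1)),
        _loglik_grid(counts, _freqs_at_dprime(pA, pB, grid, -1)),
    )
    best = ll.max()
    inside = ll >= best - CI_CHI2_CUT
    return float(grid[inside].min()), float(grid[inside].max())


def classify_pair(ci_low: float, ci_high: float) -> str:
    if ci_low >= STRONG_CI_LOW and ci_high >= STRONG_CI_HIGH:
        return "strong_ld"
    if ci_high < RECOMB_CI_HIGH:
        return "recombination"
    return "uninformative"


def pairwise_ld(
    genotypes: np.ndarray,
    ids,
    positions,
    *,
    max_pair_distance_bp: int = DEFAULT_MAX_PAIR_DISTANCE_BP,
) -> pd.DataFrame:
    """PairLD table for all pairs within the distance cap.

    ``genotypes``: hard-called (n, m) matrix; monomorphic pairs are
    classified uninformative with NaN statistics.
    """
    positions = np.asarray(positions)
    m = genotypes.shape[1]
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            if positions[j] - positions[i] > max_pair_distance_bp:
                break
            try:
                f = two_locus_em(genotypes[:, i], genotypes[:, j])
                dp, r2 = ld_stats(f)
                lo, hi = dprime_ci(genotypes[:, i], genotypes[:, j])
                cls = classify_pair(lo, hi)
            except InvalidParameterError:
                dp = r2 = lo = hi = np.nan
                cls = "uninformative"
            rows.append((ids[i], ids[j], i, j, dp, lo, hi, r2, cls))
    return pd.DataFrame(
        rows,
        columns=["ID_A", "ID_B", "IDX_A", "IDX_B", "DPRIME", "CI_LO", "CI_HI", "R2", "CLASS"],
    )


def gabriel_blocks(
    pair_table: pd.DataFrame,
    positions,
    ids=None,
    chrom: str = "1",
    *,
    max_pair_distance_bp: int = DEFAULT_MAX_PAIR_DISTANCE_BP,
) -> list:
    """Partition markers into haplotype blocks from a PairLD table.

    Candidate interval [i, j]: the outermost pair is strong LD and at
    least 95% of its informative pairs are strong LD.  Candidates are
    accepted greedily by decreasing bp span, skipping overlaps.
    """
    positions = np.asarray(positions)
    m = positions.size
    if m < 2:
        return []
    cls = {}
    for row in pair_table.itertuples(index=False):
        cls[(row.IDX_A, row.IDX_B)] = row.CLASS
    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if positions[j] - positions[i] > max_pair_distance_bp:
                break
            if cls.get((i, j)) != "strong_ld":
                continue
            strong = informative = 0
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    c = cls.get((a, b))
                    if c == "strong_ld":
                        strong += 1
                        informative += 1
                    elif c == "recombination":
                        informative += 1
            if informative and strong / informative >= STRONG_FRACTION:
                span = positions[j] - positions[i]
                candidates.append((span, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    taken = np.zeros(m, dtype=bool)
    blocks = []
    for span, i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        members = (
            [ids[x] for x in range(i, j + 1)] if ids is not None else list(range(i, j + 1))
        )
        blocks.append(LDBlock(chrom, int(positions[i]), int(positions[j]), members))
    blocks.sort(key=lambda b: b.start_bp)
    return blocks


def effective_tests_from_corr(corr: np.ndarray) -> NeffResult:
    corr = np.asarray(corr, dtype=float)
    eig = np.linalg.eigvalsh(corr)[::-1]
    eig = np.where(eig < 0, np.where(eig > -1e-10, 0.0, eig), eig)
    if np.any(eig < 0):
        raise InvalidParameterError("correlation matrix is not PSD")
    n_eff = float(eig.sum() ** 2 / np.sum(eig**2))
    return NeffResult(k=corr.shape[0], eigenvalues=eig, n_eff=n_eff)


def effective_tests(dosages: np.ndarray, ids=None) -> NeffResult:
    """Effective number of independent tests for a SNP set.

    Eigenvalues of the K x K dosage correlation matrix, combined as
    (sum lambda)^2 / sum lambda^2.  Constant columns are rejected by name.
    """
    g = np.asarray(dosages, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    k = g.shape[1]
    if k < 1:
        raise InvalidParameterError("need at least one SNP")
    sd = np.nanstd(g, axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        name = ids[bad[0]] if ids is not None else f"column {bad[0]}"
        raise InvalidParameterError(f"constant dosage column: {name}")
    if k == 1:
        return NeffResult(k=1, eigenvalues=np.array([1.0]), n_eff=1.0)
    col_mean = np.nanmean(g, axis=0)
    x = np.where(np.isnan(g), col_mean[None, :], g)
    corr = np.corrcoef(x, rowvar=False)
    return effective_tests_from_corr(corr)
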