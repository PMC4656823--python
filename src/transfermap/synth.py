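"""Synthetic cohort generation.

Everything downstream (QC, association, LD blocks, transferability) is
exercised on cohorts produced here: a block-structured haplotype panel,
genotypes drawn from it, phenotypes from a logistic disease model with
case-control ascertainment, imputation-style dosage noise, and planted
QC flaws (duplicates, sex discordance, relatedness, missingness, HWE
violations) recorded in a truth ledger.

LD within a block uses a copy-with-mutation scheme: each haplotype draws
one latent uniform score per block and carries the A1 allele at variant j
iff score <= p_j; with probability (1 - within_block_ld) a site is
resampled independently.  At within_block_ld = 1 carrier sets are nested,
so every realized within-block |D'| is exactly 1; blocks are mutually
independent (free recombination).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    DosageMatrix,
    InvalidParameterError,
    make_variant_table,
    stage_rng,
)

_BASES = np.array(list("ACGT"))


@dataclass
class HaplotypePanel:
    """Reference haplotypes with known block structure."""

    chrom_label: str
    positions: np.ndarray  # 1-based bp, strictly increasing
    haplotypes: np.ndarray  # (n_haplotypes, n_variants) uint8, 1 = A1
    block_assignment: np.ndarray  # per-variant block index, non-decreasing
    panel_tag: str = "SYN"
    a1: list = field(default_factory=list)
    a2: list = field(default_factory=list)
    variant_ids: list = field(default_factory=list)
    monomorphic: np.ndarray = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.block_assignment = np.asarray(self.block_assignment)
        if np.any(np.diff(self.positions) <= 0):
            raise InvalidParameterError("positions must be strictly increasing")
        if np.any(np.diff(self.block_assignment) < 0):
            raise InvalidParameterError("block_assignment must be non-decreasing")
        if self.monomorphic is None:
            f = self.haplotypes.mean(axis=0)
            self.monomorphic = (f == 0) | (f == 1)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def allele_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def variant_table(self) -> pd.DataFrame:
        return make_variant_table(
            self.variant_ids, self.chrom_label, self.positions, self.a1, self.a2
        )


@dataclass
class FlawSpec:
    """Counts of QC flaws to plant; categories are disjoint by construction."""

    n_duplicates: int = 0
    n_sex_discordant: int = 0
    n_related: int = 0
    related_pihat: float = 0.5
    n_missing_variants: int = 0
    missing_rate: float = 0.1
    n_hwe_variants: int = 0


@dataclass
class CohortConfig:
    n_cases: int
    n_controls: int
    causal_loci: Sequence = ()  # (variant index, per-allele OR, risk allele)
    covariate_effects: tuple = (0.0, 0.0, 0.0)  # age, sex(female), BMI log-odds
    intercept: float = 0.0
    flaw_spec: FlawSpec = field(default_factory=FlawSpec)
    imputation_r2: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise InvalidParameterError("n_cases and n_controls must be positive")
        for _, odds, _ in self.causal_loci:
            if odds <= 0:
                raise InvalidParameterError("odds ratios must be > 0")
        if self.imputation_r2 is not None and not (0 < self.imputation_r2 <= 1):
            raise InvalidParameterError("imputation_r2 must be in (0, 1]")


def simulate_panel(
    n_blocks: int,
    snps_per_block: int,
    n_haplotypes: int,
    within_block_ld: float,
    maf_range: tuple,
    seed: int,
    *,
    chrom_label: str = "1",
    panel_tag: str = "SYN",
    start_bp: int = 1_000_000,
    snp_spacing: int = 1_000,
    block_gap: int = 10_000,
    id_prefix: str = "snp",
) -> HaplotypePanel:
    """Simulate a haplotype panel with tunable within-block LD.

    ``within_block_ld = 1`` yields |D'| = 1 for every polymorphic pair in
    the same block; 0 yields independent sites.  Variants in different
    blocks are always independent.
    """
    if min(n_blocks, snps_per_block, n_haplotypes) < 1:
        raise InvalidParameterError("counts must be >= 1")
    if not (0.0 <= within_block_ld <= 1.0):
        raise InvalidParameterError("within_block_ld must be in [0, 1]")
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if not (0.0 < lo <= hi <= 0.5):
        raise InvalidParameterError("maf_range must lie within (0, 0.5]")
    if hi - lo < 1e-6:
        raise InvalidParameterError("degenerate maf_range: zero width below resolution")

    rng = stage_rng(seed, "panel")
    m = n_blocks * snps_per_block
    haps = np.empty((n_haplotypes, m), dtype=np.uint8)
    positions = np.empty(m, dtype=np.int64)
    blocks = np.repeat(np.arange(n_blocks), snps_per_block)

    for b in range(n_blocks):
        cols = slice(b * snps_per_block, (b + 1) * snps_per_block)
        block_start = start_bp + b * (snps_per_block * snp_spacing + block_gap)
        positions[cols] = block_start + np.arange(snps_per_block) * snp_spacing
        score = rng.random(n_haplotypes)
        p = rng.uniform(lo, hi, snps_per_block)
        keep = rng.random((n_haplotypes, snps_per_block)) < within_block_ld
        indep = rng.random((n_haplotypes, snps_per_block))
        block_h = np.where(keep, score[:, None] <= p[None, :], indep <= p[None, :])
        # redraw target frequencies for columns that came out monomorphic
        for j in range(snps_per_block):
            tries = 0
            while tries < 100 and block_h[:, j].min() == block_h[:, j].max():
                pj = rng.uniform(lo, hi)
                kj = rng.random(n_haplotypes) < within_block_ld
                ij = rng.random(n_haplotypes)
                block_h[:, j] = np.where(kj, score <= pj, ij <= pj)
                tries += 1
        haps[:, cols] = block_h

    alleles = _BASES[rng.integers(0, 4, m)]
    shift = rng.integers(1, 4, m)
    other = _BASES[(np.searchsorted(_BASES, alleles) + shift) % 4]
    return HaplotypePanel(
        chrom_label=chrom_label,
        positions=positions,
        haplotypes=haps,
        block_assignment=blocks,
        panel_tag=panel_tag,
        a1=list(alleles),
        a2=list(other),
        variant_ids=[f"{id_prefix}{i:05d}" for i in range(m)],
    )


def simulate_genotypes(panel: HaplotypePanel, n_samples: int, seed: int) -> DosageMatrix:
    """Draw diploid genotypes: two haplotypes uniform with replacement."""
    if panel.n_variants == 0 or panel.n_haplotypes == 0:
        raise InvalidParameterError("panel must be non-empty")
    if n_samples < 1:
        raise InvalidParameterError("n_samples must be >= 1")
    rng = stage_rng(seed, "genotypes")
    idx = rng.integers(0, panel.n_haplotypes, size=(n_samples, 2))
    g = panel.haplotypes[idx[:, 0]].astype(float) + panel.haplotypes[idx[:, 1]]
    ids = [f"S{i:05d}" for i in range(n_samples)]
    return DosageMatrix(g, ids, panel.variant_table())


def simulate_genotypes_from_freqs(
    freqs: np.ndarray,
    n_samples: int,
    seed: int,
    *,
    chrom_label: str = "1",
    start_bp: int = 1_000_000,
    spacing: int = 5_000,
    id_prefix: str = "snp",
) -> DosageMatrix:
    """Genotypes from per-variant allele frequencies (infinite-panel limit).

    Unlike :func:`simulate_genotypes`, samples never share panel
    haplotypes, so the background relatedness of every pair is exactly
    zero -- the right null for relatedness QC at large sample counts.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or np.any((freqs <= 0) | (freqs >= 1)):
        raise InvalidParameterError("freqs must be a 1-D array in (0, 1)")
    if n_samples < 1:
        raise InvalidParameterError("n_samples must be >= 1")
    rng = stage_rng(seed, "genotypes-freq")
    m = freqs.size
    g = rng.binomial(2, freqs, size=(n_samples, m)).astype(float)
    alleles = _BASES[rng.integers(0, 4, m)]
    other = _BASES[(np.searchsorted(_BASES, alleles) + rng.integers(1, 4, m)) % 4]
    variants = make_variant_table(
        [f"{id_prefix}{i:05d}" for i in range(m)],
        chrom_label,
        start_bp + np.arange(m) * spacing,
        alleles,
        other,
    )
    return DosageMatrix(g, [f"S{i:05d}" for i in range(n_samples)], variants)


def draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Age / sex / BMI plus the X-heterozygosity sex proxy."""
    age = rng.normal(52.0, 8.0, n)
    female = rng.random(n) < 0.5
    bmi = rng.normal(26.0, 4.0, n)
    # X-heterozygosity proxy travels with the TRUE sex; QC compares it to
    # the reported label, which inject_flaws may flip.  SDs keep the two
    # sexes > 5 sigma from the QC threshold so only planted flips flag.
    xhet = np.where(
        female,
        rng.normal(0.25, 0.02, n),
        rng.normal(0.02, 0.01, n),
    )
    return pd.DataFrame(
        {
            "age": age,
            "sex": np.where(female, "F", "M"),
            "bmi": bmi,
            "xhet": np.clip(xhet, 0.0, 1.0),
        }
    )


def _linear_predictor(dosages: np.ndarray, covs: pd.DataFrame, config: CohortConfig):
    lp = np.full(len(covs), config.intercept, dtype=float)
    for j, odds, risk_allele in config.causal_loci:
        d = dosages[:, j]
        lp += np.log(odds) * d
    b_age, b_sex, b_bmi = config.covariate_effects
    lp += b_age * covs["age"].to_numpy()
    lp += b_sex * (covs["sex"].to_numpy() == "F")
    lp += b_bmi * covs["bmi"].to_numpy()
    return lp


def simulate_phenotypes(genotypes: DosageMatrix, config: CohortConfig) -> pd.DataFrame:
    """Assign phenotypes under case-control ascertainment.

    Treats the rows of ``genotypes`` as a population pool read in order:
    each individual gets covariates and a case status drawn from the
    logistic model; individuals are retained while their status quota
    (``n_cases`` / ``n_controls``) is open.  Returns a sample table with
    a ``pool_row`` column pointing back into ``genotypes``; raises if
    the pool is exhausted before both quotas fill (advice: adjust the
    intercept or enlarge the pool).
    """
    for j, _, _ in config.causal_loci:
        if not (0 <= j < genotypes.n_variants):
            raise InvalidParameterError(f"causal variant index {j} out of range")
    rng = stage_rng(config.seed, "phenotypes")
    covs = draw_covariates(rng, genotypes.n_samples)
    lp = _linear_predictor(genotypes.dosages, covs, config)
    p_case = 1.0 / (1.0 + np.exp(-lp))
    status = (rng.random(genotypes.n_samples) < p_case).astype(int)

    rows, statuses = [], []
    need = {1: config.n_cases, 0: config.n_controls}
    for i in range(genotypes.n_samples):
        s = int(status[i])
        if need[s] > 0:
            need[s] -= 1
            rows.append(i)
            statuses.append(s)
        if need[1] == 0 and need[0] == 0:
            break
    if need[1] > 0 or need[0] > 0:
        short = "cases" if need[1] > 0 else "controls"
        raise InvalidParameterError(
            f"pool exhausted before filling {short} quota; adjust the intercept "
            f"(currently {config.intercept}) or enlarge the genotype pool"
        )
    out = covs.iloc[rows].reset_index(drop=True)
    out.insert(0, "status", statuses)
    out.insert(0, "sample_id", [genotypes.sample_ids[i] for i in rows])
    out["pool_row"] = rows
    return out


def ascertain(genotypes: DosageMatrix, samples: pd.DataFrame):
    """Subset the genotype pool to the ascertained individuals."""
    dm = genotypes.take_samples(samples["pool_row"].to_numpy())
    out = samples.drop(columns=["pool_row"]).reset_index(drop=True)
    return dm, out


def simulate_cohort(panel: HaplotypePanel, config: CohortConfig, *, pool_factor: int = 4):
    """Panel → ascertained (genotypes, sample table) in one call."""
    n_needed = config.n_cases + config.n_controls
    pool = simulate_genotypes(panel, pool_factor * n_needed, config.seed)
    samples = simulate_phenotypes(pool, config)
    return ascertain(pool, samples)


def apply_imputation_noise(genotypes: DosageMatrix, imputation_r2, seed: int) -> DosageMatrix:
    """Attenuate true genotypes into imputed-style dosages.

    d = 2p + r (g - 2p) + e with r = sqrt(r2) and Var(e) = (1 - r2) Var(g),
    clipped to [0, 2]; corr(d, g)^2 converges to ``imputation_r2``.
    Constant columns (Var(g) = 0) pass through unchanged, as does r2 = 1.
    """
    r2 = np.broadcast_to(np.asarray(imputation_r2, dtype=float), (genotypes.n_variants,))
    if np.any((r2 <= 0) | (r2 > 1)):
        raise InvalidParameterError("imputation_r2 must be in (0, 1]")
    rng = stage_rng(seed, "imputation-noise")
    g = genotypes.dosages
    p = genotypes.allele_freq()
    var = np.nanvar(g, axis=0)
    r = np.sqrt(r2)
    noise_sd = np.sqrt((1.0 - r2) * var)
    d = 2 * p[None, :] + r[None, :] * (g - 2 * p[None, :])
    d = d + rng.normal(0.0, 1.0, g.shape) * noise_sd[None, :]
    np.clip(d, 0.0, 2.0, out=d)
    exact = (r2 == 1.0) | (var == 0.0)
    d[:, exact] = g[:, exact]
    d[np.isnan(g)] = np.nan
    variants = genotypes.variants.copy()
    variants["imputed"] = True
    variants["imp_r2"] = r2
    return DosageMatrix(d, list(genotypes.sample_ids), variants)


def inject_flaws(
    genotypes: DosageMatrix,
    samples: pd.DataFrame,
    flaw_spec: FlawSpec,
    seed: int,
):
    """Plant QC flaws and return (genotypes, samples, truth ledger).

    Duplicates are appended as exact genotype copies under a new id
    (``<orig>_dup``).  Sex discordance flips the reported label against
    the simulated X-heterozygosity proxy.  Related pairs copy the
    partner's genotypes at a ``related_pihat`` fraction of variants, so
    the method-of-moments PiHat equals the target in expectation.  All
    sample categories are disjoint; ledger rows record what was planted.
    """
    fs = flaw_spec
    n = genotypes.n_samples
    n_flagged = fs.n_duplicates + fs.n_sex_discordant + 2 * fs.n_related
    if n_flagged > n:
        raise InvalidParameterError("flaw counts exceed sample count")
    if fs.n_missing_variants + fs.n_hwe_variants > genotypes.n_variants:
        raise InvalidParameterError("variant flaw counts exceed variant count")
    if not (0 < fs.related_pihat <= 1) and fs.n_related:
        raise InvalidParameterError("related_pihat must be in (0, 1]")

    rng = stage_rng(seed, "inject-flaws")
    ledger = []
    g = genotypes.dosages.copy()
    samples = samples.reset_index(drop=True).copy()
    ids = list(genotypes.sample_ids)

    chosen = rng.choice(n, size=n_flagged, replace=False) if n_flagged else np.array([], int)
    pos = 0
    dup_src = chosen[pos : pos + fs.n_duplicates]; pos += fs.n_duplicates
    sex_idx = chosen[pos : pos + fs.n_sex_discordant]; pos += fs.n_sex_discordant
    rel_victim = chosen[pos : pos + fs.n_related]; pos += fs.n_related
    rel_partner = chosen[pos : pos + fs.n_related]

    for i in sex_idx:
        old = samples.at[i, "sex"]
        samples.at[i, "sex"] = "F" if old == "M" else "M"
        ledger.append(("sex_discordant", ids[i], "", f"reported={samples.at[i, 'sex']}"))
    for v, p in zip(rel_victim, rel_partner):
        share = rng.random(genotypes.n_variants) < fs.related_pihat
        g[v, share] = g[p, share]
        ledger.append(("related", ids[v], ids[p], f"target_pihat={fs.related_pihat}"))

    vchosen = (
        rng.choice(genotypes.n_variants, fs.n_missing_variants + fs.n_hwe_variants, replace=False)
        if fs.n_missing_variants + fs.n_hwe_variants
        else np.array([], int)
    )
    miss_idx = vchosen[: fs.n_missing_variants]
    hwe_idx = vchosen[fs.n_missing_variants :]
    for j in miss_idx:
        mask = rng.random(n) < fs.missing_rate
        g[mask, j] = np.nan
        ledger.append(("missingness", genotypes.variants.at[j, "id"], "", f"rate={fs.missing_rate}"))
    for j in hwe_idx:
        # heterozygote-depleted column: alleles only as homozygotes
        p = np.nanmean(g[:, j]) / 2.0
        g[:, j] = 2.0 * (rng.random(n) < p)
        ledger.append(("hwe_violation", genotypes.variants.at[j, "id"], "", ""))

    # duplicates copy rows AFTER variant flaws so the copies stay exact
    extra_rows, extra_samples = [], []
    for i in dup_src:
        new_id = f"{ids[i]}_dup"
        extra_rows.append(g[i].copy())
        row = samples.iloc[i].copy()
        row["sample_id"] = new_id
        extra_samples.append(row)
        ledger.append(("duplicate", new_id, ids[i], ""))
    if extra_rows:
        g = np.vstack([g] + [r[None, :] for r in extra_rows])
        for row in extra_samples:
            samples = pd.concat([samples, row.to_frame().T], ignore_index=True)
            ids.append(row["sample_id"])

    ledger_df = pd.DataFrame(ledger, columns=["category", "entity_id", "partner_id", "detail"])
    dm = DosageMatrix(g, ids, genotypes.variants.copy())
    samples = samples.reset_index(drop=True)
    return dm, samples, ledger_df
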