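"""Sample- and variant-level quality control.

Sample cascade (fixed order, each step on the survivors of the previous):
call-rate filter → duplicate removal (PiHat >= 0.95, keep the higher
call-rate member, ties broken by removing the later id) → sex-discordance
flag → greedy relatedness pruning (repeatedly drop the sample in the most
PiHat > threshold pairs).  Variant filters are evaluated jointly on the
input data and reported with reason codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DosageMatrix, InvalidParameterError

XHET_THRESHOLD = 0.15  # reported-male above / reported-female below is discordant


@dataclass
class QCThresholds:
    sample_call_rate_min: float = 0.95
    variant_missingness_max: float = 0.05
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    pihat_max: float = 0.125
    duplicate_pihat: float = 0.95
    dosage_freq_min: float = 0.01
    imp_r2_min: float = 0.3
    hwe_controls_only: bool = False

    def __post_init__(self):
        for name in (
            "sample_call_rate_min",
            "variant_missingness_max",
            "hwe_p_min",
            "maf_min",
            "pihat_max",
            "duplicate_pihat",
            "dosage_freq_min",
            "imp_r2_min",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    samples_excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "reason"])
    )
    variants_excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "reason"])
    )

    def sample_counts(self) -> dict:
        return self.samples_excluded["reason"].value_counts().to_dict()

    def variant_counts(self) -> dict:
        return self.variants_excluded["reason"].value_counts().to_dict()

    def write(self, path) -> None:
        frames = []
        if len(self.samples_excluded):
            f = self.samples_excluded.copy()
            f.insert(0, "level", "sample")
            frames.append(f)
        if len(self.variants_excluded):
            f = self.variants_excluded.copy()
            f.insert(0, "level", "variant")
            frames.append(f)
        out = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["level", "id", "reason"])
        )
        out.to_csv(path, sep="\t", index=False)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Enumerates every heterozygote count compatible with the observed
    allele counts and sums the conditional probabilities of all
    configurations no more probable than the observed one.
    """
    counts = (int(n_AA), int(n_Aa), int(n_aa))
    if min(counts) < 0:
        raise InvalidParameterError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise InvalidParameterError("at least one genotype observation required")
    n_a = 2 * counts[2] + counts[1]
    n_rare = min(n_a, 2 * n - n_a)
    obs_het = counts[1]

    # unnormalized conditional distribution over het counts, built by the
    # upward recurrence from the smallest compatible het count
    het0 = n_rare % 2
    hets = np.arange(het0, n_rare + 1, 2)
    probs = np.empty(hets.size)
    probs[0] = 1.0
    for k in range(hets.size - 1):
        het = hets[k]
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[k + 1] = probs[k] * 4.0 * hom_r * hom_c / ((het + 1.0) * (het + 2.0))
        if probs[k + 1] > 1e250:  # rescale to avoid overflow
            probs[: k + 2] /= probs[k + 1]
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, obs_het)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def _ibs_counts(g: np.ndarray):
    """All-pairs IBS0/IBS2 counts via one-hot matmuls. g: (n, m) in {0,1,2}."""
    a0 = (g == 0).astype(np.float32)
    a1 = (g == 1).astype(np.float32)
    a2 = (g == 2).astype(np.float32)
    ibs2 = a0 @ a0.T + a1 @ a1.T + a2 @ a2.T
    ibs0 = a0 @ a2.T + a2 @ a0.T
    return ibs0, ibs2


def pairwise_pihat(g: np.ndarray, freqs: np.ndarray = None) -> np.ndarray:
    """Method-of-moments PiHat for every sample pair.

    ``g`` must be hard-called genotypes without missing values; ``freqs``
    defaults to the sample allele frequencies.  P(IBD=0,1,2) are solved
    from observed IBS counts against their expectations given allele
    frequencies; PiHat = P(IBD=1)/2 + P(IBD=2), truncated to [0, 1].
    """
    g = np.asarray(g)
    if np.isnan(g).any():
        raise InvalidParameterError("pairwise_pihat requires complete genotypes")
    m = g.shape[1]
    p = g.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    q = 1.0 - p
    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e2_ibd0 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e1_ibd1 = float(np.sum(2 * p * q))
    e2_ibd1 = float(np.sum(p**2 + q**2))

    ibs0, ibs2 = _ibs_counts(g)
    ibs1 = m - ibs0 - ibs2
    # solve the moment equations without clipping the intermediate IBD
    # probabilities: rectifying their noise at 0 biases PiHat upward and
    # fattens the null upper tail; only the final estimate is truncated
    p0 = ibs0 / e0_ibd0
    p1 = (ibs1 - p0 * e1_ibd0) / e1_ibd1
    p2 = (ibs2 - p0 * e2_ibd0 - p1 * e2_ibd1) / m
    return np.clip(p1 / 2.0 + p2, 0.0, 1.0)


def ibd_pihat(
    genotypes,
    pair,
    freqs: np.ndarray = None,
    *,
    min_variants: int = 200,
    min_maf: float = 0.05,
) -> float:
    """PiHat for one sample pair from LD-pruned common variants."""
    if isinstance(genotypes, DosageMatrix):
        g = genotypes.hard_calls()
    else:
        g = np.asarray(genotypes, dtype=float)
    if freqs is None:
        freqs = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(freqs, 1 - freqs)
    keep = (maf >= min_maf) & ~np.isnan(g).any(axis=0)
    if keep.sum() < min_variants:
        raise InvalidParameterError(
            f"need >= {min_variants} complete pruned variants with MAF >= {min_maf}; "
            f"got {int(keep.sum())}"
        )
    i, j = pair
    sub = g[np.array([i, j])][:, keep]
    return float(pairwise_pihat(sub, freqs[keep])[0, 1])


def select_ibd_variants(
    dm: DosageMatrix, *, min_maf: float = 0.05, max_variants: int = 5000
) -> np.ndarray:
    """Indices of complete, common variants to use for IBD estimation."""
    f = dm.allele_freq()
    maf = np.minimum(f, 1 - f)
    ok = np.flatnonzero((maf >= min_maf) & (dm.variant_missingness() == 0.0))
    if ok.size > max_variants:
        ok = ok[np.linspace(0, ok.size - 1, max_variants).astype(int)]
    return ok


def sample_qc(
    dm: DosageMatrix,
    samples: pd.DataFrame,
    thresholds: QCThresholds = None,
    *,
    ibd_variants: np.ndarray = None,
    min_ibd_variants: int = 200,
):
    """Run the sample-level QC cascade; returns (retained ids, QCReport)."""
    thr = thresholds or QCThresholds()
    samples = samples.set_index("sample_id", drop=False)
    if not set(dm.sample_ids) <= set(samples.index):
        raise InvalidParameterError("sample table does not cover all genotype rows")
    ids = np.array(dm.sample_ids, dtype=object)
    excluded: list = []
    active = np.ones(dm.n_samples, dtype=bool)

    call_rate = dm.sample_call_rate()
    for i in np.flatnonzero(call_rate < thr.sample_call_rate_min):
        active[i] = False
        excluded.append((ids[i], "low_call_rate"))

    if ibd_variants is None:
        ibd_variants = select_ibd_variants(dm)
    if ibd_variants.size < min_ibd_variants:
        raise InvalidParameterError(
            f"need >= {min_ibd_variants} complete common variants for IBD; "
            f"got {ibd_variants.size}"
        )
    g = dm.hard_calls()[:, ibd_variants]
    pihat = pairwise_pihat(g)
    np.fill_diagonal(pihat, 0.0)

    # duplicates: PiHat >= threshold; drop the lower call-rate member
    dup_pairs = np.argwhere(np.triu(pihat >= thr.duplicate_pihat, k=1))
    for i, j in dup_pairs:
        if not (active[i] and active[j]):
            continue
        if call_rate[i] < call_rate[j]:
            drop = i
        elif call_rate[j] < call_rate[i]:
            drop = j
        else:
            drop = i if ids[i] > ids[j] else j  # tie: later id
        active[drop] = False
        excluded.append((ids[drop], "duplicate"))

    if "xhet" in samples.columns and "sex" in samples.columns:
        xhet = samples.loc[ids, "xhet"].to_numpy(dtype=float)
        sex = samples.loc[ids, "sex"].to_numpy()
        discordant = ((sex == "M") & (xhet > XHET_THRESHOLD)) | (
            (sex == "F") & (xhet <= XHET_THRESHOLD)
        )
        for i in np.flatnonzero(discordant & active):
            active[i] = False
            excluded.append((ids[i], "sex_discordant"))

    # greedy relatedness pruning among the remaining samples
    rel = (pihat > thr.pihat_max) & np.outer(active, active)
    np.fill_diagonal(rel, False)
    degree = rel.sum(axis=1)
    while degree.max(initial=0) > 0:
        top = degree.max()
        candidates = np.flatnonzero(degree == top)
        drop = candidates[np.argmax(ids[candidates].astype(str))]  # tie: later id
        active[drop] = False
        excluded.append((ids[drop], "related"))
        rel[drop, :] = False
        rel[:, drop] = False
        degree = rel.sum(axis=1)

    report = QCReport(samples_excluded=pd.DataFrame(excluded, columns=["id", "reason"]))
    retained = [ids[i] for i in np.flatnonzero(active)]
    return retained, report


def variant_qc(dm: DosageMatrix, thresholds: QCThresholds = None, status=None):
    """Variant filters; every failing reason is reported for each variant.

    Missingness > max, HWE p < min (genotyped variants only, optionally
    restricted to controls), MAF < min; imputed variants are additionally
    dropped when the folded dosage frequency < min or imputation
    r-squared < min (strict: r2 exactly at the threshold is retained).
    """
    thr = thresholds or QCThresholds()
    vid = dm.variants["id"].to_numpy()
    imputed = dm.variants["imputed"].to_numpy(dtype=bool)
    imp_r2 = dm.variants["imp_r2"].to_numpy(dtype=float)
    excluded: list = []

    miss = dm.variant_missingness()
    for j in np.flatnonzero(miss > thr.variant_missingness_max):
        excluded.append((vid[j], "missingness"))

    freq = dm.allele_freq()
    maf = np.minimum(freq, 1 - freq)
    for j in np.flatnonzero(maf < thr.maf_min):
        excluded.append((vid[j], "maf"))

    hwe_rows = dm.hard_calls()
    if thr.hwe_controls_only and status is not None:
        hwe_rows = hwe_rows[np.asarray(status) == 0]
    for j in np.flatnonzero(~imputed):
        col = hwe_rows[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        n_aa = int(np.sum(col == 0))
        n_het = int(np.sum(col == 1))
        n_AA = int(np.sum(col == 2))
        if hwe_exact_test(n_AA, n_het, n_aa) < thr.hwe_p_min:
            excluded.append((vid[j], "hwe"))

    dosage_maf = maf
    for j in np.flatnonzero(imputed & (dosage_maf < thr.dosage_freq_min)):
        excluded.append((vid[j], "dosage_freq"))
    with np.errstate(invalid="ignore"):
        bad_r2 = imputed & (imp_r2 < thr.imp_r2_min)
    for j in np.flatnonzero(bad_r2):
        excluded.append((vid[j], "imp_r2"))

    report = QCReport(variants_excluded=pd.DataFrame(excluded, columns=["id", "reason"]))
    bad_ids = set(report.variants_excluded["id"])
    retained = [v for v in vid if v not in bad_ids]
    return retained, report
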