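"""Locus transferability calls and block-size fine mapping.

Exact transferability: the index SNP itself has p < alpha and a
harmonized direction of effect consistent with the reported odds ratio.
Local transferability: some SNP in the index SNP's LD block, in LD with
the index (r2 >= r2_min), has p * Neff < alpha.  Exact takes precedence;
index SNPs absent from the data are "untested".
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Optional

import numpy as np
import pandas as pd

from .core import InvalidParameterError
from .ld import LDBlock, NeffResult

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
AMBIGUOUS_FREQ_BAND = (0.4, 0.6)
DEFAULT_R2_MIN = 0.3


@dataclass
class IndexLocus:
    snp: str
    chrom: str
    pos: int
    risk_allele: str
    reported_or: float
    panel: str = "EUR"
    gene: str = ""

    def __post_init__(self):
        if self.reported_or <= 0:
            raise InvalidParameterError("reported OR must be > 0")


@dataclass
class TransferCall:
    locus: IndexLocus
    status: str  # exact | local | none | untested
    index_p: Optional[float] = None
    direction_consistent: Optional[bool] = None
    best_snp: Optional[str] = None
    best_snp_p: Optional[float] = None
    p_adj: Optional[float] = None
    n_eff: Optional[float] = None
    r2_to_index: Optional[float] = None
    reason: str = ""


class AlleleMismatchError(InvalidParameterError):
    pass


def harmonize_alleles(risk_allele: str, a1: str, a2: str, a1_freq: float):
    """Direction multiplier mapping the study beta onto the risk allele.

    +1 if A1 is the risk allele (directly or by strand complement), -1 if
    A2 is.  Strand-ambiguous A/T and C/G SNPs with A1 frequency in
    [0.4, 0.6] return None (untestable).  Incompatible alleles raise.
    """
    risk, a1, a2 = risk_allele.upper(), a1.upper(), a2.upper()
    for x in (risk, a1, a2):
        if x not in COMPLEMENT:
            raise AlleleMismatchError(f"not a nucleotide allele: {x}")
    ambiguous = a2 == COMPLEMENT[a1]
    if ambiguous and AMBIGUOUS_FREQ_BAND[0] <= a1_freq <= AMBIGUOUS_FREQ_BAND[1]:
        return None
    if risk == a1:
        return +1
    if risk == a2:
        return -1
    if COMPLEMENT[risk] == a1:
        return +1
    if COMPLEMENT[risk] == a2:
        return -1
    raise AlleleMismatchError(
        f"risk allele {risk} incompatible with study alleles {a1}/{a2}"
    )


def classify_exact(beta: float, p: float, multiplier: int, reported_or: float, alpha: float = 0.05):
    """(is_exact, direction_consistent) for the index SNP itself."""
    if multiplier not in (-1, 1):
        raise InvalidParameterError("multiplier must be +1 or -1")
    harmonized = multiplier * beta
    consistent = (harmonized > 0) == (reported_or > 1.0)
    return bool(p < alpha and consistent), bool(consistent)


def classify_local(
    locus: IndexLocus,
    block_assoc: pd.DataFrame,
    neff: NeffResult,
    r2_to_index: dict,
    *,
    alpha: float = 0.05,
    r2_min: float = DEFAULT_R2_MIN,
    already_exact: bool = False,
) -> TransferCall:
    """Best-SNP adjusted-p call over the index SNP's block.

    p_adj = min(1, p * Neff); the best SNP is the smallest-p SNP with
    r2 to the index >= r2_min (ties: smaller bp distance to the index,
    then lexicographic id).  Status "local" requires best p_adj < alpha
    and that the locus is not already exact.
    """
    eligible = []
    for row in block_assoc.itertuples(index=False):
        r2 = r2_to_index.get(row.SNP, np.nan)
        if np.isnan(row.P) or np.isnan(r2) or r2 < r2_min:
            continue
        eligible.append((row.P, abs(int(row.BP) - locus.pos), row.SNP))
    if not eligible:
        return TransferCall(locus, "none", reason="no SNP in LD with the index at r2_min")
    eligible.sort()
    p_best, _, snp_best = eligible[0]
    p_adj = min(1.0, p_best * neff.n_eff)
    status = "local" if (p_adj < alpha and not already_exact) else "none"
    return TransferCall(
        locus,
        status,
        best_snp=snp_best,
        best_snp_p=float(p_best),
        p_adj=float(p_adj),
        n_eff=neff.n_eff,
        r2_to_index=float(r2_to_index[snp_best]),
    )


def sign_consistency_test(n_consistent: int, n_total: int) -> float:
    """One-sided exact binomial tail P(X >= n_consistent | n_total, 1/2)."""
    if n_total < 1:
        raise InvalidParameterError("n_total must be >= 1")
    if not (0 <= n_consistent <= n_total):
        raise InvalidParameterError("n_consistent must be within [0, n_total]")
    tail = sum(comb(n_total, k) for k in range(n_consistent, n_total + 1))
    return float(tail / 2.0**n_total)


@dataclass
class FineMapVerdict:
    locus_snp: str
    study_span_bp: int
    reference_span_bp: int
    fine_mapped: bool
    refined: bool


def _containing_block(blocks, chrom, pos: int):
    hits = [
        b for b in blocks if str(b.chrom) == str(chrom) and b.start_bp <= pos <= b.end_bp
    ]
    if len(hits) > 1:
        raise InvalidParameterError("index SNP falls in more than one block")
    return hits[0] if hits else None


def compare_blocks(
    study_blocks,
    reference_blocks,
    locus: IndexLocus,
    study_assoc: pd.DataFrame,
) -> FineMapVerdict:
    """Block-span fine-mapping verdict for one index locus.

    An index SNP outside any block gets span 0 (single-marker
    resolution); ``refined`` is true when some other SNP in the study
    block beats the index SNP's p-value.
    """
    sb = _containing_block(study_blocks, locus.chrom, locus.pos)
    rb = _containing_block(reference_blocks, locus.chrom, locus.pos)
    study_span = sb.span_bp if sb else 0
    ref_span = rb.span_bp if rb else 0

    refined = False
    idx_rows = study_assoc.loc[study_assoc["SNP"] == locus.snp]
    if sb is not None and len(idx_rows):
        index_p = float(idx_rows["P"].iloc[0])
        members = set(sb.members)
        others = study_assoc.loc[
            study_assoc["SNP"].isin(members) & (study_assoc["SNP"] != locus.snp)
        ]
        if len(others) and np.nanmin(others["P"].to_numpy(dtype=float)) < index_p:
            refined = True
    return FineMapVerdict(locus.snp, int(study_span), int(ref_span), study_span < ref_span, refined)


def call_transferability(
    locus: IndexLocus,
    assoc: pd.DataFrame,
    block: Optional[LDBlock],
    neff: Optional[NeffResult],
    r2_to_index: dict,
    *,
    alpha: float = 0.05,
    r2_min: float = DEFAULT_R2_MIN,
) -> TransferCall:
    """Full per-locus decision: untested / exact / local / none."""
    idx_rows = assoc.loc[assoc["SNP"] == locus.snp]
    if not len(idx_rows):
        return TransferCall(locus, "untested", reason="index SNP absent from data")
    row = idx_rows.iloc[0]
    try:
        mult = harmonize_alleles(locus.risk_allele, row["A1"], row["A2"], row["A1_FREQ"])
    except AlleleMismatchError as exc:
        return TransferCall(locus, "untested", reason=str(exc))
    if mult is None:
        return TransferCall(locus, "untested", reason="strand-ambiguous SNP at MAF near 0.5")
    index_p = float(row["P"])
    is_exact, consistent = classify_exact(
        float(row["BETA"]), index_p, mult, locus.reported_or, alpha
    )
    if is_exact:
        return TransferCall(
            locus, "exact", index_p=index_p, direction_consistent=consistent
        )
    if block is None or neff is None:
        return TransferCall(
            locus,
            "none",
            index_p=index_p,
            direction_consistent=consistent,
            reason="index SNP not in any LD block",
        )
    members = set(block.members)
    block_assoc = assoc.loc[assoc["SNP"].isin(members)]
    call = classify_local(
        locus, block_assoc, neff, r2_to_index, alpha=alpha, r2_min=r2_min
    )
    call.index_p = index_p
    call.direction_consistent = consistent
    return call
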