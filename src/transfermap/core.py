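"""Core data containers shared across the pipeline.

The central genotype representation is :class:`DosageMatrix`: a dense
samples × variants array of allelic dosages in [0, 2] (NaN = missing)
plus a per-variant metadata table.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2", "imputed", "imp_r2"]


class TransfermapError(Exception):
    """Base class for package errors."""


class InvalidParameterError(TransfermapError, ValueError):
    """A parameter violates its documented precondition."""


class DataFormatError(TransfermapError, ValueError):
    """An input file or table violates the expected format."""


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from a master seed.

    Stage seeds are derived by hashing the stage name (CRC32) so that
    adding a stage never perturbs the streams of existing stages.
    """
    return np.random.default_rng([int(seed), zlib.crc32(stage.encode("utf-8"))])


def make_variant_table(
    ids,
    chrom,
    pos,
    a1,
    a2,
    imputed=None,
    imp_r2=None,
) -> pd.DataFrame:
    n = len(ids)
    if imputed is None:
        imputed = np.zeros(n, dtype=bool)
    if imp_r2 is None:
        imp_r2 = np.full(n, np.nan)
    chrom = np.broadcast_to(np.asarray(chrom, dtype=object), (n,))
    tbl = pd.DataFrame(
        {
            "id": list(ids),
            "chrom": chrom,
            "pos": np.asarray(pos, dtype=np.int64),
            "a1": list(a1),
            "a2": list(a2),
            "imputed": np.asarray(imputed, dtype=bool),
            "imp_r2": np.asarray(imp_r2, dtype=float),
        }
    )
    return tbl


@dataclass
class DosageMatrix:
    """Samples × variants allelic dosages with variant metadata.

    ``dosages[i, j]`` is the expected count of allele A1 of variant ``j``
    carried by sample ``i``; values lie in [0, 2] and NaN marks missing.
    """

    dosages: np.ndarray
    sample_ids: list = field(default_factory=list)
    variants: pd.DataFrame = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise InvalidParameterError("dosages must be 2-D (samples × variants)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise InvalidParameterError(
                f"sample_ids length {len(self.sample_ids)} != {n} rows"
            )
        if self.variants is None or len(self.variants) != m:
            raise InvalidParameterError("variant table must have one row per column")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise InvalidParameterError(f"variant table missing columns: {missing}")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise InvalidParameterError("dosages must lie in [0, 2] or be NaN")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def hard_calls(self) -> np.ndarray:
        """Round dosages to the nearest genotype in {0, 1, 2}; NaN kept."""
        g = np.rint(self.dosages)
        return np.clip(g, 0, 2, out=g)

    def allele_freq(self) -> np.ndarray:
        """Per-variant A1 frequency (mean dosage / 2, missing ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=1)

    def variant_missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def take_samples(self, index) -> "DosageMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return DosageMatrix(
            self.dosages[index],
            [self.sample_ids[i] for i in index],
            self.variants.copy(),
        )

    def take_variants(self, index) -> "DosageMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return DosageMatrix(
            self.dosages[:, index],
            list(self.sample_ids),
            self.variants.iloc[index].reset_index(drop=True),
        )

    def variant_index(self, variant_id: str) -> int:
        hits = np.flatnonzero(self.variants["id"].to_numpy() == variant_id)
        if hits.size == 0:
            raise KeyError(variant_id)
        return int(hits[0])
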