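"""Replication power for a reported per-allele odds ratio.

Allelic Wald log-OR model at a one-sided alpha: the risk-allele
frequency is defined in controls, the case frequency follows from the
odds ratio, and power is the normal tail of the expected Wald statistic.
A simulation counterpart serves as the validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import InvalidParameterError, stage_rng


@dataclass
class PowerSpec:
    odds_ratio: float
    raf: float  # risk-allele frequency in controls
    n_cases: int
    n_controls: int
    alpha: float = 0.05

    def __post_init__(self):
        if self.odds_ratio <= 0:
            raise InvalidParameterError("odds ratio must be > 0")
        if not (0 < self.raf < 1):
            raise InvalidParameterError("raf must be in (0, 1)")
        if self.n_cases < 1 or self.n_controls < 1:
            raise InvalidParameterError("sample counts must be >= 1")
        if not (0 < self.alpha < 0.5):
            raise InvalidParameterError("alpha must be in (0, 0.5)")


def case_allele_freq(p0: float, odds_ratio: float) -> float:
    return p0 * odds_ratio / (1.0 + p0 * (odds_ratio - 1.0))


def power_analytic(spec: PowerSpec) -> float:
    """Normal-approximation power of the one-sided allelic Wald test.

    Var(log OR-hat) = 1/(2 n1 p1) + 1/(2 n1 (1-p1)) + 1/(2 n0 p0)
    + 1/(2 n0 (1-p0)); power = Phi(|ln OR| / sd - z_{1-alpha}).  At
    OR = 1 this is exactly alpha.
    """
    p0 = spec.raf
    p1 = case_allele_freq(p0, spec.odds_ratio)
    var = (
        1.0 / (2 * spec.n_cases * p1)
        + 1.0 / (2 * spec.n_cases * (1 - p1))
        + 1.0 / (2 * spec.n_controls * p0)
        + 1.0 / (2 * spec.n_controls * (1 - p0))
    )
    z = abs(np.log(spec.odds_ratio)) / np.sqrt(var)
    return float(stats.norm.cdf(z - stats.norm.ppf(1.0 - spec.alpha)))


def power_simulated(spec: PowerSpec, n_reps: int, seed: int) -> tuple:
    """(power estimate, Monte-Carlo SE) from simulated allele-count tables.

    Allele counts are binomial draws (2n chromosomes per arm); the
    one-sided Wald test is applied to the log odds ratio of each table,
    in the direction of the reported OR.  Zero cells get the
    Haldane-Anscombe 0.5 correction.
    """
    if n_reps < 100:
        raise InvalidParameterError("n_reps must be >= 100")
    rng = stage_rng(seed, "power-sim")
    p0 = spec.raf
    p1 = case_allele_freq(p0, spec.odds_ratio)
    a = rng.binomial(2 * spec.n_cases, p1, n_reps).astype(float)  # risk alleles, cases
    c = rng.binomial(2 * spec.n_controls, p0, n_reps).astype(float)
    b = 2 * spec.n_cases - a
    d = 2 * spec.n_controls - c
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a[zero] += 0.5
    b[zero] += 0.5
    c[zero] += 0.5
    d[zero] += 0.5
    logor = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    direction = 1.0 if spec.odds_ratio >= 1.0 else -1.0
    z = direction * logor / se
    reject = z > stats.norm.ppf(1.0 - spec.alpha)
    est = float(reject.mean())
    mc_se = float(np.sqrt(est * (1 - est) / n_reps))
    return est, mc_se


def power_grid(or_values, raf_values, n_cases: int, n_controls: int, alpha: float = 0.05) -> pd.DataFrame:
    """Analytic power on the OR x RAF Cartesian grid (long format)."""
    or_values = list(or_values)
    raf_values = list(raf_values)
    if not or_values or not raf_values:
        raise InvalidParameterError("grids must be non-empty")
    rows = [
        (o, f, power_analytic(PowerSpec(o, f, n_cases, n_controls, alpha)))
        for o in or_values
        for f in raf_values
    ]
    return pd.DataFrame(rows, columns=["OR", "RAF", "POWER"])
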