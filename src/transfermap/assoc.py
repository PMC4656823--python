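"""Dosage logistic association with covariates and genotype PCs.

Per-variant model: logit P(case) = b0 + b_d * dosage + covariates.
Fitting is plain IRLS (Newton on the log-likelihood), Wald tests on the
dosage term.  Degenerate fits (constant dosage, separation,
non-convergence) come back flagged rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import DosageMatrix, InvalidParameterError

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.454936...

MAX_ITER = 50
TOL = 1e-8


@dataclass
class AssocResult:
    variant_id: str
    a1: str
    a2: str
    a1_freq: float
    beta: float
    se: float
    p: float
    n_used: int
    code: str = "ok"  # ok | degenerate | separation | no_converge


def ld_prune(dm: DosageMatrix, window: int = 50, step: int = 5, r2_max: float = 0.2):
    """Greedy windowed LD pruning on dosage correlations.

    Within each window the later-position member of any pair with
    r^2 > ``r2_max`` is dropped; the window slides by ``step``.  Returns
    retained variant ids in input order.
    """
    if window < 2:
        raise InvalidParameterError("window must be >= 2")
    g = dm.dosages
    m = dm.n_variants
    keep = np.ones(m, dtype=bool)
    col_mean = np.nanmean(g, axis=0)
    x = np.where(np.isnan(g), col_mean[None, :], g)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    keep[sd == 0] = True  # constant columns carry no LD; leave them
    start = 0
    while start < m:
        idx = [j for j in range(start, min(start + window, m)) if keep[j] and sd[j] > 0]
        for a in range(len(idx)):
            ja = idx[a]
            if not keep[ja]:
                continue
            for b in range(a + 1, len(idx)):
                jb = idx[b]
                if not keep[jb]:
                    continue
                r = float(x[:, ja] @ x[:, jb] / (len(x) * sd[ja] * sd[jb]))
                if r * r > r2_max:
                    keep[jb] = False
        if start + window >= m:
            break
        start += step
    ids = dm.variants["id"].to_numpy()
    return [ids[j] for j in np.flatnonzero(keep)]


def genotype_pca(dm: DosageMatrix, pruned_ids=None, k: int = 3):
    """Top-k genotype principal components.

    Columns are centred at 2p and scaled by sqrt(2p(1-p)); missing
    dosages are mean-imputed.  Returns (scores (n, k), eigenvalues (k,)).
    """
    if pruned_ids is not None:
        id_to_col = {v: j for j, v in enumerate(dm.variants["id"])}
        cols = np.array([id_to_col[v] for v in pruned_ids])
        g = dm.dosages[:, cols]
    else:
        g = dm.dosages
    n, m = g.shape
    if k > min(n, m):
        raise InvalidParameterError(f"k={k} exceeds min(samples, variants)={min(n, m)}")
    p = np.nanmean(g, axis=0) / 2.0
    denom = np.sqrt(2 * p * (1 - p))
    ok = denom > 0
    x = np.where(np.isnan(g), (2 * p)[None, :], g)
    x = (x - 2 * p[None, :])[:, ok] / denom[None, ok]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eigvals = s**2 / max(n - 1, 1)
    if k > np.sum(s > s[0] * 1e-12):
        raise InvalidParameterError(f"k={k} exceeds the rank of the genotype matrix")
    return u[:, :k] * s[:k], eigvals[:k]


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def logistic_dosage_fit(
    dosage: np.ndarray,
    covariates: Optional[np.ndarray],
    status: np.ndarray,
    *,
    variant_id: str = "",
    a1: str = "",
    a2: str = "",
) -> AssocResult:
    """Wald test for the dosage term in a logistic fit by IRLS.

    Samples with missing dosage are dropped (``n_used`` records the rest).
    The Wald p is exactly 2*Phi(-|beta/se|).
    """
    dosage = np.asarray(dosage, dtype=float)
    status = np.asarray(status, dtype=float)
    ok = ~np.isnan(dosage)
    if covariates is not None and len(covariates):
        covariates = np.asarray(covariates, dtype=float)
        ok &= ~np.isnan(covariates).any(axis=1)
    d = dosage[ok]
    y = status[ok]
    n = int(ok.sum())
    freq = float(d.mean() / 2.0) if n else np.nan
    if set(np.unique(y)) - {0.0, 1.0}:
        raise InvalidParameterError("status must be binary 0/1")

    cols = [np.ones(n), d]
    if covariates is not None and len(covariates):
        cols.extend(covariates[ok].T)
    x = np.column_stack(cols)

    if n == 0 or d.std() == 0 or y.min() == y.max():
        return AssocResult(variant_id, a1, a2, freq, np.nan, np.nan, np.nan, n, "degenerate")

    def separated(eta):
        # a diverging fit that perfectly discriminates = complete separation
        return np.abs(beta).max() > 5 and np.all((eta > 0) == (y == 1))

    beta = np.zeros(x.shape[1])
    code = "no_converge"
    for _ in range(MAX_ITER):
        eta = x @ beta
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu)
        xtwx = x.T @ (x * w[:, None])
        grad = x.T @ (y - mu)
        try:
            delta = np.linalg.solve(xtwx, grad)
        except np.linalg.LinAlgError:
            flag = "separation" if separated(eta) else "degenerate"
            return AssocResult(variant_id, a1, a2, freq, np.nan, np.nan, np.nan, n, flag)
        beta = beta + delta
        if np.max(np.abs(delta)) < TOL:
            code = "ok"
            break
    if code == "no_converge" and separated(x @ beta):
        code = "separation"
    mu = _sigmoid(x @ beta)
    if code == "ok" and (np.min(mu) < 1e-10 or np.max(mu) > 1 - 1e-10) and np.abs(beta).max() > 15:
        code = "separation"
    w = mu * (1.0 - mu)
    xtwx = x.T @ (x * w[:, None])
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        return AssocResult(variant_id, a1, a2, freq, np.nan, np.nan, np.nan, n, "degenerate")
    b = float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    p = float(2.0 * stats.norm.sf(abs(b / se))) if se > 0 else np.nan
    p = max(p, np.nextafter(0, 1))
    if code != "ok":
        return AssocResult(variant_id, a1, a2, freq, b, se, p, n, code)
    return AssocResult(variant_id, a1, a2, freq, b, se, p, n)


def association_scan(
    dm: DosageMatrix,
    samples: pd.DataFrame,
    *,
    covariate_cols=("age", "sex", "bmi"),
    pcs: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-variant dosage association over the whole matrix.

    ``samples`` must align row-for-row with ``dm`` and carry ``status``;
    sex is coded female=1.  Returns a table with Table-2-style columns.
    """
    if len(samples) != dm.n_samples:
        raise InvalidParameterError("sample table must align with genotype rows")
    status = samples["status"].to_numpy(dtype=float)
    cov_list = []
    for c in covariate_cols:
        v = samples[c].to_numpy()
        if c == "sex":
            v = (v == "F").astype(float)
        cov_list.append(np.asarray(v, dtype=float))
    if pcs is not None:
        cov_list.extend(np.asarray(pcs, dtype=float).T)
    covs = np.column_stack(cov_list) if cov_list else None

    rows = []
    v = dm.variants
    for j in range(dm.n_variants):
        res = logistic_dosage_fit(
            dm.dosages[:, j],
            covs,
            status,
            variant_id=v.at[j, "id"],
            a1=v.at[j, "a1"],
            a2=v.at[j, "a2"],
        )
        rows.append(
            (
                res.variant_id,
                v.at[j, "chrom"],
                int(v.at[j, "pos"]),
                res.a1,
                res.a2,
                res.a1_freq,
                res.beta,
                res.se,
                res.p,
                res.n_used,
                res.code,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["SNP", "CHR", "BP", "A1", "A2", "A1_FREQ", "BETA", "SE", "P", "N", "CODE"],
    )


def genomic_inflation(chisq) -> float:
    """lambda_GC: median association chi-square over the chi2(1) median."""
    chisq = np.asarray(chisq, dtype=float)
    chisq = chisq[~np.isnan(chisq)]
    if chisq.size == 0:
        raise InvalidParameterError("no statistics supplied")
    if chisq.size < 100:
        import warnings

        warnings.warn("genomic_inflation computed from fewer than 100 statistics")
    return float(np.median(chisq) / CHI2_1_MEDIAN)
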