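"""Inverse-variance-weighted fixed-effects meta-analysis with Cochran's Q.

The fixed-effects model assumes a single allelic log-OR shared by every
study; each study contributes with weight 1/SE^2.  Cochran's Q tests that
homogeneity assumption against a chi-square with (k - 1) degrees of freedom.
Genome-wide significance for the pooled test is the conventional
P < 5e-8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm

from .assoc import AssocResult
from .exceptions import ArgumentError

GENOME_WIDE_P = 5e-8


@dataclass(frozen=True)
class FixedMetaResult:
    snpid: str
    beta: float
    se: float
    z: float
    p: float
    or_: float
    ci_low: float
    ci_high: float
    q: float
    q_df: int
    q_p: float
    n_studies: int


def _converged(results: list[AssocResult]) -> list[AssocResult]:
    return [r for r in results if r.converged and np.isfinite(r.se) and r.se > 0]


def ivw_combine(results: list[AssocResult]) -> FixedMetaResult:
    """Pool per-study effects under inverse-variance weighting.

    beta = sum(w_s * beta_s) / sum(w_s) with w_s = 1/SE_s^2;
    SE = (sum w_s)^(-1/2); the 95% CI for the OR is exp(beta +- 1.96 SE).
    Non-converged studies are dropped; an empty input is an error.
    """
    usable = _converged(results)
    if not usable:
        raise ArgumentError("ivw_combine requires at least one converged result")
    betas = np.array([r.beta for r in usable])
    ses = np.array([r.se for r in usable])
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    z = beta / se
    p = float(2.0 * norm.sf(abs(z)))
    p = max(p, np.finfo(float).tiny)
    q, q_df, q_p = cochran_q(usable, beta)
    return FixedMetaResult(
        snpid=usable[0].snpid,
        beta=beta,
        se=se,
        z=float(z),
        p=p,
        or_=math.exp(beta),
        ci_low=math.exp(beta - 1.96 * se),
        ci_high=math.exp(beta + 1.96 * se),
        q=q,
        q_df=q_df,
        q_p=q_p,
        n_studies=len(usable),
    )


def cochran_q(results: list[AssocResult], pooled_beta: float) -> tuple[float, int, float]:
    """Cochran's heterogeneity statistic Q = sum w_s (beta_s - pooled)^2.

    P-value from chi-square with k-1 degrees of freedom; a single study
    yields (0, 0, 1) by convention.
    """
    usable = _converged(results)
    k = len(usable)
    if k <= 1:
        return 0.0, 0, 1.0
    betas = np.array([r.beta for r in usable])
    w = 1.0 / np.array([r.se for r in usable]) ** 2
    q = float(np.sum(w * (betas - pooled_beta) ** 2))
    df = k - 1
    return q, df, float(chi2.sf(q, df))


def write_meta_tsv(results: list[FixedMetaResult], path) -> None:
    """Emit the fixed-effects meta-analysis table as TSV."""
    import pandas as pd

    rows = [
        {
            "SNPID": r.snpid, "BETA": r.beta, "SE": r.se, "OR": r.or_,
            "CI_L": r.ci_low, "CI_U": r.ci_high, "P": r.p,
            "Q": r.q, "Q_DF": r.q_df, "Q_P": r.q_p, "N_STUDIES": r.n_studies,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
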