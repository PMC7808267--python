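"""Global and pairwise comparison of adaptive treatment strategies.

The global Wald test of H0: θ_1 = … = θ_G uses

    Q = (CΘ̂)ᵀ (CΣ̂Cᵀ)⁻ (CΘ̂),

with C = (1 | −I) and the Moore–Penrose generalized inverse: the contrast
covariance is singular by construction whenever overlapping strategies
impose exact linear constraints on Θ̂ (for a full-factorial binary-response
arm, θ̂_00 − θ̂_01 − θ̂_10 + θ̂_11 = 0 identically), so the reference
degrees of freedom come from the design, not from G−1.  Under H0, Q is
asymptotically central chi-squared with those df.

Pairwise comparisons report all G(G−1)/2 differences with simultaneous
confidence intervals; Bonferroni adjustment widens the critical quantile
to z_{1−α/(2 n_p)} while the reported p-values stay unadjusted (the
caller thresholds them against α/n_p).  The global test is intended as a
gate-keeper: strategy selection proceeds only if it rejects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import SmartDesign, test_df
from .estimation import AtsEstimates, estimate_gcomp, estimate_ipw
from .sizing import contrast_matrix

logger = logging.getLogger(__name__)

__all__ = ["GlobalTestResult", "PairwiseResult", "SmartReport",
           "global_test", "pairwise_comparisons", "smartest"]

_RANK_RTOL = 1e-8


@dataclass
class GlobalTestResult:
    n_total: int
    G: int
    df: int
    statistic: float
    p_value: float
    rank: int  # numerical rank of the contrast covariance, logged if != df

    def to_dict(self) -> dict:
        return {
            "N": self.n_total,
            "ATS": self.G,
            "df": self.df,
            "Q": self.statistic,
            "p_value": self.p_value,
        }


@dataclass
class PairwiseResult:
    table: pd.DataFrame
    n_p: int
    delta_jk: float
    alpha: float
    adjust: str

    def to_dict(self) -> dict:
        return {
            "n_p": self.n_p,
            "critical_quantile": self.delta_jk,
            "comparisons": self.table.to_dict(orient="records"),
        }


@dataclass
class SmartReport:
    """The three analysis blocks: strategy listing, global test, pairwise
    comparisons."""

    strategy: pd.DataFrame
    global_test: GlobalTestResult
    pairwise: PairwiseResult
    estimates: AtsEstimates = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "Strategy": self.strategy.to_dict(orient="records"),
            "Global.test": self.global_test.to_dict(),
            "Pairwise.comparisons": self.pairwise.to_dict(),
        }


def global_test(estimates: AtsEstimates, design: SmartDesign | None = None,
                ) -> GlobalTestResult:
    """Generalized-inverse Wald test that all strategy values are equal.

    ``estimates.cov`` is on the estimator scale (already divided by n), so
    Q needs no further sample-size factor.  df is taken from the design
    structure; if the numerical rank of CΣ̂Cᵀ differs (degenerate data) a
    warning is logged and both are reported.
    """
    design = design or estimates.design
    G = estimates.G
    if G < 2:
        raise ValueError("global test needs at least two strategies")
    cov = estimates.cov
    if not np.any(cov):
        raise ValueError("covariance matrix is identically zero")
    if np.isnan(cov).any():
        raise ValueError(
            "covariance matrix contains missing values (a sequence with a "
            "single record?); re-estimate with common=True"
        )
    C = contrast_matrix(G)
    M = C @ cov @ C.T
    ctheta = C @ estimates.values
    sv = np.linalg.svd(M, compute_uv=False)
    rank = int(np.sum(sv > _RANK_RTOL * sv[0]))
    df = test_df(design)
    if rank != df:
        logger.warning(
            "numerical rank of contrast covariance (%d) differs from "
            "design df (%d); using design df for the reference distribution",
            rank, df,
        )
    Q = float(ctheta @ np.linalg.pinv(M, rcond=_RANK_RTOL) @ ctheta)
    p = float(stats.chi2.sf(Q, df))
    return GlobalTestResult(n_total=estimates.n, G=G, df=df,
                            statistic=Q, p_value=p, rank=rank)


def pairwise_comparisons(
    estimates: AtsEstimates,
    alpha: float = 0.05,
    adjust: str = "bon",
    ntest: int | None = None,
) -> PairwiseResult:
    """All pairwise strategy contrasts with simultaneous confidence
    intervals.

    With ``adjust="bon"`` the CI quantile is z_{1−α/(2 n_p)} where
    n_p = ``ntest`` if given, else G(G−1)/2; with ``adjust="none"`` it is
    the unadjusted z_{1−α/2}.  p-values are two-sided unadjusted normal
    tails in both cases.
    """
    if adjust not in ("bon", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    G = estimates.G
    if G < 2:
        raise ValueError("pairwise comparison needs at least two strategies")
    theta = estimates.values
    cov = estimates.cov
    n_pairs = G * (G - 1) // 2
    n_p = ntest if ntest is not None else n_pairs
    if adjust == "bon":
        delta_jk = float(stats.norm.ppf(1.0 - alpha / (2.0 * n_p)))
    else:
        delta_jk = float(stats.norm.ppf(1.0 - alpha / 2.0))
    rows = []
    for j in range(G):
        for k in range(j + 1, G):
            diff = theta[j] - theta[k]
            var = cov[j, j] + cov[k, k] - 2.0 * cov[j, k]
            se = np.sqrt(max(var, 0.0))
            if se == 0.0:
                if diff != 0.0:
                    raise ValueError(
                        f"zero standard error with nonzero difference for "
                        f"pair ({j + 1},{k + 1})"
                    )
                z = 0.0
            else:
                z = diff / se
            rows.append(
                {
                    "pair": f"{j + 1}-{k + 1}",
                    "diff": diff,
                    "ci_low": diff - delta_jk * se,
                    "ci_high": diff + delta_jk * se,
                    "Z": z,
                    "p_value": 2.0 * float(stats.norm.sf(abs(z))),
                }
            )
    return PairwiseResult(table=pd.DataFrame(rows), n_p=n_p,
                          delta_jk=delta_jk, alpha=alpha, adjust=adjust)


def smartest(
    data: pd.DataFrame,
    design: SmartDesign,
    method: str = "gcomp",
    common: bool = False,
    alpha: float = 0.05,
    adjust: str = "bon",
    ntest: int | None = None,
    family: str = "gaussian",
    probs: str = "design",
) -> SmartReport:
    """Full comparison report: strategy listing, gate-keeping global test,
    and pairwise table.

    Pairwise selection is meaningful only when the global test rejects at
    level ``alpha``; the report always includes all blocks and leaves the
    gate-keeping decision to the reader.
    """
    if method == "gcomp":
        est = estimate_gcomp(data, design, family=family, common=common,
                             alpha=alpha)
    elif method == "ipw":
        est = estimate_ipw(data, design, probs=probs, family=family,
                           alpha=alpha)
    else:
        raise ValueError(f"unknown method {method!r}")
    gt = global_test(est, design)
    pw = pairwise_comparisons(est, alpha=alpha, adjust=adjust, ntest=ntest)
    strat_cols = [c for c in est.table.columns
                  if c in ("ATS", "d0") or c.startswith("d0") or c == "N"]
    return SmartReport(strategy=est.table[strat_cols].copy(),
                       global_test=gt, pairwise=pw, estimates=est)
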