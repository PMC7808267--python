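"""Power and sample-size machinery for the global and pairwise SMART tests.

The global route sizes the trial through a noncentral chi-squared power
equation: find the noncentrality λ* at which a chi-squared test with the
design's df rejects with probability 1−β at level α, compute the
standardized overall effect size Δ = (CΘ*)ᵀ(CΣ*Cᵀ)⁻(CΘ*) from the
design-stage strategy values and their per-subject covariance, and take
n = ⌈λ*/Δ⌉.  The pairwise route is the classic two-independent-sample
normal-approximation formula on a standardized difference d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    SmartDesign,
    Strategy,
    enumerate_strategies,
    parse_design,
    test_df,
)

__all__ = [
    "DesignMoments",
    "SizingResult",
    "get_ncp",
    "design_moments",
    "effect_size",
    "smartsize",
    "contrast_matrix",
]


def contrast_matrix(G: int) -> np.ndarray:
    """The (G−1)×G contrast C = (1 | −I) comparing every strategy with the
    first.  Any full-rank contrast gives the same Wald statistic and effect
    size through the generalized inverse."""
    return np.hstack([np.ones((G - 1, 1)), -np.eye(G - 1)])


@dataclass
class DesignMoments:
    """Design-stage targeted strategy values Θ* and the per-subject-scaled
    covariance Σ* of their estimator (i.e. n·Cov(Θ̂)), aligned with
    :func:`~smartats.design.enumerate_strategies` order."""

    theta_star: np.ndarray
    sigma_star: np.ndarray
    strategies: list[Strategy]
    design: SmartDesign

    @property
    def G(self) -> int:
        return len(self.theta_star)


@dataclass
class SizingResult:
    """Output of :func:`smartsize`; ``n_total`` on the global path,
    ``n_per_ats`` on the pairwise path."""

    alpha: float
    beta: float
    delta: float
    df: int | None = None
    ncp: float | None = None
    n_total: int | None = None
    n_per_ats: int | None = None

    def to_dict(self) -> dict:
        if self.n_total is not None:
            return {
                "NCP": self.ncp,
                "delta": self.delta,
                "df": self.df,
                "N": self.n_total,
            }
        return {"delta": self.delta, "n_per_ats": self.n_per_ats}


def get_ncp(
    df: int,
    alpha: float = 0.05,
    beta: float = 0.20,
    d: float = 1e-4,
    start: float = 5.0,
    max_iter: int = 200,
) -> float:
    """Noncentrality parameter λ* of the chi-squared global test under the
    alternative: the λ at which a noncentral χ²_df(λ) exceeds the central
    upper-α critical value with probability 1−β.

    The attained type-II error β(λ) = P(χ²_df(λ) ≤ χ²_{df,1−α}) is
    strictly decreasing in λ; a monotone upward search accepts the first
    λ whose type-II error is within ``d`` of the target β.  We return the
    infimum of that acceptance set — the root of β(λ) − β = d — located
    by an expanding bracket from ``start`` followed by bisection, so the
    result does not depend on ``start``.  A smaller ``d`` sharpens the
    answer toward the exact power equation's root.
    """
    if not (0.0 < alpha < 1.0 and 0.0 < beta < 1.0):
        raise ValueError("alpha and beta must lie in (0,1)")
    if d <= 0:
        raise ValueError("tolerance d must be positive")
    if df < 1:
        raise ValueError("df must be a positive integer")
    q = stats.chi2.ppf(1.0 - alpha, df)

    def gap(lam: float) -> float:
        # attained type-II error minus (beta + d); zero at the first
        # lambda an upward search would accept
        return stats.ncx2.cdf(q, df, lam) - (beta + d)

    if gap(0.0) <= 0.0:
        return 0.0
    lo, hi = 0.0, max(float(start), 1.0)
    it = 0
    while gap(hi) > 0:
        lo, hi = hi, hi * 2.0
        it += 1
        if it > max_iter:
            raise RuntimeError(
                f"ncp search did not bracket a root; last bracket ({lo},{hi})"
            )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if hi - lo < 1e-12 * max(1.0, hi):
            return mid
        if gap(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sim_lookup(sim: pd.DataFrame):
    """Index SIM rows by sequence (a1, o2, a2)."""
    means, sds, p2 = {}, {}, {}
    for _, row in sim.iterrows():
        key = (int(row["A1"]), int(row["O2"]), int(row["A2"]))
        means[key] = float(row["MEAN"])
        sds[key] = float(row["SD"])
        p2[(int(row["A1"]), int(row["O2"]))] = float(row["P2"])
    return means, sds, p2


def design_moments(
    sim: pd.DataFrame,
    method: str = "gcomp",
    family: str = "gaussian",
) -> DesignMoments:
    """Targeted strategy values Θ* and per-subject covariance Σ* from a
    sequence information matrix.

    Θ*_g = Σ_r P2(a1,r)·MEAN(a1,r,a2_g(r)).  For ``method="gcomp"`` the
    covariance is the delta-method form of the G-computation estimator
    (sequence-mean variability plus multinomial response-rate
    variability); for ``method="ipw"`` it is the influence-function
    variance of the inverse-probability-weighted estimator.  Both are
    block-diagonal across stage-1 arms, since strategies starting with
    different treatments share no patients.

    For ``family="binomial"`` the sequence variance is MEAN·(1−MEAN);
    the SD column is ignored.
    """
    if method not in ("gcomp", "ipw"):
        raise ValueError(f"unknown method {method!r}")
    if family not in ("gaussian", "binomial"):
        raise ValueError(f"unknown family {family!r}")
    design = parse_design(sim)
    strategies = enumerate_strategies(design)
    means, sds, p2 = _sim_lookup(sim)
    if family == "binomial":
        for key, m in means.items():
            if not (0.0 < m < 1.0):
                raise ValueError(f"binomial MEAN must lie in (0,1); got {m} at {key}")
        var = {key: m * (1.0 - m) for key, m in means.items()}
    else:
        var = {key: sds[key] ** 2 for key in sds}

    G = len(strategies)
    theta = np.zeros(G)
    for g, s in enumerate(strategies):
        theta[g] = sum(
            p2[(s.a1, r)] * means[(s.a1, r, s.rules[r])]
            for r in range(design.n_categories(s.a1))
        )

    sigma = np.zeros((G, G))
    for i, si in enumerate(strategies):
        for j, sj in enumerate(strategies):
            if sj.a1 != si.a1 or j < i:
                continue
            a1 = si.a1
            ncat = design.n_categories(a1)
            pi1 = design.pi1[a1]
            v = 0.0
            if method == "gcomp":
                for r in range(ncat):
                    if si.rules[r] == sj.rules[r]:
                        seq = (a1, r, si.rules[r])
                        q = pi1 * p2[(a1, r)] * design.pi2[seq]
                        if q <= 0:
                            raise ValueError(f"unreachable sequence {seq}")
                        v += p2[(a1, r)] ** 2 * var[seq] / q
                for r in range(ncat):
                    for rp in range(ncat):
                        covp = p2[(a1, r)] * ((r == rp) - p2[(a1, rp)]) / pi1
                        v += (
                            means[(a1, r, si.rules[r])]
                            * means[(a1, rp, sj.rules[rp])]
                            * covp
                        )
            else:  # ipw: E[w^2 IF_i IF_j], nonzero only on shared sequences
                for r in range(ncat):
                    if si.rules[r] != sj.rules[r]:
                        continue
                    seq = (a1, r, si.rules[r])
                    q = pi1 * p2[(a1, r)] * design.pi2[seq]
                    if q <= 0:
                        raise ValueError(f"unreachable sequence {seq}")
                    w = 1.0 / (pi1 * design.pi2[seq])
                    resid = (means[seq] - theta[i]) * (means[seq] - theta[j])
                    v += q * w**2 * (var[seq] + resid)
            sigma[i, j] = sigma[j, i] = v
    return DesignMoments(theta_star=theta, sigma_star=sigma,
                         strategies=strategies, design=design)


def effect_size(moments: DesignMoments) -> float:
    """Standardized overall effect size
    Δ = (CΘ*)ᵀ(CΣ*Cᵀ)⁻(CΘ*), using the Moore–Penrose generalized inverse
    (the contrast covariance is singular by construction whenever the df
    is below G−1).  Invariant to the choice of reference strategy and to
    adding a constant to all sequence means."""
    C = contrast_matrix(moments.G)
    ctheta = C @ moments.theta_star
    if np.allclose(ctheta, 0.0):
        raise ValueError("null design: strategies have equal values")
    M = C @ moments.sigma_star @ C.T
    return float(ctheta @ np.linalg.pinv(M, rcond=1e-10) @ ctheta)


def smartsize(
    global_: bool = True,
    alpha: float = 0.05,
    beta: float = 0.20,
    delta: float | None = None,
    df: int | None = None,
    sim: pd.DataFrame | None = None,
    family: str = "gaussian",
    method: str = "gcomp",
    ntest: int | None = None,
) -> SizingResult:
    """Sample size for a two-stage SMART.

    Global path (``global_=True``): supply either (``delta``, ``df``) or a
    SIM table from which both are derived; returns the total trial size
    ``n_total = ceil(λ*/Δ)``.

    Pairwise path: supply the standardized difference ``delta`` between the
    two strategies of interest; returns the per-strategy size
    ``n_per_ats = ceil(2·(z_{1−α/2}+z_{1−β})²/d²)``, the classic two-arm
    formula.  ``ntest`` optionally Bonferroni-adjusts α to α/ntest.
    """
    if not (0.0 < alpha < 1.0 and 0.0 < beta < 1.0):
        raise ValueError("alpha and beta must lie in (0,1)")
    if global_:
        if sim is not None:
            moments = design_moments(sim, method=method, family=family)
            if df is None:
                df = test_df(moments.design)
            if delta is None:
                delta = effect_size(moments)
        if delta is None or df is None:
            raise ValueError(
                "global sizing needs either a SIM table or both delta and df"
            )
        if delta <= 0:
            raise ValueError("effect size delta must be positive")
        ncp = get_ncp(df, alpha=alpha, beta=beta)
        n_total = math.ceil(ncp / delta)
        return SizingResult(alpha=alpha, beta=beta, delta=delta, df=df,
                            ncp=ncp, n_total=n_total)
    if delta is None or delta <= 0:
        raise ValueError("pairwise sizing needs a positive standardized difference")
    a_eff = alpha / ntest if ntest else alpha
    za = stats.norm.ppf(1.0 - a_eff / 2.0)
    zb = stats.norm.ppf(1.0 - beta)
    n = math.ceil(2.0 * (za + zb) ** 2 / delta**2)
    return SizingResult(alpha=alpha, beta=beta, delta=delta, n_per_ats=n)
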