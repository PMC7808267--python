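"""Sequence-level summaries and strategy-value estimation.

Two estimators of the value θ_g = E[Y | follow strategy g] are provided.

G-computation combines the per-sequence outcome means with the empirical
response-category proportions of the arm:

    θ̂_g = Σ_r p̂_r(a1) · Ȳ(a1, r, a2_g(r)).

Inverse-probability weighting (IPW) averages the outcomes of patients
whose observed path is consistent with the strategy, each weighted by the
reciprocal product of their randomization probabilities:

    θ̂_g = Σ_i 1{consistent} w_i Y_i / Σ_i 1{consistent} w_i.

Because one patient's sequence is consistent with every strategy that
agrees on the observed path, estimates of overlapping strategies are
correlated; the covariance matrix Σ̂ is block-diagonal across stage-1
arms (strategies starting with different treatments share no patients).
For G-computation Σ̂ is the plug-in delta-method form; for IPW it comes
from the empirical cross-products of influence functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import SmartDesign, Strategy, enumerate_strategies, test_df

logger = logging.getLogger(__name__)

__all__ = ["AtsEstimates", "seqmeans", "estimate_gcomp", "estimate_ipw"]

REQUIRED_DATA_COLUMNS = ["A1", "O2", "A2", "Y"]


class EstimationError(ValueError):
    """Raised when the data cannot support the requested estimate."""


@dataclass
class AtsEstimates:
    """Strategy-value estimates with covariance.

    ``table`` has one row per strategy — indicator ``ATS`` (1-based),
    decision-rule columns ``d0`` (stage-1) and ``d0r`` per response
    category, ``N`` (patients consistent with the strategy; a patient may
    count under several strategies), ``value``, ``se``, ``ci_low``,
    ``ci_high``.  ``cov`` is the G×G estimated covariance of the values
    (estimator scale, i.e. already divided by n).
    """

    table: pd.DataFrame
    cov: np.ndarray
    strategies: list[Strategy]
    design: SmartDesign
    n: int
    alpha: float
    method: str

    @property
    def values(self) -> np.ndarray:
        return self.table["value"].to_numpy()

    @property
    def G(self) -> int:
        return len(self.strategies)


def _check_data(data: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_DATA_COLUMNS if c not in data.columns]
    if missing:
        raise EstimationError(f"data is missing required columns: {missing}")
    if len(data) == 0:
        raise EstimationError("no records")
    return data


def seqmeans(
    data: pd.DataFrame,
    design: SmartDesign | None = None,
    family: str = "gaussian",
    digits: int | None = None,
) -> pd.DataFrame:
    """Descriptive statistics per treatment sequence.

    Returns one row per sequence (observed, plus any design-declared
    sequence even if unobserved) with columns
    ``SEQ, A1, O2, A2, N, MEAN, VAR, SD``.  For the gaussian family VAR is
    the n−1 sample variance; for the binomial family MEAN is the response
    proportion and VAR = MEAN·(1−MEAN).  ``digits`` rounds the returned
    display values only; computation is never rounded.
    """
    _check_data(data)
    if family not in ("gaussian", "binomial"):
        raise ValueError(f"unknown family {family!r}")
    keys = (
        design.sequences()
        if design is not None
        else sorted(
            (int(a1), int(o2), int(a2))
            for (a1, o2, a2) in data.groupby(["A1", "O2", "A2"]).groups
        )
    )
    grouped = data.groupby(["A1", "O2", "A2"])["Y"]
    rows = []
    for i, key in enumerate(keys, start=1):
        if key in grouped.groups:
            y = grouped.get_group(key).to_numpy(dtype=float)
            n = len(y)
            mean = float(np.mean(y))
            if family == "binomial":
                var = mean * (1.0 - mean)
            else:
                var = float(np.var(y, ddof=1)) if n > 1 else np.nan
            if n == 1 and family == "gaussian":
                logger.warning("sequence %s has a single record; VAR undefined", key)
        else:
            n, mean, var = 0, np.nan, np.nan
            logger.warning("sequence %s declared by the design has no records", key)
        rows.append(
            {
                "SEQ": i,
                "A1": key[0],
                "O2": key[1],
                "A2": key[2],
                "N": n,
                "MEAN": mean,
                "VAR": var,
                "SD": np.sqrt(var) if var == var else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    if digits is not None:
        for c in ("MEAN", "VAR", "SD"):
            out[c] = out[c].round(digits)
    return out


def _strategy_table(
    strategies: list[Strategy],
    design: SmartDesign,
    data: pd.DataFrame,
) -> pd.DataFrame:
    """Strategy listing with per-strategy consistent-patient counts."""
    a1 = data["A1"].to_numpy()
    o2 = data["O2"].to_numpy()
    a2 = data["A2"].to_numpy()
    rows = []
    for g, s in enumerate(strategies, start=1):
        rule = np.array([s.rules[r] for r in range(design.n_categories(s.a1))])
        cons = (a1 == s.a1) & (a2 == rule[o2])
        row = {"ATS": g, "d0": s.a1}
        for r, a in enumerate(s.rules):
            row[f"d0{r}"] = a
        row["N"] = int(cons.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def _pooled_variance(stats_by_seq: dict, family: str, data: pd.DataFrame) -> float:
    if family == "binomial":
        p = float(data["Y"].mean())
        return p * (1.0 - p)
    num = sum((n - 1) * v for (n, _, v) in stats_by_seq.values() if n > 1)
    den = sum(n - 1 for (n, _, _) in stats_by_seq.values() if n > 1)
    if den <= 0:
        logger.warning("pooled variance undefined: no sequence has n >= 2")
        return np.nan
    return num / den


def estimate_gcomp(
    data: pd.DataFrame,
    design: SmartDesign,
    family: str = "gaussian",
    common: bool = False,
    alpha: float = 0.05,
) -> AtsEstimates:
    """G-computation strategy values with delta-method covariance.

    ``common=True`` pools the outcome variance across all sequences of the
    trial (pooled proportion for the binomial family); otherwise each
    sequence keeps its own sample variance.  Confidence intervals use
    normal quantiles at level 1−``alpha``.
    """
    _check_data(data)
    strategies = enumerate_strategies(design)
    n_total = len(data)

    # per-sequence n, mean, variance and per-arm response proportions
    seq_stats: dict[tuple[int, int, int], tuple[int, float, float]] = {}
    for key, y in data.groupby(["A1", "O2", "A2"])["Y"]:
        arr = y.to_numpy(dtype=float)
        m = float(arr.mean())
        if family == "binomial":
            v = m * (1.0 - m)
        else:
            v = float(arr.var(ddof=1)) if len(arr) > 1 else np.nan
        seq_stats[(int(key[0]), int(key[1]), int(key[2]))] = (len(arr), m, v)

    n_arm = {a1: int((data["A1"] == a1).sum()) for a1 in design.stage1_arms}
    p_hat: dict[tuple[int, int], float] = {}
    for a1 in design.stage1_arms:
        if n_arm[a1] < 2:
            raise EstimationError(f"arm {a1} has fewer than 2 records")
        arm = data[data["A1"] == a1]
        for r in range(design.n_categories(a1)):
            p_hat[(a1, r)] = float((arm["O2"] == r).sum()) / n_arm[a1]

    pooled = _pooled_variance(seq_stats, family, data) if common else None

    def seq_var(key):
        if common:
            return pooled
        v = seq_stats[key][2]
        if v != v:  # single record: variance missing, propagated as NaN se
            logger.warning(
                "sequence %s has one record; its variance (and dependent "
                "standard errors) are reported missing", key,
            )
        return v

    G = len(strategies)
    theta = np.zeros(G)
    for g, s in enumerate(strategies):
        val = 0.0
        for r in range(design.n_categories(s.a1)):
            key = (s.a1, r, s.rules[r])
            if key not in seq_stats:
                raise EstimationError(
                    f"strategy {s.code} requires empty sequence {key}"
                )
            val += p_hat[(s.a1, r)] * seq_stats[key][1]
        theta[g] = val

    cov = np.zeros((G, G))
    for i, si in enumerate(strategies):
        for j in range(i, G):
            sj = strategies[j]
            if sj.a1 != si.a1:
                continue
            a1 = si.a1
            v = 0.0
            for r in range(design.n_categories(a1)):
                if si.rules[r] == sj.rules[r]:
                    key = (a1, r, si.rules[r])
                    n_seq = seq_stats[key][0]
                    v += p_hat[(a1, r)] ** 2 * seq_var(key) / n_seq
            for r in range(design.n_categories(a1)):
                for rp in range(design.n_categories(a1)):
                    covp = (
                        p_hat[(a1, r)] * ((r == rp) - p_hat[(a1, rp)]) / n_arm[a1]
                    )
                    v += (
                        seq_stats[(a1, r, si.rules[r])][1]
                        * seq_stats[(a1, rp, sj.rules[rp])][1]
                        * covp
                    )
            cov[i, j] = cov[j, i] = v

    table = _strategy_table(strategies, design, data)
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    table["value"] = theta
    table["se"] = se
    table["ci_low"] = theta - z * se
    table["ci_high"] = theta + z * se
    return AtsEstimates(
        table=table, cov=cov, strategies=strategies, design=design,
        n=n_total, alpha=alpha, method="gcomp",
    )


def estimate_ipw(
    data: pd.DataFrame,
    design: SmartDesign,
    probs: str = "design",
    family: str = "gaussian",
    alpha: float = 0.05,
) -> AtsEstimates:
    """Inverse-probability-weighted strategy values.

    ``probs="design"`` uses the known randomization probabilities;
    ``probs="empirical"`` replaces them with observed assignment
    frequencies.  The covariance is assembled from the empirical
    cross-products of the per-patient influence functions

        IF_i(g) = 1{consistent} · w_i · (Y_i − θ̂_g) / mean(1{consistent}·w),

    divided by n; strategies in different arms have disjoint consistent
    sets, so Σ̂ is exactly block-diagonal.
    """
    _check_data(data)
    if probs not in ("design", "empirical"):
        raise ValueError(f"unknown probs mode {probs!r}")
    strategies = enumerate_strategies(design)
    n = len(data)
    a1 = data["A1"].to_numpy()
    o2 = data["O2"].to_numpy()
    a2 = data["A2"].to_numpy()
    y = data["Y"].to_numpy(dtype=float)

    if probs == "design":
        pi1 = {a: design.pi1[a] for a in design.stage1_arms}
        pi2 = dict(design.pi2)
    else:
        pi1 = {a: float((a1 == a).sum()) / n for a in design.stage1_arms}
        pi2 = {}
        for (arm, r), opts in design.stage2_options.items():
            mask = (a1 == arm) & (o2 == r)
            m = int(mask.sum())
            for opt in opts:
                pi2[(arm, r, opt)] = (
                    float(((a2 == opt) & mask).sum()) / m if m else np.nan
                )

    w = np.empty(n)
    for i in range(n):
        key = (int(a1[i]), int(o2[i]), int(a2[i]))
        denom = pi1[key[0]] * pi2[key]
        if not denom > 0:
            raise EstimationError(f"non-positive probability for sequence {key}")
        w[i] = 1.0 / denom

    G = len(strategies)
    theta = np.zeros(G)
    IF = np.zeros((n, G))
    for g, s in enumerate(strategies):
        rule = np.array([s.rules[r] for r in range(design.n_categories(s.a1))])
        cons = (a1 == s.a1) & (a2 == rule[o2])
        total_w = float((w * cons).sum())
        if total_w <= 0:
            raise EstimationError(f"zero total weight for strategy {s.code}")
        theta[g] = float((w * cons * y).sum()) / total_w
        IF[:, g] = cons * w * (y - theta[g]) / (total_w / n)
    cov = (IF.T @ IF) / n**2

    table = _strategy_table(strategies, design, data)
    se = np.sqrt(np.diag(cov))
    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    table["value"] = theta
    table["se"] = se
    table["ci_low"] = theta - zq * se
    table["ci_high"] = theta + zq * se
    return AtsEstimates(
        table=table, cov=cov, strategies=strategies, design=design,
        n=n, alpha=alpha, method="ipw",
    )
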