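"""Seeded SMART trial simulation and Monte Carlo operating characteristics.

A trial is generated directly from a sequence information matrix (SIM):
for each patient, the stage-1 arm A1 is categorical with the stage-1
randomization probabilities, the intermediate response O2 is categorical
with the arm's response rates, the stage-2 treatment A2 is categorical
with the branch's randomization probabilities (probability one in a
degenerate branch), and the outcome Y is Normal(MEAN, SD) for the
gaussian family or Bernoulli(MEAN) for the binomial family.  Draws are
made column-by-column in the fixed order (A1, O2, A2, Y) from a single
``numpy.random.default_rng`` stream, so a fixed seed reproduces the
dataset exactly.

The module also ships a fixed synthetic depression-management trial
(:func:`make_codiacs_like`) emulating the structure of the stepped-care
SMART analyzed in the package's worked examples — two stage-1 arms
(medication vs problem-solving therapy, coded 0/1), a binary response
defined by early symptom reduction, re-randomization between the same
two options, and a continuous outcome (depression-score reduction at six
months) — for demonstrations and tests.  It is synthetic data, not the
deposited trial.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import SIM_COLUMNS, parse_design
from .estimation import estimate_gcomp, estimate_ipw
from .inference import global_test, pairwise_comparisons

__all__ = [
    "simulate_trial",
    "operating_characteristics",
    "make_codiacs_like",
    "codiacs_like_sim",
]


def simulate_trial(
    sim: pd.DataFrame,
    n: int,
    seed: int | np.random.Generator | None = None,
    family: str = "gaussian",
) -> pd.DataFrame:
    """Simulate ``n`` completed patients from a SIM.

    Returns a data frame with columns ``A1, O2, A2, Y`` (one row per
    patient).  ``seed`` may be an integer or an existing Generator (the
    latter lets a caller chain replicates off one stream).
    """
    if n < 1:
        raise ValueError("n must be positive")
    if family not in ("gaussian", "binomial"):
        raise ValueError(f"unknown family {family!r}")
    design = parse_design(sim)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    arms = np.array(design.stage1_arms)
    p1 = np.array([design.pi1[a] for a in arms])
    a1 = arms[rng.choice(len(arms), size=n, p=p1)]

    # response-rate table from the SIM
    p2 = {}
    for _, row in sim.iterrows():
        p2[(int(row["A1"]), int(row["O2"]))] = float(row["P2"])
    o2 = np.empty(n, dtype=int)
    for a in arms:
        mask = a1 == a
        ncat = design.n_categories(a)
        probs = np.array([p2[(a, r)] for r in range(ncat)])
        o2[mask] = rng.choice(ncat, size=int(mask.sum()), p=probs)

    a2 = np.empty(n, dtype=int)
    for a in arms:
        for r in range(design.n_categories(a)):
            mask = (a1 == a) & (o2 == r)
            m = int(mask.sum())
            if m == 0:
                continue
            opts = np.array(design.options(a, r))
            probs = np.array([design.pi2[(a, r, opt)] for opt in opts])
            a2[mask] = opts[rng.choice(len(opts), size=m, p=probs)]

    mean = np.empty(n)
    sd = np.empty(n)
    lut_mean = {}
    lut_sd = {}
    for _, row in sim.iterrows():
        key = (int(row["A1"]), int(row["O2"]), int(row["A2"]))
        lut_mean[key] = float(row["MEAN"])
        lut_sd[key] = float(row["SD"])
    for key, mu in lut_mean.items():
        mask = (a1 == key[0]) & (o2 == key[1]) & (a2 == key[2])
        mean[mask] = mu
        sd[mask] = lut_sd[key]
    if family == "gaussian":
        y = rng.normal(mean, sd)
    else:
        y = rng.binomial(1, mean).astype(float)
    return pd.DataFrame({"A1": a1, "O2": o2, "A2": a2, "Y": y})


def operating_characteristics(
    sim: pd.DataFrame,
    n: int,
    reps: int,
    alpha: float = 0.05,
    analysis: str = "global",
    method: str = "gcomp",
    family: str = "gaussian",
    seed: int | None = None,
) -> dict:
    """Monte Carlo rejection rate of the chosen analysis.

    ``analysis="global"`` counts replicates in which the generalized-
    inverse Wald test rejects at level ``alpha``; ``analysis="pairwise"``
    counts replicates in which any Bonferroni-adjusted pairwise test
    rejects.  Returns the empirical power and its binomial standard
    error.
    """
    if reps < 100:
        raise ValueError("reps must be at least 100 for a stable estimate")
    if analysis not in ("global", "pairwise"):
        raise ValueError(f"unknown analysis {analysis!r}")
    design = parse_design(sim)
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        data = simulate_trial(sim, n, seed=rng, family=family)
        if method == "gcomp":
            # pooled variance keeps small trials estimable when a sparse
            # sequence has a single record
            est = estimate_gcomp(data, design, family=family, common=True)
        else:
            est = estimate_ipw(data, design, family=family)
        if analysis == "global":
            res = global_test(est, design)
            rejections += res.p_value < alpha
        else:
            pw = pairwise_comparisons(est, alpha=alpha, adjust="bon")
            rejections += bool((pw.table["p_value"] < alpha / pw.n_p).any())
    power = rejections / reps
    se = float(np.sqrt(power * (1.0 - power) / reps))
    return {"power": power, "rejection_se": se, "reps": reps, "n": n}


def codiacs_like_sim() -> pd.DataFrame:
    """SIM of the synthetic depression-management trial: 2 arms, binary
    response, 2 stage-2 options per branch, all randomization
    probabilities 0.5, response rates 0.5, and sequence means/SDs in the
    range typical of a six-month depression-score reduction."""
    rows = []
    means = {
        (0, 0, 0): 1.5, (0, 0, 1): 6.0, (0, 1, 0): 11.0, (0, 1, 1): 9.0,
        (1, 0, 0): 3.0, (1, 0, 1): 8.0, (1, 1, 0): 14.5, (1, 1, 1): 12.0,
    }
    sds = {
        (0, 0, 0): 7.0, (0, 0, 1): 8.0, (0, 1, 0): 8.5, (0, 1, 1): 9.0,
        (1, 0, 0): 7.5, (1, 0, 1): 9.5, (1, 1, 0): 10.0, (1, 1, 1): 8.0,
    }
    seq = 1
    for a1 in (0, 1):
        for o2 in (0, 1):
            for a2 in (0, 1):
                rows.append(
                    {
                        "SEQ": seq, "A1": a1, "PI1": 0.5, "O2": o2,
                        "P2": 0.5, "A2": a2, "PI2": 0.5,
                        "MEAN": means[(a1, o2, a2)], "SD": sds[(a1, o2, a2)],
                    }
                )
                seq += 1
    return pd.DataFrame(rows, columns=SIM_COLUMNS)


def make_codiacs_like(seed: int = 20210111, n: int = 108) -> pd.DataFrame:
    """A synthetic 108-patient two-stage depression-management SMART.

    Structure mirrors the stepped-care trial used in the worked examples
    (2 arms coded 0/1, binary intermediate response, re-randomization
    between the same two options, continuous outcome); values are
    simulated, not the deposited data.  The default seed is chosen so
    that every sequence is populated.
    """
    data = simulate_trial(codiacs_like_sim(), n=n, seed=seed)
    counts = data.groupby(["A1", "O2", "A2"]).size()
    if len(counts) < 8:  # pragma: no cover - guards unlucky custom seeds
        raise RuntimeError(
            "an empty treatment sequence was drawn; pick a different seed"
        )
    return data
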