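import numpy as np
import pandas as pd
import pytest

from smartats.design import SIM_COLUMNS, SmartDesign, parse_design


def make_sim(means, sds, pi1=0.5, p2=0.5, pi2=0.5):
    """Build the standard 2-arm / binary-response / 2-options-per-branch
    SIM with the given 8 sequence means and SDs (design order: arm, then
    response category, then option)."""
    rows, seq = [], 1
    it = iter(zip(means, sds))
    for a1 in (0, 1):
        for o2 in (0, 1):
            for a2 in (0, 1):
                m, s = next(it)
                rows.append({"SEQ": seq, "A1": a1, "PI1": pi1, "O2": o2,
                             "P2": p2, "A2": a2, "PI2": pi2,
                             "MEAN": m, "SD": s})
                seq += 1
    return pd.DataFrame(rows, columns=SIM_COLUMNS)


@pytest.fixture
def benchmark_sim():
    """The worked sample-size example: equal randomization, response rate
    one half, sequence means (1,8,11,10,9,6,20,12), common SD 10."""
    return make_sim([1, 8, 11, 10, 9, 6, 20, 12], [10] * 8)


@pytest.fixture
def benchmark_design(benchmark_sim):
    return parse_design(benchmark_sim)


@pytest.fixture
def null_sim():
    """All sequence means equal: no strategy differs from any other."""
    return make_sim([5.0] * 8, [10] * 8)


@pytest.fixture
def alcohol_design():
    """The addiction-trial design: CBT(1)/MED(2) at stage 1, binary
    response (category 0 = response), responders re-randomized to
    TMC(3)/TM(4), non-responders to MED-continuation or the enhanced
    combination (5)."""
    return SmartDesign(
        stage1_arms=(1, 2),
        response_categories=(2, 2),
        stage2_options={
            (1, 0): (3, 4), (1, 1): (2, 5),
            (2, 0): (3, 4), (2, 1): (1, 5),
        },
        pi1={1: 0.5, 2: 0.5},
        pi2={
            (1, 0, 3): 0.5, (1, 0, 4): 0.5, (1, 1, 2): 0.5, (1, 1, 5): 0.5,
            (2, 0, 3): 0.5, (2, 0, 4): 0.5, (2, 1, 1): 0.5, (2, 1, 5): 0.5,
        },
    )


@pytest.fixture
def tiny_data():
    """Four patients, one per sequence of arm 0 plus two of arm 1, with
    outcomes chosen for hand-checkable estimates."""
    return pd.DataFrame(
        {
            "A1": [0, 0, 0, 0, 1, 1, 1, 1],
            "O2": [0, 0, 1, 1, 0, 0, 1, 1],
            "A2": [0, 1, 0, 1, 0, 1, 0, 1],
            "Y": [2.0, 4.0, 6.0, 8.0, 1.0, 3.0, 5.0, 7.0],
        }
    )


def random_design(rng: np.random.Generator) -> SmartDesign:
    """A small random valid design: 1-3 arms, 1-3 response categories per
    arm, 1-3 stage-2 options per branch, random probabilities."""
    n_arms = int(rng.integers(1, 4))
    arms = tuple(range(n_arms))
    p1 = rng.dirichlet(np.ones(n_arms) * 5)
    ncats, stage2, pi2 = [], {}, {}
    code = 0
    for a1 in arms:
        ncat = int(rng.integers(1, 4))
        ncats.append(ncat)
        for o2 in range(ncat):
            nopt = int(rng.integers(1, 4))
            opts = tuple(range(code, code + nopt))
            code += nopt
            stage2[(a1, o2)] = opts
            probs = rng.dirichlet(np.ones(nopt) * 5) if nopt > 1 else np.array([1.0])
            for a2, p in zip(opts, probs):
                pi2[(a1, o2, a2)] = float(p)
    return SmartDesign(arms, tuple(ncats), stage2,
                       {a: float(p) for a, p in zip(arms, p1)}, pi2)
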