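"""Two-stage SMART design structures.

A two-stage sequential multiple assignment randomized trial (SMART)
randomizes each patient twice: at baseline among the stage-1 arms, and
again after an intermediate evaluation among the stage-2 options open to
patients with that arm/response history.  A *treatment sequence* is one
realized path ``(A1, O2, A2)``; an *adaptive treatment strategy* (ATS) is
a decision rule ``(a1; a2 per response category)`` mapping each possible
intermediate response to a stage-2 treatment.  This module represents the
branching structure, enumerates the embedded strategies, decides which
strategies a patient's observed sequence is consistent with, and computes
the degrees of freedom of the global strategy-comparison test.

Degenerate branches — a history with a single stage-2 option and no
re-randomization — are first-class: they contribute one sequence, no
branching, and probability one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Exact column set of a sequence information matrix (SIM).
SIM_COLUMNS = ["SEQ", "A1", "PI1", "O2", "P2", "A2", "PI2", "MEAN", "SD"]

_PROB_TOL = 1e-8


class DesignValidationError(ValueError):
    """Raised when a design table or trial record violates an invariant."""


@dataclass(frozen=True)
class TrialRecord:
    """One completed patient: stage-1 arm, intermediate response category,
    stage-2 treatment, final outcome.  ``o1`` is an optional baseline
    category, accepted but treated as a single (non-adaptive) stratum."""

    a1: int
    o2: int
    a2: int
    y: float
    o1: int | None = None


@dataclass(frozen=True)
class Strategy:
    """A two-stage decision rule: start with ``a1``; on observing response
    category ``r`` give ``rules[r]``.  ``code`` is the display form
    ``(a1;rules[0],rules[1],...)`` with raw treatment codes."""

    a1: int
    rules: tuple[int, ...]

    @property
    def code(self) -> str:
        return f"({self.a1};{','.join(str(a) for a in self.rules)})"

    def stage2_for(self, o2: int) -> int:
        return self.rules[o2]


@dataclass(frozen=True)
class SmartDesign:
    """Branching structure plus randomization probabilities of a two-stage
    SMART.

    Parameters
    ----------
    stage1_arms
        Ordered stage-1 treatment codes.
    response_categories
        Number of intermediate response categories per arm (>= 1),
        aligned with ``stage1_arms``.
    stage2_options
        Mapping ``(a1, o2) -> ordered tuple of stage-2 codes`` for every
        arm and response category.
    pi1
        Stage-1 randomization probability per arm; sums to one.
    pi2
        Stage-2 randomization probability per ``(a1, o2, a2)``; sums to
        one within each branch.  A degenerate branch (single option) has
        probability one.
    """

    stage1_arms: tuple[int, ...]
    response_categories: tuple[int, ...]
    stage2_options: dict[tuple[int, int], tuple[int, ...]] = field(hash=False)
    pi1: dict[int, float] = field(hash=False)
    pi2: dict[tuple[int, int, int], float] = field(hash=False)

    def __post_init__(self) -> None:
        if not self.stage1_arms:
            raise DesignValidationError("design needs at least one stage-1 arm")
        if len(set(self.stage1_arms)) != len(self.stage1_arms):
            raise DesignValidationError("duplicate stage-1 arm codes")
        if len(self.response_categories) != len(self.stage1_arms):
            raise DesignValidationError(
                "response_categories must align with stage1_arms"
            )
        if any(r < 1 for r in self.response_categories):
            raise DesignValidationError("each arm needs >= 1 response category")
        s1 = sum(self.pi1[a] for a in self.stage1_arms)
        if abs(s1 - 1.0) > _PROB_TOL:
            raise DesignValidationError(f"stage-1 probabilities sum to {s1}, not 1")
        for a1, p in self.pi1.items():
            if not (0.0 < p <= 1.0):
                raise DesignValidationError(f"pi1[{a1}]={p} outside (0,1]")
        for a1, ncat in zip(self.stage1_arms, self.response_categories):
            for o2 in range(ncat):
                opts = self.stage2_options.get((a1, o2))
                if not opts:
                    raise DesignValidationError(
                        f"no stage-2 options for arm {a1}, response {o2}"
                    )
                if len(set(opts)) != len(opts):
                    raise DesignValidationError(
                        f"duplicate stage-2 options in branch ({a1},{o2})"
                    )
                s2 = sum(self.pi2[(a1, o2, a2)] for a2 in opts)
                if abs(s2 - 1.0) > _PROB_TOL:
                    raise DesignValidationError(
                        f"branch ({a1},{o2}) probabilities sum to {s2}, not 1"
                    )
                for a2 in opts:
                    p = self.pi2[(a1, o2, a2)]
                    if not (0.0 < p <= 1.0):
                        raise DesignValidationError(
                            f"pi2[{a1},{o2},{a2}]={p} outside (0,1]"
                        )
                if len(opts) == 1 and abs(self.pi2[(a1, o2, opts[0])] - 1.0) > _PROB_TOL:
                    raise DesignValidationError(
                        f"degenerate branch ({a1},{o2}) must have pi2 = 1"
                    )

    # -- structure queries -------------------------------------------------

    def n_categories(self, a1: int) -> int:
        return self.response_categories[self.stage1_arms.index(a1)]

    def options(self, a1: int, o2: int) -> tuple[int, ...]:
        return self.stage2_options[(a1, o2)]

    def is_degenerate_branch(self, a1: int, o2: int) -> bool:
        return len(self.options(a1, o2)) == 1

    def sequences(self) -> list[tuple[int, int, int]]:
        """All treatment sequences ``(a1, o2, a2)`` in design order."""
        out = []
        for a1, ncat in zip(self.stage1_arms, self.response_categories):
            for o2 in range(ncat):
                for a2 in self.options(a1, o2):
                    out.append((a1, o2, a2))
        return out

    def validate_record(self, record: TrialRecord) -> None:
        if record.a1 not in self.stage1_arms:
            raise DesignValidationError(f"unknown stage-1 arm {record.a1}")
        if not (0 <= record.o2 < self.n_categories(record.a1)):
            raise DesignValidationError(
                f"response category {record.o2} outside arm {record.a1}"
            )
        if record.a2 not in self.options(record.a1, record.o2):
            raise DesignValidationError(
                f"stage-2 code {record.a2} not an option in branch "
                f"({record.a1},{record.o2})"
            )
        if not np.isfinite(record.y):
            raise DesignValidationError("outcome must be finite")


def parse_design(sim: pd.DataFrame) -> SmartDesign:
    """Build and validate a :class:`SmartDesign` from a sequence information
    matrix — one row per treatment sequence with columns
    ``SEQ, A1, PI1, O2, P2, A2, PI2, MEAN, SD``.

    Raises :class:`DesignValidationError` naming the offending row or branch
    on duplicate sequences, branch probabilities not summing to one,
    non-positive SD, or unknown columns.
    """
    if sim is None or len(sim) == 0:
        raise DesignValidationError("SIM table is empty")
    unknown = [c for c in sim.columns if c not in SIM_COLUMNS]
    if unknown:
        raise DesignValidationError(f"unknown SIM columns: {unknown}")
    missing = [c for c in SIM_COLUMNS if c not in sim.columns]
    if missing:
        raise DesignValidationError(f"missing SIM columns: {missing}")

    dup = sim.duplicated(subset=["A1", "O2", "A2"])
    if dup.any():
        row = sim.index[dup][0]
        raise DesignValidationError(f"duplicate sequence row at index {row}")
    if (sim["SD"] <= 0).any():
        row = sim.index[sim["SD"] <= 0][0]
        raise DesignValidationError(f"SD <= 0 at row index {row}")

    arms = tuple(int(a) for a in pd.unique(sim["A1"]))
    pi1: dict[int, float] = {}
    ncats: list[int] = []
    stage2: dict[tuple[int, int], tuple[int, ...]] = {}
    pi2: dict[tuple[int, int, int], float] = {}
    for a1 in arms:
        arm = sim[sim["A1"] == a1]
        p1 = arm["PI1"].unique()
        if len(p1) != 1:
            raise DesignValidationError(f"inconsistent PI1 within arm {a1}")
        pi1[a1] = float(p1[0])
        cats = sorted(int(o) for o in arm["O2"].unique())
        if cats != list(range(len(cats))):
            raise DesignValidationError(
                f"response categories of arm {a1} must be 0..R-1, got {cats}"
            )
        ncats.append(len(cats))
        p2s = []
        for o2 in cats:
            br = arm[arm["O2"] == o2]
            p2 = br["P2"].unique()
            if len(p2) != 1:
                raise DesignValidationError(
                    f"inconsistent P2 within branch ({a1},{o2})"
                )
            p2s.append(float(p2[0]))
            opts = tuple(int(a) for a in br["A2"])
            stage2[(a1, o2)] = opts
            for a2, p in zip(opts, br["PI2"]):
                pi2[(a1, o2, a2)] = float(p)
        if abs(sum(p2s) - 1.0) > _PROB_TOL:
            raise DesignValidationError(
                f"response rates P2 of arm {a1} sum to {sum(p2s)}, not 1"
            )
    return SmartDesign(
        stage1_arms=arms,
        response_categories=tuple(ncats),
        stage2_options=stage2,
        pi1=pi1,
        pi2=pi2,
    )


def enumerate_strategies(design: SmartDesign) -> list[Strategy]:
    """All adaptive treatment strategies embedded in the design.

    For each arm, the Cartesian product of the stage-2 option sets over
    response categories, in arm order and with the last category varying
    fastest; ``G = sum over arms of prod_r |options(a1, r)|``.
    """
    out: list[Strategy] = []
    for a1, ncat in zip(design.stage1_arms, design.response_categories):
        option_sets = [design.options(a1, o2) for o2 in range(ncat)]
        for rules in itertools.product(*option_sets):
            out.append(Strategy(a1=a1, rules=rules))
    return out


def is_consistent(record: TrialRecord, strategy: Strategy,
                  design: SmartDesign | None = None) -> bool:
    """True iff the patient's observed sequence could have arisen while
    following the strategy: same stage-1 arm, and the stage-2 treatment
    equals the strategy's rule for the observed response category.

    A patient is typically consistent with several strategies (all those
    agreeing on the observed path), which is what induces covariance
    between strategy-value estimates.
    """
    if design is not None:
        design.validate_record(record)
    return record.a1 == strategy.a1 and record.a2 == strategy.rules[record.o2]


def test_df(design: SmartDesign) -> int:
    """Degrees of freedom of the global Wald test comparing all strategy
    values: the rank of the contrast space of achievable strategy values,

        df = [ sum over arms ( sum_r |options(a1,r)| - R(a1) + 1 ) ] - 1.

    Within one arm the strategy values are a bilinear function of the
    per-branch choices, so the arm contributes ``sum_r |options| - R + 1``
    free dimensions; subtracting one removes the overall level that the
    contrast matrix annihilates.  A degenerate branch (one option)
    contributes nothing.  This is the df that makes the Wald statistic
    asymptotically chi-squared.
    """
    total = 0
    n_strategies = 0
    for a1, ncat in zip(design.stage1_arms, design.response_categories):
        sizes = [len(design.options(a1, o2)) for o2 in range(ncat)]
        n_strategies += int(np.prod(sizes))
        total += sum(sizes) - ncat + 1
    if n_strategies < 2:
        raise DesignValidationError(
            "global test undefined: design embeds a single strategy"
        )
    return total - 1
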