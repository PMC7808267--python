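"""Design structure: SIM parsing, strategy enumeration, consistency,
degrees of freedom."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smartats.design import (
    DesignValidationError,
    SmartDesign,
    TrialRecord,
    enumerate_strategies,
    is_consistent,
    parse_design,
)
from smartats.design import test_df as design_df

from conftest import random_design


def strategy_value_map(design):
    """Oracle for df: the matrix M mapping per-sequence means to strategy
    values at fixed response rates; df must equal the numerical rank of
    C @ M, the contrast space of achievable strategy values."""
    seqs = design.sequences()
    strategies = enumerate_strategies(design)
    rng = np.random.default_rng(0)
    # arbitrary fixed positive response rates per branch
    p2 = {}
    for a1, ncat in zip(design.stage1_arms, design.response_categories):
        probs = rng.dirichlet(np.ones(ncat) * 3)
        for r in range(ncat):
            p2[(a1, r)] = probs[r]
    M = np.zeros((len(strategies), len(seqs)))
    for g, s in enumerate(strategies):
        for j, (a1, o2, a2) in enumerate(seqs):
            if a1 == s.a1 and a2 == s.rules[o2]:
                M[g, j] = p2[(a1, o2)]
    return M


class TestParseDesign:
    def test_standard_two_arm_design(self, benchmark_sim):
        design = parse_design(benchmark_sim)
        assert design.stage1_arms == (0, 1)
        assert len(design.sequences()) == 8
        assert len(design.stage2_options) == 4
        assert not any(
            design.is_degenerate_branch(a, r) for (a, r) in design.stage2_options
        )

    def test_degenerate_branch_accepted_and_flagged(self):
        rows = [
            {"SEQ": 1, "A1": 0, "PI1": 0.5, "O2": 0, "P2": 0.5, "A2": 0,
             "PI2": 1.0, "MEAN": 1.0, "SD": 1.0},
            {"SEQ": 2, "A1": 0, "PI1": 0.5, "O2": 1, "P2": 0.5, "A2": 1,
             "PI2": 0.5, "MEAN": 2.0, "SD": 1.0},
            {"SEQ": 3, "A1": 0, "PI1": 0.5, "O2": 1, "P2": 0.5, "A2": 2,
             "PI2": 0.5, "MEAN": 3.0, "SD": 1.0},
            {"SEQ": 4, "A1": 1, "PI1": 0.5, "O2": 0, "P2": 1.0, "A2": 3,
             "PI2": 1.0, "MEAN": 4.0, "SD": 1.0},
        ]
        design = parse_design(pd.DataFrame(rows))
        assert design.is_degenerate_branch(0, 0)
        assert not design.is_degenerate_branch(0, 1)
        assert design.is_degenerate_branch(1, 0)

    def test_branch_probabilities_must_sum_to_one(self, benchmark_sim):
        bad = benchmark_sim.copy()
        bad.loc[0, "PI2"] = 0.4  # branch (0,0) now sums to 0.9
        with pytest.raises(DesignValidationError, match=r"\(0,0\)"):
            parse_design(bad)

    def test_duplicate_sequence_rejected(self, benchmark_sim):
        bad = pd.concat([benchmark_sim, benchmark_sim.iloc[[0]]], ignore_index=True)
        with pytest.raises(DesignValidationError, match="duplicate"):
            parse_design(bad)

    def test_nonpositive_sd_rejected(self, benchmark_sim):
        bad = benchmark_sim.copy()
        bad.loc[3, "SD"] = 0.0
        with pytest.raises(DesignValidationError, match="SD"):
            parse_design(bad)

    def test_unknown_column_rejected(self, benchmark_sim):
        bad = benchmark_sim.copy()
        bad["NOTE"] = "x"
        with pytest.raises(DesignValidationError, match="NOTE"):
            parse_design(bad)

    def test_empty_table_rejected(self):
        with pytest.raises(DesignValidationError, match="empty"):
            parse_design(pd.DataFrame())

    def test_response_rates_must_sum_to_one(self, benchmark_sim):
        bad = benchmark_sim.copy()
        bad.loc[bad["A1"] == 0, "P2"] = 0.4
        with pytest.raises(DesignValidationError, match="P2|response rates"):
            parse_design(bad)


class TestEnumerateStrategies:
    def test_addiction_trial_codes(self, alcohol_design):
        strategies = enumerate_strategies(alcohol_design)
        assert len(strategies) == 8
        codes = [s.code for s in strategies]
        # category 0 is response: first code pairs TMC for responders
        # with MED for non-responders; row 8 follows the factorial
        # pattern (2;4,5)
        assert codes == [
            "(1;3,2)", "(1;3,5)", "(1;4,2)", "(1;4,5)",
            "(2;3,1)", "(2;3,5)", "(2;4,1)", "(2;4,5)",
        ]

    def test_three_options_per_branch_gives_18(self, alcohol_design):
        widened = SmartDesign(
            stage1_arms=(1, 2),
            response_categories=(2, 2),
            stage2_options={
                (a, r): (10 * a + 3 * r, 10 * a + 3 * r + 1, 10 * a + 3 * r + 2)
                for a in (1, 2) for r in (0, 1)
            },
            pi1={1: 0.5, 2: 0.5},
            pi2={
                (a, r, 10 * a + 3 * r + k): 1 / 3
                for a in (1, 2) for r in (0, 1) for k in range(3)
            },
        )
        assert len(enumerate_strategies(widened)) == 18

    def test_single_path_design_has_one_strategy(self):
        design = SmartDesign((0,), (1,), {(0, 0): (0,)}, {0: 1.0},
                             {(0, 0, 0): 1.0})
        strategies = enumerate_strategies(design)
        assert len(strategies) == 1
        assert strategies[0].rules == (0,)

    @pytest.mark.parametrize("seed", range(10))
    def test_count_matches_product_formula(self, seed):
        design = random_design(np.random.default_rng(seed))
        G = len(enumerate_strategies(design))
        expected = sum(
            int(np.prod([len(design.options(a, r)) for r in range(ncat)]))
            for a, ncat in zip(design.stage1_arms, design.response_categories)
        )
        assert G == expected


class TestConsistency:
    def test_one_record_supports_overlapping_strategies(self, alcohol_design):
        # CBT (1), no response (category 1), switched to MED (2): matches
        # both strategies that continue MED for non-responders
        record = TrialRecord(a1=1, o2=1, a2=2, y=0.0)
        strategies = enumerate_strategies(alcohol_design)
        supported = [s.code for s in strategies
                     if is_consistent(record, s, alcohol_design)]
        assert supported == ["(1;3,2)", "(1;4,2)"]

    def test_arm_mismatch_is_inconsistent(self, alcohol_design):
        record = TrialRecord(a1=1, o2=0, a2=3, y=0.0)
        med_first = [s for s in enumerate_strategies(alcohol_design) if s.a1 == 2]
        assert not any(is_consistent(record, s) for s in med_first)

    def test_out_of_design_record_rejected(self, alcohol_design):
        bad = TrialRecord(a1=1, o2=5, a2=3, y=0.0)
        strategy = enumerate_strategies(alcohol_design)[0]
        with pytest.raises(DesignValidationError):
            is_consistent(bad, strategy, alcohol_design)

    @pytest.mark.parametrize("seed", range(15))
    def test_support_size_is_product_over_unobserved_branches(self, seed):
        """Brute force: the number of strategies consistent with a record
        equals the product of |options| over the arm's unobserved
        response categories."""
        rng = np.random.default_rng(seed)
        design = random_design(rng)
        strategies = enumerate_strategies(design)
        a1 = design.stage1_arms[rng.integers(len(design.stage1_arms))]
        o2 = int(rng.integers(design.n_categories(a1)))
        opts = design.options(a1, o2)
        a2 = opts[rng.integers(len(opts))]
        record = TrialRecord(a1=a1, o2=o2, a2=a2, y=1.0)
        supported = [s for s in strategies if is_consistent(record, s, design)]
        expected = int(
            np.prod([len(design.options(a1, r))
                     for r in range(design.n_categories(a1)) if r != o2])
        )
        assert len(supported) == expected >= 1
        # all supporting strategies agree on the observed path
        assert all(s.a1 == a1 and s.rules[o2] == a2 for s in supported)


class TestDegreesOfFreedom:
    def test_two_by_two_factorial_design(self, benchmark_design):
        assert design_df(benchmark_design) == 5

    def test_three_options_per_branch(self):
        design = SmartDesign(
            (0, 1), (2, 2),
            {(a, r): (0, 1, 2) for a in (0, 1) for r in (0, 1)},
            {0: 0.5, 1: 0.5},
            {(a, r, k): 1 / 3 for a in (0, 1) for r in (0, 1) for k in range(3)},
        )
        assert design_df(design) == 9

    def test_single_arm_binary_response(self):
        design = SmartDesign(
            (0,), (2,), {(0, 0): (0, 1), (0, 1): (0, 1)}, {0: 1.0},
            {(0, 0, 0): 0.5, (0, 0, 1): 0.5, (0, 1, 0): 0.5, (0, 1, 1): 0.5},
        )
        assert design_df(design) == 2

    def test_single_strategy_design_is_an_error(self):
        design = SmartDesign((0,), (1,), {(0, 0): (0,)}, {0: 1.0},
                             {(0, 0, 0): 1.0})
        with pytest.raises(DesignValidationError, match="global test undefined"):
            design_df(design)

    @pytest.mark.parametrize("seed", range(50))
    def test_df_equals_rank_of_contrast_space(self, seed):
        """df must equal the numerical rank of C·M where M maps sequence
        means to strategy values at fixed response rates."""
        design = random_design(np.random.default_rng(seed))
        strategies = enumerate_strategies(design)
        if len(strategies) < 2:
            return
        M = strategy_value_map(design)
        G = M.shape[0]
        C = np.hstack([np.ones((G - 1, 1)), -np.eye(G - 1)])
        sv = np.linalg.svd(C @ M, compute_uv=False)
        rank = int(np.sum(sv > 1e-8 * max(sv[0], 1.0)))
        assert design_df(design) == rank


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10**6))
def test_df_bounds_hold_for_arbitrary_designs(seed):
    """For any valid design with at least two strategies, the global-test
    df is at least 1 and at most G-1 (equality iff the strategy values
    are unconstrained), and enumeration order is deterministic."""
    design = random_design(np.random.default_rng(seed))
    strategies = enumerate_strategies(design)
    if len(strategies) < 2:
        return
    df = design_df(design)
    assert 1 <= df <= len(strategies) - 1
    again = enumerate_strategies(design)
    assert [s.code for s in strategies] == [s.code for s in again]
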