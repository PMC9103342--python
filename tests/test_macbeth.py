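"""MACBETH scale construction, consistency, transitivity, anchoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import macbeth_triage as mt
from brute_oracle import brute_force_feasible
from macbeth_triage.macbeth import (
    InconsistentJudgmentsError,
    _lp_constraints,
    category_label,
    category_ordinal,
)


class TestCategories:
    @pytest.mark.parametrize(
        "label,k",
        [("null", 0), ("VW", 1), ("W", 2), ("M", 3), ("ST", 4), ("VST", 5), ("E", 6)],
    )
    def test_label_ordinal_bijection(self, label, k):
        assert category_ordinal(label) == k
        assert category_label(k) == label

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            category_ordinal("huge")


class TestElicitationPlan:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (2, [(0, 1)]),
            (3, [(0, 2), (1, 2), (0, 1)]),
            (5, [(0, 4), (1, 4), (2, 4), (3, 4), (0, 1), (1, 2), (2, 3)]),
        ],
    )
    def test_worst_column_plus_diagonal(self, n, expected):
        assert mt.elicitation_plan(n) == expected

    @given(st.integers(min_value=2, max_value=30))
    def test_cardinality_is_2n_minus_3(self, n):
        plan = mt.elicitation_plan(n)
        assert len(plan) == max(1, 2 * n - 3)
        assert len(set(plan)) == len(plan)

    def test_rejects_single_stimulus(self):
        with pytest.raises(ValueError):
            mt.elicitation_plan(1)


class TestImpliedInterval:
    def test_two_weak_links_give_two_to_four(self):
        m = mt.JudgmentMatrix(["a", "b", "c"], [(0, 1, 2), (1, 2, 2)])
        iv = mt.implied_category_interval(m, (0, 2))
        assert (iv.lo, iv.hi) == (2, 4)

    def test_null_link_contributes_nothing(self):
        m = mt.JudgmentMatrix(["a", "b", "c"], [(0, 1, 0), (1, 2, 4)])
        iv = mt.implied_category_interval(m, (0, 2))
        assert (iv.lo, iv.hi) == (4, 4)

    def test_disjoint_chains_flag_inconsistency(self):
        # a->b->d forces [5,6]; a->c->d forces [1,2]; intersection is empty
        m = mt.JudgmentMatrix(
            ["a", "b", "c", "d"],
            [(0, 1, 5), (1, 3, 5), (0, 2, 1), (2, 3, 1)],
        )
        iv = mt.implied_category_interval(m, (0, 3))
        assert iv.empty

    def test_unconnected_pair_is_undetermined(self):
        m = mt.JudgmentMatrix(["a", "b", "c"], [(0, 1, 2)])
        with pytest.raises(mt.UndeterminedPairError):
            mt.implied_category_interval(m, (0, 2))

    def test_directly_judged_pair_rejected(self):
        m = mt.JudgmentMatrix(["a", "b"], [(0, 1, 2)])
        with pytest.raises(ValueError):
            mt.implied_category_interval(m, (0, 1))


class TestConsistency:
    def test_single_judgment_always_feasible(self):
        for k in range(7):
            m = mt.JudgmentMatrix(["a", "b"], [(0, 1, k)])
            assert mt.check_consistency(m).feasible

    def test_whole_smaller_than_parts_is_infeasible(self):
        m = mt.JudgmentMatrix(["a", "b", "c"], [(0, 1, 4), (1, 2, 4), (0, 2, 2)])
        report = mt.check_consistency(m)
        assert not report.feasible
        assert report.certificate  # non-empty irreducible subset
        assert not brute_force_feasible(m)

    def test_certificate_empty_iff_feasible(self):
        good = mt.JudgmentMatrix(["a", "b", "c"], [(0, 1, 2), (1, 2, 2), (0, 2, 4)])
        assert mt.check_consistency(good).certificate == []

    def test_consistent_generator_mode_always_feasible(self):
        for seed in range(40):
            spec = mt.SyntheticSpec(n_stimuli=2 + seed % 5, mode="consistent", seed=seed)
            m = mt.generate_synthetic_judgments(spec)
            assert mt.check_consistency(m).feasible, m.label


class TestSolveBasicScale:
    @pytest.mark.parametrize(
        "stimuli,judgments,expected",
        [
            (["a", "b"], [(0, 1, 3)], {"a": 3.0, "b": 0.0}),
            (
                ["a", "b", "c"],
                [(0, 1, 2), (1, 2, 2), (0, 2, 4)],
                {"a": 4.0, "b": 2.0, "c": 0.0},
            ),
            (
                ["a", "b", "c"],
                [(0, 1, 0), (1, 2, 3)],
                {"a": 3.0, "b": 3.0, "c": 0.0},
            ),
        ],
    )
    def test_minimal_scales(self, stimuli, judgments, expected):
        raw = mt.solve_basic_scale(mt.JudgmentMatrix(stimuli, judgments))
        assert raw.scores == pytest.approx(expected)

    def test_infeasible_matrix_raises(self):
        m = mt.JudgmentMatrix(["a", "b", "c"], [(0, 1, 4), (1, 2, 4), (0, 2, 2)])
        with pytest.raises(InconsistentJudgmentsError):
            mt.solve_basic_scale(m)

    def test_solution_satisfies_all_constraints(self):
        for seed in range(25):
            spec = mt.SyntheticSpec(n_stimuli=2 + seed % 6, mode="consistent", seed=seed)
            m = mt.generate_synthetic_judgments(spec)
            raw = mt.solve_basic_scale(m)
            assert_satisfies_lp(m, raw)

    def test_worst_scores_zero_and_monotone(self):
        for seed in range(25):
            m = mt.generate_synthetic_judgments(
                mt.SyntheticSpec(n_stimuli=5, mode="consistent", seed=seed)
            )
            raw = mt.solve_basic_scale(m)
            vals = [raw.scores[s] for s in m.stimuli]
            assert vals[-1] == 0.0
            assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))


def assert_satisfies_lp(matrix, raw, tol=1e-9):
    """Substitute a scale into every LP constraint of the matrix."""
    A_ub, b_ub, A_eq, b_eq, tags = _lp_constraints(matrix)
    x = raw.as_array(matrix.stimuli)
    n_ub = len(A_ub)
    for r, (row, b) in enumerate(zip(A_ub, b_ub)):
        assert float(np.dot(row, x)) <= b + tol, tags[r]
    for r, (row, b) in enumerate(zip(A_eq, b_eq)):
        assert abs(float(np.dot(row, x)) - b) <= tol, tags[n_ub + r]


class TestAnchoring:
    def test_affine_formula(self):
        raw = mt.RawScale({"a": 4.0, "b": 2.0, "c": 0.0})
        anchored = mt.anchor_scale(raw, good="a", neutral="b")
        assert anchored.scores == {"a": 100.0, "b": 0.0, "c": -100.0}

    def test_reanchoring_is_identity(self):
        raw = mt.RawScale({"a": 100.0, "b": 0.0, "c": -100.0})
        again = mt.anchor_scale(raw, good="a", neutral="b")
        assert again.scores == raw.scores

    def test_anchor_error_when_good_not_above_neutral(self):
        raw = mt.RawScale({"a": 1.0, "b": 1.0})
        with pytest.raises(ValueError):
            mt.anchor_scale(raw, good="a", neutral="b")

    @settings(deadline=None)
    @given(
        alpha=st.floats(min_value=0.01, max_value=100),
        beta=st.floats(min_value=-50, max_value=50),
    )
    def test_affine_invariance(self, alpha, beta):
        raw = mt.RawScale({"a": 6.0, "b": 3.0, "c": 1.0, "d": 0.0})
        transformed = mt.RawScale({k: alpha * v + beta for k, v in raw.scores.items()})
        w1 = mt.anchor_scale(raw, "a", "c").scores
        w2 = mt.anchor_scale(transformed, "a", "c").scores
        assert w1 == pytest.approx(w2, abs=1e-8)

    def test_bauru_bodily_injury_anchors(self, bauru):
        """Every sector's bodily-injury scale pins mild=100 and moderate=0."""
        for sid, model in bauru.sectors.items():
            sc = model.scales["bodily_injury"]
            assert sc.scores["mild"] == 100.0
            assert sc.scores["moderate"] == 0.0


class TestOracleAgreement:
    """LP feasibility matches exhaustive integer search on small matrices."""

    def test_consistent_and_perturbed_modes(self):
        rng_seeds = range(60)
        for seed in rng_seeds:
            mode = "perturbed" if seed % 2 else "consistent"
            m = mt.generate_synthetic_judgments(
                mt.SyntheticSpec(n_stimuli=2 + seed % 3, max_category=3,
                                 mode=mode, seed=seed)
            )
            assert mt.check_consistency(m).feasible == brute_force_feasible(m), m.label
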