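"""Bayesian update tracks: single steps, full cases, and the enumeration oracle."""

import itertools

import numpy as np
import pytest

import intersamm as im
from intersamm.bayes_engine import MISSING, NO, YES
from intersamm.model_registry import DegeneratePriorError, SchemaError

from conftest import make_matrix, random_matrix


def brute_force_posteriors(matrix, affirmative_codes):
    """Direct Bayes' theorem by explicit product over the affirmative set.

    Cause track: P(C|I1..Ik) proportional to P(C) * prod_j P(Ij|C).
    All-cause track: two-hypothesis posterior from P(S) * prod P(Ij|S)
    against (1-P(S)) * prod P(Ij|not S).  Independent of the sequential
    log-space implementation under test.
    """
    positions = [matrix.indicators.position(c) for c in affirmative_codes]
    p_cause = matrix.normalized_cause_prior().copy()
    for i in positions:
        p_cause = p_cause * matrix.conditional[i, :]
    p_cause = p_cause / p_cause.sum()

    num = matrix.prior_samm
    den = 1.0 - matrix.prior_samm
    for i in positions:
        num *= matrix.conditional_samm[i]
        den *= im.derive_baseline_negative(matrix, i)
    return num / (num + den), p_cause


def case_of(codes, case_id="c"):
    return im.CaseRecord(case_id=case_id, responses={c: YES for c in codes})


class TestSingleSteps:
    def test_samm_update_hand_odds(self):
        # odds = 0.15/0.85 * (0.4/0.0471...) = 1.5 -> p = 0.600
        m = make_matrix([[0.2]], [0.1], prior_samm=0.15,
                        baseline=[0.1], cond_samm=[0.4])
        assert im.update_samm(0.15, "i1", m) == pytest.approx(0.600, abs=5e-4)

    def test_neutral_likelihood_ratio_leaves_p_unchanged(self):
        m = make_matrix([[0.2]], [0.1], prior_samm=0.3,
                        baseline=[0.25], cond_samm=[0.25])
        assert im.update_samm(0.42, "i1", m) == pytest.approx(0.42)

    def test_contraindicating_indicator_lowers_p(self):
        # P(I|S)=0.1 < P(I|not S)=0.5
        m = make_matrix([[0.2]], [0.1], prior_samm=0.2,
                        baseline=[0.42], cond_samm=[0.1])
        assert im.update_samm(0.5, "i1", m) < 0.5

    def test_absorbing_state_rejected(self):
        m = make_matrix([[0.2]], [0.1])
        for p in (0.0, 1.0):
            with pytest.raises(DegeneratePriorError):
                im.update_samm(p, "i1", m)

    def test_cause_update_hand_normalization(self):
        # uniform prior, P(I|C) = (0.4, 0.1)  ->  (0.8, 0.2)
        m = make_matrix([[0.4, 0.1]], [0.05, 0.05])
        out = im.update_causes([0.5, 0.5], "i1", m)
        assert np.allclose(out, [0.8, 0.2])

    def test_equal_conditionals_are_renormalization_identity(self):
        m = make_matrix([[0.3, 0.3, 0.3]], [0.05, 0.05, 0.05])
        p = np.array([0.2, 0.5, 0.3])
        assert np.allclose(im.update_causes(p, "i1", m), p)

    def test_tiny_conditional_shrinks_but_stays_positive(self):
        m = make_matrix([[1e-5, 0.5]], [0.05, 0.05])
        out = im.update_causes([0.5, 0.5], "i1", m)
        assert 0.0 < out[0] < 1e-3
        assert out.sum() == pytest.approx(1.0)


class TestEvaluateCase:
    def test_no_affirmatives_returns_priors(self, matrix72):
        case = im.CaseRecord(case_id="empty", responses={})
        prof = im.evaluate_case(case, matrix72)
        assert prof.n_positive == 0
        assert prof.trace == []
        assert prof.p_samm == pytest.approx(matrix72.prior_samm)
        assert np.allclose(prof.p_cause, matrix72.normalized_cause_prior())

    def test_explicit_no_is_not_evidence(self, matrix72):
        all_no = im.CaseRecord(
            case_id="n", responses={c: NO for c in matrix72.indicators.codes})
        all_missing = im.CaseRecord(case_id="m", responses={})
        a = im.evaluate_case(all_no, matrix72)
        b = im.evaluate_case(all_missing, matrix72)
        assert a.p_samm == b.p_samm
        assert np.allclose(a.p_cause, b.p_cause)

    def test_single_indicator_composes_single_steps(self):
        m = make_matrix([[0.4, 0.1]], [0.05, 0.05], prior_samm=0.15,
                        baseline=[0.1], cond_samm=[0.4])
        prof = im.evaluate_case(case_of(["i1"]), m)
        assert prof.p_samm == pytest.approx(
            im.update_samm(0.15, "i1", m), abs=1e-12)
        assert np.allclose(
            prof.p_cause, im.update_causes([0.5, 0.5], "i1", m), atol=1e-12)

    def test_matches_enumeration_oracle(self):
        """Sequential log-space updating equals direct Bayes enumeration
        for every affirmative subset of up to 4 indicators and 3 causes,
        over a grid of random matrices."""
        rng = np.random.default_rng(1234)
        for _ in range(20):
            n_ind = int(rng.integers(1, 5))
            n_causes = int(rng.integers(2, 4))
            m = random_matrix(rng, n_ind, n_causes)
            codes = m.indicators.codes
            for k in range(n_ind + 1):
                for subset in itertools.combinations(codes, k):
                    prof = im.evaluate_case(case_of(list(subset)), m)
                    p_samm, p_cause = brute_force_posteriors(m, subset)
                    assert prof.p_samm == pytest.approx(p_samm, abs=1e-12)
                    assert np.allclose(prof.p_cause, p_cause, atol=1e-12)

    def test_order_invariance_against_sequential_updates(self):
        """Permuting the affirmative set never changes the posteriors: the
        final result equals step-by-step single updates in any order."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            m = random_matrix(rng, n_ind=6, n_causes=4)
            codes = m.indicators.codes
            k = int(rng.integers(2, 7))
            chosen = list(rng.choice(codes, size=k, replace=False))
            reference = im.evaluate_case(case_of(chosen), m)
            for _ in range(20):
                perm = list(rng.permutation(chosen))
                p = m.prior_samm
                vec = m.normalized_cause_prior()
                for code in perm:
                    p = im.update_samm(p, code, m)
                    vec = im.update_causes(vec, code, m)
                assert p == pytest.approx(reference.p_samm, abs=1e-12)
                assert np.allclose(vec, reference.p_cause, atol=1e-12)

    def test_trace_mirrors_updates(self):
        m = make_matrix([[0.4, 0.1], [0.3, 0.2], [0.1, 0.6]],
                        [0.05, 0.05])
        prof = im.evaluate_case(case_of(["i3", "i1"]), m)
        assert prof.n_positive == 2
        assert [s.indicator for s in prof.trace] == ["i1", "i3"]  # registry order
        assert prof.trace[-1].p_samm == pytest.approx(prof.p_samm)
        assert np.allclose(prof.trace[-1].p_cause, prof.p_cause)

    def test_supporting_indicator_strictly_raises_p_samm(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, n_ind=3, n_causes=2)
        # force a likelihood ratio > 1 on i2
        m.conditional_samm[1] = 0.6
        m.baseline_indicator[1] = (0.6 * m.prior_samm
                                   + 0.2 * (1 - m.prior_samm))
        a = im.evaluate_case(case_of(["i1"]), m)
        b = im.evaluate_case(case_of(["i1", "i2"]), m)
        assert b.p_samm > a.p_samm

    def test_posterior_is_proper_distribution(self, matrix72):
        rng = np.random.default_rng(21)
        codes = matrix72.indicators.codes
        for _ in range(25):
            chosen = list(rng.choice(codes, size=int(rng.integers(1, 23)),
                                     replace=False))
            prof = im.evaluate_case(case_of(chosen), matrix72)
            assert 0.0 < prof.p_samm < 1.0
            assert prof.p_cause.min() >= 0.0
            assert prof.p_cause.sum() == pytest.approx(1.0, abs=1e-9)


class TestCohortIO:
    def test_round_trip(self, matrix72, tmp_path):
        codes = matrix72.indicators.codes
        cases = [
            im.CaseRecord("a", {codes[0]: YES, codes[1]: NO}),
            im.CaseRecord("b", {codes[2]: YES}),
        ]
        path = tmp_path / "cohort.csv"
        from intersamm.bayes_engine import write_cohort
        write_cohort(cases, matrix72.indicators, path)
        back = im.read_cohort(path, matrix72.indicators)
        assert [c.case_id for c in back] == ["a", "b"]
        assert back[0].responses[codes[0]] == YES
        assert back[0].responses[codes[1]] == NO
        assert back[0].responses[codes[2]] == MISSING

    def test_unknown_column_rejected_unless_ignored(self, matrix72, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text("case_id,not_an_indicator\nx,1\n")
        with pytest.raises(SchemaError, match="not_an_indicator"):
            im.read_cohort(path, matrix72.indicators)
        cases = im.read_cohort(path, matrix72.indicators, ignore_unknown=True)
        assert cases[0].case_id == "x"

    def test_bad_cell_value_rejected(self, matrix72, tmp_path):
        code = matrix72.indicators.codes[0]
        path = tmp_path / "cohort.csv"
        path.write_text(f"case_id,{code}\nx,maybe\n")
        with pytest.raises(SchemaError, match="maybe"):
            im.read_cohort(path, matrix72.indicators)
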