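"""Reviewer reconciliation and Cohen's kappa against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.inter_rater import cohens_kappa as sm_cohens_kappa

from gccm.cohort import CATEGORY_ORDER, CategoryLabel, ValidationError
from gccm.reliability import (
    Resolution,
    UnresolvedDisagreementError,
    cohen_kappa,
    confusion_matrix,
    kappa_by_confidence,
    paired_assessments,
    reconcile,
)

from conftest import make_assessment

C, F, L, U = (CategoryLabel.COMFORT, CategoryLabel.FUNCTION,
              CategoryLabel.LIFE_EXTENSION, CategoryLabel.UNCLEAR)


def hand_kappa(matrix):
    """Independent p_o/p_e oracle computed from first principles."""
    m = np.asarray(matrix, dtype=float)
    n = m.sum()
    p_o = sum(m[i, i] for i in range(m.shape[0])) / n
    p_e = sum(m[i, :].sum() * m[:, i].sum() for i in range(m.shape[0])) / n ** 2
    return (p_o - p_e) / (1 - p_e)


class TestReconcile:
    def test_agreement_stands(self):
        call = reconcile((make_assessment(reviewer="R1", category=C),
                          make_assessment(reviewer="R2", category=C)))
        assert (call.category, call.resolution) == (C, Resolution.AGREEMENT)

    def test_consensus_resolves_disagreement(self):
        call = reconcile((make_assessment(reviewer="R1", category=L),
                          make_assessment(reviewer="R2", category=F)),
                         consensus_label=F)
        assert (call.category, call.resolution) == (F, Resolution.CONSENSUS)

    def test_adjudication_when_consensus_fails(self):
        call = reconcile((make_assessment(reviewer="R1", category=L),
                          make_assessment(reviewer="R2", category=F)),
                         adjudicator_label=L)
        assert (call.category, call.resolution) == (L, Resolution.ADJUDICATED)

    def test_unresolved_disagreement_raises(self):
        with pytest.raises(UnresolvedDisagreementError):
            reconcile((make_assessment(reviewer="R1", category=L),
                       make_assessment(reviewer="R2", category=F)))

    def test_consensus_on_agreement_warns(self):
        with pytest.warns(UserWarning, match="consensus"):
            reconcile((make_assessment(reviewer="R1", category=C),
                       make_assessment(reviewer="R2", category=C)),
                      consensus_label=F)

    def test_reviewer_roles_are_lexicographic(self):
        # same epoch given in either order -> same recorded category pair
        a = make_assessment(reviewer="R2", category=L)
        b = make_assessment(reviewer="R1", category=F)
        call = reconcile((a, b), consensus_label=F)
        assert call.reviewer_categories == (F, L)


class TestConfusionMatrix:
    def test_all_agreement_is_diagonal(self):
        assessments = []
        for i in range(10):
            assessments += [make_assessment(epoch=i, reviewer="R1", category=C),
                            make_assessment(epoch=i, reviewer="R2", category=C)]
        mat = confusion_matrix(assessments)
        assert mat[0, 0] == 10 and mat.sum() == 10

    def test_direct_count_example(self):
        pairs = [(C, C), (F, F), (L, F), (U, U)]
        assessments = []
        for i, (x, y) in enumerate(pairs):
            assessments += [make_assessment(epoch=i, reviewer="R1", category=x),
                            make_assessment(epoch=i, reviewer="R2", category=y)]
        mat = confusion_matrix(assessments)
        assert np.trace(mat) == 3
        assert mat[CATEGORY_ORDER.index(L), CATEGORY_ORDER.index(F)] == 1

    def test_swapping_reviewer_roles_transposes(self):
        pairs = [(C, F), (L, U), (F, F)]
        fwd, rev = [], []
        for i, (x, y) in enumerate(pairs):
            fwd += [make_assessment(epoch=i, reviewer="R1", category=x),
                    make_assessment(epoch=i, reviewer="R2", category=y)]
            rev += [make_assessment(epoch=i, reviewer="R1", category=y),
                    make_assessment(epoch=i, reviewer="R2", category=x)]
        assert np.array_equal(confusion_matrix(fwd).T, confusion_matrix(rev))

    def test_epoch_without_two_assessments_is_structural_error(self):
        with pytest.raises(ValidationError, match="exactly 2"):
            paired_assessments([make_assessment(epoch=0, reviewer="R1")])


class TestCohenKappa:
    def test_hand_computed_example(self):
        res = cohen_kappa([[20, 5], [5, 70]])
        assert res.percent_agreement == pytest.approx(0.90)
        assert res.kappa == pytest.approx((0.90 - 0.625) / (1 - 0.625), abs=1e-12)
        assert res.kappa == pytest.approx(0.733333333, abs=1e-6)

    def test_perfect_agreement_gives_kappa_one(self):
        res = cohen_kappa(np.diag([10, 7, 3, 1]))
        assert res.kappa == pytest.approx(1.0)
        assert res.percent_agreement == 1.0

    def test_chance_level_agreement_gives_kappa_zero(self):
        res = cohen_kappa([[25, 25], [25, 25]])
        assert res.kappa == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_marginals_raise(self):
        with pytest.raises(ValidationError, match="degenerate"):
            cohen_kappa([[10, 0], [0, 0]])

    def test_ci_brackets_kappa_and_truncates(self):
        res = cohen_kappa(np.diag([5, 5, 5, 5]))
        assert res.ci_low <= res.kappa <= res.ci_high <= 1.0

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(0, 40), min_size=16, max_size=16))
    def test_matches_oracle_and_statsmodels(self, cells):
        m = np.array(cells).reshape(4, 4)
        if m.sum() == 0 or np.trace(m) == m.sum():
            m[0, 1] += 1
        res = cohen_kappa(m)
        assert res.kappa == pytest.approx(hand_kappa(m), abs=1e-12)
        sm_res = sm_cohens_kappa(m, return_results=True)
        assert res.kappa == pytest.approx(float(sm_res.kappa), abs=1e-10)
        sm_var = float(sm_res.var_kappa)
        # statsmodels can yield nan or a tiny negative variance on near-empty
        # tables (floating cancellation); we clamp to zero, so compare the
        # variances where well defined rather than their square roots
        if np.isfinite(sm_var) and sm_var >= 0:
            assert res.se ** 2 == pytest.approx(sm_var, abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.integers(0, 30), min_size=16, max_size=16),
           st.permutations(range(4)))
    def test_invariance_under_label_permutation_and_transpose(self, cells, perm):
        m = np.array(cells).reshape(4, 4)
        if m.sum() == 0 or np.trace(m) == m.sum():
            m[1, 0] += 1
        k = cohen_kappa(m).kappa
        perm = list(perm)
        assert cohen_kappa(m[np.ix_(perm, perm)]).kappa == pytest.approx(k, abs=1e-12)
        assert cohen_kappa(m.T).kappa == pytest.approx(k, abs=1e-12)


class TestKappaByConfidence:
    def test_all_high_confidence_leaves_low_band_absent(self):
        assessments = []
        for i in range(6):
            cat = C if i % 2 else F
            assessments += [make_assessment(epoch=i, reviewer="R1", category=cat,
                                            confidence=5),
                            make_assessment(epoch=i, reviewer="R2", category=cat,
                                            confidence=5)]
        res = kappa_by_confidence(assessments)
        assert res["low"] is None
        assert res["high"].n == 6

    def test_min_rule_assigns_mixed_pair_to_low_band(self):
        assessments = [
            # epoch 0: confidences (1, 5) -> min rule puts it in the low band
            make_assessment(epoch=0, reviewer="R1", category=C, confidence=1),
            make_assessment(epoch=0, reviewer="R2", category=C, confidence=5),
            make_assessment(epoch=1, reviewer="R1", category=F, confidence=2),
            make_assessment(epoch=1, reviewer="R2", category=C, confidence=2),
            make_assessment(epoch=2, reviewer="R1", category=F, confidence=4),
            make_assessment(epoch=2, reviewer="R2", category=F, confidence=3),
            make_assessment(epoch=3, reviewer="R1", category=C, confidence=5),
            make_assessment(epoch=3, reviewer="R2", category=C, confidence=4),
        ]
        res = kappa_by_confidence(assessments)
        assert res["low"].n == 2 and res["high"].n == 2

    def test_degenerate_band_is_flagged_absent(self):
        assessments = [
            make_assessment(epoch=0, reviewer="R1", category=C, confidence=1),
            make_assessment(epoch=0, reviewer="R2", category=C, confidence=1),
        ]
        res = kappa_by_confidence(assessments)
        assert res["low"] is None and res["high"] is None

    def test_banded_kappa_equals_brute_force_subsetting(self, small_sim):
        """Oracle: re-filter the paired assessments by min-confidence by hand
        and recompute kappa on each subset independently."""
        assessments = small_sim.bundle.all_assessments()
        res = kappa_by_confidence(assessments)
        low_subset, high_subset = [], []
        for pair in paired_assessments(assessments).values():
            target = low_subset if min(a.confidence for a in pair) <= 2 else high_subset
            target.extend(pair)
        for band, subset in (("low", low_subset), ("high", high_subset)):
            if not subset:
                assert res[band] is None
                continue
            expected = cohen_kappa(confusion_matrix(subset))
            assert res[band].kappa == pytest.approx(expected.kappa, abs=1e-12)
            assert res[band].n == expected.n


def test_realized_kappa_converges_to_analytic_value_of_generating_process():
    """Simulated reviewer pairs with known confusion probabilities: the
    estimated kappa approaches the analytic kappa of the process."""
    from gccm.simulate import analytic_kappa

    rng = np.random.default_rng(42)
    confusion = np.full((4, 4), 0.05)
    np.fill_diagonal(confusion, 0.85)
    mix = np.array([0.3, 0.3, 0.3, 0.1])
    n = 4000
    true = rng.choice(4, size=n, p=mix)
    a = np.array([rng.choice(4, p=confusion[t]) for t in true])
    b = np.array([rng.choice(4, p=confusion[t]) for t in true])
    mat = np.zeros((4, 4), dtype=int)
    np.add.at(mat, (a, b), 1)
    res = cohen_kappa(mat)
    expected = analytic_kappa(confusion, mix)
    assert abs(res.kappa - expected) < 3 * res.se
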