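"""Cosine similarity, matching score, and the three-session reactivation logic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmfreact import (EnsembleSet, MatchConfig, MatchError,
                      classify_matched, cosine_similarity_matrix,
                      matching_score, reactivation_analysis, welch_ttest)


def _ens(patterns, session_id="s", neuron_ids=None):
    patterns = np.asarray(patterns, dtype=float)
    n_ens, n_neu = patterns.shape
    if neuron_ids is None:
        neuron_ids = np.arange(n_neu)
    return EnsembleSet(patterns=patterns, occurrences=np.zeros((1, n_ens)),
                       n_ensembles=n_ens, session_id=session_id, cost=0.0,
                       neuron_ids=neuron_ids)


def brute_force_ms(px, py, c):
    """Independent double-loop reference for the matching score."""
    matched = 0
    for p in px:
        best = 0.0
        for q in py:
            np_, nq = np.linalg.norm(p), np.linalg.norm(q)
            cos = 0.0 if np_ == 0 or nq == 0 else float(p @ q) / (np_ * nq)
            best = max(best, cos)
        if best > c:
            matched += 1
    return matched / len(px)


class TestCosineSimilarity:
    def test_self_similarity_diagonal_is_one(self, rng):
        x = _ens(rng.uniform(0.1, 1.0, (4, 10)))
        sims = cosine_similarity_matrix(x, x).values
        np.testing.assert_allclose(np.diag(sims), 1.0)

    def test_disjoint_supports_are_orthogonal(self):
        sims = cosine_similarity_matrix(_ens([[1, 1, 0, 0]]), _ens([[0, 0, 1, 1]]))
        assert sims.values[0, 0] == 0.0

    def test_closed_form_pair(self):
        sims = cosine_similarity_matrix(_ens([[1, 1, 0]]), _ens([[1, 0, 0]]))
        assert sims.values[0, 0] == pytest.approx(1 / np.sqrt(2), abs=1e-4)

    def test_zero_pattern_has_zero_similarity(self):
        sims = cosine_similarity_matrix(_ens([[0, 0, 0]]), _ens([[1, 1, 0]]))
        assert sims.values[0, 0] == 0.0

    def test_neuron_mismatch_lists_difference(self):
        x = _ens([[1.0, 0.0]], neuron_ids=[0, 1])
        y = _ens([[1.0, 0.0]], neuron_ids=[0, 2])
        with pytest.raises(MatchError, match=r"only in X: \[1\], only in Y: \[2\]"):
            cosine_similarity_matrix(x, y)


class TestMatchingScore:
    def test_identical_sets_score_one(self, rng):
        x = _ens(rng.uniform(0.1, 1.0, (5, 12)))
        assert matching_score(x, x).matching_score == 1.0

    def test_all_below_threshold_scores_zero(self):
        x = _ens(np.eye(4, 8))
        y = _ens(np.eye(8)[4:])  # disjoint supports: all cosines are zero
        assert matching_score(x, y).matching_score == 0.0

    def test_hand_built_half_match(self):
        """4 patterns whose best partners have cosines {0.95, 0.61, 0.59, 0.10}."""
        def unit(v):
            v = np.asarray(v, dtype=float)
            return v / np.linalg.norm(v)

        q = np.eye(3, 8)  # 3 unit partner patterns
        a, b, g = 0.95, 0.61, 0.59
        px = np.vstack([
            a * q[0] + np.sqrt(1 - a ** 2) * unit([0, 0, 0, 1, 0, 0, 0, 0]),
            b * q[1] + np.sqrt(1 - b ** 2) * unit([0, 0, 0, 0, 1, 0, 0, 0]),
            g * q[2] + np.sqrt(1 - g ** 2) * unit([0, 0, 0, 0, 0, 1, 0, 0]),
            unit([0.1, 0, 0, 0, 0, 0, 1, 1]),
        ])
        x, y = _ens(px), _ens(q)
        res = matching_score(x, y, MatchConfig(0.6))
        best = cosine_similarity_matrix(x, y).values.max(axis=1)
        np.testing.assert_allclose(best, [0.95, 0.61, 0.59, best[3]], atol=1e-9)
        assert best[3] < 0.2
        assert res.matching_score == 0.5
        assert res.matching_score == brute_force_ms(px, q, 0.6)

    def test_tie_at_threshold_is_unmatched(self):
        x = _ens([[1.0, 0.0]])
        c = cosine_similarity_matrix(x, x).values[0, 0]
        res = matching_score(x, x, MatchConfig(0.999999))
        assert c == 1.0 and res.matching_score == 1.0
        # construct exact tie: cosine equals the threshold
        y = _ens([[0.6, 0.8]])
        z = _ens([[1.0, 0.0]])
        sims = cosine_similarity_matrix(y, z).values
        assert sims[0, 0] == pytest.approx(0.6)
        assert matching_score(y, z, MatchConfig(0.6)).matching_score == 0.0

    def test_asymmetry(self):
        x = _ens([[1, 0, 0, 0]])
        y = _ens([[1, 0, 0, 0], [0, 1, 0, 0]])
        assert matching_score(x, y).matching_score == 1.0
        assert matching_score(y, x).matching_score == 0.5

    def test_empty_set_raises(self):
        x = _ens(np.empty((0, 4)))
        with pytest.raises(MatchError):
            matching_score(x, _ens([[1, 0, 0, 0]]))

    def test_oracle_equivalence_random_instances(self, rng):
        """Exact agreement with the brute-force double loop on random sets."""
        for _ in range(300):
            nx, ny = rng.integers(1, 9, 2)
            nn = rng.integers(2, 21)
            px = rng.uniform(0, 1, (nx, nn)) * (rng.uniform(0, 1, (nx, nn)) < 0.5)
            py = rng.uniform(0, 1, (ny, nn)) * (rng.uniform(0, 1, (ny, nn)) < 0.5)
            ms = matching_score(_ens(px), _ens(py)).matching_score
            assert ms == brute_force_ms(px, py, 0.6)

    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_threshold_monotonicity(self, c1, c2):
        rng = np.random.default_rng(5)
        x = _ens(rng.uniform(0, 1, (6, 15)))
        y = _ens(rng.uniform(0, 1, (7, 15)))
        lo, hi = sorted((c1, c2))
        assert (matching_score(x, y, MatchConfig(hi)).matching_score
                <= matching_score(x, y, MatchConfig(lo)).matching_score)

    @given(st.floats(1e-3, 1e3))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(8)
        px = rng.uniform(0, 1, (4, 10))
        py = rng.uniform(0, 1, (5, 10))
        base = matching_score(_ens(px), _ens(py))
        px2 = px.copy()
        px2[2] *= scale
        res = matching_score(_ens(px2), _ens(py))
        assert res.matching_score == base.matching_score
        np.testing.assert_array_equal(res.matched_x, base.matched_x)


class TestClassifyMatched:
    def test_paper_examples_of_matched_and_unmatched(self):
        """Pattern pairs at cosine 0.704 are matched and 0.105 are not (c = 0.6)."""
        def pattern_at(target, axis):
            p = np.zeros(6)
            p[axis] = target
            p[5] = np.sqrt(1 - target ** 2)
            return p

        x = _ens(np.vstack([pattern_at(0.704, 0), pattern_at(0.105, 1)]))
        y = _ens(np.vstack([np.eye(6)[0], np.eye(6)[1]]))
        sims = cosine_similarity_matrix(x, y).values
        assert sims[0, 0] == pytest.approx(0.704)
        assert sims[1, 1] == pytest.approx(0.105)
        mx, my = classify_matched(x, y)
        assert mx.tolist() == [True, False]

    def test_symmetric_labels_from_one_matrix(self):
        x = _ens([[1, 0, 0], [0, 1, 0]])
        y = _ens([[1, 0.1, 0]])
        mx, my = classify_matched(x, y)
        assert mx.tolist() == [True, False]
        assert my.tolist() == [True]


class TestReactivationAnalysis:
    def _sets(self, day1, rest, day2):
        return _ens(day1, "day1"), _ens(rest, "rest"), _ens(day2, "day2")

    def test_all_reactivated(self):
        e = np.eye(3, 6)
        d1, r, d2 = self._sets(e, e, e)
        res = reactivation_analysis(d1, r, d2)
        assert res.pct_reactivated_also_in_day2 == 100.0
        assert res.pct_nonreactivated_also_in_day2 is None

    def test_planted_6_3_2_counts(self):
        """6 Day 1 ensembles, 3 in rest, 2 of those in Day 2 → 66.7 % vs 0 %."""
        eye = np.eye(6, 24)
        d1 = eye
        rest = eye[:3]
        d2 = eye[:2]
        res = reactivation_analysis(*self._sets(d1, rest, d2))
        assert res.n_reactivated_in_rest == 3
        assert res.n_nonreactivated_in_rest == 3
        assert res.pct_reactivated_also_in_day2 == pytest.approx(200 / 3)
        assert res.pct_nonreactivated_also_in_day2 == 0.0

    def test_rest_unrelated_day2_identical(self):
        eye = np.eye(3, 12)
        rest = np.roll(np.eye(3, 12), 6, axis=1)
        res = reactivation_analysis(*self._sets(eye, rest, eye))
        assert res.pct_reactivated_also_in_day2 is None
        assert res.pct_nonreactivated_also_in_day2 == 100.0


def test_welch_ttest_separates_clear_groups():
    t, p = welch_ttest([0.30, 0.28, 0.33, 0.29], [0.10, 0.12, 0.08, 0.13])
    assert t > 0 and p < 0.01
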