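"""Outlier preprocessing, the accuracy/speed/summary formulas, and trends."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icatest import (
    ScoringConfig,
    ScoringError,
    compute_accuracy,
    compute_ica_score,
    compute_speed,
    compute_trends,
    remove_rt_outliers,
    score_session,
)
from tests.conftest import make_session, make_trial


def brute_force_fences(rts, w=1.5):
    """Independent oracle: per-element check against explicitly computed fences."""
    rts = np.asarray(rts, dtype=float)
    srt = np.sort(rts)

    def quantile(q):
        # linear interpolation between order statistics
        h = (len(srt) - 1) * q
        lo, hi = int(math.floor(h)), int(math.ceil(h))
        return srt[lo] + (h - lo) * (srt[hi] - srt[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    kept = [x for x in rts if q1 - w * iqr <= x <= q3 + w * iqr]
    removed = [x for x in rts if x < q1 - w * iqr or x > q3 + w * iqr]
    return kept, removed


class TestOutlierRemoval:
    def test_single_extreme_value_removed(self):
        kept, removed = remove_rt_outliers([400, 420, 440, 460, 3000], w=1.5)
        assert list(removed) == [3000]
        assert sorted(kept) == [400, 420, 440, 460]

    def test_degenerate_iqr_removes_nothing(self):
        kept, removed = remove_rt_outliers([500.0] * 10)
        assert removed.size == 0 and kept.size == 10

    def test_empty_input_rejected(self):
        with pytest.raises(ScoringError):
            remove_rt_outliers([])

    @given(st.lists(st.floats(100, 5000), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_conservation(self, rts):
        kept, removed = remove_rt_outliers(rts)
        assert sorted(np.concatenate([kept, removed])) == pytest.approx(sorted(rts))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(4, 60))
            rts = np.exp(rng.normal(6.3, 0.4, n)) + rng.choice(
                [0.0, 4000.0], p=[0.9, 0.1], size=n)
            kept, removed = remove_rt_outliers(rts)
            okept, oremoved = brute_force_fences(rts)
            assert sorted(kept) == pytest.approx(sorted(okept))
            assert sorted(removed) == pytest.approx(sorted(oremoved))


class TestFormulas:
    @pytest.mark.parametrize("n_correct,n_total,expected",
                             [(90, 100, 90.0), (0, 100, 0.0), (47, 90, 52.2222222)])
    def test_accuracy(self, n_correct, n_total, expected):
        assert compute_accuracy(n_correct, n_total) == pytest.approx(expected)

    def test_accuracy_needs_trials(self):
        with pytest.raises(ScoringError):
            compute_accuracy(0, 0)

    @pytest.mark.parametrize("rt,expected", [
        (349.525, 100.0),   # exponent exactly zero: cap boundary
        (1025.0, 51.74),    # 100*e^(-1+0.341)
        (200.0, 100.0),     # raw 115.7 capped
    ])
    def test_speed_examples(self, rt, expected):
        assert compute_speed(rt) == pytest.approx(expected, abs=5e-3)

    def test_speed_monotone_and_capped(self):
        rts = np.linspace(1, 3000, 400)
        speeds = [compute_speed(r) for r in rts]
        assert all(a >= b for a, b in zip(speeds, speeds[1:]))
        assert all(s == 100.0 for r, s in zip(rts, speeds) if r <= 349.525)
        assert all(s < 100.0 for r, s in zip(rts, speeds) if r > 349.6)
        assert all(s > 0 for s in speeds)

    def test_speed_rejects_nonpositive_rt(self):
        with pytest.raises(ScoringError):
            compute_speed(0.0)

    @pytest.mark.parametrize("speed,acc,expected", [
        (100, 100, 100.0), (50, 80, 40.0), (71.04, 90, 63.94)])
    def test_summary_score(self, speed, acc, expected):
        assert compute_ica_score(speed, acc) == pytest.approx(expected, abs=5e-3)

    def test_summary_score_range_checks(self):
        with pytest.raises(ScoringError):
            compute_ica_score(101, 50)
        assert compute_ica_score(50, 0) == 0.0


class TestTrends:
    def test_accuracy_trend_closed_form(self):
        recs = [make_trial(i + 1, correct=i >= 2, rt=500.0) for i in range(4)]
        cfg = ScoringConfig(trend_window=4)
        acc_trend, _ = compute_trends(recs, cfg)
        assert acc_trend == pytest.approx(0.4)

    def test_flat_series_has_zero_trend(self):
        recs = [make_trial(i, correct=True, rt=500.0) for i in range(20)]
        acc_trend, speed_trend = compute_trends(recs)
        assert acc_trend == 0.0
        assert speed_trend == 0.0

    def test_speeding_up_gives_positive_speed_trend(self):
        recs = [make_trial(i, correct=True, rt=900.0 - 5 * i) for i in range(50)]
        _, speed_trend = compute_trends(recs)
        assert speed_trend > 0

    def test_too_few_trials_rejected(self):
        with pytest.raises(ScoringError):
            compute_trends([make_trial(0, rt=500.0)])


class TestScoreSession:
    def test_all_correct_at_cap_boundary_scores_100(self):
        sess = make_session(rts=[349.525] * 100)
        res = score_session(sess)
        assert res.accuracy == 100.0
        assert res.speed == pytest.approx(100.0)
        assert res.ica_score == pytest.approx(100.0)
        assert res.valid

    def test_41_percent_outliers_invalidates(self):
        # 59 identical central RTs give a zero IQR; the 41 extremes (on both
        # sides, each side below the 25% quartile breakdown point) all fall
        # outside the fences, crossing the 40% validity cutoff
        sess = make_session(rts=[1.0] * 20 + [500.0] * 59 + [4000.0] * 21)
        res = score_session(sess)
        assert res.n_outliers_removed == 41
        assert not res.valid

    def test_40_percent_exactly_remains_valid(self):
        sess = make_session(rts=[1.0] * 20 + [500.0] * 60 + [4000.0] * 20)
        res = score_session(sess)
        assert res.outlier_pct == pytest.approx(40.0)
        assert res.valid

    def test_moderate_outlier_rate_is_valid(self):
        sess = make_session(rts=[500.0] * 85 + [5000.0] * 15)
        res = score_session(sess)
        assert res.outlier_pct == pytest.approx(15.0)
        assert res.valid

    def test_outlier_trials_leave_accuracy_denominator(self):
        # 10 outlier trials dropped; 47 correct of the remaining 90
        rts = [500.0] * 90 + [5000.0] * 10
        correct = [True] * 47 + [False] * 43 + [True] * 10
        res = score_session(make_session(rts=rts, correct=correct))
        assert res.accuracy == pytest.approx(100 * 47 / 90)

    def test_non_responses_count_against_accuracy(self):
        rts = [500.0] * 90 + [None] * 10
        res = score_session(make_session(rts=rts))
        assert res.accuracy == pytest.approx(90.0)

    def test_aborted_session_refused(self):
        from icatest import Session

        sess = Session(subject_id="s", practice_outcome="aborted",
                       records=[make_trial(i, correct=False, phase="practice_1")
                                for i in range(10)])
        with pytest.raises(ScoringError, match="aborted"):
            score_session(sess)

    def test_practice_trials_never_reach_the_score(self):
        # identical main trials, radically different practice performance
        a = score_session(make_session(rts=[400.0] * 100, practice_correct=10))
        b = score_session(make_session(rts=[400.0] * 100, practice_correct=6))
        assert a == b

    def test_shuffling_trials_changes_only_trends(self, rng):
        rts = list(600.0 + 200 * rng.random(100))
        correct = list(rng.random(100) < 0.85)
        sess = make_session(rts=rts, correct=correct)
        order = rng.permutation(100)
        shuffled = make_session(rts=[rts[i] for i in order],
                                correct=[correct[i] for i in order])
        a, b = score_session(sess), score_session(shuffled)
        assert a.accuracy == pytest.approx(b.accuracy)
        assert a.speed == pytest.approx(b.speed)
        assert a.ica_score == pytest.approx(b.ica_score)

    def test_score_invariants(self, rng):
        for _ in range(20):
            n = 100
            rts = list(np.exp(rng.normal(6.4, 0.3, n)))
            correct = list(rng.random(n) < rng.uniform(0.3, 1.0))
            res = score_session(make_session(rts=rts, correct=correct))
            assert 0 <= res.ica_score <= 100
            assert res.ica_score == pytest.approx(res.speed * res.accuracy / 100)
            assert (res.ica_score == 0) == (res.accuracy == 0)
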