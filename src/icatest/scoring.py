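"""Session scoring: outlier preprocessing, accuracy, speed, and the composite score.

Accuracy is percent correct over the main trials.  Speed maps the mean
reaction time on correctly categorized images through a decaying exponential,

    speed = min(100, 100 * exp(-meanRT / 1025 + 0.341)),

so a mean correct RT of 349.525 ms (= 1025 * 0.341) or faster saturates at
100.  The summary score multiplies the two on a 0-100 scale:

    score = (speed / 100) * (accuracy / 100) * 100.

Before scoring, reaction times beyond the Tukey boxplot fences
(q1 - w*IQR, q3 + w*IQR with w = 1.5) are discarded; if the discarded
fraction exceeds 40% of the observed trials the whole result is flagged
invalid and the test should be repeated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .session import Session, TrialRecord


class ScoringError(ValueError):
    """Invalid input to a scoring operation."""


@dataclass
class ScoringConfig:
    """Constants of the scoring pipeline.

    tau_ms and offset are the decay constant and intercept of the speed
    transform; speed_cap bounds speed at 100; whisker_w is the Tukey fence
    multiplier; invalid_outlier_pct is the validity cutoff (results at
    exactly the cutoff remain valid); trend_window is the minimum number of
    trials required to estimate score trends.
    """

    tau_ms: float = 1025.0
    offset: float = 0.341
    speed_cap: float = 100.0
    whisker_w: float = 1.5
    invalid_outlier_pct: float = 40.0
    trend_window: int = 10

    def __post_init__(self) -> None:
        for name in ("tau_ms", "offset", "speed_cap", "whisker_w", "trend_window"):
            if getattr(self, name) <= 0:
                raise ScoringError(f"{name} must be positive")
        if not 0 < self.invalid_outlier_pct < 100:
            raise ScoringError("invalid_outlier_pct must be in (0, 100)")


@dataclass
class SessionResult:
    """Scored session summary."""

    accuracy: float
    speed: float
    ica_score: float
    mean_correct_rt_ms: float
    n_outliers_removed: int
    outlier_pct: float
    valid: bool
    accuracy_trend: float
    speed_trend: float


def remove_rt_outliers(
    rts: Sequence[float], w: float = 1.5
) -> tuple[np.ndarray, np.ndarray]:
    """Split reaction times into (kept, removed) by the Tukey boxplot fences.

    Quartiles use linear interpolation between order statistics; only values
    strictly beyond a fence are removed, so a degenerate IQR of zero removes
    nothing but exact non-duplicates.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ScoringError("cannot compute fences on an empty RT list")
    q1, q3 = np.percentile(rts, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - w * iqr, q3 + w * iqr
    outlier = (rts < lo) | (rts > hi)
    return rts[~outlier], rts[outlier]


def compute_accuracy(n_correct: int, n_total: int) -> float:
    """Percent correct: 100 * correct / total over the retained main trials."""
    if n_total <= 0:
        raise ScoringError("accuracy needs at least one trial")
    if not 0 <= n_correct <= n_total:
        raise ScoringError("correct count out of range")
    return 100.0 * n_correct / n_total


def compute_speed(mean_correct_rt_ms: float, cfg: ScoringConfig | None = None) -> float:
    """Exponential speed transform of the mean correct reaction time, capped at 100."""
    cfg = cfg or ScoringConfig()
    if mean_correct_rt_ms <= 0:
        raise ScoringError("mean correct RT must be positive")
    raw = 100.0 * math.exp(-mean_correct_rt_ms / cfg.tau_ms + cfg.offset)
    return min(cfg.speed_cap, raw)


def compute_ica_score(speed: float, accuracy: float) -> float:
    """Composite summary score: (speed/100 * accuracy/100) * 100."""
    if not (0 <= speed <= 100 and 0 <= accuracy <= 100):
        raise ScoringError("speed and accuracy must be in [0, 100]")
    return speed / 100.0 * accuracy / 100.0 * 100.0


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        return 0.0
    return float(xc @ (y - y.mean()) / denom)


def compute_trends(
    records: Sequence[TrialRecord], cfg: ScoringConfig | None = None
) -> tuple[float, float]:
    """Within-session performance drift as ordinary-least-squares slopes.

    The accuracy trend regresses per-trial correctness (0/1) on trial index
    over all main trials; the speed trend regresses the per-trial speed
    transform of each correct response's RT on its trial index.  Positive
    slopes mean performance improved over the course of the test.
    """
    cfg = cfg or ScoringConfig()
    records = [r for r in records if r.phase == "main"]
    if len(records) < cfg.trend_window:
        raise ScoringError(
            f"need at least {cfg.trend_window} main trials to estimate trends"
        )
    idx = np.array([r.trial_index for r in records], dtype=float)
    correct = np.array([r.correct for r in records], dtype=float)
    accuracy_trend = _ols_slope(idx, correct)

    corr_resp = [r for r in records if r.correct and r.rt_ms is not None]
    if len(corr_resp) >= 2:
        sp = np.array([compute_speed(r.rt_ms, cfg) for r in corr_resp])
        speed_trend = _ols_slope(
            np.array([r.trial_index for r in corr_resp], dtype=float), sp
        )
    else:
        speed_trend = 0.0
    return accuracy_trend, speed_trend


def score_session(session: Session, cfg: ScoringConfig | None = None) -> SessionResult:
    """Run the full scoring pipeline on a completed session.

    Practice trials are excluded by phase tag.  The Tukey fences are computed
    over the reaction times of all responded main trials; trials whose RT
    falls outside the fences are dropped from both the accuracy denominator
    and the speed computation.  Non-responses count as incorrect and stay in
    the denominator.  The result is flagged invalid when the removed fraction
    of observed main trials exceeds the configured cutoff (default 40%).
    """
    cfg = cfg or ScoringConfig()
    if session.practice_outcome == "aborted":
        raise ScoringError("session was aborted during practice; nothing to score")
    main = session.main_records()
    if not main:
        raise ScoringError("session has no main-phase trials")

    responded = [r for r in main if r.rt_ms is not None]
    non_resp = [r for r in main if r.rt_ms is None]
    if responded:
        rts = np.array([r.rt_ms for r in responded])
        _, removed = remove_rt_outliers(rts, cfg.whisker_w)
        q1, q3 = np.percentile(rts, [25, 75], method="linear")
        iqr = q3 - q1
        lo, hi = q1 - cfg.whisker_w * iqr, q3 + cfg.whisker_w * iqr
        kept_records = [r for r in responded if lo <= r.rt_ms <= hi]
    else:
        removed = np.array([])
        kept_records = []

    n_outliers = len(responded) - len(kept_records)
    assert n_outliers == len(removed)
    outlier_pct = 100.0 * n_outliers / len(main)
    valid = outlier_pct <= cfg.invalid_outlier_pct

    n_total = len(kept_records) + len(non_resp)
    n_correct = sum(r.correct for r in kept_records)
    accuracy = compute_accuracy(n_correct, n_total)

    correct_rts = [r.rt_ms for r in kept_records if r.correct]
    if correct_rts:
        mean_correct_rt = float(np.mean(correct_rts))
        speed = compute_speed(mean_correct_rt, cfg)
    else:
        # no correct responses: speed is undefined; report the floor
        mean_correct_rt = float("nan")
        speed = 0.0

    ica = compute_ica_score(speed, accuracy)

    kept_ids = {id(r) for r in kept_records}
    trend_records = [r for r in main if r.rt_ms is None or id(r) in kept_ids]
    accuracy_trend, speed_trend = compute_trends(trend_records, cfg)

    return SessionResult(
        accuracy=accuracy,
        speed=speed,
        ica_score=ica,
        mean_correct_rt_ms=mean_correct_rt,
        n_outliers_removed=n_outliers,
        outlier_pct=outlier_pct,
        valid=valid,
        accuracy_trend=accuracy_trend,
        speed_trend=speed_trend,
    )
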