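"""Synthetic cohort and trial-level response simulator.

No participant data ship with this package, so every downstream module is
exercised on simulated subjects.  The response model is deliberately minimal
but touches every branch of the scoring pipeline:

* accuracy — per trial, P(correct) = (1 - lapse) * sigmoid(ability -
  gain * (difficulty - 1/2)) + lapse / 2, a logistic psychometric function
  of the image's difficulty with a symmetric lapse floor;
* reaction time — a shifted lognormal, rt = shift + exp(mu + gamma *
  difficulty + eps), eps ~ N(0, sigma^2), so harder images are slower;
* contaminants — with a small probability each RT is replaced by a uniform
  draw from [3000, 10000] ms, emulating distracted trials that the Tukey
  fences must catch.

Subjects within a group share a latent cognitive factor: it raises or lowers
categorization ability, response speed, and the battery subtest scores
together, which is what makes impairment labels learnable from the test
features.  Group-level parameter distributions are calibrated by iterated
moment matching so the simulated summary-score distributions reproduce the
reference group means/SDs (MS 63.67 +/- 13.30, HC 78.43 +/- 9.86 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .psychometrics import SubjectRecord
from .scoring import ScoringConfig, SessionResult, score_session
from .session import Session, TrialRecord, resolve_practice_outcome
from .stimulus import StimulusSet, TrialSchedule

#: Logistic slope mapping the difficulty scalar in [0, 1] onto logit units.
DIFFICULTY_GAIN = 4.0
#: Log-ms RT penalty per unit difficulty (harder images are slower).
DIFFICULTY_RT_GAMMA = 0.3
#: Contaminant RT range (ms).
OUTLIER_RT_RANGE = (3000.0, 10000.0)


class SimulationError(ValueError):
    """Invalid simulator configuration or unattainable calibration target."""


@dataclass
class SubjectParams:
    """Generative parameters for one simulated participant."""

    ability: float              # logit units; higher = more accurate
    rt_mu: float                # log-ms location of the lognormal RT component
    rt_sigma: float = 0.25      # log-ms trial-to-trial RT noise
    rt_shift_ms: float = 200.0  # irreducible sensory/motor latency
    lapse_prob: float = 0.02    # attention-lapse rate (random guess)
    outlier_prob: float = 0.02  # contaminant-trial rate

    def __post_init__(self) -> None:
        if self.rt_sigma <= 0:
            raise SimulationError("rt_sigma must be positive")
        if self.rt_shift_ms < 0:
            raise SimulationError("rt_shift_ms must be non-negative")
        if not 0 <= self.lapse_prob <= 0.2:
            raise SimulationError("lapse_prob must be in [0, 0.2]")
        if not 0 <= self.outlier_prob <= 0.5:
            raise SimulationError("outlier_prob must be in [0, 0.5]")


@dataclass
class GroupParams:
    """Population distribution of :class:`SubjectParams` within one group.

    A standard-normal latent cognitive factor is shared (with loading
    ``cog_loading``) between ability and log-RT, and re-used for the battery
    subtest scores, so all cognitive measures co-vary within a subject.
    """

    ability_mu: float
    ability_sd: float
    rtmu_mu: float
    rtmu_sd: float
    rt_sigma: float = 0.25
    rt_shift_ms: float = 200.0
    lapse_prob: float = 0.02
    outlier_prob: float = 0.02
    cog_loading: float = 0.9

    def sample(self, cog: float, rng: np.random.Generator) -> SubjectParams:
        lam = self.cog_loading
        resid = np.sqrt(1.0 - lam**2)
        f_ab = lam * cog + resid * rng.standard_normal()
        f_rt = lam * cog + resid * rng.standard_normal()
        return SubjectParams(
            ability=self.ability_mu + self.ability_sd * f_ab,
            rt_mu=self.rtmu_mu - self.rtmu_sd * f_rt,
            rt_sigma=self.rt_sigma,
            rt_shift_ms=self.rt_shift_ms,
            lapse_prob=self.lapse_prob,
            outlier_prob=self.outlier_prob,
        )


# Group parameter values produced by calibrate_group_params against the
# reference summary-score targets (see docs/methods.md).
DEFAULT_MS_PARAMS = GroupParams(
    ability_mu=2.414, ability_sd=0.913, rtmu_mu=5.937, rtmu_sd=0.274)
DEFAULT_HC_PARAMS = GroupParams(
    ability_mu=3.264, ability_sd=0.801, rtmu_mu=5.560, rtmu_sd=0.240)


@dataclass
class GroupConfig:
    """Demographics and battery-score distributions for one cohort group."""

    params: GroupParams
    age_mean: float
    age_sd: float
    educ_mean: float
    educ_sd: float
    female_frac: float
    bicams_mean: dict[str, float]
    bicams_sd: dict[str, float]
    bicams_loading: float = 0.8
    edss_mean: Optional[float] = None
    edss_sd: Optional[float] = None
    duration_mean: Optional[float] = None
    duration_sd: Optional[float] = None


def default_ms_group() -> GroupConfig:
    return GroupConfig(
        params=replace(DEFAULT_MS_PARAMS),
        age_mean=37.24, age_sd=10.2, educ_mean=14.21, educ_sd=3.16,
        female_frac=0.82,
        bicams_mean={"sdmt": 41.04, "bvmtr": 21.89, "cvlt2": 48.96},
        bicams_sd={"sdmt": 11.02, "bvmtr": 6.95, "cvlt2": 11.13},
        edss_mean=1.27, edss_sd=1.8, duration_mean=6.8, duration_sd=4.0,
    )


def default_hc_group() -> GroupConfig:
    return GroupConfig(
        params=replace(DEFAULT_HC_PARAMS),
        age_mean=36.0, age_sd=10.0, educ_mean=14.81, educ_sd=2.5,
        female_frac=0.70,
        bicams_mean={"sdmt": 54.73, "bvmtr": 23.69, "cvlt2": 58.28},
        bicams_sd={"sdmt": 9.77, "bvmtr": 5.17, "cvlt2": 6.59},
    )


@dataclass
class SimConfig:
    """Full cohort-simulation configuration.

    NfL (a serum neurodegeneration marker, recorded for the patient group
    only) is generated as a noisy negative-linear function of the summary
    score; the default noise SD puts the population correlation near -0.79.
    """

    n_ms: int = 91
    n_hc: int = 83
    ms: GroupConfig = field(default_factory=default_ms_group)
    hc: GroupConfig = field(default_factory=default_hc_group)
    nfl_beta0: float = 110.0
    nfl_beta1: float = -1.0
    nfl_noise_sd: float = 10.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ms <= 0 or self.n_hc <= 0:
            raise SimulationError("group sizes must be positive")
        if self.nfl_beta1 > 0:
            raise SimulationError("nfl_beta1 must be non-positive")


# ---------------------------------------------------------------------------
# Trial-level simulation
# ---------------------------------------------------------------------------

def _p_correct(params: SubjectParams, difficulty: float) -> float:
    logit = params.ability - DIFFICULTY_GAIN * (difficulty - 0.5)
    base = 1.0 / (1.0 + np.exp(-logit))
    return (1.0 - params.lapse_prob) * base + params.lapse_prob / 2.0


def _draw_rt(params: SubjectParams, difficulty: float,
             rng: np.random.Generator) -> float:
    if rng.random() < params.outlier_prob:
        return float(rng.uniform(*OUTLIER_RT_RANGE))
    eps = rng.normal(0.0, params.rt_sigma)
    return params.rt_shift_ms + float(
        np.exp(params.rt_mu + DIFFICULTY_RT_GAMMA * difficulty + eps))


def _other_label(label: str) -> str:
    return "non_animal" if label == "animal" else "animal"


def _simulate_block(params: SubjectParams, stimset: StimulusSet, image_ids,
                    phase: str, start_index: int,
                    rng: np.random.Generator) -> list[TrialRecord]:
    lookup = {stimset.image_ids[i]: i for i in range(len(stimset.image_ids))}
    records = []
    for k, image_id in enumerate(image_ids):
        i = lookup[image_id]
        label = stimset.labels[i]
        correct = bool(rng.random() < _p_correct(params, stimset.difficulty[i]))
        response = label if correct else _other_label(label)
        rt = _draw_rt(params, stimset.difficulty[i], rng)
        records.append(TrialRecord.model_construct(
            trial_index=start_index + k, image_id=image_id, true_label=label,
            phase=phase, response=response, correct=correct, rt_ms=rt))
    return records


def simulate_session(params: SubjectParams, stimset: StimulusSet,
                     schedule: TrialSchedule, rng: np.random.Generator,
                     subject_id: str = "sim") -> Session:
    """Generate a full administration: practice gate, retry rule, main task.

    The same response model drives practice and main trials, so low-ability
    subjects can genuinely fail the practice gate and abort.
    Deterministic for a fixed random generator state.
    """
    records: list[TrialRecord] = []
    p1_ids = [stimset.image_ids[i] for i in stimset.indices_of_role("practice_1")]
    block1 = _simulate_block(params, stimset, p1_ids, "practice_1", 0, rng)
    records.extend(block1)
    from .session import evaluate_practice
    block2 = None
    if evaluate_practice(block1) == "fail":
        p2_ids = [stimset.image_ids[i] for i in stimset.indices_of_role("practice_2")]
        block2 = _simulate_block(params, stimset, p2_ids, "practice_2",
                                 len(records), rng)
        records.extend(block2)
    outcome = resolve_practice_outcome(block1, block2)
    if outcome != "aborted":
        records.extend(_simulate_block(params, stimset, schedule.image_ids,
                                       "main", len(records), rng))
    return Session(subject_id=subject_id, schedule_ref=f"seed:{schedule.order_seed}",
                   practice_outcome=outcome, records=records)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    """Simulated cohort: subject table, raw sessions, and scored results.

    ``results[i]`` is None for the (rare) subject whose session aborted at
    the practice gate.
    """

    subjects: list[SubjectRecord]
    sessions: list[Session]
    results: list[Optional[SessionResult]]
    params: list[SubjectParams]
    latent_cog: np.ndarray

    def frame(self) -> pd.DataFrame:
        rows = []
        for s, res in zip(self.subjects, self.results):
            row = dict(s.__dict__)
            if res is not None:
                row.update(ica_score=res.ica_score, accuracy=res.accuracy,
                           speed=res.speed, accuracy_trend=res.accuracy_trend,
                           speed_trend=res.speed_trend, valid=res.valid)
            else:
                row.update(ica_score=np.nan, accuracy=np.nan, speed=np.nan,
                           accuracy_trend=np.nan, speed_trend=np.nan, valid=False)
            rows.append(row)
        return pd.DataFrame(rows)


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def simulate_cohort(cfg: SimConfig, stimset: Optional[StimulusSet] = None,
                    scoring_cfg: Optional[ScoringConfig] = None) -> CohortData:
    """Sample both groups, run each subject's session, and score it.

    Battery subtest scores are drawn from the group's normal distributions,
    coupled to the subject's latent cognitive factor by ``bicams_loading``;
    NfL is attached to patient-group subjects from the configured linear
    model on the summary score.  Bit-exact for a fixed config seed.
    """
    from .stimulus import build_trial_schedule, generate_mask_pool, generate_stimulus_set

    rng = np.random.default_rng(cfg.seed)
    if stimset is None:
        stimset = generate_stimulus_set(seed=int(rng.integers(2**31)))
    pool = generate_mask_pool(64, seed=int(rng.integers(2**31)))
    scoring_cfg = scoring_cfg or ScoringConfig()

    subjects, sessions, results, all_params = [], [], [], []
    cogs = []
    for group_name, gcfg, n in (("MS", cfg.ms, cfg.n_ms), ("HC", cfg.hc, cfg.n_hc)):
        for j in range(n):
            sid = f"{group_name}{j:03d}"
            cog = float(rng.standard_normal())
            params = gcfg.params.sample(cog, rng)
            schedule = build_trial_schedule(stimset, pool,
                                            order_seed=int(rng.integers(2**31)))
            session = simulate_session(params, stimset, schedule, rng, subject_id=sid)
            result = (score_session(session, scoring_cfg)
                      if session.practice_outcome != "aborted" else None)

            lam = gcfg.bicams_loading
            resid = np.sqrt(1.0 - lam**2)
            scores = {}
            for name in ("sdmt", "bvmtr", "cvlt2"):
                z = lam * cog + resid * rng.standard_normal()
                scores[name] = gcfg.bicams_mean[name] + gcfg.bicams_sd[name] * z

            edss = duration = nfl = None
            if gcfg.edss_mean is not None:
                edss = float(_truncnorm(rng, gcfg.edss_mean, gcfg.edss_sd, 0, 10))
            if gcfg.duration_mean is not None:
                duration = float(np.maximum(
                    rng.normal(gcfg.duration_mean, gcfg.duration_sd), 0.0))
            if group_name == "MS" and result is not None:
                nfl = float(cfg.nfl_beta0 + cfg.nfl_beta1 * result.ica_score
                            + rng.normal(0.0, cfg.nfl_noise_sd))

            subjects.append(SubjectRecord(
                subject_id=sid, group=group_name,
                age=float(_truncnorm(rng, gcfg.age_mean, gcfg.age_sd, 18, 65)),
                gender="female" if rng.random() < gcfg.female_frac else "male",
                education=float(_truncnorm(rng, gcfg.educ_mean, gcfg.educ_sd, 5, 24)),
                sdmt=scores["sdmt"], bvmtr=scores["bvmtr"], cvlt2=scores["cvlt2"],
                edss=edss, nfl=nfl, disease_duration=duration,
            ))
            sessions.append(session)
            results.append(result)
            all_params.append(params)
            cogs.append(cog)
    return CohortData(subjects=subjects, sessions=sessions, results=results,
                      params=all_params, latent_cog=np.asarray(cogs))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

_ABILITY_BOUNDS = (-4.0, 6.0)
_RTMU_BOUNDS = (np.log(50.0), np.log(2000.0))
_SPREAD_BOUNDS = (0.05, 4.0)


class CalibrationError(SimulationError):
    """Target moments unattainable; carries the best achieved moments."""

    def __init__(self, msg: str, achieved_mean: float, achieved_sd: float):
        super().__init__(f"{msg} (achieved mean={achieved_mean:.2f}, sd={achieved_sd:.2f})")
        self.achieved_mean = achieved_mean
        self.achieved_sd = achieved_sd


def _simulate_group_scores(gp: GroupParams, n: int, stimset: StimulusSet,
                           schedule: TrialSchedule, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n):
        params = gp.sample(float(rng.standard_normal()), rng)
        session = simulate_session(params, stimset, schedule, rng, subject_id=f"cal{j}")
        if session.practice_outcome == "aborted":
            continue
        res = score_session(session)
        rows.append((res.ica_score, res.accuracy, res.speed))
    return pd.DataFrame(rows, columns=["ica", "accuracy", "speed"])


def calibrate_group_params(
    target_mean: float,
    target_sd: float,
    base: Optional[GroupParams] = None,
    *,
    n_sim: int = 400,
    tol_mean: float = 1.0,
    tol_sd: float = 1.5,
    max_iter: int = 30,
    seed: int = 0,
) -> tuple[GroupParams, float, float]:
    """Tune a group's parameter distribution to hit summary-score moments.

    Iterated moment matching with common random numbers: each round simulates
    ``n_sim`` subjects through the full session/scoring pipeline, then (a)
    nudges mean ability toward an accuracy target implied by the score
    target, (b) applies a Newton-style correction to the log-RT location
    using the inverse of the speed transform, and (c) rescales the ability
    and log-RT spreads by the SD ratio.  Returns the calibrated distribution
    and the achieved (mean, sd).

    Raises :class:`CalibrationError` when the target cannot be reached
    within the parameter bounds (e.g. a zero-SD target: trial-level noise
    puts a floor on the score SD).
    """
    if not 0 < target_mean < 100:
        raise SimulationError("target_mean must be in (0, 100)")
    if target_sd < 0:
        raise SimulationError("target_sd must be non-negative")

    from .stimulus import build_trial_schedule, generate_mask_pool, generate_stimulus_set

    stimset = generate_stimulus_set(seed=seed + 1)
    pool = generate_mask_pool(64, seed=seed + 2)
    schedule = build_trial_schedule(stimset, pool, order_seed=seed + 3)

    gp = replace(base) if base is not None else GroupParams(
        ability_mu=2.0, ability_sd=1.0, rtmu_mu=6.0, rtmu_sd=0.3)
    spread = 1.0
    base_ab_sd, base_rt_sd = gp.ability_sd, gp.rtmu_sd

    # split the score target into implied accuracy and speed components
    acc_target = 100.0 * (target_mean / 100.0) ** 0.35
    speed_target = min(99.0, 100.0 * target_mean / acc_target)
    achieved_mean = achieved_sd = float("nan")

    for it in range(max_iter):
        sim = _simulate_group_scores(gp, n_sim, stimset, schedule, seed=seed + 10)
        if len(sim) < 2:
            raise CalibrationError("all simulated sessions aborted", float("nan"), float("nan"))
        achieved_mean = float(sim["ica"].mean())
        achieved_sd = float(sim["ica"].std(ddof=1))
        if abs(achieved_mean - target_mean) <= 0.5 * tol_mean and \
           abs(achieved_sd - target_sd) <= 0.75 * tol_sd:
            return gp, achieved_mean, achieved_sd

        # (a) ability toward the implied accuracy component
        acc_ach = float(sim["accuracy"].mean())
        gp.ability_mu = float(np.clip(
            gp.ability_mu + 0.05 * (acc_target - acc_ach), *_ABILITY_BOUNDS))
        # (b) log-RT location via the inverted speed transform (Newton-style)
        speed_ach = float(np.clip(sim["speed"].mean(), 1e-3, 99.9))
        rt_target = 1025.0 * (0.341 - np.log(speed_target / 100.0))
        rt_ach = 1025.0 * (0.341 - np.log(speed_ach / 100.0))
        num = max(rt_target - gp.rt_shift_ms, 30.0)
        den = max(rt_ach - gp.rt_shift_ms, 30.0)
        gp.rtmu_mu = float(np.clip(gp.rtmu_mu + 0.8 * np.log(num / den), *_RTMU_BOUNDS))
        # (c) spread toward the SD target
        if target_sd > 0 and achieved_sd > 0:
            spread = float(np.clip(spread * np.clip(target_sd / achieved_sd, 0.6, 1.6),
                                   *_SPREAD_BOUNDS))
        elif target_sd == 0:
            spread = _SPREAD_BOUNDS[0]
        gp.ability_sd = base_ab_sd * spread
        gp.rtmu_sd = base_rt_sd * spread

    if abs(achieved_mean - target_mean) <= tol_mean and \
       abs(achieved_sd - target_sd) <= tol_sd:
        return gp, achieved_mean, achieved_sd
    raise CalibrationError(
        f"could not reach target mean={target_mean}, sd={target_sd}",
        achieved_mean, achieved_sd)
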