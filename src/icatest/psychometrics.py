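"""Cohort-level statistics: impairment labelling, effect sizes, reliability.

Cognitive impairment is defined against a normative table for the three
battery subtests (SDMT, BVMT-R, CVLT-II): severe abnormality on any one
subtest (z at or below -2) or mild abnormality (z at or below -1) on at
least two subtests.  Effect sizes use Cohen's d with the simple-average
pooled SD, sqrt((s_a^2 + s_b^2)/2); correlations are Pearson product-moment
with two-sided p from the t transform; test-retest reliability is banded
"adequate" above 0.70 and "good" above 0.80 (strict inequalities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SUBTESTS = ("sdmt", "bvmtr", "cvlt2")


class PsychometricsError(ValueError):
    """Invalid input to a psychometric computation."""


@dataclass
class SubjectRecord:
    """Demographics, battery scores and optional clinical measures for one subject."""

    subject_id: str
    group: str                      # "MS" or "HC"
    age: float
    gender: str                     # "female" or "male"
    education: float
    sdmt: float
    bvmtr: float
    cvlt2: float
    edss: Optional[float] = None
    nfl: Optional[float] = None
    disease_duration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.edss is not None and not 0 <= self.edss <= 10:
            raise PsychometricsError(f"EDSS {self.edss} outside the 0-10 scale")


@dataclass
class NormTable:
    """Normative mean/SD per subtest; SDs must be positive."""

    sdmt: tuple[float, float]
    bvmtr: tuple[float, float]
    cvlt2: tuple[float, float]

    def __post_init__(self) -> None:
        for name in SUBTESTS:
            _, sd = getattr(self, name)
            if sd <= 0:
                raise PsychometricsError(f"norm SD for {name} must be positive")

    def z(self, subtest: str, score: float) -> float:
        mean, sd = getattr(self, subtest)
        return (score - mean) / sd


def label_impairment(subject: SubjectRecord, norms: NormTable) -> bool:
    """Impaired iff any subtest z <= -2, or at least two subtests with z <= -1.

    The boundary is inclusive at both cutoffs (a score exactly 2 SD below
    the norm counts as severe abnormality).
    """
    zs = []
    for name in SUBTESTS:
        score = getattr(subject, name)
        if score is None or (isinstance(score, float) and math.isnan(score)):
            raise PsychometricsError(f"subject {subject.subject_id}: missing {name}")
        zs.append(norms.z(name, score))
    severe = any(z <= -2.0 for z in zs)
    mild = sum(z <= -1.0 for z in zs) >= 2
    return severe or mild


def cohens_d_from_stats(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Cohen's d from group summaries: (mean_b - mean_a) / sqrt((sd_a^2 + sd_b^2)/2)."""
    if sd_a <= 0 or sd_b <= 0:
        raise PsychometricsError("group SDs must be positive")
    return (mean_b - mean_a) / math.sqrt((sd_a**2 + sd_b**2) / 2.0)


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Cohen's d between two samples (n-1 SDs, simple-average pooling)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise PsychometricsError("each group needs at least 2 observations")
    sd_a, sd_b = a.std(ddof=1), b.std(ddof=1)
    if sd_a == 0 and sd_b == 0:
        if a.mean() == b.mean():
            return 0.0
        raise PsychometricsError("degenerate groups with zero variance")
    return cohens_d_from_stats(a.mean(), sd_a, b.mean(), sd_b)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise PsychometricsError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise PsychometricsError("constant vector has no defined correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def composite_z(cohort: Sequence[SubjectRecord]) -> np.ndarray:
    """Battery composite: mean of the three subtest z-scores against the cohort.

    Each subtest is standardized by the cohort's own mean and SD (n-1), then
    the three z-scores are averaged per subject; the composite is therefore
    centered at zero over the cohort by construction.
    """
    if len(cohort) < 2:
        raise PsychometricsError("composite z-scores need at least 2 subjects")
    scores = np.array([[getattr(s, name) for name in SUBTESTS] for s in cohort],
                      dtype=float)
    sd = scores.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = SUBTESTS[int(np.flatnonzero(sd == 0)[0])]
        raise PsychometricsError(f"zero variance in subtest {bad}")
    z = (scores - scores.mean(axis=0)) / sd
    return z.mean(axis=1)


@dataclass
class GroupComparison:
    t: float
    p: float
    d: float
    paired: bool


def group_compare(a: Sequence[float], b: Sequence[float], paired: bool = False) -> GroupComparison:
    """Student t-test (pooled-variance two-sample, or paired) with Cohen's d.

    For paired data d is the mean difference over the SD of differences; a
    zero-variance difference vector yields d = 0 with an undefined-safe
    t/p of 0/1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise PsychometricsError("each sample needs n >= 2")
    if paired:
        if a.size != b.size:
            raise PsychometricsError("paired samples must have equal length")
        diff = b - a
        sd = diff.std(ddof=1)
        if sd == 0:
            return GroupComparison(t=0.0, p=1.0, d=0.0, paired=True)
        t, p = stats.ttest_rel(b, a)
        return GroupComparison(t=float(t), p=float(p), d=float(diff.mean() / sd), paired=True)
    t, p = stats.ttest_ind(b, a, equal_var=True)
    return GroupComparison(t=float(t), p=float(p), d=cohens_d(a, b), paired=False)


@dataclass
class RetestResult:
    r: float
    p: float
    band: str   # "good" (> 0.80), "adequate" (> 0.70), else "poor"


def test_retest(scores_t1: Sequence[float], scores_t2: Sequence[float]) -> RetestResult:
    """Test-retest reliability: Pearson r between two administrations, banded."""
    r, p = pearson_r(scores_t1, scores_t2)
    if r > 0.80:
        band = "good"
    elif r > 0.70:
        band = "adequate"
    else:
        band = "poor"
    return RetestResult(r=r, p=p, band=band)


# ---------------------------------------------------------------------------
# Cohort table I/O
# ---------------------------------------------------------------------------

def cohort_to_frame(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in cohort])


def cohort_from_frame(df: pd.DataFrame) -> list[SubjectRecord]:
    records = []
    for row in df.to_dict("records"):
        for opt in ("edss", "nfl", "disease_duration"):
            v = row.get(opt)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                row[opt] = None
        records.append(SubjectRecord(**{k: row[k] for k in SubjectRecord.__dataclass_fields__
                                        if k in row}))
    return records


def load_cohort_csv(path) -> list[SubjectRecord]:
    return cohort_from_frame(pd.read_csv(path))


def save_cohort_csv(cohort: Sequence[SubjectRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)
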