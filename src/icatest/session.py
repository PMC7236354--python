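"""Test-administration records: trials, the practice gate, and persistence.

A session starts with a 10-image practice block.  Above-chance performance
(strictly more than 50% correct) admits the participant to the 100-image main
task; at-or-below-chance performance triggers one retry with a fresh practice
block, and a second failure aborts the session.  Practice trials carry phase
tags so the scorer can exclude them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, ValidationError, model_validator

SESSION_FORMAT_VERSION = 1

Phase = Literal["practice_1", "practice_2", "main"]
Label = Literal["animal", "non_animal"]
Response = Literal["animal", "non_animal", "none"]
PracticeOutcome = Literal["passed_first", "passed_second", "aborted"]

PRACTICE_BLOCK_SIZE = 10
PRACTICE_PASS_FRACTION = 0.5  # strictly-greater-than threshold


class SessionFormatError(ValueError):
    """Session file violates the schema; message names the offending field."""


class TrialRecord(BaseModel):
    """One stimulus presentation with the participant's response.

    ``correct`` is derived: true iff the response equals the true label; a
    non-response is never correct and carries no reaction time.
    """

    trial_index: int = Field(ge=0)
    image_id: str
    true_label: Label
    phase: Phase
    response: Response
    correct: bool
    rt_ms: Optional[float] = None

    @model_validator(mode="after")
    def _check_consistency(self) -> "TrialRecord":
        if self.correct != (self.response == self.true_label):
            raise ValueError(
                f"trial {self.trial_index}: correct={self.correct} inconsistent "
                f"with response={self.response!r} vs true_label={self.true_label!r}"
            )
        if self.response == "none":
            if self.rt_ms is not None:
                raise ValueError(f"trial {self.trial_index}: non-response must not carry rt_ms")
        else:
            if self.rt_ms is None:
                raise ValueError(f"trial {self.trial_index}: responded trial is missing rt_ms")
            if self.rt_ms <= 0:
                raise ValueError(f"trial {self.trial_index}: rt_ms must be positive")
        return self


class Session(BaseModel):
    """An ordered run of trial records for one subject."""

    subject_id: str
    schedule_ref: str = ""
    practice_outcome: PracticeOutcome
    records: list[TrialRecord]
    format_version: int = SESSION_FORMAT_VERSION

    @model_validator(mode="after")
    def _check_structure(self) -> "Session":
        n_main = sum(r.phase == "main" for r in self.records)
        if self.practice_outcome == "aborted" and n_main > 0:
            raise ValueError("aborted session must not contain main-phase records")
        for phase in ("practice_1", "practice_2"):
            n = sum(r.phase == phase for r in self.records)
            if n not in (0, PRACTICE_BLOCK_SIZE):
                raise ValueError(f"{phase} block has {n} records, expected 0 or {PRACTICE_BLOCK_SIZE}")
        return self

    def main_records(self) -> list[TrialRecord]:
        return [r for r in self.records if r.phase == "main"]

    def practice_records(self, which: Phase) -> list[TrialRecord]:
        return [r for r in self.records if r.phase == which]


def evaluate_practice(block: list[TrialRecord]) -> str:
    """Gate a 10-trial practice block: 'pass' iff strictly above chance.

    Exactly half correct counts as chance-level performance and fails.
    """
    if len(block) != PRACTICE_BLOCK_SIZE:
        raise ValueError(f"practice block must have {PRACTICE_BLOCK_SIZE} trials, got {len(block)}")
    n_correct = sum(r.correct for r in block)
    return "pass" if n_correct / PRACTICE_BLOCK_SIZE > PRACTICE_PASS_FRACTION else "fail"


def resolve_practice_outcome(
    block1: list[TrialRecord],
    block2: Optional[list[TrialRecord]] = None,
) -> PracticeOutcome:
    """Apply the two-attempt practice rule.

    A passed first block admits immediately; a failed first block is followed
    by one retry, and a second failure aborts the test.
    """
    first = evaluate_practice(block1)
    if first == "pass":
        if block2 is not None:
            raise ValueError("second practice block supplied although the first passed")
        return "passed_first"
    if block2 is None:
        return "aborted"
    return "passed_second" if evaluate_practice(block2) == "pass" else "aborted"


def save_session(session: Session, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(session.model_dump_json(indent=2))
    return path


def load_session(path: str | Path) -> Session:
    """Parse and schema-validate a session JSON file.

    Raises :class:`SessionFormatError` with the field path of the first
    violation (e.g. a responded trial that lacks its reaction time).
    """
    raw = Path(path).read_text()
    try:
        data = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise SessionFormatError(f"not valid JSON: {exc}") from exc
    try:
        return Session.model_validate(data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise SessionFormatError(f"invalid session at {loc}: {first['msg']}") from exc


def session_to_frame(session: Session) -> pd.DataFrame:
    """Trial-level table with one row per presentation."""
    return pd.DataFrame(
        [
            {
                "trial_index": r.trial_index,
                "image_id": r.image_id,
                "true_label": r.true_label,
                "phase": r.phase,
                "response": r.response,
                "correct": r.correct,
                "rt_ms": r.rt_ms,
            }
            for r in session.records
        ]
    )


def export_trials_csv(session: Session, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    session_to_frame(session).to_csv(path, index=False)
    return path
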