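"""Ordinal scoring of the seven football training indicators.

A training session is summarised by seven ordinal indicators drawn from
Event-Group training theory, which splits competitive ability into
physical-fitness factors (strength, speed, endurance) and skill factors:

====  =========================  ==============
key   indicator                  allowed scores
====  =========================  ==============
STT   strength training          0, 5, 10
SPT   speed training             0, 10
ENT   endurance training         0, 5, 10
RET   regional training          0, 5, 10
RST   resisted-stress training   0, 10
RCT   recovery training          5, 10
BST   basic-skill training       0, 10
====  =========================  ==============

Scores are awarded from a :class:`SessionLog`, a record of what the athlete
actually completed in the session.  The rules are deliberately simple and
auditable: quotas are minimum counts, the speed cut-off and the physiological
recovery standards are judged upstream by whoever fills in the log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from .errors import ScoreValidationError

__all__ = [
    "INDICATORS",
    "LEVEL_SETS",
    "SessionLog",
    "IndicatorScores",
    "score_indicator",
    "score_session",
    "read_logs",
]

#: Indicator keys in canonical order (column order of the score tables).
INDICATORS: tuple[str, ...] = ("STT", "SPT", "ENT", "RET", "RST", "RCT", "BST")

#: Allowed score levels per indicator.  RCT has no 0 level: even a slow
#: recovery earns 5 points.
LEVEL_SETS: dict[str, tuple[int, ...]] = {
    "STT": (0, 5, 10),
    "SPT": (0, 10),
    "ENT": (0, 5, 10),
    "RET": (0, 5, 10),
    "RST": (0, 10),
    "RCT": (5, 10),
    "BST": (0, 10),
}

ENDURANCE_TYPES = frozenset({"aerobic", "anaerobic", "hybrid"})
REGIONAL_TYPES = frozenset({"barrier_free", "obstacle"})


@dataclass(frozen=True)
class SessionLog:
    """What one athlete completed in one training session.

    Counts are completed bouts within the session window; the sprint cut-off
    and the basic-skill standard are pass/fail judgements made by the coach;
    recovery times are in minutes.
    """

    moderate_strength_bouts: int = 0
    high_strength_bouts: int = 0
    sprint_within_time: bool = False
    endurance_types_completed: frozenset[str] = field(default_factory=frozenset)
    regional_completed: frozenset[str] = field(default_factory=frozenset)
    stress_test_passed: bool = False
    recovery_time: float = 30.0
    group_mean_recovery_time: float = 30.0
    basic_skills_standard: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "endurance_types_completed", frozenset(self.endurance_types_completed)
        )
        object.__setattr__(self, "regional_completed", frozenset(self.regional_completed))
        if self.moderate_strength_bouts < 0 or self.high_strength_bouts < 0:
            raise ValueError("strength bout counts must be >= 0")
        if not (self.recovery_time > 0 and self.group_mean_recovery_time > 0):
            raise ValueError("recovery times must be > 0")
        unknown = self.endurance_types_completed - ENDURANCE_TYPES
        if unknown:
            raise ValueError(f"unknown endurance types: {sorted(unknown)}")
        unknown = self.regional_completed - REGIONAL_TYPES
        if unknown:
            raise ValueError(f"unknown regional conditions: {sorted(unknown)}")


@dataclass(frozen=True)
class IndicatorScores:
    """The seven scores of one session, in canonical indicator order."""

    scores: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", tuple(int(s) for s in self.scores))
        if len(self.scores) != len(INDICATORS):
            raise ScoreValidationError(
                f"expected {len(INDICATORS)} scores, got {len(self.scores)}"
            )
        for key, value in zip(INDICATORS, self.scores):
            if value not in LEVEL_SETS[key]:
                raise ScoreValidationError(
                    f"score {value} not allowed for {key}; levels are {LEVEL_SETS[key]}"
                )

    def __getitem__(self, key: str) -> int:
        return self.scores[INDICATORS.index(key)]

    def __iter__(self):
        return iter(self.scores)

    @property
    def total(self) -> int:
        return sum(self.scores)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(INDICATORS, self.scores))


def score_indicator(log: SessionLog, indicator: str) -> int:
    """Score one indicator from a session log.

    STT requires 6 moderate-intensity and 3 high-intensity bouts for the full
    10 points (5 if only one quota is met); ENT requires all three endurance
    types (5 for exactly two); RET requires both the barrier-free and the
    obstacle condition (5 for one); SPT, RST and BST are pass/fail at 10/0;
    RCT awards 5 when recovery is strictly slower than the group average,
    10 otherwise.
    """
    if indicator == "STT":
        met = (log.moderate_strength_bouts >= 6) + (log.high_strength_bouts >= 3)
        return (0, 5, 10)[met]
    if indicator == "SPT":
        return 10 if log.sprint_within_time else 0
    if indicator == "ENT":
        done = len(log.endurance_types_completed & ENDURANCE_TYPES)
        return 10 if done == 3 else (5 if done == 2 else 0)
    if indicator == "RET":
        done = len(log.regional_completed & REGIONAL_TYPES)
        return (0, 5, 10)[done]
    if indicator == "RST":
        return 10 if log.stress_test_passed else 0
    if indicator == "RCT":
        # "slower than average" is strict; exactly average still earns 10.
        return 5 if log.recovery_time > log.group_mean_recovery_time else 10
    if indicator == "BST":
        return 10 if log.basic_skills_standard else 0
    raise ValueError(f"unknown indicator key {indicator!r}; expected one of {INDICATORS}")


def score_session(log: SessionLog) -> IndicatorScores:
    """Apply all seven scoring rules to one session log."""
    return IndicatorScores(tuple(score_indicator(log, key) for key in INDICATORS))


_BOOL_FIELDS = ("sprint_within_time", "stress_test_passed", "basic_skills_standard")
_SET_FIELDS = ("endurance_types_completed", "regional_completed")


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and not math.isnan(value):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "yes", "1", "y"}:
        return True
    if text in {"false", "no", "0", "n", "", "nan"}:
        return False
    raise ValueError(f"cannot parse boolean value {value!r}")


def _parse_set(value) -> frozenset[str]:
    if isinstance(value, float) and math.isnan(value):
        return frozenset()
    text = str(value).strip()
    if not text:
        return frozenset()
    parts = text.replace(";", "|").split("|")
    return frozenset(p.strip() for p in parts if p.strip())


def read_logs(source: str | Path) -> list[SessionLog]:
    """Read raw session logs from CSV, one log per row.

    Columns are named after :class:`SessionLog` fields; the two set-valued
    columns hold ``|``- or ``;``-separated entries.  Missing columns take the
    field defaults.
    """
    frame = pd.read_csv(source)
    known = {f.name for f in fields(SessionLog)}
    logs = []
    for _, row in frame.iterrows():
        kwargs = {}
        for name in frame.columns:
            if name not in known:
                continue
            value = row[name]
            if name in _BOOL_FIELDS:
                kwargs[name] = _parse_bool(value)
            elif name in _SET_FIELDS:
                kwargs[name] = _parse_set(value)
            elif name in ("recovery_time", "group_mean_recovery_time"):
                kwargs[name] = float(value)
            else:
                kwargs[name] = int(value)
        logs.append(SessionLog(**kwargs))
    return logs
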