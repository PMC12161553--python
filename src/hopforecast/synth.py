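"""Synthetic athlete training-score tables.

Emulates the design of the study dataset: a squad of athletes trains
several sessions per day over a number of days, and each session is scored
on the seven ordinal indicators (defaults: 20 athletes × 30 days × 4
sessions/day = 2400 rows × 7 columns).

The generative model has two latent levels.  Each athlete draws a
persistent ability a ~ N(0, ability_sd²); each session additionally draws a
shared readiness shock η ~ N(0, session_sd²) (the athlete's "good day / bad
day"), and each indicator adds unit-variance idiosyncratic noise.  The
resulting latent value a + η + e is cut into the indicator's allowed score
levels at fixed population quantiles — three-level indicators score
0/5/10 with frequencies 45/10/45 %, two-level indicators split at the
median — so every level keeps probability ≥ 0.05 and higher latent quality
means higher scores.  The session's continuous outcome is a weighted sum of
its seven scores plus Gaussian noise; the binary training-performance label
splits the outcomes at the within-dataset median.  Concentrating
``indicator_weights`` on a few indicators makes exactly those indicators
the strongly outcome-correlated ones, which is the phenomenology the
downstream importance analysis is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, FormatError, ScoreValidationError

__all__ = [
    "GeneratorConfig",
    "SessionTable",
    "SCORE_COLUMNS",
    "COLUMN_LEVELS",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

#: Score column names, in indicator order 1..7 (STT..BST).
SCORE_COLUMNS: tuple[str, ...] = tuple(f"ind{k}" for k in range(1, 8))

#: Allowed levels per score column (same level sets as the scoring rules).
COLUMN_LEVELS: dict[str, tuple[int, ...]] = {
    "ind1": (0, 5, 10),
    "ind2": (0, 10),
    "ind3": (0, 5, 10),
    "ind4": (0, 5, 10),
    "ind5": (0, 10),
    "ind6": (5, 10),
    "ind7": (0, 10),
}

#: Default outcome weights, concentrated on strength (1), speed (2) and
#: basic skill (7) at twice the weight of the remaining indicators, so those
#: three dominate the outcome correlations (mirroring the strong/weak split
#: the importance analysis is expected to find).
DEFAULT_WEIGHTS: tuple[float, ...] = (1.0, 1.0, 0.5, 0.5, 0.5, 0.5, 1.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Design and signal parameters of the synthetic squad.

    ``ability_sd`` sets the spread of the persistent athlete-ability factor
    and ``session_sd`` the spread of the per-session readiness shock shared
    by all indicators of one session, both against unit indicator-specific
    noise.  The defaults (1.0 and 1.5) make within-session indicator scores
    strongly correlated (day-to-day readiness dominates) while athletes
    still differ persistently.  ``noise_sd`` is the sd of the outcome noise
    on the 0–70 total-score scale.
    """

    n_athletes: int = 20
    n_days: int = 30
    sessions_per_day: int = 4
    seed: int | None = 0
    indicator_weights: tuple[float, ...] = DEFAULT_WEIGHTS
    ability_sd: float = 1.0
    session_sd: float = 1.5
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_athletes", "n_days", "sessions_per_day"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        weights = tuple(float(w) for w in self.indicator_weights)
        object.__setattr__(self, "indicator_weights", weights)
        if len(weights) != 7:
            raise ConfigurationError("indicator_weights must have exactly 7 entries")
        if any(w < 0 for w in weights):
            raise ConfigurationError("indicator_weights must be non-negative")
        if not any(w > 0 for w in weights):
            raise ConfigurationError("indicator_weights must not be all zero")
        if not self.ability_sd > 0:
            raise ConfigurationError("ability_sd must be > 0")
        if self.session_sd < 0:
            raise ConfigurationError("session_sd must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def n_rows(self) -> int:
        return self.n_athletes * self.n_days * self.sessions_per_day


class SessionTable:
    """A table of scored athlete-sessions.

    Wraps a :class:`pandas.DataFrame` with columns ``ID`` (athlete), ``session``
    (ordinal text, session of the day), the seven score columns ``ind1..ind7``
    and optionally ``label`` (binary training-performance class) and
    ``latent_outcome`` (the generator's continuous outcome, never serialised).
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        self.frame = frame.reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        missing = [c for c in ("ID", "session", *SCORE_COLUMNS) if c not in self.frame.columns]
        if missing:
            raise FormatError(f"missing columns: {missing}")
        for col in SCORE_COLUMNS:
            values = self.frame[col]
            allowed = COLUMN_LEVELS[col]
            bad = ~values.isin(allowed)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ScoreValidationError(
                    f"row {row}, column {col}: score {values.iloc[row]!r} "
                    f"not in allowed levels {allowed}"
                )
        if "label" in self.frame.columns:
            if not self.frame["label"].isin((0, 1)).all():
                raise ScoreValidationError("label column must be binary 0/1")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def scores(self) -> np.ndarray:
        """V×7 integer score matrix."""
        return self.frame[list(SCORE_COLUMNS)].to_numpy(dtype=int)

    @property
    def labels(self) -> np.ndarray | None:
        if "label" not in self.frame.columns:
            return None
        return self.frame["label"].to_numpy(dtype=int)

    @property
    def latent_outcome(self) -> np.ndarray | None:
        if "latent_outcome" not in self.frame.columns:
            return None
        return self.frame["latent_outcome"].to_numpy(dtype=float)

    def equals(self, other: "SessionTable") -> bool:
        """Equality on the serialisable columns (ID, session, scores, label)."""
        cols = ["ID", "session", *SCORE_COLUMNS]
        if ("label" in self.frame.columns) != ("label" in other.frame.columns):
            return False
        if "label" in self.frame.columns:
            cols.append("label")
        if len(self) != len(other):
            return False
        a = self.frame[cols].reset_index(drop=True)
        b = other.frame[cols].reset_index(drop=True)
        return bool((a.astype(str) == b.astype(str)).all().all())


def _ordinal(i: int) -> str:
    if 10 <= i % 100 <= 20:
        suffix = "th"
    else:
        suffix = {1: "st", 2: "nd", 3: "rd"}.get(i % 10, "th")
    return f"{i}{suffix}"


def generate_dataset(config: GeneratorConfig | None = None) -> SessionTable:
    """Draw a full synthetic squad table (deterministic per seed)."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_rows
    per_athlete = config.n_days * config.sessions_per_day

    ability = rng.normal(0.0, config.ability_sd, config.n_athletes)
    athlete_idx = np.repeat(np.arange(config.n_athletes), per_athlete)
    readiness = rng.normal(0.0, config.session_sd, n)
    z = ability[athlete_idx][:, None] + readiness[:, None] + rng.standard_normal((n, 7))

    # Cut latent values at fixed population quantiles of the marginal law
    # N(0, ability_sd² + session_sd² + 1): three-level indicators score
    # 0/5/10 at frequencies 45/10/45 % (partial completion is the rare
    # middle ground), two-level indicators split at the median.
    total_sd = float(np.sqrt(config.ability_sd**2 + config.session_sd**2 + 1.0))
    three_level_cuts = stats.norm.ppf([0.45, 0.55], scale=total_sd)
    scores = np.empty((n, 7), dtype=int)
    for k, col in enumerate(SCORE_COLUMNS):
        levels = np.asarray(COLUMN_LEVELS[col])
        cuts = three_level_cuts if len(levels) == 3 else np.array([0.0])
        scores[:, k] = levels[np.searchsorted(cuts, z[:, k])]

    weights = np.asarray(config.indicator_weights)
    latent = scores @ weights + rng.normal(0.0, config.noise_sd, n)
    label = (latent >= np.median(latent)).astype(int)

    frame = pd.DataFrame(
        {
            "ID": [f"A{a + 1}" for a in athlete_idx],
            "session": [_ordinal(s % config.sessions_per_day + 1) for s in range(n)],
            **{col: scores[:, k] for k, col in enumerate(SCORE_COLUMNS)},
            "label": label,
            "latent_outcome": latent,
        }
    )
    return SessionTable(frame)


def write_dataset(table: SessionTable, destination: str | Path) -> None:
    """Write a table as CSV (ID, session, ind1..ind7[, label]); UTF-8, header."""
    cols = ["ID", "session", *SCORE_COLUMNS]
    if "label" in table.frame.columns:
        cols.append("label")
    table.frame[cols].to_csv(destination, index=False)


def read_dataset(source: str | Path) -> SessionTable:
    """Read a CSV written by :func:`write_dataset` (label column optional).

    The session column is parsed leniently as text; scores are validated
    against each indicator's allowed levels.
    """
    try:
        frame = pd.read_csv(source, dtype={"ID": str, "session": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{source}: empty file") from exc
    expected = ["ID", "session", *SCORE_COLUMNS]
    got = list(frame.columns)
    if got != expected and got != expected + ["label"]:
        raise FormatError(
            f"{source}: unexpected header {got}; expected {expected} (+ optional 'label')"
        )
    for col in SCORE_COLUMNS:
        if len(frame) and not np.issubdtype(frame[col].dtype, np.number):
            raise FormatError(f"{source}: column {col} is not numeric")
    return SessionTable(frame)
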