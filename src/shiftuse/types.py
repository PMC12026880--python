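"""Shared domain types for the time-use / substitution-model pipeline."""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional

#: Behaviour categories that enter the regression models, in canonical order.
BEHAVIORS: tuple[str, ...] = ("SB", "LPA", "MVPA", "sleep")

#: Epoch-level categories (behaviours plus pass-through states).
EPOCH_CATEGORIES: tuple[str, ...] = BEHAVIORS + ("nonmain_sleep", "nonwear")

#: The eleven cardiovascular risk-factor outcomes, canonical column names.
OUTCOMES: tuple[str, ...] = (
    "weight", "bmi", "wc", "sbp", "dbp", "hdl", "ldl", "tg", "ast", "alt", "ggtp",
)

#: Outcomes log-transformed (base 10) before modelling, by default.
DEFAULT_LOG_OUTCOMES: frozenset[str] = frozenset({"tg", "ast", "alt", "ggtp"})

MINUTES_PER_DAY = 1440.0


class EpochState(str, enum.Enum):
    WAKE = "wake"
    MAIN_SLEEP = "main_sleep"
    NONMAIN_SLEEP = "nonmain_sleep"
    NONWEAR = "nonwear"


class DayType(str, enum.Enum):
    WORKDAY = "workday"
    LEISURE = "leisure"


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    DAY_WORKER = "day_worker"
    NO_CONSENT = "no_consent"
    NOT_WORN = "not_worn"
    NO_EXAM = "no_exam"
    INSUFFICIENT_DAYS = "insufficient_days"


class ValidationError(ValueError):
    """Raised when an input record violates a declared invariant."""


@dataclass(frozen=True)
class EpochRecord:
    """One scored accelerometer epoch.

    ``mets`` must be present iff ``state`` is wake; ``duration_s`` is a
    positive number of seconds and epochs of one participant must be
    non-overlapping under the half-open convention
    ``[start, start + duration)``.
    """

    participant_id: str
    start: datetime
    duration_s: float
    state: EpochState
    mets: Optional[float] = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError(
                f"epoch duration must be positive, got {self.duration_s} "
                f"(participant {self.participant_id} at {self.start})"
            )
        if self.state == EpochState.WAKE:
            if self.mets is None:
                raise ValidationError(
                    f"wake epoch missing METs value "
                    f"(participant {self.participant_id} at {self.start})"
                )
            if self.mets < 0:
                raise ValidationError(
                    f"negative METs value {self.mets} "
                    f"(participant {self.participant_id} at {self.start})"
                )
        elif self.mets is not None:
            raise ValidationError(
                f"METs value given for non-wake epoch "
                f"(participant {self.participant_id} at {self.start})"
            )

    @property
    def end(self) -> datetime:
        return self.start + timedelta(seconds=self.duration_s)


@dataclass(frozen=True)
class DayWindow:
    """A 24 h (or shorter, partial) day window with its day-type label."""

    start: datetime
    end: datetime
    day_type: DayType
    partial: bool = False

    @property
    def minutes(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


@dataclass
class DayTimeUse:
    """Minutes per behaviour for one participant-day."""

    participant_id: str
    day_index: int
    day_type: DayType
    minutes: dict[str, float]            # keys: SB, LPA, MVPA, sleep
    nonwear_minutes: float = 0.0
    nonmain_sleep_minutes: float = 0.0
    covered_minutes: float = 0.0
    window_minutes: float = MINUTES_PER_DAY
    partial_window: bool = False

    @property
    def complete(self) -> bool:
        """True when the window is a full 24 h and epochs cover all of it."""
        tol = 1.0 / 60.0
        return (
            not self.partial_window
            and abs(self.window_minutes - MINUTES_PER_DAY) <= tol
            and abs(self.covered_minutes - self.window_minutes) <= tol
        )


@dataclass
class ParticipantTimeUse:
    """Per-day-type behaviour means and inclusion status for one participant."""

    participant_id: str
    workday_means: dict[str, float]
    leisure_means: dict[str, float]
    n_workdays: int
    n_leisure_days: int
    n_wear_days: int
    included: bool
    exclusion_reason: ExclusionReason = ExclusionReason.NONE


@dataclass
class CascadeResult:
    """Outcome of the staged participant-exclusion cascade."""

    stage_counts: dict[str, int]      # stage name -> number excluded there
    n_initial: int
    included_ids: list[str] = field(default_factory=list)

    @property
    def n_included(self) -> int:
        return len(self.included_ids)

    def to_dict(self) -> dict:
        return {
            "n_initial": self.n_initial,
            "stage_counts": dict(self.stage_counts),
            "n_included": self.n_included,
            "included_ids": list(self.included_ids),
        }
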