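"""Epoch-level time-use extraction.

Turns scored accelerometer epochs plus a work roster into per-day behaviour
minutes, per-participant day-type means, and a staged exclusion cascade.

Classification bands (METs, wake epochs): sedentary behaviour is the closed
band [0, 1.5], light activity the open band (1.5, 3.0), and
moderate-to-vigorous activity [3.0, inf).  Main sleep is the only state
counted as the sleep behaviour; non-main sleep and non-wear pass through
unchanged and never contribute to sleep or SB.
"""
from __future__ import annotations

import logging
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    BEHAVIORS,
    CascadeResult,
    DayTimeUse,
    DayType,
    DayWindow,
    EpochRecord,
    EpochState,
    ExclusionReason,
    ParticipantTimeUse,
    ValidationError,
)

logger = logging.getLogger(__name__)

SB_MAX_METS = 1.5
MVPA_MIN_METS = 3.0

_DAY = timedelta(hours=24)

#: Fixed order of the exclusion stages (applied sequentially).
CASCADE_STAGES: tuple[str, ...] = (
    "day_worker", "no_consent", "not_worn", "no_exam", "insufficient_days",
)

MIN_WEAR_DAYS = 3


def classify_epoch(epoch: EpochRecord) -> str:
    """Map one epoch to its behaviour category.

    Returns one of ``SB``, ``LPA``, ``MVPA``, ``sleep``, ``nonmain_sleep``,
    ``nonwear``.
    """
    if epoch.state == EpochState.MAIN_SLEEP:
        return "sleep"
    if epoch.state == EpochState.NONMAIN_SLEEP:
        return "nonmain_sleep"
    if epoch.state == EpochState.NONWEAR:
        return "nonwear"
    return classify_mets(epoch.mets)


def classify_mets(mets: float) -> str:
    """Classify a wake-epoch METs value into SB / LPA / MVPA."""
    if mets is None or not np.isfinite(mets) or mets < 0:
        raise ValidationError(f"invalid METs value: {mets!r}")
    if mets <= SB_MAX_METS:
        return "SB"
    if mets < MVPA_MIN_METS:
        return "LPA"
    return "MVPA"


def classify_epochs(epochs: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_epoch` over an epoch table.

    ``epochs`` needs columns ``state`` and ``mets``; wake rows with missing
    METs raise a :class:`ValidationError` naming participant and timestamp.
    """
    state = epochs["state"].astype(str)
    mets = pd.to_numeric(epochs["mets"], errors="coerce")
    wake = state == EpochState.WAKE.value
    bad = wake & (mets.isna() | (mets < 0))
    if bad.any():
        row = epochs.loc[bad.idxmax()]
        raise ValidationError(
            f"wake epoch missing or invalid METs "
            f"(participant {row.get('participant_id', '?')} at {row.get('start', '?')})"
        )
    cat = pd.Series("nonwear", index=epochs.index, dtype=object)
    cat[state == EpochState.MAIN_SLEEP.value] = "sleep"
    cat[state == EpochState.NONMAIN_SLEEP.value] = "nonmain_sleep"
    cat[wake & (mets <= SB_MAX_METS)] = "SB"
    cat[wake & (mets > SB_MAX_METS) & (mets < MVPA_MIN_METS)] = "LPA"
    cat[wake & (mets >= MVPA_MIN_METS)] = "MVPA"
    return cat


def _merge_intervals(
    intervals: Sequence[tuple[datetime, datetime]],
) -> list[tuple[datetime, datetime]]:
    ivs = sorted(intervals)
    for arrival, departure in ivs:
        if arrival >= departure:
            raise ValidationError(f"roster interval with arrival >= departure: {arrival} / {departure}")
    merged: list[tuple[datetime, datetime]] = []
    for a, d in ivs:
        if merged and a < merged[-1][1]:
            raise ValidationError(f"overlapping roster intervals at {a}")
        if merged and a == merged[-1][1]:
            merged[-1] = (merged[-1][0], d)
        else:
            merged.append((a, d))
    return merged


def _split_segment(
    start: datetime, end: datetime, day_type: DayType
) -> list[DayWindow]:
    """Split [start, end) into 24 h windows from ``start``; remainder partial."""
    out: list[DayWindow] = []
    t = start
    while t + _DAY <= end:
        out.append(DayWindow(t, t + _DAY, day_type))
        t += _DAY
    if t < end:
        out.append(DayWindow(t, end, day_type, partial=True))
    return out


def build_day_windows(
    intervals: Sequence[tuple[datetime, datetime]],
    span_start: datetime,
    span_end: datetime,
) -> list[DayWindow]:
    """Tile the observation span with labelled 24 h day windows.

    Roster intervals become workday windows (24 h blocks counted from
    arrival; an interval longer than 24 h is split, the remainder flagged
    partial).  All uncovered time — gaps between stays and the stretches
    before the first arrival / after the last departure — is leisure.  An
    empty roster yields an all-leisure tiling with a logged warning.
    """
    if span_start >= span_end:
        raise ValidationError("empty observation span")
    merged = _merge_intervals(intervals)
    if not merged:
        logger.warning("empty work roster: labelling the whole span as leisure")
        return _split_segment(span_start, span_end, DayType.LEISURE)

    lo = min(span_start, merged[0][0])
    hi = max(span_end, merged[-1][1])
    windows: list[DayWindow] = []
    cursor = lo
    for arrival, departure in merged:
        if cursor < arrival:
            windows.extend(_split_segment(cursor, arrival, DayType.LEISURE))
        windows.extend(_split_segment(arrival, departure, DayType.WORKDAY))
        cursor = departure
    if cursor < hi:
        windows.extend(_split_segment(cursor, hi, DayType.LEISURE))
    return windows


def label_days(
    epochs: pd.DataFrame, roster: pd.DataFrame
) -> dict[str, list[DayWindow]]:
    """Build per-participant day windows covering each participant's epochs.

    ``epochs`` columns: participant_id, start, duration_s;
    ``roster`` columns: participant_id, arrival, departure.
    Participants with epochs but no roster rows get all-leisure windows.
    """
    windows: dict[str, list[DayWindow]] = {}
    roster_by_pid = {
        pid: list(zip(grp["arrival"], grp["departure"]))
        for pid, grp in roster.groupby("participant_id")
    }
    for pid, grp in epochs.groupby("participant_id"):
        start = grp["start"].min()
        dur = pd.to_timedelta(grp["duration_s"], unit="s")
        end = (grp["start"] + dur).max()
        windows[str(pid)] = build_day_windows(
            roster_by_pid.get(pid, []), start.to_pydatetime(), end.to_pydatetime()
        )
    return windows


def _check_overlaps(grp: pd.DataFrame, pid: str) -> None:
    starts = grp["start"].to_numpy()
    ends = (grp["start"] + pd.to_timedelta(grp["duration_s"], unit="s")).to_numpy()
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    # allow sub-millisecond slack from float second arithmetic
    bad = starts[1:] < ends[:-1] - np.timedelta64(1, "ms")
    if bad.any():
        i = int(np.argmax(bad))
        raise ValidationError(
            f"overlapping epochs for participant {pid} near {pd.Timestamp(starts[1:][i])}"
        )


def aggregate_timeuse(
    epochs: pd.DataFrame, windows: dict[str, list[DayWindow]]
) -> list[DayTimeUse]:
    """Sum classified epoch minutes into per-day behaviour totals.

    Epochs are assigned to the window containing their start (half-open).
    Epochs outside every window are dropped with a warning.  Overlapping
    epochs for a participant raise a :class:`ValidationError`.
    """
    out: list[DayTimeUse] = []
    if epochs.empty:
        return out
    cats = classify_epochs(epochs)
    epochs = epochs.assign(_cat=cats, _minutes=epochs["duration_s"] / 60.0)
    for pid, grp in epochs.groupby("participant_id"):
        pid = str(pid)
        _check_overlaps(grp, pid)
        wins = windows.get(pid, [])
        if not wins:
            logger.warning("participant %s has no day windows; epochs skipped", pid)
            continue
        wins = sorted(wins, key=lambda w: w.start)
        bounds = np.array([np.datetime64(w.start) for w in wins] + [np.datetime64(wins[-1].end)])
        idx = np.searchsorted(bounds, grp["start"].to_numpy(), side="right") - 1
        unassigned = (idx < 0) | (idx >= len(wins))
        if unassigned.any():
            logger.warning(
                "participant %s: %d epochs outside roster coverage excluded",
                pid, int(unassigned.sum()),
            )
        sub = grp.loc[~unassigned].assign(_win=idx[~unassigned])
        sums = sub.groupby(["_win", "_cat"])["_minutes"].sum().unstack(fill_value=0.0)
        for day_index, win in enumerate(wins):
            row = sums.loc[day_index] if day_index in sums.index else pd.Series(dtype=float)
            minutes = {b: float(row.get(b, 0.0)) for b in BEHAVIORS}
            covered = float(row.sum()) if len(row) else 0.0
            out.append(
                DayTimeUse(
                    participant_id=pid,
                    day_index=day_index,
                    day_type=win.day_type,
                    minutes=minutes,
                    nonwear_minutes=float(row.get("nonwear", 0.0)),
                    nonmain_sleep_minutes=float(row.get("nonmain_sleep", 0.0)),
                    covered_minutes=covered,
                    window_minutes=win.minutes,
                    partial_window=win.partial,
                )
            )
    return out


def summarize_participant(
    days: Sequence[DayTimeUse], *, include_partial: bool = False
) -> ParticipantTimeUse:
    """Per-day-type behaviour means and the wear-day inclusion rule.

    Only complete days (full 24 h window, fully covered by epochs) count as
    wear days unless ``include_partial``.  Inclusion requires at least
    ``MIN_WEAR_DAYS`` wear days with at least one workday and one leisure
    day.
    """
    if not days:
        return ParticipantTimeUse(
            participant_id="", workday_means={}, leisure_means={},
            n_workdays=0, n_leisure_days=0, n_wear_days=0,
            included=False, exclusion_reason=ExclusionReason.INSUFFICIENT_DAYS,
        )
    pid = days[0].participant_id
    usable = [d for d in days if d.complete or (include_partial and d.covered_minutes > 0)]
    by_type: dict[DayType, list[DayTimeUse]] = {DayType.WORKDAY: [], DayType.LEISURE: []}
    for d in usable:
        by_type[d.day_type].append(d)

    def _means(rows: list[DayTimeUse]) -> dict[str, float]:
        if not rows:
            return {}
        return {
            b: float(np.mean([r.minutes[b] for r in rows])) for b in BEHAVIORS
        }

    n_work = len(by_type[DayType.WORKDAY])
    n_leis = len(by_type[DayType.LEISURE])
    n_wear = n_work + n_leis
    ok = n_wear >= MIN_WEAR_DAYS and n_work >= 1 and n_leis >= 1
    return ParticipantTimeUse(
        participant_id=pid,
        workday_means=_means(by_type[DayType.WORKDAY]),
        leisure_means=_means(by_type[DayType.LEISURE]),
        n_workdays=n_work,
        n_leisure_days=n_leis,
        n_wear_days=n_wear,
        included=ok,
        exclusion_reason=ExclusionReason.NONE if ok else ExclusionReason.INSUFFICIENT_DAYS,
    )


def apply_exclusion_cascade(
    status: pd.DataFrame, *, order: Sequence[str] = CASCADE_STAGES
) -> CascadeResult:
    """Apply the staged exclusion rules and report per-stage counts.

    ``status`` columns: ``participant_id``, ``is_day_worker``, ``consented``,
    ``wore_device``, ``has_exam``, ``n_wear_days``.  Stages apply in the
    fixed order day workers -> no consent -> device not worn -> no health
    exam -> fewer than ``MIN_WEAR_DAYS`` wear days; each participant is
    counted at the first stage that excludes them.  The final included set
    does not depend on the stage order, only the per-stage counts do.
    """
    required = {
        "participant_id", "is_day_worker", "consented",
        "wore_device", "has_exam", "n_wear_days",
    }
    missing = required - set(status.columns)
    if missing:
        raise ValidationError(f"cohort-status table missing columns: {sorted(missing)}")
    contradiction = (~status["wore_device"].astype(bool)) & (status["n_wear_days"].astype(int) > 0)
    if contradiction.any():
        bad = status.loc[contradiction, "participant_id"].iloc[0]
        raise ValidationError(
            f"participant {bad}: wear data present but wore_device is false"
        )

    fails = {
        "day_worker": status["is_day_worker"].astype(bool),
        "no_consent": ~status["consented"].astype(bool),
        "not_worn": ~status["wore_device"].astype(bool),
        "no_exam": ~status["has_exam"].astype(bool),
        "insufficient_days": status["n_wear_days"].astype(int) < MIN_WEAR_DAYS,
    }
    if set(order) != set(CASCADE_STAGES):
        raise ValueError(f"order must be a permutation of {CASCADE_STAGES}")
    remaining = pd.Series(True, index=status.index)
    stage_counts: dict[str, int] = {}
    for stage in order:
        hit = remaining & fails[stage]
        stage_counts[stage] = int(hit.sum())
        remaining &= ~hit
    return CascadeResult(
        stage_counts=stage_counts,
        n_initial=len(status),
        included_ids=[str(x) for x in status.loc[remaining, "participant_id"]],
    )


def days_to_frame(days: Iterable[DayTimeUse]) -> pd.DataFrame:
    """Tidy per-day table mirroring :class:`DayTimeUse`."""
    rows = []
    for d in days:
        row = {
            "participant_id": d.participant_id,
            "day_index": d.day_index,
            "day_type": d.day_type.value,
        }
        row.update({f"{b.lower()}_min": d.minutes[b] for b in BEHAVIORS})
        row.update(
            nonmain_sleep_min=d.nonmain_sleep_minutes,
            nonwear_min=d.nonwear_minutes,
            covered_min=d.covered_minutes,
            window_min=d.window_minutes,
            partial=d.partial_window,
            complete=d.complete,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def participants_to_frame(parts: Iterable[ParticipantTimeUse]) -> pd.DataFrame:
    """Per-participant wide table with day-type behaviour means."""
    rows = []
    for p in parts:
        row: dict = {
            "participant_id": p.participant_id,
            "n_workdays": p.n_workdays,
            "n_leisure_days": p.n_leisure_days,
            "n_wear_days": p.n_wear_days,
            "included": p.included,
            "exclusion_reason": p.exclusion_reason.value,
        }
        for b in BEHAVIORS:
            row[f"workday_{b.lower()}"] = p.workday_means.get(b, np.nan)
            row[f"leisure_{b.lower()}"] = p.leisure_means.get(b, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def extract_participants(
    epochs: pd.DataFrame, roster: pd.DataFrame, *, include_partial: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end extraction: epochs + roster -> (per-day, per-participant) tables."""
    windows = label_days(epochs, roster)
    days = aggregate_timeuse(epochs, windows)
    by_pid: dict[str, list[DayTimeUse]] = {}
    for d in days:
        by_pid.setdefault(d.participant_id, []).append(d)
    parts = [
        summarize_participant(rows, include_partial=include_partial)
        for rows in by_pid.values()
    ]
    return days_to_frame(days), participants_to_frame(parts)
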