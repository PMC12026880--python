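"""Synthetic cohort generation with known ground truth.

Everything the pipeline consumes can be simulated here: an alternating
night-shift calendar, minute-grid epoch streams, an exclusion-cascade
status table, and risk-factor outcomes driven by configurable true
reallocation effects — so each pipeline stage is testable end to end.

Randomness is keyed per participant: participant ``i`` draws from
``SeedSequence(seed, spawn_key=(i,))``, so individual outputs are stable
under changes to cohort size.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional

from functools import lru_cache

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.optimize import fsolve
from scipy.special import ndtr, ndtri
from scipy.stats import truncnorm

from .types import BEHAVIORS, MINUTES_PER_DAY

# Schedule anchors: the working day runs arrival -> arrival + 24 h, with
# night work 18:30-04:00, in-company free time 04:00-10:00 (capsule-bed
# sleep) and day work 10:00-18:30.
ARRIVAL_TIME = timedelta(hours=18, minutes=30)
FREE_TIME_OFFSET_MIN = 570          # minutes from arrival (18:30) to 04:00
FREE_TIME_LEN_MIN = 360             # 04:00 -> 10:00
LEISURE_SLEEP_OFFSET_MIN = 300      # leisure sleep starts ~23:30

DEFAULT_BASE_DATE = datetime(2018, 9, 3)


class BehaviorDist(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mean: float
    sd: float = Field(ge=0)


class OutcomeModel(BaseModel):
    """Linear generating model for one risk factor.

    ``gamma`` holds partition-model coefficients per day type and
    behaviour: the outcome contribution of ``minutes / delta`` of that
    behaviour.  Planted reallocation effects are contrasts
    ``gamma[to] - gamma[from]``.  Log-scale outcomes are generated on the
    log scale (given base) and exponentiated.
    """

    model_config = ConfigDict(extra="forbid")
    target_mean: float
    noise_sd: float = Field(ge=0)
    log_scale: bool = False
    gamma: dict[str, dict[str, float]] = Field(default_factory=dict)
    age_coef: float = 0.0
    alcohol_coef: float = 0.0

    def gamma_at(self, day_type: str, behavior: str) -> float:
        return self.gamma.get(day_type, {}).get(behavior, 0.0)


class CohortPlan(BaseModel):
    """Full parameterisation of the synthetic study."""

    model_config = ConfigDict(extra="forbid")

    n_employees: int = 157
    n_day_workers: int = 24
    n_no_consent: int = 2
    n_not_worn: int = 44
    n_no_exam: int = 15
    n_short_wear: int = 6

    wear_days_mean: float = 6.2
    wear_days_sd: float = Field(default=1.3, ge=0)

    target_shifts_per_month: float = 10.8
    n_calendar_days: int = 7

    behavior: dict[str, dict[str, BehaviorDist]] = Field(
        default_factory=lambda: {
            "workday": {
                "SB": BehaviorDist(mean=372.2, sd=124.2),
                "LPA": BehaviorDist(mean=599.3, sd=127.6),
                "MVPA": BehaviorDist(mean=68.9, sd=37.8),
                "sleep": BehaviorDist(mean=294.7, sd=68.4),
            },
            "leisure": {
                "SB": BehaviorDist(mean=383.8, sd=104.2),
                "LPA": BehaviorDist(mean=215.0, sd=79.8),
                "MVPA": BehaviorDist(mean=28.6, sd=21.6),
                "sleep": BehaviorDist(mean=549.3, sd=119.3),
            },
        }
    )

    age_mean: float = 40.2
    age_sd: float = Field(default=9.9, ge=0)
    drinker_prop: float = Field(default=39 / 66, ge=0, le=1)

    delta: float = 30.0
    outcomes: dict[str, OutcomeModel] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "CohortPlan":
        total_excluded = (
            self.n_day_workers + self.n_no_consent + self.n_not_worn
            + self.n_no_exam + self.n_short_wear
        )
        if total_excluded > self.n_employees:
            raise ValueError("exclusion counts exceed the employee population")
        for day_type, dists in self.behavior.items():
            if set(dists) != set(BEHAVIORS):
                raise ValueError(f"behavior params for {day_type} must cover {BEHAVIORS}")
            if sum(d.mean for d in dists.values()) > MINUTES_PER_DAY:
                raise ValueError(f"{day_type} behaviour means exceed 1440 min")
        return self

    @property
    def n_included(self) -> int:
        return self.n_employees - (
            self.n_day_workers + self.n_no_consent + self.n_not_worn
            + self.n_no_exam + self.n_short_wear
        )


def default_outcome_models(plan: Optional["CohortPlan"] = None) -> dict[str, OutcomeModel]:
    """Outcome models calibrated to the study's descriptive table.

    Intercept targets and noise SDs follow the published means/SDs
    (log-scale values for TG and the liver enzymes).  The default planted
    gamma reproduce the five significant direction cells of the published
    summary — workday SB->LPA lowering waist circumference, workday
    sleep->SB and sleep->MVPA raising triglycerides, leisure SB->MVPA and
    sleep->MVPA lowering AST — with null contrasts elsewhere.  This is a
    calibration device, not an estimate of the study's true effects.
    """
    out = {
        "weight": OutcomeModel(target_mean=69.5, noise_sd=9.7),
        "bmi": OutcomeModel(target_mean=23.7, noise_sd=3.5),
        "wc": OutcomeModel(
            target_mean=84.8, noise_sd=9.3,
            gamma={"workday": {"LPA": -1.0}},
        ),
        "sbp": OutcomeModel(target_mean=121.9, noise_sd=13.0),
        "dbp": OutcomeModel(target_mean=75.2, noise_sd=9.6),
        "hdl": OutcomeModel(target_mean=55.7, noise_sd=14.2),
        "ldl": OutcomeModel(target_mean=115.4, noise_sd=27.4),
        "tg": OutcomeModel(
            target_mean=2.0, noise_sd=0.3, log_scale=True,
            gamma={"workday": {"sleep": -0.05}},
        ),
        "ast": OutcomeModel(
            target_mean=1.4, noise_sd=0.1, log_scale=True,
            gamma={"leisure": {"MVPA": -0.02}},
        ),
        "alt": OutcomeModel(target_mean=1.5, noise_sd=0.2, log_scale=True),
        "ggtp": OutcomeModel(target_mean=1.7, noise_sd=0.3, log_scale=True),
    }
    return out


def default_plan(**overrides) -> CohortPlan:
    plan = CohortPlan(**overrides)
    if not plan.outcomes:
        plan.outcomes = default_outcome_models(plan)
    return plan


#: The five planted direction cells of the published summary table:
#: (day_type, from, to, outcome, sign).
PLANTED_PATTERN: tuple[tuple[str, str, str, str, int], ...] = (
    ("workday", "SB", "LPA", "wc", -1),
    ("workday", "sleep", "SB", "tg", +1),
    ("workday", "sleep", "MVPA", "tg", +1),
    ("leisure", "SB", "MVPA", "ast", -1),
    ("leisure", "sleep", "MVPA", "ast", -1),
)

#: The summary table's full surface: 5 directed pairs x 3 outcomes.
PATTERN_PAIRS: tuple[tuple[str, str, str], ...] = (
    ("workday", "SB", "LPA"),
    ("workday", "sleep", "SB"),
    ("workday", "sleep", "MVPA"),
    ("leisure", "SB", "MVPA"),
    ("leisure", "sleep", "MVPA"),
)
PATTERN_OUTCOMES: tuple[str, ...] = ("wc", "ast", "tg")


def participant_rng(seed: int, index: int) -> np.random.Generator:
    """Per-participant RNG stream (stable under cohort-size changes)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _truncnorm_vec(rng, mean, sd, low, high):
    """Vectorised truncated-normal draws via the inverse CDF."""
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    low = np.broadcast_to(np.asarray(low, float), mean.shape)
    high = np.broadcast_to(np.asarray(high, float), mean.shape)
    out = np.clip(mean, low, high)
    pos = sd > 0
    if np.any(pos):
        a = ndtr((low[pos] - mean[pos]) / sd[pos])
        b = ndtr((high[pos] - mean[pos]) / sd[pos])
        u = rng.random(int(pos.sum()))
        q = np.clip(a + u * (b - a), 1e-12, 1 - 1e-12)
        drawn = mean[pos] + sd[pos] * ndtri(q)
        out = out.copy()
        out[pos] = np.clip(drawn, low[pos], high[pos])
    return out


def _truncnorm_draw(rng, mean, sd, low, high) -> float:
    return float(_truncnorm_vec(rng, np.array([mean]), np.array([sd]), low, high)[0])


#: Fill order for the per-day budget: SB absorbs what the earlier draws leave.
FILL_ORDER = ("sleep", "MVPA", "LPA", "SB")


@lru_cache(maxsize=None)
def _matched_params(
    mean: float, sd: float, low: float = 0.0, high: float = MINUTES_PER_DAY
) -> tuple[float, float]:
    """Location/scale whose [low, high]-truncated normal matches mean/sd.

    Plain truncation at 0 would inflate the mean of low-mean behaviours
    (for example leisure MVPA); solving for matched parameters keeps the
    drawn minutes faithful to the plan's printed means and SDs.
    """
    if sd == 0:
        return float(mean), 0.0

    def eqs(x):
        m, s = x[0], abs(x[1])
        if s < 1e-9:
            s = 1e-9
        a, b = (low - m) / s, (high - m) / s
        mu, var = truncnorm.stats(a, b, loc=m, scale=s, moments="mv")
        return [mu - mean, np.sqrt(var) - sd]

    sol, _, ier, _ = fsolve(eqs, [mean, sd], full_output=True)
    if ier != 1:
        return float(mean), float(sd)   # infeasible targets: fall back
    return float(sol[0]), float(abs(sol[1]))


def _draw_days(
    rng: np.random.Generator, plan: "CohortPlan", day_types: np.ndarray
) -> dict[str, np.ndarray]:
    """Whole-minute behaviour draws for a participant's sequence of days.

    Truncated-normal draws bounded at 0 and the day's remaining budget, in
    the fixed fill order sleep, MVPA, LPA, SB; whatever budget remains
    after the four behaviours becomes non-wear filler.
    """
    day_types = np.asarray(day_types)
    n = len(day_types)
    is_work = day_types == "workday"
    remaining = np.full(n, int(MINUTES_PER_DAY))
    cols: dict[str, np.ndarray] = {}
    for b in FILL_ORDER:
        w, l = plan.behavior["workday"][b], plan.behavior["leisure"][b]
        wm, ws = _matched_params(w.mean, w.sd)
        lm, ls = _matched_params(l.mean, l.sd)
        means = np.where(is_work, wm, lm)
        sds = np.where(is_work, ws, ls)
        vals = _truncnorm_vec(rng, means, sds, 0.0, remaining)
        vals = np.minimum(np.round(vals), remaining).astype(int)
        cols[b] = vals
        remaining = remaining - vals
    cols["nonwear"] = remaining.astype(int)
    return cols


def _participant_day_types(
    plan: "CohortPlan", rng: np.random.Generator, n_days: int
) -> np.ndarray:
    """One participant's day-type sequence from the alternating template.

    The weekly template is work/leisure alternation with one extra
    consecutive leisure day (W L W L W L L), rotated by a random offset;
    workdays are then dropped independently so that the expected count over
    30 days matches the plan's target shifts per month.
    """
    template = np.array(["workday", "leisure"] * 3 + ["leisure"])
    base_rate = 3.0 / 7.0
    drop_p = 1.0 - plan.target_shifts_per_month / (30.0 * base_rate)
    drop_p = float(np.clip(drop_p, 0.0, 1.0))
    offset = int(rng.integers(0, 7))
    days = np.resize(np.roll(template, offset), n_days).copy()
    work_idx = np.flatnonzero(days == "workday")
    drop = work_idx[rng.random(len(work_idx)) < drop_p]
    days[drop] = "leisure"
    return days


def generate_calendar(
    plan: CohortPlan,
    n_participants: int,
    seed: int,
    *,
    n_days: Optional[int] = None,
    base_date: datetime = DEFAULT_BASE_DATE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-participant shift calendars and the matching roster.

    Days are anchored at the 18:30 arrival time: calendar day ``i`` of a
    participant covers ``base + i*24h`` to ``base + (i+1)*24h``.  The base
    pattern alternates work and leisure days with one extra consecutive
    leisure day per week; workdays are then dropped at random (company
    closure, paid holidays) so the expected shift count over 30 days matches
    ``plan.target_shifts_per_month``.

    Returns ``(calendar, roster)``: the ground-truth day-type table
    (participant_id, day_index, day_type, start) and the work roster
    (participant_id, arrival, departure).
    """
    if n_days is None:
        n_days = plan.n_calendar_days
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    base = base_date + ARRIVAL_TIME

    cal_rows, roster_rows = [], []
    for i in range(n_participants):
        rng = participant_rng(seed, i)
        pid = f"P{i:04d}"
        days = _participant_day_types(plan, rng, n_days)
        for d, day_type in enumerate(days):
            start = base + timedelta(days=d)
            cal_rows.append(
                {"participant_id": pid, "day_index": d, "day_type": day_type, "start": start}
            )
            if day_type == "workday":
                roster_rows.append(
                    {"participant_id": pid, "arrival": start, "departure": start + timedelta(days=1)}
                )
    calendar = pd.DataFrame(cal_rows)
    roster = pd.DataFrame(roster_rows, columns=["participant_id", "arrival", "departure"])
    return calendar, roster


def generate_epochs(
    plan: CohortPlan, calendar: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a 1-minute epoch grid realising the calendar, plus ground truth.

    Each calendar day receives whole-minute behaviour draws
    (:func:`_draw_day_minutes`).  On workdays the main-sleep block starts at
    the 04:00 free-time boundary; on leisure days it starts late evening.
    Wake minutes fill the remaining grid in LPA, MVPA, SB order, non-wear
    filler last.  METs codes: SB 1.0, LPA 2.0, MVPA 4.0.

    Returns ``(epochs, ground_truth)`` where ground truth records the
    planted per-day minutes.
    """
    mets_code = {"SB": 1.0, "LPA": 2.0, "MVPA": 4.0}
    pids = sorted(calendar["participant_id"].unique())
    pid_index = {pid: i for i, pid in enumerate(pids)}
    epoch_rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for pid, grp in calendar.groupby("participant_id"):
        # separate stream from the calendar's (different spawn branch)
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(pid_index[pid], 1))
        )
        grp = grp.sort_values("day_index")
        draws = _draw_days(rng, plan, grp["day_type"].to_numpy())
        for k, (_, day) in enumerate(grp.iterrows()):
            dr = {key: int(vals[k]) for key, vals in draws.items()}
            truth_rows.append(
                {
                    "participant_id": pid,
                    "day_index": int(day["day_index"]),
                    "day_type": day["day_type"],
                    **{b: dr[b] for b in BEHAVIORS},
                    "nonwear": dr["nonwear"],
                }
            )
            sleep_min = int(dr["sleep"])
            if day["day_type"] == "workday":
                sleep_start = FREE_TIME_OFFSET_MIN
            else:
                sleep_start = LEISURE_SLEEP_OFFSET_MIN
            sleep_start = min(sleep_start, int(MINUTES_PER_DAY) - sleep_min)
            n_min = int(MINUTES_PER_DAY)
            is_sleep = np.zeros(n_min, dtype=bool)
            is_sleep[sleep_start:sleep_start + sleep_min] = True
            wake_slots = np.flatnonzero(~is_sleep)
            n_rest = len(wake_slots) - int(dr["LPA"] + dr["MVPA"] + dr["SB"])
            fill_states = np.repeat(
                np.array(["wake", "wake", "wake", "nonwear"], dtype=object),
                [int(dr["LPA"]), int(dr["MVPA"]), int(dr["SB"]), n_rest],
            )
            fill_mets = np.concatenate(
                [
                    np.full(int(dr["LPA"]), mets_code["LPA"]),
                    np.full(int(dr["MVPA"]), mets_code["MVPA"]),
                    np.full(int(dr["SB"]), mets_code["SB"]),
                    np.full(n_rest, np.nan),
                ]
            )
            states = np.full(n_min, "main_sleep", dtype=object)
            mets = np.full(n_min, np.nan)
            states[wake_slots] = fill_states
            mets[wake_slots] = fill_mets
            starts = pd.date_range(day["start"], periods=n_min, freq="min")
            epoch_rows.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "start": starts,
                        "duration_s": 60.0,
                        "state": states,
                        "mets": mets,
                    }
                )
            )
    epochs = pd.concat(epoch_rows, ignore_index=True) if epoch_rows else pd.DataFrame(
        columns=["participant_id", "start", "duration_s", "state", "mets"]
    )
    return epochs, pd.DataFrame(truth_rows)


def generate_covariates(plan: CohortPlan, n: int, seed: int) -> pd.DataFrame:
    """Ages and drinker status for ``n`` participants."""
    rows = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, 2)))
        rows.append(
            {
                "participant_id": f"P{i:04d}",
                "age": _truncnorm_draw(rng, plan.age_mean, plan.age_sd, 18.0, 70.0),
                "alcohol": int(rng.random() < plan.drinker_prop),
            }
        )
    return pd.DataFrame(rows)


def generate_outcomes(
    plan: CohortPlan, participants: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Risk-factor outcomes from the planted linear model.

    ``participants`` must carry ``participant_id``, ``age``, ``alcohol``
    and the day-type behaviour means (``workday_sb`` ... ``leisure_sleep``,
    minutes).  For each outcome::

        eta = intercept + sum_k gamma[day_type][k] * minutes_k / delta
                        + age_coef * age + alcohol_coef * alcohol
        value = eta + noise            (identity scale)
        value = base ** (eta + noise)  (log-scale outcomes, base 10)

    The intercept is chosen so the population mean matches the plan's
    target mean given the planned behaviour/covariate means.
    """
    out = participants.copy()
    n = len(participants)
    # one noise stream per participant; outcomes drawn in plan order
    noise_rngs = [
        np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, 3)))
        for i in range(n)
    ]
    for name, om in plan.outcomes.items():
        intercept = om.target_mean - om.age_coef * plan.age_mean \
            - om.alcohol_coef * plan.drinker_prop
        for day_type in ("workday", "leisure"):
            for b in BEHAVIORS:
                intercept -= om.gamma_at(day_type, b) * (
                    plan.behavior[day_type][b].mean / plan.delta
                )
        eta = np.full(n, intercept)
        eta += om.age_coef * participants["age"].to_numpy(float)
        eta += om.alcohol_coef * participants["alcohol"].to_numpy(float)
        for day_type in ("workday", "leisure"):
            for b in BEHAVIORS:
                g = om.gamma_at(day_type, b)
                if g:
                    col = f"{day_type}_{b.lower()}"
                    eta += g * participants[col].to_numpy(float) / plan.delta
        noise = np.array([r.normal(0.0, om.noise_sd) for r in noise_rngs])
        vals = eta + noise
        if om.log_scale:
            vals = np.power(10.0, vals)
        out[name] = vals
    return out


def generate_exclusion_roster(plan: CohortPlan, seed: int) -> pd.DataFrame:
    """Cohort-status table whose cascade reproduces the planned stage counts.

    Emits one row per employee with flags ``is_day_worker``, ``consented``,
    ``wore_device``, ``has_exam`` and an integer ``n_wear_days``; the row
    order is shuffled but deterministic for a given seed.
    """
    n = plan.n_employees
    counts = [
        plan.n_day_workers, plan.n_no_consent, plan.n_not_worn,
        plan.n_no_exam, plan.n_short_wear,
    ]
    if sum(counts) > n:
        raise ValueError("exclusion counts exceed population")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, 4)))
    rows = []
    stage_of = np.repeat(
        ["day_worker", "no_consent", "not_worn", "no_exam", "short_wear", "included"],
        counts + [n - sum(counts)],
    )
    for i, stage in enumerate(stage_of):
        row = {
            "participant_id": f"E{i:04d}",
            "is_day_worker": stage == "day_worker",
            "consented": stage not in ("no_consent",),
            "wore_device": stage not in ("no_consent", "not_worn"),
            "has_exam": stage not in ("no_exam",),
        }
        if stage in ("day_worker", "no_consent", "not_worn"):
            row["n_wear_days"] = 0
        elif stage == "short_wear":
            row["n_wear_days"] = int(rng.integers(0, 3))
        else:
            row["n_wear_days"] = max(
                3, int(round(_truncnorm_draw(rng, plan.wear_days_mean, plan.wear_days_sd, 3.0, 14.0)))
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(drop=True)


def generate_participant_table(
    plan: CohortPlan, n: int, seed: int, *, n_days: Optional[int] = None
) -> pd.DataFrame:
    """Fast path: per-participant day-type behaviour means plus outcomes.

    Skips the epoch grid: per-participant means are averages of per-day
    truncated-normal draws over the participant's simulated wear days
    (matching the full pipeline's averaging), then outcomes come from
    :func:`generate_outcomes`.  Used for large recovery simulations where
    generating minute-grid epochs would dominate runtime.
    """
    if n_days is None:
        n_days = plan.n_calendar_days
    cols: dict[str, list] = {"participant_id": []}
    for dt in ("workday", "leisure"):
        for b in BEHAVIORS:
            cols[f"{dt}_{b.lower()}"] = []
    cols["n_workdays"], cols["n_leisure_days"] = [], []
    for i in range(n):
        cal_rng = participant_rng(seed, i)
        day_types = _participant_day_types(plan, cal_rng, n_days)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, 1)))
        draws = _draw_days(rng, plan, day_types)
        is_work = day_types == "workday"
        cols["participant_id"].append(f"P{i:04d}")
        for dt, mask in (("workday", is_work), ("leisure", ~is_work)):
            k = int(mask.sum())
            for b in BEHAVIORS:
                cols[f"{dt}_{b.lower()}"].append(
                    float(draws[b][mask].mean()) if k else np.nan
                )
        cols["n_workdays"].append(int(is_work.sum()))
        cols["n_leisure_days"].append(int((~is_work).sum()))
    table = pd.DataFrame(cols)
    # participants with no day of one type carry NaN means for that type
    cov = generate_covariates(plan, n, seed)
    table = table.merge(cov, on="participant_id")
    return generate_outcomes(plan, table, seed)


@dataclass
class SimulatedCohort:
    """Bundle of every artefact the pipeline consumes, plus ground truth."""

    plan: CohortPlan
    seed: int
    calendar: pd.DataFrame
    roster: pd.DataFrame
    epochs: pd.DataFrame
    status: pd.DataFrame
    participants: pd.DataFrame      # covariates + behaviour means + outcomes
    ground_truth: pd.DataFrame      # planted per-day minutes


def generate_cohort(
    plan: CohortPlan,
    seed: int,
    *,
    n_participants: Optional[int] = None,
    n_days: Optional[int] = None,
) -> SimulatedCohort:
    """Full simulation: calendar, epochs, status roster, outcomes."""
    n = plan.n_included if n_participants is None else n_participants
    calendar, roster = generate_calendar(plan, n, seed, n_days=n_days)
    epochs, truth = generate_epochs(plan, calendar, seed)
    status = generate_exclusion_roster(plan, seed)

    means = (
        truth.groupby(["participant_id", "day_type"])[list(BEHAVIORS)]
        .mean()
        .unstack("day_type")
    )
    table = pd.DataFrame({"participant_id": means.index})
    for b in BEHAVIORS:
        for dt in ("workday", "leisure"):
            col = f"{dt}_{b.lower()}"
            if (b, dt) in means.columns:
                table[col] = means[(b, dt)].to_numpy()
            else:
                table[col] = np.nan
    cov = generate_covariates(plan, n, seed)
    table = table.merge(cov, on="participant_id")
    participants = generate_outcomes(plan, table, seed)
    return SimulatedCohort(
        plan=plan, seed=seed, calendar=calendar, roster=roster,
        epochs=epochs, status=status, participants=participants,
        ground_truth=truth,
    )
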