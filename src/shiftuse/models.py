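"""Single-factor and isotemporal substitution regression models.

The isotemporal model regresses an outcome on all behaviours except a
reference plus the total behaviour time; the coefficient of an included
behaviour estimates the effect of reallocating ``delta`` minutes from the
reference to that behaviour.  The single-factor model regresses the outcome
on one behaviour plus total time; the sum of the two coefficients estimates
the effect of adding ``delta`` minutes of that behaviour.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .types import BEHAVIORS, DEFAULT_LOG_OUTCOMES, OUTCOMES, ValidationError

logger = logging.getLogger(__name__)

DAY_TYPES = ("workday", "leisure")
DEFAULT_DELTA = 30.0
DEFAULT_ALPHA = 0.05
VIF_THRESHOLD = 5.0


class CollinearityError(ValueError):
    """Raised when the design matrix is rank deficient."""


@dataclass(frozen=True)
class ModelSpec:
    """Declaration of one regression model."""

    family: str                      # "single_factor" | "isotemporal"
    outcome: str
    day_type: str                    # "workday" | "leisure"
    reference: Optional[str] = None  # isotemporal only
    focal: Optional[str] = None      # single_factor only
    delta: float = DEFAULT_DELTA
    covariates: tuple[str, ...] = ("age", "alcohol")
    standardize: bool = True
    log_outcomes: frozenset[str] = DEFAULT_LOG_OUTCOMES
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if self.family not in ("single_factor", "isotemporal"):
            raise ValueError(f"unknown model family: {self.family}")
        if self.day_type not in DAY_TYPES:
            raise ValueError(f"unknown day type: {self.day_type}")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.family == "isotemporal":
            if self.reference not in BEHAVIORS:
                raise ValueError(f"reference must be one of {BEHAVIORS}")
        else:
            if self.focal not in BEHAVIORS:
                raise ValueError(f"focal must be one of {BEHAVIORS}")


@dataclass
class ModelFit:
    """Fitted OLS model with coefficient table and diagnostics."""

    spec: ModelSpec
    params: pd.DataFrame        # index: term; columns: estimate, se, ci_low, ci_high, p
    cov_params: pd.DataFrame
    n: int
    df_resid: float
    vif: dict[str, float]
    r_squared: float
    n_dropped: int = 0

    def term(self, name: str) -> pd.Series:
        return self.params.loc[name]


@dataclass(frozen=True)
class SubstitutionEstimate:
    """Effect of reallocating ``delta`` minutes between two behaviours."""

    from_behavior: str
    to_behavior: str
    day_type: str
    outcome: str
    beta: float
    ci: tuple[float, float]
    p: float
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return bool(self.p < self.alpha)


def behavior_column(day_type: str, behavior: str) -> str:
    return f"{day_type}_{behavior.lower()}"


def prepare_design(
    records: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Build the response and design matrix for one model.

    ``records`` is the per-participant wide table with columns ``age``,
    ``alcohol`` (0/1), the outcome columns and ``{day_type}_{behavior}``
    behaviour means in minutes.  Behaviour predictors are divided by
    ``spec.delta`` so coefficients are per-delta-minute effects; log-flagged
    outcomes are log-transformed (default base 10); with
    ``spec.standardize`` the response and all continuous predictors are
    z-scored after the delta scaling.  Rows with any missing value are
    dropped (count returned).
    """
    beh_cols = {b: behavior_column(spec.day_type, b) for b in BEHAVIORS}
    missing_cols = [c for c in list(beh_cols.values()) + [spec.outcome] + list(spec.covariates)
                    if c not in records.columns]
    if missing_cols:
        raise ValidationError(f"participant table missing columns: {missing_cols}")

    if spec.family == "isotemporal":
        predictors = [b for b in BEHAVIORS if b != spec.reference]
    else:
        predictors = [spec.focal]

    cols = pd.DataFrame(index=records.index)
    for b in predictors:
        cols[b] = records[beh_cols[b]] / spec.delta
    cols["total"] = sum(records[beh_cols[b]] for b in BEHAVIORS) / spec.delta
    for c in spec.covariates:
        cols[c] = records[c]

    y = pd.to_numeric(records[spec.outcome], errors="coerce")
    keep = y.notna() & cols.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "%s/%s %s: dropped %d incomplete rows",
            spec.family, spec.day_type, spec.outcome, n_dropped,
        )
    y, cols = y[keep], cols.loc[keep]
    if len(y) == 0:
        raise ValidationError(f"no complete rows for outcome {spec.outcome}")

    if spec.outcome in spec.log_outcomes:
        if (y <= 0).any():
            raise ValidationError(
                f"outcome {spec.outcome} flagged for log transform has non-positive values"
            )
        y = np.log(y) / math.log(spec.log_base)

    if spec.standardize:
        y = _zscore(y)
        for c in cols.columns:
            vals = cols[c]
            if _is_binary(vals):
                continue
            cols[c] = _zscore(vals)

    X = sm.add_constant(cols, prepend=False, has_constant="add")
    if len(y) < X.shape[1] + 2:
        raise ValidationError(
            f"too few rows ({len(y)}) for {X.shape[1]} parameters"
        )
    return y, X, n_dropped


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError(f"zero-variance column cannot be standardized: {x.name}")
    return (x - x.mean()) / sd


def _is_binary(x: pd.Series) -> bool:
    u = set(pd.unique(x.dropna()))
    return u <= {0, 1, 0.0, 1.0, True, False}


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns whose auxiliary R^2 on the rest is numerically 1."""
    out = []
    vals = X.to_numpy(dtype=float)
    for j, name in enumerate(X.columns):
        if name == "const":
            continue
        others = np.delete(vals, j, axis=1)
        xj = vals[:, j]
        resid = xj - others @ np.linalg.lstsq(others, xj, rcond=None)[0]
        denom = np.sum((xj - xj.mean()) ** 2)
        if denom == 0 or np.sum(resid**2) / denom < 1e-10:
            out.append(name)
    return out


def compute_vif(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors via explicit auxiliary regressions.

    For each non-intercept column, VIF = 1 / (1 - R^2) of that column
    regressed on all the others (intercept included).
    """
    vif: dict[str, float] = {}
    vals = X.to_numpy(dtype=float)
    for j, name in enumerate(X.columns):
        if name == "const":
            continue
        others = np.delete(vals, j, axis=1)
        xj = vals[:, j]
        beta = np.linalg.lstsq(others, xj, rcond=None)[0]
        resid = xj - others @ beta
        sst = np.sum((xj - xj.mean()) ** 2)
        if sst == 0:
            vif[name] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / sst
        vif[name] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return vif


def fit_model(
    y: pd.Series, X: pd.DataFrame, spec: ModelSpec, *, n_dropped: int = 0
) -> ModelFit:
    """Ordinary least squares with Wald 95% CIs and VIF diagnostics.

    A rank-deficient design (for example all four behaviours plus their
    total) raises :class:`CollinearityError` naming the collinear columns
    instead of silently fitting a pseudo-inverse solution.
    """
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        cols = _collinear_columns(X)
        raise CollinearityError(
            f"design matrix is rank deficient; collinear columns: {cols or list(X.columns)}"
        )
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    ci = res.conf_int(alpha=0.05)
    params = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": res.pvalues,
        }
    )
    return ModelFit(
        spec=spec,
        params=params,
        cov_params=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        n=int(res.nobs),
        df_resid=float(res.df_resid),
        vif=compute_vif(X),
        r_squared=float(res.rsquared),
        n_dropped=n_dropped,
    )


def fit(records: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Convenience wrapper: :func:`prepare_design` then :func:`fit_model`."""
    y, X, n_dropped = prepare_design(records, spec)
    return fit_model(y, X, spec, n_dropped=n_dropped)


def substitution_effect(
    fit_: ModelFit, to_behavior: str, *, alpha: float = DEFAULT_ALPHA
) -> SubstitutionEstimate:
    """Reallocation effect reference -> ``to_behavior`` from an isotemporal fit."""
    spec = fit_.spec
    if spec.family != "isotemporal":
        raise ValueError("substitution_effect requires an isotemporal fit")
    if to_behavior == spec.reference:
        raise ValueError(
            "self-substitution undefined; the effect of reallocating a "
            "behaviour to itself is identically 0"
        )
    if to_behavior not in BEHAVIORS:
        raise ValueError(f"unknown behaviour: {to_behavior}")
    row = fit_.term(to_behavior)
    return SubstitutionEstimate(
        from_behavior=spec.reference,
        to_behavior=to_behavior,
        day_type=spec.day_type,
        outcome=spec.outcome,
        beta=float(row["estimate"]),
        ci=(float(row["ci_low"]), float(row["ci_high"])),
        p=float(row["p"]),
        alpha=alpha,
    )


def single_factor_effect(
    fit_: ModelFit, *, alpha: float = DEFAULT_ALPHA
) -> SubstitutionEstimate:
    """Effect of adding ``delta`` minutes of the focal behaviour.

    Computed as the sum of the focal-behaviour and total-time coefficients,
    with a linear-combination standard error from the coefficient
    covariance.
    """
    spec = fit_.spec
    if spec.family != "single_factor":
        raise ValueError("single_factor_effect requires a single-factor fit")
    b = spec.focal
    est = float(fit_.params.loc[b, "estimate"] + fit_.params.loc["total", "estimate"])
    var = float(
        fit_.cov_params.loc[b, b]
        + fit_.cov_params.loc["total", "total"]
        + 2.0 * fit_.cov_params.loc[b, "total"]
    )
    se = math.sqrt(max(var, 0.0))
    tcrit = scipy.stats.t.ppf(0.975, fit_.df_resid)
    if se > 0:
        p = 2.0 * scipy.stats.t.sf(abs(est / se), fit_.df_resid)
    else:
        p = 0.0 if est != 0 else 1.0
    return SubstitutionEstimate(
        from_behavior="",
        to_behavior=b,
        day_type=spec.day_type,
        outcome=spec.outcome,
        beta=est,
        ci=(est - tcrit * se, est + tcrit * se),
        p=float(p),
        alpha=alpha,
    )


@dataclass(frozen=True)
class GridConfig:
    """Which cells of the outcome x day-type x behaviour grid to estimate."""

    outcomes: tuple[str, ...] = OUTCOMES
    day_types: tuple[str, ...] = DAY_TYPES
    references: tuple[str, ...] = BEHAVIORS
    delta: float = DEFAULT_DELTA
    covariates: tuple[str, ...] = ("age", "alcohol")
    log_outcomes: frozenset[str] = DEFAULT_LOG_OUTCOMES
    log_base: float = 10.0
    alpha: float = DEFAULT_ALPHA
    vif_threshold: float = VIF_THRESHOLD
    families: tuple[str, ...] = ("isotemporal", "single_factor")


def run_analysis_grid(records: pd.DataFrame, config: GridConfig = GridConfig()) -> pd.DataFrame:
    """Estimate every grid cell; failed cells are reported, not fatal.

    Returns a tidy long table with one row per (family, outcome, day type,
    from, to) cell carrying both the fully standardized coefficient
    (``beta_std``) and the unstandardized per-delta-minute effect
    (``beta_raw``), plus CI, p, the fit's maximum VIF and sample size.
    """
    rows: list[dict] = []
    for outcome in config.outcomes:
        for day_type in config.day_types:
            if "isotemporal" in config.families:
                for ref in config.references:
                    rows.extend(_iso_cells(records, config, outcome, day_type, ref))
            if "single_factor" in config.families:
                for focal in BEHAVIORS:
                    rows.append(_sf_cell(records, config, outcome, day_type, focal))
    return pd.DataFrame(rows)


def _fit_pair(records, config, outcome, day_type, **kw):
    """Fit a spec twice: standardized and raw scale."""
    common = dict(
        outcome=outcome, day_type=day_type, delta=config.delta,
        covariates=config.covariates, log_outcomes=config.log_outcomes,
        log_base=config.log_base, **kw,
    )
    f_std = fit(records, ModelSpec(standardize=True, **common))
    f_raw = fit(records, ModelSpec(standardize=False, **common))
    return f_std, f_raw


def _base_row(config, family, outcome, day_type, frm, to) -> dict:
    return {
        "family": family, "outcome": outcome, "day_type": day_type,
        "from": frm, "to": to, "delta": config.delta,
        "beta_std": np.nan, "ci_low_std": np.nan, "ci_high_std": np.nan,
        "beta_raw": np.nan, "ci_low_raw": np.nan, "ci_high_raw": np.nan,
        "p": np.nan, "significant": False, "vif_max": np.nan,
        "vif_ok": None, "n": 0, "status": "ok", "message": "",
    }


def _iso_cells(records, config, outcome, day_type, ref) -> list[dict]:
    targets = [b for b in BEHAVIORS if b != ref]
    try:
        f_std, f_raw = _fit_pair(
            records, config, outcome, day_type, family="isotemporal", reference=ref
        )
    except (ValidationError, CollinearityError, ValueError) as exc:
        out = []
        for to in targets:
            row = _base_row(config, "isotemporal", outcome, day_type, ref, to)
            row.update(status="failed", message=str(exc))
            out.append(row)
        return out
    vif_max = max(f_std.vif.values())
    out = []
    for to in targets:
        est_std = substitution_effect(f_std, to, alpha=config.alpha)
        est_raw = substitution_effect(f_raw, to, alpha=config.alpha)
        row = _base_row(config, "isotemporal", outcome, day_type, ref, to)
        row.update(
            beta_std=est_std.beta, ci_low_std=est_std.ci[0], ci_high_std=est_std.ci[1],
            beta_raw=est_raw.beta, ci_low_raw=est_raw.ci[0], ci_high_raw=est_raw.ci[1],
            p=est_std.p, significant=est_std.significant,
            vif_max=vif_max, vif_ok=bool(vif_max < config.vif_threshold),
            n=f_std.n,
        )
        out.append(row)
    return out


def _sf_cell(records, config, outcome, day_type, focal) -> dict:
    row = _base_row(config, "single_factor", outcome, day_type, None, focal)
    try:
        f_std, f_raw = _fit_pair(
            records, config, outcome, day_type, family="single_factor", focal=focal
        )
    except (ValidationError, CollinearityError, ValueError) as exc:
        row.update(status="failed", message=str(exc))
        return row
    est_std = single_factor_effect(f_std, alpha=config.alpha)
    est_raw = single_factor_effect(f_raw, alpha=config.alpha)
    vif_max = max(f_std.vif.values())
    row.update(
        beta_std=est_std.beta, ci_low_std=est_std.ci[0], ci_high_std=est_std.ci[1],
        beta_raw=est_raw.beta, ci_low_raw=est_raw.ci[0], ci_high_raw=est_raw.ci[1],
        p=est_std.p, significant=est_std.significant,
        vif_max=vif_max, vif_ok=bool(vif_max < config.vif_threshold),
        n=f_std.n,
    )
    return row


def compare_daytypes(records: pd.DataFrame) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank comparison of workday vs leisure minutes.

    ``records`` must carry ``workday_*`` and ``leisure_*`` behaviour-mean
    columns.  Returns one row per behaviour with day-type means/SDs, the
    signed-rank statistic and two-sided p value.  All-zero differences make
    the test degenerate; the row is reported with ``p`` = NaN and a note.
    """
    rows = []
    for b in BEHAVIORS:
        wcol, lcol = behavior_column("workday", b), behavior_column("leisure", b)
        sub = records[[wcol, lcol]].dropna()
        if len(sub) < 2:
            raise ValidationError(
                f"need at least 2 complete pairs for {b}, got {len(sub)}"
            )
        w, l = sub[wcol].to_numpy(float), sub[lcol].to_numpy(float)
        diffs = w - l
        row = {
            "behavior": b,
            "n_pairs": len(sub),
            "workday_mean": float(w.mean()),
            "workday_sd": float(w.std(ddof=1)),
            "leisure_mean": float(l.mean()),
            "leisure_sd": float(l.std(ddof=1)),
        }
        if np.allclose(diffs, 0.0):
            row.update(statistic=np.nan, p=np.nan, note="all differences zero; test degenerate")
        else:
            stat = scipy.stats.wilcoxon(w, l)
            row.update(statistic=float(stat.statistic), p=float(stat.pvalue), note="")
        rows.append(row)
    return pd.DataFrame(rows)


def arrow_summary(
    estimates: pd.DataFrame,
    *,
    outcomes: Optional[Sequence[str]] = None,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Direction summary of isotemporal cells: up / down arrows or ``ns``.

    One row per directed behaviour pair, one column per (day type, outcome)
    combination present in ``estimates``.
    """
    iso = estimates[(estimates["family"] == "isotemporal") & (estimates["status"] == "ok")]
    if outcomes is not None:
        iso = iso[iso["outcome"].isin(outcomes)]
    if pairs is not None:
        keys = {(f, t) for f, t in pairs}
        iso = iso[[(f, t) in keys for f, t in zip(iso["from"], iso["to"])]]
    rows = []
    for (day_type, frm, to), grp in iso.groupby(["day_type", "from", "to"]):
        row = {"day_type": day_type, "from": frm, "to": to}
        for _, r in grp.iterrows():
            if not r["significant"]:
                row[r["outcome"]] = "ns"
            else:
                row[r["outcome"]] = "↑" if r["beta_std"] > 0 else "↓"
        rows.append(row)
    return pd.DataFrame(rows)
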