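"""Circadian summaries and mixed models for sentinel-fish telemetry.

Sentinel fish carry implanted tags inside a larger free-swimming group; their
hourly heart rate and activity metrics are summarised by hour of day and by a
day/night partition (day = clock hours 06-17 inclusive, night = 18-23 and
00-05), and treatment effects are estimated with a random-intercept linear
mixed model fitted by REML::

    y ~ Treatment + Period_of_Day + (1 | fish)

with an optional Treatment x Period interaction included only when a
likelihood-ratio test under ML finds it significant at alpha = 0.05.
Reported cell summaries are mean +/- s.e.m. across fish (each fish first
reduced to its own cell mean), matching the repeated-measures structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "DAY_HOURS",
    "METRICS",
    "LmmFit",
    "label_period",
    "hourly_aggregate",
    "fit_lmm",
    "day_night_summary",
]

#: inclusive clock-hour bounds of "day"
DAY_HOURS = (6, 17)

#: metric columns of a sentinel series
METRICS = ("hr_bpm", "ext_accel_mg", "var_mg2", "odba_ms2")


@dataclass(frozen=True)
class LmmFit:
    """Random-intercept mixed-model estimates for one response."""

    response: str
    fe_params: dict  # name -> estimate
    fe_se: dict
    fe_pvalues: dict
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_fish: int
    interaction_included: bool
    converged: bool
    singular: bool  # random-intercept variance collapsed to ~0


def label_period(timestamp, day_hours: tuple[int, int] = DAY_HOURS) -> str:
    """'day' when the clock hour falls in the inclusive day window."""
    hour = pd.Timestamp(timestamp).hour
    return "day" if day_hours[0] <= hour <= day_hours[1] else "night"


def _with_period(data: pd.DataFrame, day_hours: tuple[int, int]) -> pd.DataFrame:
    data = data.copy()
    if "period" not in data:
        hours = pd.to_datetime(data["timestamp"]).dt.hour
        data["period"] = np.where(
            (hours >= day_hours[0]) & (hours <= day_hours[1]), "day", "night"
        )
    return data


def hourly_aggregate(
    data: pd.DataFrame, day_hours: tuple[int, int] = DAY_HOURS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean metrics per fish x hour-of-day x treatment, plus group summary.

    Returns ``(per_fish, group)``: per-fish arithmetic means, and the
    across-fish mean +/- s.e.m. per hour and treatment.
    """
    data = _with_period(data, day_hours)
    data["hour"] = pd.to_datetime(data["timestamp"]).dt.hour
    metrics = [m for m in METRICS if m in data]
    per_fish = (
        data.groupby(["fish_id", "treatment", "hour"], observed=True)[metrics]
        .mean()
        .reset_index()
    )
    group = (
        per_fish.groupby(["treatment", "hour"], observed=True)[metrics]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    group.columns = [
        c[0] if not c[1] else f"{c[0]}_{c[1]}" for c in group.columns.to_flat_index()
    ]
    return per_fish, group


def _fit_mixed(formula: str, df: pd.DataFrame, reml: bool):
    """Fit a random-intercept model, robust to boundary (zero-variance) cases.

    Gradient optimizers can report degenerate solutions when the intercept
    variance collapses; several methods are tried and the finite fit with the
    best (restricted) likelihood wins.
    """
    best = None
    for method in ("lbfgs", "powell", "nm"):
        fit = smf.mixedlm(formula, df, groups=df["fish_id"]).fit(reml=reml, method=method)
        ok = np.isfinite(fit.llf) and np.all(np.isfinite(fit.fe_params.to_numpy()))
        if ok and (best is None or fit.llf > best.llf):
            best = fit
        if ok and fit.converged and method == "lbfgs":
            break  # the common, well-behaved case
    if best is None:
        raise RuntimeError("mixed-model fit failed for all optimizers")
    return best


def fit_lmm(
    data: pd.DataFrame,
    response: str = "hr_bpm",
    interaction: str | bool = "auto",
    day_hours: tuple[int, int] = DAY_HOURS,
) -> LmmFit:
    """REML random-intercept model of a sentinel metric.

    Fixed effects are treatment (reference: steady) and period of day
    (reference: night), so the ``period_day`` coefficient is the day-minus-
    night difference.  ``interaction='auto'`` pre-tests the Treatment x
    Period term by an ML likelihood-ratio test at alpha = 0.05 and refits
    with REML.  A singular fit (random-intercept variance ~ 0) converges
    with a warning flag rather than failing.
    """
    if response not in data:
        raise ValueError(f"response {response!r} not in data")
    data = _with_period(data, day_hours).dropna(subset=[response])
    if data["fish_id"].nunique() < 2:
        raise ValueError("need >= 2 fish to identify a random intercept")
    for col, levels in (("treatment", ("steady", "unsteady")), ("period", ("day", "night"))):
        present = set(data[col].unique())
        if not set(levels) <= present:
            raise ValueError(f"both {col} levels required, found {sorted(present)}")

    df = pd.DataFrame(
        {
            "y": data[response].astype(float),
            "unsteady": (data["treatment"] == "unsteady").astype(float),
            "day": (data["period"] == "day").astype(float),
            "fish_id": data["fish_id"],
        }
    )
    base = "y ~ unsteady + day"
    full = base + " + unsteady:day"

    include = bool(interaction) if interaction != "auto" else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if include is None:
            ml0 = _fit_mixed(base, df, reml=False)
            ml1 = _fit_mixed(full, df, reml=False)
            lrt = 2.0 * (ml1.llf - ml0.llf)
            include = stats.chi2.sf(max(lrt, 0.0), df=1) < 0.05
        formula = full if include else base
        fit = _fit_mixed(formula, df, reml=True)

    fe_names = [n for n in fit.fe_params.index]
    re_var = float(fit.cov_re.iloc[0, 0])
    singular = re_var < 1e-6 * float(fit.scale)
    converged = bool(fit.converged) or (
        singular and np.all(np.isfinite(list(fit.fe_params)))
    )
    rename = {"unsteady": "treatment_unsteady", "day": "period_day",
              "unsteady:day": "treatment_unsteady:period_day"}
    return LmmFit(
        response=response,
        fe_params={rename.get(n, n): float(fit.fe_params[n]) for n in fe_names},
        fe_se={rename.get(n, n): float(fit.bse[n]) for n in fe_names},
        fe_pvalues={rename.get(n, n): float(fit.pvalues[n]) for n in fe_names},
        random_intercept_var=re_var,
        residual_var=float(fit.scale),
        n_obs=int(fit.nobs),
        n_fish=int(df["fish_id"].nunique()),
        interaction_included=bool(include),
        converged=converged,
        singular=singular,
    )


def day_night_summary(
    data: pd.DataFrame, day_hours: tuple[int, int] = DAY_HOURS
) -> pd.DataFrame:
    """2 x 2 (treatment x period) cell means +/- s.e.m. per metric.

    Each fish contributes one cell mean; the table reports the across-fish
    mean, s.e.m. and fish count, one row per (metric, treatment, period).
    """
    data = _with_period(data, day_hours)
    metrics = [m for m in METRICS if m in data]
    per_fish = (
        data.groupby(["fish_id", "treatment", "period"], observed=True)[metrics]
        .mean()
        .reset_index()
    )
    rows = []
    for metric in metrics:
        cell = (
            per_fish.groupby(["treatment", "period"], observed=True)[metric]
            .agg(["mean", "sem", "count"])
            .reset_index()
        )
        cell.insert(0, "metric", metric)
        rows.append(cell)
    out = pd.concat(rows, ignore_index=True)
    return out.rename(columns={"count": "n_fish"})
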