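"""Dormancy phase transitions and cultivar chilling / heat requirements.

The endodormancy -> ecodormancy transition is dated from weekly forcing
assays: shoots cut on successive dates are forced under warm long days, and
the transition date is the earliest cutting date whose buds reach a target
BBCH stage (default 59, "balloon") within a fixed horizon (default 5 weeks).
The chilling requirement (CR) is the chill accumulated from a season start to
that transition; the heat requirement (HR) is the growing degree hours
accumulated from the transition to field bud break.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date

import pandas as pd

from .thermal import (
    GDHParams,
    HourlyTemperatureSeries,
    accumulate_between,
    chill_portions,
    chilling_hours,
    growing_degree_hours,
)

__all__ = [
    "PhenologyError",
    "PhenologyEvents",
    "transition_from_forcing",
    "chilling_requirement",
    "heat_requirement",
    "derive_events",
]

FORCING_COLUMNS = ["cultivar", "cutting_date", "replicate", "weeks_in_forcing", "bbch_stage"]


class PhenologyError(ValueError):
    pass


@dataclass(frozen=True)
class PhenologyEvents:
    """Per-cultivar transition date, bud-break window and derived requirements."""

    cultivar: str
    transition_date: pd.Timestamp
    budbreak_start: pd.Timestamp
    budbreak_end: pd.Timestamp
    chilling_requirement_ch: float
    chilling_requirement_cp: float
    heat_requirement_gdh_min: float
    heat_requirement_gdh_max: float

    def __post_init__(self) -> None:
        if not (self.transition_date < self.budbreak_start <= self.budbreak_end):
            raise PhenologyError(
                "require transition_date < budbreak_start <= budbreak_end"
            )

    def to_dict(self) -> dict:
        return {
            "cultivar": self.cultivar,
            "transition_date": str(self.transition_date.date()),
            "budbreak_start": str(self.budbreak_start.date()),
            "budbreak_end": str(self.budbreak_end.date()),
            "chilling_requirement_ch": self.chilling_requirement_ch,
            "chilling_requirement_cp": self.chilling_requirement_cp,
            "heat_requirement_gdh_min": self.heat_requirement_gdh_min,
            "heat_requirement_gdh_max": self.heat_requirement_gdh_max,
        }


_AGGREGATORS = {
    "median": lambda s: s.median(),
    "min": lambda s: s.min(),
    "any": lambda s: s.max(),
}


def transition_from_forcing(
    observations: pd.DataFrame,
    stage_threshold: int = 59,
    horizon_weeks: int = 5,
    aggregate: str = "median",
) -> dict[str, pd.Timestamp]:
    """Date the endodormancy release per cultivar from a forcing table.

    For each cultivar, returns the earliest cutting date at which the
    replicate-aggregated BBCH stage observed after ``horizon_weeks`` of
    forcing reaches ``stage_threshold``.  Replicates are aggregated by the
    median by default ("min" requires every replicate to qualify, "any" a
    single one).
    """
    if aggregate not in _AGGREGATORS:
        raise PhenologyError(f"unknown aggregation rule {aggregate!r}")
    obs = observations.copy()
    missing = [c for c in FORCING_COLUMNS if c not in obs.columns]
    if missing:
        raise PhenologyError(f"forcing table lacks columns {missing}")
    obs["cutting_date"] = pd.to_datetime(obs["cutting_date"])
    if obs["cutting_date"].nunique() < 2:
        raise PhenologyError("forcing table must span at least 2 cutting dates")
    at_horizon = obs[obs["weeks_in_forcing"] == horizon_weeks]
    if at_horizon.empty:
        raise PhenologyError(f"no observations at the {horizon_weeks}-week horizon")

    agg = _AGGREGATORS[aggregate]
    out: dict[str, pd.Timestamp] = {}
    for cultivar, grp in at_horizon.groupby("cultivar"):
        stage = grp.groupby("cutting_date")["bbch_stage"].apply(agg).sort_index()
        qualifying = stage[stage >= stage_threshold]
        if qualifying.empty:
            raise PhenologyError(
                f"endodormancy of {cultivar!r} not released within the observed "
                f"window (no cutting date reached BBCH {stage_threshold})"
            )
        out[str(cultivar)] = qualifying.index[0]
    return out


def chilling_requirement(
    series: HourlyTemperatureSeries,
    season_start: Date | str,
    transition_date: Date | str,
    model: str = "CP",
) -> float:
    """Chill accumulated in ``(season_start, transition_date]``.

    ``model`` selects chill hours ("CH") or dynamic-model chill portions
    ("CP").  The season start is the instant chill counting begins; the
    study-campaign first sampling date is a sensible default upstream.
    """
    start = pd.Timestamp(season_start)
    stop = pd.Timestamp(transition_date)
    if stop < start:
        raise PhenologyError("transition date precedes season start")
    if model == "CH":
        acc = chilling_hours(series)
    elif model == "CP":
        acc = chill_portions(series)
    else:
        raise PhenologyError(f"unknown chill model {model!r}")
    return accumulate_between(acc, start, stop)


def heat_requirement(
    series: HourlyTemperatureSeries,
    transition_date: Date | str,
    budbreak_date: Date | str,
    params: GDHParams | None = None,
) -> float:
    """GDH accumulated in ``(transition_date, budbreak_date]``."""
    start = pd.Timestamp(transition_date)
    stop = pd.Timestamp(budbreak_date)
    if stop < start:
        raise PhenologyError("bud break precedes the dormancy transition")
    acc = growing_degree_hours(series, params)
    return accumulate_between(acc, start, stop)


def derive_events(
    series: HourlyTemperatureSeries,
    forcing: pd.DataFrame,
    budbreak_windows: dict[str, tuple],
    season_start: Date | str,
    stage_threshold: int = 59,
    horizon_weeks: int = 5,
    gdh_params: GDHParams | None = None,
) -> list[PhenologyEvents]:
    """Full phenology report: transition dates, CR (CH and CP), HR range.

    ``budbreak_windows`` maps cultivar to the (first, last) field date of the
    scored bud-break window; the HR is reported for both endpoints.
    """
    transitions = transition_from_forcing(forcing, stage_threshold, horizon_weeks)
    ch_acc = chilling_hours(series)
    cp_acc = chill_portions(series)
    start = pd.Timestamp(season_start)
    events = []
    for cultivar, tdate in sorted(transitions.items()):
        if cultivar not in budbreak_windows:
            raise PhenologyError(f"no bud-break window for cultivar {cultivar!r}")
        bb_start, bb_end = (pd.Timestamp(d) for d in budbreak_windows[cultivar])
        events.append(
            PhenologyEvents(
                cultivar=cultivar,
                transition_date=tdate,
                budbreak_start=bb_start,
                budbreak_end=bb_end,
                chilling_requirement_ch=accumulate_between(ch_acc, start, tdate),
                chilling_requirement_cp=accumulate_between(cp_acc, start, tdate),
                heat_requirement_gdh_min=heat_requirement(series, tdate, bb_start, gdh_params),
                heat_requirement_gdh_max=heat_requirement(series, tdate, bb_end, gdh_params),
            )
        )
    return events
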