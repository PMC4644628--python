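"""Per-animal attendance at hotspots and seasonal use summaries.

Day classification follows the tracking-study convention: a calendar (UTC)
day counts as a *sea* day when at least one of the animal's fixes that day
falls on sea and lies farther from the home-range boundary than its Argos
error radius; days with no retained fix are dropped from all denominators.
A *presence* day at a hotspot is a day with a sea-classified fix within its
location error of the hotspot polygon; a *visit* is a maximal run of
consecutive presence days.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from ._util import consecutive_runs, round_half_up
from .grids import UDGrid
from .landmask import LandMask


def sea_fix_flags(traj: pd.DataFrame, home_range: BaseGeometry, mask: LandMask) -> np.ndarray:
    """Per-fix flag: on sea and beyond the home range by more than the fix's
    error radius (distance to the range polygon, 0 inside)."""
    x = traj["x"].to_numpy(dtype=float)
    y = traj["y"].to_numpy(dtype=float)
    err = traj["error_radius"].to_numpy(dtype=float)
    err = np.where(np.isfinite(err), err, 0.0)
    on_land = mask.is_land(x, y)
    pts = shapely.points(x, y)
    d = shapely.distance(pts, home_range)
    return (~on_land) & (d > err)


def classify_days(traj: pd.DataFrame, sea_flags: np.ndarray) -> pd.Series:
    """Per tracked day, 'sea' or 'land' (index: UTC date). Days without a
    fix simply do not appear."""
    days = traj["timestamp"].dt.date
    sea = pd.Series(sea_flags, index=traj.index).groupby(days.to_numpy()).any()
    return sea.map({True: "sea", False: "land"})


def daily_presence(
    traj: pd.DataFrame,
    sea_flags: np.ndarray,
    polygon: BaseGeometry,
    start: date | None = None,
    end: date | None = None,
    error_aware: bool = True,
) -> set[date]:
    """Dates (within [start, end), if given) with a sea-classified fix at
    the hotspot polygon.

    With ``error_aware`` (the default) a fix attends the polygon when it
    lies within its own Argos error radius of it — hotspot areas are often
    no wider than the location error, so exact point-in-polygon would
    undercount attendance; set False for strict containment.
    """
    pts = shapely.points(
        traj["x"].to_numpy(dtype=float), traj["y"].to_numpy(dtype=float)
    )
    if error_aware:
        err = traj["error_radius"].to_numpy(dtype=float)
        err = np.where(np.isfinite(err), err, 0.0)
        inside = shapely.dwithin(pts, polygon, err)
    else:
        inside = shapely.intersects(pts, polygon)
    hit = inside & sea_flags
    days = traj["timestamp"].dt.date.to_numpy()
    out = set(days[hit])
    if start is not None:
        out = {d for d in out if d >= start}
    if end is not None:
        out = {d for d in out if d < end}
    return out


def visits(presence_dates) -> list[tuple[date, date]]:
    """Maximal runs of consecutive presence dates, as (first, last) pairs."""
    return consecutive_runs(presence_dates)


def join_distance(traj: pd.DataFrame, visit_start: date, center: tuple[float, float]) -> float | None:
    """Distance (km) from the animal's chronologically last fix on the day
    before the visit started to the hotspot center; None when the prior day
    has no fix (excluded from distance summaries)."""
    prior = visit_start - timedelta(days=1)
    day_fixes = traj[traj["timestamp"].dt.date == prior]
    if len(day_fixes) == 0:
        return None
    last = day_fixes.iloc[-1]
    return float(np.hypot(last["x"] - center[0], last["y"] - center[1])) / 1000.0


def nonjoiner_distance(
    traj: pd.DataFrame, center: tuple[float, float], start: date, end: date
) -> float | None:
    """Closest approach (km) to the hotspot center over its active dates
    [start, end], for an animal never detected at the hotspot."""
    days = traj["timestamp"].dt.date
    sub = traj[(days >= start) & (days <= end)]
    if len(sub) == 0:
        return None
    d = np.hypot(sub["x"].to_numpy() - center[0], sub["y"].to_numpy() - center[1])
    return float(d.min()) / 1000.0


def home_range_centroid(contour: np.ndarray, ud: UDGrid) -> tuple[float, float]:
    """UD-mass-weighted centroid of the home-range (50%) contour cells."""
    w = np.where(contour, ud.values, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("contour carries no UD mass")
    xs = ud.geometry.x_centers
    ys = ud.geometry.y_centers
    cx = float((w.sum(axis=0) * xs).sum() / total)
    cy = float((w.sum(axis=1) * ys).sum() / total)
    return cx, cy


def coast_distance(contour: np.ndarray, ud: UDGrid, mask: LandMask) -> float:
    """Distance (km) from the home-range centroid to the coastline."""
    cx, cy = home_range_centroid(contour, ud)
    return mask.coast_distance(cx, cy) / 1000.0


@dataclass
class AttendanceRecord:
    animal_id: str
    hotspot_id: str
    presence_dates: list[date]
    visits: list[tuple[date, date]]
    join_distances_km: list[float | None]  # aligned with visits

    @property
    def n_days(self) -> int:
        return len(self.presence_dates)

    @property
    def n_visits(self) -> int:
        return len(self.visits)


def build_attendance_record(
    animal_id: str,
    hotspot_id: str,
    traj: pd.DataFrame,
    sea_flags: np.ndarray,
    polygon: BaseGeometry,
    center: tuple[float, float],
    start: date | None = None,
    end: date | None = None,
) -> AttendanceRecord:
    dates = daily_presence(traj, sea_flags, polygon, start, end)
    runs = visits(dates)
    dists = [join_distance(traj, first, center) for first, _ in runs]
    return AttendanceRecord(
        animal_id=animal_id,
        hotspot_id=hotspot_id,
        presence_dates=sorted(dates),
        visits=runs,
        join_distances_km=dists,
    )


def return_lag(
    traj: pd.DataFrame, home_range: BaseGeometry, visit_end: date, horizon: int = 10
) -> int | None:
    """Days after the end of a visit until the animal is first located inside
    its home range again (1 = the very next day); None if not seen inside
    within ``horizon`` days."""
    inside = shapely.intersects_xy(
        home_range, traj["x"].to_numpy(dtype=float), traj["y"].to_numpy(dtype=float)
    )
    days = traj["timestamp"].dt.date.to_numpy()
    for lag in range(1, horizon + 1):
        target = visit_end + timedelta(days=lag)
        sel = days == target
        if sel.any() and inside[sel].any():
            return lag
    return None


# ----------------------------------------------------------------- summaries

@dataclass
class SeasonSummary:
    animal_id: str
    tracked_days: int
    land_days: int
    sea_days: int
    hotspot_days: int
    n_hotspots: int

    @property
    def pct_land(self) -> float:
        return round_half_up(100.0 * self.land_days / self.tracked_days, 1)

    @property
    def pct_sea_days_at_hotspots(self) -> float | None:
        if self.sea_days == 0:
            return None
        return round_half_up(100.0 * self.hotspot_days / self.sea_days, 1)


def season_summary(
    animal_id: str,
    day_classes: pd.Series,
    presence_by_hotspot: dict[str, set[date]],
    window: tuple[date, date],
) -> SeasonSummary:
    """Seasonal use summary over ``window`` (inclusive of both end dates).

    Denominator = days with at least one retained location; hotspot days are
    the union of presence dates across hotspots, clipped to the window.
    """
    w0, w1 = window
    in_window = day_classes[(day_classes.index >= w0) & (day_classes.index <= w1)]
    tracked = len(in_window)
    sea_days = int((in_window == "sea").sum())
    land_days = tracked - sea_days
    all_presence: set[date] = set()
    n_hot = 0
    for dates in presence_by_hotspot.values():
        clipped = {d for d in dates if w0 <= d <= w1}
        if clipped:
            n_hot += 1
        all_presence |= clipped
    if tracked == 0:
        raise ValueError(f"animal {animal_id}: no tracked days in the window")
    return SeasonSummary(
        animal_id=animal_id,
        tracked_days=tracked,
        land_days=land_days,
        sea_days=sea_days,
        hotspot_days=len(all_presence),
        n_hotspots=n_hot,
    )


def visitor_summary_stats(summaries: list[SeasonSummary]) -> dict[str, float]:
    """Means and sample SDs (over animals with at least one hotspot day) of
    the percentage of days on land and the percentage of sea-ice days spent
    at hotspots, computed from the 1-decimal per-animal percentages."""
    visitors = [s for s in summaries if s.hotspot_days > 0]
    if not visitors:
        raise ValueError("no hotspot visitors among the summaries")
    shares = np.array([s.pct_sea_days_at_hotspots for s in visitors], dtype=float)
    land = np.array([s.pct_land for s in visitors], dtype=float)
    return {
        "n_visitors": len(visitors),
        "mean_pct_sea_days_at_hotspots": float(shares.mean()),
        "sd_pct_sea_days_at_hotspots": float(shares.std(ddof=1)),
        "mean_pct_land": float(land.mean()),
        "sd_pct_land": float(land.std(ddof=1)),
    }


def repeat_visit_share(visit_counts) -> float:
    """Percentage (1 decimal) of joining instances with 2 or more visits."""
    counts = list(visit_counts)
    if not counts:
        raise ValueError("no joining instances")
    return round_half_up(100.0 * sum(1 for c in counts if c >= 2) / len(counts), 1)


def next_day_return_share(return_lags) -> float:
    """Percentage (1 decimal) of instances where the animal was back inside
    its home range the day after leaving the hotspot (lag == 1)."""
    lags = [lag for lag in return_lags if lag is not None]
    if not lags:
        raise ValueError("no return lags recorded")
    return round_half_up(100.0 * sum(1 for lag in lags if lag == 1) / len(lags), 1)


def hotspot_summary(records: list[AttendanceRecord]) -> dict:
    """Duration, membership, per-animal mean days, peak same-day attendance
    and repeat-visit instances for one hotspot."""
    with_presence = [r for r in records if r.n_days > 0]
    if not with_presence:
        raise ValueError("no attendance records with presence")
    all_dates = sorted(set().union(*(set(r.presence_dates) for r in with_presence)))
    per_day = {}
    for r in with_presence:
        for d in r.presence_dates:
            per_day.setdefault(d, set()).add(r.animal_id)
    return {
        "duration_days": (all_dates[-1] - all_dates[0]).days + 1,
        "first_date": all_dates[0],
        "last_date": all_dates[-1],
        "n_members": len(with_presence),
        "mean_days_per_member": float(np.mean([r.n_days for r in with_presence])),
        "peak_attendance": max(len(v) for v in per_day.values()),
        "repeat_visit_instances": sum(1 for r in with_presence if r.n_visits >= 2),
    }
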