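"""Two-stage Argos location filtering.

Stage one keeps only high-quality location classes (LC 3, 2, 1, with nominal
error radii < 250 m, 250-500 m and 500-1500 m). Stage two is an iterative
forward speed filter: a location is dropped when reaching it from the last
retained location would require an unrealistic speed, and the scan then
re-evaluates the next location against the same anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import logger
from .io_formats import VALID_LC

#: Nominal Argos error radius (m) per retained location class: the upper
#: bound of the class's error band, used when no per-row radius is supplied.
CLASS_ERROR_RADIUS = {"3": 250.0, "2": 500.0, "1": 1500.0}


@dataclass
class FilterParams:
    keep_classes: frozenset[str] = frozenset({"3", "2", "1"})
    v_max: float = 7.0  # km/h, sustained speed ceiling
    v_burst: float = 10.0  # km/h, allowed over short acceleration bouts
    t_burst: float = 12.0  # minutes, maximum bout duration

    def __post_init__(self) -> None:
        if not (self.v_burst >= self.v_max > 0):
            raise ValueError("need v_burst >= v_max > 0")
        if self.t_burst <= 0:
            raise ValueError("t_burst must be positive")
        object.__setattr__(self, "keep_classes", frozenset(str(c) for c in self.keep_classes))


def filter_location_class(table: pd.DataFrame, params: FilterParams | None = None) -> pd.DataFrame:
    """Retain rows whose location class is in ``params.keep_classes``."""
    params = params or FilterParams()
    lc = table["lc"].astype(str)
    unknown = ~lc.isin(VALID_LC)
    if unknown.any():
        bad = table.index[unknown][0]
        raise ValueError(f"unknown Argos location class {lc.loc[bad]!r} at row {bad}")
    return table[lc.isin(params.keep_classes)].copy()


def default_error_radius(lc: str) -> float:
    """Nominal error radius (m) for a retained class; only LC 3/2/1 have one."""
    lc = str(lc)
    if lc not in CLASS_ERROR_RADIUS:
        raise ValueError(f"no default error radius for location class {lc!r}")
    return CLASS_ERROR_RADIUS[lc]


def fill_error_radius(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing per-row error radii from the class defaults."""
    out = table.copy()
    missing = out["error_radius"].isna()
    if missing.any():
        out.loc[missing, "error_radius"] = out.loc[missing, "lc"].map(CLASS_ERROR_RADIUS)
    if out["error_radius"].isna().any():
        raise ValueError("error radius unavailable for some rows outside LC 3/2/1")
    return out


def speed_filter(traj: pd.DataFrame, params: FilterParams | None = None) -> pd.DataFrame:
    """Iterative forward speed filter on a single animal's trajectory.

    Scan keeping an anchor (the last retained location). For each candidate
    compute the straight-line speed from the anchor; the threshold is
    ``v_burst`` when the elapsed time is at most ``t_burst`` minutes, else
    ``v_max``. A violating candidate is dropped and the scan continues from
    the same anchor. The first location is always retained, so the result is
    a fixed point of the filter.
    """
    params = params or FilterParams()
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if traj["animal_id"].nunique() > 1:
        raise ValueError("speed_filter expects a single animal")
    t = traj["timestamp"].astype("int64").to_numpy() / 1e9  # seconds
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing (deduplicate first)")
    x = traj["x"].to_numpy()
    y = traj["y"].to_numpy()
    keep = [0]
    anchor = 0
    for i in range(1, len(traj)):
        dt_s = t[i] - t[anchor]
        dist_m = float(np.hypot(x[i] - x[anchor], y[i] - y[anchor]))
        speed_kmh = (dist_m / 1000.0) / (dt_s / 3600.0)
        threshold = params.v_burst if dt_s <= params.t_burst * 60.0 else params.v_max
        if speed_kmh > threshold:
            continue  # drop the later point; anchor persists
        keep.append(i)
        anchor = i
    return traj.iloc[keep].copy()


def apply_censor(table: pd.DataFrame, censor: pd.DataFrame | None) -> pd.DataFrame:
    """Drop rows on/after each censored animal's last_valid_date (UTC)."""
    if censor is None or len(censor) == 0:
        return table.copy()
    cutoff = dict(zip(censor["animal_id"].astype(str), censor["last_valid_date"]))
    dates = table["timestamp"].dt.date
    drop = pd.Series(False, index=table.index)
    for animal, last in cutoff.items():
        drop |= (table["animal_id"] == animal) & (dates >= last)
    return table[~drop].copy()


def filter_locations(
    table: pd.DataFrame,
    params: FilterParams | None = None,
    censor: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full filtering pipeline: class screen, censoring, per-animal speed
    filter, and error-radius fill-in. Returns a location table."""
    params = params or FilterParams()
    kept = filter_location_class(table, params)
    kept = apply_censor(kept, censor)
    parts = []
    for animal, traj in kept.groupby("animal_id", sort=True):
        if len(traj) == 0:
            continue
        out = speed_filter(traj, params)
        logger.info("animal %s: %d -> %d locations after speed filter",
                    animal, len(traj), len(out))
        parts.append(out)
    if not parts:
        return kept.iloc[0:0].copy()
    return fill_error_radius(pd.concat(parts, ignore_index=True))
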