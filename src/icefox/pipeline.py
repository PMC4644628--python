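"""End-to-end orchestration: filter -> home ranges -> sliced population UDs
-> hotspots -> attendance -> model-ready records."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from ._util import logger
from .argos_filter import FilterParams, filter_locations
from .attendance import (
    AttendanceRecord,
    SeasonSummary,
    build_attendance_record,
    classify_days,
    coast_distance,
    daily_presence,
    nonjoiner_distance,
    sea_fix_flags,
    season_summary,
)
from .dbbmm import DbbmmParams, compute_ud, estimate_variance_profile, home_range
from .grids import GridGeometry, UDGrid
from .hotspots import (
    Hotspot,
    candidate_regions,
    hotspot_center,
    make_time_slices,
    mask_and_rescale,
    merge_across_slices,
    overlap_count,
    population_ud,
    synchrony_filter,
)
from .landmask import LandMask


@dataclass
class PipelineParams:
    filter_params: FilterParams = field(default_factory=FilterParams)
    dbbmm_params: DbbmmParams = field(default_factory=DbbmmParams)
    start: date = date(2010, 10, 25)
    end: date = date(2011, 6, 1)
    season_window: tuple[date, date] = (date(2010, 10, 25), date(2011, 3, 15))
    slice_days: int = 30
    step_days: int = 14
    individual_contour: float = 0.75
    min_foxes: int = 3
    grid_pad_m: float = 3000.0

    @property
    def min_slice_locations(self) -> int:
        return 2 * self.dbbmm_params.margin + 1


@dataclass
class PipelineResult:
    filtered: pd.DataFrame
    grid: GridGeometry
    home_ranges: dict  # animal -> (contour mask, polygon, UDGrid)
    sea_flags: dict  # animal -> bool array aligned with its filtered rows
    day_classes: dict  # animal -> Series date -> 'sea'/'land'
    slices: list
    slice_pop_uds: dict  # slice index -> sea-masked population UDGrid
    slice_counts: dict  # slice index -> overlap count array
    hotspots: list[Hotspot]
    attendance: dict  # hotspot_id -> list[AttendanceRecord]
    season_summaries: list[SeasonSummary]
    joining_records: pd.DataFrame
    stay_records: pd.DataFrame


def shared_grid(table: pd.DataFrame, cell_size: float, pad: float) -> GridGeometry:
    return GridGeometry.from_bounds(
        table["x"].min() - pad,
        table["y"].min() - pad,
        table["x"].max() + pad,
        table["y"].max() + pad,
        cell_size,
    )


def run_pipeline(
    locations: pd.DataFrame,
    mask: LandMask,
    params: PipelineParams | None = None,
    censor: pd.DataFrame | None = None,
) -> PipelineResult:
    params = params or PipelineParams()
    dparams = params.dbbmm_params
    filtered = filter_locations(locations, params.filter_params, censor)
    if len(filtered) == 0:
        raise ValueError("no locations survive filtering")
    grid = shared_grid(filtered, dparams.cell_size, params.grid_pad_m)
    land_cells = mask.land_grid(grid)
    trajs = {a: t.reset_index(drop=True) for a, t in filtered.groupby("animal_id")}

    home_ranges = {}
    for animal, traj in trajs.items():
        try:
            home_ranges[animal] = home_range(traj, mask, dparams, grid=grid)
        except ValueError as err:
            logger.warning("no home range for %s: %s", animal, err)

    sea_flags = {}
    day_classes = {}
    for animal, traj in trajs.items():
        if animal not in home_ranges:
            continue
        flags = sea_fix_flags(traj, home_ranges[animal][1], mask)
        sea_flags[animal] = flags
        day_classes[animal] = classify_days(traj, flags)

    slices = make_time_slices(params.start, params.end, params.slice_days,
                              params.step_days)
    slice_pop_uds: dict[int, UDGrid] = {}
    slice_counts: dict[int, np.ndarray] = {}
    candidates_per_slice = []
    for ts in slices:
        uds = []
        for animal, traj in trajs.items():
            days = traj["timestamp"].dt.date
            sub = traj[(days >= ts.start) & (days < ts.end)].reset_index(drop=True)
            if len(sub) < params.min_slice_locations:
                if len(sub):
                    logger.warning("%s excluded from slice %d (%d locations)",
                                   animal, ts.index, len(sub))
                continue
            profile = estimate_variance_profile(sub, dparams)
            uds.append(compute_ud(sub, profile, dparams, grid=grid))
        if not uds:
            continue
        pop = population_ud(uds)
        try:
            slice_pop_uds[ts.index] = mask_and_rescale(pop, mask)
        except ValueError:
            continue
        counts = overlap_count(uds, params.individual_contour)
        slice_counts[ts.index] = counts
        regions = candidate_regions(counts, land_cells, params.min_foxes)
        if regions:
            candidates_per_slice.append((ts, regions))

    # Screen each per-slice candidate with the attendance rules before
    # merging across slices: a candidate with fewer than min_foxes attending
    # animals, or without a 2-consecutive-day stay, is discarded here.
    # Without this, artifact regions (e.g. the offshore smear of several
    # adjacent coastal home ranges) can chain genuine hotspots together.
    from icefox.dbbmm import cells_to_polygon
    from ._util import consecutive_runs

    screened = []
    for ts, regions in candidates_per_slice:
        kept = []
        for region in regions:
            poly = cells_to_polygon(region, grid)
            chron = {}
            for animal in sea_flags:
                dates = daily_presence(trajs[animal], sea_flags[animal], poly,
                                       ts.start, ts.end)
                if dates:
                    chron[animal] = dates
            if len(chron) < params.min_foxes:
                continue
            if not any(
                max((b - a).days + 1 for a, b in consecutive_runs(d)) >= 2
                for d in chron.values()
            ):
                continue
            kept.append(region)
        if kept:
            screened.append((ts, kept))

    drafts = merge_across_slices(screened, grid) if screened else []

    presence: dict[int, dict[str, set]] = {}
    for idx, draft in enumerate(drafts):
        span0, span1 = draft.date_span
        chron = {}
        for animal in sea_flags:
            dates = daily_presence(trajs[animal], sea_flags[animal], draft.polygon,
                                   span0, span1)
            if dates:
                chron[animal] = dates
        presence[idx] = chron

    hotspots = synchrony_filter(drafts, presence)
    for h in hotspots:
        pops = [slice_pop_uds[ts.index].values for ts in h.slices
                if ts.index in slice_pop_uds]
        mean_pop = UDGrid(grid, np.mean(pops, axis=0)).normalized()
        h.center = hotspot_center(h.cells, mean_pop)

    attendance: dict[str, list[AttendanceRecord]] = {}
    for h in hotspots:
        span0, span1 = min(s.start for s in h.slices), max(s.end for s in h.slices)
        records = [
            build_attendance_record(a, h.hotspot_id, trajs[a], sea_flags[a],
                                    h.polygon, h.center, span0, span1)
            for a in h.members
        ]
        attendance[h.hotspot_id] = [r for r in records if r.n_days > 0]

    season_summaries = []
    for animal in sorted(day_classes):
        presence_by_hotspot = {
            h.hotspot_id: set(r.presence_dates)
            for h in hotspots
            for r in attendance[h.hotspot_id]
            if r.animal_id == animal
        }
        try:
            season_summaries.append(
                season_summary(animal, day_classes[animal], presence_by_hotspot,
                               params.season_window)
            )
        except ValueError as err:
            logger.warning("%s", err)

    joining_rows = []
    stay_rows = []
    for h in hotspots:
        by_animal = {r.animal_id: r for r in attendance[h.hotspot_id]}
        for animal in sorted(home_ranges):
            contour, _, ud = home_ranges[animal]
            coast_km = coast_distance(contour, ud, mask)
            rec = by_animal.get(animal)
            if rec is not None:
                dist = next((d for d in rec.join_distances_km if d is not None), None)
                joined = 1
                arrival = (rec.presence_dates[0] - h.first_date).days
                stay_rows.append(
                    {
                        "animal_id": animal,
                        "hotspot_id": h.hotspot_id,
                        "days_at_hotspot": rec.n_days,
                        "arrival_day": arrival,
                        "travel_distance": dist,
                    }
                )
            else:
                dist = nonjoiner_distance(trajs[animal], h.center,
                                          h.first_date, h.last_date)
                joined = 0
            if dist is None:
                continue  # untracked during the hotspot or missing prior-day fix
            joining_rows.append(
                {
                    "animal_id": animal,
                    "hotspot_id": h.hotspot_id,
                    "joined": joined,
                    "distance_to_hotspot": dist,
                    "coast_distance": coast_km,
                }
            )

    return PipelineResult(
        filtered=filtered,
        grid=grid,
        home_ranges=home_ranges,
        sea_flags=sea_flags,
        day_classes=day_classes,
        slices=slices,
        slice_pop_uds=slice_pop_uds,
        slice_counts=slice_counts,
        hotspots=hotspots,
        attendance=attendance,
        season_summaries=season_summaries,
        joining_records=pd.DataFrame(joining_rows),
        stay_records=pd.DataFrame(stay_rows),
    )


def match_hotspots_to_sites(
    hotspots: list[Hotspot],
    sites,
    cell_size: float,
    max_cells: float = 2.0,
) -> dict[str, bool]:
    """For each site, whether some detected hotspot center lies within
    ``max_cells`` grid cells of the site position."""
    out = {}
    for site in sites:
        out[site.site_id] = any(
            h.center is not None
            and np.hypot(h.center[0] - site.x, h.center[1] - site.y)
            <= max_cells * cell_size
            for h in hotspots
        )
    return out
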