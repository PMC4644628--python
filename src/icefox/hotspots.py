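"""Population-level sea-ice use and spatio-temporal hotspot extraction.

The sea-ice season is divided into overlapping 30-day time slices stepped by
14 days. Within a slice, each animal's UD is computed, the population UD is
the renormalized cellwise sum, land mass is zeroed out and the remainder
rescaled, and hotspot candidates are the 8-connected groups of sea cells
covered by the 75% contours of at least ``min_foxes`` individuals.
Candidates from different slices whose footprints intersect are merged
(transitive closure), and a merged draft is retained only if at least 3
distinct animals attended it and at least one animal was present on 2 or
more consecutive days.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
from scipy import ndimage
from shapely.geometry.base import BaseGeometry

from .grids import GridGeometry, UDGrid, cumulative_contour
from .dbbmm import cells_to_polygon
from .landmask import LandMask


@dataclass(frozen=True)
class TimeSlice:
    index: int
    start: date
    end: date  # half-open: [start, end)
    truncated: bool = False

    @property
    def days(self) -> int:
        return (self.end - self.start).days


def make_time_slices(
    start_date: date,
    end_date: date,
    slice_days: int = 30,
    step_days: int = 14,
) -> list[TimeSlice]:
    """Overlapping half-open slices [start + k*step, start + k*step + slice)
    for every k with slice start strictly before ``end_date``."""
    if end_date <= start_date:
        raise ValueError("end_date must be after start_date")
    slices = []
    k = 0
    while True:
        s = start_date + timedelta(days=k * step_days)
        if s >= end_date:
            break
        e = s + timedelta(days=slice_days)
        slices.append(TimeSlice(index=k, start=s, end=e, truncated=e > end_date))
        k += 1
    return slices


def population_ud(individual_uds: list[UDGrid]) -> UDGrid:
    """Cellwise sum of normalized individual UDs, renormalized to mass 1."""
    if not individual_uds:
        raise ValueError("no individual UDs supplied")
    geom = individual_uds[0].geometry
    total = np.zeros_like(individual_uds[0].values)
    for ud in individual_uds:
        if ud.geometry != geom:
            raise ValueError("individual UDs do not share grid geometry")
        if not ud.is_normalized(tol=1e-6):
            raise ValueError("individual UDs must be normalized")
        total += ud.values
    return UDGrid(geom, total).normalized()


def mask_and_rescale(ud: UDGrid, mask: LandMask) -> UDGrid:
    """Zero out the probability of land cells and rescale to unit mass."""
    land = mask.land_grid(ud.geometry)
    values = np.where(land, 0.0, ud.values)
    sea_mass = values.sum()
    if sea_mass <= 0:
        raise ValueError("UD has zero mass at sea; cannot rescale")
    return UDGrid(ud.geometry, values / sea_mass)


def overlap_count(individual_uds: list[UDGrid], p: float = 0.75) -> np.ndarray:
    """Per cell, how many individuals' p-level cumulative contours cover it.

    Returns an integer (nrows, ncols) array on the shared geometry.
    """
    if not individual_uds:
        raise ValueError("no individual UDs supplied")
    geom = individual_uds[0].geometry
    counts = np.zeros((geom.nrows, geom.ncols), dtype=int)
    for ud in individual_uds:
        if ud.geometry != geom:
            raise ValueError("individual UDs do not share grid geometry")
        counts += cumulative_contour(ud, p)
    return counts


_QUEEN = np.ones((3, 3), dtype=int)


def candidate_regions(
    counts: np.ndarray,
    land_cells: np.ndarray,
    min_foxes: int = 3,
) -> list[np.ndarray]:
    """8-connected components of sea cells used by >= min_foxes individuals.

    ``land_cells`` is a boolean grid (True = land). Returns a list of boolean
    cell masks, ordered by first (row, col) occurrence.
    """
    hot = (counts >= min_foxes) & ~land_cells
    labels, n = ndimage.label(hot, structure=_QUEEN)
    return [labels == i for i in range(1, n + 1)]


@dataclass
class HotspotDraft:
    """A candidate hotspot merged across time slices, before the attendance
    synchrony screen."""

    cells: np.ndarray  # boolean mask on the shared grid
    polygon: BaseGeometry
    slices: list[TimeSlice]

    @property
    def date_span(self) -> tuple[date, date]:
        return (min(s.start for s in self.slices),
                max(s.end for s in self.slices))


@dataclass
class Hotspot:
    """A retained spatio-temporal hotspot."""

    hotspot_id: str
    cells: np.ndarray
    polygon: BaseGeometry
    slices: list[TimeSlice]
    members: list[str]
    center: tuple[float, float] | None = None
    first_date: date | None = None
    last_date: date | None = None


def merge_across_slices(
    candidates_per_slice: list[tuple[TimeSlice, list[np.ndarray]]],
    geometry: GridGeometry,
) -> list[HotspotDraft]:
    """Union candidates from different (and overlapping) slices whose
    footprints intersect, with transitive closure.

    Footprints intersect when they share a cell or are 8-adjacent on the
    shared grid (consistent with the within-slice connectivity rule).
    """
    entries = []  # (slice, mask)
    for ts, masks in candidates_per_slice:
        for m in masks:
            entries.append((ts, m))
    n = len(entries)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    dilated = [ndimage.binary_dilation(m, structure=_QUEEN.astype(bool))
               for _, m in entries]
    for i in range(n):
        for j in range(i + 1, n):
            if np.any(dilated[i] & entries[j][1]):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    drafts = []
    for members in groups.values():
        cells = np.zeros((geometry.nrows, geometry.ncols), dtype=bool)
        slices = []
        for i in members:
            cells |= entries[i][1]
            slices.append(entries[i][0])
        slices = sorted(set(slices), key=lambda s: s.index)
        drafts.append(
            HotspotDraft(cells=cells, polygon=cells_to_polygon(cells, geometry),
                         slices=slices)
        )
    drafts.sort(key=lambda d: (d.slices[0].index, tuple(np.argwhere(d.cells)[0])))
    return drafts


def synchrony_filter(
    drafts: list[HotspotDraft],
    presence: dict[int, dict[str, set[date]]],
    min_members: int = 3,
    min_consecutive: int = 2,
) -> list[Hotspot]:
    """Keep drafts where >= min_members distinct animals have presence days
    and at least one animal was present min_consecutive days in a row.

    ``presence[draft_index][animal_id]`` is that animal's set of presence
    dates at the draft (computed by the attendance module).
    """
    from ._util import consecutive_runs

    retained = []
    for idx, draft in enumerate(drafts):
        chron = {a: d for a, d in presence.get(idx, {}).items() if d}
        if len(chron) < min_members:
            continue
        has_run = any(
            max((last - first).days + 1 for first, last in consecutive_runs(dates))
            >= min_consecutive
            for dates in chron.values()
        )
        if not has_run:
            continue
        all_dates = sorted(set().union(*chron.values()))
        retained.append(
            Hotspot(
                hotspot_id=f"H{len(retained) + 1}",
                cells=draft.cells,
                polygon=draft.polygon,
                slices=draft.slices,
                members=sorted(chron),
                first_date=all_dates[0],
                last_date=all_dates[-1],
            )
        )
    return retained


def hotspot_center(cells: np.ndarray, pop_ud: UDGrid) -> tuple[float, float]:
    """Center of a hotspot: the center coordinates of its cell with maximal
    population-UD value; exact ties break by (row, col) order."""
    vals = np.where(cells, pop_ud.values, -np.inf)
    flat = int(np.argmax(vals))  # argmax returns the first (row, col) maximum
    row, col = np.unravel_index(flat, vals.shape)
    return pop_ud.geometry.cell_center(int(row), int(col))
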