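"""Synthetic landscapes, fox movement, carcass events and Argos observations.

The generator emulates the study conditions the pipeline was designed for:
~24 territorial foxes spaced along a ~60 km coastline with home ranges up to
15 km inland, duty-cycled collars transmitting in a daily 3-hour UTC window
yielding ~5.3 +/- 2.1 usable locations per day with class-dependent error,
and occasional excursions onto the sea ice to planted carcass sites that are
each active for one to a few weeks in midwinter.

Movement is an Ornstein-Uhlenbeck (OU) walk around the territory center,
interrupted by scheduled excursions: directed travel to the carcass at a
sustained sub-filter speed, a local OU wander around the carcass for the
scheduled number of days, and a directed return. Every draw flows from one
seeded generator, so outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ._util import logger
from .argos_filter import CLASS_ERROR_RADIUS
from .landmask import LandMask, straight_coast_mask

DT_S = 60.0  # path resolution, seconds


@dataclass
class ScenarioParams:
    n_foxes: int = 24
    coast_km: float = 60.0
    inland_km: float = 15.0
    start: date = date(2010, 10, 25)
    end: date = date(2011, 6, 1)
    # movement
    ou_sd_m: float = 2000.0  # stationary SD of the territorial walk
    ou_tau_s: float = 6.0 * 3600.0  # OU relaxation time
    stay_sd_m: float = 1000.0  # wander SD around a carcass
    stay_tau_s: float = 2.0 * 3600.0
    travel_speed_kmh: float = 5.0  # sustained, below the 7 km/h filter
    min_center_spacing_m: float = 1500.0
    # observation model
    fix_window_utc: tuple[int, int] = (14, 17)  # hours
    fixes_per_day_mean: float = 5.3
    fixes_per_day_sd: float = 2.1
    max_fixes_per_day: int = 9
    lc_probs: dict = field(default_factory=lambda: {"3": 0.35, "2": 0.40, "1": 0.25})
    noise_sd_factor: float = 0.5  # Gaussian noise SD = factor * class radius
    # carcass scenario
    n_planted: int = 5
    n_distractor: int = 2
    carcass_offshore_km: tuple[float, float] = (3.0, 10.0)
    carcass_duration_days: tuple[int, int] = (8, 17)
    carcass_earliest: date = date(2010, 12, 1)
    carcass_latest_start: date = date(2011, 2, 1)
    planted_members: tuple[int, int] = (3, 12)
    distractor_members: tuple[int, int] = (1, 2)
    stay_days_range: tuple[int, int] = (1, 8)
    repeat_visit_prob: float = 0.35
    min_site_spacing_m: float = 8000.0

    @property
    def n_minutes(self) -> int:
        return (self.end - self.start).days * 1440

    @property
    def t0(self) -> datetime:
        return datetime.combine(self.start, time(0), tzinfo=timezone.utc)


@dataclass
class CarcassSite:
    site_id: str
    x: float
    y: float
    start: date
    end: date  # last active day, inclusive
    planted: bool


@dataclass
class Excursion:
    animal_id: str
    site_id: str
    t_dep: datetime
    t_arr: datetime
    t_leave: datetime
    t_ret: datetime
    stay_days: int


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for recovery tests."""

    centers: dict[str, tuple[float, float]]
    carcasses: list[CarcassSite]
    excursions: list[Excursion]
    times_s: np.ndarray  # seconds since params.t0, shared by all paths
    paths: dict[str, np.ndarray]  # animal -> (n, 2)

    def members_of(self, site_id: str) -> set[str]:
        return {e.animal_id for e in self.excursions if e.site_id == site_id}

    def eligible_sites(self, min_members: int = 3, min_stay: int = 2) -> list[CarcassSite]:
        """Planted sites that should be recoverable: at least ``min_members``
        scheduled visitors and at least one stay of ``min_stay`` days."""
        out = []
        for c in self.carcasses:
            if not c.planted:
                continue
            exc = [e for e in self.excursions if e.site_id == c.site_id]
            if len({e.animal_id for e in exc}) >= min_members and any(
                e.stay_days >= min_stay for e in exc
            ):
                out.append(c)
        return out


def _fox_ids(n: int) -> list[str]:
    return [f"F{i + 1:02d}" for i in range(n)]


def make_landscape(
    params: ScenarioParams, rng: np.random.Generator
) -> tuple[LandMask, dict[str, tuple[float, float]]]:
    """Straight-coast strip landscape plus territory centers on land.

    Centers are stratified along the coast (one per equal coastal interval,
    jittered) with depths uniform in (0, inland depth); the jitter is
    redrawn until pairwise spacing clears the configured minimum.
    """
    if params.n_foxes < 1:
        raise ValueError("need at least one fox")
    coast_m = params.coast_km * 1000.0
    inland_m = params.inland_km * 1000.0
    mask = straight_coast_mask(coast_m, inland_m)
    seg = coast_m / params.n_foxes
    for _ in range(200):
        xs = (np.arange(params.n_foxes) + rng.uniform(0.25, 0.75, params.n_foxes)) * seg
        ys = rng.uniform(0.0, inland_m, params.n_foxes)
        pts = np.column_stack([xs, ys])
        if params.n_foxes == 1:
            break
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        if d.min() >= params.min_center_spacing_m:
            break
    centers = {a: (float(x), float(y)) for a, (x, y) in zip(_fox_ids(params.n_foxes), pts)}
    return mask, centers


def _ou_series(n: int, sd: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Exact stationary OU samples at DT_S resolution (deviation from center)."""
    phi = float(np.exp(-DT_S / tau))
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), n)
    x0 = rng.normal(0.0, sd)
    out, _ = lfilter([1.0], [1.0, -phi], innov, zi=[phi * x0])
    return out


def simulate_paths(
    params: ScenarioParams,
    centers: dict[str, tuple[float, float]],
    sites: list[CarcassSite],
    excursions: list[Excursion],
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """True 1-minute paths: territorial OU with excursion segments spliced in.

    Foxes without excursions never cross the coast (the OU depth coordinate
    is reflected at the shoreline).
    """
    n = params.n_minutes
    times_s = np.arange(n) * DT_S
    site_by_id = {c.site_id: c for c in sites}
    by_fox: dict[str, list[Excursion]] = {a: [] for a in centers}
    for e in excursions:
        by_fox[e.animal_id].append(e)

    def t_idx(t: datetime) -> int:
        return int(np.clip((t - params.t0).total_seconds() // DT_S, 0, n - 1))

    paths = {}
    for animal, (cx, cy) in centers.items():
        px = cx + _ou_series(n, params.ou_sd_m, params.ou_tau_s, rng)
        py = np.abs(cy + _ou_series(n, params.ou_sd_m, params.ou_tau_s, rng))
        for e in sorted(by_fox[animal], key=lambda e: e.t_dep):
            i_dep, i_arr = t_idx(e.t_dep), t_idx(e.t_arr)
            i_leave, i_ret = t_idx(e.t_leave), t_idx(e.t_ret)
            site = site_by_id[e.site_id]
            # outbound travel: linear from the current position
            frac = np.linspace(0.0, 1.0, max(i_arr - i_dep, 1) + 1)
            px[i_dep : i_arr + 1] = px[i_dep] + frac * (site.x - px[i_dep])
            py[i_dep : i_arr + 1] = py[i_dep] + frac * (site.y - py[i_dep])
            # local wander around the carcass
            m = i_leave - i_arr
            if m > 0:
                wx = _ou_series(m, params.stay_sd_m, params.stay_tau_s, rng)
                wy = _ou_series(m, params.stay_sd_m, params.stay_tau_s, rng)
                px[i_arr + 1 : i_leave + 1] = site.x + wx
                py[i_arr + 1 : i_leave + 1] = site.y + wy
            # return travel: linear back onto the territorial walk
            frac = np.linspace(0.0, 1.0, max(i_ret - i_leave, 1) + 1)
            px[i_leave : i_ret + 1] = px[i_leave] + frac * (px[i_ret] - px[i_leave])
            py[i_leave : i_ret + 1] = py[i_leave] + frac * (py[i_ret] - py[i_leave])
        paths[animal] = np.column_stack([px, py])
    return times_s, paths


def observe_argos(
    times_s: np.ndarray,
    paths: dict[str, np.ndarray],
    params: ScenarioParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample Argos-like fixes from the true paths.

    Per fox-day the usable-fix count is a rounded normal (mean 5.3, SD 2.1)
    clipped to [0, 9]; fix times are stratified within the 3-hour duty
    window (one per equal sub-bin, jittered, so successive fixes stay well
    separated); each fix draws a location class, adds isotropic Gaussian
    noise with SD = noise_sd_factor * class radius, and records the class
    error radius.
    """
    classes = list(params.lc_probs)
    probs = np.array([params.lc_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    radius = np.array([CLASS_ERROR_RADIUS[c] for c in classes])
    w0, w1 = params.fix_window_utc
    window_s = (w1 - w0) * 3600.0
    n_days = (params.end - params.start).days
    rows = []
    for animal in sorted(paths):
        path = paths[animal]
        for day in range(n_days):
            n_fix = int(np.clip(round(rng.normal(params.fixes_per_day_mean,
                                                 params.fixes_per_day_sd)),
                                0, params.max_fixes_per_day))
            if n_fix == 0:
                continue
            binw = window_s / n_fix
            offs = (np.arange(n_fix) + rng.uniform(0.15, 0.85, n_fix)) * binw
            day_start_s = day * 86400.0 + w0 * 3600.0
            idx = ((day_start_s + offs) // DT_S).astype(int)
            idx = np.unique(np.clip(idx, 0, len(path) - 1))
            ci = rng.choice(len(classes), size=len(idx), p=probs)
            noise = rng.normal(0.0, 1.0, (len(idx), 2)) * (
                params.noise_sd_factor * radius[ci]
            )[:, None]
            for j, i in enumerate(idx):
                rows.append(
                    (
                        animal,
                        params.t0 + timedelta(seconds=float(times_s[i])),
                        path[i, 0] + noise[j, 0],
                        path[i, 1] + noise[j, 1],
                        classes[ci[j]],
                        radius[ci[j]],
                    )
                )
    table = pd.DataFrame(
        rows, columns=["animal_id", "timestamp", "x", "y", "lc", "error_radius"]
    )
    table["timestamp"] = pd.to_datetime(table["timestamp"], utc=True)
    return table.sort_values(["animal_id", "timestamp"]).reset_index(drop=True)


def _schedule_sites(
    params: ScenarioParams, centers: dict[str, tuple[float, float]],
    rng: np.random.Generator,
) -> tuple[list[CarcassSite], list[Excursion]]:
    coast_m = params.coast_km * 1000.0
    span_days = (params.carcass_latest_start - params.carcass_earliest).days
    sites: list[CarcassSite] = []
    n_sites = params.n_planted + params.n_distractor
    for s in range(n_sites):
        planted = s < params.n_planted
        for _ in range(500):
            x = rng.uniform(0.08, 0.92) * coast_m
            y = -rng.uniform(*params.carcass_offshore_km) * 1000.0
            if all(np.hypot(x - c.x, y - c.y) >= params.min_site_spacing_m for c in sites):
                break
        start = params.carcass_earliest + timedelta(days=int(rng.integers(0, span_days + 1)))
        dur = int(rng.integers(params.carcass_duration_days[0],
                               params.carcass_duration_days[1] + 1))
        sites.append(
            CarcassSite(
                site_id=f"{'C' if planted else 'D'}{s + 1}",
                x=float(x), y=float(y),
                start=start, end=start + timedelta(days=dur - 1),
                planted=planted,
            )
        )

    animals = list(centers)
    busy: dict[str, list[tuple[datetime, datetime]]] = {a: [] for a in animals}
    excursions: list[Excursion] = []

    def schedule_visit(animal: str, site: CarcassSite) -> Excursion | None:
        cx, cy = centers[animal]
        travel_s = np.hypot(cx - site.x, cy - site.y) / (
            params.travel_speed_kmh * 1000.0 / 3600.0
        )
        window_days = (site.end - site.start).days + 1
        for _ in range(8):
            stay = int(rng.integers(params.stay_days_range[0],
                                    min(params.stay_days_range[1], window_days) + 1))
            first = int(rng.integers(0, window_days - stay + 1))
            d0 = site.start + timedelta(days=first)
            t_arr = datetime.combine(d0, time(10), tzinfo=timezone.utc)
            t_leave = datetime.combine(d0 + timedelta(days=stay - 1), time(20),
                                       tzinfo=timezone.utc)
            t_dep = t_arr - timedelta(seconds=float(travel_s))
            t_ret = t_leave + timedelta(seconds=float(travel_s))
            if t_dep <= params.t0 + timedelta(hours=1):
                continue
            if t_ret >= datetime.combine(params.end, time(0), tzinfo=timezone.utc):
                continue
            pad = timedelta(hours=2)
            if any(not (t_ret + pad < b0 or t_dep - pad > b1) for b0, b1 in busy[animal]):
                continue
            busy[animal].append((t_dep, t_ret))
            return Excursion(animal, site.site_id, t_dep, t_arr, t_leave, t_ret, stay)
        return None

    for site in sites:
        lo, hi = (params.planted_members if site.planted else params.distractor_members)
        m = int(rng.integers(lo, min(hi, len(animals)) + 1))
        chosen = list(rng.choice(animals, size=m, replace=False))
        scheduled: set[str] = set()
        for animal in chosen:
            e = schedule_visit(animal, site)
            if e is None:
                continue
            excursions.append(e)
            scheduled.add(animal)
            if (
                rng.random() < params.repeat_visit_prob
                and (site.end - site.start).days >= 3
            ):
                e2 = schedule_visit(animal, site)
                if e2 is not None:
                    excursions.append(e2)
        if site.planted and len(scheduled) < lo:
            for animal in rng.permutation([a for a in animals if a not in set(chosen)]):
                if len(scheduled) >= lo:
                    break
                e = schedule_visit(str(animal), site)
                if e is not None:
                    excursions.append(e)
                    scheduled.add(str(animal))
        logger.debug("site %s: %d scheduled visitors", site.site_id, len(scheduled))
    return sites, excursions


def default_scenario(seed: int, params: ScenarioParams | None = None):
    """Full synthetic study: returns (location table, land mask, truth).

    24 foxes, 5 planted carcass sites active 8-17 days each in midwinter
    with 3-12 scheduled visitors and occasional repeat visits, plus 2
    distractor sites visited by at most 2 foxes.
    """
    params = params or ScenarioParams()
    rng = np.random.default_rng(seed)
    mask, centers = make_landscape(params, rng)
    sites, excursions = _schedule_sites(params, centers, rng)
    times_s, paths = simulate_paths(params, centers, sites, excursions, rng)
    locations = observe_argos(times_s, paths, params, rng)
    truth = SyntheticTruth(
        centers=centers, carcasses=sites, excursions=excursions,
        times_s=times_s, paths=paths,
    )
    return locations, mask, truth


def simulate_brownian_track(
    rng: np.random.Generator,
    n_fixes: int = 200,
    dt_s: float = 1800.0,
    sigma2m: float = 100.0,
    sigma2m_second: float | None = None,
    error_sd_m: float = 125.0,
    animal_id: str = "B01",
    start: datetime | None = None,
) -> pd.DataFrame:
    """Pure planar Brownian motion sampled at regular intervals with known
    Gaussian observation error; the calibration input for variance-recovery
    and changepoint checks of the dBBMM estimator.

    If ``sigma2m_second`` is given, the second half of the track diffuses at
    that rate instead (a step change at the midpoint). The emitted
    ``error_radius`` is ``2 * error_sd_m``, matching the package's
    radius-to-SD convention.
    """
    start = start or datetime(2010, 11, 1, tzinfo=timezone.utc)
    t = np.arange(n_fixes) * dt_s
    s2 = np.full(n_fixes - 1, sigma2m)
    if sigma2m_second is not None:
        s2[(n_fixes - 1) // 2 :] = sigma2m_second
    step_sd = np.sqrt(s2 * dt_s)
    x = np.concatenate([[0.0], np.cumsum(rng.normal(0.0, step_sd))])
    y = np.concatenate([[0.0], np.cumsum(rng.normal(0.0, step_sd))])
    x_obs = x + rng.normal(0.0, error_sd_m, n_fixes)
    y_obs = y + rng.normal(0.0, error_sd_m, n_fixes)
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "timestamp": [start + timedelta(seconds=float(s)) for s in t],
            "x": x_obs,
            "y": y_obs,
            "lc": "3",
            "error_radius": 2.0 * error_sd_m,
        }
    )


def truth_to_json(truth: SyntheticTruth) -> dict:
    """Serializable ledger (without the full-resolution paths)."""
    return {
        "centers": {a: list(c) for a, c in truth.centers.items()},
        "carcasses": [
            {
                "site_id": c.site_id, "x": c.x, "y": c.y,
                "start": c.start.isoformat(), "end": c.end.isoformat(),
                "planted": c.planted,
            }
            for c in truth.carcasses
        ],
        "excursions": [
            {
                "animal_id": e.animal_id, "site_id": e.site_id,
                "t_dep": e.t_dep.isoformat(), "t_arr": e.t_arr.isoformat(),
                "t_leave": e.t_leave.isoformat(), "t_ret": e.t_ret.isoformat(),
                "stay_days": e.stay_days,
            }
            for e in truth.excursions
        ],
    }
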