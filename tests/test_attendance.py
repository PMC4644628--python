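from datetime import date

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from icefox.attendance import (
    SeasonSummary,
    classify_days,
    coast_distance,
    daily_presence,
    hotspot_summary,
    join_distance,
    next_day_return_share,
    nonjoiner_distance,
    repeat_visit_share,
    return_lag,
    sea_fix_flags,
    season_summary,
    visitor_summary_stats,
    visits,
)
from icefox.grids import GridGeometry, UDGrid
from icefox.landmask import straight_coast_mask
from conftest import make_traj

MASK = straight_coast_mask(60_000, 15_000)
HR = box(0, 0, 4000, 4000)  # a 4x4 km home range on land


def day_pts(day, pts, **kw):
    """(minutes within day, x, y) -> location rows on the given day index."""
    return make_traj([(day * 1440 + m, x, y) for m, x, y in pts], **kw)


class TestSeaFixFlags:
    def test_inside_home_range_is_land(self):
        traj = make_traj([(0, 2000, 2000)])
        assert not sea_fix_flags(traj, HR, MASK)[0]

    def test_far_offshore_is_sea(self):
        traj = make_traj([(0, 2000, -5000)], error_radius=500.0)
        assert sea_fix_flags(traj, HR, MASK)[0]

    def test_within_error_of_boundary_is_land(self):
        # 200 m beyond the range boundary with a 1500 m error radius
        traj = make_traj([(0, 2000, -200)], error_radius=1500.0, lc="1")
        assert not sea_fix_flags(traj, HR, MASK)[0]

    def test_beyond_error_radius_is_sea(self):
        traj = make_traj([(0, 2000, -2000)], error_radius=1500.0, lc="1")
        assert sea_fix_flags(traj, HR, MASK)[0]


class TestClassifyDays:
    def test_any_sea_fix_makes_a_sea_day(self):
        traj = pd.concat(
            [day_pts(0, [(600, 2000, 2000), (700, 2000, -6000)]),
             day_pts(1, [(600, 2000, 2000)])],
            ignore_index=True,
        )
        flags = sea_fix_flags(traj, HR, MASK)
        days = classify_days(traj, flags)
        assert days[date(2010, 11, 1)] == "sea"
        assert days[date(2010, 11, 2)] == "land"
        # hotspot presence days must be a subset of sea days
        poly = box(1000, -7000, 3000, -5000)
        presence = daily_presence(traj, flags, poly)
        assert presence <= {d for d, c in days.items() if c == "sea"}


class TestPresenceAndVisits:
    def test_no_fixes_in_polygon_empty(self):
        traj = day_pts(0, [(600, 2000, -6000)], error_radius=250.0)
        flags = sea_fix_flags(traj, HR, MASK)
        assert daily_presence(traj, flags, box(20000, -9000, 22000, -7000)) == set()

    def test_dates_with_fixes_inside(self):
        poly = box(1000, -7000, 3000, -5000)
        traj = pd.concat(
            [day_pts(d, [(600, 2000, -6000)]) for d in (0, 1, 4)], ignore_index=True
        )
        flags = sea_fix_flags(traj, HR, MASK)
        got = daily_presence(traj, flags, poly)
        assert got == {date(2010, 11, 1), date(2010, 11, 2), date(2010, 11, 5)}

    def test_visit_runs(self):
        d = date(2010, 11, 1)
        assert visits({d}) == [(d, d)]
        got = visits({date(2010, 11, 1), date(2010, 11, 2), date(2010, 11, 5)})
        assert got == [
            (date(2010, 11, 1), date(2010, 11, 2)),
            (date(2010, 11, 5), date(2010, 11, 5)),
        ]
        assert visits(set()) == []


class TestDistances:
    def test_join_distance_due_north(self):
        traj = day_pts(0, [(600, 0, 10_000)])
        d = join_distance(traj, date(2010, 11, 2), (0.0, 0.0))
        assert d == pytest.approx(10.0)

    def test_join_distance_at_center_zero(self):
        traj = day_pts(0, [(600, 0, 0)])
        assert join_distance(traj, date(2010, 11, 2), (0.0, 0.0)) == pytest.approx(0.0)

    def test_join_distance_uses_last_fix_of_prior_day(self):
        traj = day_pts(0, [(600, 0, 20_000), (700, 0, 5_000)])
        assert join_distance(traj, date(2010, 11, 2), (0.0, 0.0)) == pytest.approx(5.0)

    def test_join_distance_missing_prior_day(self):
        traj = day_pts(3, [(600, 0, 5000)])
        assert join_distance(traj, date(2010, 11, 2), (0.0, 0.0)) is None

    def test_nonjoiner_stationary(self):
        traj = pd.concat([day_pts(d, [(600, 20_000, 0)]) for d in range(3)],
                         ignore_index=True)
        d = nonjoiner_distance(traj, (0.0, 0.0), date(2010, 11, 1), date(2010, 11, 3))
        assert d == pytest.approx(20.0)

    def test_nonjoiner_closest_approach(self):
        traj = pd.concat(
            [day_pts(0, [(600, 30_000, 0)]), day_pts(2, [(600, 8_000, 0)]),
             day_pts(3, [(600, 25_000, 0)])],
            ignore_index=True,
        )
        d = nonjoiner_distance(traj, (0.0, 0.0), date(2010, 11, 1), date(2010, 11, 4))
        assert d == pytest.approx(8.0)

    def test_distances_ignore_fixes_outside_date_range(self):
        base = pd.concat([day_pts(0, [(600, 0, 10_000)])], ignore_index=True)
        extra = pd.concat([base, day_pts(9, [(600, 0, 1)])], ignore_index=True)
        assert join_distance(base, date(2010, 11, 2), (0, 0)) == join_distance(
            extra, date(2010, 11, 2), (0, 0)
        )
        assert nonjoiner_distance(
            base, (0, 0), date(2010, 11, 1), date(2010, 11, 3)
        ) == nonjoiner_distance(extra, (0, 0), date(2010, 11, 1), date(2010, 11, 3))

    def test_coast_distance_inland(self):
        geom = GridGeometry(0, 14_000, 1000, 2, 2)  # centers at y=14.5/15.5 km
        vals = np.array([[0.0, 0.0], [0.5, 0.5]])  # mass at y=14.5 km
        ud = UDGrid(geom, vals)
        contour = vals > 0
        assert coast_distance(contour, ud, MASK) == pytest.approx(14.5)
        assert coast_distance(contour, ud, MASK) >= 0


class TestReturnLag:
    def test_next_day_return(self):
        traj = pd.concat(
            [day_pts(0, [(600, 2000, -6000)]), day_pts(1, [(600, 2000, 2000)])],
            ignore_index=True,
        )
        assert return_lag(traj, HR, date(2010, 11, 1)) == 1

    def test_two_day_return(self):
        traj = pd.concat(
            [day_pts(0, [(600, 2000, -6000)]), day_pts(1, [(600, 9000, 9000)]),
             day_pts(2, [(600, 2000, 2000)])],
            ignore_index=True,
        )
        assert return_lag(traj, HR, date(2010, 11, 1)) == 2

    def test_never_back_within_horizon(self):
        traj = day_pts(0, [(600, 2000, -6000)])
        assert return_lag(traj, HR, date(2010, 11, 1)) is None


class TestSeasonSummary:
    def _summary(self, land, sea, hotspot):
        return SeasonSummary("A", tracked_days=land + sea, land_days=land,
                             sea_days=sea, hotspot_days=hotspot,
                             n_hotspots=1 if hotspot else 0)

    def test_printed_per_row_shares(self):
        # published rows: 16 hotspot days of 26 sea days; 13 of 29
        assert self._summary(74, 26, 16).pct_sea_days_at_hotspots == 61.5
        assert self._summary(71, 29, 13).pct_sea_days_at_hotspots == 44.8

    def test_never_at_sea_share_undefined(self):
        s = self._summary(100, 0, 0)
        assert s.pct_land == 100.0
        assert s.pct_sea_days_at_hotspots is None

    def test_from_day_classes(self):
        days = pd.Series(
            {date(2010, 11, 1): "land", date(2010, 11, 2): "sea",
             date(2010, 11, 3): "sea", date(2011, 4, 1): "sea"},
        )
        presence = {"H1": {date(2010, 11, 2), date(2011, 4, 1)}}
        s = season_summary("A", days, presence,
                           (date(2010, 10, 25), date(2011, 3, 15)))
        assert s.tracked_days == 3  # the April day is outside the window
        assert s.sea_days == 2
        assert s.hotspot_days == 1
        assert s.pct_land == pytest.approx(33.3)

    def test_visitor_stats_require_visitors(self):
        with pytest.raises(ValueError):
            visitor_summary_stats([self._summary(10, 0, 0)])


class TestPrintedProportionOps:
    def test_repeat_visit_share(self):
        assert repeat_visit_share([2, 1, 1, 3]) == 50.0

    def test_next_day_return_share(self):
        assert next_day_return_share([1, 1, 2, None]) == pytest.approx(66.7)


class TestHotspotSummary:
    def test_single_member_single_day(self):
        from icefox.attendance import AttendanceRecord
        r = AttendanceRecord("A", "H1", [date(2010, 11, 1)],
                             [(date(2010, 11, 1), date(2010, 11, 1))], [None])
        s = hotspot_summary([r])
        assert s["duration_days"] == 1
        assert s["peak_attendance"] == 1
        assert s["repeat_visit_instances"] == 0

    def test_overlapping_members_peak(self):
        from icefox.attendance import AttendanceRecord
        d1, d2 = date(2010, 11, 1), date(2010, 11, 2)
        a = AttendanceRecord("A", "H1", [d1, d2], [(d1, d2)], [None])
        b = AttendanceRecord("B", "H1", [d2], [(d2, d2)], [None])
        s = hotspot_summary([a, b])
        assert s["peak_attendance"] == 2
        assert s["n_members"] == 2
        assert s["duration_days"] == 2

    def test_repeat_instance_counted(self):
        from icefox.attendance import AttendanceRecord
        d1, d3 = date(2010, 11, 1), date(2010, 11, 3)
        a = AttendanceRecord("A", "H1", [d1, d3], [(d1, d1), (d3, d3)], [None, None])
        assert hotspot_summary([a])["repeat_visit_instances"] == 1
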