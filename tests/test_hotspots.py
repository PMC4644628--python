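from datetime import date

import numpy as np
import pytest

from icefox.grids import GridGeometry, UDGrid
from icefox.hotspots import (
    HotspotDraft,
    candidate_regions,
    hotspot_center,
    make_time_slices,
    mask_and_rescale,
    merge_across_slices,
    overlap_count,
    population_ud,
    synchrony_filter,
)
from icefox.landmask import straight_coast_mask

GEOM = GridGeometry(0, -4000, 1000, 8, 10)  # rows 0-3 land (y>0), 4-7 sea


def _ud(values):
    v = np.asarray(values, dtype=float)
    return UDGrid(GEOM, v / v.sum())


def _mask():
    return straight_coast_mask(10_000, 3_000, pad_m=1000.0)


class TestTimeSlices:
    def test_documented_start_dates(self):
        slices = make_time_slices(date(2010, 10, 25), date(2010, 12, 1))
        assert [s.start for s in slices[:3]] == [
            date(2010, 10, 25), date(2010, 11, 8), date(2010, 11, 22),
        ]
        assert all(s.days == 30 for s in slices)

    def test_short_span_single_truncated_slice(self):
        slices = make_time_slices(date(2010, 10, 25), date(2010, 11, 5))
        assert len(slices) == 1
        assert slices[0].truncated

    def test_step_is_14_days(self):
        slices = make_time_slices(date(2010, 10, 25), date(2011, 6, 1))
        steps = {(b.start - a.start).days for a, b in zip(slices, slices[1:])}
        assert steps == {14}
        assert all(s.start < date(2011, 6, 1) for s in slices)


class TestPopulationUD:
    def test_single_animal_identity(self, rng):
        ud = _ud(rng.random((8, 10)))
        np.testing.assert_allclose(population_ud([ud]).values, ud.values)

    def test_two_identical_uds_unchanged(self, rng):
        ud = _ud(rng.random((8, 10)))
        np.testing.assert_allclose(population_ud([ud, ud]).values, ud.values)

    def test_disjoint_uds_split_mass(self):
        a = np.zeros((8, 10)); a[0, 0] = 1.0
        b = np.zeros((8, 10)); b[7, 9] = 1.0
        pop = population_ud([_ud(a), _ud(b)])
        assert pop.values[0, 0] == pytest.approx(0.5)
        assert pop.values[7, 9] == pytest.approx(0.5)

    def test_permutation_invariance(self, rng):
        uds = [_ud(rng.random((8, 10))) for _ in range(4)]
        p1 = population_ud(uds)
        p2 = population_ud(uds[::-1])
        np.testing.assert_allclose(p1.values, p2.values)

    def test_geometry_mismatch_errors(self, rng):
        other = UDGrid(GridGeometry(0, 0, 1000, 8, 10), np.full((8, 10), 1 / 80))
        with pytest.raises(ValueError, match="geometry"):
            population_ud([_ud(rng.random((8, 10))), other])


class TestMaskAndRescale:
    def test_sea_only_ud_identity(self):
        v = np.zeros((8, 10)); v[5, :] = 1.0
        out = mask_and_rescale(_ud(v), _mask())
        np.testing.assert_allclose(out.values, _ud(v).values)

    def test_half_mass_on_land_doubles_sea(self):
        v = np.zeros((8, 10)); v[0, 0] = 0.5; v[6, 0] = 0.5
        out = mask_and_rescale(_ud(v), _mask())
        assert out.values[0, 0] == 0.0
        assert out.values[6, 0] == pytest.approx(1.0)
        assert abs(out.total_mass - 1.0) <= 1e-9

    def test_zero_sea_mass_errors(self):
        v = np.zeros((8, 10)); v[0, 0] = 1.0
        with pytest.raises(ValueError, match="zero mass at sea"):
            mask_and_rescale(_ud(v), _mask())


class TestOverlapAndRegions:
    def test_single_animal_counts_binary(self, rng):
        counts = overlap_count([_ud(rng.random((8, 10)))])
        assert set(np.unique(counts)) <= {0, 1}

    def test_common_high_use_cell_counts_three(self):
        uds = []
        for _ in range(3):
            v = np.full((8, 10), 1e-6)
            v[5, 5] = 1.0
            uds.append(_ud(v))
        counts = overlap_count(uds)
        assert counts[5, 5] == 3
        assert counts.max() <= 3

    def test_all_below_threshold_no_regions(self):
        counts = np.zeros((8, 10), dtype=int)
        land = _mask().land_grid(GEOM)
        assert candidate_regions(counts, land) == []

    def test_single_blob_one_region(self):
        counts = np.zeros((8, 10), dtype=int)
        counts[5, 2:4] = 3
        regions = candidate_regions(counts, _mask().land_grid(GEOM))
        assert len(regions) == 1
        assert regions[0].sum() == 2

    def test_diagonal_blobs_join_under_queen_connectivity(self):
        counts = np.zeros((8, 10), dtype=int)
        counts[5, 2] = 3
        counts[6, 3] = 3
        regions = candidate_regions(counts, _mask().land_grid(GEOM))
        assert len(regions) == 1

    def test_land_cells_never_candidates(self):
        counts = np.full((8, 10), 5, dtype=int)
        regions = candidate_regions(counts, _mask().land_grid(GEOM))
        land = _mask().land_grid(GEOM)
        for reg in regions:
            assert not np.any(reg & land)


def _slice(i):
    return make_time_slices(date(2010, 10, 25), date(2011, 6, 1))[i]


def _blob(cells):
    m = np.zeros((8, 10), dtype=bool)
    for r, c in cells:
        m[r, c] = True
    return m


class TestMergeAcrossSlices:
    def test_same_blob_in_overlapping_slices_is_one_draft(self):
        blob = _blob([(5, 5), (5, 6)])
        drafts = merge_across_slices([(_slice(0), [blob]), (_slice(1), [blob])], GEOM)
        assert len(drafts) == 1
        assert [s.index for s in drafts[0].slices] == [0, 1]

    def test_disjoint_blobs_stay_separate(self):
        d = merge_across_slices(
            [(_slice(0), [_blob([(5, 1)])]), (_slice(2), [_blob([(7, 8)])])], GEOM
        )
        assert len(d) == 2

    def test_transitive_chain_unions(self):
        a = _blob([(5, 1), (5, 2)])
        b = _blob([(5, 2), (5, 3)])
        c = _blob([(5, 3), (5, 4)])
        drafts = merge_across_slices(
            [(_slice(0), [a]), (_slice(1), [b]), (_slice(2), [c])], GEOM
        )
        assert len(drafts) == 1
        assert drafts[0].cells.sum() == 4


class TestSynchronyFilter:
    def _draft(self):
        cells = _blob([(5, 5)])
        from icefox.dbbmm import cells_to_polygon
        return HotspotDraft(cells, cells_to_polygon(cells, GEOM), [_slice(0)])

    def test_isolated_single_days_removed(self):
        presence = {0: {
            "F1": {date(2010, 11, 1)},
            "F2": {date(2010, 11, 3)},
            "F3": {date(2010, 11, 6)},
        }}
        assert synchrony_filter([self._draft()], presence) == []

    def test_three_members_one_consecutive_run_retained(self):
        presence = {0: {
            "F1": {date(2010, 11, 1), date(2010, 11, 2), date(2010, 11, 3)},
            "F2": {date(2010, 11, 2)},
            "F3": {date(2010, 11, 5)},
        }}
        out = synchrony_filter([self._draft()], presence)
        assert len(out) == 1
        assert out[0].members == ["F1", "F2", "F3"]
        assert out[0].first_date == date(2010, 11, 1)
        assert out[0].last_date == date(2010, 11, 5)

    def test_two_members_insufficient(self):
        presence = {0: {
            "F1": {date(2010, 11, 1), date(2010, 11, 2)},
            "F2": {date(2010, 11, 2)},
        }}
        assert synchrony_filter([self._draft()], presence) == []

    def test_empty_draft_list(self):
        assert synchrony_filter([], {}) == []


class TestHotspotCenter:
    def test_single_cell(self):
        v = np.zeros((8, 10)); v[5, 5] = 1.0
        center = hotspot_center(_blob([(5, 5)]), _ud(v))
        assert center == GEOM.cell_center(5, 5)

    def test_picks_highest_ud_cell(self):
        v = np.full((8, 10), 1e-9)
        v[5, 5] = 0.2; v[5, 6] = 0.1
        assert hotspot_center(_blob([(5, 5), (5, 6)]), _ud(v)) == GEOM.cell_center(5, 5)

    def test_exact_tie_breaks_lexicographically(self):
        v = np.full((8, 10), 1e-9)
        v[5, 6] = v[6, 5] = 0.25
        assert hotspot_center(_blob([(5, 6), (6, 5)]), _ud(v)) == GEOM.cell_center(5, 6)
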