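"""Zone delineation and zone statistics against brute-force oracles."""

import numpy as np
import pytest

from ppct import (
    ThicknessGrid,
    ZoneBinSpec,
    cube_bin_counts,
    delineate_zones,
    group_zone_summary,
    mean_thickness_map,
    subject_zone_means,
)
from ppct.zones import ZONE_LABELS

from conftest import make_grid


def oracle_zone(v):
    """Exhaustive if/else classification of one cube mean."""
    if v < 105:
        return 2
    elif v < 140:
        return 3
    elif v < 175:
        return 4
    return 5


class TestMeanMap:
    def test_single_subject_identity(self, random_grid, mask):
        mm = mean_thickness_map([random_grid])
        np.testing.assert_array_equal(
            mm.values[mask.analyzed], random_grid.values[mask.analyzed]
        )

    def test_two_constant_grids_average(self, mask):
        mm = mean_thickness_map([make_grid(100.0), make_grid(120.0)])
        assert np.allclose(mm.values[mask.analyzed], 110.0)

    def test_matches_per_cell_loop_oracle(self, rng, mask, geometry):
        grids = [
            make_grid(rng.uniform(50, 250, (geometry.n_rows, geometry.n_cols)))
            for _ in range(5)
        ]
        mm = mean_thickness_map(grids)
        for r in range(geometry.n_rows):
            for c in range(geometry.n_cols):
                if mask.analyzed[r, c]:
                    expected = sum(g.values[r, c] for g in grids) / 5
                    assert mm.values[r, c] == pytest.approx(expected)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_thickness_map([])

    def test_mixed_laterality_rejected_unless_mirroring(self, constant_grid):
        os_grid = make_grid(100.0, subject_id="s2", laterality="OS")
        with pytest.raises(ValueError, match="laterality"):
            mean_thickness_map([constant_grid, os_grid])
        mm = mean_thickness_map([constant_grid, os_grid], allow_mirroring=True)
        assert mm.n_subjects == 2


class TestDelineation:
    @pytest.mark.parametrize(
        "value,zone", [(104.9, 2), (105.0, 3), (139.9, 3), (140.0, 4),
                       (174.9, 4), (175.0, 5), (70.0, 2), (300.0, 5)]
    )
    def test_threshold_boundaries(self, value, zone, mask):
        mm = mean_thickness_map([make_grid(value)])
        zm = delineate_zones(mm, ZoneBinSpec(), mask)
        assert zm.zone_cube_counts[zone] == 588

    def test_constant_map_single_zone(self, mask):
        zm = delineate_zones(mean_thickness_map([make_grid(150.0)]),
                             ZoneBinSpec(), mask)
        assert zm.zone_cube_counts == {2: 0, 3: 0, 4: 588, 5: 0}

    def test_matches_if_else_oracle(self, rng, mask, geometry):
        vals = rng.uniform(60, 220, (geometry.n_rows, geometry.n_cols))
        zm = delineate_zones(mean_thickness_map([make_grid(vals)]),
                             ZoneBinSpec(), mask)
        for r in range(geometry.n_rows):
            for c in range(geometry.n_cols):
                if mask.analyzed[r, c]:
                    assert zm.assignment[r, c] == oracle_zone(vals[r, c])
                else:
                    assert zm.assignment[r, c] == 1  # ONH is zone 1

    def test_partition_covers_all_analyzed_cubes(self, random_grid, mask):
        zm = delineate_zones(mean_thickness_map([random_grid]), ZoneBinSpec(), mask)
        assert sum(zm.zone_cube_counts.values()) == 588

    def test_undefined_cell_rejected(self, random_grid, mask):
        mm = mean_thickness_map([random_grid])
        mm.values[0, 0] = np.nan  # an analysed corner cube
        with pytest.raises(ValueError, match="undefined"):
            delineate_zones(mm, ZoneBinSpec(), mask)

    def test_bad_bin_spec(self):
        with pytest.raises(ValueError):
            ZoneBinSpec(edges=(140.0, 105.0, 175.0))
        with pytest.raises(ValueError):
            ZoneBinSpec(reporting_floor=120.0)


class TestZoneStatistics:
    @pytest.fixture()
    def zonemap(self, rng, mask):
        vals = rng.uniform(60, 220, (26, 26))
        return delineate_zones(mean_thickness_map([make_grid(vals)]),
                               ZoneBinSpec(), mask)

    def test_constant_grid_zone_means(self, zonemap, constant_grid):
        means = subject_zone_means(constant_grid, zonemap)
        for z in ZONE_LABELS:
            if zonemap.zone_cube_counts[z] > 0:
                assert means[z] == pytest.approx(100.0)

    def test_matches_per_zone_loop_oracle(self, zonemap, random_grid):
        means = subject_zone_means(random_grid, zonemap)
        for z in ZONE_LABELS:
            cubes = [
                random_grid.values[r, c]
                for r in range(26) for c in range(26)
                if zonemap.assignment[r, c] == z
            ]
            if cubes:
                assert means[z] == pytest.approx(np.mean(cubes))

    def test_identical_subjects_zero_sd(self, zonemap, constant_grid):
        twin = make_grid(100.0, subject_id="s2")
        summary = group_zone_summary([constant_grid, twin], zonemap)
        for z in ZONE_LABELS:
            if zonemap.zone_cube_counts[z] > 0:
                assert summary[z][1] == pytest.approx(0.0)

    def test_two_point_closed_form_sd(self, zonemap):
        cohort = [make_grid(100.0, "a"), make_grid(120.0, "b")]
        summary = group_zone_summary(cohort, zonemap)
        for z in ZONE_LABELS:
            if zonemap.zone_cube_counts[z] > 0:
                mean, sd, n = summary[z]
                assert mean == pytest.approx(110.0)
                assert sd == pytest.approx(np.sqrt(200.0))  # ~14.142
                assert n == 2

    def test_single_subject_sd_flagged_nan(self, zonemap, constant_grid):
        summary = group_zone_summary([constant_grid], zonemap)
        assert all(np.isnan(summary[z][1]) for z in ZONE_LABELS)


class TestBinCounts:
    def test_constant_map(self, mask):
        counts = cube_bin_counts(mean_thickness_map([make_grid(150.0)]),
                                 ZoneBinSpec(), mask)
        assert counts == (0, 0, 0, 588, 0)

    def test_below_floor_boundary(self, mask, geometry):
        vals = np.full((26, 26), 150.0)
        rr, cc = np.nonzero(mask.analyzed)
        vals[rr[0], cc[0]] = 69.9
        counts = cube_bin_counts(mean_thickness_map([make_grid(vals)]),
                                 ZoneBinSpec(), mask)
        assert counts[0] == 1
        assert sum(counts) == 588

    def test_matches_histogram_oracle(self, rng, mask):
        vals = rng.uniform(40, 260, (26, 26))
        counts = cube_bin_counts(mean_thickness_map([make_grid(vals)]),
                                 ZoneBinSpec(), mask)
        v = vals[mask.analyzed]
        expected = (
            int((v < 70).sum()),
            int(((v >= 70) & (v < 105)).sum()),
            int(((v >= 105) & (v < 140)).sum()),
            int(((v >= 140) & (v < 175)).sum()),
            int((v >= 175).sum()),
        )
        assert counts == expected
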