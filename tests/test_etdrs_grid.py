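import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from colorfaf import etdrs_grid as eg
from colorfaf.imaging_io import ExclusionMask, ImageMetadata, SECTORS
from colorfaf.spectral import decompose

from conftest import make_uniform_image


def small_grid(nasal_side="right", um_per_pixel=15.0, shape=(421, 421)):
    center = ((shape[0] - 1) / 2, (shape[1] - 1) / 2)
    return eg.ETDRSGrid(center=center, um_per_pixel=um_per_pixel, nasal_side=nasal_side), shape


def brute_force_sector_labels(grid, shape):
    """Independent per-pixel sector assignment by explicit loops."""
    labels = np.full(shape, "", dtype=object)
    cr, cc = grid.center
    for r in range(shape[0]):
        for c in range(shape[1]):
            d = math.hypot(r - cr, c - cc) * grid.um_per_pixel
            if d >= 3000:
                continue
            if d < 500:
                labels[r, c] = "fovea"
                continue
            ring = "inner" if d < 1500 else "outer"
            ang = math.degrees(math.atan2(cr - r, c - cc)) % 360.0
            # boundary pixels belong to the counter-clockwise side
            if 45.0 <= ang < 135.0:
                quad = "superior"
            elif 135.0 <= ang < 225.0:
                quad = "left"
            elif 225.0 <= ang < 315.0:
                quad = "inferior"
            else:
                quad = "right"
            if quad in ("left", "right"):
                quad = "nasal" if quad == grid.nasal_side else "temporal"
            labels[r, c] = f"{ring}_{quad}"
    return labels


def brute_force_best_site(allowed, margin=25):
    """Exhaustive largest-inscribed-clean-disc search (lexicographic ties).

    The search is cropped to the allowed region's bounding box plus a
    margin exceeding any possible clearance, keeping the pairwise
    distance matrix small without changing the optimum.
    """
    rows, cols = np.nonzero(allowed)
    r0, r1 = max(rows.min() - margin, 0), min(rows.max() + margin + 1, allowed.shape[0])
    c0, c1 = max(cols.min() - margin, 0), min(cols.max() + margin + 1, allowed.shape[1])
    window = allowed[r0:r1, c0:c1]
    good = np.argwhere(window)
    bad = np.argwhere(~window)
    dists = cdist(good, bad).min(axis=1)
    best = np.max(dists)
    candidates = good[dists == best]
    order = np.lexsort((candidates[:, 1], candidates[:, 0]))
    winner = candidates[order[0]]
    return (int(winner[0]) + r0, int(winner[1]) + c0), float(best)


class TestSectorGeometry:
    def test_sector_labels_match_brute_force(self):
        grid, shape = small_grid(um_per_pixel=100.0, shape=(71, 71))
        expected = brute_force_sector_labels(grid, shape)
        masks = eg.all_sector_masks(grid, shape)
        for s in SECTORS:
            assert np.array_equal(masks[s], expected == s), s

    def test_partition_of_six_mm_disc(self):
        grid, shape = small_grid()
        masks = eg.all_sector_masks(grid, shape)
        union = np.zeros(shape, dtype=bool)
        total = 0
        for s in SECTORS:
            assert not (union & masks[s]).any(), f"{s} overlaps another sector"
            union |= masks[s]
            total += masks[s].sum()
        disc = eg.grid_disc_mask(grid, shape)
        assert np.array_equal(union, disc)
        assert total == disc.sum()

    def test_central_area_near_analytic(self):
        grid, shape = small_grid(um_per_pixel=5.0, shape=(1205, 1205))
        area = eg.sector_mask(grid, "fovea", shape).sum()
        assert area == pytest.approx(math.pi * 100.0**2, rel=0.01)

    def test_inner_to_central_area_ratio(self):
        grid, shape = small_grid()
        masks = eg.all_sector_masks(grid, shape)
        ratio = masks["inner_superior"].sum() / masks["fovea"].sum()
        # analytic: pi (1.5^2 - 0.5^2) / 4 / (pi 0.5^2) = 2
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_laterality_flip_swaps_nasal_temporal_only(self):
        od, shape = small_grid(nasal_side="right")
        os_, _ = small_grid(nasal_side="left")
        m_od = eg.all_sector_masks(od, shape)
        m_os = eg.all_sector_masks(os_, shape)
        for ring in ("inner", "outer"):
            assert np.array_equal(m_od[f"{ring}_nasal"], m_os[f"{ring}_temporal"])
            assert np.array_equal(m_od[f"{ring}_temporal"], m_os[f"{ring}_nasal"])
        for s in ("fovea", "inner_superior", "inner_inferior", "outer_superior", "outer_inferior"):
            assert np.array_equal(m_od[s], m_os[s])

    def test_grid_exceeding_bounds_rejected(self):
        grid = eg.ETDRSGrid(center=(10, 10), um_per_pixel=15.0, nasal_side="right")
        with pytest.raises(eg.GridError, match="exceeds image"):
            eg.all_sector_masks(grid, (421, 421))


class TestSelectSite:
    def test_symmetric_central_sector_picks_grid_center(self):
        grid, shape = small_grid()
        mask = eg.sector_mask(grid, "fovea", shape)
        site = eg.select_site(mask, None, radius_um=100, grid=grid, sector="fovea")
        assert site.center == (210, 210)

    def test_fully_excluded_sector_errors(self):
        grid, shape = small_grid()
        mask = eg.sector_mask(grid, "fovea", shape)
        excl = ExclusionMask(np.ones(shape, dtype=bool))
        with pytest.raises(eg.GridError, match="no clean site"):
            eg.select_site(mask, excl, radius_um=100, grid=grid, sector="fovea")

    def test_vessel_split_matches_brute_force(self):
        """A vessel splitting the sector 1/3-2/3 pushes the site into the
        larger sub-region, at the exhaustive-search optimum."""
        grid = eg.ETDRSGrid(center=(100, 100), um_per_pixel=30.0, nasal_side="right")
        shape = (201, 201)
        mask = eg.sector_mask(grid, "fovea", shape)
        excl_px = np.zeros(shape, dtype=bool)
        excl_px[:, 95:97] = True  # vertical vessel left of center
        site = eg.select_site(mask, ExclusionMask(excl_px), radius_um=60, grid=grid)
        allowed = mask & ~excl_px
        expected_center, expected_clearance = brute_force_best_site(allowed)
        assert site.center == expected_center
        assert site.center[1] > 97  # larger (right) sub-region

    def test_site_disc_never_overlaps_exclusion(self, rng):
        grid = eg.ETDRSGrid(center=(100, 100), um_per_pixel=30.0, nasal_side="right")
        shape = (201, 201)
        masks = eg.all_sector_masks(grid, shape)
        for trial in range(10):
            excl = ExclusionMask(rng.uniform(size=shape) < 0.02)
            for s in SECTORS:
                try:
                    site = eg.select_site(masks[s], excl, radius_um=45, grid=grid, sector=s)
                except eg.GridError:
                    continue
                rr, cc = np.mgrid[: shape[0], : shape[1]]
                disc = np.hypot(rr - site.center[0], cc - site.center[1]) < site.radius_px
                assert not (disc & excl.pixels).any()

    def test_max_clearance_below_radius_errors(self):
        grid = eg.ETDRSGrid(center=(100, 100), um_per_pixel=30.0, nasal_side="right")
        shape = (201, 201)
        mask = eg.sector_mask(grid, "fovea", shape)
        excl_px = np.zeros(shape, dtype=bool)
        excl_px[::6, :] = True  # dense horizontal grid: max clearance < 3 px
        with pytest.raises(eg.GridError, match="no clean site"):
            eg.select_site(mask, ExclusionMask(excl_px), radius_um=200, grid=grid)


class TestMeasure:
    def test_uniform_image_measures_programmed_values(self, uniform_image):
        m = eg.measure_eye(uniform_image, radius_um=300)
        assert set(m) == set(SECTORS)
        for s in SECTORS:
            assert m[s].gefc_mean == 17.0
            assert m[s].refc_mean == 26.0
            assert m[s].n_pixels > 0

    def test_half_and_half_site_weighted_mean(self):
        img = make_uniform_image(0, 0, shape=(61, 61))
        px = img.pixels.copy()
        px[:, :30, 0] = 40
        px[:, 30:, 0] = 20
        smap = decompose(type(img)(pixels=px, metadata=img.metadata))
        site = eg.MeasurementSite(center=(30, 30), radius_um=1000, radius_px=10, sector="fovea")
        got = eg.measure_sector(smap, site)
        # pixel-count-weighted oracle over the open disc
        rr, cc = np.mgrid[:61, :61]
        disc = np.hypot(rr - 30, cc - 30) < 10
        expected = (40 * (disc[:, :30]).sum() + 20 * (disc[:, 30:]).sum()) / disc.sum()
        assert got.refc_mean == pytest.approx(expected)
        assert abs(got.refc_mean - 30.0) < 1.0  # near-even split

    def test_one_pixel_radius_site_is_that_pixel(self):
        img = make_uniform_image(0, 0, shape=(61, 61))
        px = img.pixels.copy()
        px[30, 30] = (77, 33, 0)
        smap = decompose(type(img)(pixels=px, metadata=img.metadata))
        site = eg.MeasurementSite(center=(30, 30), radius_um=100, radius_px=1, sector="fovea")
        got = eg.measure_sector(smap, site)
        assert (got.refc_mean, got.gefc_mean, got.n_pixels) == (77.0, 33.0, 1)

    def test_fully_excluded_sector_leaves_it_missing(self, uniform_image):
        grid = eg.grid_from_metadata(uniform_image.metadata)
        masks = eg.all_sector_masks(grid, uniform_image.shape)
        excl = ExclusionMask(masks["outer_temporal"].copy())
        m = eg.measure_eye(uniform_image, excl, radius_um=300)
        assert "outer_temporal" not in m
        assert len(m) == 8

    def test_whole_sector_mode_matches_site_on_uniform_image(self, uniform_image):
        m = eg.measure_eye(uniform_image, mode="sector")
        for s in SECTORS:
            assert m[s].gefc_mean == 17.0
            assert m[s].refc_mean == 26.0
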