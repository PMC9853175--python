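"""Segmentation, moments-ellipse morphometry and Delaunay statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.draw import disk, ellipse

import morphocensus as mc
from conftest import synth_patch


def _uniform_patch(shape=(64, 64)):
    px = np.full(shape + (3,), 180, dtype=np.uint8)
    return mc.TilePatch(px, "u", 0, 0)


def _measure_mask(mask):
    """Measure a bare mask on a flat-intensity patch."""
    return mc.measure_cells(mask.astype(np.int32), _uniform_patch(mask.shape))


class TestSegmentCells:
    def test_blank_eosin_patch_yields_no_instances(self):
        h = np.full((256, 256), 0.02)
        e = np.full((256, 256), 0.25)
        mask = mc.segment_cells(synth_patch(h, e))
        assert mask.max() == 0

    def test_well_separated_cells_recovered(self):
        spec = mc.SlideSpec("sep", n_tiles=1, cell_density=30, touch_rate=0.0,
                            shc_fraction=0.0, seed=13)
        patch, truth = mc.generate_tile(spec, 0)
        norm = mc.macenko_normalize(patch, mc.fit_stain_model(patch))
        pred = mc.segment_cells(norm, stain_model=mc.DEFAULT_REFERENCE_STAIN)
        hits = 0
        n_true = truth.mask.max()
        for lab in range(1, n_true + 1):
            gt = truth.mask == lab
            overlap = np.bincount(pred[gt])
            overlap[0] = 0
            if overlap.max() == 0:
                continue
            best = pred == overlap.argmax()
            iou = (gt & best).sum() / (gt | best).sum()
            hits += iou > 0.5
        assert hits / n_true >= 0.95

    def test_touching_cells_split_by_watershed(self):
        # two disks overlapping ~20% of their area
        h = np.full((128, 128), 0.02)
        for c in ((64, 48), (64, 80)):
            rr, cc = disk(c, 18, shape=(128, 128))
            h[rr, cc] = 0.8
        e = np.full((128, 128), 0.25)
        mask = mc.segment_cells(synth_patch(h, e),
                                stain_model=mc.DEFAULT_REFERENCE_STAIN)
        assert mask.max() == 2

    def test_mask_labels_consecutive(self, dense_slide):
        patch = dense_slide[0][0]
        mask = mc.segment_cells(patch)
        labels = np.unique(mask)
        assert np.array_equal(labels, np.arange(labels.max() + 1))


class TestFilterSparsePatch:
    @pytest.mark.parametrize("n,cutoff,keep", [
        (14, 15, False), (10, 10, True), (0, 1, False), (0, 5, False),
    ])
    def test_cutoff_boundary(self, n, cutoff, keep):
        mask = np.zeros((100, 100), dtype=np.int32)
        for i in range(n):
            mask[i * 5:i * 5 + 3, :3] = i + 1
        assert mc.filter_sparse_patch(mask, cutoff) is keep


class TestMeasureCells:
    def test_single_pixel_instance(self):
        mask = np.zeros((8, 8), dtype=np.int32)
        mask[3, 4] = 1
        (rec,) = _measure_mask(mask)
        assert rec.area == 1
        expected = 4 * np.sqrt(1 / 12)
        assert rec.major_axis == pytest.approx(expected, rel=1e-9)
        assert rec.minor_axis == pytest.approx(expected, rel=1e-9)

    def test_rasterized_disk(self):
        mask = np.zeros((64, 64), dtype=np.int32)
        rr, cc = disk((32, 32), 10, shape=(64, 64))  # radius-10 pixel disk
        mask[rr, cc] = 1
        (rec,) = _measure_mask(mask)
        assert rec.area == pytest.approx(100 * np.pi, rel=0.03)
        assert rec.axis_ratio == pytest.approx(1.0, rel=0.03)

    def test_axis_aligned_rectangle(self):
        mask = np.zeros((64, 64), dtype=np.int32)
        mask[10:20, 5:45] = 1  # 10 rows x 40 cols
        (rec,) = _measure_mask(mask)
        assert rec.axis_ratio == pytest.approx(4.0, rel=0.02)
        # exact: 4 * sqrt(W^2/12) for a W-wide uniform strip
        assert rec.major_axis == pytest.approx(4 * np.sqrt(40 ** 2 / 12), rel=1e-6)

    def test_rotation_invariance_of_axes(self):
        base = None
        for deg in (0, 30, 60, 117):
            mask = np.zeros((128, 128), dtype=np.int32)
            rr, cc = ellipse(64, 64, 22, 9, shape=(128, 128),
                             rotation=np.deg2rad(deg))
            mask[rr, cc] = 1
            (rec,) = _measure_mask(mask)
            if base is None:
                base = (rec.major_axis, rec.minor_axis)
            else:
                assert rec.major_axis == pytest.approx(base[0], rel=0.02)
                assert rec.minor_axis == pytest.approx(base[1], rel=0.02)

    def test_mean_rgb_over_instance_pixels(self):
        px = np.zeros((10, 10, 3), dtype=np.uint8)
        px[2:4, 2:4] = (100, 150, 200)
        mask = np.zeros((10, 10), dtype=np.int32)
        mask[2:4, 2:4] = 1
        (rec,) = mc.measure_cells(mask, mc.TilePatch(px, "p", 0, 0))
        assert rec.mean_rgb == (100.0, 150.0, 200.0)

    def test_areas_bounded_by_tile(self, dense_slide):
        patch, truth = dense_slide[0]
        cells = mc.measure_cells(truth.mask, patch)
        assert sum(c.area for c in cells) <= truth.mask.size
        assert all(c.major_axis >= c.minor_axis > 0 for c in cells)
        assert all(c.axis_ratio >= 1 for c in cells)


class TestDelaunay:
    def test_right_triangle_hand_computed(self):
        stats = mc.delaunay_neighbor_stats([(0, 0), (3, 0), (0, 4)])
        dmin, dmax, dmean = stats[0]
        assert (dmin, dmax, dmean) == (3.0, 4.0, 3.5)

    def test_two_points_fallback(self):
        stats = mc.delaunay_neighbor_stats([(0, 0), (3, 4)])
        assert np.allclose(stats, 5.0)

    def test_collinear_points_fallback(self):
        stats = mc.delaunay_neighbor_stats([(0, 0), (1, 0), (2, 0), (5, 0)])
        assert np.isfinite(stats).all()
        assert stats[0][0] == 1.0  # nearest neighbor of the first point

    def test_square_grid_interior_min_distance(self):
        s = 20.0
        pts = [(i * s, j * s) for i in range(5) for j in range(5)]
        stats = mc.delaunay_neighbor_stats(pts)
        interior = [i for i, (x, y) in enumerate(pts)
                    if 0 < x < 4 * s and 0 < y < 4 * s]
        assert all(stats[i][0] == pytest.approx(s) for i in interior)

    def test_single_centroid_rejected(self):
        with pytest.raises(ValueError):
            mc.delaunay_neighbor_stats([(0, 0)])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_point_sets_have_ordered_finite_stats(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, size=(rng.integers(2, 40), 2))
        stats = mc.delaunay_neighbor_stats(pts)
        assert np.isfinite(stats).all()
        assert (stats[:, 0] <= stats[:, 2] + 1e-12).all()
        assert (stats[:, 2] <= stats[:, 1] + 1e-12).all()
        assert (stats[:, 0] > 0).all()  # every cell has >= 1 neighbor


def _cell(area, ratio, intensity):
    return mc.CellRecord(
        cell_id=1, patch_ref=("s", 0, 0), centroid_xy=(0, 0), area=area,
        major_axis=ratio, minor_axis=1.0, axis_ratio=ratio,
        mean_rgb=(intensity, intensity, intensity))


class TestSmallHyperchromatic:
    @pytest.mark.parametrize("area,ratio,intensity,flagged", [
        (449, 1.9, 30, True),    # just inside all three rules
        (450, 1.9, 30, False),   # area boundary is strict
        (300, 2.5, 30, False),   # too elongated
        (300, 1.5, 90, False),   # too pale
    ])
    def test_flag_rules(self, area, ratio, intensity, flagged):
        assert mc.flag_small_hyperchromatic(
            _cell(area, ratio, intensity), intensity_threshold=80) is flagged

    def test_summary_counts_and_density(self):
        cells = [_cell(300, 1.2, 30) for _ in range(20)]
        for c in cells[:5]:
            c.is_shc = True
        s = mc.summarize_patch(cells)
        assert (s.n_cells, s.shc_count, s.shc_density) == (20, 5, 0.25)

    def test_zero_flagged_density(self):
        s = mc.summarize_patch([_cell(300, 1.2, 90) for _ in range(4)])
        assert s.shc_density == 0.0

    def test_empty_patch_rejected(self):
        with pytest.raises(ValueError):
            mc.summarize_patch([])

    def test_planted_shc_fraction_recovered(self):
        # generator draws shc cells small/round/dark; the rule cutoffs plus
        # the adaptive intensity threshold should recover roughly the
        # planted fraction over ~1000 pooled cells
        spec = mc.SlideSpec("shc", n_tiles=8, cell_density=120,
                            shc_fraction=0.3, seed=31)
        m = mc.process_slide([mc.generate_tile(spec, i)[0]
                              for i in range(spec.n_tiles)], slide_id="shc")
        assert len(m.cells) >= 800
        dens = [p.shc_density for p in m.patch_summaries]
        assert abs(float(np.mean(dens)) - 0.3) < 0.05
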