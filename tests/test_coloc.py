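import numpy as np
import pytest

from ramantag.coloc import (
    ColocPartition,
    EXCLUDED_CODE,
    SEG_HIGH_RATIO_HIGH_I,
    SEG_LOW_RATIO_LOW_I,
    back_project,
    coloc_points,
    density_mode,
    fit_partition,
    partition,
)
from ramantag.quantify import AreaMap, BandWindow

CN = BandWindow(center=2223.0)
CC = BandWindow(center=2115.0)


def _maps(x_values, y_values):
    return (
        AreaMap(values=np.asarray(x_values, float), window=CN, normalized=True,
                reference_value=1.0),
        AreaMap(values=np.asarray(y_values, float), window=CC, normalized=True,
                reference_value=1.0),
    )


def _cluster_points(center, n=400, sd=0.05, seed=0):
    rng = np.random.default_rng(seed)
    shape = (int(np.ceil(n ** 0.5)),) * 2
    x = np.abs(rng.normal(center[0], sd, shape))
    y = np.abs(rng.normal(center[1], sd, shape))
    cn, cc = _maps(x, y)
    return coloc_points(cn, cc, np.ones(shape, bool))


class TestColocPoints:
    def test_all_positive_maps_have_no_exclusions(self):
        cn, cc = _maps([[1.0, 2.0]], [[0.5, 0.1]])
        points = coloc_points(cn, cc, np.ones((1, 2), bool))
        assert points.n_points == 2 and points.n_excluded == 0

    def test_negative_coordinate_is_excluded_and_listed(self):
        cn, cc = _maps([[-0.1, 2.0]], [[0.5, 0.1]])
        points = coloc_points(cn, cc, np.ones((1, 2), bool))
        assert points.n_points == 1
        assert (points.excluded_rows[0], points.excluded_cols[0]) == (0, 0)

    def test_retained_plus_excluded_cover_the_mask(self):
        rng = np.random.default_rng(5)
        cn, cc = _maps(rng.normal(size=(9, 9)), rng.normal(size=(9, 9)))
        mask = rng.random((9, 9)) < 0.7
        points = coloc_points(cn, cc, mask)
        assert points.n_points + points.n_excluded == int(mask.sum())

    def test_no_retained_points_is_an_error(self):
        cn, cc = _maps([[-1.0]], [[-1.0]])
        with pytest.raises(ValueError, match="non-negative"):
            coloc_points(cn, cc, np.ones((1, 1), bool))


class TestDensityMode:
    def _histogram_mode(self, points, bins=40):
        """Independent oracle: argmax of a fine 2-D histogram."""
        h, xe, ye = np.histogram2d(points.x, points.y, bins=bins)
        i, j = np.unravel_index(np.argmax(h), h.shape)
        return 0.5 * (xe[i] + xe[i + 1]), 0.5 * (ye[j] + ye[j + 1])

    def test_tight_cluster_mode_near_its_center(self):
        points = _cluster_points((2.0, 1.0), sd=0.05)
        mx, my = density_mode(points)
        assert mx == pytest.approx(2.0, abs=0.15)
        assert my == pytest.approx(1.0, abs=0.15)

    def test_duplicated_point_set_gives_identical_mode(self):
        points = _cluster_points((1.0, 1.0))
        assert density_mode(points) == density_mode(points)

    def test_mode_sits_at_the_heavy_cluster(self):
        rng = np.random.default_rng(1)
        heavy = rng.normal((1.0, 0.5), 0.05, (900, 2))
        light = rng.normal((3.0, 2.0), 0.05, (100, 2))
        xy = np.abs(np.vstack([heavy, light]))
        cn, cc = _maps(xy[:, 0].reshape(40, 25), xy[:, 1].reshape(40, 25))
        points = coloc_points(cn, cc, np.ones((40, 25), bool))
        kde_mode = density_mode(points)
        hist_mode = self._histogram_mode(points)
        assert np.hypot(kde_mode[0] - 1.0, kde_mode[1] - 0.5) < 0.3
        assert np.hypot(kde_mode[0] - hist_mode[0], kde_mode[1] - hist_mode[1]) < 0.3

    def test_too_few_points_suggests_larger_phantom(self):
        cn, cc = _maps(np.ones((2, 2)), np.ones((2, 2)))
        points = coloc_points(cn, cc, np.ones((2, 2), bool))
        with pytest.raises(ValueError, match="phantom"):
            density_mode(points)


class TestPartition:
    GEOM = ColocPartition(slope=0.5, t0=1.0, mode=(0.8, 0.4))

    def _points(self, xy):
        xy = np.asarray(xy, float)
        cn, cc = _maps(xy[:, 0].reshape(1, -1), xy[:, 1].reshape(1, -1))
        return coloc_points(cn, cc, np.ones((1, xy.shape[0]), bool))

    def test_boundary_point_takes_lower_labels(self):
        # exactly on the central line, below t0 -> low-ratio, low-intensity
        points = self._points([[0.4, 0.2]])
        assert partition(points, self.GEOM)[0] == SEG_LOW_RATIO_LOW_I

    def test_double_mode_projection_is_high_intensity(self):
        geom = self.GEOM
        t_mode = geom.projection(*geom.mode)
        far = [geom.mode[0] * 2.2, geom.mode[1] * 2.2]
        points = self._points([far])
        label = partition(points, geom)[0]
        assert geom.projection(*far) > 1.05 * t_mode
        assert label in (SEG_LOW_RATIO_LOW_I + 1, SEG_HIGH_RATIO_HIGH_I)

    def test_four_segments_partition_every_point_exactly_once(self):
        points = _cluster_points((1.0, 1.0), n=900, sd=0.6, seed=2)
        geom = fit_partition(points)
        labels = partition(points, geom)
        assert labels.shape == (points.n_points,)
        assert set(np.unique(labels)) <= {1, 2, 3, 4}

    def test_labels_invariant_to_common_positive_rescale(self):
        points = _cluster_points((1.5, 1.0), n=900, sd=0.4, seed=3)
        geom = fit_partition(points)
        labels = partition(points, geom)

        cn, cc = _maps(points.x.reshape(30, 30) * 40.0, points.y.reshape(30, 30) * 40.0)
        scaled = coloc_points(cn, cc, np.ones((30, 30), bool))
        geom_scaled = fit_partition(scaled)
        assert geom_scaled.slope == pytest.approx(geom.slope, rel=1e-6)
        assert geom_scaled.t0 == pytest.approx(40.0 * geom.t0, rel=1e-6)
        assert np.array_equal(partition(scaled, geom_scaled), labels)


class TestBackProject:
    def test_round_trip_and_excluded_code(self):
        cn, cc = _maps([[1.0, -0.2], [0.5, 2.0]], [[0.5, 0.5], [0.2, 1.0]])
        mask = np.ones((2, 2), bool)
        points = coloc_points(cn, cc, mask)
        labels = np.arange(points.n_points) % 4 + 1
        image = back_project(points, labels, mask.shape)
        assert np.array_equal(image[points.rows, points.cols], labels)
        assert image[0, 1] == EXCLUDED_CODE

    def test_background_outside_mask(self):
        cn, cc = _maps(np.ones((3, 3)), np.ones((3, 3)))
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        points = coloc_points(cn, cc, mask)
        image = back_project(points, np.array([2]), mask.shape)
        assert image[1, 1] == 2 and (image == 0).sum() == 8

    def test_misaligned_labels_rejected(self):
        cn, cc = _maps(np.ones((2, 2)), np.ones((2, 2)))
        points = coloc_points(cn, cc, np.ones((2, 2), bool))
        with pytest.raises(ValueError, match="align"):
            back_project(points, np.array([1, 2]), (2, 2))
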