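import numpy as np
import pytest

from guanloc import artery as am
from guanloc.edges import EdgeMap
from guanloc.errors import (
    ArteryNotFoundError,
    FitError,
    LocalizationError,
    ParameterError,
    ThresholdError,
    ValidationError,
)
from guanloc.io import ThermalImage


def make_edges(shape, points):
    mask = np.zeros(shape, dtype=bool)
    for c, r in points:
        mask[r, c] = True
    return EdgeMap(mask)


def brute_force_stats(image, edges, size=10):
    half = size // 2
    arr = image.pixels
    h, w = arr.shape
    out = []
    for r, c in zip(*np.nonzero(edges.mask)):
        if r < half or r > h - half or c < half or c > w - half:
            continue
        win = arr[r - half : r + half, c - half : c + half]
        out.append(((int(c), int(r)), win.mean(), win.std()))
    return out


class TestRegionStats:
    def test_constant_image(self):
        img = ThermalImage(np.full((32, 32), 9.0))
        stats = am.region_stats(img, make_edges((32, 32), [(16, 16), (10, 20)]))
        assert len(stats) == 2
        for s in stats:
            assert s.mean == 9.0 and s.std == 0.0

    def test_sequential_region_values(self):
        """A region holding the values 0..99 has mean 49.5 and population
        std sqrt((100^2-1)/12)."""
        arr = np.zeros((32, 32))
        arr[10:20, 10:20] = np.arange(100.0).reshape(10, 10)
        stats = am.region_stats(ThermalImage(arr), make_edges((32, 32), [(15, 15)]))
        assert stats[0].mean == pytest.approx(49.5)
        assert stats[0].std == pytest.approx(np.sqrt((100**2 - 1) / 12), abs=1e-9)

    def test_matches_brute_force_on_random_image(self, rng):
        img = ThermalImage(rng.uniform(0, 255, size=(32, 32)))
        mask = rng.uniform(size=(32, 32)) < 0.2
        edges = EdgeMap(mask)
        got = am.region_stats(img, edges)
        expected = brute_force_stats(img, edges)
        assert len(got) == len(expected)
        for g, (center, mean, std) in zip(got, expected):
            assert g.center == center
            assert g.mean == pytest.approx(mean, abs=1e-9)
            assert g.std == pytest.approx(std, abs=1e-9)

    def test_border_points_skipped(self):
        img = ThermalImage(np.zeros((32, 32)))
        stats = am.region_stats(img, make_edges((32, 32), [(0, 0), (16, 16)]))
        assert len(stats) == 1

    def test_odd_size_rejected(self, small_image):
        with pytest.raises(ParameterError):
            am.region_stats(small_image, make_edges((32, 32), [(16, 16)]), size=9)


def stats_list(pairs):
    return [am.RegionStats(center=(i, i), mean=m, std=s) for i, (m, s) in enumerate(pairs)]


class TestDeriveThresholds:
    def test_identical_regions_rejected(self, small_image):
        with pytest.raises(ThresholdError):
            am.derive_thresholds(small_image, stats_list([(5.0, 1.0)] * 20))

    def test_too_few_stats_rejected(self, small_image):
        with pytest.raises(ValidationError):
            am.derive_thresholds(small_image, stats_list([(5.0, 1.0)] * 5))

    def test_bimodal_means_separated(self, small_image, rng):
        cool = [(100 + rng.normal(0, 2), 10 + rng.normal(0, 1)) for _ in range(80)]
        warm = [(170 + rng.normal(0, 2), 10 + rng.normal(0, 1)) for _ in range(20)]
        th = am.derive_thresholds(small_image, stats_list(cool + warm))
        means = np.array([m for m, _ in cool + warm])
        assert 100 < th.mean_min < 170  # between the cluster means
        assert np.mean(means[80:] > th.mean_min) == 1.0  # all warm kept
        assert np.mean(means[:80] > th.mean_min) <= 0.05

    def test_shift_equivariance(self, small_image, rng):
        pairs = [(rng.uniform(50, 200), rng.uniform(1, 30)) for _ in range(60)]
        shifted = [(m + 25.0, s) for m, s in pairs]
        a = am.derive_thresholds(small_image, stats_list(pairs))
        b = am.derive_thresholds(small_image, stats_list(shifted))
        assert b.mean_min == pytest.approx(a.mean_min + 25.0, abs=1e-6)
        assert b.std_max == pytest.approx(a.std_max, abs=1e-9)

    def test_percentile_method_uses_config_windows(self, small_image, rng):
        pairs = [(rng.uniform(50, 200), rng.uniform(1, 30)) for _ in range(200)]
        th = am.derive_thresholds(
            small_image, stats_list(pairs), method="percentile",
            mean_pct=(70, 99.5), std_pct=(40, 98),
        )
        means = np.array([m for m, _ in pairs])
        stds = np.array([s for _, s in pairs])
        assert th.mean_min == pytest.approx(np.percentile(means, 70))
        assert th.std_min == pytest.approx(np.percentile(stds, 40))


class TestSelectArteryPixels:
    def test_nothing_qualifies(self, small_image):
        th = am.Thresholds(mean_min=1e6, mean_max=2e6, std_min=0, std_max=1)
        stats = [am.RegionStats(center=(16, 16), mean=5.0, std=0.5)]
        with pytest.raises(ArteryNotFoundError):
            am.select_artery_pixels(small_image, stats, th)

    def test_single_region_column_means(self):
        img = ThermalImage(np.zeros((64, 64)))
        stats = [am.RegionStats(center=(30, 25), mean=5.0, std=1.0)]
        th = am.Thresholds(mean_min=0, mean_max=10, std_min=0, std_max=2)
        model = am.select_artery_pixels(img, stats, th)
        # region spans rows 20..29: every column mean is 24.5
        np.testing.assert_allclose(model.col_means, 24.5)
        assert model.columns.min() == 25 and model.columns.max() == 34

    def test_row_min_excludes_regions(self):
        img = ThermalImage(np.zeros((64, 64)))
        stats = [
            am.RegionStats(center=(30, 10), mean=5.0, std=1.0),
            am.RegionStats(center=(30, 40), mean=5.0, std=1.0),
        ]
        th = am.Thresholds(mean_min=0, mean_max=10, std_min=0, std_max=2)
        model = am.select_artery_pixels(img, stats, th, row_min=np.full(64, 20.0))
        assert model.pixels[:, 1].min() >= 35


class TestFitAndLocate:
    def test_exact_line_recovered(self):
        cols = np.arange(20)
        model = am.ArteryModel(
            pixels=np.empty((0, 2)), columns=cols, col_means=0.5 * cols + 10
        )
        slope, intercept = am.fit_artery_line(model)
        assert slope == pytest.approx(0.5, abs=1e-9)
        assert intercept == pytest.approx(10.0, abs=1e-9)

    def test_three_point_hand_solution(self):
        model = am.ArteryModel(
            pixels=np.empty((0, 2)),
            columns=np.array([0, 1, 2]),
            col_means=np.array([1.0, 2.0, 2.0]),
        )
        slope, intercept = am.fit_artery_line(model)
        assert slope == pytest.approx(0.5, abs=1e-9)
        assert intercept == pytest.approx(7.0 / 6.0, abs=1e-9)

    def test_matches_normal_equations(self, rng):
        for _ in range(5):
            x = rng.uniform(0, 100, size=50)
            y = rng.uniform(0, 100, size=50)
            model = am.ArteryModel(pixels=np.empty((0, 2)), columns=x, col_means=y)
            slope, intercept = am.fit_artery_line(model, outlier_px=np.inf)
            n = x.size
            det = n * (x**2).sum() - x.sum() ** 2
            s_exp = (n * (x * y).sum() - x.sum() * y.sum()) / det
            i_exp = ((x**2).sum() * y.sum() - x.sum() * (x * y).sum()) / det
            assert slope == pytest.approx(s_exp, abs=1e-9)
            assert intercept == pytest.approx(i_exp, abs=1e-9)

    def test_outlier_column_rejected(self):
        cols = np.arange(30.0)
        means = 0.2 * cols + 50
        means[5] = 120.0  # a stray marker column
        model = am.ArteryModel(pixels=np.empty((0, 2)), columns=cols, col_means=means)
        slope, intercept = am.fit_artery_line(model)
        assert slope == pytest.approx(0.2, abs=1e-6)
        assert intercept == pytest.approx(50.0, abs=1e-6)
        assert model.diagnostics["n_outlier_cols"] >= 1

    def test_single_column_fit_error(self):
        model = am.ArteryModel(
            pixels=np.empty((0, 2)), columns=np.array([3, 3]), col_means=np.array([1.0, 2.0])
        )
        with pytest.raises(FitError):
            am.fit_artery_line(model)

    def test_locate_y_arithmetic(self):
        model = am.ArteryModel(
            pixels=np.empty((0, 2)),
            columns=np.arange(5),
            col_means=np.zeros(5),
            slope=0.0,
            intercept=33.0,
        )
        assert am.locate_y(model, 200, (240, 320)) == 33
        model.slope, model.intercept = 0.5, 10.0
        assert am.locate_y(model, 100, (240, 320)) == 60
        assert model.diagnostics["y0_raw"] == pytest.approx(60.0)

    def test_locate_y_outside_image(self):
        model = am.ArteryModel(
            pixels=np.empty((0, 2)),
            columns=np.arange(5),
            col_means=np.zeros(5),
            slope=2.0,
            intercept=100.0,
        )
        with pytest.raises(LocalizationError):
            am.locate_y(model, 300, (240, 320))


class TestShiftInvariance:
    def test_selection_invariant_to_intensity_shift(self, noisy_phantom):
        """Adding a constant to the image leaves the selected artery pixel
        set unchanged (thresholds shift with the data)."""
        from guanloc.edges import detect_edges

        image, _ = noisy_phantom
        shifted = ThermalImage(image.pixels + 40.0)
        sets = []
        for img in (image, shifted):
            edges = detect_edges(img)
            stats = am.region_stats(img, edges)
            th = am.derive_thresholds(img, stats)
            model = am.select_artery_pixels(img, stats, th)
            sets.append({tuple(p) for p in model.pixels})
        assert sets[0] == sets[1]
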