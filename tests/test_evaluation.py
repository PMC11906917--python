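import numpy as np
import pandas as pd
import pytest

from anatlayout.errors import GeometryError, InputError
from anatlayout.evaluation import (
    TopoImage,
    group_t_map,
    interpolate_topo,
    subselect_channels,
    zscore_image,
)
from anatlayout.projection import Layout2D, SensorLocation2D


def layout_from_xy(xy: np.ndarray) -> Layout2D:
    channels = {}
    for i, (x, y) in enumerate(xy):
        lab = f"c{i}"
        channels[lab] = SensorLocation2D(
            label=lab,
            eccentricity=float(np.hypot(x, y)),
            angle=float(np.mod(np.rad2deg(np.arctan2(y, x)), 360.0)),
            xy=np.array([x, y], dtype=float),
        )
    return Layout2D(channels=channels)


@pytest.fixture()
def random_layout():
    rng = np.random.default_rng(5)
    r = np.sqrt(rng.uniform(0, 1, 30))
    th = rng.uniform(0, 2 * np.pi, 30)
    return layout_from_xy(np.column_stack([r * np.cos(th), r * np.sin(th)]))


class TestInterpolateTopo:
    def test_constant_values_reproduced(self, random_layout):
        vals = {l: 3.25 for l in random_layout.labels}
        img = interpolate_topo(random_layout, vals, resolution=41)
        assert np.allclose(img.grid[img.mask], 3.25, atol=1e-12)
        assert np.all(np.isnan(img.grid[~img.mask]))

    def test_centroid_is_mean_of_three(self):
        lay = layout_from_xy(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))
        vals = {"c0": 1.0, "c1": 2.0, "c2": 6.0}
        img = interpolate_topo(lay, vals, resolution=301)
        xx = np.linspace(-1.2, 1.2, 301)
        cx = cy = 1.0 / 3.0
        ix = int(np.argmin(np.abs(xx - cx)))
        iy = int(np.argmin(np.abs(xx - cy)))
        # nearest pixel to the centroid: barycentric mean of the 3 values
        assert img.grid[iy, ix] == pytest.approx(3.0, abs=0.05)

    def test_affine_field_exact(self, random_layout):
        vals = {l: 2.0 * ch.xy[0] + 3.0 * ch.xy[1] for l, ch in random_layout.channels.items()}
        img = interpolate_topo(random_layout, vals, resolution=67)
        xx, yy = np.meshgrid(np.linspace(-1.2, 1.2, 67), np.linspace(-1.2, 1.2, 67))
        expected = 2.0 * xx + 3.0 * yy
        assert np.allclose(img.grid[img.mask], expected[img.mask], atol=1e-9)

    def test_missing_values_rejected(self, random_layout):
        vals = {l: 0.0 for l in random_layout.labels[:-1]}
        with pytest.raises(InputError, match="missing"):
            interpolate_topo(random_layout, vals)

    def test_collinear_channels_rejected(self):
        lay = layout_from_xy(np.column_stack([np.linspace(-1, 1, 5), np.linspace(-1, 1, 5)]))
        with pytest.raises((GeometryError, InputError)):
            interpolate_topo(lay, {l: 1.0 for l in lay.labels})

    def test_masked_pixels_are_nan_not_zero(self, random_layout):
        vals = {l: 5.0 for l in random_layout.labels}
        img = interpolate_topo(random_layout, vals, resolution=41)
        assert not np.any(img.grid[~img.mask] == 0)


class TestZscore:
    def test_mean_zero_sd_one(self, random_layout):
        rng = np.random.default_rng(0)
        vals = {l: rng.normal() for l in random_layout.labels}
        z = zscore_image(interpolate_topo(random_layout, vals, resolution=41))
        v = z.valid_values()
        assert v.mean() == pytest.approx(0.0, abs=1e-12)
        assert v.std() == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, random_layout):
        rng = np.random.default_rng(1)
        vals = {l: rng.normal() for l in random_layout.labels}
        img = interpolate_topo(random_layout, vals, resolution=41)
        scaled = TopoImage(grid=4.0 * img.grid - 7.0, mask=img.mask, resolution=img.resolution)
        z1, z2 = zscore_image(img), zscore_image(scaled)
        assert np.allclose(z1.grid[z1.mask], z2.grid[z2.mask], atol=1e-9)

    def test_two_pixel_closed_form(self):
        grid = np.array([[1.0, 3.0]])
        img = TopoImage(grid=grid, mask=np.array([[True, True]]), resolution=2)
        z = zscore_image(img)
        assert np.allclose(z.grid, [[-1.0, 1.0]])

    def test_zero_spread_rejected(self):
        img = TopoImage(grid=np.ones((2, 2)), mask=np.ones((2, 2), bool), resolution=2)
        with pytest.raises(InputError, match="spread"):
            zscore_image(img)


class TestGroupTMap:
    def _img(self, grid, mask=None):
        grid = np.asarray(grid, dtype=float)
        mask = np.isfinite(grid) if mask is None else mask
        return TopoImage(grid=np.where(mask, grid, np.nan), mask=mask, resolution=grid.shape[0])

    def test_hand_computed_t(self):
        imgs = [self._img([[v, v], [v, 2 * v]]) for v in (1.0, 2.0, 3.0)]
        out = group_t_map(imgs)
        # pixelwise {1,2,3}: t = 2 / (1 / sqrt(3))
        assert out.t[0, 0] == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-12)
        assert out.t[0, 0] == pytest.approx(3.464, abs=1e-3)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(2)
        grids = rng.normal(size=(4, 5, 5))
        pos = group_t_map([self._img(g) for g in grids])
        neg = group_t_map([self._img(-g) for g in grids])
        assert np.allclose(pos.t[pos.mask], -neg.t[neg.mask], atol=1e-9)

    def test_identical_images_masked_not_propagated(self):
        g = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = group_t_map([self._img(g)] * 3)
        assert not np.any(out.mask)
        assert np.all(np.isnan(out.t))

    def test_partial_masks_and_n_effective(self):
        a = self._img([[1.0, np.nan], [1.0, 1.0]])
        b = self._img([[2.0, 5.0], [2.0, np.nan]])
        c = self._img([[3.0, 6.0], [np.nan, np.nan]])
        out = group_t_map([a, b, c])
        assert out.n_effective[0, 0] == 3
        assert out.n_effective[0, 1] == 2
        assert out.n_effective[1, 1] == 1
        assert not out.mask[1, 1]

    def test_no_common_pixels_rejected(self):
        a = self._img([[1.0, np.nan]])
        b = self._img([[np.nan, 1.0]])
        with pytest.raises(GeometryError):
            group_t_map([a, b])

    def test_needs_two_images(self):
        with pytest.raises(InputError):
            group_t_map([self._img([[1.0]])])


class TestSubselect:
    labels = [f"S{i:02d}" for i in range(10)]
    positions = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])

    def test_full_set_is_noop(self):
        vals = pd.Series(np.arange(10.0), index=self.labels)
        for mode in ("sparse", "focal"):
            keep = subselect_channels(self.labels, self.positions, 10, mode, values=vals, seed=0)
            assert sorted(keep) == sorted(self.labels)

    def test_focal_contains_peak_and_neighbours(self):
        vals = pd.Series(np.zeros(10), index=self.labels)
        vals["S07"] = 5.0
        keep = subselect_channels(self.labels, self.positions, 3, "focal", values=vals)
        assert keep == ["S06", "S07", "S08"]

    def test_sparse_nested_and_deterministic(self):
        k8a = subselect_channels(self.labels, self.positions, 8, "sparse", seed=42)
        k8b = subselect_channels(self.labels, self.positions, 8, "sparse", seed=42)
        k5 = subselect_channels(self.labels, self.positions, 5, "sparse", seed=42)
        assert k8a == k8b
        assert set(k5) <= set(k8a)

    def test_invalid_n_keep(self):
        with pytest.raises(InputError):
            subselect_channels(self.labels, self.positions, 0, "sparse", seed=0)
        with pytest.raises(InputError):
            subselect_channels(self.labels, self.positions, 11, "sparse", seed=0)
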