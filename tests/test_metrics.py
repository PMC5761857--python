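import numpy as np
import pytest

from pcdquant import (EnFaceAngiogram, GeometryError, PCDQuantifier, density_map,
                      make_annulus, quantify, region_pcd, render_density_map,
                      whole_image_pcd)
from pcdquant.metrics import DensityMap
from pcdquant.segmentation import PerfusionSegmentation

SIDE = 140
SCALE = SIDE / 4.5


def _seg(capillary, vessel=None, side=None):
    side = capillary.shape[0] if side is None else side
    vessel = np.zeros((side, side), dtype=bool) if vessel is None else vessel
    img = EnFaceAngiogram(pixels=np.zeros((side, side)))
    return PerfusionSegmentation(
        capillary_binary=capillary & ~vessel, vessel_mask=vessel,
        global_binary=capillary, adaptive_binary=capillary,
        stretched=np.zeros((side, side)), angiogram=img)


def _roi(side=SIDE):
    c = (side - 1) / 2
    return make_annulus((c, c), SCALE, (side, side))


def brute_force_pcd(capillary, vessel, region, exclude_vessels=True):
    """Independent exhaustive pixel count (plain Python loops)."""
    num = den = 0
    for r in range(region.shape[0]):
        for c in range(region.shape[1]):
            if not region[r, c]:
                continue
            if exclude_vessels and vessel[r, c]:
                continue
            den += 1
            if capillary[r, c] and not vessel[r, c]:
                num += 1
    return 100.0 * num / den


class TestRegionPCD:
    def test_all_white_no_vessels_is_100(self):
        seg, roi = _seg(np.ones((SIDE, SIDE), dtype=bool)), _roi()
        assert whole_image_pcd(seg, roi) == 100.0
        assert region_pcd(seg, roi.annulus_mask) == 100.0

    def test_all_black_is_0(self):
        seg, roi = _seg(np.zeros((SIDE, SIDE), dtype=bool)), _roi()
        assert whole_image_pcd(seg, roi) == 0.0

    def test_constructed_half_annulus_is_50(self):
        roi = _roi()
        capillary = np.zeros((SIDE, SIDE), dtype=bool)
        idx = np.flatnonzero(roi.annulus_mask)
        capillary.flat[idx[::2]] = True
        n = roi.annulus_mask.sum()
        expected = 100.0 * len(idx[::2]) / n
        assert region_pcd(_seg(capillary), roi.annulus_mask) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_with_vessels(self, rng):
        capillary = rng.random((SIDE, SIDE)) < 0.5
        vessel = rng.random((SIDE, SIDE)) < 0.10
        seg, roi = _seg(capillary, vessel), _roi()
        assert whole_image_pcd(seg, roi) == brute_force_pcd(
            seg.capillary_binary, vessel, ~roi.inner_mask)
        for name, mask in roi.sector_masks.items():
            assert region_pcd(seg, mask) == brute_force_pcd(
                seg.capillary_binary, vessel, mask), name

    def test_denominator_flag(self, rng):
        capillary = rng.random((SIDE, SIDE)) < 0.5
        vessel = rng.random((SIDE, SIDE)) < 0.10
        seg, roi = _seg(capillary, vessel), _roi()
        incl = region_pcd(seg, roi.annulus_mask, exclude_vessels_from_denominator=False)
        excl = region_pcd(seg, roi.annulus_mask, exclude_vessels_from_denominator=True)
        assert incl < excl  # same numerator, larger denominator

    def test_empty_mask_rejected(self):
        seg = _seg(np.ones((SIDE, SIDE), dtype=bool))
        with pytest.raises(GeometryError):
            region_pcd(seg, np.zeros((SIDE, SIDE), dtype=bool))

    def test_zero_denominator_rejected(self):
        seg = _seg(np.ones((SIDE, SIDE), dtype=bool),
                   vessel=np.ones((SIDE, SIDE), dtype=bool))
        with pytest.raises(GeometryError):
            region_pcd(seg, np.ones((SIDE, SIDE), dtype=bool))


class TestQuantify:
    def test_annulus_numerator_is_sum_of_sectors(self, rng):
        capillary = rng.random((SIDE, SIDE)) < 0.4
        vessel = rng.random((SIDE, SIDE)) < 0.05
        res = quantify(_seg(capillary, vessel), _roi())
        sector_nums = sum(res.numerators[s] for s in
                          ("superior", "nasal", "inferior", "temporal"))
        assert res.numerators["annulus"] == sector_nums

    def test_annulus_pcd_between_sector_extremes(self, rng):
        capillary = rng.random((SIDE, SIDE)) < 0.4
        res = quantify(_seg(capillary), _roi())
        vals = list(res.sector_pcd_pct.values())
        assert min(vals) <= res.whole_annulus_pcd_pct <= max(vals)

    def test_percentages_bounded_and_counts_consistent(self, rng):
        capillary = rng.random((SIDE, SIDE)) < 0.7
        res = quantify(_seg(capillary), _roi())
        for region, num in res.numerators.items():
            assert 0 <= num <= res.denominators[region]


class TestDensityMap:
    def test_grid_dimensions_at_study_scale(self):
        seg = _seg(np.zeros((1824, 1824), dtype=bool), side=1824)
        dm = density_map(seg, window_px=16, stride_px=8)
        assert dm.values.shape == (227, 227)  # floor((1824-16)/8)+1

    def test_all_white_gives_100_everywhere(self):
        seg = _seg(np.ones((128, 128), dtype=bool))
        np.testing.assert_allclose(density_map(seg).values, 100.0)

    def test_cells_match_brute_force(self, rng):
        capillary = rng.random((96, 96)) < 0.5
        vessel = rng.random((96, 96)) < 0.1
        seg = _seg(capillary, vessel, side=96)
        dm = density_map(seg, 16, 8)
        for i in range(dm.values.shape[0]):
            for j in range(dm.values.shape[1]):
                win_c = seg.capillary_binary[8 * i:8 * i + 16, 8 * j:8 * j + 16]
                win_v = vessel[8 * i:8 * i + 16, 8 * j:8 * j + 16]
                expected = 100.0 * win_c.sum() / (~win_v).sum()
                assert dm.values[i, j] == pytest.approx(expected, abs=1e-9), (i, j)

    def test_cell_mean_tracks_global_density(self, rng):
        capillary = rng.random((320, 320)) < 0.37
        seg = _seg(capillary, side=320)
        dm = density_map(seg)
        assert abs(np.nanmean(dm.values) - 100 * capillary.mean()) < 1.0

    def test_window_stride_validation(self):
        seg = _seg(np.zeros((64, 64), dtype=bool), side=64)
        with pytest.raises(ValueError):
            density_map(seg, window_px=8, stride_px=16)
        with pytest.raises(ValueError):
            density_map(seg, window_px=128)


class TestRenderDensityMap:
    def test_uniform_map_uniform_color(self, tmp_path):
        dm = DensityMap(values=np.full((20, 20), 42.0), window_px=16, stride_px=8)
        p = render_density_map(dm, tmp_path / "m.png")
        from PIL import Image
        arr = np.array(Image.open(p))
        assert (arr == arr[0, 0]).all()

    def test_rendering_is_byte_deterministic(self, tmp_path, rng):
        dm = DensityMap(values=rng.random((20, 20)) * 100, window_px=16, stride_px=8)
        p1 = render_density_map(dm, tmp_path / "a.png")
        p2 = render_density_map(dm, tmp_path / "b.png")
        assert p1.read_bytes() == p2.read_bytes()

    def test_scale_endpoints_map_to_colormap_endpoints(self, tmp_path):
        from matplotlib import colormaps
        from PIL import Image
        dm = DensityMap(values=np.array([[0.0, 100.0]]), window_px=16, stride_px=8)
        arr = np.array(Image.open(render_density_map(dm, tmp_path / "e.png", upscale=1)))
        cm = colormaps["turbo"]
        np.testing.assert_array_equal(arr[0, 0], cm(0.0, bytes=True)[:3])
        np.testing.assert_array_equal(arr[0, 1], cm(1.0, bytes=True)[:3])


class TestQuantifierEstimator:
    def test_pipeline_composition(self):
        from sklearn.pipeline import Pipeline
        from pcdquant import AngiogramSimSpec, CapillarySegmenter, generate_angiogram
        imgs = []
        for i, lat in enumerate(["OD", "OS"]):
            img, _ = generate_angiogram(AngiogramSimSpec(
                image_size_px=160, capillary_fraction=0.3, laterality=lat, seed=i))
            img.subject_id, img.eye_id = "s0", f"s0-{lat}"
            imgs.append(img)
        pipe = Pipeline([("segment", CapillarySegmenter(resize_factor=4)),
                         ("quantify", PCDQuantifier())])
        out = pipe.fit(imgs).transform(imgs)
        assert len(out) == 2
        assert {"pcd_whole_pct", "pcd_annulus_pct", "pcd_sup_pct"} <= set(out.columns)
        assert out["pcd_whole_pct"].between(0, 100).all()

    def test_clone_and_params(self):
        from sklearn.base import clone
        est = PCDQuantifier(exclude_vessels_from_denominator=False)
        assert clone(est).get_params()["exclude_vessels_from_denominator"] is False
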