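"""Segmentation: prefilter and background subtraction semantics, watershed
splitting, size/border filters, NC-to-PSD assignment, and recovery of
ground-truth structure from rendered scenes."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

import nanopsd as n
from nanopsd.core import RenderedImage, fwhm_to_sigma
from nanopsd.segmentation import (SegmentationParams, assign_nc_to_psd,
                                  detect_and_split, preprocess,
                                  subtract_background)

from conftest import make_pair_scene, make_single_nc_scene


def _img(data, px=20.0):
    return RenderedImage(np.asarray(data, dtype=np.float64), px)


class TestPreprocess:
    def test_sigma_zero_is_identity(self):
        img = _img(np.random.default_rng(0).random((30, 30)))
        assert preprocess(img, 0.0) is img

    def test_delta_spike_becomes_discrete_gaussian(self):
        data = np.zeros((41, 41))
        data[20, 20] = 1.0
        out = preprocess(_img(data), 40.0)  # sigma 2 px at 20 nm pixels
        ys, xs = np.mgrid[0:41, 0:41]
        expected = np.exp(-((xs - 20.0) ** 2 + (ys - 20.0) ** 2) / (2 * 2.0 ** 2))
        expected /= expected.sum()
        assert np.isclose(out.data.sum(), 1.0, atol=1e-6)
        assert np.allclose(out.data, expected, atol=1e-4)

    def test_constant_image_unchanged(self):
        img = _img(np.full((25, 25), 3.3))
        out = preprocess(img, 60.0)
        assert np.allclose(out.data, 3.3, rtol=1e-9)


class TestSubtractBackground:
    def test_constant_image_goes_to_zero(self):
        out = subtract_background(_img(np.full((30, 30), 7.0)), 140.0)
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_all_zero_stays_zero(self):
        out = subtract_background(_img(np.zeros((20, 20))), 140.0)
        assert np.all(out.data == 0.0)

    def test_spot_on_offset_keeps_peak_removes_offset(self):
        # explicit low-pass oracle: out = clip(img - G_sigma(img), 0)
        rng = np.random.default_rng(1)
        data = np.full((51, 51), 5.0)
        ys, xs = np.mgrid[0:51, 0:51]
        spot = 10.0 * np.exp(-((xs - 25) ** 2 + (ys - 25) ** 2) / (2 * 2.5 ** 2))
        data = data + spot
        out = subtract_background(_img(data), 140.0)
        sigma_px = fwhm_to_sigma(140.0) / 20.0
        oracle = np.clip(data - ndimage.gaussian_filter(data, sigma_px,
                                                        mode="nearest"), 0, None)
        assert np.allclose(out.data, oracle)
        assert out.data[25, 25] > 0  # peak survives
        assert np.allclose(out.data[:5, :5], 0.0, atol=1e-6)  # offset removed


class TestDetectAndSplit:
    def _spots_image(self, separations_nm, fwhm=120.0, px=20.0, size=100):
        data = np.zeros((size, size))
        centre = size // 2
        for dx in separations_nm:
            c = centre + dx / px
            ys, xs = np.mgrid[0:size, 0:size]
            s = fwhm_to_sigma(fwhm) / px
            data += np.exp(-((xs - c) ** 2 + (ys - centre) ** 2) / (2 * s ** 2))
        return _img(data, px)

    def test_two_spots_400nm_apart_split(self):
        img = self._spots_image([-200.0, 200.0])
        params = SegmentationParams(seed_point_diameter=160.0, min_pixels=5)
        res = detect_and_split(img, params)
        assert len(res.objects) == 2

    def test_two_spots_60nm_apart_merge(self):
        img = self._spots_image([-30.0, 30.0])
        params = SegmentationParams(seed_point_diameter=160.0, min_pixels=5)
        res = detect_and_split(img, params)
        assert len(res.objects) == 1

    def test_min_pixels_filter_removes_small_objects(self):
        data = np.zeros((50, 50))
        data[10:13, 10:13] = 1.0   # 9 px object
        data[30:37, 30:37] = 1.0   # 49 px object
        params = SegmentationParams(seed_point_diameter=160.0, min_pixels=10,
                                    support_fraction=None)
        res = detect_and_split(_img(data), params)
        assert len(res.objects) == 1
        assert res.objects[0].pixel_count == 49

    def test_empty_foreground_returns_empty_list(self):
        params = SegmentationParams(seed_point_diameter=160.0, min_pixels=5)
        res = detect_and_split(_img(np.zeros((30, 30))), params)
        assert res.objects == []

    def test_border_objects_excluded_when_requested(self):
        data = np.zeros((40, 40))
        data[0:6, 0:6] = 1.0     # touches border
        data[20:26, 20:26] = 1.0
        p_excl = SegmentationParams(seed_point_diameter=160.0, min_pixels=5)
        p_keep = dataclasses.replace(p_excl, exclude_border=False)
        assert len(detect_and_split(_img(data), p_excl).objects) == 1
        assert len(detect_and_split(_img(data), p_keep).objects) == 2

    def test_watershed_fragments_tile_component(self):
        img = self._spots_image([-200.0, 200.0])
        params = SegmentationParams(seed_point_diameter=160.0, min_pixels=1,
                                    exclude_border=False)
        res = detect_and_split(img, params)
        thr = res.threshold
        fg = img.data > thr
        comp, _ = ndimage.label(fg, structure=np.ones((3, 3), bool))
        # union of fragments equals the foreground; fragments disjoint by label
        assert np.array_equal(res.labels > 0, fg)
        assert set(np.unique(res.labels[fg])) == {o.label for o in res.objects}

    def test_min_pixels_monotonicity(self):
        rng = np.random.default_rng(5)
        data = ndimage.gaussian_filter(rng.random((80, 80)), 2.0)
        counts = []
        for mp in (1, 5, 10, 20, 40):
            params = SegmentationParams(seed_point_diameter=160.0, min_pixels=mp)
            counts.append(len(detect_and_split(_img(data), params).objects))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_scale_consistency_at_double_resolution(self):
        scene = make_single_nc_scene(axes=(120.0, 220.0), orientation=0.5)
        diams = []
        for px in (20.0, 10.0):
            img = n.render_image(scene, psf_fwhm=0.0, pixel_size=px)
            params = SegmentationParams(seed_point_diameter=160.0, min_pixels=4)
            res = detect_and_split(img, params)
            assert len(res.objects) == 1
            diams.append(res.objects[0].equivalent_diameter)
        assert abs(diams[1] - diams[0]) / diams[0] < 0.05


class TestAssignment:
    def _result_from_labels(self, labels, px=20.0):
        from skimage.measure import regionprops
        from nanopsd.segmentation import SegmentationResult, _props_to_object
        labels = np.asarray(labels)
        objs = [_props_to_object(p, px, labels.shape)
                for p in regionprops(labels, intensity_image=np.ones_like(labels,
                                                                          dtype=float))]
        return SegmentationResult(objs, labels, px, 0.0)

    def test_two_ncs_in_one_psd(self):
        psd = np.zeros((20, 20), dtype=int)
        psd[5:15, 5:15] = 1
        nc = np.zeros((20, 20), dtype=int)
        nc[6:9, 6:9] = 1
        nc[11:14, 11:14] = 2
        records, summary = assign_nc_to_psd(self._result_from_labels(psd),
                                            self._result_from_labels(nc))
        assert len(records) == 1
        assert records[0].nc_count == 2
        assert records[0].subtype == "2NC"
        assert summary["empty_psd_fraction"] == 0.0

    def test_psd_without_nc_excluded_and_counted(self):
        psd = np.zeros((30, 30), dtype=int)
        psd[2:10, 2:10] = 1
        psd[18:26, 18:26] = 2
        nc = np.zeros((30, 30), dtype=int)
        nc[4:7, 4:7] = 1
        records, summary = assign_nc_to_psd(self._result_from_labels(psd),
                                            self._result_from_labels(nc))
        assert len(records) == 1
        assert summary["empty_psd_fraction"] == pytest.approx(0.5)

    def test_orphan_nc_discarded_and_counted(self):
        psd = np.zeros((30, 30), dtype=int)
        psd[2:10, 2:10] = 1
        nc = np.zeros((30, 30), dtype=int)
        nc[20:23, 20:23] = 1
        records, summary = assign_nc_to_psd(self._result_from_labels(psd),
                                            self._result_from_labels(nc))
        assert records == []
        assert summary["n_ncs_unassigned"] == 1

    def test_shape_mismatch_raises(self):
        a = self._result_from_labels(np.zeros((10, 10), dtype=int))
        b = self._result_from_labels(np.zeros((12, 12), dtype=int))
        with pytest.raises(ValueError):
            assign_nc_to_psd(a, b)


class TestStedWorkflow:
    def test_blank_images_give_empty_records(self):
        blank = _img(np.zeros((100, 100)))
        records, summary = n.run_sted_workflow(blank, blank)
        assert records == []

    def test_single_nc_scene_recovers_1nc_subtype(self, small_config):
        # modest density so chance apposition of two PSDs is rare
        cfg = dataclasses.replace(small_config, subtype_mixture=(1, 0, 0, 0),
                                  psd_density=8.0)
        scene = n.sample_scene(cfg, seed=13)
        confocal, sted = n.render_scene_pair(scene, cfg)
        records, _ = n.run_sted_workflow(confocal, sted)
        assert len(records) > 0
        frac_1nc = np.mean([r.subtype == "1NC" for r in records])
        assert frac_1nc >= 0.9

    def test_three_nc_psd_at_250nm_recovered(self):
        from nanopsd.simulate import NanoclusterTruth, PSDTruth, SyntheticScene
        # equilateral triangle, side 250 nm
        cx = cy = 1500.0
        r = 250.0 / np.sqrt(3.0)
        ncs = [NanoclusterTruth((cx + r * np.cos(a), cy + r * np.sin(a)),
                                189.0, 86.0, 0.4, 150)
               for a in (0.0, 2 * np.pi / 3, 4 * np.pi / 3)]
        scene = SyntheticScene(3000.0, 3000.0, [PSDTruth(ncs)], 0)
        cfg = n.SimulationConfig(field_width_nm=3000, field_height_nm=3000)
        confocal, sted = n.render_scene_pair(scene, cfg)
        records, _ = n.run_sted_workflow(confocal, sted)
        assert len(records) == 1
        assert records[0].nc_count == 3

    @pytest.mark.parametrize("sep,expected", [(60.0, 1), (250.0, 2)])
    def test_pair_splitting_by_separation(self, sep, expected):
        scene = make_pair_scene(sep, seed=1)
        cfg = n.SimulationConfig(field_width_nm=3000, field_height_nm=3000)
        confocal, sted = n.render_scene_pair(scene, cfg)
        records, _ = n.run_sted_workflow(confocal, sted)
        assert sum(r.nc_count for r in records) == expected

    def test_mismatched_shapes_raise(self):
        a = _img(np.zeros((50, 50)))
        b = _img(np.zeros((60, 60)))
        with pytest.raises(ValueError, match="shapes"):
            n.run_sted_workflow(a, b)
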