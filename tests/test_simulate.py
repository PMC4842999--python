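"""Scene generator and renderer behaviour: determinism, constraint
satisfaction, mass conservation, PSF width, and localisation statistics."""

import numpy as np
import pytest

import nanopsd as n
from nanopsd.morphometry import LineProfile, fwhm_from_profile
from nanopsd.simulate import scene_from_json, scene_to_json

from conftest import make_single_nc_scene


class TestSampleScene:
    def test_degenerate_mixture_gives_only_single_nc_psds(self):
        cfg = n.SimulationConfig(field_width_nm=8000, field_height_nm=8000,
                                 subtype_mixture=(1, 0, 0, 0))
        scene = n.sample_scene(cfg, seed=3)
        assert len(scene.psds) > 0
        assert all(p.subtype_truth == 1 for p in scene.psds)

    def test_spacing_constraint_enforced_for_all_pairs(self):
        cfg = n.SimulationConfig(field_width_nm=12000, field_height_nm=12000,
                                 subtype_mixture=(0, 0, 1, 0),
                                 spacing_interval=(100.0, 300.0))
        scene = n.sample_scene(cfg, seed=5)
        for psd in scene.psds:
            cs = [nc.centre for nc in psd.nanoclusters]
            assert len(cs) == 3
            for i in range(3):
                for j in range(i + 1, 3):
                    d = np.hypot(cs[i][0] - cs[j][0], cs[i][1] - cs[j][1])
                    assert 100.0 - 1e-9 <= d <= 300.0 + 1e-9

    def test_unsatisfiable_spacing_raises_naming_psd(self):
        # 4 NCs all pairwise in a near-degenerate ring is geometrically impossible
        cfg = n.SimulationConfig(field_width_nm=8000, field_height_nm=8000,
                                 subtype_mixture=(0, 0, 0, 1),
                                 spacing_interval=(299.0, 300.0))
        with pytest.raises(RuntimeError, match=r"PSD \d+"):
            n.sample_scene(cfg, seed=0)

    def test_poisson_psd_count_matches_density(self):
        # Monte-Carlo oracle: field 20x20 um at 19.2 per 20 um^2 -> mean 384
        cfg = n.SimulationConfig(field_width_nm=20000, field_height_nm=20000)
        counts = [len(n.sample_scene(cfg, seed=s).psds) for s in range(60)]
        mean = np.mean(counts)
        expected = 19.2 * 400 / 20
        # 3 standard errors of the Poisson mean over 60 draws
        tol = 3 * np.sqrt(expected / 60)
        assert abs(mean - expected) < tol

    def test_axes_ordered_and_positive(self, small_scene):
        for nc in small_scene.nanoclusters:
            assert 0 < nc.short_axis <= nc.long_axis
            assert nc.molecule_count >= 1

    def test_determinism_byte_for_byte(self, small_config):
        a = scene_to_json(n.sample_scene(small_config, seed=11))
        b = scene_to_json(n.sample_scene(small_config, seed=11))
        assert a == b
        c = scene_to_json(n.sample_scene(small_config, seed=12))
        assert a != c

    def test_scene_json_round_trip(self, small_scene):
        restored = scene_from_json(scene_to_json(small_scene))
        assert len(restored.psds) == len(small_scene.psds)
        a = small_scene.nanoclusters[0]
        b = restored.nanoclusters[0]
        assert a.centre == b.centre and a.long_axis == b.long_axis

    def test_mixture_recovery_over_many_psds(self):
        # empirical subtype frequencies within 3 binomial SEs of the mixture
        cfg = n.SimulationConfig(field_width_nm=20000, field_height_nm=20000)
        counts = np.zeros(4)
        total = 0
        for s in range(30):
            for p in n.sample_scene(cfg, seed=100 + s).psds:
                counts[p.subtype_truth - 1] += 1
                total += 1
        assert total >= 10_000
        freq = counts / total
        for k, pk in enumerate(cfg.subtype_mixture):
            se = np.sqrt(pk * (1 - pk) / total)
            assert abs(freq[k] - pk) < 3 * se + 1e-12


class TestRenderImage:
    def test_point_nc_renders_at_psf_fwhm(self):
        scene = make_single_nc_scene(axes=(2.0, 2.0), molecule_count=1000)
        img = n.render_image(scene, psf_fwhm=85.0, pixel_size=20.0)
        row = img.data[img.data.shape[0] // 2 - 3:img.data.shape[0] // 2 + 4].sum(0)
        # fit the horizontal profile through the spot
        m = fwhm_from_profile(LineProfile(row, spacing=20.0))
        assert m.valid
        assert abs(m.fwhm - 85.0) < 20.0 + 1e-9  # within one pixel quantisation

    def test_no_blur_support_equals_ellipse_mask(self):
        scene = make_single_nc_scene(axes=(200.0, 400.0), orientation=0.3)
        img = n.render_image(scene, psf_fwhm=0.0, pixel_size=20.0)
        nc = scene.nanoclusters[0]
        # pixel-centre containment test against the analytic ellipse
        h, w = img.data.shape
        ys, xs = np.mgrid[0:h, 0:w]
        px = (xs + 0.5) * 20.0 - nc.centre[0]
        py = (ys + 0.5) * 20.0 - nc.centre[1]
        ct, st = np.cos(nc.orientation), np.sin(nc.orientation)
        u = (px * ct + py * st) / (nc.long_axis / 2)
        v = (-px * st + py * ct) / (nc.short_axis / 2)
        inside = u * u + v * v <= 1.0
        support = img.data > 0
        # interior pixels must be lit; support may extend at most ~1 px further
        assert (support & inside).sum() >= 0.9 * inside.sum()
        dil = np.zeros_like(inside)
        from scipy import ndimage
        dil = ndimage.binary_dilation(inside, iterations=2)
        assert not (support & ~dil).any()

    def test_intensity_linear_in_molecule_count(self):
        s1 = make_single_nc_scene(molecule_count=100)
        s2 = make_single_nc_scene(molecule_count=200)
        i1 = n.render_image(s1, psf_fwhm=85.0, pixel_size=20.0)
        i2 = n.render_image(s2, psf_fwhm=85.0, pixel_size=20.0)
        assert np.isclose(i2.data.sum(), 2 * i1.data.sum(), rtol=1e-9)

    def test_noiseless_mass_conservation(self, small_scene, small_config):
        img = n.render_image(small_scene, psf_fwhm=small_config.psf_fwhm_sted,
                             pixel_size=20.0)
        total_molecules = sum(nc.molecule_count for nc in small_scene.nanoclusters)
        assert np.isclose(img.data.sum(), total_molecules, rtol=1e-6)

    def test_invalid_pixel_size_raises(self, small_scene):
        with pytest.raises(ValueError):
            n.render_image(small_scene, psf_fwhm=85.0, pixel_size=0.0)

    def test_noise_requires_seed_and_is_reproducible(self, small_scene):
        with pytest.raises(ValueError):
            n.render_image(small_scene, 85.0, 20.0, noise={"poisson_gain": 5.0})
        a = n.render_image(small_scene, 85.0, 20.0,
                           noise={"poisson_gain": 5.0}, seed=3)
        b = n.render_image(small_scene, 85.0, 20.0,
                           noise={"poisson_gain": 5.0}, seed=3)
        assert np.array_equal(a.data, b.data)


class TestSimulatePalm:
    def test_zero_error_events_inside_parent_ellipse(self):
        cfg = n.SimulationConfig(field_width_nm=4000, field_height_nm=4000,
                                 subtype_mixture=(1, 0, 0, 0),
                                 localisation_precision=1e-12,
                                 background_rate=0.0)
        scene = n.sample_scene(cfg, seed=2)
        table = n.simulate_palm(scene, cfg, seed=3)
        ncs = scene.nanoclusters
        for _, row in table.iterrows():
            nc = ncs[int(row.truth_nc_id)]
            dx = row.x_nm - nc.centre[0]
            dy = row.y_nm - nc.centre[1]
            ct, st = np.cos(nc.orientation), np.sin(nc.orientation)
            u = (dx * ct + dy * st) / (nc.long_axis / 2)
            v = (-dx * st + dy * ct) / (nc.short_axis / 2)
            assert u * u + v * v <= 1.0 + 1e-9

    def test_mean_event_count_matches_rate(self):
        cfg = n.SimulationConfig(field_width_nm=3000, field_height_nm=3000,
                                 localisations_per_nc=100.0, background_rate=0.0)
        scene = make_single_nc_scene()
        counts = [len(n.simulate_palm(scene, cfg, seed=s)) for s in range(300)]
        # Monte-Carlo oracle: Poisson(100) mean within 3 SEs
        assert abs(np.mean(counts) - 100.0) < 3 * np.sqrt(100.0 / 300)

    def test_parent_ids_cover_all_psds_without_background(self):
        cfg = n.SimulationConfig(field_width_nm=8000, field_height_nm=8000,
                                 subtype_mixture=(1, 0, 0, 0),
                                 background_rate=0.0)
        scene = n.sample_scene(cfg, seed=4)
        table = n.simulate_palm(scene, cfg, seed=5)
        assert table.truth_nc_id.min() >= 0
        assert table.truth_nc_id.nunique() == len(scene.psds)

    def test_determinism(self, small_scene, small_config):
        a = n.simulate_palm(small_scene, small_config, seed=9)
        b = n.simulate_palm(small_scene, small_config, seed=9)
        assert a.equals(b)


class TestTwoChannel:
    def test_fully_paired_all_within_600(self, small_config):
        cfg = small_config
        scene = n.sample_scene(cfg, seed=21)
        _, _, truth = n.simulate_two_channel(scene, cfg, seed=1,
                                             offset_nm=200.0, fraction_paired=1.0,
                                             unpaired_density=0.0)
        from nanopsd.spatial import juxtaposition
        a = truth[["a_x_nm", "a_y_nm"]].to_numpy()
        b = truth.attrs["b_centres"]
        res = juxtaposition(a, b, threshold=600.0,
                            field=(cfg.field_width_nm, cfg.field_height_nm))
        assert res.percent_juxtaposed == 100.0

    def test_unpaired_far_b_gives_zero(self, small_config):
        cfg = small_config
        scene = n.sample_scene(cfg, seed=22)
        _, _, truth = n.simulate_two_channel(scene, cfg, seed=1,
                                             fraction_paired=0.0,
                                             unpaired_density=3.0,
                                             min_unpaired_clearance=1000.0)
        from nanopsd.spatial import juxtaposition
        a = truth[["a_x_nm", "a_y_nm"]].to_numpy()
        b = truth.attrs["b_centres"]
        res = juxtaposition(a, b, threshold=600.0,
                            field=(cfg.field_width_nm, cfg.field_height_nm))
        assert res.percent_juxtaposed == 0.0
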