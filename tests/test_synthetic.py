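"""Generator contracts: truth maps, signatures, scene series, polygons."""

import numpy as np
import pytest
import shapely
from scipy import ndimage

from bogmap import synthetic as syn
from bogmap.lucip import CLASS_NAMES, SWIR_BANDS, VISIBLE_NIR_BANDS

from conftest import PROPORTIONS


class TestGenerateClassMap:
    def test_degenerate_proportions_single_class(self):
        cmap = syn.generate_class_map(50, 40, (1, 0, 0, 0, 0, 0, 0), seed=0)
        assert (cmap.grid == 1).all()

    def test_realised_shares_track_request(self):
        cmap = syn.generate_class_map(500, 500, PROPORTIONS, patch_scale=20, seed=7)
        props = cmap.proportions()
        for code, want in zip(range(1, 8), PROPORTIONS):
            assert abs(props.get(code, 0.0) - want) < 0.05

    def test_same_seed_identical(self):
        a = syn.generate_class_map(80, 80, PROPORTIONS, seed=3)
        b = syn.generate_class_map(80, 80, PROPORTIONS, seed=3)
        np.testing.assert_array_equal(a.grid, b.grid)

    def test_patches_are_contiguous_not_salt_and_pepper(self):
        patch_scale = 15
        cmap = syn.generate_class_map(300, 300, PROPORTIONS, patch_scale, seed=2)
        n_patches = 0
        for code in range(1, 8):
            _, n = ndimage.label(cmap.grid == code)
            n_patches += n
        mean_patch = cmap.grid.size / n_patches
        assert mean_patch >= patch_scale**2 / 4

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(width=0, height=10, class_proportions=PROPORTIONS),
            dict(width=10, height=10, class_proportions=(0.5,) * 7),
            dict(width=10, height=10, class_proportions=(-0.1, 1.1, 0, 0, 0, 0, 0)),
            dict(width=10, height=10, class_proportions=PROPORTIONS, patch_scale=0),
        ],
    )
    def test_input_errors(self, kwargs):
        with pytest.raises(ValueError):
            syn.generate_class_map(seed=0, **kwargs)


class TestDefaultSignatures:
    def test_means_in_unit_interval(self, signatures):
        assert ((signatures.means >= 0) & (signatures.means <= 1)).all()

    def test_water_has_lowest_nir(self, signatures):
        nir = signatures.means[:, 6]  # B8
        assert np.argmin(nir) == 5  # water, code 6

    def test_built_up_brightest_in_visible(self, signatures):
        for b in (0, 1, 2):  # B2, B3, B4
            assert np.argmax(signatures.means[:, b]) == 6  # built_up, code 7

    def test_grassland_and_cutaway_high_nir(self, signatures):
        nir = signatures.means[:, 6]
        top2 = set(np.argsort(-nir)[:2] + 1)
        assert top2 == {1, 3}  # cutaway, grassland

    def test_closest_pair_is_cutover_remnant(self, signatures):
        assert signatures.closest_pair() == (2, 5)

    def test_swir_contrast_below_visible_nir(self, signatures):
        spread = signatures.means.std(axis=0)
        assert spread[SWIR_BANDS].max() < spread[VISIBLE_NIR_BANDS].min()

    def test_separability_exceeds_three_noise_sd(self, signatures):
        assert signatures.separability_margin() > 3 * signatures.noise_sd.max()

    def test_nearest_mean_oracle_recovers_truth(self, truth_map, clean_scene, signatures):
        """Noiseless class means classified by nearest mean give 100% recovery."""
        flat = clean_scene.bands.reshape(10, -1).T
        d = np.linalg.norm(flat[:, None, :] - signatures.means[None], axis=2)
        pred = d.argmin(axis=1) + 1
        assert (pred.reshape(truth_map.shape) == truth_map.grid).all()


class TestSceneSeries:
    def test_no_clouds_means_zero_qa(self, truth_map, signatures):
        scenes = syn.generate_scene_series(truth_map, signatures, 3, (0.0, 0.0), seed=0)
        assert all((s.qa == 0).all() for s in scenes)

    def test_noiseless_scene_equals_class_means(self, truth_map, clean_scene, signatures):
        expected = signatures.means[truth_map.grid - 1].transpose(2, 0, 1)
        np.testing.assert_allclose(clean_scene.bands, expected, atol=1e-7)

    def test_cloud_fractions_within_requested_range(self, scene_series):
        for s in scene_series:
            assert 0.05 <= s.cloud_fraction <= 0.4

    def test_qa_fraction_matches_cloud_fraction_exactly(self, scene_series):
        n = scene_series[0].qa.size
        for s in scene_series:
            assert abs(s.cloudy_mask().mean() - s.cloud_fraction) <= 1 / n

    def test_every_pixel_clear_in_some_scene(self, scene_series):
        cloudy = np.stack([s.cloudy_mask() for s in scene_series])
        assert (~cloudy).any(axis=0).all()

    def test_reflectance_in_unit_interval(self, scene_series):
        for s in scene_series:
            vals = s.bands[~np.isnan(s.bands)]
            assert ((vals >= 0) & (vals <= 1)).all()

    def test_same_seed_identical(self, truth_map, signatures):
        a = syn.generate_scene_series(truth_map, signatures, 4, (0.1, 0.3), seed=9)
        b = syn.generate_scene_series(truth_map, signatures, 4, (0.1, 0.3), seed=9)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.bands, sb.bands)
            np.testing.assert_array_equal(sa.qa, sb.qa)
            assert sa.date == sb.date

    def test_bad_cloud_range_rejected(self, truth_map, signatures):
        with pytest.raises(ValueError):
            syn.generate_scene_series(truth_map, signatures, 2, (0.5, 1.5), seed=0)
        with pytest.raises(ValueError):
            syn.generate_scene_series(truth_map, signatures, 0, (0.0, 0.1), seed=0)


class TestTrainingPolygons:
    def test_minimal_request_one_polygon_per_class(self, truth_map):
        polys = syn.generate_training_polygons(truth_map, [1] * 7, 3, seed=0)
        assert len(polys) == 7
        assert polys.counts() == {c: 1 for c in range(1, 8)}
        geoms = [p for p, _ in polys.items]
        for i in range(len(geoms)):
            for j in range(i + 1, len(geoms)):
                assert geoms[i].disjoint(geoms[j])

    def test_published_sample_structure_reproduced(self):
        """The 366-polygon training design (37+45+32+100+62+64+26) fits."""
        big = syn.generate_class_map(600, 600, PROPORTIONS, patch_scale=25, seed=4)
        request = [37, 45, 32, 100, 62, 64, 26]
        polys = syn.generate_training_polygons(big, request, 2, seed=4)
        assert len(polys) == 366
        counts = polys.counts()
        assert [counts[c] for c in range(1, 8)] == request

    def test_polygon_pixels_are_pure_class(self, truth_map):
        polys = syn.generate_training_polygons(truth_map, [3] * 7, 3, seed=2)
        for poly, code in polys.items:
            minx, miny, maxx, maxy = poly.bounds
            cc, rr = np.meshgrid(
                np.arange(int(minx), int(np.ceil(maxx))),
                np.arange(int(miny), int(np.ceil(maxy))),
            )
            inside = shapely.contains_xy(poly, cc.ravel() + 0.5, rr.ravel() + 0.5)
            sampled = truth_map.grid[rr.ravel()[inside], cc.ravel()[inside]]
            assert (sampled == code).all()

    def test_absent_class_reported_unsatisfiable(self):
        cmap = syn.generate_class_map(60, 60, (1, 0, 0, 0, 0, 0, 0), seed=0)
        with pytest.raises(ValueError, match="cutover"):
            syn.generate_training_polygons(cmap, [1, 1, 0, 0, 0, 0, 0], 3, seed=0)

    def test_same_seed_identical(self, truth_map):
        a = syn.generate_training_polygons(truth_map, [2] * 7, 3, seed=6)
        b = syn.generate_training_polygons(truth_map, [2] * 7, 3, seed=6)
        assert [(p.wkt, c) for p, c in a.items] == [(p.wkt, c) for p, c in b.items]
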