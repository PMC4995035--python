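"""Tests of the ground-truthed scene generator."""

import numpy as np
import pytest
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize

from actintrace.synthetic import (
    FilamentSpec,
    compose_scene,
    generate_artifacts,
    random_scene,
    rasterize_filaments,
)


class TestRasterize:
    def test_empty_specs_give_blank_image(self):
        img, mask = rasterize_filaments([], (128, 128))
        assert img.shape == (128, 128)
        assert not img.any()
        assert not mask.any()

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            rasterize_filaments([], (0, 128))

    def test_horizontal_mask_area_matches_length_times_width(self):
        # brute-force expectation: pixels within distance 1.5 of a length-100
        # horizontal centerline through the image center
        spec = FilamentSpec(center=(64.0, 64.0), angle_deg=0.0, length_px=100,
                            width_px=3.0)
        _, mask = rasterize_filaments([spec], (128, 128))
        rr, cc = np.mgrid[0:128, 0:128].astype(float)
        # centerline spans cols [14, 114] on row 64
        t = np.clip(cc, 64 - 50, 64 + 50)
        d = np.hypot(rr - 64.0, cc - t)
        expected = int(np.sum(d <= 1.5))
        assert expected == pytest.approx(300, rel=0.10)
        assert mask.sum() == pytest.approx(expected, rel=0.02)

    def test_rotating_by_90_transposes_the_mask(self):
        h = FilamentSpec(center=(64.0, 64.0), angle_deg=0.0, length_px=100,
                         width_px=3.0)
        v = FilamentSpec(center=(64.0, 64.0), angle_deg=90.0, length_px=100,
                         width_px=3.0)
        _, mh = rasterize_filaments([h], (128, 128))
        _, mv = rasterize_filaments([v], (128, 128))
        assert np.array_equal(mv, mh.T)

    @pytest.mark.parametrize("angle", [0.0, 30.0, 75.0, 120.0, 155.0])
    def test_mask_principal_axis_matches_spec_angle(self, angle):
        spec = FilamentSpec(center=(64.0, 64.0), angle_deg=angle, length_px=80,
                            width_px=3.0)
        _, mask = rasterize_filaments([spec], (128, 128))
        props = regionprops(label(mask))[0]
        # regionprops orientation is measured from the row axis; convert to
        # the horizontal-axis convention used by FilamentSpec
        measured = (90.0 + np.degrees(props.orientation)) % 180.0
        diff = min(abs(measured - angle), 180 - abs(measured - angle))
        assert diff <= 1.0

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FilamentSpec(center=(0, 0), angle_deg=190.0, length_px=50)
        with pytest.raises(ValueError):
            FilamentSpec(center=(0, 0), angle_deg=10.0, length_px=0.5)
        with pytest.raises(ValueError):
            FilamentSpec(center=(0, 0), angle_deg=10.0, length_px=100,
                         curvature=1.0)


class TestArtifacts:
    def test_zero_blobs_give_zero_image(self):
        assert not generate_artifacts((64, 64), 0, seed=1).any()

    def test_fixed_seed_is_deterministic(self):
        a = generate_artifacts((64, 64), 5, seed=42)
        b = generate_artifacts((64, 64), 5, seed=42)
        assert np.array_equal(a, b)

    def test_blobs_are_smooth_and_non_negative(self):
        img = generate_artifacts((128, 128), 5, seed=3)
        assert (img >= 0).all()
        # smoothness: finite differences bounded well below blob amplitude
        assert np.abs(np.diff(img, axis=0)).max() < 0.05

    def test_no_straight_ridge_longer_than_10px(self):
        # threshold the blob image and measure skeleton branch lengths:
        # blob skeletons are compact, unlike filament skeletons
        from actintrace.extract import skeletonize_and_trace

        img = generate_artifacts((128, 128), 5, seed=3)
        thr = img > 0.5 * img.max()
        for chain in skeletonize_and_trace(thr):
            p0, p1 = chain[0].astype(float), chain[-1].astype(float)
            assert np.hypot(*(p1 - p0)) <= 10


class TestComposeScene:
    def test_zero_noise_composite_is_exact_sum(self):
        specs = [FilamentSpec(center=(32, 32), angle_deg=45.0, length_px=40)]
        sc = compose_scene(specs, shape=(64, 64), n_blobs=2, noise_sigma=0.0,
                           seed=0)
        unclipped = sc.truth_image + sc.artifacts_image
        ok = unclipped <= 1.0
        assert np.allclose(sc.composite[ok], unclipped[ok])

    def test_noise_std_matches_requested_sigma(self):
        # elevated blob background keeps the noise away from the clip
        # bounds, so the residual on those pixels is the injected noise
        sc = compose_scene(
            [], shape=(128, 128), n_blobs=6, noise_sigma=0.04, seed=5,
            artifact_kwargs=dict(amplitude_range=(0.3, 0.5)),
        )
        base = sc.truth_image + sc.artifacts_image
        ok = (base > 0.2) & (base < 0.8)
        assert ok.sum() > 1000
        resid = sc.composite - base
        assert abs(resid[ok].std() - 0.04) < 0.005

    def test_pure_noise_scene_has_empty_truth(self):
        sc = compose_scene([], shape=(64, 64), n_blobs=0, noise_sigma=0.04,
                           seed=2)
        assert not sc.truth_mask.any()
        assert sc.composite.std() > 0

    def test_scene_determinism_under_fixed_seed(self):
        a = random_scene(n_fibers=4, shape=(96, 96), seed=9)
        b = random_scene(n_fibers=4, shape=(96, 96), seed=9)
        assert np.array_equal(a.composite, b.composite)
        assert np.array_equal(a.truth_mask, b.truth_mask)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            compose_scene([], shape=(64, 64), noise_sigma=-0.1)

    def test_well_separated_scene_respects_separation(self):
        sc = random_scene(n_fibers=6, shape=(256, 256), seed=1,
                          min_separation=12.0)
        polys = [f.centerline(step=1.0) for f in sc.truth_fibers]
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                d = np.linalg.norm(
                    polys[i][:, None, :] - polys[j][None, :, :], axis=2
                )
                assert d.min() >= 12.0
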