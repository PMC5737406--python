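"""Phantom construction, atrophy model and film rendering ground truth."""

import numpy as np
import pytest

from filmrecon.errors import ValidationError
from filmrecon.films import extract_slices
from filmrecon.synth import (
    FilmRenderSpec,
    PhantomSpec,
    make_phantom,
    make_reference,
    render_films,
    save_films,
)

IDENTITY_RENDER = dict(
    rotation_deg=0.0,
    translation_px=0.0,
    scale_range=(1.0, 1.0),
    gain_range=(1.0, 1.0),
    offset_range=(0.0, 0.0),
    blur_sigma2=0.0,
    noise_std=0.0,
    pedestal=0.0,
    landmark_jitter_px=0,
)


class TestMakePhantom:
    def test_deterministic_under_fixed_seed(self):
        a = make_phantom(PhantomSpec(seed=7))
        b = make_phantom(PhantomSpec(seed=7))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_skull_voxels_carry_skull_intensity(self):
        spec = PhantomSpec(seed=1)
        vol, brain, skull = make_phantom(spec)
        assert np.all(vol[skull] == spec.skull_intensity)

    def test_no_lesions_means_no_hyperintense_brain(self):
        # texture off: the check is about lesion structures, not texture tails
        spec = PhantomSpec(seed=1, lesion_count=0, texture_amplitude=0.0)
        vol, brain, skull = make_phantom(spec)
        assert np.all(vol[brain] < spec.lesion_intensity)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValidationError):
            PhantomSpec(skull_outer_semiaxes=(0.0, 40.0, 36.0))

    def test_intensity_ordering(self):
        spec = PhantomSpec(seed=2)
        vol, brain, skull = make_phantom(spec)
        assert vol[skull].min() > vol[brain].max()
        assert vol[brain].min() > 0


class TestMakeReference:
    def test_factor_one_with_matched_fov_reproduces_phantom(self):
        vol, brain, skull = make_phantom(PhantomSpec(seed=1))
        ref = make_reference(vol, brain, skull, atrophy_factor=1.0, z_fov_crop_top=0)
        np.testing.assert_array_equal(ref.data, vol)

    def test_brain_volume_shrinks_by_cubed_factor(self):
        # texture off so the tissue/CSF threshold classifies voxels cleanly;
        # the dome must close inside the FOV for the 0.95^3 voxel-count oracle
        # (the default phantom truncates the head at the acquisition borders)
        vol, brain, skull = make_phantom(
            PhantomSpec(
                seed=1,
                shape=(100, 96, 96),
                skull_outer_semiaxes=(40.0, 42.0, 36.0),
                texture_amplitude=0.0,
            )
        )
        ref = make_reference(vol, brain, skull, atrophy_factor=0.95, z_fov_crop_top=0)
        threshold = 0.35  # above CSF, below tissue
        before = int((vol[brain] > threshold).sum())
        after = int((ref.data[brain] > threshold).sum())
        assert after / before == pytest.approx(0.95**3, rel=0.02)

    def test_skull_unchanged_by_atrophy(self):
        vol, brain, skull = make_phantom(PhantomSpec(seed=1))
        ref = make_reference(vol, brain, skull, atrophy_factor=0.9, z_fov_crop_top=0)
        np.testing.assert_array_equal(ref.data[skull], vol[skull])

    def test_fov_crop_removes_top_planes(self):
        vol, brain, skull = make_phantom(PhantomSpec(seed=1))
        ref = make_reference(vol, brain, skull, atrophy_factor=1.0, z_fov_crop_top=8)
        assert ref.shape[0] == vol.shape[0] - 8
        np.testing.assert_array_equal(ref.data, vol[:-8])

    def test_out_of_range_factor_rejected(self):
        vol, brain, skull = make_phantom(PhantomSpec(seed=1))
        with pytest.raises(ValidationError):
            make_reference(vol, brain, skull, atrophy_factor=1.5)


class TestRenderFilms:
    def test_identity_rendering_is_exactly_invertible(self):
        vol, brain, skull = make_phantom(PhantomSpec(seed=1))
        sheets, sidecar, gt = render_films(
            vol, brain, skull, FilmRenderSpec(seed=1, **IDENTITY_RENDER)
        )
        stack = extract_slices(sheets, sidecar)
        np.testing.assert_array_equal(stack.data, gt.sharp_stack.data)

    def test_deterministic_under_fixed_seed(self):
        vol, brain, skull = make_phantom(PhantomSpec(seed=1))
        s1, _, gt1 = render_films(vol, brain, skull, FilmRenderSpec(seed=9))
        s2, _, gt2 = render_films(vol, brain, skull, FilmRenderSpec(seed=9))
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.pixels, b.pixels)
        np.testing.assert_array_equal(gt1.gains, gt2.gains)
        for (m1, t1), (m2, t2) in zip(gt1.poses, gt2.poses):
            np.testing.assert_array_equal(m1, m2)
            np.testing.assert_array_equal(t1, t2)

    def test_record_covers_every_slice(self):
        vol, brain, skull = make_phantom(PhantomSpec(seed=1))
        sheets, sidecar, gt = render_films(vol, brain, skull, FilmRenderSpec(seed=0))
        k = sidecar.n_slices
        assert len(gt.poses) == k
        assert gt.gains.shape == (k,)
        assert gt.sharp_stack.n_slices == k
        assert gt.brain_mask.shape == gt.sharp_stack.shape

    def test_true_pose_encodes_landmark_jitter(self):
        # with jitter as the only perturbation, the recorded affine is a pure
        # integer translation equal to the jitter actually applied
        vol, brain, skull = make_phantom(PhantomSpec(seed=1))
        spec = FilmRenderSpec(seed=5, **{**IDENTITY_RENDER, "landmark_jitter_px": 2})
        sheets, sidecar, gt = render_films(vol, brain, skull, spec)
        stack = extract_slices(sheets, sidecar)
        from filmrecon.register import SlicePose, warp_slice

        for k in (0, 5, 10):
            m, t = gt.poses[k]
            np.testing.assert_array_equal(m, np.eye(2))
            pose = SlicePose(matrix=m, translation=t)
            warped, valid = warp_slice(pose.inverse(), stack.data[k])
            np.testing.assert_allclose(
                warped[valid], gt.sharp_stack.data[k][valid], atol=1e-10
            )

    def test_film_png_round_trip(self, tmp_path):
        vol, brain, skull = make_phantom(PhantomSpec(seed=1))
        sheets, _, _ = render_films(vol, brain, skull, FilmRenderSpec(seed=0))
        paths = save_films(sheets, tmp_path)
        from filmrecon.films import read_film

        back = read_film(paths[0])
        assert back.pixels.shape == sheets[0].pixels.shape
        # 16-bit quantisation: correlation with the original is essentially 1
        a, b = sheets[0].pixels.ravel(), back.pixels.ravel()
        assert np.corrcoef(a, b)[0, 1] > 0.9999
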