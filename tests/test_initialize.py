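"""Metadata recovery: neighbour alignment, 3D similarity, r_k extraction, flips."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from filmrecon.errors import ValidationError
from filmrecon.initialize import (
    Similarity3DInPlane,
    detect_lr_flip,
    extract_reference_slices,
    neighbour_rigid_align,
    similarity_align_3d,
)
from filmrecon.masks import compute_brain_and_skull_masks
from filmrecon.stack import ReferenceVolume, SliceStack
from filmrecon.synth import PhantomSpec, make_phantom


@pytest.fixture(scope="module")
def head():
    vol, brain, skull = make_phantom(PhantomSpec(seed=3))
    return vol, brain, skull


def _slab_stack(vol, thickness=5):
    k = vol.shape[0] // thickness
    data = np.stack([vol[i * thickness : (i + 1) * thickness].mean(axis=0) for i in range(k)])
    return SliceStack(data, spacing=(1.0, 1.0, float(thickness)))


class TestNeighbourRigidAlign:
    def test_recovers_known_integer_shifts(self, rng):
        # identical zero-padded content placed at known integer offsets; the
        # shifts sum to zero so the centroid anchor leaves no common offset
        blob = ndimage.gaussian_filter(rng.uniform(0, 200, (20, 20)), 1.5)
        shifts = [(-2, 1), (0, 0), (3, -4), (0, 0), (-1, 3)]
        slices = []
        for (dr, dc) in shifts:
            canvas = np.zeros((48, 48))
            canvas[14 + dr : 34 + dr, 14 + dc : 34 + dc] = blob
            slices.append(canvas)
        stack = SliceStack(np.stack(slices), spacing=(1, 1, 5))
        poses = neighbour_rigid_align(stack)
        # content placed at +shift is undone by sampling at p + shift
        for pose, shift in zip(poses, shifts):
            np.testing.assert_allclose(pose.translation, shift, atol=0.5)
            assert abs(pose.rotation) < np.deg2rad(1.0)

    def test_aligned_constant_stack_is_fixed_point(self):
        stack = SliceStack(np.full((4, 16, 16), 2.0), spacing=(1, 1, 5))
        poses = neighbour_rigid_align(stack)
        for pose in poses:
            assert np.linalg.norm(pose.translation) < 1e-3
            assert abs(pose.rotation) < 1e-3

    def test_single_slice_rejected(self, rng):
        with pytest.raises(ValidationError):
            neighbour_rigid_align(SliceStack(rng.uniform(0, 1, (1, 8, 8))))

    def test_intensities_untouched(self, rng):
        stack = SliceStack(rng.uniform(0, 1, (3, 16, 16)))
        before = stack.data.copy()
        neighbour_rigid_align(stack)
        np.testing.assert_array_equal(stack.data, before)


class TestSimilarityAlign3D:
    def _masks(self, stack, reference):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, sk = compute_brain_and_skull_masks(stack, dilate_skull=False)
            _, rk = compute_brain_and_skull_masks(reference, dilate_skull=False)
        return sk, rk

    def test_identity_pair_recovers_identity(self, head):
        vol, _, _ = head
        stack = _slab_stack(vol)
        ref = ReferenceVolume(vol)
        sk, rk = self._masks(stack, ref)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = similarity_align_3d(stack, ref, sk, rk)
        assert abs(np.rad2deg(sim.rotation)) < 1.0
        assert sim.scale == pytest.approx(1.0, abs=0.02)
        # slab centres sit 2 mm above the voxel index plane
        np.testing.assert_allclose(sim.translation, [0, 0, 2.0], atol=1.0)

    def test_recovers_misstated_inplane_spacing(self, head):
        # content rendered at 0.8 mm/px while the stack claims 1.0 mm/px
        vol, _, _ = head
        stack = _slab_stack(vol)
        h, w = stack.data.shape[1:]
        c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        rr, cc = np.mgrid[0:h, 0:w].astype(float)
        zoomed = []
        for sl in stack.data:
            coords = np.stack([c[0] + 0.8 * (rr - c[0]), c[1] + 0.8 * (cc - c[1])])
            zoomed.append(ndimage.map_coordinates(sl, coords, order=1, mode="constant"))
        claimed = SliceStack(np.stack(zoomed), spacing=(1.0, 1.0, 5.0))
        ref = ReferenceVolume(vol)
        sk, rk = self._masks(claimed, ref)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = similarity_align_3d(claimed, ref, sk, rk)
        assert sim.scale == pytest.approx(0.8, rel=0.03)

    def test_recovers_10mm_translation(self, head):
        vol, _, _ = head
        stack = _slab_stack(vol)
        shifted = np.roll(vol, 10, axis=2)  # content moved +10 voxels along x
        ref = ReferenceVolume(shifted)
        sk, rk = self._masks(stack, ref)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = similarity_align_3d(stack, ref, sk, rk)
        assert sim.translation[0] == pytest.approx(10.0, abs=1.0)
        assert abs(sim.translation[1]) < 1.0

    def test_empty_mask_rejected(self, head):
        vol, _, _ = head
        stack = _slab_stack(vol)
        ref = ReferenceVolume(vol)
        from filmrecon.stack import RegionMask

        empty = RegionMask(np.zeros(stack.shape, bool), role="skull")
        good = RegionMask(np.ones(ref.shape, bool), role="skull")
        with pytest.raises(ValidationError):
            similarity_align_3d(stack, ref, empty, good)


class TestExtractReferenceSlices:
    def test_identity_transform_reproduces_reference(self, rng):
        data = rng.uniform(0, 1, (4, 16, 16))
        ref = ReferenceVolume(data, spacing=(1, 1, 5))
        stack = SliceStack(np.zeros_like(data), spacing=(1, 1, 5))
        transform = Similarity3DInPlane()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, overlap, support = extract_reference_slices(ref, stack, transform)
        np.testing.assert_allclose(r.data, data, atol=1e-10)
        assert r.n_slices == stack.n_slices
        np.testing.assert_allclose(overlap, 1.0)

    def test_out_of_fov_slices_flagged(self, rng):
        data = rng.uniform(0.5, 1, (4, 16, 16))
        ref = ReferenceVolume(data, spacing=(1, 1, 5))
        stack = SliceStack(np.zeros_like(data), spacing=(1, 1, 5))
        transform = Similarity3DInPlane(translation=np.array([0.0, 0.0, 100.0]))
        with pytest.warns(UserWarning, match="low reference overlap"):
            r, overlap, _ = extract_reference_slices(ref, stack, transform)
        assert np.all(overlap < 0.05)
        assert np.all(r.data == 0)

    def test_commutes_with_integer_reference_shift(self, rng):
        inner = rng.uniform(0, 1, (4, 10, 10))
        data = np.zeros((4, 20, 20))
        data[:, 5:15, 5:15] = inner
        ref = ReferenceVolume(data, spacing=(1, 1, 5))
        stack = SliceStack(np.zeros_like(data), spacing=(1, 1, 5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_base, _, _ = extract_reference_slices(ref, stack, Similarity3DInPlane())
            shifted_ref = ReferenceVolume(np.roll(data, 3, axis=2), spacing=(1, 1, 5))
            r_shift, _, _ = extract_reference_slices(shifted_ref, stack, Similarity3DInPlane())
        np.testing.assert_allclose(r_shift.data, np.roll(r_base.data, 3, axis=2), atol=1e-10)

    def test_from_matrix_round_trip(self):
        center = np.array([10.0, 20.0, 5.0])
        sim = Similarity3DInPlane(0.2, 1.1, np.array([1.0, -2.0, 3.0]), center)
        back = Similarity3DInPlane.from_matrix(sim.matrix(), center)
        assert back.rotation == pytest.approx(sim.rotation)
        assert back.scale == pytest.approx(sim.scale)
        np.testing.assert_allclose(back.translation, sim.translation, atol=1e-10)


class TestDetectLrFlip:
    def test_unflipped_pair_not_flipped(self, head):
        vol, _, _ = head
        stack = _slab_stack(vol)
        out, flipped = detect_lr_flip(stack, stack)
        assert not flipped
        np.testing.assert_array_equal(out.data, stack.data)

    def test_mirrored_stack_detected_and_restored(self, head):
        vol, _, _ = head
        stack = _slab_stack(vol)
        mirrored = stack.with_data(stack.data[:, :, ::-1].copy())
        out, flipped = detect_lr_flip(mirrored, stack)
        assert flipped
        np.testing.assert_array_equal(out.data, stack.data)

    def test_symmetric_constant_image_not_flipped(self):
        const = SliceStack(np.full((3, 12, 12), 1.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, flipped = detect_lr_flip(const, const)
        assert not flipped
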