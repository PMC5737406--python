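"""Robust loss, slice warping, residual terms, Jacobians and stage recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from filmrecon.errors import ValidationError
from filmrecon.register import (
    ObjectiveWeights,
    RobustLoss,
    SlicePose,
    StageProblem,
    compose_poses,
    joint_objective,
    neighbour_residuals,
    optimize_stage,
    reference_residuals,
    robust_loss,
    robust_loss_derivative,
    warp_slice,
)
from filmrecon.stack import SliceStack

finite_e = st.floats(-1e6, 1e6, allow_nan=False)
gammas = st.floats(0.0, 1e3, allow_nan=False)


class TestRobustLoss:
    def test_plug_in_values(self):
        assert robust_loss(0.0, 0.7) == 0.0
        assert robust_loss(np.sqrt(3.0), 1.0) == pytest.approx(1.0)
        assert robust_loss(-3.0, 0.0) == pytest.approx(3.0)

    @settings(max_examples=200, derandomize=True)
    @given(e=finite_e, gamma=gammas)
    def test_identities(self, e, gamma):
        v = robust_loss(e, gamma)
        assert v == pytest.approx(robust_loss(-e, gamma), rel=1e-12)  # even
        # relative slack: sqrt of ~1e12 carries float error above 1e-9 absolute
        assert v <= abs(e) * (1 + 1e-12) + 1e-9
        assert v >= abs(e) - gamma - abs(e) * 1e-12 - 1e-9
        assert v >= 0.0

    @settings(max_examples=100, derandomize=True)
    @given(e=st.floats(0.01, 1e5), gamma=gammas)
    def test_strictly_increasing_in_magnitude(self, e, gamma):
        assert robust_loss(1.05 * e, gamma) > robust_loss(e, gamma)

    def test_derivative_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        e = rng.uniform(-5, 5, 50)
        h = 1e-6
        fd = (robust_loss(e + h, 0.8) - robust_loss(e - h, 0.8)) / (2 * h)
        np.testing.assert_allclose(robust_loss_derivative(e, 0.8), fd, atol=1e-8)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValidationError):
            RobustLoss(-1.0)


class TestWarpSlice:
    def test_identity_reproduces_slice(self, rng):
        y = rng.uniform(0, 1, (16, 16))
        warped, valid = warp_slice(SlicePose.identity(), y)
        np.testing.assert_allclose(warped, y, atol=1e-12)
        assert valid.all()

    def test_unit_translation_shifts_by_one_pixel(self, rng):
        y = rng.uniform(0, 1, (16, 16))
        pose = SlicePose(translation=np.array([1.0, 0.0]))
        warped, valid = warp_slice(pose, y)
        np.testing.assert_allclose(warped[:-1, :], y[1:, :], atol=1e-12)
        assert not valid[-1, :].any()  # border row falls outside the support

    def test_scaling_constant_image(self):
        y = np.full((20, 20), 2.5)
        pose = SlicePose(matrix=2.0 * np.eye(2))
        warped, valid = warp_slice(pose, y)
        np.testing.assert_allclose(warped[valid], 2.5, atol=1e-12)

    def test_singular_matrix_rejected(self, rng):
        pose = SlicePose.identity()
        pose.matrix = np.array([[1.0, 0.0], [1.0, 0.0]])  # bypass validation
        with pytest.raises(ValidationError):
            warp_slice(pose, rng.uniform(0, 1, (8, 8)))


class TestResidualTerms:
    def test_identical_slices_zero_neighbour_term(self, rng):
        y = rng.uniform(0, 1, (12, 12))
        e, valid = neighbour_residuals(SlicePose.identity(), SlicePose.identity(), y, y)
        assert np.all(e == 0)
        assert valid.all()

    def test_gain_mismatch_constant_residual(self):
        y = np.full((10, 10), 3.0)
        pose_a = SlicePose(alpha=2.0, beta=0.0)
        e, _ = neighbour_residuals(pose_a, SlicePose.identity(), y, y)
        np.testing.assert_allclose(e, 3.0)  # 2*3 - 3

    def test_swapping_roles_negates_residuals(self, rng):
        ya, yb = rng.uniform(0, 1, (2, 12, 12))
        pa = SlicePose(alpha=1.1, beta=0.05)
        pb = SlicePose(alpha=0.9, beta=-0.02)
        e1, _ = neighbour_residuals(pa, pb, ya, yb)
        e2, _ = neighbour_residuals(pb, pa, yb, ya)
        np.testing.assert_allclose(e1, -e2, atol=1e-12)
        # the robust loss is even, so the term value is unchanged
        assert robust_loss(e1, 1.0).sum() == pytest.approx(robust_loss(e2, 1.0).sum())

    def test_reference_term_zero_when_matched(self, rng):
        y = rng.uniform(0, 1, (12, 12))
        mask = np.zeros((12, 12), bool)
        mask[3:9, 3:9] = True
        e, _ = reference_residuals(SlicePose.identity(), y, y, mask)
        np.testing.assert_allclose(e, 0.0, atol=1e-12)

    def test_offset_absorbs_constant_shift(self, rng):
        y = rng.uniform(0, 1, (12, 12))
        mask = np.ones((12, 12), bool)
        pose = SlicePose(alpha=1.0, beta=1.0)
        e, _ = reference_residuals(pose, y, y + 1.0, mask)
        np.testing.assert_allclose(e, 0.0, atol=1e-12)

    def test_zero_reference_leaves_warped_intensity(self, rng):
        y = rng.uniform(0, 1, (12, 12))
        mask = np.ones((12, 12), bool)
        pose = SlicePose(alpha=1.3, beta=0.2)
        e, valid = reference_residuals(pose, y, np.zeros_like(y), mask)
        np.testing.assert_allclose(e, (1.3 * y + 0.2)[valid], atol=1e-12)

    def test_empty_mask_rejected(self, rng):
        y = rng.uniform(0, 1, (8, 8))
        with pytest.raises(ValidationError):
            reference_residuals(SlicePose.identity(), y, y, np.zeros((8, 8), bool))


def generic_affine_params(problem):
    """Identity parameters plus small deterministic perturbations chosen so no
    warped sample lands on a bilinear cell boundary (where the interpolant's
    derivative jumps and central differences straddle the kink)."""
    import numpy as np

    x0 = problem.identity_params()
    for k in range(problem.K):
        o = k * problem.P
        if problem.stage == "rigid":
            x0[o] += 0.004 * (k - 1)
            x0[o + 1 : o + 3] += [0.3, -0.35]
        elif problem.stage == "similarity":
            x0[o] += 0.004 * (k - 1)
            x0[o + 1] += 0.003
            x0[o + 2 : o + 4] += [0.3, -0.35]
            x0[o + 4] += 0.02
            x0[o + 5] += 0.01
        else:
            x0[o : o + 4] += 0.004 * np.array([1.0, -0.7, 0.5, -0.9]) * (k + 1) / 3
            x0[o + 4 : o + 6] += [0.3, -0.35]
            x0[o + 6] += 0.02
            x0[o + 7] += 0.01
    return x0


def _small_instance(rng, K=3, size=16):
    stack = ndimage.gaussian_filter(rng.uniform(0, 200, (K, size, size)), (0, 1, 1))
    ref = ndimage.gaussian_filter(rng.uniform(0, 200, (K, size, size)), (0, 1, 1))
    skull = np.zeros((K, size, size), bool)
    skull[:, 4:12, 4:12] = True
    ref[skull] += 60.0
    return SliceStack(stack), SliceStack(ref), skull


class TestJointObjective:
    def test_zero_cost_at_prior_on_matched_constant_data(self):
        K, n = 3, 12
        const = np.full((K, n, n), 5.0)
        skull = np.ones((K, n, n), bool)
        cost, residuals, jac = joint_objective(
            [SlicePose.identity()] * K,
            SliceStack(const),
            SliceStack(const),
            skull,
            ObjectiveWeights(10.0, 1.0, 1e3),
        )
        assert cost == pytest.approx(0.0, abs=1e-12)
        assert np.all(residuals == 0)

    def test_prior_only_minimiser_is_prior(self, rng):
        stack, ref, skull = _small_instance(rng)
        weights = ObjectiveWeights(lam_r=1e-12, lam_n=1e-12, lam_p=1e4)
        poses, info = optimize_stage(stack, None, None, "similarity", weights, n_iter=30)
        for pose in poses:
            assert pose.scale == pytest.approx(1.0, abs=1e-3)
            assert pose.alpha == pytest.approx(1.0, abs=1e-3)
            assert pose.beta == pytest.approx(0.0, abs=1e-3)

    @pytest.mark.parametrize("stage", ["rigid", "similarity", "affine"])
    def test_analytic_jacobian_matches_central_differences(self, rng, stage):
        stack, ref, skull = _small_instance(rng)
        weights = ObjectiveWeights(10.0, 1.0, 1e3)
        problem = StageProblem(stack.data, ref.data, skull, stage, weights)
        x0 = generic_affine_params(problem)
        jac = problem.jacobian(x0).toarray()
        eps = 1e-6
        fd = np.zeros_like(jac)
        for m in range(x0.size):
            dp = np.zeros_like(x0)
            dp[m] = eps
            fd[:, m] = (problem.residuals(x0 + dp) - problem.residuals(x0 - dp)) / (2 * eps)
        denom = np.maximum(np.abs(fd), 1e-3)
        assert (np.abs(jac - fd) / denom).max() <= 1e-4

    def test_translation_equivariance_with_reference(self, rng):
        # shifting all poses AND the reference slices by the same integer
        # translation leaves the objective unchanged on zero-padded data
        K, n = 3, 24
        inner = ndimage.gaussian_filter(rng.uniform(0, 100, (K, n, n)), (0, 1, 1))
        stack = np.zeros((K, n + 8, n + 8))
        stack[:, 4 : 4 + n, 4 : 4 + n] = inner
        ref = np.zeros_like(stack)
        ref[:, 4 : 4 + n, 4 : 4 + n] = inner
        skull = np.zeros_like(stack, dtype=bool)
        skull[:, 8:20, 8:20] = True
        weights = ObjectiveWeights(10.0, 1.0, 0.0)
        poses0 = [SlicePose.identity()] * K
        cost0, _, _ = joint_objective(
            poses0, SliceStack(stack), SliceStack(ref), skull, ObjectiveWeights(10.0, 1.0, 1e-12)
        )
        shift = np.array([2.0, -1.0])
        poses1 = [SlicePose(translation=shift.copy()) for _ in range(K)]
        ref_shifted = np.roll(ref, (-int(shift[0]), -int(shift[1])), axis=(1, 2))
        skull_shifted = np.roll(skull, (-int(shift[0]), -int(shift[1])), axis=(1, 2))
        cost1, _, _ = joint_objective(
            poses1,
            SliceStack(stack),
            SliceStack(ref_shifted),
            skull_shifted,
            ObjectiveWeights(10.0, 1.0, 1e-12),
        )
        assert cost1 == pytest.approx(cost0, rel=1e-6)

    def test_too_few_slices_rejected(self, rng):
        with pytest.raises(ValidationError):
            StageProblem(
                rng.uniform(0, 1, (1, 8, 8)), None, None, "rigid", ObjectiveWeights(0.0, 1.0, 0.0)
            )


class TestOptimizeStage:
    def test_cost_never_increases(self, rng):
        stack, ref, skull = _small_instance(rng)
        weights = ObjectiveWeights(10.0, 1.0, 1e3)
        poses, info = optimize_stage(stack, ref, skull, "affine", weights, n_iter=10)
        assert info["cost"] <= info["initial_cost"] + 1e-9

    def test_unperturbed_stack_stays_near_identity(self, rng):
        base = ndimage.gaussian_filter(rng.uniform(0, 200, (16, 16)), 1.0)
        stack = SliceStack(np.stack([base] * 3))
        skull = np.ones((3, 16, 16), bool)
        weights = ObjectiveWeights(10.0, 1.0, 1e6)
        poses, _ = optimize_stage(
            stack, stack, skull, "similarity", weights, n_iter=10, use_moments_init=False
        )
        for pose in poses:
            assert np.linalg.norm(pose.translation) < 0.05
            assert abs(pose.rotation) < np.deg2rad(0.1)
            assert pose.scale == pytest.approx(1.0, abs=1e-3)

    def test_known_shift_recovery(self, rng):
        # one slice shifted by a known offset; reference anchors the others
        base = ndimage.gaussian_filter(rng.uniform(0, 200, (40, 40)), 1.5)
        shifted = np.roll(base, (3, -2), axis=(0, 1))
        stack = SliceStack(np.stack([base, shifted, base]))
        ref = SliceStack(np.stack([base] * 3))
        skull = np.zeros((3, 40, 40), bool)
        skull[:, 5:35, 5:35] = True
        weights = ObjectiveWeights(10.0, 1.0, 1e3)
        poses, _ = optimize_stage(stack, ref, skull, "similarity", weights, n_iter=30)
        # sampling base at p + (3, -2) undoes np.roll's content shift
        np.testing.assert_allclose(poses[1].translation, [3.0, -2.0], atol=0.3)
        np.testing.assert_allclose(poses[0].translation, [0.0, 0.0], atol=0.3)


def test_compose_and_inverse_round_trip(rng):
    a = SlicePose.from_similarity(0.3, 0.1, (2.0, -1.0), alpha=1.2, beta=0.1)
    b = SlicePose.from_similarity(-0.2, -0.05, (0.5, 3.0))
    ab = compose_poses(a, b)
    pts = rng.uniform(0, 20, (10, 2))
    center = np.array([10.0, 10.0])
    np.testing.assert_allclose(ab.apply(pts, center), a.apply(b.apply(pts, center), center))
    ident = compose_poses(a, a.inverse())
    np.testing.assert_allclose(ident.matrix, np.eye(2), atol=1e-12)
    np.testing.assert_allclose(ident.translation, 0.0, atol=1e-12)
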