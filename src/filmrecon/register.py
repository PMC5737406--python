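"""Joint per-slice 2D motion and affine intensity correction.

Each historical slice ``y_k`` carries an unknown in-plane affine distortion
(printing, manual scanning, imprecise landmark clicks) and an unknown
photometric drift.  Both are recovered at once by minimising the regularised
objective

    min_Theta  lam_R * sum_k R_k  +  lam_N * sum_{k<K} N_k  +  lam_P * P(Theta - Theta_0)

where the reference term ``R_k`` compares the warped, intensity-adjusted slice
``alpha_k * y_k(T(theta_k, .)) + beta_k`` with the oblique reference slice
``r_k`` on a neighbourhood of the skull (the structure assumed stable over
decades), the neighbour term ``N_k`` compares adjacent historical slices over
the full slice domain (coupling the per-slice estimates), and the prior ``P``
pins the in-plane scale, gain and offset near (1, 1, 0).  Every residual
passes through the smooth l1 loss ``rho_gamma(e) = sqrt(gamma^2 + e^2) - gamma``;
weighting the raw residuals by ``lam`` and applying the solver's soft-l1 loss
realises exactly ``lam * sum rho_{1/lam}(e)`` per term.

Transform complexity is staged: a per-slice similarity (rotation, uniform
scale, translation) with a strong prior first, then a full 2D affine with a
relaxed prior, both solved by trust-region least squares with an analytic
sparse Jacobian (chain rule through the bilinear interpolation gradients).

All transforms act on pixel coordinates of the slice grid, about the grid
centre: ``T(p) = A (p - c) + c + t`` with ``p = (row, col)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, sparse

from .errors import NumericalError, ValidationError
from .stack import SliceStack

STAGE_PARAMS = {"rigid": 3, "similarity": 6, "affine": 8}


# ---------------------------------------------------------------------------
# Robust loss


def robust_loss(
    e: np.ndarray | float, gamma: np.ndarray | float
) -> np.ndarray | float:
    """Smooth l1 loss ``sqrt(gamma^2 + e^2) - gamma`` (gamma=0 gives |e|)."""
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma < 0):
        raise ValidationError(f"gamma must be >= 0, got {gamma}")
    e = np.asarray(e, dtype=float)
    # the max guards against negative round-off when gamma**2 underflows
    out = np.maximum(np.sqrt(gamma**2 + e**2) - gamma, 0.0)
    return out if out.ndim else float(out)


def robust_loss_derivative(
    e: np.ndarray | float, gamma: np.ndarray | float
) -> np.ndarray | float:
    """d/de of the smooth l1 loss: ``e / sqrt(gamma^2 + e^2)``."""
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma < 0):
        raise ValidationError(f"gamma must be >= 0, got {gamma}")
    e = np.asarray(e, dtype=float)
    denom = np.sqrt(gamma**2 + e**2)
    out = np.where(denom > 0, e / np.where(denom > 0, denom, 1.0), 0.0)
    return out if out.ndim else float(out)


@dataclass
class RobustLoss:
    """Smooth l1 approximation with scale gamma (>0; 0 means absolute value)."""

    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValidationError(f"gamma must be >= 0, got {self.gamma}")

    def __call__(self, e):
        return robust_loss(e, self.gamma)

    def derivative(self, e):
        return robust_loss_derivative(e, self.gamma)


# ---------------------------------------------------------------------------
# Slice poses


def rotation_matrix(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


@dataclass
class SlicePose:
    """Joint motion + intensity parameters of one slice.

    ``matrix`` is the 2x2 linear block (orientation-preserving) and
    ``translation`` the in-plane shift in pixels of the slice grid, both acting
    about the grid centre; ``alpha``/``beta`` are the slice's intensity gain
    and offset.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))
    alpha: float = 1.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if np.linalg.det(self.matrix) <= 0:
            raise ValidationError("pose linear block must be orientation-preserving")
        if self.alpha <= 0:
            raise ValidationError(f"intensity gain must be > 0, got {self.alpha}")

    @classmethod
    def identity(cls) -> "SlicePose":
        return cls()

    @classmethod
    def from_similarity(
        cls,
        rotation: float,
        log_scale: float = 0.0,
        translation: Sequence[float] = (0.0, 0.0),
        alpha: float = 1.0,
        beta: float = 0.0,
    ) -> "SlicePose":
        return cls(
            matrix=np.exp(log_scale) * rotation_matrix(rotation),
            translation=np.asarray(translation, dtype=float),
            alpha=alpha,
            beta=beta,
        )

    @property
    def rotation(self) -> float:
        """Rotation angle of the polar decomposition of the linear block."""
        u, _, vt = np.linalg.svd(self.matrix)
        r = u @ vt
        if np.linalg.det(r) < 0:  # guard; det(matrix) > 0 keeps this unreachable
            r = u @ np.diag([1.0, -1.0]) @ vt
        return float(np.arctan2(r[1, 0], r[0, 0]))

    @property
    def scale(self) -> float:
        """Uniform scale factor, sqrt(det) of the linear block."""
        return float(np.sqrt(np.linalg.det(self.matrix)))

    def apply(self, points: np.ndarray, center: np.ndarray) -> np.ndarray:
        """Map (N, 2) pixel points through T(p) = A (p - c) + c + t."""
        return (points - center) @ self.matrix.T + center + self.translation

    def inverse(self) -> "SlicePose":
        ainv = np.linalg.inv(self.matrix)
        return SlicePose(
            matrix=ainv, translation=-ainv @ self.translation, alpha=self.alpha, beta=self.beta
        )


def compose_poses(outer: SlicePose, inner: SlicePose) -> SlicePose:
    """Motion composition (outer o inner)(p) = outer(inner(p)); intensity from outer."""
    return SlicePose(
        matrix=outer.matrix @ inner.matrix,
        translation=outer.matrix @ inner.translation + outer.translation,
        alpha=outer.alpha,
        beta=outer.beta,
    )


@dataclass
class SimilarityPose:
    """4-parameter restriction used by the first refinement stage."""

    rotation: float = 0.0
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError(f"scale must be > 0, got {self.scale}")

    def to_pose(self, alpha: float = 1.0, beta: float = 0.0) -> SlicePose:
        return SlicePose.from_similarity(
            self.rotation, np.log(self.scale), self.translation, alpha, beta
        )


@dataclass
class ObjectiveWeights:
    """Term weights of the joint objective; gamma per term is 1/lambda_term."""

    lam_r: float = 10.0
    lam_n: float = 1.0
    lam_p: float = 1e6

    def __post_init__(self) -> None:
        if min(self.lam_r, self.lam_n, self.lam_p) < 0:
            raise ValidationError("weights must be >= 0")
        if self.lam_r == 0 and self.lam_n == 0:
            raise ValidationError("at least one of lam_r, lam_n must be > 0")


# ---------------------------------------------------------------------------
# Bilinear sampling with exact gradients


def sample_bilinear(img: np.ndarray, rows: np.ndarray, cols: np.ndarray):
    """Sample ``img`` at fractional (rows, cols) with the interpolant's gradient.

    Returns (values, d/drow, d/dcol, valid); samples outside the support
    [0, H-1] x [0, W-1] are invalid and zero-filled.
    """
    h, w = img.shape
    valid = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    r = np.clip(rows, 0, h - 1)
    c = np.clip(cols, 0, w - 1)
    r0 = np.minimum(np.floor(r).astype(int), h - 2)
    c0 = np.minimum(np.floor(c).astype(int), w - 2)
    fr = r - r0
    fc = c - c0
    i00 = img[r0, c0]
    i01 = img[r0, c0 + 1]
    i10 = img[r0 + 1, c0]
    i11 = img[r0 + 1, c0 + 1]
    top = i00 + fc * (i01 - i00)
    bot = i10 + fc * (i11 - i10)
    val = top + fr * (bot - top)
    drow = bot - top
    dcol = (i01 - i00) + fr * ((i11 - i10) - (i01 - i00))
    val = np.where(valid, val, 0.0)
    drow = np.where(valid, drow, 0.0)
    dcol = np.where(valid, dcol, 0.0)
    return val, drow, dcol, valid


def warp_slice(
    pose: SlicePose, y: np.ndarray, domain: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Warp a slice: sample ``y`` at T(theta, p) for every grid point p.

    Returns (warped, valid): out-of-support samples are flagged invalid (and
    zero-filled for display), not silently zero-weighted into residuals.
    ``domain`` optionally restricts the evaluated pixel set (others invalid).
    """
    y = np.asarray(y, dtype=float)
    if abs(np.linalg.det(pose.matrix)) < 1e-12:
        raise ValidationError("singular affine in warp_slice")
    h, w = y.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rr, cc = np.mgrid[0:h, 0:w]
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    q = pose.apply(pts, center)
    val, _, _, valid = sample_bilinear(y, q[:, 0], q[:, 1])
    warped = val.reshape(h, w)
    valid = valid.reshape(h, w)
    if domain is not None:
        valid = valid & np.asarray(domain, dtype=bool)
        warped = np.where(valid, warped, 0.0)
    return warped, valid


def warp_stack(stack: SliceStack, poses: Sequence[SlicePose], intensity: bool = False) -> SliceStack:
    """Resample every slice through its pose; optionally apply gain/offset."""
    out = np.empty_like(stack.data)
    for k, pose in enumerate(poses):
        warped, valid = warp_slice(pose, stack.data[k])
        if intensity:
            warped = np.where(valid, np.maximum(pose.alpha * warped + pose.beta, 0.0), 0.0)
        out[k] = warped
    return stack.with_data(out)


# ---------------------------------------------------------------------------
# Residual terms (per-pair / per-slice views used by tests and diagnostics)


def neighbour_residuals(
    pose_k: SlicePose,
    pose_k1: SlicePose,
    y_k: np.ndarray,
    y_k1: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals of the neighbour term N_k over the joint validity domain.

    e(p) = [a_k y_k(T_k p) + b_k] - [a_{k+1} y_{k+1}(T_{k+1} p) + b_{k+1}].
    Returns (residual vector, joint validity mask).
    """
    if y_k.shape != y_k1.shape:
        raise ValidationError("neighbouring slices must be congruent")
    wk, vk = warp_slice(pose_k, y_k)
    wk1, vk1 = warp_slice(pose_k1, y_k1)
    valid = vk & vk1
    if not valid.any():
        warnings.warn("empty joint validity domain in neighbour term", stacklevel=2)
        return np.zeros(0), valid
    e = (pose_k.alpha * wk + pose_k.beta) - (pose_k1.alpha * wk1 + pose_k1.beta)
    return e[valid], valid


def reference_residuals(
    pose: SlicePose,
    y: np.ndarray,
    r: np.ndarray,
    skull_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals of the reference term R_k on the skull neighbourhood.

    e(p) = a y(T p) + b - r(p) over valid skull pixels.
    """
    skull_mask = np.asarray(skull_mask, dtype=bool)
    if not skull_mask.any():
        raise ValidationError("empty skull mask in reference term")
    w, valid = warp_slice(pose, y, domain=skull_mask)
    e = pose.alpha * w + pose.beta - np.asarray(r, dtype=float)
    return e[valid], valid


# ---------------------------------------------------------------------------
# The staged joint problem


class StageProblem:
    """Residual/Jacobian machinery of the joint objective for one stage.

    Parameterisation per slice: rigid (rotation, t_row, t_col) with intensity
    fixed; similarity (rotation, log-scale, t_row, t_col, alpha, beta); affine
    (a11, a12, a21, a22, t_row, t_col, alpha, beta).  Residual layout:
    reference rows per slice (skull pixels), neighbour rows per adjacent pair
    (full slice domain), prior rows.  Invalid (out-of-support) samples give
    structurally zero residual and Jacobian rows; costs are not renormalised
    by the valid-pixel count.
    """

    def __init__(
        self,
        stack_data: np.ndarray,
        ref_slices: np.ndarray | None,
        skull_masks: np.ndarray | None,
        stage: str,
        weights: ObjectiveWeights,
        loss: str = "soft_l1",
        min_ref_overlap: float = 0.05,
    ) -> None:
        if stage not in STAGE_PARAMS:
            raise ValidationError(f"unknown stage '{stage}'")
        self.stack = np.asarray(stack_data, dtype=float)
        self.K, self.H, self.W = self.stack.shape
        if self.K < 2:
            raise ValidationError(f"need at least 2 slices, got {self.K}")
        self.stage = stage
        self.P = STAGE_PARAMS[stage]
        self.weights = weights
        self.loss = loss
        self.center = np.array([(self.H - 1) / 2.0, (self.W - 1) / 2.0])
        rr, cc = np.mgrid[0 : self.H, 0 : self.W]
        self.grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        self.grid_centered = self.grid - self.center
        self.n_pix = self.H * self.W

        self.use_ref = ref_slices is not None and weights.lam_r > 0
        if self.use_ref:
            self.ref = np.asarray(ref_slices, dtype=float)
            if skull_masks is None:
                raise ValidationError("reference term requires skull masks")
            self.skull = np.asarray(skull_masks, dtype=bool)
            if self.ref.shape != self.stack.shape or self.skull.shape != self.stack.shape:
                raise ValidationError("stack, reference slices and masks must be congruent")
            self.skull_idx = [np.flatnonzero(self.skull[k].ravel()) for k in range(self.K)]
            self.ref_enabled = []
            for k in range(self.K):
                idx = self.skull_idx[k]
                overlap = (
                    np.count_nonzero(self.ref[k].ravel()[idx]) / idx.size if idx.size else 0.0
                )
                enabled = overlap >= min_ref_overlap
                if not enabled:
                    warnings.warn(
                        f"slice {k}: reference/skull overlap {overlap:.1%} < "
                        f"{min_ref_overlap:.0%}; falling back to neighbour term only",
                        stacklevel=2,
                    )
                self.ref_enabled.append(enabled)
            if not any(self.ref_enabled) and weights.lam_n == 0:
                raise ValidationError("no slice has a usable reference term")
        else:
            self.ref = None
            self.skull_idx = [np.zeros(0, dtype=int)] * self.K
            self.ref_enabled = [False] * self.K

        self.use_prior = stage != "rigid" and weights.lam_p > 0
        self.n_prior_per_slice = 3 if self.use_prior else 0  # log-scale, alpha, beta

        # residual layout offsets
        self.ref_rows = [idx.size if en else 0 for idx, en in zip(self.skull_idx, self.ref_enabled)]
        self.n_ref = sum(self.ref_rows)
        self.n_neigh = (self.K - 1) * self.n_pix if weights.lam_n > 0 else 0
        self.n_res = self.n_ref + self.n_neigh + self.K * self.n_prior_per_slice
        self._cache_key: bytes | None = None
        self._cache: tuple[np.ndarray, sparse.csr_matrix] | None = None

    # -- parameter packing ---------------------------------------------------

    def identity_params(self) -> np.ndarray:
        return self.params_from_poses([SlicePose.identity()] * self.K)

    def params_from_poses(self, poses: Sequence[SlicePose]) -> np.ndarray:
        x = np.zeros(self.K * self.P)
        for k, pose in enumerate(poses):
            o = k * self.P
            if self.stage == "rigid":
                x[o : o + 3] = [pose.rotation, *pose.translation]
            elif self.stage == "similarity":
                x[o : o + 6] = [
                    pose.rotation,
                    np.log(pose.scale),
                    *pose.translation,
                    pose.alpha,
                    pose.beta,
                ]
            else:
                x[o : o + 8] = [*pose.matrix.ravel(), *pose.translation, pose.alpha, pose.beta]
        return x

    def pose_from_params(self, x: np.ndarray, k: int) -> SlicePose:
        o = k * self.P
        if self.stage == "rigid":
            return SlicePose.from_similarity(x[o], 0.0, x[o + 1 : o + 3])
        if self.stage == "similarity":
            return SlicePose.from_similarity(
                x[o], x[o + 1], x[o + 2 : o + 4], max(x[o + 4], 1e-6), x[o + 5]
            )
        return SlicePose(
            matrix=x[o : o + 4].reshape(2, 2),
            translation=x[o + 4 : o + 6],
            alpha=max(x[o + 6], 1e-6),
            beta=x[o + 7],
        )

    def poses_from_params(
        self, x: np.ndarray, fallback: np.ndarray | None = None
    ) -> list[SlicePose]:
        """Poses per slice; a slice whose solution degenerated (e.g. an
        orientation-flipping matrix on a slice with no data term) falls back
        to its value in ``fallback`` with a warning."""
        poses = []
        for k in range(self.K):
            try:
                poses.append(self.pose_from_params(x, k))
            except ValidationError as exc:
                if fallback is None:
                    raise
                warnings.warn(
                    f"slice {k}: degenerate optimised pose ({exc}); keeping its "
                    "initialisation",
                    stacklevel=2,
                )
                poses.append(self.pose_from_params(fallback, k))
        return poses

    def x_scale(self) -> np.ndarray:
        """Characteristic parameter scales for the trust-region solver."""
        if self.stage == "rigid":
            per = [0.05, 2.0, 2.0]
        elif self.stage == "similarity":
            per = [0.05, 0.05, 2.0, 2.0, 0.1, 0.1]
        else:
            per = [0.05, 0.05, 0.05, 0.05, 2.0, 2.0, 0.1, 0.1]
        return np.tile(per, self.K)

    # -- per-slice warp with parameter derivatives ----------------------------

    def _slice_terms(self, x: np.ndarray, k: int):
        """Warped values, validity and d(warped)/d(motion params) for slice k."""
        o = k * self.P
        pc = self.grid_centered
        if self.stage == "rigid":
            rot = x[o]
            a = rotation_matrix(rot)
            dA = [np.array([[-np.sin(rot), -np.cos(rot)], [np.cos(rot), -np.sin(rot)]])]
            n_motion = 3
        elif self.stage == "similarity":
            rot, logs = x[o], x[o + 1]
            r = rotation_matrix(rot)
            a = np.exp(logs) * r
            dr = np.array([[-np.sin(rot), -np.cos(rot)], [np.cos(rot), -np.sin(rot)]])
            dA = [np.exp(logs) * dr, a]  # d/drot, d/dlogs
            n_motion = 4
        else:
            a = x[o : o + 4].reshape(2, 2)
            dA = [
                np.array([[1.0, 0.0], [0.0, 0.0]]),
                np.array([[0.0, 1.0], [0.0, 0.0]]),
                np.array([[0.0, 0.0], [1.0, 0.0]]),
                np.array([[0.0, 0.0], [0.0, 1.0]]),
            ]
            n_motion = 6
        t = x[o + n_motion - 2 : o + n_motion]
        q = pc @ a.T + self.center + t
        val, drow, dcol, valid = sample_bilinear(self.stack[k], q[:, 0], q[:, 1])

        # d(val)/d(param) = grad_val . d(q)/d(param)
        dval = np.empty((self.n_pix, self.P))
        for m, da in enumerate(dA):
            dq = pc @ da.T
            dval[:, m] = drow * dq[:, 0] + dcol * dq[:, 1]
        dval[:, n_motion - 2] = drow
        dval[:, n_motion - 1] = dcol
        if self.stage == "rigid":
            alpha, beta = 1.0, 0.0
        else:
            alpha, beta = x[o + self.P - 2], x[o + self.P - 1]
            dval[:, self.P - 2] = 0.0  # handled separately (dval is motion-only there)
            dval[:, self.P - 1] = 0.0
        return val, dval, valid, alpha, beta

    # -- residuals and Jacobian ----------------------------------------------

    def _evaluate(self, x: np.ndarray) -> tuple[np.ndarray, sparse.csr_matrix]:
        key = np.asarray(x, dtype=float).tobytes()
        if key == self._cache_key and self._cache is not None:
            return self._cache
        x = np.asarray(x, dtype=float)
        w = self.weights
        vals, dvals, valids, alphas, betas = [], [], [], [], []
        for k in range(self.K):
            v, dv, vd, al, be = self._slice_terms(x, k)
            vals.append(v)
            dvals.append(dv)
            valids.append(vd)
            alphas.append(al)
            betas.append(be)

        f = np.zeros(self.n_res)
        rows_list, cols_list, data_list = [], [], []
        n_int = 0 if self.stage == "rigid" else 2  # trailing intensity params

        def add_block(row0, rows_local, k, dcoef, alpha_col=None, beta_col=None):
            # dcoef: (n, P_motion-only) scaled derivative block for slice k
            n = rows_local.size
            nm = self.P - n_int
            rows_list.append(np.repeat(row0 + np.arange(n), nm))
            cols_list.append(np.tile(k * self.P + np.arange(nm), n))
            data_list.append(dcoef[:, :nm].ravel())
            if n_int:
                if alpha_col is not None:
                    rows_list.append(row0 + np.arange(n))
                    cols_list.append(np.full(n, k * self.P + self.P - 2))
                    data_list.append(alpha_col)
                if beta_col is not None:
                    rows_list.append(row0 + np.arange(n))
                    cols_list.append(np.full(n, k * self.P + self.P - 1))
                    data_list.append(beta_col)

        row = 0
        # reference terms
        for k in range(self.K):
            n = self.ref_rows[k]
            if n == 0:
                continue
            idx = self.skull_idx[k]
            vk = valids[k][idx]
            e = alphas[k] * vals[k][idx] + betas[k] - self.ref[k].ravel()[idx]
            e = np.where(vk, e, 0.0)
            f[row : row + n] = w.lam_r * e
            coef = w.lam_r * alphas[k] * dvals[k][idx] * vk[:, None]
            add_block(
                row,
                np.arange(n),
                k,
                coef,
                alpha_col=w.lam_r * vals[k][idx] * vk,
                beta_col=w.lam_r * np.ones(n) * vk,
            )
            row += n

        # neighbour terms
        if self.n_neigh:
            for k in range(self.K - 1):
                joint = valids[k] & valids[k + 1]
                e = (alphas[k] * vals[k] + betas[k]) - (alphas[k + 1] * vals[k + 1] + betas[k + 1])
                e = np.where(joint, e, 0.0)
                f[row : row + self.n_pix] = w.lam_n * e
                jn = joint.astype(float)
                coef_k = w.lam_n * alphas[k] * dvals[k] * jn[:, None]
                coef_k1 = -w.lam_n * alphas[k + 1] * dvals[k + 1] * jn[:, None]
                add_block(
                    row,
                    np.arange(self.n_pix),
                    k,
                    coef_k,
                    alpha_col=w.lam_n * vals[k] * jn,
                    beta_col=w.lam_n * jn,
                )
                add_block(
                    row,
                    np.arange(self.n_pix),
                    k + 1,
                    coef_k1,
                    alpha_col=-w.lam_n * vals[k + 1] * jn,
                    beta_col=-w.lam_n * jn,
                )
                row += self.n_pix

        # prior rows: in-plane log-scale, alpha - 1, beta - 0
        if self.use_prior:
            for k in range(self.K):
                o = k * self.P
                if self.stage == "similarity":
                    f[row] = w.lam_p * x[o + 1]
                    rows_list.append(np.array([row]))
                    cols_list.append(np.array([o + 1]))
                    data_list.append(np.array([w.lam_p]))
                else:
                    a = x[o : o + 4].reshape(2, 2)
                    det = np.linalg.det(a)
                    ddet = np.array([a[1, 1], -a[1, 0], -a[0, 1], a[0, 0]])
                    # log-scale prior 0.5*log(det); below det=eps, extrapolate
                    # linearly so trial points with collapsing determinant are
                    # penalised smoothly instead of erroring out
                    eps = 1e-2
                    if det >= eps:
                        f[row] = w.lam_p * 0.5 * np.log(det)
                        dlogdet = 0.5 * ddet / det
                    else:
                        f[row] = w.lam_p * 0.5 * (np.log(eps) + (det - eps) / eps)
                        dlogdet = 0.5 * ddet / eps
                    rows_list.append(np.full(4, row))
                    cols_list.append(o + np.arange(4))
                    data_list.append(w.lam_p * dlogdet)
                f[row + 1] = w.lam_p * (x[o + self.P - 2] - 1.0)
                f[row + 2] = w.lam_p * x[o + self.P - 1]
                rows_list.append(np.array([row + 1, row + 2]))
                cols_list.append(np.array([o + self.P - 2, o + self.P - 1]))
                data_list.append(np.array([w.lam_p, w.lam_p]))
                row += 3

        if not np.all(np.isfinite(f)):
            bad = np.flatnonzero(~np.isfinite(f))[0]
            raise NumericalError(f"non-finite residual at row {bad}")
        jac = sparse.csr_matrix(
            (np.concatenate(data_list), (np.concatenate(rows_list), np.concatenate(cols_list))),
            shape=(self.n_res, self.K * self.P),
        )
        self._cache_key = key
        self._cache = (f, jac)
        return self._cache

    def residuals(self, x: np.ndarray) -> np.ndarray:
        return self._evaluate(x)[0]

    def jacobian(self, x: np.ndarray) -> sparse.csr_matrix:
        return self._evaluate(x)[1]

    def cost(self, x: np.ndarray) -> float:
        f = self.residuals(x)
        if self.loss == "linear":
            return float(0.5 * np.sum(f**2))
        return float(np.sum(np.sqrt(1.0 + f**2) - 1.0))


def joint_objective(
    poses: Sequence[SlicePose],
    stack: SliceStack,
    ref_slices: SliceStack | None,
    skull_masks: np.ndarray | None,
    weights: ObjectiveWeights,
    stage: str = "affine",
    loss: str = "soft_l1",
) -> tuple[float, np.ndarray, sparse.csr_matrix]:
    """Cost, stacked residuals and analytic sparse Jacobian of the joint objective."""
    problem = StageProblem(
        stack.data,
        ref_slices.data if ref_slices is not None else None,
        skull_masks,
        stage,
        weights,
        loss=loss,
    )
    x = problem.params_from_poses(poses)
    f, jac = problem._evaluate(x)
    return problem.cost(x), f, jac


# ---------------------------------------------------------------------------
# Moments-based initialisation


def _intensity_moments(img: np.ndarray, mask: np.ndarray | None = None):
    w = np.clip(np.asarray(img, dtype=float), 0, None)
    if mask is not None:
        w = w * mask
    total = w.sum()
    if total <= 0:
        return None
    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    mu = np.array([(w * rr).sum(), (w * cc).sum()]) / total
    dr, dc = rr - mu[0], cc - mu[1]
    cov = (
        np.array(
            [[(w * dr * dr).sum(), (w * dr * dc).sum()], [(w * dr * dc).sum(), (w * dc * dc).sum()]]
        )
        / total
    )
    return mu, cov


def _principal_angle(cov: np.ndarray) -> float:
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]
    return float(np.arctan2(v[1], v[0]))


def moments_init_pose(
    y: np.ndarray, r: np.ndarray, skull_mask: np.ndarray | None = None
) -> SlicePose:
    """Rigid pose aligning the intensity moments of y to those of r.

    Centroids are matched exactly; the rotation is the principal-axis angle
    difference, wrapped so the smaller rotation magnitude is chosen (axes are
    unoriented), and skipped for nearly isotropic second moments.
    """
    my = _intensity_moments(y, skull_mask)
    mr = _intensity_moments(r, skull_mask)
    if my is None or mr is None:
        return SlicePose.identity()
    mu_y, cov_y = my
    mu_r, cov_r = mr
    rot = 0.0
    ey = np.linalg.eigvalsh(cov_y)
    er = np.linalg.eigvalsh(cov_r)
    if ey[-1] > 1.1 * ey[0] and er[-1] > 1.1 * er[0]:
        delta = _principal_angle(cov_y) - _principal_angle(cov_r)
        delta = (delta + np.pi / 2) % np.pi - np.pi / 2  # smallest |angle| mod pi
        rot = delta
    h, w = y.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    a = rotation_matrix(rot)
    t = mu_y - center - a @ (mu_r - center)
    return SlicePose(matrix=a, translation=t)


def rotation_sweep_init(
    stack_data: np.ndarray,
    ref_data: np.ndarray,
    smooth_sigma: float = 1.5,
    max_rot_deg: float = 7.0,
    step_deg: float = 1.0,
) -> list[SlicePose]:
    """Per-slice initial poses: centroid-moment translation + coarse rotation sweep.

    The translation matches intensity centroids; the rotation is the NCC
    -maximising angle of a coarse sweep on in-plane-smoothed slices.  Pure
    second-moment (principal-axis) rotation estimates are unreliable on
    near-elliptical brain slices, while a +-``max_rot_deg`` sweep lands inside
    the capture range of the trust-region refinement.
    """
    from scipy import ndimage

    if smooth_sigma > 0:
        smc = ndimage.gaussian_filter(stack_data, (0, smooth_sigma, smooth_sigma))
        smr = ndimage.gaussian_filter(ref_data, (0, smooth_sigma, smooth_sigma))
    else:
        smc, smr = stack_data, ref_data
    poses = []
    for k in range(stack_data.shape[0]):
        base = moments_init_pose(smc[k], smr[k], None)
        best_rot, best_ncc = 0.0, -2.0
        for rot_deg in np.arange(-max_rot_deg, max_rot_deg + step_deg / 2, step_deg):
            pose = SlicePose.from_similarity(np.deg2rad(rot_deg), 0.0, base.translation)
            warped, valid = warp_slice(pose, smc[k])
            if valid.sum() < 100:
                continue
            a, b = warped[valid], smr[k][valid]
            if a.std() == 0 or b.std() == 0:
                continue
            ncc = float(np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std()))
            if ncc > best_ncc:
                best_rot, best_ncc = float(rot_deg), ncc
        poses.append(SlicePose.from_similarity(np.deg2rad(best_rot), 0.0, base.translation))
    return poses


# ---------------------------------------------------------------------------
# Stage optimisation


def optimize_stage(
    stack: SliceStack,
    ref_slices: SliceStack | None,
    skull_masks: np.ndarray | None,
    stage: str,
    weights: ObjectiveWeights,
    n_iter: int | None = None,
    init_poses: Sequence[SlicePose] | None = None,
    loss: str = "soft_l1",
    use_moments_init: bool = True,
    ftol: float = 1e-6,
) -> tuple[list[SlicePose], dict]:
    """Optimise one transformation-complexity stage of the joint objective.

    The similarity stage (4 motion + 2 intensity parameters per slice,
    lam_p = 1e6, 10 iterations) is run from both the identity and a
    moments-of-skull-masked-slices initialisation, keeping the lower-cost
    result; the affine stage (6 + 2 parameters, lam_p = 1e3, 20 iterations)
    starts from the similarity result.  The trust-region solver only accepts
    cost-decreasing steps, so the final cost never exceeds the initial one.
    """
    if n_iter is None:
        n_iter = {"rigid": 10, "similarity": 10, "affine": 20}[stage]
    problem = StageProblem(
        stack.data,
        ref_slices.data if ref_slices is not None else None,
        skull_masks,
        stage,
        weights,
        loss=loss,
    )

    starts: list[np.ndarray] = []
    if init_poses is not None:
        starts.append(problem.params_from_poses(init_poses))
    else:
        starts.append(problem.identity_params())
    if stage == "similarity" and use_moments_init and ref_slices is not None:
        poses_m = rotation_sweep_init(stack.data, ref_slices.data)
        starts.append(problem.params_from_poses(poses_m))

    best = None
    for x0 in starts:
        init_cost = problem.cost(x0)
        res = optimize.least_squares(
            problem.residuals,
            x0,
            jac=problem.jacobian,
            method="trf",
            loss=loss,
            f_scale=1.0,
            max_nfev=n_iter,
            x_scale=problem.x_scale(),
            tr_solver="lsmr",
            ftol=ftol,
            xtol=1e-10,
            gtol=1e-10,
        )
        final_cost = problem.cost(res.x)
        if final_cost > init_cost * (1 + 1e-9):
            warnings.warn(
                f"stage '{stage}': cost increased ({init_cost:.4g} -> {final_cost:.4g}); "
                "returning initialisation",
                stacklevel=2,
            )
            cand = (init_cost, x0, x0)
        else:
            cand = (final_cost, res.x, x0)
        if best is None or cand[0] < best[0]:
            best = cand

    info = {
        "stage": stage,
        "cost": best[0],
        "initial_cost": problem.cost(starts[0]),
        "n_starts": len(starts),
    }
    return problem.poses_from_params(best[1], fallback=best[2]), info
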