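"""Recovery of provisional spatial metadata for the naive film stack.

Four steps turn landmark-order crops into a stack that can be compared with
the later reference volume:

1. :func:`neighbour_rigid_align` — per-slice in-plane rigid alignment driven
   purely by the inter-slice similarity term, to undo landmark-click scatter;
2. :func:`similarity_align_3d` — a 5-parameter in-plane 3D similarity
   (rotation about the slice normal, uniform in-plane scale, 3D translation)
   maximising normalised cross-correlation between the skull masks' image
   content, recovering the lost in-plane pixel spacing;
3. :func:`extract_reference_slices` — the reference volume resampled through
   that transform onto the stack grid, producing the oblique reference slices
   r_k;
4. :func:`detect_lr_flip` — scanned films are sometimes mirrored; the flip is
   detected by comparing masked NCC of the stack and its left-right mirror
   against the resampled reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
import numpy as np
from scipy import ndimage, optimize

from .errors import ValidationError
from .register import (
    ObjectiveWeights,
    SlicePose,
    StageProblem,
    _intensity_moments,
    _principal_angle,
    rotation_matrix,
)
from .stack import RegionMask, ReferenceVolume, SliceStack, resample_to_grid


# ---------------------------------------------------------------------------
# Neighbour-regularised rigid alignment


def neighbour_rigid_align(
    stack: SliceStack, n_iter: int = 10
) -> list[SlicePose]:
    """Per-slice in-plane rigid alignment from the inter-slice term alone.

    Minimises the sum of neighbour terms over per-slice (rotation, 2
    translations) with intensity parameters fixed at (1, 0) and plain
    least-squares residuals, initialised by matching each slice's intensity
    centroid to the stack-mean centroid.  Returns the transforms; the stack
    data is not resampled here.
    """
    if stack.n_slices < 2:
        raise ValidationError(f"need at least 2 slices, got {stack.n_slices}")
    weights = ObjectiveWeights(lam_r=0.0, lam_n=1.0, lam_p=0.0)
    problem = StageProblem(stack.data, None, None, "rigid", weights, loss="linear")

    centroids = []
    for k in range(stack.n_slices):
        m_k = _intensity_moments(stack.data[k])
        centroids.append(m_k[0] if m_k is not None else None)
    known = [c for c in centroids if c is not None]
    anchor = np.mean(known, axis=0) if known else np.zeros(2)
    poses = [
        SlicePose.from_similarity(0.0, 0.0, (c - anchor) if c is not None else np.zeros(2))
        for c in centroids
    ]
    x0 = problem.params_from_poses(poses)
    res = optimize.least_squares(
        problem.residuals,
        x0,
        jac=problem.jacobian,
        method="trf",
        loss="linear",
        max_nfev=n_iter,
        x_scale=problem.x_scale(),
        tr_solver="lsmr",
        ftol=1e-6,
        xtol=1e-10,
        gtol=1e-10,
    )
    x_best = res.x if problem.cost(res.x) <= problem.cost(x0) else x0
    return problem.poses_from_params(x_best)


# ---------------------------------------------------------------------------
# In-plane 3D similarity alignment to the reference


@dataclass
class Similarity3DInPlane:
    """Rotation about the slice normal, uniform in-plane scale, 3D translation.

    Acts on world coordinates about ``center`` (mm):
    ``G(p) = Rz(rotation) @ diag(scale, scale, 1) @ (p - center) + center + translation``.
    ``G`` maps stack-world points into reference-world points; the recovered
    ``scale`` is the factor by which the stack's provisional in-plane spacing
    must be multiplied.
    """

    rotation: float = 0.0
    scale: float = 1.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError(f"scale must be > 0, got {self.scale}")
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    def matrix(self) -> np.ndarray:
        rz = np.eye(3)
        rz[:2, :2] = rotation_matrix(self.rotation)
        lin = rz @ np.diag([self.scale, self.scale, 1.0])
        m = np.eye(4)
        m[:3, :3] = lin
        m[:3, 3] = self.center + self.translation - lin @ self.center
        return m

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, center: np.ndarray) -> "Similarity3DInPlane":
        """Recover (rotation, scale, translation) about ``center`` from a 4x4 map.

        The matrix must be an in-plane similarity (rotation about z, uniform
        in-plane scale, translation) — e.g. a composition of two such maps.
        """
        lin = np.asarray(matrix, dtype=float)[:3, :3]
        rot = float(np.arctan2(lin[1, 0], lin[0, 0]))
        scale = float(np.hypot(lin[0, 0], lin[1, 0]))
        center = np.asarray(center, dtype=float)
        t = (np.asarray(matrix) @ np.append(center, 1.0))[:3] - center
        return cls(rotation=rot, scale=scale, translation=t, center=center)


def _world_coords(volume: SliceStack | ReferenceVolume, mask: np.ndarray) -> np.ndarray:
    """World coordinates (N, 3) of masked voxels."""
    kk, ii, jj = np.nonzero(mask)
    sr, sc, sz = volume.spacing
    local = np.column_stack([jj * sc, ii * sr, kk * sz])
    return local @ volume.direction.T + np.asarray(volume.origin)


def _masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    x = a[mask]
    y = b[mask]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0 or x.size < 2:
        return -np.inf
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def _downsample_inplane(stack: SliceStack, mask: np.ndarray, factor: int):
    """Gaussian-smooth and decimate in-plane by ``factor`` (origin preserved)."""
    if factor == 1:
        return stack, mask
    data = ndimage.gaussian_filter(stack.data, sigma=(0, factor / 2.0, factor / 2.0))
    data = data[:, ::factor, ::factor]
    m = mask[:, ::factor, ::factor]
    sr, sc, sz = stack.spacing
    return (
        replace(stack, data=data, spacing=(sr * factor, sc * factor, sz)),
        m,
    )


def _central_band(pts: np.ndarray, frac: float = 0.3) -> np.ndarray:
    """Mask points whose z lies within ``frac`` of the z-extent around the centroid."""
    z = pts[:, 2]
    mid = z.mean()
    half = max(frac * (z.max() - z.min()), 1e-6)
    return np.abs(z - mid) <= half


def similarity_align_3d(
    stack: SliceStack,
    reference: ReferenceVolume,
    stack_skull: RegionMask,
    ref_skull: RegionMask,
    levels: int = 3,
    max_iter: int = 30,
    min_step: float = 1e-3,
    initial_step: float = 1.0,
    optimize_scale: bool = True,
    smooth_sigma: float = 1.0,
) -> Similarity3DInPlane:
    """Align the whole stack with the reference by an in-plane 3D similarity.

    Maximises NCC between the two skull masks (as in-plane-smoothed mask
    images, over their union support) over rotation about the slice normal, a
    uniform in-plane scale and 3D translation.  Initialised from the 3D mask
    moments — centroids for translation, central-band in-plane radii for the
    scale (the band avoids the bias from the reference's apex/base skull caps,
    which the thick-slice stack does not resolve), principal axes for the
    rotation; optimised by regular-step gradient ascent (finite-difference
    gradient, step halving on failure, stop at ``min_step``) over a
    coarse-to-fine in-plane pyramid.  Only NCC-improving steps are accepted,
    so the final NCC is never below the initial one.
    """
    if not stack_skull.data.any() or not ref_skull.data.any():
        raise ValidationError("empty skull mask")

    # --- moments initialisation -------------------------------------------
    pts_s = _world_coords(stack, stack_skull.data)
    pts_r = _world_coords(reference, ref_skull.data)
    mu_s, mu_r = pts_s.mean(axis=0), pts_r.mean(axis=0)
    band_s = pts_s[_central_band(pts_s)]
    band_r = pts_r[_central_band(pts_r)]
    if optimize_scale:
        rad_s = np.linalg.norm(band_s[:, :2] - band_s[:, :2].mean(axis=0), axis=1)
        rad_r = np.linalg.norm(band_r[:, :2] - band_r[:, :2].mean(axis=0), axis=1)
        scale0 = float(np.percentile(rad_r, 95) / max(np.percentile(rad_s, 95), 1e-6))
    else:
        scale0 = 1.0
    rot0 = 0.0
    cov_s = np.cov(band_s[:, :2].T)
    cov_r = np.cov(band_r[:, :2].T)
    es, er = np.linalg.eigvalsh(cov_s), np.linalg.eigvalsh(cov_r)
    if es[-1] > 1.1 * es[0] and er[-1] > 1.1 * er[0]:
        delta = _principal_angle(cov_r) - _principal_angle(cov_s)
        rot0 = (delta + np.pi / 2) % np.pi - np.pi / 2

    # rotation/scale centre: world position of the stack's grid centre
    nk, ni, nj = stack.shape
    sr, sc, sz = stack.spacing
    local_c = np.array([(nj - 1) / 2.0 * sc, (ni - 1) / 2.0 * sr, (nk - 1) / 2.0 * sz])
    center = stack.direction @ local_c + np.asarray(stack.origin)
    rz0 = np.eye(3)
    rz0[:2, :2] = rotation_matrix(rot0)
    lin0 = rz0 @ np.diag([scale0, scale0, 1.0])
    t0 = mu_r - (lin0 @ (mu_s - center) + center)

    # parameter vector z = (rot, log-scale, tx, ty, tz) in natural step units
    scales = np.array([0.02, 0.02, 1.0, 1.0, 1.0])
    z = np.array([rot0, np.log(scale0), *t0])

    def transform_of(zv: np.ndarray) -> Similarity3DInPlane:
        return Similarity3DInPlane(
            rotation=zv[0], scale=float(np.exp(zv[1])), translation=zv[2:5], center=center
        )

    # fixed image: the stack's skull mask smoothed in-plane; moving image: the
    # reference's, resampled per candidate transform
    mask_stack = replace(
        stack,
        data=ndimage.gaussian_filter(
            stack_skull.data.astype(float), sigma=(0, smooth_sigma, smooth_sigma)
        ),
    )
    mask_ref = ReferenceVolume(
        ndimage.gaussian_filter(ref_skull.data.astype(float), sigma=smooth_sigma),
        spacing=reference.spacing,
        origin=reference.origin,
        direction=reference.direction,
    )

    def make_objective(level_stack: SliceStack):
        def ncc_of(zv: np.ndarray) -> float:
            res = resample_to_grid(mask_ref, level_stack, transform_of(zv).matrix())
            support = (level_stack.data > 0.01) | (res.data > 0.01)
            if not support.any():
                return -np.inf
            return _masked_ncc(level_stack.data, res.data, support)

        return ncc_of

    free = np.array([True, optimize_scale, True, True, True])
    improved_any = False
    for level in range(levels - 1, -1, -1):
        level_stack, _ = _downsample_inplane(mask_stack, stack_skull.data, 2**level)
        ncc_of = make_objective(level_stack)
        current = ncc_of(z)
        step = initial_step
        for _ in range(max_iter):
            # central finite-difference gradient in scaled units
            grad = np.zeros(5)
            for m in range(5):
                if not free[m]:
                    continue
                dz = np.zeros(5)
                dz[m] = 0.25 * scales[m]
                grad[m] = (ncc_of(z + dz) - ncc_of(z - dz)) / (2 * dz[m] / scales[m])
            gnorm = np.linalg.norm(grad)
            if gnorm == 0:
                break
            direction = grad / gnorm
            moved = False
            while step >= min_step:
                cand = z + step * direction * scales
                val = ncc_of(cand)
                if val > current:
                    z, current = cand, val
                    moved = True
                    improved_any = True
                    break
                step *= 0.5
            if not moved:
                break
        # reset the step for the next (finer) level
    if not improved_any:
        warnings.warn(
            "similarity_align_3d: no NCC-improving step found; returning the "
            "moments initialisation",
            stacklevel=2,
        )
    return transform_of(z)


def apply_scale_to_stack(stack: SliceStack, transform: Similarity3DInPlane) -> SliceStack:
    """Rescale the stack's provisional in-plane spacing by the recovered factor."""
    sr, sc, sz = stack.spacing
    return replace(stack, spacing=(sr * transform.scale, sc * transform.scale, sz))


# ---------------------------------------------------------------------------
# Oblique reference slices


def extract_reference_slices(
    reference: ReferenceVolume,
    aligned_stack: SliceStack,
    transform: Similarity3DInPlane,
    low_overlap_threshold: float = 0.05,
    slab_average: int | None = None,
) -> tuple[SliceStack, np.ndarray]:
    """Resample the reference through the similarity transform onto the stack grid.

    Slice k of the result is the oblique reference slice r_k, congruent with
    y_k's pixel grid.  The historical slices are thick-slab averages, so by
    default each r_k is the through-plane mean of ``slab_average`` reference
    planes spread over the slice thickness (a box through-plane PSF) rather
    than a single centre-plane sample — on curved structures such as the
    skull dome a centre-plane sample systematically misstates the ring
    radius.  ``slab_average`` defaults to slice-thickness / reference
    z-spacing.  Also returns the per-slice in-FOV overlap fraction; slices
    below ``low_overlap_threshold`` are flagged with a warning (their
    reference term is later dropped by the joint registration).
    """
    thickness = aligned_stack.spacing[2]
    if slab_average is None:
        slab_average = max(1, int(round(thickness / reference.spacing[2])))

    def _slab_resample(src: ReferenceVolume) -> np.ndarray:
        acc = np.zeros(aligned_stack.shape)
        for i in range(slab_average):
            dz = (i - (slab_average - 1) / 2.0) * thickness / slab_average
            shift = np.eye(4)
            shift[2, 3] = dz
            acc += resample_to_grid(
                src, aligned_stack, transform.matrix() @ shift, "linear"
            ).data
        return acc / slab_average

    support_src = ReferenceVolume(
        np.ones(reference.shape),
        spacing=reference.spacing,
        origin=reference.origin,
        direction=reference.direction,
    )
    support_data = _slab_resample(support_src)
    # normalise by the in-FOV fraction so slabs straddling the reference FOV
    # edge are not dimmed by out-of-volume zeros; pixels with no support stay 0
    raw = _slab_resample(reference)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(support_data > 0.2, raw / np.maximum(support_data, 0.2), 0.0)
    r = aligned_stack.with_data(norm)
    overlap = (support_data > 0.5).mean(axis=(1, 2))
    low = np.flatnonzero(overlap < low_overlap_threshold)
    if low.size:
        warnings.warn(f"low reference overlap for slices {low.tolist()}", stacklevel=2)
    return r, overlap, support_data


# ---------------------------------------------------------------------------
# Left-right flip detection


def detect_lr_flip(
    stack: SliceStack,
    reference_resampled: SliceStack,
    margin: float = 0.02,
    mask: np.ndarray | None = None,
) -> tuple[SliceStack, bool]:
    """Mirror the stack left-right iff the mirrored stack matches the reference better.

    Compares masked NCC of the stack vs. the resampled reference with the NCC
    of the left-right-mirrored stack; the mirror must win by more than
    ``margin`` (default 0.02) so near-symmetric content is never flipped on
    noise.  Degenerate overlap returns the stack unchanged with a warning.
    """
    if stack.shape != reference_resampled.shape:
        raise ValidationError("stack and resampled reference must be congruent")
    if mask is None:
        mask = reference_resampled.data > 0
    if not mask.any():
        warnings.warn("degenerate overlap in flip detection; assuming no flip", stacklevel=2)
        return stack, False
    ncc_direct = _masked_ncc(stack.data, reference_resampled.data, mask)
    mirrored = stack.data[:, :, ::-1]
    ncc_mirror = _masked_ncc(mirrored, reference_resampled.data, mask)
    if not np.isfinite(ncc_direct) or not np.isfinite(ncc_mirror):
        warnings.warn("constant image in flip detection; assuming no flip", stacklevel=2)
        return stack, False
    if ncc_mirror > ncc_direct + margin:
        return stack.with_data(mirrored.copy()), True
    return stack, False
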