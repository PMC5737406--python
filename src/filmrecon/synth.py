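"""Synthetic phantom, film renderer and ground-truth records.

Every pipeline stage is testable without clinical data: a nested-ellipsoid
head phantom (bright skull ring, two-level brain tissue, dark ventricles,
bright lesions placed asymmetrically) is sliced into thick slabs, each slab is
perturbed by a known in-plane affine motion and linear intensity distortion,
blurred, noised and composited onto film canvases, and a "later" reference
volume is derived by radially shrinking the brain compartment while leaving
the skull untouched — emulating atrophy over the years between acquisitions.

Intensities live in [0, 1] (film optical density scale): background 0,
cerebrospinal fluid ~0.2, white matter ~0.45, grey matter ~0.6, lesions
~0.85, skull 1.0.  The ground-truth record stores, per rendered slice, the
exact effective affine (including the integer landmark jitter actually
applied), the intensity gain/offset, the sharp pre-blur slices and the
brain/skull label masks — enough to score every stage without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .films import FilmSheet, LandmarkSidecar
from .stack import ReferenceVolume, SliceStack


@dataclass
class PhantomSpec:
    """Geometry and intensities of the head phantom (voxel units/mm)."""

    shape: tuple[int, int, int] = (75, 96, 96)  # (z, y, x), 1 mm isotropic
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (row, col, z) mm
    # the head extends beyond the acquired FOV along z (historical axial
    # acquisitions covered the mid-head; the vertex is typically cut off), so
    # the z semi-axis deliberately exceeds the grid: every slice then shows a
    # substantial skull ring, as on real films
    skull_outer_semiaxes: tuple[float, float, float] = (60.0, 42.0, 36.0)  # (z, y, x)
    skull_thickness: float = 3.0
    skull_intensity: float = 1.0
    gray_intensity: float = 0.60
    white_intensity: float = 0.45
    csf_intensity: float = 0.20
    lesion_count: int = 3
    lesion_radius: float = 3.0
    lesion_intensity: float = 0.85
    # smooth intra-brain intensity texture emulating gyral/sulcal pattern and
    # tissue inhomogeneity; without it slices are nearly rotationally
    # featureless, which no real PD acquisition is
    texture_amplitude: float = 0.08
    texture_scale_vox: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.skull_outer_semiaxes) <= 0 or self.skull_thickness <= 0:
            raise ValidationError("degenerate skull geometry")
        if not (self.skull_intensity > self.gray_intensity > 0):
            raise ValidationError("skull intensity must exceed tissue intensities > 0")


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(float)
    az, ay, ax = semiaxes
    cz, cy, cx = center
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the head phantom; returns (volume, brain labels, skull labels).

    The skull is a bright ellipsoidal shell; inside it, a grey-matter rim
    surrounds a white-matter core with two dark ventricles and optional
    hyperintense lesions whose placement is deliberately left-right
    asymmetric (so mirror detection has signal).  Labels are exact.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    center = tuple((s - 1) / 2.0 for s in shape)
    az, ay, ax = spec.skull_outer_semiaxes
    th = spec.skull_thickness

    outer = _ellipsoid(shape, center, (az, ay, ax))
    inner = _ellipsoid(shape, center, (az - th, ay - th, ax - th))
    skull = outer & ~inner
    brain = inner

    vol = np.zeros(shape)
    vol[skull] = spec.skull_intensity
    vol[brain] = spec.gray_intensity
    white = _ellipsoid(
        shape, center, (0.72 * (az - th), 0.72 * (ay - th), 0.72 * (ax - th))
    )
    vol[brain & white] = spec.white_intensity
    # two ventricles, slightly anterior, symmetric about the midline
    cz, cy, cx = center
    for dx in (-0.18 * ax, 0.18 * ax):
        vent = _ellipsoid(shape, (cz, cy - 0.10 * ay, cx + dx), (0.30 * az, 0.22 * ay, 0.08 * ax))
        vol[brain & vent] = spec.csf_intensity

    # lesions in white matter; the first is planted off-midline to guarantee
    # left-right asymmetry, the rest are random
    lesion_centers = []
    if spec.lesion_count > 0:
        lesion_centers.append((cz + 0.15 * az, cy + 0.2 * ay, cx - 0.35 * ax))
        for _ in range(spec.lesion_count - 1):
            u = rng.uniform(-0.5, 0.5, size=3)
            lesion_centers.append((cz + u[0] * az, cy + u[1] * ay, cx + u[2] * ax))
    for lc in lesion_centers:
        les = _ellipsoid(shape, lc, (spec.lesion_radius,) * 3)
        vol[brain & les & ~_near(skull, les)] = spec.lesion_intensity

    if spec.texture_amplitude > 0:
        tex = ndimage.gaussian_filter(
            rng.standard_normal(shape), sigma=spec.texture_scale_vox
        )
        tex /= max(tex.std(), 1e-12)
        textured = vol + spec.texture_amplitude * tex
        # texture only inside the brain, keep intensities in (0, skull)
        vol[brain] = np.clip(
            textured[brain], 0.05, spec.skull_intensity - 0.05
        )

    return vol, brain, skull


def _near(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Voxels of b adjacent to a (keeps lesions off the skull)."""
    return b & ndimage.binary_dilation(a, iterations=2)


def make_reference(
    phantom: np.ndarray,
    brain_label: np.ndarray,
    skull_label: np.ndarray,
    atrophy_factor: float = 0.95,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    csf_intensity: float = 0.20,
    z_fov_crop_top: int = 8,
) -> ReferenceVolume:
    """Derive the later reference: brain radially shrunk, skull untouched.

    The brain compartment is shrunk by ``atrophy_factor`` about its centroid;
    vacated space fills with CSF intensity.  Full NIfTI-style metadata is
    attached.  ``atrophy_factor`` = 1 reproduces the phantom intensities
    exactly.

    By default the reference's axial coverage stops ``z_fov_crop_top`` planes
    short of the top of the historical FOV: longitudinal scans rarely share
    their coverage exactly, and border slices of the historical stack then
    have little or no reference overlap — the regime where only the
    inter-slice term anchors them.  Set ``z_fov_crop_top=0`` for matching
    coverage.
    """
    if not 0 < atrophy_factor <= 1:
        raise ValidationError(f"atrophy factor must be in (0, 1], got {atrophy_factor}")
    if not 0 <= z_fov_crop_top < phantom.shape[0]:
        raise ValidationError(f"z_fov_crop_top out of range: {z_fov_crop_top}")
    out = phantom.copy()
    if atrophy_factor < 1:
        centroid = np.array(ndimage.center_of_mass(brain_label))
        # brain-only source image (non-brain voxels read as CSF when sampled)
        src = np.where(brain_label, phantom, csf_intensity)
        zz, yy, xx = np.mgrid[0 : phantom.shape[0], 0 : phantom.shape[1], 0 : phantom.shape[2]]
        coords = np.stack([zz, yy, xx]).astype(float)
        coords = centroid[:, None, None, None] + (coords - centroid[:, None, None, None]) / atrophy_factor
        shrunk = ndimage.map_coordinates(src, coords, order=1, mode="nearest")
        out[brain_label] = shrunk[brain_label]
        out[skull_label] = phantom[skull_label]
    if z_fov_crop_top:
        out = out[: out.shape[0] - z_fov_crop_top]
    return ReferenceVolume(data=out, spacing=spacing, origin=origin)


@dataclass
class FilmRenderSpec:
    """Per-slice perturbation ranges and film compositing parameters.

    Defaults are the package's standard study conditions: rotation U(-5, 5)
    degrees, translation U(-4, 4) px, scale U(0.95, 1.05), no shear, gain
    U(0.8, 1.2), offset U(-0.05, 0.05), blur variance 0.25 px^2, additive
    Gaussian noise (sd 0.02) clipped at 0, film-base pedestal 0.06, landmark
    jitter up to 2 px.
    """

    slice_thickness_vox: int = 5
    rotation_deg: float = 5.0
    translation_px: float = 4.0
    scale_range: tuple[float, float] = (0.95, 1.05)
    shear: float = 0.0
    gain_range: tuple[float, float] = (0.8, 1.2)
    offset_range: tuple[float, float] = (-0.05, 0.05)
    blur_sigma2: float = 0.25
    noise_std: float = 0.02
    pedestal: float = 0.06
    layout: tuple[int, int] = (4, 4)  # slices per sheet (rows, cols)
    margin_px: int = 8
    landmark_jitter_px: int = 2
    seed: int = 0


@dataclass
class GroundTruthRecord:
    """Everything needed to score the pipeline on synthetic films."""

    poses: list  # per-slice effective true affine: (matrix 2x2, translation 2) px
    gains: np.ndarray
    offsets: np.ndarray
    inplane_spacing_mm: float
    slice_thickness_mm: float
    sharp_stack: SliceStack  # thick slabs before distortion/blur/noise
    brain_mask: np.ndarray  # (K, H, W) slab-majority brain labels
    skull_mask: np.ndarray
    window_anchors: list  # (row, col) canvas position of each pasted slice


def _warp_affine_2d(img: np.ndarray, matrix: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Sample img at T(p) = M (p - c) + c + t (bilinear, zero outside)."""
    h, w = img.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center + translation - matrix @ center
    return ndimage.affine_transform(
        img, matrix, offset=offset, order=1, mode="constant", cval=0.0, prefilter=False
    )


def _gaussian_blur_2d(img: np.ndarray, sigma2: float) -> np.ndarray:
    if sigma2 <= 0:
        return img
    from .tv import BlurOperator

    return BlurOperator(sigma2).apply(img)


def render_films(
    phantom: np.ndarray,
    brain_label: np.ndarray,
    skull_label: np.ndarray,
    spec: FilmRenderSpec,
    inplane_spacing_mm: float = 1.0,
) -> tuple[list[FilmSheet], LandmarkSidecar, GroundTruthRecord]:
    """Render the phantom as perturbed thick slices composited onto film sheets.

    Thick-slice formation is the intra-slab mean (box through-plane PSF).
    Each slab is warped by a per-slice true affine drawn from the spec ranges,
    intensity-distorted by (gain, offset), blurred in-plane, pasted onto a
    film canvas (row-major), then the whole canvas receives the film-base
    pedestal and additive noise clipped at 0.  Landmarks are the paste anchors
    jittered by up to ``landmark_jitter_px`` integer pixels, emulating
    imprecise manual clicks; the jitter is folded into the recorded true
    affine so the ground truth stays exact.
    """
    rng = np.random.default_rng(spec.seed)
    nz, h, w = phantom.shape
    tvox = spec.slice_thickness_vox
    n_slices = nz // tvox
    rows, cols = spec.layout
    per_sheet = rows * cols
    n_sheets = int(np.ceil(n_slices / per_sheet))
    if n_slices < 1:
        raise ValidationError("phantom too thin for a single slice")
    if per_sheet < 1:
        raise ValidationError("film layout holds no slices")

    sharp = np.stack([phantom[k * tvox : (k + 1) * tvox].mean(axis=0) for k in range(n_slices)])
    brain_k = np.stack(
        [brain_label[k * tvox : (k + 1) * tvox].mean(axis=0) > 0.5 for k in range(n_slices)]
    )
    skull_k = np.stack(
        [skull_label[k * tvox : (k + 1) * tvox].mean(axis=0) > 0.5 for k in range(n_slices)]
    )

    canvas_h = rows * h + (rows + 1) * spec.margin_px
    canvas_w = cols * w + (cols + 1) * spec.margin_px
    sheets = []
    landmarks_by_film: dict[str, list[tuple[float, float]]] = {}
    poses, gains, offsets, anchors = [], [], [], []

    lo_s, hi_s = spec.scale_range
    for s_idx in range(n_sheets):
        canvas = np.zeros((canvas_h, canvas_w))
        fid = f"film{s_idx}"
        landmarks_by_film[fid] = []
        for slot in range(per_sheet):
            k = s_idx * per_sheet + slot
            if k >= n_slices:
                break
            rot = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg))
            t = rng.uniform(-spec.translation_px, spec.translation_px, size=2)
            scale = np.exp(rng.uniform(np.log(lo_s), np.log(hi_s))) if hi_s > lo_s else lo_s
            shear = rng.uniform(-spec.shear, spec.shear) if spec.shear > 0 else 0.0
            gain = rng.uniform(*spec.gain_range)
            offset = rng.uniform(*spec.offset_range)

            c, s = np.cos(rot), np.sin(rot)
            m = scale * np.array([[c, -s], [s, c]]) @ np.array([[1.0, shear], [0.0, 1.0]])
            distorted = gain * _warp_affine_2d(sharp[k], m, t) + offset
            distorted = _gaussian_blur_2d(distorted, spec.blur_sigma2)

            r_slot, c_slot = divmod(slot, cols)
            r0 = spec.margin_px + r_slot * (h + spec.margin_px)
            c0 = spec.margin_px + c_slot * (w + spec.margin_px)
            canvas[r0 : r0 + h, c0 : c0 + w] = distorted

            jit = (
                rng.integers(-spec.landmark_jitter_px, spec.landmark_jitter_px + 1, size=2)
                if spec.landmark_jitter_px > 0
                else np.zeros(2, dtype=int)
            )
            landmarks_by_film[fid].append((float(r0 + jit[0]), float(c0 + jit[1])))
            # crop starts at anchor + jitter, so x(p) = y(p + jit):
            # effective true affine is M, t + M @ jit
            poses.append((m, t + m @ jit.astype(float)))
            gains.append(gain)
            offsets.append(offset)
            anchors.append((r0, c0))
        canvas = canvas + spec.pedestal
        if spec.noise_std > 0:
            canvas = canvas + rng.normal(0.0, spec.noise_std, size=canvas.shape)
        canvas = np.clip(canvas, 0.0, None)
        sheets.append(FilmSheet(pixels=canvas, film_id=fid, film_index=s_idx))

    thickness_mm = tvox * 1.0  # phantom z spacing is 1 mm
    sidecar = LandmarkSidecar(
        films=landmarks_by_film,
        window_offset=(0, 0),
        window_size=(h, w),
        slice_thickness_mm=thickness_mm,
    )
    gt = GroundTruthRecord(
        poses=poses,
        gains=np.array(gains),
        offsets=np.array(offsets),
        inplane_spacing_mm=inplane_spacing_mm,
        slice_thickness_mm=thickness_mm,
        sharp_stack=SliceStack(
            data=sharp, spacing=(inplane_spacing_mm, inplane_spacing_mm, thickness_mm)
        ),
        brain_mask=brain_k,
        skull_mask=skull_k,
        window_anchors=anchors,
    )
    return sheets, sidecar, gt


def save_films(sheets: list[FilmSheet], directory: str | Path) -> list[Path]:
    """Write film sheets as 16-bit grayscale PNGs (intensities scaled to [0, 65535])."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for sheet in sheets:
        arr = np.clip(sheet.pixels, 0, None)
        peak = arr.max() if arr.max() > 0 else 1.0
        img = Image.fromarray(np.round(arr / peak * 65535).astype(np.uint16))
        p = directory / f"{sheet.film_id}.png"
        img.save(p)
        paths.append(p)
    return paths
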