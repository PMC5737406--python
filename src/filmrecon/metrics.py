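"""Masked image-similarity metrics and the boundary edge-motion surrogate.

Reconstruction variants are compared against ground truth over a brain mask
with MSE, NCC (Pearson), SSIM and PSNR, plus a slice-wise symmetric
boundary-distance measure standing in for SIENA-style edge motion (mean
in-plane displacement between the brain-mask boundaries of two
segmentations).  The surrogate captures the same notion — how far the brain
edge moved — but is not SIENA and is not numerically comparable with it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .errors import ValidationError
from .stack import RegionMask, SliceStack

PSNR_IDENTICAL = float("inf")


@dataclass
class MetricReport:
    """Per-variant metric values; variants keep their pipeline short-hands."""

    rows: dict[str, dict[str, float]] = field(default_factory=dict)

    def add(self, variant: str, **metrics: float) -> None:
        self.rows.setdefault(variant, {}).update(metrics)

    def to_json(self) -> dict:
        return {v: dict(m) for v, m in self.rows.items()}

    def to_csv(self, path) -> None:
        import csv

        names = sorted({name for m in self.rows.values() for name in m})
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["variant", *names])
            for variant, m in self.rows.items():
                writer.writerow([variant, *[m.get(n, "") for n in names]])


def masked_metrics(
    a: SliceStack | np.ndarray,
    b: SliceStack | np.ndarray,
    mask: RegionMask | np.ndarray,
) -> tuple[float, float, float, float]:
    """(MSE, NCC, SSIM, PSNR) of ``a`` against reference ``b`` over ``mask``.

    MSE and NCC are symmetric; SSIM and the PSNR/SSIM dynamic range take the
    second argument as the reference (L = max(b) - min(b)).  SSIM uses a
    Gaussian window (11 taps, sigma 1.5) per slice, averaged over the mask.
    Identical inputs report PSNR = +inf.
    """
    a = a.data if isinstance(a, SliceStack) else np.asarray(a, dtype=float)
    b = b.data if isinstance(b, SliceStack) else np.asarray(b, dtype=float)
    m = mask.data if isinstance(mask, RegionMask) else np.asarray(mask, dtype=bool)
    if a.shape != b.shape or m.shape != a.shape:
        raise ValidationError("volumes and mask must be congruent")
    if not m.any():
        raise ValidationError("empty metric mask")

    diff = a[m] - b[m]
    mse = float(np.mean(diff**2))

    xa, xb = a[m], b[m]
    if xa.std() == 0 or xb.std() == 0:
        raise ValidationError("constant image under mask: NCC undefined")
    ncc = float(np.mean((xa - xa.mean()) * (xb - xb.mean())) / (xa.std() * xb.std()))

    data_range = float(np.ptp(b))
    if data_range == 0:
        raise ValidationError("reference has zero dynamic range")
    ssim_vals = []
    weights = []
    for k in range(a.shape[0]):
        if not m[k].any():
            continue
        _, smap = structural_similarity(
            a[k],
            b[k],
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            data_range=data_range,
            full=True,
        )
        ssim_vals.append(smap[m[k]].sum())
        weights.append(m[k].sum())
    ssim = float(np.sum(ssim_vals) / np.sum(weights))

    psnr = PSNR_IDENTICAL if mse == 0 else float(10.0 * np.log10(data_range**2 / mse))
    return mse, ncc, ssim, psnr


def _boundary(mask2d: np.ndarray) -> np.ndarray:
    """Inner boundary: mask pixels with a background 4-neighbour."""
    er = ndimage.binary_erosion(mask2d, structure=ndimage.generate_binary_structure(2, 1))
    return mask2d & ~er


def edge_motion_surrogate(
    mask_a: RegionMask | np.ndarray, mask_b: RegionMask | np.ndarray
) -> float:
    """Mean symmetric in-plane distance between slice-wise mask boundaries.

    For each slice where both masks have a boundary, averages the distance
    -transform values of one boundary sampled on the other (both directions),
    then averages over slices.  Identical masks give 0; a uniform 1-px
    dilation gives about 1.
    """
    a = mask_a.data if isinstance(mask_a, RegionMask) else np.asarray(mask_a, dtype=bool)
    b = mask_b.data if isinstance(mask_b, RegionMask) else np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("masks must be congruent")
    if not a.any() or not b.any():
        raise ValidationError("empty mask in edge-motion surrogate")
    per_slice = []
    for k in range(a.shape[0]):
        ba, bb = _boundary(a[k]), _boundary(b[k])
        if not ba.any() or not bb.any():
            continue
        dist_to_b = ndimage.distance_transform_edt(~bb)
        dist_to_a = ndimage.distance_transform_edt(~ba)
        d_ab = dist_to_b[ba].mean()
        d_ba = dist_to_a[bb].mean()
        per_slice.append(0.5 * (d_ab + d_ba))
    if not per_slice:
        raise ValidationError("no slice has boundaries in both masks")
    return float(np.mean(per_slice))


def rigid_prealign(
    a: SliceStack,
    b: SliceStack,
    mask: np.ndarray | None = None,
    levels: int = 2,
    max_iter: int = 20,
) -> SliceStack:
    """Rigidly align volume ``a`` to ``b`` by masked-NCC maximisation.

    Multi-resolution in-plane rotation + 3D translation (no scale), applied
    before metric computation; returns ``a`` resampled onto ``b``'s grid.
    Already-aligned inputs come back (numerically) unchanged; on degenerate
    overlap the identity is used with a warning.
    """
    from skimage.filters import threshold_otsu

    from .initialize import _masked_ncc, similarity_align_3d
    from .stack import ReferenceVolume, resample_to_grid

    def _foreground(data: np.ndarray) -> np.ndarray:
        # Otsu foreground; scans carry a noise/pedestal floor, so ``> 0`` is
        # not a usable support mask
        if np.ptp(data) == 0:
            return np.zeros(data.shape, dtype=bool)
        return data > threshold_otsu(data)

    fg_a = _foreground(a.data)
    fg_b = _foreground(b.data)
    if mask is None:
        mask = fg_b
    if not mask.any() or not fg_a.any():
        warnings.warn("degenerate overlap in rigid_prealign; returning input", stacklevel=2)
        return a
    src = ReferenceVolume(a.data, spacing=a.spacing, origin=a.origin, direction=a.direction)
    identity_res = resample_to_grid(src, b)
    ncc0 = _masked_ncc(identity_res.data, b.data, mask)
    try:
        transform = similarity_align_3d(
            b,
            src,
            RegionMask(fg_b, role="skull"),
            RegionMask(fg_a, role="skull"),
            levels=levels,
            max_iter=max_iter,
            optimize_scale=False,
        )
    except ValidationError:
        warnings.warn("rigid_prealign diverged; returning unaligned input", stacklevel=2)
        return identity_res
    aligned = resample_to_grid(src, b, transform.matrix())
    if _masked_ncc(aligned.data, b.data, mask) >= ncc0:
        return aligned
    return identity_res
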