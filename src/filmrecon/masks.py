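"""Brain / skull mask surrogate built from thresholds and morphology.

The registration anchors on the skull — the structure assumed most stable over
decades — so both the historical stack and the later reference need a brain
mask and a surrounding skull mask.  A dedicated brain-extraction tool can be
plugged in via the ``brain_extractor`` hook; the built-in surrogate is a
two-level Otsu-style segmentation: the first threshold separates head
foreground from background, a second threshold within the foreground separates
the bright skull ring from brain tissue.  The brain mask is the hole-filled,
largest connected component of the non-skull foreground after one in-plane
erosion; the skull mask is the remaining foreground, optionally dilated
in-plane to absorb geometric discontinuities across thick slices.

All morphology is applied slice-wise (in-plane): the stacks are a handful of
5 mm slices, and 3D structuring elements would eat the top and bottom slices.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ValidationError
from .stack import RegionMask, ReferenceVolume, SliceStack


def _inplane_binary(op, mask: np.ndarray, radius: int) -> np.ndarray:
    """Apply a 2D disc-structured binary operation to every slice."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    selem = (yy**2 + xx**2) <= radius**2
    out = np.empty_like(mask)
    for k in range(mask.shape[0]):
        out[k] = op(mask[k], structure=selem)
    return out


def _bright_class_threshold(values: np.ndarray, n_iter: int = 30) -> float:
    """Boundary between the brightest and middle of three 1D Lloyd classes.

    Class centres start at the 10/50/95% quantiles and iterate on a 512-bin
    histogram; the returned threshold is the midpoint of the top two final
    centres.  Degenerate histograms (fewer than three distinct levels) return
    max(values), i.e. an empty bright class.
    """
    if np.unique(values).size < 3:
        return float(values.max())
    counts, edges = np.histogram(values, bins=512)
    centers_bin = 0.5 * (edges[:-1] + edges[1:])
    mu = np.quantile(values, [0.10, 0.50, 0.95])
    for _ in range(n_iter):
        bounds = 0.5 * (mu[:-1] + mu[1:])
        labels = np.digitize(centers_bin, bounds)
        new_mu = mu.copy()
        for c in range(3):
            sel = labels == c
            w = counts[sel]
            if w.sum() > 0:
                new_mu[c] = np.average(centers_bin[sel], weights=w)
        if np.allclose(new_mu, mu):
            mu = new_mu
            break
        mu = np.sort(new_mu)
    return float(0.5 * (mu[1] + mu[2]))


def compute_brain_and_skull_masks(
    volume: SliceStack | ReferenceVolume,
    dilate_skull: bool = True,
    dilation_radius: int = 2,
    brain_extractor: Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[RegionMask, RegionMask]:
    """Segment a head volume into a brain mask and a surrounding skull mask.

    Parameters
    ----------
    volume:
        Stack or reference volume with non-constant intensities.
    dilate_skull:
        If set, the skull mask is dilated in-plane by ``dilation_radius``
        voxels; the dilated mask is a superset of the undilated one.
    brain_extractor:
        Optional replacement for the built-in surrogate: a callable mapping the
        intensity array to a boolean brain mask of the same shape.
    """
    data = volume.data
    if np.ptp(data) == 0:
        raise ValidationError("cannot segment a constant image: no threshold exists")

    # Thresholds are computed per slice: historical films carry strong
    # slice-to-slice illumination differences (per-slice gain/offset), so a
    # pooled histogram mixes the classes.  Per slice: stage 1 separates head
    # foreground from film background (Otsu); stage 2 separates the bright
    # skull ring from brain tissue by a three-class Lloyd split of the
    # foreground intensities (tissue has two dominant modes, skull a third);
    # the split is histogram-based and seeded at foreground quantiles, which
    # stays well-defined on spiky discrete histograms where a binned
    # multi-Otsu threshold can land on either side of a mode.
    foreground = np.zeros(data.shape, dtype=bool)
    bright = np.zeros(data.shape, dtype=bool)
    for k in range(data.shape[0]):
        sl = data[k]
        if np.ptp(sl) == 0:
            continue
        t_fg = threshold_otsu(sl)
        fg = sl > t_fg
        if fg.mean() < 0.02 or fg.all():  # background-only or degenerate slice
            continue
        foreground[k] = fg
        bright[k] = sl > _bright_class_threshold(sl[fg])
    if not foreground.any():
        raise ValidationError("degenerate foreground segmentation")

    if brain_extractor is not None:
        brain = np.asarray(brain_extractor(data)).astype(bool)
        if brain.shape != data.shape:
            raise ValidationError("brain_extractor returned a mask of wrong shape")
    else:
        # bright also catches hyperintense lesions; the hole fill re-claims
        # them.  Per slice, keep only the largest non-bright component (the
        # tissue disc) first: blur smears the ring into a faint outer halo
        # which would otherwise enclose the ring and let the fill absorb it.
        brain0 = foreground & ~bright
        slices = []
        for sl in brain0:
            lab, n = ndimage.label(sl)
            if n > 1:
                sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, n + 1))
                sl = lab == (1 + int(np.argmax(sizes)))
            slices.append(ndimage.binary_fill_holes(sl))
        brain = np.stack(slices)
        labels, n = ndimage.label(brain)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
            brain = labels == (1 + int(np.argmax(sizes)))
        brain = _inplane_binary(ndimage.binary_erosion, brain, 1)

    skull = foreground & ~brain
    if dilate_skull:
        skull = _inplane_binary(ndimage.binary_dilation, skull, dilation_radius)
    return RegionMask(brain, role="brain"), RegionMask(skull, role="skull")
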