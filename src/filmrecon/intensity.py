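"""Global intensity correction of the historical stack.

Scanned films carry a background pedestal (film base plus scanner noise) and
arbitrary photometric scaling.  Two global steps bring the stack onto the
reference volume's intensity scale before any per-slice correction:

1. background capping: subtract the global q-quantile (default 20%) of all
   pooled stack intensities and clip at zero;
2. a single linear map ``i -> a*i + b`` fitted by least squares against the
   resampled reference over a foreground mask, uniform across slices.

Residual per-slice photometric drift is left to the per-slice gain/offset
(alpha_k, beta_k) of the joint registration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .stack import RegionMask, SliceStack


@dataclass
class GlobalIntensityModel:
    """Background percentile threshold plus one global gain/offset."""

    q: float = 0.20
    threshold: float = 0.0
    gain: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.q < 1:
            raise ValidationError(f"percentile level must be in [0, 1), got {self.q}")
        if self.gain <= 0:
            raise ValidationError(f"gain must be > 0, got {self.gain}")

    def apply(self, stack: SliceStack) -> SliceStack:
        """Apply cap and linear map: i -> max(a * max(i - q%, 0) + b, 0)."""
        capped = np.maximum(stack.data - self.threshold, 0.0)
        return stack.with_data(np.maximum(self.gain * capped + self.offset, 0.0))


def cap_background(stack: SliceStack, q: float = 0.20) -> tuple[SliceStack, float]:
    """Subtract the pooled q-quantile from every intensity and clip at zero.

    The quantile is the linear-interpolation quantile of all stack intensities
    pooled across slices.  Returns the capped stack and the threshold used.
    """
    if not 0 <= q < 1:
        raise ValidationError(f"percentile level must be in [0, 1), got {q}")
    if stack.data.size == 0:
        raise ValidationError("empty stack")
    threshold = float(np.quantile(stack.data, q))
    return stack.with_data(np.maximum(stack.data - threshold, 0.0)), threshold


def fit_global_linear(
    capped: SliceStack,
    reference: SliceStack,
    mask: RegionMask,
    q: float = 0.20,
    threshold: float = 0.0,
) -> GlobalIntensityModel:
    """Least-squares fit of reference ~ a * stack + b over masked voxels.

    One (a, b) pair for the whole stack.  Degenerate fits (zero stack variance
    under the mask) fall back to the identity with a warning; a non-positive
    fitted gain is clipped to a small positive value.
    """
    if capped.shape != reference.shape or mask.data.shape != capped.shape:
        raise ValidationError("stack, reference and mask must be congruent")
    m = mask.data
    n_nonzero_ref = int(np.count_nonzero(reference.data[m]))
    if n_nonzero_ref < 100:
        raise ValidationError(
            f"mask covers only {n_nonzero_ref} voxels with nonzero reference (need >= 100)"
        )
    x = capped.data[m].ravel()
    y = reference.data[m].ravel()
    if np.ptp(x) == 0:
        warnings.warn(
            "stack is constant under the fit mask; falling back to identity "
            "intensity model",
            stacklevel=2,
        )
        return GlobalIntensityModel(q=q, threshold=threshold, gain=1.0, offset=0.0)
    design = np.column_stack([x, np.ones_like(x)])
    (a, b), *_ = np.linalg.lstsq(design, y, rcond=None)
    if a <= 0:
        warnings.warn(f"fitted gain {a:.3g} <= 0; clipping", stacklevel=2)
        a = 1e-6
    return GlobalIntensityModel(q=q, threshold=threshold, gain=float(a), offset=float(b))


def apply_intensity_model(stack: SliceStack, model: GlobalIntensityModel) -> SliceStack:
    """Apply a fitted gain/offset to an already-capped stack, clipping at zero."""
    return stack.with_data(np.maximum(model.gain * stack.data + model.offset, 0.0))
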