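"""Core spatial containers: slice stacks, reference volumes, masks, NIfTI I/O.

Array convention
----------------
All volumetric data is indexed ``[k, i, j]`` = (slice, row, column).  Voxel
``(k, i, j)`` maps to world coordinates (mm) via

    world = origin + direction @ (j * s_col, i * s_row, k * s_slice)

i.e. columns advance along world x, rows along y, slices along z, matching an
axial acquisition.  ``spacing`` is stored as (in-plane row, in-plane column,
slice thickness) in mm; for the historical stacks the two in-plane components
are always equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ValidationError


def _as_direction(direction) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    if d.shape != (3, 3):
        raise ValidationError(f"direction must be 3x3, got {d.shape}")
    if not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
        raise ValidationError("direction matrix must be orthonormal")
    return d


@dataclass
class SliceStack:
    """An ordered stack of K thick axial 2D slices on a common grid.

    The central evolving object of the reconstruction: it starts life as naive
    film crops with provisional spacing and gradually acquires recovered
    metadata (in-plane spacing from the 3D similarity alignment, slice
    thickness from the film printout).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    axial: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"stack data must be K x H x W, got {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("stack intensities must be finite")
        self.direction = _as_direction(self.direction)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def inplane_spacing(self) -> float:
        return float(self.spacing[0])

    def affine(self) -> np.ndarray:
        """4x4 voxel-(j,i,k)-to-world affine (NIfTI style, x fastest)."""
        sr, sc, sz = self.spacing
        aff = np.eye(4)
        aff[:3, :3] = self.direction @ np.diag([sc, sr, sz])
        aff[:3, 3] = self.origin
        return aff

    def with_data(self, data: np.ndarray) -> "SliceStack":
        return replace(self, data=np.asarray(data, dtype=float))

    def copy(self) -> "SliceStack":
        return replace(self, data=self.data.copy())


@dataclass
class ReferenceVolume:
    """A later 3D scan of the same subject with trusted spatial metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be 3D, got {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing components must be > 0, got {self.spacing}")
        self.direction = _as_direction(self.direction)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def affine(self) -> np.ndarray:
        sr, sc, sz = self.spacing
        aff = np.eye(4)
        aff[:3, :3] = self.direction @ np.diag([sc, sr, sz])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class RegionMask:
    """Binary mask congruent with its parent stack or volume."""

    data: np.ndarray
    role: str = "brain"  # {"brain", "skull"}

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.role not in ("brain", "skull"):
            raise ValidationError(f"mask role must be 'brain' or 'skull', got '{self.role}'")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def assign_metadata(
    stack: SliceStack, slice_thickness_mm: float, inplane_spacing_mm: float
) -> SliceStack:
    """Attach the film-printed slice thickness and a provisional in-plane spacing.

    Metadata-only: the voxel data is untouched.
    """
    if slice_thickness_mm <= 0 or inplane_spacing_mm <= 0:
        raise ValidationError(
            f"spacings must be > 0, got thickness={slice_thickness_mm}, "
            f"inplane={inplane_spacing_mm}"
        )
    return replace(
        stack,
        spacing=(float(inplane_spacing_mm), float(inplane_spacing_mm), float(slice_thickness_mm)),
    )


# ---------------------------------------------------------------------------
# NIfTI I/O


def save_nifti(obj: SliceStack | ReferenceVolume | RegionMask, path: str | Path) -> None:
    if isinstance(obj, RegionMask):
        data = obj.data.astype(np.uint8)
        aff = np.eye(4)
    else:
        data = obj.data
        aff = obj.affine()
    # internal order [k, i, j] -> NIfTI order [x=j, y=i, z=k]
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), aff)
    nib.save(img, str(path))


def load_stack(path: str | Path) -> SliceStack:
    img = nib.load(str(path))
    data = np.transpose(np.asarray(img.dataobj, dtype=float), (2, 1, 0))
    aff = img.affine
    lin = aff[:3, :3]
    sc, sr, sz = (np.linalg.norm(lin[:, a]) for a in range(3))
    direction = lin @ np.diag([1.0 / sc, 1.0 / sr, 1.0 / sz])
    return SliceStack(
        data=data,
        spacing=(float(sr), float(sc), float(sz)),
        origin=tuple(aff[:3, 3]),
        direction=direction,
    )


def load_reference(path: str | Path) -> ReferenceVolume:
    s = load_stack(path)
    return ReferenceVolume(
        data=s.data, spacing=s.spacing, origin=s.origin, direction=s.direction
    )


# ---------------------------------------------------------------------------
# Resampling


def resample_to_grid(
    source: ReferenceVolume | SliceStack,
    target: SliceStack,
    transform: np.ndarray | None = None,
    interpolation: str = "linear",
) -> SliceStack:
    """Resample ``source`` onto the grid of ``target``.

    ``transform`` is a 4x4 world-to-world map taking target-world points into
    source-world points (identity if omitted).  Out-of-source samples are 0.
    """
    from scipy import ndimage

    if interpolation not in ("linear", "nearest"):
        raise ValidationError(f"unknown interpolation '{interpolation}'")
    order = 1 if interpolation == "linear" else 0
    t = np.eye(4) if transform is None else np.asarray(transform, dtype=float)
    if t.shape != (4, 4):
        raise ValidationError(f"transform must be 4x4, got {t.shape}")
    if abs(np.linalg.det(t[:3, :3])) < 1e-12:
        raise ValidationError("singular transform")

    # voxel(j,i,k)->world affines; internal arrays are [k,i,j] so conjugate
    # with the axis flip P: (k,i,j) -> (j,i,k).
    P = np.eye(4)[:, [2, 1, 0, 3]]
    P[3, 3] = 1.0
    tgt_v2w = target.affine() @ P  # maps (k,i,j,1) -> world
    src_v2w = source.affine() @ P
    full = np.linalg.inv(src_v2w) @ t @ tgt_v2w  # target voxel -> source voxel
    matrix = full[:3, :3]
    offset = full[:3, 3]
    out = ndimage.affine_transform(
        source.data,
        matrix=matrix,
        offset=offset,
        output_shape=target.shape,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return SliceStack(
        data=out,
        spacing=target.spacing,
        origin=target.origin,
        direction=target.direction,
        axial=target.axial,
    )
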