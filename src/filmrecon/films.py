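"""Reading scanned film sheets and extracting printed slices into a naive stack.

A historical axial acquisition survives as one or more photographic films, each
holding several slices printed side by side.  The only interaction the workflow
needs is one landmark per printed slice (recorded in a JSON sidecar together
with a uniform crop window); everything downstream is deterministic.  The
extracted crops are stacked in landmark order into a :class:`~filmrecon.stack.SliceStack`
that carries no trustworthy spatial metadata yet — only the slice thickness
printed on the film and a provisional unit in-plane spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InputDataError, ValidationError
from .stack import SliceStack


@dataclass
class FilmSheet:
    """One scanned film: a 2D grayscale raster plus identity metadata."""

    pixels: np.ndarray
    film_id: str = ""
    acquisition_id: str = ""
    film_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValidationError(
                f"film '{self.film_id}': expected a 2D raster with >= 2 rows and "
                f"columns, got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError(f"film '{self.film_id}': non-finite intensities")


@dataclass
class LandmarkSidecar:
    """Landmarks and the uniform extraction window for one acquisition.

    ``films`` maps film_id -> ordered landmark list [(row, col), ...] in pixel
    coordinates of that film.  The landmark order defines the slice stacking
    order.  ``window_offset`` positions the crop window relative to each
    landmark and ``window_size`` is identical for every slice of the
    acquisition.  Coordinates are 0-based; windows are half-open
    [start, start + size).
    """

    films: dict[str, list[tuple[float, float]]]
    window_offset: tuple[int, int] = (0, 0)
    window_size: tuple[int, int] = (64, 64)
    slice_thickness_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.slice_thickness_mm <= 0:
            raise ValidationError(
                f"slice_thickness_mm must be > 0, got {self.slice_thickness_mm}"
            )
        h, w = self.window_size
        if h <= 0 or w <= 0:
            raise ValidationError(f"window_size must be positive, got {self.window_size}")

    @property
    def n_slices(self) -> int:
        return sum(len(lms) for lms in self.films.values())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "films": [
                {"film_id": fid, "landmarks": [list(lm) for lm in lms]}
                for fid, lms in self.films.items()
            ],
            "window_offset": list(self.window_offset),
            "window_size": list(self.window_size),
            "slice_thickness_mm": self.slice_thickness_mm,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSidecar":
        try:
            payload = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise InputDataError(f"cannot read sidecar '{path}': {exc}") from exc
        films = {
            entry["film_id"]: [tuple(lm) for lm in entry["landmarks"]]
            for entry in payload["films"]
        }
        return cls(
            films=films,
            window_offset=tuple(payload.get("window_offset", (0, 0))),
            window_size=tuple(payload.get("window_size", (64, 64))),
            slice_thickness_mm=float(payload.get("slice_thickness_mm", 5.0)),
        )


def read_film(
    path: str | Path,
    film_id: str = "",
    acquisition_id: str = "",
    film_index: int = 0,
) -> FilmSheet:
    """Read a scanned film raster (PNG/TIFF, optionally single-frame DICOM).

    Multi-channel input is collapsed to grayscale by channel averaging;
    intensities are otherwise preserved as scanned.
    """
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"film file does not exist: '{path}'")
    suffix = path.suffix.lower()
    try:
        if suffix in (".dcm", ".dicom"):
            import pydicom

            arr = np.asarray(pydicom.dcmread(str(path)).pixel_array, dtype=float)
        else:
            from PIL import Image

            with Image.open(path) as img:
                arr = np.asarray(img, dtype=float)
    except Exception as exc:  # decoding failures vary by backend
        raise InputDataError(f"cannot decode film file '{path}': {exc}") from exc
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"film file '{path}' is not a 2D raster")
    return FilmSheet(
        pixels=arr,
        film_id=film_id or path.stem,
        acquisition_id=acquisition_id,
        film_index=film_index,
    )


def _crop_with_zero_padding(
    pixels: np.ndarray, start: tuple[int, int], size: tuple[int, int]
) -> np.ndarray:
    """Crop the half-open window [start, start+size); out-of-film pixels are 0."""
    h, w = size
    out = np.zeros((h, w), dtype=float)
    r0, c0 = start
    rs, re = max(r0, 0), min(r0 + h, pixels.shape[0])
    cs, ce = max(c0, 0), min(c0 + w, pixels.shape[1])
    if rs < re and cs < ce:
        out[rs - r0 : re - r0, cs - c0 : ce - c0] = pixels[rs:re, cs:ce]
    return out


def extract_slices(films: Sequence[FilmSheet], sidecar: LandmarkSidecar) -> SliceStack:
    """Crop one window per landmark and stack the crops in landmark order.

    Films are processed in ``film_index`` order; within a film the sidecar's
    landmark order defines the stacking order.  Windows extending past a film
    border are zero-padded.  The returned stack has provisional spacing
    (1, 1, slice_thickness_mm) and no recovered origin.
    """
    if sidecar.n_slices == 0:
        raise ValidationError("sidecar contains no landmarks")
    by_id = {f.film_id: f for f in films}
    missing = [fid for fid in sidecar.films if fid not in by_id]
    if missing:
        raise ValidationError(f"sidecar references unknown film_id(s): {missing}")

    ordered_ids = sorted(sidecar.films, key=lambda fid: by_id[fid].film_index)
    dr, dc = sidecar.window_offset
    crops = []
    for fid in ordered_ids:
        film = by_id[fid]
        for (lr, lc) in sidecar.films[fid]:
            start = (int(round(lr)) + int(dr), int(round(lc)) + int(dc))
            crops.append(_crop_with_zero_padding(film.pixels, start, sidecar.window_size))
    data = np.stack(crops, axis=0)
    return SliceStack(
        data=data,
        spacing=(1.0, 1.0, float(sidecar.slice_thickness_mm)),
        origin=(0.0, 0.0, 0.0),
    )
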