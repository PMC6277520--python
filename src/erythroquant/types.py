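"""Core value types shared across the analysis stages.

An :class:`ImagePlane` is a calibrated 2-D intensity raster; a
:class:`CellRegion` is one delineated cell with its geometry and the local
background level used for background-subtracted quantities; the profile
types hold per-radius / per-distance summaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class ImagePlane:
    """A single-plane grayscale image with pixel-size calibration.

    Parameters
    ----------
    pixels
        2-D array of finite, nonnegative intensities.
    pixel_size
        Physical size of one pixel in micrometres (default 0.5 um/px).
    """

    pixels: np.ndarray
    pixel_size: float = 0.5

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValidationError(f"image must be 2-D, got ndim={px.ndim}")
        if not np.all(np.isfinite(px)):
            raise ValidationError("image contains non-finite values")
        if px.min() < 0:
            raise ValidationError("image contains negative intensities")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def as_pixels(img) -> np.ndarray:
    """Accept an :class:`ImagePlane` or a bare 2-D array; return the array."""
    if isinstance(img, ImagePlane):
        return img.pixels
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D image")
    return arr


@dataclass
class CellRegion:
    """One segmented cell.

    ``coords`` is an (N, 2) integer array of (row, col) member pixels.
    ``local_background`` is the median intensity of an annulus just outside
    the region, excluding pixels belonging to other regions.
    """

    label: int
    coords: np.ndarray
    centroid: tuple[float, float]
    equivalent_radius: float
    local_background: float = field(default=np.nan)

    @property
    def area(self) -> int:
        return int(self.coords.shape[0])

    @property
    def max_extent(self) -> float:
        """Largest centroid-to-member-pixel distance (outer radius, px)."""
        d = self.coords - np.asarray(self.centroid)
        return float(np.hypot(d[:, 0], d[:, 1]).max())


@dataclass
class RadialProfile:
    """Background-subtracted mean intensity per integer radius bin."""

    bins: np.ndarray          # integer radii, contiguous from 0
    mean_intensity: np.ndarray
    n_pixels: np.ndarray
    cell_id: int | None = None

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=int)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels, dtype=int)
        if len(self.bins) == 0:
            raise ValidationError("empty radial profile")
        if self.bins[0] != 0 or np.any(np.diff(self.bins) != 1):
            raise ValidationError("radial bins must be contiguous from 0")
        if np.any(self.n_pixels < 1):
            raise ValidationError("every reported bin needs >= 1 pixel")

    @property
    def total_intensity(self) -> float:
        """Sum of background-subtracted intensity over the profiled pixels."""
        return float(np.sum(self.mean_intensity * self.n_pixels))


@dataclass
class PopulationProfile:
    """Per-bin mean and SEM over a population of cells."""

    bins: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_cells: np.ndarray        # contributing cells per bin


@dataclass
class DistanceProfile:
    """Mean fluorescence of vessel-wall pixels vs distance from the lumen."""

    distance_px: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_pixels: np.ndarray
    pixel_size: float = 0.5

    @property
    def distance_um(self) -> np.ndarray:
        return self.distance_px * self.pixel_size
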