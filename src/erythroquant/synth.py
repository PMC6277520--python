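"""Seeded synthetic microscopy scenes with full ground truth.

Three scene families are generated, each mirroring the measurement it
exercises:

* 415 nm transmitted-light fields of red blood cells.  Haemoglobin absorbs
  strongly at 415 nm (the Soret band), so absorbance maps cell thickness: an
  intact discocyte renders as a dark absorbing ring with a brighter centre
  and outer edge, plus a thin bright halo just outside its boundary.  A
  lysed cell has released its haemoglobin and renders as a faint
  low-absorbance outline of its membrane only.
* Registered two-channel fluorescence pairs for ratiometric dipole-potential
  measurement, where each cell's channel ratio encodes its true membrane
  dipole potential through a linear calibration.
* Vessel cross-sections in which tracer fluorescence in the intima decays
  exponentially with distance from the luminal surface.

Every generator is a deterministic function of its truth object: identical
seed and parameters give bit-identical rasters, and with ``noise_sd = 0``
the raster is an exact function of the geometry.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import ImagePlane, ValidationError

INTACT = "intact"
LYSED = "lysed"

# Relative discocyte thickness t(rho) = sqrt(1-rho^2) (c0 + c1 rho^2 + c2 rho^4)
# with the classic biconcave-disc coefficients; rho = r / R in [0, 1].
_C0, _C1, _C2 = 0.81, 7.83, -4.39
_RHO_GRID = np.linspace(0.0, 1.0, 4001)


def thickness_profile(rho: np.ndarray) -> np.ndarray:
    """Relative biconcave-disc thickness at normalized radius ``rho``.

    Normalized so the maximum over [0, 1] equals 1; zero outside the disc.
    The profile is dimpled: thinnest at the centre and the rim, thickest in
    the ring between.
    """
    rho = np.asarray(rho, dtype=float)
    inside = np.clip(rho, 0.0, 1.0)
    t = np.sqrt(np.clip(1.0 - inside**2, 0.0, None)) * (
        _C0 + _C1 * inside**2 + _C2 * inside**4
    )
    t = np.where(rho <= 1.0, t, 0.0)
    return t / _THICKNESS_MAX


_THICKNESS_MAX = 1.0
_THICKNESS_MAX = float(
    np.max(
        np.sqrt(1.0 - _RHO_GRID**2) * (_C0 + _C1 * _RHO_GRID**2 + _C2 * _RHO_GRID**4)
    )
)


def cell_absorbance(r: np.ndarray, radius: float, state: str,
                    peak_absorbance: float, center_boost: float = 0.0,
                    rim_fraction: float = 0.25,
                    rim_width: float = 1.0) -> np.ndarray:
    """Optical absorbance at centre distance ``r`` for one cell.

    Intact cells follow the biconcave thickness map scaled so the ring peak
    reaches ``peak_absorbance``; a positive ``center_boost`` adds a
    Gaussian bump of that amplitude at the centre (sigma 0.35 radius),
    emulating the central swelling of a treated cell.  Lysed cells keep
    only a faint membrane outline: a thin ring of absorbance
    ``rim_fraction * peak_absorbance`` at the cell boundary.
    """
    r = np.asarray(r, dtype=float)
    if state == INTACT:
        a = peak_absorbance * thickness_profile(r / radius)
        if center_boost:
            a = a + center_boost * np.exp(-(r / (0.35 * radius)) ** 2) \
                * (r <= radius)
        return a
    if state == LYSED:
        return np.where(
            np.abs(r - radius) <= rim_width, rim_fraction * peak_absorbance, 0.0
        )
    raise ValidationError(f"unknown cell state {state!r}")


@dataclass(frozen=True)
class CellSpec:
    """Ground truth for one cell in a scene."""

    center: tuple[float, float]           # (row, col), px
    radius: float                         # px
    state: str = INTACT
    peak_absorbance: float = 0.8          # dimensionless optical density
    center_boost: float = 0.0             # extra central absorbance (swelling)
    true_mdp: float | None = None         # mV, for ratiometric scenes

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("cell radius must be positive")
        if self.state not in (INTACT, LYSED):
            raise ValidationError(f"state must be intact or lysed, got {self.state!r}")
        if self.peak_absorbance < 0:
            raise ValidationError("peak_absorbance must be >= 0")


@dataclass(frozen=True)
class SceneTruth:
    """Complete description of a synthetic RBC scene."""

    shape: tuple[int, int]
    cells: tuple[CellSpec, ...] = ()
    background_level: float = 1000.0
    noise_sd: float = 0.0
    seed: int = 0
    pixel_size: float = 0.5               # um / px
    halo_contrast: float = 0.10           # bright rim outside intact cells
    halo_width: float = 2.0               # px
    min_separation: float = 1.0           # fraction of radius sum
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.background_level < 0:
            raise ValidationError("background_level must be >= 0")


@dataclass(frozen=True)
class VesselTruth:
    """Ground truth for a synthetic vessel cross-section."""

    lumen_mask: np.ndarray
    intima_mask: np.ndarray
    surface_intensity: float = 1000.0     # I0 at the luminal surface
    decay_length: float = 10.0            # lambda, px
    background_level: float = 0.0         # detector offset everywhere
    noise_sd: float = 0.0
    seed: int = 0
    pixel_size: float = 0.5

    def __post_init__(self) -> None:
        lum = np.asarray(self.lumen_mask, dtype=bool)
        intima = np.asarray(self.intima_mask, dtype=bool)
        if lum.shape != intima.shape:
            raise ValidationError("lumen and intima masks must share a shape")
        if np.any(lum & intima):
            raise ValidationError("lumen and intima masks must be disjoint")
        if not intima.any():
            raise ValidationError("intima mask is empty")
        if self.decay_length <= 0:
            raise ValidationError("decay_length must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        object.__setattr__(self, "lumen_mask", lum)
        object.__setattr__(self, "intima_mask", intima)


class PlacementError(ValidationError):
    """A cell does not fit in the scene or violates the separation rule."""


def _validate_placement(truth: SceneTruth) -> None:
    nrow, ncol = truth.shape
    margin = truth.halo_width
    for c in truth.cells:
        r0, c0 = c.center
        reach = c.radius + margin
        if (r0 - reach < 0 or c0 - reach < 0
                or r0 + reach > nrow - 1 or c0 + reach > ncol - 1):
            raise PlacementError(
                f"cell at {c.center} with radius {c.radius} leaves the scene"
            )
    if truth.allow_overlap:
        return
    cells = truth.cells
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            a, b = cells[i], cells[j]
            d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d < truth.min_separation * (a.radius + b.radius):
                raise PlacementError(
                    f"cells {i} and {j} closer than the configured separation"
                )


def _distance_map(shape: tuple[int, int], center: tuple[float, float]):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return np.hypot(rr - center[0], cc - center[1])


def _add_noise(noiseless: np.ndarray, noise_sd: float, rng: np.random.Generator):
    if noise_sd == 0:
        return noiseless.copy()
    return np.clip(noiseless + rng.normal(0.0, noise_sd, noiseless.shape), 0.0, None)


def generate_rbc_field(truth: SceneTruth) -> tuple[ImagePlane, SceneTruth]:
    """Render a 415 nm transmitted-light field from its ground truth.

    Transmitted intensity follows Beer–Lambert attenuation of the background
    illumination, ``I = I_bg * 10**(-A(r))``, with ``A`` the cell's radial
    absorbance; intact cells additionally receive an additive bright halo
    just outside the boundary.  Returns the raster and the truth used.
    """
    _validate_placement(truth)
    bg = truth.background_level
    img = np.full(truth.shape, bg, dtype=float)
    for cell in truth.cells:
        reach = int(np.ceil(cell.radius + truth.halo_width)) + 1
        r0, c0 = cell.center
        rlo = max(int(np.floor(r0)) - reach, 0)
        rhi = min(int(np.ceil(r0)) + reach + 1, truth.shape[0])
        clo = max(int(np.floor(c0)) - reach, 0)
        chi = min(int(np.ceil(c0)) + reach + 1, truth.shape[1])
        rr, cc = np.ogrid[rlo:rhi, clo:chi]
        d = np.hypot(rr - r0, cc - c0)
        absorb = cell_absorbance(d, cell.radius, cell.state,
                                 cell.peak_absorbance, cell.center_boost)
        patch = img[rlo:rhi, clo:chi]
        patch *= 10.0 ** (-absorb)
        if cell.state == INTACT and truth.halo_contrast > 0:
            halo_zone = (d > cell.radius) & (d <= cell.radius + truth.halo_width)
            taper = np.clip(1.0 - (d - cell.radius) / truth.halo_width, 0.0, 1.0)
            patch += np.where(halo_zone, bg * truth.halo_contrast * taper, 0.0)
    rng = np.random.default_rng(truth.seed)
    img = _add_noise(img, truth.noise_sd, rng)
    return ImagePlane(img, truth.pixel_size), truth


def generate_ratiometric_pair(
    truth: SceneTruth,
    calibration,
    cell_intensity: float = 1000.0,
) -> tuple[ImagePlane, ImagePlane, SceneTruth]:
    """Render a co-registered two-channel fluorescence pair.

    Each cell is a uniform fluorescent disc.  Channel B carries the base
    intensity ``cell_intensity``; channel A carries ``target_ratio`` times
    that, where ``target_ratio = intercept + slope * true_mdp``.  Before
    noise, the per-cell background-subtracted channel ratio therefore equals
    the calibrated ratio of its true dipole potential exactly.
    """
    slope, intercept = calibration.slope, calibration.intercept
    if slope == 0:
        raise ValidationError("calibration slope must be nonzero")
    _validate_placement(truth)
    bg = truth.background_level
    chan_a = np.full(truth.shape, bg, dtype=float)
    chan_b = np.full(truth.shape, bg, dtype=float)
    for cell in truth.cells:
        if cell.true_mdp is None:
            raise ValidationError("ratiometric scenes need true_mdp on every cell")
        target_ratio = intercept + slope * cell.true_mdp
        if target_ratio <= 0:
            raise ValidationError(
                f"calibration maps mdp={cell.true_mdp} to nonpositive ratio"
            )
        d = _distance_map(truth.shape, cell.center)
        disc = d <= cell.radius
        chan_b[disc] += cell_intensity
        chan_a[disc] += target_ratio * cell_intensity
    rng = np.random.default_rng(truth.seed)
    chan_a = _add_noise(chan_a, truth.noise_sd, rng)
    chan_b = _add_noise(chan_b, truth.noise_sd, rng)
    return (
        ImagePlane(chan_a, truth.pixel_size),
        ImagePlane(chan_b, truth.pixel_size),
        truth,
    )


def generate_vessel_section(truth: VesselTruth) -> tuple[ImagePlane, VesselTruth]:
    """Render tracer fluorescence over a vessel cross-section.

    Intima pixels carry ``I0 * exp(-d / lambda)`` where ``d`` is the
    Euclidean distance to the nearest lumen pixel; lumen pixels carry the
    surface intensity ``I0`` (tracer-filled lumen); everything else is dark.
    ``decay_length = numpy.inf`` gives the flat-profile limit.
    """
    if not truth.lumen_mask.any():
        raise ValidationError("intima pixels unreachable: lumen mask is empty")
    img = np.full(truth.lumen_mask.shape, float(truth.background_level))
    dist = ndimage.distance_transform_edt(~truth.lumen_mask)
    decay = (
        np.ones_like(dist)
        if np.isinf(truth.decay_length)
        else np.exp(-dist / truth.decay_length)
    )
    img[truth.intima_mask] += truth.surface_intensity * decay[truth.intima_mask]
    img[truth.lumen_mask] += truth.surface_intensity
    rng = np.random.default_rng(truth.seed)
    img = _add_noise(img, truth.noise_sd, rng)
    return ImagePlane(img, truth.pixel_size), truth


def regions_from_truth(img, truth: SceneTruth):
    """Ground-truth :class:`~erythroquant.types.CellRegion` objects.

    Builds one region per cell from its true disc (pixels within the cell
    radius of the centre), with the local background measured on the image
    by the same annulus rule segmentation uses.  Lets downstream operations
    be exercised with perfect delineation, independent of the detector.
    """
    from .segment import local_background
    from .types import CellRegion, as_pixels

    px = as_pixels(img)
    labels = np.zeros(truth.shape, dtype=int)
    for i, cell in enumerate(truth.cells):
        d = _distance_map(truth.shape, cell.center)
        labels[d <= cell.radius] = i + 1
    regions = []
    for i, cell in enumerate(truth.cells):
        rows, cols = np.nonzero(labels == i + 1)
        regions.append(
            CellRegion(
                label=i + 1,
                coords=np.column_stack([rows, cols]),
                centroid=cell.center,
                equivalent_radius=float(np.sqrt(rows.size / np.pi)),
                local_background=local_background(px, labels, i + 1),
            )
        )
    return regions


# ---------------------------------------------------------------------------
# Scene builders


def random_cell_layout(
    n_cells: int,
    shape: tuple[int, int],
    radius: float,
    rng: np.random.Generator,
    min_separation: float = 1.15,
    halo_width: float = 2.0,
    max_tries: int = 20000,
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping cell centres inside the scene."""
    margin = radius + halo_width + 1.0
    centers: list[tuple[float, float]] = []
    min_dist = min_separation * 2 * radius
    for _ in range(max_tries):
        if len(centers) == n_cells:
            break
        cand = (
            rng.uniform(margin, shape[0] - 1 - margin),
            rng.uniform(margin, shape[1] - 1 - margin),
        )
        if all(np.hypot(cand[0] - r, cand[1] - c) >= min_dist for r, c in centers):
            centers.append(cand)
    if len(centers) < n_cells:
        raise PlacementError(
            f"could not place {n_cells} cells of radius {radius} in {shape}"
        )
    return centers


def signal_amplitude(background_level: float, peak_absorbance: float) -> float:
    """Intensity drop at the absorbing ring of an intact cell."""
    return background_level * (1.0 - 10.0 ** (-peak_absorbance))


def noise_sd_for_snr(snr: float, background_level: float = 1000.0,
                     peak_absorbance: float = 0.8) -> float:
    """Noise standard deviation giving the requested peak signal-to-noise."""
    if snr <= 0:
        raise ValidationError("snr must be positive")
    return signal_amplitude(background_level, peak_absorbance) / snr


def make_rbc_scene(
    n_cells: int,
    radius: float = 8.0,
    shape: tuple[int, int] | None = None,
    snr: float | None = None,
    background_level: float = 1000.0,
    peak_absorbance: float = 0.8,
    lysed_fraction: float = 0.0,
    seed: int = 0,
    mdp_mean: float = 300.0,
    mdp_sd: float = 50.0,
    lysis_mdp_slope: float = 0.0,
) -> SceneTruth:
    """Build a randomized RBC scene truth.

    ``snr = None`` means noiseless.  If ``lysed_fraction > 0`` cells are
    lysed with that probability; with ``lysis_mdp_slope > 0`` the lysis
    probability is instead logistic in the cell's true dipole potential,
    centred so the population fraction stays near ``lysed_fraction``
    (higher potential -> more likely to lyse).
    """
    if shape is None:
        side = int(np.ceil(np.sqrt(max(n_cells, 1)) * 2.6 * 2 * radius)) + 20
        shape = (side, side)
    rng = np.random.default_rng(seed)
    centers = random_cell_layout(n_cells, shape, radius, rng)
    mdps = rng.normal(mdp_mean, mdp_sd, n_cells)
    if lysed_fraction > 0 and lysis_mdp_slope > 0:
        z = lysis_mdp_slope * (mdps - mdp_mean) / mdp_sd
        offset = _logistic_offset(z, lysed_fraction)
        p_lyse = 1.0 / (1.0 + np.exp(-(z + offset)))
        states = np.where(rng.uniform(size=n_cells) < p_lyse, LYSED, INTACT)
    elif lysed_fraction > 0:
        # exact count at the nominal fraction, randomly assigned
        n_lysed = int(round(lysed_fraction * n_cells))
        states = np.full(n_cells, INTACT, dtype=object)
        states[rng.permutation(n_cells)[:n_lysed]] = LYSED
    else:
        states = np.full(n_cells, INTACT, dtype=object)
    cells = tuple(
        CellSpec(
            center=centers[i],
            radius=radius,
            state=str(states[i]),
            peak_absorbance=peak_absorbance,
            true_mdp=float(mdps[i]),
        )
        for i in range(n_cells)
    )
    noise_sd = 0.0 if snr is None else noise_sd_for_snr(
        snr, background_level, peak_absorbance
    )
    return SceneTruth(
        shape=shape,
        cells=cells,
        background_level=background_level,
        noise_sd=noise_sd,
        seed=seed,
    )


RATIOMETRIC_BACKGROUND = 500.0   # fluorescence offset, both channels
RATIOMETRIC_CELL_INTENSITY = 1000.0


def make_ratiometric_scene(
    n_cells: int,
    radius: float = 8.0,
    snr: float | None = None,
    seed: int = 0,
    mdp_mean: float = 300.0,
    mdp_sd: float = 50.0,
) -> SceneTruth:
    """Randomized scene truth for a two-channel ratiometric pair.

    ``snr`` is the cell amplitude over the per-pixel noise standard
    deviation in each channel; both channels share a uniform background
    offset of :data:`RATIOMETRIC_BACKGROUND`.
    """
    truth = make_rbc_scene(n_cells, radius=radius, seed=seed,
                           mdp_mean=mdp_mean, mdp_sd=mdp_sd)
    noise_sd = 0.0 if snr is None else RATIOMETRIC_CELL_INTENSITY / snr
    return dataclasses.replace(
        truth, background_level=RATIOMETRIC_BACKGROUND, noise_sd=noise_sd
    )


def _logistic_offset(z: np.ndarray, target_fraction: float) -> float:
    """Intercept making mean(sigmoid(z + offset)) hit the target fraction."""
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(z + mid)))) < target_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def relyse_scene(truth: SceneTruth, seed_offset: int = 0) -> SceneTruth:
    """Scene with every cell intact, same geometry: the 'before' image."""
    cells = tuple(dataclasses.replace(c, state=INTACT) for c in truth.cells)
    return dataclasses.replace(truth, cells=cells, seed=truth.seed + seed_offset)


def make_annular_vessel(
    shape: tuple[int, int] = (160, 160),
    lumen_radius: float = 30.0,
    wall_thickness: float = 45.0,
    surface_intensity: float = 1000.0,
    decay_length: float = 10.0,
    background_level: float = 300.0,
    snr: float | None = None,
    seed: int = 0,
) -> VesselTruth:
    """Disc lumen with an annular intima, the idealized cross-section.

    A nonzero detector offset keeps additive noise from rectifying at zero
    in the dim outer wall, as on a real camera.
    """
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    d = _distance_map(shape, center)
    lumen = d <= lumen_radius
    intima = (d > lumen_radius) & (d <= lumen_radius + wall_thickness)
    noise_sd = 0.0 if snr is None else surface_intensity / snr
    return VesselTruth(
        lumen_mask=lumen,
        intima_mask=intima,
        surface_intensity=surface_intensity,
        decay_length=decay_length,
        background_level=background_level,
        noise_sd=noise_sd,
        seed=seed,
    )
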