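"""Single-cell segmentation of 415 nm transmitted-light RBC images.

The pipeline mirrors a classic absorbance-imaging workflow: estimate the
characteristic cell scale from the strongest scale-space blob responses,
flatten the illumination with a rolling-ball background subtraction,
threshold with Otsu's method, split touching cells with a marker-based
watershed on the distance transform, and discard regions outside plausible
size bounds.  Cells absorb at 415 nm and appear dark, so the image is
inverted internally and "foreground" always means high absorbance.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology, segmentation as skseg

from .types import CellRegion, ValidationError, as_pixels

logger = logging.getLogger(__name__)


class NoScaleError(ValidationError):
    """No blob structure found above the response floor."""


class DegenerateImageError(ValidationError):
    """The intensity histogram has fewer than two distinct values."""


@dataclass
class SegmentationConfig:
    """Tunable parameters of the segmentation pipeline.

    ``dark_cells`` states the polarity of the raw image (absorbing cells on
    a bright background); the pipeline inverts so thresholding selects
    high-absorbance pixels.  Size bounds default to ``size_bounds_factor``
    times the area of a disc at the estimated cell radius.
    """

    dark_cells: bool = True
    sigma_grid: tuple = tuple(np.arange(2.0, 10.5, 0.5))
    cell_radius: float | None = None        # px; None -> estimate from image
    ball_radius_factor: float = 3.0
    smooth_sigma_factor: float = 0.25       # denoising sigma as fraction of radius
    h_maxima_depth: float = 1.0
    size_bounds_factor: tuple[float, float] = (0.4, 2.5)
    annulus_gap: float = 2.0                # px between region edge and annulus
    annulus_width: float = 2.0
    connectivity: int = 2                   # 8-connected foreground


def estimate_cell_scale(img, sigma_grid=None, response_floor: float = 1e-6,
                        dark_cells: bool = True) -> float:
    """Estimate the characteristic cell radius from the strongest
    scale-space peak.

    For each sigma in the grid the scale-normalized Laplacian-of-Gaussian
    response ``-sigma**2 * LoG`` is computed and its maximum over the image
    taken; the winning sigma is the one with the strongest peak and the
    returned radius is ``sqrt(2) * sigma``.  Raises :class:`NoScaleError`
    on a featureless image.
    """
    px = as_pixels(img)
    if sigma_grid is None:
        sigma_grid = SegmentationConfig().sigma_grid
    sigmas = np.asarray(sorted(sigma_grid), dtype=float)
    if sigmas.size == 0:
        raise ValidationError("sigma_grid must be non-empty")
    work = px.max() - px if dark_cells else px.copy()
    span = work.max() - work.min()
    if span <= response_floor:
        raise NoScaleError("image has no structure above the response floor")
    responses = np.array([
        float((-s**2 * ndimage.gaussian_laplace(work, s)).max()) for s in sigmas
    ])
    if responses.max() <= response_floor:
        raise NoScaleError("no scale-space peak above the response floor")
    return float(sigmas[int(np.argmax(responses))] * np.sqrt(2.0))


def ball_structuring_element(radius: float):
    """Height map of the upper half-ball, with its circular footprint."""
    r_int = int(np.ceil(radius))
    yy, xx = np.mgrid[-r_int:r_int + 1, -r_int:r_int + 1]
    d2 = (yy**2 + xx**2).astype(float)
    footprint = d2 <= radius**2
    heights = np.sqrt(np.clip(radius**2 - d2, 0.0, None))
    return np.where(footprint, heights, 0.0), footprint


def rolling_ball_background(img, ball_radius: float):
    """Rolling-ball background estimation (ImageJ-style ball opening).

    The background is the grayscale opening of the image with a ball
    structuring element: the envelope traced by the apex of a ball of the
    given radius rolled under the intensity surface.  Operates on the
    polarity being corrected (foreground = high); edges are handled by
    replicating the border.  Returns ``(background, corrected)`` with
    ``background <= img`` pointwise and ``corrected = img - background``
    clipped at zero.
    """
    px = as_pixels(img)
    if ball_radius < 1:
        raise ValidationError("ball_radius must be >= 1")
    heights, footprint = ball_structuring_element(ball_radius)
    eroded = ndimage.grey_erosion(px, footprint=footprint, structure=heights,
                                  mode="nearest")
    background = ndimage.grey_dilation(eroded, footprint=footprint,
                                       structure=heights, mode="nearest")
    background = np.minimum(background, px)
    corrected = np.clip(px - background, 0.0, None)
    return background, corrected


def otsu_threshold(img):
    """Otsu threshold by exhaustive between-class-variance maximization.

    Candidate thresholds are the distinct pixel values (classes are
    ``<= t`` vs ``> t``); the returned threshold maximizes the between-class
    variance ``w0 * w1 * (mu0 - mu1)**2``, smallest value on ties.  Returns
    ``(threshold, mask)`` with ``mask = img > threshold``.
    """
    px = as_pixels(img)
    values, counts = np.unique(px.ravel(), return_counts=True)
    if values.size < 2:
        raise DegenerateImageError("constant image: Otsu threshold undefined")
    n = px.size
    w0 = np.cumsum(counts)[:-1] / n
    w1 = 1.0 - w0
    cum_sum = np.cumsum(values * counts)
    mu0 = cum_sum[:-1] / np.cumsum(counts)[:-1]
    mu1 = (cum_sum[-1] - cum_sum[:-1]) / (n - np.cumsum(counts)[:-1])
    between = w0 * w1 * (mu0 - mu1) ** 2
    t = values[int(np.argmax(between))]
    return float(t), px > t


def split_touching(mask, connectivity: int = 2, h_maxima_depth: float = 1.0):
    """Delineate touching cells by marker-based watershed.

    Markers are the regional maxima of the Euclidean distance transform of
    the mask after suppressing maxima shallower than ``h_maxima_depth``
    (h-maxima); the watershed floods the negated distance transform from
    those markers.  Marker labels are assigned in raster order, so ties
    break toward the smallest (row, col).  With no markers the connected
    components are returned with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    footprint = np.ones((3, 3)) if connectivity == 2 else None
    if not mask.any():
        return np.zeros(mask.shape, dtype=int)
    edt = ndimage.distance_transform_edt(mask)
    if h_maxima_depth > 0:
        peaks = morphology.h_maxima(edt, h_maxima_depth)
    else:
        peaks = morphology.local_maxima(edt)
    markers, n_markers = ndimage.label(peaks, structure=np.ones((3, 3)))
    if n_markers == 0:
        warnings.warn("no watershed markers found; returning connected components",
                      stacklevel=2)
        labels, _ = ndimage.label(mask, structure=np.ones((3, 3)))
        return labels
    labels = skseg.watershed(-edt, markers=markers, mask=mask,
                             connectivity=footprint)
    return relabel_sequential(labels)


def relabel_sequential(labels) -> np.ndarray:
    """Relabel positive regions contiguously from 1, preserving order."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    mapping = np.zeros(labels.max() + 1 if labels.size else 1, dtype=int)
    mapping[present] = np.arange(1, present.size + 1)
    return mapping[labels]


def size_filter(labels, min_area: float, max_area: float) -> np.ndarray:
    """Retain regions with ``min_area <= area <= max_area``; relabel from 1."""
    if not (0 < min_area < max_area):
        raise ValidationError("need 0 < min_area < max_area")
    labels = np.asarray(labels, dtype=int)
    if labels.max() == 0:
        return labels.copy()
    areas = np.bincount(labels.ravel())
    keep = np.zeros_like(areas, dtype=bool)
    keep[1:] = (areas[1:] >= min_area) & (areas[1:] <= max_area)
    filtered = np.where(keep[labels], labels, 0)
    return relabel_sequential(filtered)


def local_background(img, labels, label: int, gap: float = 2.0,
                     width: float = 2.0) -> float:
    """Median intensity in an annulus outside one region.

    The annulus starts ``gap`` px outside the region's boundary and is
    ``width`` px wide; pixels belonging to any segmented region are
    excluded.  Falls back to the median over all background pixels if the
    annulus is empty.
    """
    px = as_pixels(img)
    labels = np.asarray(labels)
    region = labels == label
    rows, cols = np.nonzero(region)
    pad = int(np.ceil(gap + width)) + 1
    rlo, rhi = max(rows.min() - pad, 0), min(rows.max() + pad + 1, px.shape[0])
    clo, chi = max(cols.min() - pad, 0), min(cols.max() + pad + 1, px.shape[1])
    sub = region[rlo:rhi, clo:chi]
    dist = ndimage.distance_transform_edt(~sub)
    ring = (dist > gap) & (dist <= gap + width) & (labels[rlo:rhi, clo:chi] == 0)
    if not ring.any():
        outside = labels[rlo:rhi, clo:chi] == 0
        if not outside.any():
            return float("nan")
        return float(np.median(px[rlo:rhi, clo:chi][outside]))
    return float(np.median(px[rlo:rhi, clo:chi][ring]))


def regions_from_labels(img, labels, config: SegmentationConfig | None = None
                        ) -> list[CellRegion]:
    """Build :class:`CellRegion` records (with local background) from labels."""
    config = config or SegmentationConfig()
    px = as_pixels(img)
    labels = np.asarray(labels, dtype=int)
    regions = []
    for lab in range(1, labels.max() + 1):
        rows, cols = np.nonzero(labels == lab)
        if rows.size == 0:
            continue
        coords = np.column_stack([rows, cols])
        centroid = (float(rows.mean()), float(cols.mean()))
        regions.append(
            CellRegion(
                label=lab,
                coords=coords,
                centroid=centroid,
                equivalent_radius=float(np.sqrt(rows.size / np.pi)),
                local_background=local_background(
                    px, labels, lab, config.annulus_gap, config.annulus_width
                ),
            )
        )
    return regions


def segment_cells(img, config: SegmentationConfig | None = None
                  ) -> tuple[list[CellRegion], np.ndarray]:
    """Full segmentation pipeline; returns (cell regions, label map).

    Steps: polarity inversion, scale estimation (unless a cell radius is
    supplied), rolling-ball background subtraction at 3x the cell radius,
    Otsu thresholding of the corrected image, watershed splitting, size
    filtering at ``size_bounds_factor`` times the nominal disc area.  Local
    background per cell is measured on the original (uninverted) image.
    """
    config = config or SegmentationConfig()
    px = as_pixels(img)
    work = px.max() - px if config.dark_cells else px.copy()
    radius = config.cell_radius
    if radius is None:
        try:
            radius = estimate_cell_scale(work, config.sigma_grid,
                                         dark_cells=False)
        except NoScaleError:
            return [], np.zeros(px.shape, dtype=int)
    logger.debug("segmenting with cell radius %.2f px", radius)
    ball_radius = max(int(round(config.ball_radius_factor * radius)), 1)
    _, corrected = rolling_ball_background(work, ball_radius)
    if config.smooth_sigma_factor > 0:
        corrected = ndimage.gaussian_filter(
            corrected, config.smooth_sigma_factor * radius
        )
    try:
        _, mask = otsu_threshold(corrected)
    except DegenerateImageError:
        return [], np.zeros(px.shape, dtype=int)
    labels = split_touching(mask, config.connectivity, config.h_maxima_depth)
    lo, hi = config.size_bounds_factor
    nominal = np.pi * radius**2
    labels = size_filter(labels, lo * nominal, hi * nominal)
    return regions_from_labels(px, labels, config), labels


def match_detections(pred_centroids, true_centers, max_dist: float = 5.0):
    """Greedy one-to-one matching of detections to ground-truth centres.

    Returns (matches, errors): index pairs matched within ``max_dist`` px
    (closest pairs first) and their centroid distances.
    """
    pred = np.asarray(pred_centroids, dtype=float).reshape(-1, 2)
    true = np.asarray(true_centers, dtype=float).reshape(-1, 2)
    if pred.size == 0 or true.size == 0:
        return [], np.array([])
    d = np.hypot(
        pred[:, None, 0] - true[None, :, 0], pred[:, None, 1] - true[None, :, 1]
    )
    matches, errors = [], []
    used_p, used_t = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for i, j in order:
        if d[i, j] > max_dist:
            break
        if i in used_p or j in used_t:
            continue
        used_p.add(int(i))
        used_t.add(int(j))
        matches.append((int(i), int(j)))
        errors.append(d[i, j])
    return matches, np.asarray(errors)


def detection_f1(pred_centroids, true_centers, max_dist: float = 5.0):
    """Detection F1 score and mean centroid error against ground truth."""
    matches, errors = match_detections(pred_centroids, true_centers, max_dist)
    tp = len(matches)
    n_pred = len(np.atleast_2d(pred_centroids)) if len(pred_centroids) else 0
    n_true = len(np.atleast_2d(true_centers)) if len(true_centers) else 0
    if tp == 0:
        return 0.0, np.nan
    precision = tp / n_pred
    recall = tp / n_true
    return 2 * precision * recall / (precision + recall), float(errors.mean())
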