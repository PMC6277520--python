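"""Haemolysis classification, % lysis, and the MDP–lysis association.

A lysed red cell has released its haemoglobin, so its interior no longer
absorbs 415 nm light: only a faint membrane outline remains, while intact
cells keep a strongly absorbing interior and a bright halo at their edge.
The classifier scores each cell by the fractional absorbance of its
interior and thresholds the score; % lysis follows the counting protocol
(cells counted before incubation vs intact cells counted after).  The
association between a cell's pre-treatment dipole potential and its lysis
fate is tested per donor with unpaired t-tests under Holm–Šidák.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import stats
from .segment import otsu_threshold
from .types import CellRegion, ValidationError, as_pixels

logger = logging.getLogger(__name__)

INTACT = "intact"
LYSED = "lysed"
MIN_CELLS_ASSOCIATION = 20   # per-treatment minimum for the MDP-lysis test


def contrast_score(img, cell: CellRegion, interior_fraction: float = 0.6) -> float:
    """Fractional interior absorbance of one cell.

    score = (local_background - mean interior intensity) / local_background.
    The interior is the filled disc of radius ``interior_fraction`` times
    the region's outer radius around its centroid (a lysed cell segments as
    a thin rim, so the diagnostic empty interior must come from the image,
    not from the region's member pixels).  0 means interior at background
    (fully lysed limit); 1 means opaque.
    """
    px = as_pixels(img)
    b = cell.local_background
    if not np.isfinite(b) or b <= 0:
        raise ValidationError("local_background must be positive")
    r_outer = max(cell.max_extent, 1.0)
    r_in = max(interior_fraction * r_outer, 1.0)
    r0, c0 = cell.centroid
    rlo = max(int(np.floor(r0 - r_in)), 0)
    rhi = min(int(np.ceil(r0 + r_in)) + 1, px.shape[0])
    clo = max(int(np.floor(c0 - r_in)), 0)
    chi = min(int(np.ceil(c0 + r_in)) + 1, px.shape[1])
    rr, cc = np.ogrid[rlo:rhi, clo:chi]
    disc = np.hypot(rr - r0, cc - c0) <= r_in
    if not disc.any():
        raise ValidationError("empty interior disc")
    interior_mean = float(px[rlo:rhi, clo:chi][disc].mean())
    return (b - interior_mean) / b


FALLBACK_THRESHOLD = 0.3   # fractional interior absorbance floor for "intact"


def score_threshold(scores, min_separation: float = 4.0,
                    fallback: float = FALLBACK_THRESHOLD) -> float:
    """Self-calibrating class boundary: Otsu on the score histogram.

    Otsu's split is meaningful only when the scores are genuinely bimodal
    (a mixed intact/lysed population).  When the two Otsu classes are
    separated by less than ``min_separation`` pooled within-class standard
    deviations — a unimodal population — the fixed absorbance floor
    ``fallback`` is used instead: an interior absorbing less than that
    fraction of the background light has lost its haemoglobin.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2 or np.unique(scores).size < 2:
        return fallback
    t, _ = otsu_threshold(scores.reshape(1, -1))
    lo = scores[scores <= t]
    hi = scores[scores > t]
    if lo.size < 2 or hi.size < 2:
        return fallback
    within_sd = np.sqrt(0.5 * (lo.var(ddof=1) + hi.var(ddof=1)))
    if within_sd == 0:
        return t
    if (hi.mean() - lo.mean()) / within_sd < min_separation:
        return fallback
    return t


def classify_cells(img, cells: list[CellRegion], threshold: float | None = None,
                   border_margin: float | None = None) -> pd.DataFrame:
    """Score and classify cells as intact vs lysed.

    ``threshold = None`` calibrates the boundary from the score histogram
    (Otsu on scores); cells score below it are called lysed.  Cells whose
    extent reaches within ``border_margin`` px of the image edge are
    excluded (partial interiors bias the score); the default margin is each
    cell's own outer radius.
    """
    px = as_pixels(img)
    rows = []
    for cell in cells:
        margin = cell.max_extent if border_margin is None else border_margin
        r0, c0 = cell.centroid
        if (r0 - margin < 0 or c0 - margin < 0
                or r0 + margin > px.shape[0] - 1 or c0 + margin > px.shape[1] - 1):
            logger.info("cell %s touches the border; excluded", cell.label)
            continue
        rows.append((cell.label, contrast_score(px, cell)))
    table = pd.DataFrame(rows, columns=["cell_id", "contrast_score"])
    if table.empty:
        table["class"] = pd.Series(dtype=object)
        return table
    if threshold is None:
        threshold = score_threshold(table["contrast_score"].to_numpy())
    # the calibrated threshold is the top of the lower (lysed) class
    table["class"] = np.where(
        table["contrast_score"] <= threshold, LYSED, INTACT
    )
    return table


def count_cells(img, cells: list[CellRegion],
                border_margin: float | None = None) -> int:
    """Count cells excluding those touching the image border."""
    px = as_pixels(img)
    n = 0
    for cell in cells:
        margin = cell.max_extent if border_margin is None else border_margin
        r0, c0 = cell.centroid
        if (r0 - margin < 0 or c0 - margin < 0
                or r0 + margin > px.shape[0] - 1 or c0 + margin > px.shape[1] - 1):
            continue
        n += 1
    return n


def percent_lysis(classified: pd.DataFrame) -> tuple[float, int, int]:
    """% lysed cells with counts: 100 * lysed / total."""
    if classified.empty:
        raise ValidationError("no classified cells")
    n_total = len(classified)
    n_lysed = int((classified["class"] == LYSED).sum())
    return 100.0 * n_lysed / n_total, n_lysed, n_total


def percent_lysis_by_counts(n_before: int, n_intact_after: int
                            ) -> tuple[float, int, int]:
    """% lysis from the before/after counting protocol.

    Cells are counted before incubation; after incubation only cells still
    classified intact are counted.  Cells that lysed beyond detection are
    thereby counted as lysed.
    """
    if n_before <= 0:
        raise ValidationError("need >= 1 cell before incubation")
    n_lost = max(n_before - n_intact_after, 0)
    return 100.0 * n_lost / n_before, n_lost, n_before


def mdp_lysis_association(records: pd.DataFrame,
                          alpha: float = stats.ALPHA_DEFAULT,
                          min_cells: int = MIN_CELLS_ASSOCIATION,
                          enforce_min: bool = True) -> pd.DataFrame:
    """Pre-treatment MDP vs lysis fate, one unpaired t-test per donor.

    ``records`` needs columns donor_id, pre_mdp, class.  Per donor the mean
    ± SEM of the pre-treatment MDP is reported for intact and lysed cells,
    with a Welch t-test per donor and Holm–Šidák adjustment across donors.
    Donors with a single class (or fewer than 2 cells in a class) are
    skipped and logged.
    """
    rows = []
    for donor, grp in records.groupby("donor_id", sort=True):
        intact = grp.loc[grp["class"] == INTACT, "pre_mdp"].to_numpy()
        lysed = grp.loc[grp["class"] == LYSED, "pre_mdp"].to_numpy()
        if len(intact) < 2 or len(lysed) < 2:
            logger.warning("donor %s skipped: class with < 2 cells", donor)
            continue
        if enforce_min and len(grp) < min_cells:
            raise ValidationError(
                f"donor {donor}: fewer than {min_cells} cells"
            )
        r = stats.welch_t(lysed, intact)   # positive diff = lysed higher MDP
        rows.append((donor, len(intact), len(lysed),
                     intact.mean(), stats.sem(intact),
                     lysed.mean(), stats.sem(lysed),
                     r.mean_diff, r.statistic, r.df, r.pvalue))
    if not rows:
        raise ValidationError("no donor had both classes")
    table = pd.DataFrame(
        rows, columns=["donor_id", "n_intact", "n_lysed",
                       "mean_intact", "sem_intact", "mean_lysed", "sem_lysed",
                       "mean_diff", "statistic", "df", "p_raw"],
    )
    p_adj, reject = stats.holm_sidak(table["p_raw"].to_numpy(), alpha)
    table["p_adj"] = p_adj
    table["significant"] = reject
    return table
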