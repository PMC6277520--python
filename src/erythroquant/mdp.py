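"""Ratiometric quantification of the membrane dipole potential (MDP).

The MDP — the potential set up by oriented lipid head-group and water
dipoles at the membrane surface — is read out with a voltage-sensitive
styryl dye whose two-channel fluorescence ratio shifts with the potential.
Each cell yields one background-subtracted channel ratio, converted to
millivolts through a linear calibration; donors are screened for a
treatment effect with one unpaired t-test per donor under a Holm–Šidák
family correction, and multi-condition experiments are compared with
one-way ANOVA plus Dunnett's many-to-one test against the control.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .types import CellRegion, ValidationError, as_pixels

logger = logging.getLogger(__name__)

MIN_CELLS_DONOR_SCREEN = 50    # per-treatment minimum for the donor screen
MIN_CELLS_CONDITION_ANOVA = 100


class UndefinedRatioError(ValidationError):
    """Denominator channel is nonpositive after background subtraction."""


@dataclass(frozen=True)
class Calibration:
    """Linear map between channel ratio and dipole potential.

    ratio = intercept + slope * mdp_mV.  The default is an identity-like
    placeholder; a real calibration must be supplied for physical
    millivolt output.
    """

    slope: float = 1.0       # ratio units per mV
    intercept: float = 1.0   # ratio at 0 mV

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValidationError("calibration slope must be nonzero")


def ratio_to_mdp(ratio, cal: Calibration):
    """Invert the calibration: mdp = (ratio - intercept) / slope."""
    return (np.asarray(ratio, dtype=float) - cal.intercept) / cal.slope


def mdp_to_ratio(mdp, cal: Calibration):
    return cal.intercept + cal.slope * np.asarray(mdp, dtype=float)


def _annulus_background(px: np.ndarray, cell: CellRegion, gap: float,
                        width: float) -> float:
    from .segment import local_background

    labels = np.zeros(px.shape, dtype=int)
    labels[cell.coords[:, 0], cell.coords[:, 1]] = 1
    return local_background(px, labels, 1, gap, width)


def per_cell_ratio(chan_a, chan_b, cell: CellRegion,
                   background_a: float | None = None,
                   background_b: float | None = None,
                   annulus_gap: float = 2.0, annulus_width: float = 2.0) -> float:
    """Background-subtracted channel ratio of one cell.

    ratio = mean(chanA - bgA over the cell) / mean(chanB - bgB over the
    cell).  Backgrounds default to the median of an annulus just outside
    the region in each channel (the same annulus rule segmentation uses).
    Raises :class:`UndefinedRatioError` when the denominator is
    nonpositive; callers exclude and log such cells.
    """
    a = as_pixels(chan_a)
    b = as_pixels(chan_b)
    if a.shape != b.shape:
        raise ValidationError("channels must be co-registered with equal shape")
    if background_a is None:
        background_a = _annulus_background(a, cell, annulus_gap, annulus_width)
    if background_b is None:
        background_b = _annulus_background(b, cell, annulus_gap, annulus_width)
    num = a[cell.coords[:, 0], cell.coords[:, 1]].mean() - background_a
    den = b[cell.coords[:, 0], cell.coords[:, 1]].mean() - background_b
    if den <= 0:
        raise UndefinedRatioError(
            f"cell {cell.label}: denominator channel <= background"
        )
    return float(num / den)


def quantify_cells(chan_a, chan_b, cells: list[CellRegion], cal: Calibration,
                   condition: str = "", donor_id: str = "",
                   annulus_gap: float = 2.0,
                   annulus_width: float = 6.0) -> pd.DataFrame:
    """Per-cell ratio and calibrated MDP records for one field of view.

    Per-cell channel backgrounds are annulus medians with every segmented
    region excluded, so a neighbouring cell cannot contaminate the
    estimate.  Cells with an undefined ratio are excluded and logged.
    Columns: donor_id, condition, cell_id, ratio, mdp_mv.
    """
    from .segment import local_background

    a = as_pixels(chan_a)
    b = as_pixels(chan_b)
    labels = np.zeros(a.shape, dtype=int)
    for cell in cells:
        labels[cell.coords[:, 0], cell.coords[:, 1]] = cell.label
    rows = []
    for cell in cells:
        bg_a = local_background(a, labels, cell.label, annulus_gap, annulus_width)
        bg_b = local_background(b, labels, cell.label, annulus_gap, annulus_width)
        try:
            r = per_cell_ratio(chan_a, chan_b, cell,
                               background_a=bg_a, background_b=bg_b)
        except UndefinedRatioError as exc:
            logger.warning("excluding cell: %s", exc)
            continue
        rows.append((donor_id, condition, cell.label, r, float(ratio_to_mdp(r, cal))))
    return pd.DataFrame(
        rows, columns=["donor_id", "condition", "cell_id", "ratio", "mdp_mv"]
    )


def donor_screen(records: pd.DataFrame, control: str = "control",
                 treated: str | None = None, value: str = "mdp_mv",
                 alpha: float = stats.ALPHA_DEFAULT,
                 min_cells: int = MIN_CELLS_DONOR_SCREEN,
                 enforce_min: bool = True) -> pd.DataFrame:
    """Per-donor treatment screen: one unpaired t-test per donor.

    For each donor, Welch's t compares the control arm against the treated
    arm; p-values are Holm–Šidák-adjusted across donors (the family is the
    rows of the screen).  Donors missing an arm are skipped and logged.
    """
    conditions = sorted(records["condition"].unique())
    if treated is None:
        others = [c for c in conditions if c != control]
        if len(others) != 1:
            raise ValidationError(
                f"cannot infer treated condition from {conditions}; pass treated="
            )
        treated = others[0]
    rows = []
    for donor, grp in records.groupby("donor_id", sort=True):
        x = grp.loc[grp["condition"] == control, value].to_numpy()
        y = grp.loc[grp["condition"] == treated, value].to_numpy()
        if len(x) < 2 or len(y) < 2:
            logger.warning("donor %s skipped: missing arm", donor)
            continue
        if enforce_min and (len(x) < min_cells or len(y) < min_cells):
            raise ValidationError(
                f"donor {donor}: fewer than {min_cells} cells per treatment"
            )
        r = stats.welch_t(x, y)
        rows.append((donor, len(x), len(y), x.mean(), y.mean(),
                     r.mean_diff, r.statistic, r.df, r.pvalue))
    if not rows:
        raise ValidationError("no donor had both arms")
    table = pd.DataFrame(
        rows, columns=["donor_id", "n_control", "n_treated", "mean_control",
                       "mean_treated", "mean_diff", "statistic", "df", "p_raw"],
    )
    p_adj, reject = stats.holm_sidak(table["p_raw"].to_numpy(), alpha)
    table["p_adj"] = p_adj
    table["significant"] = reject
    return table


def condition_anova(records: pd.DataFrame, control: str = "control",
                    value: str = "mdp_mv", alpha: float = stats.ALPHA_DEFAULT,
                    min_cells: int = MIN_CELLS_CONDITION_ANOVA,
                    enforce_min: bool = True):
    """One-way ANOVA across conditions plus Dunnett comparisons vs control.

    Used for single-donor multi-treatment designs (e.g. control vs
    immunotoxin vs antibody-only vs toxin-only).  Returns
    (F, p_anova, dunnett_table).
    """
    conditions = sorted(records["condition"].unique())
    if control not in conditions:
        raise ValidationError(f"control condition {control!r} absent")
    if len(conditions) < 2:
        raise ValidationError("need >= 2 conditions")
    groups, labels = [], []
    for cond in [control] + [c for c in conditions if c != control]:
        g = records.loc[records["condition"] == cond, value].to_numpy()
        if len(g) < 2:
            raise ValidationError(f"condition {cond!r} has fewer than 2 cells")
        if enforce_min and len(g) < min_cells:
            raise ValidationError(
                f"condition {cond!r}: fewer than {min_cells} cells"
            )
        groups.append(g)
        labels.append(cond)
    return stats.anova_dunnett(groups, control_index=0, alpha=alpha, labels=labels)
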