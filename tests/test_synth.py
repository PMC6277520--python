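"""Generator contracts: determinism, analytic rendering, scene validity."""
import dataclasses

import numpy as np
import pytest
from scipy import ndimage
from skimage import morphology

from erythroquant import mdp as mdpmod, synth
from erythroquant.types import ValidationError


def test_empty_scene_is_uniform_background():
    truth = synth.SceneTruth(shape=(40, 50), cells=(), background_level=1000.0)
    img, out = synth.generate_rbc_field(truth)
    assert np.all(img.pixels == 1000.0)
    assert out.cells == ()


def test_each_intact_cell_hosts_the_transmitted_minimum(small_field):
    """Brute-force enumeration: every sub-background regional minimum of the
    transmitted intensity lies inside exactly one of the 25 cells (the
    absorbing ring), and all 25 cells are represented."""
    img, truth = small_field
    px = img.pixels
    minima = morphology.local_minima(px, connectivity=2)
    comps, n = ndimage.label(minima, structure=np.ones((3, 3)))
    centers = np.array([c.center for c in truth.cells])
    hosts = set()
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(comps == lab)
        if px[rows, cols].min() >= truth.background_level:
            continue  # the flat background plateau
        cy, cx = rows.mean(), cols.mean()
        d = np.hypot(centers[:, 0] - cy, centers[:, 1] - cx)
        j = int(np.argmin(d))
        assert d[j] <= truth.cells[j].radius, "minimum outside every cell"
        hosts.add(j)
    assert len(hosts) == len(truth.cells) == 25


def test_rendered_cell_matches_analytic_radial_absorbance(single_cell_scene):
    """Per-radius means of the rendered cell equal the analytic transmitted
    intensity averaged over the same pixel distances (fine-grid oracle)."""
    img, truth = single_cell_scene
    cell = truth.cells[0]
    bg = truth.background_level
    rr, cc = np.mgrid[0:64, 0:64]
    d = np.hypot(rr - cell.center[0], cc - cell.center[1])
    inside = d <= cell.radius
    bins = np.round(d[inside]).astype(int)
    rendered = img.pixels[inside]
    for b in range(int(cell.radius)):
        sel = bins == b
        if not sel.any():
            continue
        # oracle: Beer-Lambert of the thickness function at each distance
        analytic = bg * 10.0 ** (
            -synth.cell_absorbance(d[inside][sel], cell.radius, cell.state,
                                   cell.peak_absorbance)
        )
        assert rendered[sel].mean() == pytest.approx(analytic.mean(), abs=1e-9)


def test_discocyte_signature_center_dimmer_than_ring():
    """Absorbance is unimodal in radius with a dimple: lower at r = 0 than
    at the ring peak, and low again at the rim."""
    r = np.linspace(0, 8, 200)
    a = synth.cell_absorbance(r, 8.0, synth.INTACT, 0.8)
    peak = int(np.argmax(a))
    assert a[0] < a[peak]
    assert a[-1] < a[peak]
    assert 0 < r[peak] < 8
    # unimodal: non-decreasing to the peak, non-increasing after
    assert np.all(np.diff(a[: peak + 1]) >= -1e-12)
    assert np.all(np.diff(a[peak:]) <= 1e-12)


def test_bit_identical_regeneration():
    truth = synth.make_rbc_scene(10, snr=5, seed=7)
    img1, _ = synth.generate_rbc_field(truth)
    img2, _ = synth.generate_rbc_field(truth)
    assert np.array_equal(img1.pixels, img2.pixels)


def test_noiseless_scene_independent_of_seed():
    t1 = synth.SceneTruth(shape=(40, 40),
                          cells=(synth.CellSpec((20.0, 20.0), 6.0),), seed=1)
    t2 = dataclasses.replace(t1, seed=99)
    img1, _ = synth.generate_rbc_field(t1)
    img2, _ = synth.generate_rbc_field(t2)
    assert np.array_equal(img1.pixels, img2.pixels)


@pytest.mark.parametrize(
    "cells",
    [
        (synth.CellSpec((3.0, 20.0), 6.0),),                     # leaves frame
        (synth.CellSpec((20.0, 20.0), 6.0),
         synth.CellSpec((24.0, 20.0), 6.0)),                     # overlapping
    ],
)
def test_invalid_placement_rejected(cells):
    truth = synth.SceneTruth(shape=(40, 40), cells=cells)
    with pytest.raises(synth.PlacementError):
        synth.generate_rbc_field(truth)


def test_cellspec_validation():
    with pytest.raises(ValidationError):
        synth.CellSpec((10.0, 10.0), radius=-1.0)
    with pytest.raises(ValidationError):
        synth.CellSpec((10.0, 10.0), radius=5.0, state="ghost")
    with pytest.raises(ValidationError):
        synth.SceneTruth(shape=(20, 20), noise_sd=-1.0)


# ---------------------------------------------------------------- ratiometric


CAL = mdpmod.Calibration(slope=2e-3, intercept=0.4)


def test_single_cell_ratio_equals_target_by_construction():
    target = 2.0
    mdp_val = (target - CAL.intercept) / CAL.slope
    cell = synth.CellSpec((20.0, 20.0), 6.0, true_mdp=mdp_val)
    truth = synth.SceneTruth(shape=(40, 40), cells=(cell,), background_level=0.0)
    a, b, _ = synth.generate_ratiometric_pair(truth, CAL)
    disc = a.pixels > 0
    assert a.pixels[disc].mean() / b.pixels[disc].mean() == pytest.approx(2.0)


def test_all_target_ratios_recovered_exactly_noiseless():
    truth = synth.make_ratiometric_scene(50, seed=3)
    a, b, truth = synth.generate_ratiometric_pair(truth, CAL)
    bg = truth.background_level
    for cell in truth.cells:
        rr, cc = np.mgrid[0:truth.shape[0], 0:truth.shape[1]]
        disc = np.hypot(rr - cell.center[0], cc - cell.center[1]) <= cell.radius
        ratio = (a.pixels[disc].mean() - bg) / (b.pixels[disc].mean() - bg)
        target = CAL.intercept + CAL.slope * cell.true_mdp
        assert ratio == pytest.approx(target, rel=1e-12)


def test_pure_mdp_shift_moves_every_ratio_by_slope_times_delta():
    delta = 40.0
    truth = synth.make_ratiometric_scene(10, seed=5)
    shifted = dataclasses.replace(
        truth,
        cells=tuple(dataclasses.replace(c, true_mdp=c.true_mdp + delta)
                    for c in truth.cells),
    )
    a1, b1, _ = synth.generate_ratiometric_pair(truth, CAL)
    a2, b2, _ = synth.generate_ratiometric_pair(shifted, CAL)
    bg = truth.background_level
    for cell in truth.cells:
        rr, cc = np.mgrid[0:truth.shape[0], 0:truth.shape[1]]
        disc = np.hypot(rr - cell.center[0], cc - cell.center[1]) <= cell.radius
        r1 = (a1.pixels[disc].mean() - bg) / (b1.pixels[disc].mean() - bg)
        r2 = (a2.pixels[disc].mean() - bg) / (b2.pixels[disc].mean() - bg)
        assert r2 - r1 == pytest.approx(CAL.slope * delta, rel=1e-9)


def test_missing_mdp_rejected():
    truth = synth.SceneTruth(shape=(40, 40),
                             cells=(synth.CellSpec((20.0, 20.0), 6.0),))
    with pytest.raises(ValidationError):
        synth.generate_ratiometric_pair(truth, CAL)


# --------------------------------------------------------------------- vessel


def test_flat_profile_limit_all_intima_at_surface_intensity():
    truth = synth.make_annular_vessel(decay_length=np.inf, background_level=0.0)
    img, truth = synth.generate_vessel_section(truth)
    assert np.allclose(img.pixels[truth.intima_mask], truth.surface_intensity)


def test_intima_intensity_follows_brute_force_lumen_distance():
    """Noiseless intensities equal I0*exp(-d/10) with d recomputed by
    exhaustive nearest-lumen-pixel search."""
    truth = synth.make_annular_vessel(shape=(80, 80), lumen_radius=15.0,
                                      wall_thickness=20.0, decay_length=10.0,
                                      background_level=0.0)
    img, truth = synth.generate_vessel_section(truth)
    lum = np.argwhere(truth.lumen_mask)
    for r, c in np.argwhere(truth.intima_mask)[::17]:
        d = np.min(np.hypot(lum[:, 0] - r, lum[:, 1] - c))
        assert img.pixels[r, c] == pytest.approx(
            truth.surface_intensity * np.exp(-d / 10.0), rel=1e-9
        )


def test_noiseless_vessel_independent_of_seed():
    t1 = synth.make_annular_vessel(seed=0)
    t2 = synth.make_annular_vessel(seed=123)
    img1, _ = synth.generate_vessel_section(t1)
    img2, _ = synth.generate_vessel_section(t2)
    assert np.array_equal(img1.pixels, img2.pixels)


def test_vessel_truth_validation():
    good = synth.make_annular_vessel()
    with pytest.raises(ValidationError):
        synth.VesselTruth(lumen_mask=good.lumen_mask,
                          intima_mask=good.lumen_mask)   # not disjoint
    with pytest.raises(ValidationError):
        synth.VesselTruth(lumen_mask=good.lumen_mask,
                          intima_mask=np.zeros_like(good.lumen_mask))
    with pytest.raises(ValidationError):
        synth.VesselTruth(lumen_mask=good.lumen_mask,
                          intima_mask=good.intima_mask, decay_length=0.0)
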