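"""Segmentation stages against brute-force and geometric oracles."""
import numpy as np
import pytest

from erythroquant import segment, synth
from erythroquant.segment import (
    DegenerateImageError,
    NoScaleError,
    SegmentationConfig,
    ball_structuring_element,
    otsu_threshold,
    rolling_ball_background,
    size_filter,
    split_touching,
)
from erythroquant.types import ValidationError
from oracles import ball_opening_oracle, otsu_oracle


# ----------------------------------------------------------------- scale


def test_uniform_image_has_no_scale():
    with pytest.raises(NoScaleError):
        segment.estimate_cell_scale(np.full((64, 64), 5.0))


def test_scale_estimate_matches_cell_radius(small_field):
    img, truth = small_field
    r = segment.estimate_cell_scale(img)
    assert abs(r - 8.0) <= 2.0


def test_scale_estimate_doubles_when_image_upscaled(small_field):
    img, truth = small_field
    r1 = segment.estimate_cell_scale(img)
    upscaled = np.kron(img.pixels, np.ones((2, 2)))
    r2 = segment.estimate_cell_scale(
        upscaled, sigma_grid=tuple(np.arange(2.0, 20.0, 0.5))
    )
    assert r2 == pytest.approx(2 * r1, rel=0.25)


# ---------------------------------------------------------- rolling ball


def test_flat_field_background_is_the_field():
    flat = np.full((32, 32), 7.5)
    bg, corrected = rolling_ball_background(flat, 4)
    assert np.allclose(bg, 7.5)
    assert np.allclose(corrected, 0.0)


def test_small_disc_preserved_on_flat_background():
    """A bright disc narrower than the ball passes into the corrected
    image; the background stays at the base level under it."""
    img = np.full((48, 48), 10.0)
    rr, cc = np.mgrid[0:48, 0:48]
    disc = np.hypot(rr - 24, cc - 24) <= 3
    img[disc] += 50.0
    bg, corrected = rolling_ball_background(img, 8)
    oracle = ball_opening_oracle(img, 8)
    assert np.allclose(bg, oracle, atol=1e-9)
    assert bg[24, 24] == pytest.approx(10.0, abs=1.0)
    assert corrected[24, 24] == pytest.approx(50.0, abs=1.0)


def test_slow_ramp_absorbed_into_background():
    ramp = np.tile(np.linspace(0, 5, 40), (40, 1))
    bg, corrected = rolling_ball_background(ramp, 30)
    oracle = ball_opening_oracle(ramp, 30)
    assert np.allclose(bg, oracle, atol=1e-9)
    assert np.max(corrected) <= 0.6   # ramp (slope ~0.13/px) mostly absorbed


def test_rolling_ball_matches_oracle_on_random_images(rng):
    img = rng.uniform(0, 100, (40, 40))
    bg, _ = rolling_ball_background(img, 5)
    assert np.allclose(bg, ball_opening_oracle(img, 5), atol=1e-9)
    assert np.all(bg <= img + 1e-12)


def test_rolling_ball_rejects_small_radius():
    with pytest.raises(ValidationError):
        rolling_ball_background(np.zeros((10, 10)), 0.5)


# ------------------------------------------------------------------ Otsu


def test_two_value_image_split_exactly():
    img = np.array([[10.0] * 6 + [200.0] * 4] * 5)
    t, mask = otsu_threshold(img)
    assert 10.0 <= t < 200.0
    assert np.array_equal(mask, img == 200.0)


@pytest.mark.parametrize("n_levels", [2, 3, 5, 8, 16])
def test_otsu_equals_exhaustive_search(n_levels, rng):
    for _ in range(5):
        img = rng.integers(0, n_levels, (24, 24)).astype(float)
        if np.unique(img).size < 2:
            continue
        t, _ = otsu_threshold(img)
        assert t == otsu_oracle(img)


def test_inverted_image_flips_mask():
    img = np.array([[10.0] * 6 + [200.0] * 4] * 5)
    _, mask = otsu_threshold(img)
    _, mask_inv = otsu_threshold(img.max() - img)
    assert np.array_equal(mask_inv, ~mask)


def test_constant_image_degenerate():
    with pytest.raises(DegenerateImageError):
        otsu_threshold(np.full((8, 8), 3.0))


# ------------------------------------------------------------- watershed


def _disc_mask(shape, centers, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for r0, c0 in centers:
        mask |= np.hypot(rr - r0, cc - c0) <= radius
    return mask


def test_isolated_disc_stays_one_region():
    mask = _disc_mask((40, 40), [(20, 20)], 10)
    labels = split_touching(mask)
    assert labels.max() == 1
    assert np.array_equal(labels > 0, mask)


def test_two_overlapping_discs_split_at_the_bisector():
    mask = _disc_mask((40, 60), [(20, 23), (20, 37)], 10)
    labels = split_touching(mask)
    assert labels.max() == 2
    assert (labels > 0).sum() == mask.sum()     # conservation
    cc = np.indices(mask.shape)[1]
    # the geometric bisector is the column midway between the centres
    left = cc[labels == labels[20, 23]]
    right = cc[labels == labels[20, 37]]
    assert left.max() <= 31 and right.min() >= 30


def test_three_disc_chain_splits_into_three_even_regions():
    mask = _disc_mask((40, 80), [(20, 20), (20, 36), (20, 52)], 10)
    labels = split_touching(mask)
    assert labels.max() == 3
    disc_area = np.pi * 100
    for lab in (1, 2, 3):
        assert (labels == lab).sum() == pytest.approx(disc_area, rel=0.15)


def test_empty_mask_gives_empty_labels():
    assert split_touching(np.zeros((10, 10), dtype=bool)).max() == 0


# ----------------------------------------------------------- size filter


def test_size_filter_retains_only_in_bounds():
    labels = np.zeros((80, 80), dtype=int)
    labels[0, :5] = 1                       # area 5
    labels[10:22, 10:20] = 2                # area 120
    labels[30:80, 30:80] = 3                # area 2500
    out = size_filter(labels, 50, 1000)
    assert set(np.unique(out)) == {0, 1}
    assert (out == 1).sum() == 120


def test_size_filter_wide_bounds_is_identity_up_to_relabel():
    labels = np.zeros((20, 20), dtype=int)
    labels[2:6, 2:6] = 3
    labels[10:15, 10:15] = 7
    out = size_filter(labels, 1, 10000)
    assert np.array_equal(out > 0, labels > 0)
    assert set(np.unique(out)) == {0, 1, 2}


def test_size_filter_matches_brute_force_area_scan(rng):
    from scipy import ndimage as ndi
    mask = rng.uniform(size=(48, 48)) < 0.3
    labels, _ = ndi.label(mask)
    lo, hi = 3, 12
    out = size_filter(labels, lo, hi)
    kept_out = {frozenset(map(tuple, np.argwhere(out == lab)))
                for lab in range(1, out.max() + 1)}
    kept_oracle = set()
    for lab in range(1, labels.max() + 1):
        coords = np.argwhere(labels == lab)
        if lo <= len(coords) <= hi:
            kept_oracle.add(frozenset(map(tuple, coords)))
    assert kept_out == kept_oracle


def test_size_filter_validates_bounds():
    with pytest.raises(ValidationError):
        size_filter(np.zeros((5, 5), dtype=int), 10, 5)


# -------------------------------------------------------------- pipeline


def test_segment_cells_recovers_all_cells_noiseless(small_field):
    img, truth = small_field
    cells, labels = segment.segment_cells(img)
    assert len(cells) == 25
    matches, errors = segment.match_detections(
        [c.centroid for c in cells], [c.center for c in truth.cells]
    )
    assert len(matches) == 25
    assert errors.max() <= 2.0


def test_segment_cells_empty_scene():
    truth = synth.SceneTruth(shape=(64, 64), cells=())
    img, _ = synth.generate_rbc_field(truth)
    cells, labels = segment.segment_cells(img)
    assert cells == []
    assert labels.max() == 0


def test_pipeline_is_deterministic(small_field):
    img, _ = small_field
    _, labels1 = segment.segment_cells(img)
    _, labels2 = segment.segment_cells(img)
    assert np.array_equal(labels1, labels2)


def test_local_background_recovers_field_level(small_field):
    img, truth = small_field
    cells, _ = segment.segment_cells(img)
    bgs = np.array([c.local_background for c in cells])
    # annulus sits in the halo-free zone; background is the illumination level
    assert np.all(np.abs(bgs - truth.background_level) <= 30.0)
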