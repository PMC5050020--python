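import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage import draw, measure

from quadfoci.foci import (
    ThresholdConfig,
    count_cells,
    estimate_foci_count,
    gate_by_blue,
    label_objects,
    quantify_image,
    threshold_channel,
    trimmed_mean_area,
)
from quadfoci.io import MultichannelImage, QuadfociError
from quadfoci.simulate import SimImageSpec, generate_image


def _image(red, blue, green=None, px=0.2):
    green = green if green is not None else np.zeros_like(red)
    return MultichannelImage(red=red, green=green, blue=blue, pixel_size_um=px)


# ---------------------------------------------------------------- threshold


def test_threshold_boundary_inclusive():
    plane = np.array([[0.0, 0.0999, 0.1, 0.5, 1.0]])
    assert threshold_channel(plane, 0.1).tolist() == [[False, False, True, True, True]]


def test_threshold_extremes():
    assert not threshold_channel(np.zeros((3, 3)), 0.1).any()
    assert threshold_channel(np.ones((3, 3)), 0.1).all()


def test_threshold_rejects_out_of_range():
    with pytest.raises(QuadfociError):
        threshold_channel(np.zeros((2, 2)), 1.5)


def test_threshold_matches_planted_disk_exactly():
    plane = np.full((64, 64), 0.02)
    rr, cc = draw.disk((32, 32), 6)
    plane[rr, cc] = 0.5
    mask = threshold_channel(plane, 0.1)
    expected = np.zeros_like(mask)
    expected[rr, cc] = True
    assert np.array_equal(mask, expected)


# ------------------------------------------------------------------ gating


def test_gate_removes_object_without_blue_overlap():
    red = np.zeros((10, 10), dtype=bool)
    red[1:3, 1:3] = True
    blue = np.zeros_like(red)
    blue[7:9, 7:9] = True
    assert not gate_by_blue(red, blue).any()


def test_gate_keeps_whole_object_on_single_pixel_overlap():
    red = np.zeros((10, 10), dtype=bool)
    red[2:6, 2:6] = True
    blue = np.zeros_like(red)
    blue[2, 2] = True  # one corner pixel
    assert np.array_equal(gate_by_blue(red, blue), red)


def test_gate_shape_mismatch_fatal():
    with pytest.raises(QuadfociError):
        gate_by_blue(np.zeros((3, 3), dtype=bool), np.zeros((4, 4), dtype=bool))


@pytest.mark.parametrize("seed", range(5))
def test_gate_matches_brute_force_object_oracle(seed):
    """On random scenes the gated set equals a per-object overlap test."""
    rng = np.random.default_rng(seed)
    red = rng.uniform(size=(48, 48)) > 0.7
    blue = rng.uniform(size=(48, 48)) > 0.8
    gated = gate_by_blue(red, blue, connectivity=8)
    labels = measure.label(red, connectivity=2)
    expected = np.zeros_like(red)
    for lab in range(1, labels.max() + 1):
        obj = labels == lab
        if (obj & blue).any():
            expected |= obj
    assert np.array_equal(gated, expected)


def test_gate_monotone_in_blue_coverage():
    rng = np.random.default_rng(3)
    red = rng.uniform(size=(40, 40)) > 0.75
    blue_small = rng.uniform(size=(40, 40)) > 0.9
    blue_big = blue_small | (rng.uniform(size=(40, 40)) > 0.85)
    kept_small = gate_by_blue(red, blue_small)
    kept_big = gate_by_blue(red, blue_big)
    assert (kept_small & ~kept_big).sum() == 0  # enlarging blue never removes


# ---------------------------------------------------------------- labeling


def test_diagonal_pixels_connectivity():
    mask = np.zeros((5, 5), dtype=bool)
    mask[1, 1] = mask[2, 2] = True
    eight = label_objects(mask, connectivity=8)
    four = label_objects(mask, connectivity=4)
    assert len(eight) == 1 and eight[0].area_px == 2
    assert len(four) == 2 and all(o.area_px == 1 for o in four)


def test_label_objects_scale_equivariance():
    mask = np.zeros((20, 20), dtype=bool)
    mask[2:6, 3:9] = True
    (obj,) = label_objects(mask, pixel_size_um=0.25)
    assert obj.area_px == 24
    assert obj.area_um2 == pytest.approx(24 * 0.25**2)
    assert obj.max_dim_um == pytest.approx(6 * 0.25)


def test_planted_disks_measured_exactly():
    spec = SimImageSpec(
        shape=(256, 256), n_cells=4, foci_per_cell_mean=6.0,
        green_foci_per_cell_mean=0.0, noise_sd=0.0,
    )
    image, truth = generate_image(spec, seed=11)
    mask = threshold_channel(image.red, 0.1)
    objects = label_objects(mask, 8, spec.pixel_size_um)
    assert len(objects) == truth.n_red_foci
    assert sum(o.area_px for o in objects) == truth.red_area_px


# -------------------------------------------------------------- trimmed mean


def test_trimmed_mean_removes_ten_percent_tails():
    assert trimmed_mean_area(list(range(1, 11)), 0.10) == pytest.approx(5.5)


def test_trimmed_mean_short_lists_fall_back_to_mean():
    assert trimmed_mean_area([4.0], 0.10) == 4.0
    assert trimmed_mean_area([2.0, 6.0], 0.10) == 4.0


def test_trimmed_mean_empty_is_error():
    with pytest.raises(QuadfociError):
        trimmed_mean_area([], 0.10)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    areas=st.lists(st.floats(0.5, 1e4), min_size=1, max_size=400),
    trim=st.floats(0.0, 0.49),
)
def test_trimmed_mean_matches_sort_and_slice_oracle(areas, trim):
    got = trimmed_mean_area(areas, trim)
    s = sorted(areas)
    n = len(s)
    if n < 3:
        expected = sum(s) / n
    else:
        k = int(np.floor(trim * n))
        kept = s[k : n - k]
        expected = sum(kept) / len(kept)
    assert got == pytest.approx(expected, abs=1e-9, rel=1e-9)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(area=st.floats(1, 1e3), n=st.integers(1, 50), trim=st.floats(0, 0.49))
def test_trimmed_mean_invariant_for_equal_areas(area, n, trim):
    assert trimmed_mean_area([area] * n, trim) == pytest.approx(area)


def test_trimmed_mean_lognormal_against_oracle():
    rng = np.random.default_rng(5)
    areas = rng.lognormal(2.0, 0.5, size=1000)
    s = np.sort(areas)
    k = int(np.floor(0.10 * 1000))
    assert trimmed_mean_area(areas, 0.10) == pytest.approx(s[k:-k].mean(), abs=1e-9)


# ---------------------------------------------------------------- counting


def test_equal_area_objects_give_exact_count():
    mask = np.zeros((40, 40), dtype=bool)
    for i in range(6):  # six 2x2 squares
        mask[5 * i + 1 : 5 * i + 3, 1:3] = True
    objects = label_objects(mask)
    areas = [o.area_px for o in objects]
    count = estimate_foci_count(sum(areas), trimmed_mean_area(areas, 0.10))
    assert count == pytest.approx(6.0)


def test_empty_image_count_zero():
    assert estimate_foci_count(0, float("nan")) == 0.0


def test_count_cells_min_area_filter():
    px = 1.0  # 1 um pixels: areas in px == um2
    blue = np.zeros((40, 40))
    rr, cc = draw.disk((10, 10), 4)  # ~45 um2 nucleus
    blue[rr, cc] = 0.6
    rr, cc = draw.disk((30, 30), 2)  # ~12 um2 debris, below the 20 um2 floor
    blue[rr, cc] = 0.6
    cfg = ThresholdConfig()
    assert count_cells(blue, cfg, px) == 1


def test_count_cells_blank_plane():
    assert count_cells(np.zeros((20, 20)), ThresholdConfig(), 0.2) == 0


# ------------------------------------------------------------- full pipeline


def test_quantify_blank_scene():
    spec = SimImageSpec(
        shape=(256, 256), n_cells=5, foci_per_cell_mean=0.0,
        green_foci_per_cell_mean=0.0,
    )
    image, truth = generate_image(spec, seed=3)
    res = quantify_image(image)
    assert res.foci_count == 0.0
    assert res.area_total_px == 0
    assert res.n_cells == truth.n_cells


def test_quantify_recovers_planted_count(small_spec):
    image, truth = generate_image(small_spec, seed=21)
    res = quantify_image(image)
    assert res.n_cells == truth.n_cells
    assert res.foci_count == pytest.approx(truth.n_red_foci, rel=0.10)


def test_threshold_invariance_to_brightening():
    image, _ = generate_image(SimImageSpec(shape=(256, 256), n_cells=4), seed=9)
    res = quantify_image(image)
    brighter = MultichannelImage(
        red=np.where(image.red >= 0.1, np.minimum(image.red * 2, 1.0), image.red),
        green=image.green,
        blue=image.blue,
        pixel_size_um=image.pixel_size_um,
        source_id=image.source_id,
    )
    res2 = quantify_image(brighter)
    assert res2.foci_count == res.foci_count
    assert res2.area_total_px == res.area_total_px


def test_raising_threshold_never_increases_area(small_spec):
    image, _ = generate_image(small_spec, seed=13)
    areas = []
    for thr in (0.05, 0.1, 0.3, 0.6):
        res = quantify_image(image, ThresholdConfig(red_threshold=thr))
        areas.append(res.area_total_px)
    assert areas == sorted(areas, reverse=True)


def test_per_cell_fields_undefined_without_cells():
    red = np.zeros((30, 30))
    red[5:8, 5:8] = 0.5
    blue = np.zeros((30, 30))
    blue[5, 5] = 0.5  # overlaps red but too small to count as a nucleus
    res = quantify_image(_image(red, blue))
    assert res.n_cells == 0
    assert res.foci_per_cell is None and res.area_per_cell_um2 is None
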