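"""Cortex density/thickness, segmentation, profiles, anisotropy, timing."""

import math

import numpy as np
import pytest
from scipy.ndimage import binary_erosion

from blebmech.errors import (
    EmptyRegion,
    NeverAboveBackground,
    NoBleb,
    NoPeak,
    ZeroMean,
)
from blebmech.morphometry import (
    ArrivalTiming,
    BlebSegmentation,
    ImageFrame,
    bleb_arrival_timing,
    anisotropy_nematic,
    contrast_index,
    leader_bleb_area_percent,
    measure_cortex_density,
    measure_cortex_thickness,
    migration_fraction,
    regional_profile,
    segment_cell_and_bleb,
)
from blebmech.synthetic import gen_cell_image, gen_linescan


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def density_frame(cortex_val, bg_val):
    img = np.full((64, 64), bg_val, dtype=float)
    img[10:20, 10:50] = cortex_val
    frame = ImageFrame(data=img[None], pixel_size=0.1,
                       channel_roles={"cortex_stain": 0})
    # keep the widened 5-px line strictly inside the cortex band
    line = np.array([[15, 14], [15, 45]])
    roi = np.zeros((64, 64), dtype=bool)
    roi[40:50, 40:50] = True
    return frame, line, roi


@pytest.mark.parametrize("cortex,bg,expected", [(100.0, 10.0, 90.0), (10.0, 10.0, 0.0)])
def test_density_is_cortex_minus_background(cortex, bg, expected):
    frame, line, roi = density_frame(cortex, bg)
    assert measure_cortex_density(frame, line, roi) == pytest.approx(expected)


def test_density_invariant_under_constant_offset():
    frame, line, roi = density_frame(100.0, 10.0)
    d0 = measure_cortex_density(frame, line, roi)
    frame.data = frame.data + 37.5
    assert measure_cortex_density(frame, line, roi) == pytest.approx(d0)


def test_density_recovers_generator_rim_amplitude():
    frame, seg, truth = gen_cell_image(noise_sd=0.01, seed=11)
    cy, cx = 128, 80
    # short arc along the rim, away from the neck (neck exits at +x)
    angles = np.linspace(math.pi * 0.6, math.pi * 1.4, 60)
    line = np.column_stack([cy + 58.5 * np.sin(angles), cx + 58.5 * np.cos(angles)])
    roi = np.zeros(frame.data.shape[1:], dtype=bool)
    roi[118:138, 60:90] = True  # cytoplasm inside the body
    d = measure_cortex_density(frame, line, roi, line_width=3, channel="cortex_stain")
    assert d == pytest.approx(truth["rim_amplitude"], rel=0.05)


def test_density_empty_region_raises():
    frame, line, _ = density_frame(100.0, 10.0)
    with pytest.raises(EmptyRegion):
        measure_cortex_density(frame, line, np.zeros((64, 64), bool))


# ---------------------------------------------------------------------------
# thickness
# ---------------------------------------------------------------------------

def test_thickness_noiseless_separation():
    scan, truth = gen_linescan(separation_um=0.2, noise_sd=0.0)
    sep, th = measure_cortex_thickness(scan)
    px = truth["pixel_um"]
    assert abs(sep - 0.2) <= 0.25 * px
    assert th == pytest.approx(2 * sep)


def test_thickness_identical_profiles_zero():
    scan, _ = gen_linescan(separation_um=0.0, noise_sd=0.0)
    sep, th = measure_cortex_thickness(scan)
    assert sep == pytest.approx(0.0, abs=1e-9)
    assert th == pytest.approx(0.0, abs=1e-9)


def test_thickness_subpixel_bias_below_5pct_of_pixel():
    worst = 0.0
    for off in np.linspace(0.0, 1.0, 20):
        scan, truth = gen_linescan(
            separation_um=0.21, center_um=1.5 + off * 0.04, noise_sd=0.0
        )
        sep, _ = measure_cortex_thickness(scan)
        worst = max(worst, abs(sep - 0.21) / truth["pixel_um"])
    assert worst <= 0.05


def test_thickness_correction_hook():
    scan, _ = gen_linescan(separation_um=0.2, noise_sd=0.0)
    sep, th = measure_cortex_thickness(scan, correction=lambda s: 3.0 * s)
    assert th == pytest.approx(3.0 * sep)


def test_thickness_monotone_profile_raises(rng):
    scan, _ = gen_linescan(noise_sd=0.0)
    scan.intensity_a = np.linspace(0, 1, len(scan.positions))
    with pytest.raises(NoPeak):
        measure_cortex_thickness(scan)


# ---------------------------------------------------------------------------
# segmentation & area
# ---------------------------------------------------------------------------

def test_provided_masks_identity():
    _, seg_true, _ = gen_cell_image()
    seg = segment_cell_and_bleb(
        None, "provided_masks",
        body_mask=seg_true.body_mask, bleb_mask=seg_true.bleb_mask,
        axis=seg_true.axis, neck_point=seg_true.neck_point,
    )
    assert np.array_equal(seg.body_mask, seg_true.body_mask)
    assert np.array_equal(seg.bleb_mask, seg_true.bleb_mask)


def test_provided_masks_derives_axis_and_neck():
    _, seg_true, _ = gen_cell_image()
    seg = segment_cell_and_bleb(
        None, "provided_masks",
        body_mask=seg_true.body_mask, bleb_mask=seg_true.bleb_mask,
    )
    assert seg.neck_point is not None and seg.bleb_mask[seg.neck_point]
    # axis spans essentially the full bleb length
    assert len(seg.axis) >= 0.9 * 200


def test_auto_segmentation_jaccard():
    frame, seg_true, _ = gen_cell_image(cap_style="round", noise_sd=0.02, seed=5)
    seg = segment_cell_and_bleb(frame, "threshold_auto", channel="fill")
    inter = (seg.bleb_mask & seg_true.bleb_mask).sum()
    union = (seg.bleb_mask | seg_true.bleb_mask).sum()
    assert inter / union >= 0.9


def test_auto_segmentation_lone_disk_is_nobleb():
    img = np.zeros((128, 128))
    rr, cc = np.mgrid[0:128, 0:128]
    img[(rr - 64) ** 2 + (cc - 64) ** 2 <= 40 ** 2] = 1.0
    with pytest.raises(NoBleb):
        segment_cell_and_bleb(img, "threshold_auto")


def test_area_percent_exact_pixel_arithmetic():
    body = np.zeros((30, 30), bool)
    body[:10, :10] = True  # 100 px
    bleb = np.zeros((30, 30), bool)
    bleb[20:25, 20:30] = True  # 50 px
    seg = BlebSegmentation(body_mask=body, bleb_mask=bleb)
    assert leader_bleb_area_percent(seg) == 50.0


def test_area_percent_no_bleb_is_zero():
    body = np.zeros((30, 30), bool)
    body[:10, :10] = True
    seg = BlebSegmentation(body_mask=body, bleb_mask=np.zeros((30, 30), bool))
    assert leader_bleb_area_percent(seg) == 0.0


def test_area_percent_matches_generator_counts():
    _, seg, truth = gen_cell_image()
    assert leader_bleb_area_percent(seg) == pytest.approx(
        100.0 * truth["bleb_area_px"] / truth["body_area_px"]
    )


# ---------------------------------------------------------------------------
# migration
# ---------------------------------------------------------------------------

def track(displacement, n=13, window=60.0):
    t = np.linspace(0, window, n)
    x = np.linspace(0, displacement, n)
    return np.column_stack([t, x, np.zeros(n)])


def test_migration_fraction_extremes():
    assert migration_fraction([track(0.0)] * 5) == 0.0
    assert migration_fraction([track(50.0)] * 5) == 100.0


def test_migration_fraction_mixed():
    tracks = [track(50.0)] * 3 + [track(2.0)] * 7
    assert migration_fraction(tracks) == pytest.approx(30.0)


def test_migration_uses_window_not_full_track():
    # moves 50 um but only after the 60-min window closes
    t = np.array([0.0, 30.0, 60.0, 120.0])
    x = np.array([0.0, 1.0, 2.0, 50.0])
    tr = np.column_stack([t, x, np.zeros(4)])
    assert migration_fraction([tr]) == 0.0


# ---------------------------------------------------------------------------
# regional profiles
# ---------------------------------------------------------------------------

def test_uniform_bleb_gives_flat_profile():
    frame, seg, _ = gen_cell_image(gradient="uniform")
    prof = regional_profile(frame, seg, channels=["gradient"])
    m = prof.mean_intensity["gradient"]
    assert np.allclose(m, m[0])
    assert np.allclose(prof.normalized_intensity["gradient"], 1.0)


def test_linear_ramp_bin_means_match_analytic():
    frame, seg, truth = gen_cell_image(gradient="linear")
    prof = regional_profile(frame, seg, channels=["gradient"])
    m = prof.mean_intensity["gradient"] - truth["background_level"]
    expected = np.array(truth["bin_means"])
    assert np.all(np.abs(m - expected) / expected < 0.01)


def test_monotone_gradient_gives_strictly_decreasing_bins():
    """Neck-high protein gradients must come out strictly decreasing."""
    frame, seg, _ = gen_cell_image(gradient="linear", noise_sd=0.005, seed=3)
    prof = regional_profile(frame, seg, channels=["gradient"])
    m = prof.mean_intensity["gradient"]
    assert np.all(np.diff(m) < 0)


def test_bins_partition_bleb_exactly():
    frame, seg, _ = gen_cell_image()
    prof = regional_profile(frame, seg, channels=["gradient"])
    assert prof.pixels_per_bin.sum() == seg.bleb_mask.sum()
    assert (prof.pixels_per_bin > 0).all()


# ---------------------------------------------------------------------------
# anisotropy & contrast
# ---------------------------------------------------------------------------

def test_anisotropy_constant_image_zero():
    a, th = anisotropy_nematic(np.full((32, 32), 5.0))
    assert a == 0.0 and math.isnan(th)


def test_anisotropy_vertical_stripes():
    x = np.arange(128)
    img = np.tile(0.5 + 0.5 * np.sin(2 * np.pi * x / 16.0), (128, 1))
    a, th = anisotropy_nematic(img)
    assert a >= 0.99
    assert abs(abs(th) - math.pi / 2) <= math.radians(1.0)


def test_anisotropy_generator_stripes_at_30deg():
    frame, seg, truth = gen_cell_image(fibril_angle_deg=30.0)
    roi = binary_erosion(seg.bleb_mask, iterations=3)
    a, th = anisotropy_nematic(frame.channel("texture"), roi)
    assert a >= 0.95
    assert abs(th - truth["fibril_angle_rad"]) <= math.radians(1.0)


def test_anisotropy_iid_noise_is_isotropic(rng):
    a, _ = anisotropy_nematic(rng.normal(size=(512, 512)))
    assert a <= 0.05


def test_anisotropy_rot90_invariance():
    frame, seg, _ = gen_cell_image(fibril_angle_deg=30.0)
    img = frame.channel("texture")
    a1, t1 = anisotropy_nematic(img)
    a2, t2 = anisotropy_nematic(np.rot90(img))
    assert abs(a1 - a2) <= 1e-6
    dt = abs(t1 - t2) % math.pi
    assert min(dt, math.pi - dt) == pytest.approx(math.pi / 2, abs=1e-9)


def test_anisotropy_affine_intensity_invariance(rng):
    img = rng.normal(size=(64, 64)).cumsum(axis=1)  # anisotropic-ish field
    a1, t1 = anisotropy_nematic(img)
    a2, t2 = anisotropy_nematic(3.7 * img + 11.0)
    assert a1 == pytest.approx(a2, abs=1e-12)
    assert t1 == pytest.approx(t2, abs=1e-12)


def test_contrast_index_closed_forms():
    assert contrast_index(np.full((20, 20), 5.0)) == 0.0
    two = np.zeros((20, 20))
    two[:10] = 10.0  # equal counts of 0 and 10: mean 5, SD 5
    assert contrast_index(two) == pytest.approx(1.0)
    with pytest.raises(ZeroMean):
        contrast_index(np.zeros((20, 20)))


# ---------------------------------------------------------------------------
# arrival timing
# ---------------------------------------------------------------------------

def test_arrival_one_frame_after_max_protrusion():
    protr = np.array([0.0, 1.0, 3.0, 2.0, 1.0, 1.0])  # max at frame 2
    protein = np.array([0.0, 0.0, 0.0, 5.0, 6.0, 6.0])  # rises at frame 3
    t = bleb_arrival_timing(protein, protr, background_level=1.0, frame_interval=5.0)
    assert t.arrival_time == 5.0


def test_arrival_at_time_zero():
    protr = np.array([3.0, 2.0, 1.0, 0.5])
    protein = np.array([5.0, 5.0, 5.0, 5.0])
    t = bleb_arrival_timing(protein, protr, background_level=1.0, frame_interval=5.0)
    assert t.arrival_time == 0.0


def test_arrival_never_above_background():
    with pytest.raises(NeverAboveBackground):
        bleb_arrival_timing(
            np.zeros(6), np.arange(6.0), background_level=1.0
        )


def test_arrival_is_multiple_of_frame_interval():
    protr = np.array([0.0, 2.0, 1.0, 0.5, 0.2])
    protein = np.array([2.0, 0.0, 0.0, 0.0, 0.0])  # above bg before max protrusion
    t = bleb_arrival_timing(protein, protr, background_level=1.0, frame_interval=5.0)
    assert t.arrival_time == -5.0
    assert t.arrival_time % 5.0 == 0.0
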