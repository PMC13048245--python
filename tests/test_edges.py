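"""Adaptive-threshold Canny stages: smoothing, gradients, thresholds,
non-maximum suppression, hysteresis, and segment extraction."""

import numpy as np
import pytest

from actin_dispersion import (
    FormatError,
    ParameterError,
    RasterImage,
    canny_edges,
    compute_gradients,
    compute_thresholds,
    extract_segments,
    gaussian_smooth,
    segment_orientation,
)
from actin_dispersion.edges import EdgeSegment, GradientField, _non_maximum_suppression


# ---------------------------------------------------------------- smoothing
def test_gaussian_constant_image_unchanged():
    out = gaussian_smooth(np.full((32, 32), 0.6), sigma=1.4)
    np.testing.assert_allclose(out, 0.6, atol=1e-12)


def test_gaussian_point_spread_symmetric_peak():
    img = np.zeros((21, 21))
    img[10, 10] = 1.0
    out = gaussian_smooth(img, sigma=1.0)
    assert np.unravel_index(out.argmax(), out.shape) == (10, 10)
    np.testing.assert_allclose(out, out[::-1, :], atol=1e-12)
    np.testing.assert_allclose(out, out[:, ::-1], atol=1e-12)
    assert out.sum() == pytest.approx(1.0, rel=5e-3)  # intensity conserved


def test_gaussian_reduces_white_noise_variance():
    for seed in range(10):
        noise = np.random.default_rng(seed).normal(0, 1, size=(64, 64))
        assert gaussian_smooth(noise, sigma=1.4).var() < noise.var()


def test_gaussian_invalid_sigma():
    with pytest.raises(ParameterError):
        gaussian_smooth(np.zeros((8, 8)), sigma=0.0)


# ---------------------------------------------------------------- gradients
def test_sobel_ramp_gives_3_4_5_magnitude():
    # intensity (3*col + 4*row)/8: classic 3x3 Sobel responds with 8x the slope
    r, c = np.mgrid[0:12, 0:12]
    field = compute_gradients((3.0 * c + 4.0 * r) / 8.0)
    interior = np.s_[2:-2, 2:-2]
    np.testing.assert_allclose(field.gx[interior], 3.0, atol=1e-10)
    np.testing.assert_allclose(field.gy[interior], 4.0, atol=1e-10)
    np.testing.assert_allclose(field.magnitude[interior], 5.0, atol=1e-10)


def test_sobel_constant_image_all_zero():
    field = compute_gradients(np.full((16, 16), 0.3))
    np.testing.assert_allclose(field.magnitude, 0.0, atol=1e-12)
    assert field.mean_mag == 0.0 and field.sd_mag == 0.0


def test_sobel_vertical_step_matches_direct_stencil():
    """5x5 toy: compare against explicit kernel arithmetic at one pixel."""
    img = np.zeros((5, 5))
    img[:, 3:] = 1.0
    field = compute_gradients(img)
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    window = img[1:4, 1:4]
    expected_gx = float((kx * window).sum())  # cross-correlation with the stencil
    assert field.gx[2, 2] == pytest.approx(expected_gx)
    assert abs(field.gx[2, 2]) == field.magnitude[2, 2]  # gy = 0 on interior rows
    np.testing.assert_allclose(field.gy[2, :], 0.0, atol=1e-12)


def test_gradients_reject_multichannel():
    with pytest.raises(FormatError):
        compute_gradients(np.zeros((8, 8, 3)))


# ---------------------------------------------------------------- thresholds
def test_thresholds_zero_variance_field():
    field = GradientField(None, None, np.full((4, 4), 10.0), mean_mag=10.0, sd_mag=0.0)
    pair = compute_thresholds(field, reduction_ratio=2.0)
    assert pair.t_max == 10.0 and pair.t_min == 5.0


def test_thresholds_two_level_population_sd():
    mags = np.array([[0.0, 20.0]] * 2)
    field = GradientField(None, None, mags, mean_mag=float(mags.mean()), sd_mag=float(mags.std()))
    pair = compute_thresholds(field, reduction_ratio=2.0)
    assert pair.t_max == pytest.approx(30.0)  # 10 + 2*10 with population sd
    assert pair.t_min == pytest.approx(15.0)


def test_thresholds_match_two_pass_oracle_on_random_fields():
    for seed in range(10):
        mag = np.random.default_rng(seed).random((64, 64))
        field = GradientField(None, None, mag, mean_mag=float(mag.mean()), sd_mag=float(mag.std()))
        pair = compute_thresholds(field, reduction_ratio=2.5)
        # independent two-pass mean/population-sd
        flat = mag.ravel().tolist()
        m = sum(flat) / len(flat)
        s = (sum((v - m) ** 2 for v in flat) / len(flat)) ** 0.5
        assert pair.t_max == pytest.approx(m + 2 * s, rel=1e-9)
        assert pair.t_min == pair.t_max / 2.5


def test_thresholds_invalid_ratio():
    field = GradientField(None, None, np.ones((2, 2)), 1.0, 0.0)
    with pytest.raises(ParameterError):
        compute_thresholds(field, reduction_ratio=0.5)


# ---------------------------------------------------------------- canny
def _line_image(angle_deg=0.0, contrast=0.8, width=3, side=128, noise=None, seed=0):
    img = np.full((side, side), 0.05)
    theta = np.deg2rad(angle_deg)
    d = np.array([-np.sin(theta), np.cos(theta)]) * side * 0.35
    center = np.array([side / 2, side / 2])
    _stamp_segment_local(img, center - d, center + d, width, contrast)
    if noise:
        img = img + np.random.default_rng(seed).normal(0, noise, img.shape)
    return np.clip(img, 0, 1)


def _stamp_segment_local(channel, p0, p1, width, intensity):
    rr, cc = np.mgrid[0 : channel.shape[0], 0 : channel.shape[1]]
    d = p1 - p0
    t = np.clip(((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / (d @ d), 0, 1)
    dist = np.hypot(rr - p0[0] - t * d[0], cc - p0[1] - t * d[1])
    np.maximum(channel, np.clip(width / 2 + 0.5 - dist, 0, 1) * intensity, out=channel)


def test_canny_blank_image_gives_empty_map():
    assert not canny_edges(np.full((64, 64), 0.2)).any()


def test_canny_line_edges_near_line_border():
    img = _line_image()
    edges = canny_edges(img)
    assert edges.sum() >= 1
    # every edge pixel lies within 2 px of the drawn line support
    line_mask = img > 0.06
    from scipy import ndimage as ndi

    dist_to_line = ndi.distance_transform_edt(~line_mask)
    assert dist_to_line[edges].max() <= 2.0


def test_canny_adaptive_thresholds_suppress_faint_texture():
    clean = _line_image()
    textured = np.clip(clean + np.random.default_rng(7).normal(0, 0.05 / 3, clean.shape), 0, 1)
    n_clean = canny_edges(clean).sum()
    n_tex = canny_edges(textured).sum()
    assert abs(n_tex - n_clean) <= 0.10 * n_clean


def test_canny_deterministic():
    img = _line_image(angle_deg=30, noise=0.02, seed=3)
    np.testing.assert_array_equal(canny_edges(img), canny_edges(img))


def test_nms_edges_are_thin_along_gradient():
    """After NMS no pixel keeps both its along-gradient neighbors."""
    img = gaussian_smooth(_line_image(angle_deg=20), sigma=1.4)
    field = compute_gradients(img)
    keep = _non_maximum_suppression(field)
    ang = np.rad2deg(np.arctan2(field.gy, field.gx)) % 180.0
    offsets = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}
    sector = np.zeros(ang.shape, dtype=int)
    sector[(ang >= 22.5) & (ang < 67.5)] = 1
    sector[(ang >= 67.5) & (ang < 112.5)] = 2
    sector[(ang >= 112.5) & (ang < 157.5)] = 3
    rows, cols = np.nonzero(keep)
    h, w = keep.shape
    for r, c in zip(rows, cols):
        dr, dc = offsets[sector[r, c]]
        fwd = keep[r + dr, c + dc] if 0 <= r + dr < h and 0 <= c + dc < w else False
        bwd = keep[r - dr, c - dc] if 0 <= r - dr < h and 0 <= c - dc < w else False
        assert not (fwd and bwd), f"thick edge at {(r, c)}"


# ---------------------------------------------------------------- segments
def test_extract_segments_filters_short_components():
    edge_map = np.zeros((64, 64), dtype=bool)
    edge_map[5, 2:42] = True  # length 40
    edge_map[30, 2:5] = True  # length 3
    segs = extract_segments(edge_map, min_edge_length=10)
    assert len(segs) == 1 and segs[0].length == 40


def test_extract_segments_empty_map():
    assert extract_segments(np.zeros((32, 32), dtype=bool)) == []


def test_extract_segments_recovers_disjoint_ground_truth():
    rng = np.random.default_rng(9)
    edge_map = np.zeros((128, 128), dtype=bool)
    truth = []
    for k in range(5):
        r = 10 + 24 * k
        c0 = int(rng.integers(5, 60))
        pixels = {(r, c) for c in range(c0, c0 + 20)}
        truth.append(pixels)
        for rr, cc in pixels:
            edge_map[rr, cc] = True
    segs = extract_segments(edge_map, min_edge_length=10)
    assert len(segs) == 5
    recovered = [set(map(tuple, s.pixel_coords)) for s in segs]
    for pixels in truth:
        assert pixels in recovered


# ---------------------------------------------------------------- orientation
@pytest.mark.parametrize(
    "coords, expected",
    [
        ([(5, c) for c in range(10)], 0.0),  # one row -> horizontal
        ([(r, 7) for r in range(10)], 90.0),  # one column -> vertical
        ([(10 - i, i) for i in range(10)], 45.0),  # slope +1 in math convention
        ([(i, i) for i in range(10)], 135.0),
    ],
)
def test_orientation_of_collinear_pixels(coords, expected):
    assert segment_orientation(np.array(coords)) == pytest.approx(expected, abs=1e-9)


def test_orientation_matches_least_squares_fit():
    coords = np.array([(20 - i, i) for i in range(15)], dtype=float)
    slope = np.polyfit(coords[:, 1], -coords[:, 0], 1)[0]
    expected = np.rad2deg(np.arctan(slope)) % 180.0
    assert segment_orientation(coords) == pytest.approx(expected, abs=1e-6)


def test_orientation_invariant_to_order_and_translation(rng):
    coords = np.column_stack([rng.integers(0, 50, 30), rng.integers(0, 50, 30)])
    base = segment_orientation(coords)
    assert segment_orientation(coords[::-1]) == pytest.approx(base, abs=1e-9)
    assert segment_orientation(coords + [17, -4]) == pytest.approx(base, abs=1e-9)


def test_orientation_single_pixel_error():
    with pytest.raises(ParameterError):
        segment_orientation(np.array([[3, 3]]))


def test_rotating_image_90_degrees_rotates_orientations():
    img = _line_image(angle_deg=25)
    rotated = np.rot90(img)  # counterclockwise 90 degrees
    segs = extract_segments(canny_edges(img), min_edge_length=10)
    segs_rot = extract_segments(canny_edges(rotated), min_edge_length=10)
    assert segs and segs_rot
    theta = segs[0].angle_deg
    theta_rot = segs_rot[0].angle_deg
    diff = (theta_rot - theta - 90.0 + 90.0) % 180.0 - 90.0
    assert abs(diff) <= 3.0
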