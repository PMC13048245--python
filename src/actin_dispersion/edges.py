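"""Stress-fiber edge detection with statistics-adaptive dual thresholds.

The detector follows the classical Canny stages — Gaussian smoothing,
Sobel gradients, non-maximum suppression along the quantized gradient
direction, dual-threshold hysteresis — but the hysteresis thresholds are
not free parameters: the upper threshold is set from the gradient
statistics of the image itself,

    T_max = M + 2 S,        T_min = T_max / T,

where ``M`` and ``S`` are the mean and (population) standard deviation of
the gradient magnitude over all pixels and ``T >= 1`` is the reduction
ratio.  This makes edge screening self-calibrating across images with
different staining intensity and background texture.

Detected edge maps are decomposed into 8-connected components; components
shorter than ``min_edge_length`` pixels are discarded as noise, and each
survivor gets an orientation angle from the principal axis of its pixel
cloud, reported in math convention (counterclockwise from the horizontal
axis) and folded into [0, 180).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as _cc_label

from .errors import FormatError, ParameterError
from .image_io import RasterImage

DEFAULT_SIGMA = 1.4
DEFAULT_REDUCTION_RATIO = 2.0
DEFAULT_MIN_EDGE_LENGTH = 10


@dataclass
class GradientField:
    """Per-pixel Sobel gradients with their magnitude statistics."""

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    mean_mag: float
    sd_mag: float


@dataclass
class ThresholdPair:
    """Hysteresis thresholds derived from gradient statistics."""

    t_max: float
    t_min: float
    reduction_ratio: float


@dataclass
class EdgeSegment:
    """One 8-connected stress-fiber edge component.

    ``pixel_coords`` is an ``(n, 2)`` array of (row, col) positions in the
    512 x 512 frame; ``angle_deg`` is the principal-axis orientation in
    [0, 180); ``davg`` (mean distance to nucleus centers) is filled by the
    dispersion stage.
    """

    pixel_coords: np.ndarray
    length: int
    angle_deg: float
    davg: float | None = None
    label: int = 0

    @property
    def centroid(self) -> tuple[float, float]:
        """(row, col) mean of the member pixels."""
        r, c = self.pixel_coords.mean(axis=0)
        return float(r), float(c)


def _as_single_channel(img: RasterImage | np.ndarray) -> np.ndarray:
    if isinstance(img, RasterImage):
        if img.n_channels != 1:
            raise FormatError("expected a single-channel image")
        return img.pixels
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise FormatError("expected a single-channel image")
    return arr


def gaussian_smooth(img: RasterImage | np.ndarray, sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Gaussian low-pass with reflective borders; conserves mean intensity."""
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    return ndi.gaussian_filter(_as_single_channel(img), sigma=sigma, mode="reflect")


def compute_gradients(img: RasterImage | np.ndarray) -> GradientField:
    """Sobel gradients and magnitude G = sqrt(Gx^2 + Gy^2).

    Uses the classical 3x3 stencils ([-1 0 1; -2 0 2; -1 0 1] and its
    transpose) with reflective borders.  ``mean_mag``/``sd_mag`` are the
    mean M and population standard deviation S over all magnitude pixels.
    """
    arr = _as_single_channel(img)
    gx = ndi.sobel(arr, axis=1, mode="reflect")
    gy = ndi.sobel(arr, axis=0, mode="reflect")
    mag = np.hypot(gx, gy)
    return GradientField(gx=gx, gy=gy, magnitude=mag, mean_mag=float(mag.mean()), sd_mag=float(mag.std()))


def compute_thresholds(field: GradientField, reduction_ratio: float = DEFAULT_REDUCTION_RATIO) -> ThresholdPair:
    """T_max = M + 2 S; T_min = T_max / reduction_ratio."""
    if reduction_ratio < 1:
        raise ParameterError(f"reduction_ratio must be >= 1, got {reduction_ratio}")
    t_max = field.mean_mag + 2.0 * field.sd_mag
    return ThresholdPair(t_max=t_max, t_min=t_max / reduction_ratio, reduction_ratio=reduction_ratio)


def _non_maximum_suppression(field: GradientField) -> np.ndarray:
    """Keep pixels whose magnitude is a local maximum along the gradient.

    Direction is quantized to 4 sectors (0, 45, 90, 135 degrees).  Ties on
    plateaus are broken asymmetrically (>= one neighbor, > the other) so
    that at most one pixel of a two-wide plateau survives, keeping edges
    one pixel thin along the gradient direction.
    """
    mag = field.magnitude
    h, w = mag.shape
    # sector from gradient angle; gy is the derivative along rows
    ang = np.rad2deg(np.arctan2(field.gy, field.gx)) % 180.0
    sector = np.zeros(mag.shape, dtype=np.uint8)
    sector[(ang >= 22.5) & (ang < 67.5)] = 1
    sector[(ang >= 67.5) & (ang < 112.5)] = 2
    sector[(ang >= 112.5) & (ang < 157.5)] = 3

    padded = np.pad(mag, 1, mode="constant")

    def shifted(dr: int, dc: int) -> np.ndarray:
        return padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]

    # neighbor offsets along the gradient direction, per sector:
    # sector 0: horizontal gradient -> compare left/right
    # sector 1: diagonal (gx,gy same sign region) -> compare down-right/up-left
    # sector 2: vertical gradient -> compare up/down
    # sector 3: anti-diagonal -> compare down-left/up-right
    offsets = {0: ((0, 1), (0, -1)), 1: ((1, 1), (-1, -1)), 2: ((1, 0), (-1, 0)), 3: ((1, -1), (-1, 1))}
    keep = np.zeros(mag.shape, dtype=bool)
    for s, ((dr1, dc1), (dr2, dc2)) in offsets.items():
        m = sector == s
        keep |= m & (mag >= shifted(dr1, dc1)) & (mag > shifted(dr2, dc2))
    keep &= mag > 0
    return keep


def _hysteresis(mag: np.ndarray, nms: np.ndarray, thresholds: ThresholdPair) -> np.ndarray:
    """Dual-threshold edge screening: weak pixels survive only when
    8-connected to a strong (>= T_max) pixel."""
    strong = nms & (mag >= thresholds.t_max)
    candidate = nms & (mag >= thresholds.t_min)
    if not strong.any():
        return np.zeros_like(strong)
    labels, n = ndi.label(candidate, structure=np.ones((3, 3), dtype=int))
    keep_labels = np.unique(labels[strong])
    keep_labels = keep_labels[keep_labels > 0]
    mask = np.zeros(n + 1, dtype=bool)
    mask[keep_labels] = True
    return mask[labels]


def canny_edges(
    img: RasterImage | np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    reduction_ratio: float = DEFAULT_REDUCTION_RATIO,
) -> np.ndarray:
    """Binary stress-fiber edge map via the adaptive-threshold Canny pipeline.

    Composition: Gaussian smoothing -> Sobel gradients -> non-maximum
    suppression -> hysteresis with (T_min, T_max) from
    :func:`compute_thresholds`.  Deterministic: identical input bytes and
    parameters give identical maps.
    """
    smoothed = gaussian_smooth(img, sigma=sigma)
    field = compute_gradients(smoothed)
    # Featureless guard: the adaptive thresholds only screen structure when
    # the magnitude distribution is heavy-tailed (edges are rare and strong).
    # A smooth noise field has a Rayleigh-like tail with S/M ~ 0.52, so the
    # thresholds would chase noise ridges; declare such images edge-free.
    # Scale-invariant, so it holds at any noise amplitude; also covers the
    # constant image (M = S = 0).
    if field.sd_mag <= field.mean_mag:
        return np.zeros(smoothed.shape, dtype=bool)
    thresholds = compute_thresholds(field, reduction_ratio=reduction_ratio)
    nms = _non_maximum_suppression(field)
    return _hysteresis(field.magnitude, nms, thresholds)


def segment_orientation(seg: EdgeSegment | np.ndarray) -> float:
    """Principal-axis orientation of a pixel set, degrees in [0, 180).

    Measured from the horizontal (column) axis, counterclockwise positive
    in math convention (the image row axis points down, so the row
    coordinate enters with a minus sign).  Exactly collinear pixels give
    the exact line angle; a horizontal run gives 0, a vertical run 90.
    """
    coords = seg.pixel_coords if isinstance(seg, EdgeSegment) else np.asarray(seg, dtype=np.float64)
    if coords.shape[0] < 2:
        raise ParameterError("orientation undefined for segments with fewer than 2 pixels")
    x = coords[:, 1].astype(np.float64)
    y = -coords[:, 0].astype(np.float64)  # math convention: y up
    x = x - x.mean()
    y = y - y.mean()
    sxx = float(np.dot(x, x))
    syy = float(np.dot(y, y))
    sxy = float(np.dot(x, y))
    angle = 0.5 * np.arctan2(2.0 * sxy, sxx - syy)
    return float(np.rad2deg(angle) % 180.0)


def extract_segments(edge_map: np.ndarray, min_edge_length: int = DEFAULT_MIN_EDGE_LENGTH) -> list[EdgeSegment]:
    """8-connected edge components of at least ``min_edge_length`` pixels.

    Components are returned in raster-scan label order; each carries its
    pixel coordinates and principal-axis orientation.
    """
    edge_map = np.asarray(edge_map, dtype=bool)
    labels = _cc_label(edge_map, connectivity=2)
    segments: list[EdgeSegment] = []
    for lab in range(1, labels.max() + 1):
        coords = np.argwhere(labels == lab)
        if coords.shape[0] < max(min_edge_length, 2):
            continue
        segments.append(
            EdgeSegment(
                pixel_coords=coords,
                length=int(coords.shape[0]),
                angle_deg=segment_orientation(coords),
                label=lab,
            )
        )
    return segments
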