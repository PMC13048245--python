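"""The spatial-dispersion statistic and two-group comparison.

Every surviving stress-fiber edge ``i`` is reduced to a feature point
``(Davg_i, A_i)``: the mean Euclidean distance from the edge's centroid
to all detected nucleus centers, and the edge orientation angle.  The
feature points are binned on an equal-width 2D grid (distance x angle),
the Shannon entropy of the occupancy probabilities is

    etp = sum_cells [ -p * ln(p) ],      0 * ln(0) := 0,

and the spatial dispersion is the entropy normalized by its maximum,

    dsp = etp / ln(n),    n = number of grid cells,

so dsp = 0 for a perfectly concentrated point cloud (ordered, parallel,
equidistant fibers) and dsp = 1 for a uniformly spread one (disorganized
cytoskeleton).  The normalization ratio is independent of the logarithm
base; natural logarithms are used throughout.

Two experimental groups of per-image dsp values are compared with the
unpaired pooled-variance Student t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Any, Sequence

import numpy as np
from scipy import stats as sps

from .edges import EdgeSegment, canny_edges, extract_segments
from .errors import DataError, NoEdgesError, NoNucleiError, ParameterError
from .image_io import RasterImage, extract_channel, standardize
from .nuclei import HSVRange, NucleusRegion, detect_nuclei

if TYPE_CHECKING:
    from .config import RunConfig

DEFAULT_N_DIST_BINS = 8
DEFAULT_N_ANGLE_BINS = 8


@dataclass
class FeaturePoint:
    """One (Davg, angle) point contributed by a stress-fiber edge."""

    davg: float
    angle_deg: float
    segment_id: int


@dataclass
class Histogram2D:
    """Occupancy counts and probabilities on the (distance, angle) grid."""

    n_dist_bins: int
    n_angle_bins: int
    edges_dist: np.ndarray
    edges_angle: np.ndarray
    counts: np.ndarray  # (n_dist_bins, n_angle_bins) ints
    probs: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.n_dist_bins * self.n_angle_bins


@dataclass
class DispersionResult:
    """End-to-end result for one micrograph."""

    etp: float
    dsp: float
    n_points: int
    n_nuclei: int
    n_bins: int
    params: dict[str, Any] = field(default_factory=dict)
    histogram: Histogram2D | None = None
    feature_points: list[FeaturePoint] = field(default_factory=list)


def compute_davg(seg: EdgeSegment, centers: Sequence[tuple[float, float]]) -> float:
    """Mean Euclidean distance from the segment centroid to the nucleus centers."""
    if len(centers) == 0:
        raise NoNucleiError("no nuclei detected: Davg is undefined without a reference center")
    cr, cc = seg.centroid
    pts = np.asarray(centers, dtype=np.float64)
    return float(np.hypot(pts[:, 0] - cr, pts[:, 1] - cc).mean())


def build_feature_points(
    segments: Sequence[EdgeSegment], nuclei: Sequence[NucleusRegion]
) -> list[FeaturePoint]:
    """One (Davg_i, A_i) point per surviving edge segment."""
    if len(nuclei) == 0:
        raise NoNucleiError("no nuclei detected")
    if len(segments) == 0:
        raise NoEdgesError("no fiber edges detected")
    centers = [n.centroid for n in nuclei]
    points = []
    for seg in segments:
        seg.davg = compute_davg(seg, centers)
        points.append(FeaturePoint(davg=seg.davg, angle_deg=seg.angle_deg, segment_id=seg.label))
    return points


def bin_features(
    points: Sequence[FeaturePoint],
    n_dist_bins: int = DEFAULT_N_DIST_BINS,
    n_angle_bins: int = DEFAULT_N_ANGLE_BINS,
    d_max: float | None = None,
) -> Histogram2D:
    """Equal-width 2D binning of the feature points.

    The distance axis spans [0, d_max]; by default d_max is the largest
    observed Davg (that point lands in the top bin).  A fixed d_max can be
    supplied for cross-image comparability; distances above it are clipped
    into the top bin.  The angle axis always spans [0, 180) degrees.
    """
    if len(points) == 0:
        raise DataError("cannot bin an empty feature set")
    if n_dist_bins < 1 or n_angle_bins < 1 or n_dist_bins * n_angle_bins < 2:
        raise ParameterError("need n_dist_bins, n_angle_bins >= 1 with product >= 2")
    d = np.array([p.davg for p in points], dtype=np.float64)
    a = np.array([p.angle_deg for p in points], dtype=np.float64)
    if d_max is None:
        d_max = float(d.max())
    else:
        d = np.minimum(d, d_max)
    if d_max <= 0:
        d_max = 1.0  # all-zero distances: everything in the first bin
    counts, edges_d, edges_a = np.histogram2d(
        d, a, bins=[n_dist_bins, n_angle_bins], range=[[0.0, d_max], [0.0, 180.0]]
    )
    counts = counts.astype(np.int64)
    return Histogram2D(
        n_dist_bins=n_dist_bins,
        n_angle_bins=n_angle_bins,
        edges_dist=edges_d,
        edges_angle=edges_a,
        counts=counts,
        probs=counts / counts.sum(),
    )


def entropy(h: Histogram2D | np.ndarray) -> float:
    """Shannon entropy (nats) of the cell probabilities, with 0 ln 0 = 0."""
    p = h.probs if isinstance(h, Histogram2D) else np.asarray(h, dtype=np.float64)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() + 0.0)  # +0.0 normalizes -0.0


def dispersion(etp: float, n_bins: int) -> float:
    """Normalize entropy by its maximum ln(n_bins); clipped to [0, 1]."""
    if n_bins < 2:
        raise ParameterError(f"need at least 2 bins to normalize, got {n_bins}")
    if etp < -1e-9 or etp > np.log(n_bins) + 1e-9:
        raise ParameterError(f"entropy {etp} outside [0, ln({n_bins})]")
    return float(np.clip(etp / np.log(n_bins), 0.0, 1.0) + 0.0)


def compute_dispersion(img: RasterImage, config: "RunConfig | None" = None) -> DispersionResult:
    """End-to-end spatial dispersion of one RGB micrograph.

    Deterministic composition: standardize -> channel split -> adaptive
    Canny -> segment extraction/filtering -> nucleus detection -> feature
    points -> 2D histogram -> entropy -> normalized dispersion.  Raises
    :class:`NoEdgesError` / :class:`NoNucleiError` when the metric is
    undefined for the input.
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    std = standardize(img, side=cfg.side)
    if cfg.channel_mapping is not None:
        std.channel_roles = dict(cfg.channel_mapping)
    actin = extract_channel(std, "actin")
    edge_map = canny_edges(actin, sigma=cfg.sigma, reduction_ratio=cfg.reduction_ratio)
    segments = extract_segments(edge_map, min_edge_length=cfg.min_edge_length)
    nuclei = detect_nuclei(std, hsv_range=cfg.hsv_range, min_region_area=cfg.min_region_area)
    points = build_feature_points(segments, nuclei)
    d_max = cfg.fixed_d_max if cfg.distance_range_mode == "fixed" else None
    hist = bin_features(points, cfg.n_dist_bins, cfg.n_angle_bins, d_max=d_max)
    etp = entropy(hist)
    dsp = dispersion(etp, hist.n_bins)
    return DispersionResult(
        etp=etp,
        dsp=dsp,
        n_points=len(points),
        n_nuclei=len(nuclei),
        n_bins=hist.n_bins,
        params=cfg.to_dict(),
        histogram=hist,
        feature_points=points,
    )


def compare_groups(
    dsp_a: Sequence[float], dsp_b: Sequence[float]
) -> dict[str, float]:
    """Unpaired pooled-variance Student t test between two dsp groups.

    Returns t, two-sided p, df = n_a + n_b - 2, and per-group mean/SEM.
    """
    a = np.asarray(dsp_a, dtype=np.float64)
    b = np.asarray(dsp_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs at least 2 values for a t test")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return {
        "t": float(t),
        "p": float(p),
        "df": float(a.size + b.size - 2),
        "n_a": int(a.size),
        "n_b": int(b.size),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sem_a": float(sps.sem(a)),
        "sem_b": float(sps.sem(b)),
    }
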