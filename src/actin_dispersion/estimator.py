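"""Scikit-learn-style front end to the dispersion pipeline.

:class:`ActinDispersion` is a stateless transformer: ``fit`` only
validates parameters (there is nothing to learn — the thresholds adapt
per image), and ``transform`` maps a batch of micrographs to a column of
spatial-dispersion scores.  Being a proper estimator, it supports
``get_params``/``set_params``, cloning, and composition inside sklearn
pipelines or cross-validation wrappers that treat dsp as an input
feature.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .config import RunConfig
from .dispersion import DispersionResult, compute_dispersion
from .image_io import RasterImage, load_image
from .nuclei import HSVRange


def _coerce_image(item: Any) -> RasterImage:
    if isinstance(item, RasterImage):
        return item
    if isinstance(item, (str, Path)):
        return load_image(item)
    return RasterImage(np.asarray(item, dtype=np.float64))


class ActinDispersion(BaseEstimator, TransformerMixin):
    """Spatial-dispersion transformer for F-actin micrographs.

    Parameters mirror :class:`~actin_dispersion.config.RunConfig`; see its
    docstring for units and defaults.

    Examples
    --------
    >>> est = ActinDispersion(n_dist_bins=8, n_angle_bins=8)
    >>> dsp = est.fit_transform(list_of_rgb_arrays)   # doctest: +SKIP
    """

    def __init__(
        self,
        side: int = 512,
        sigma: float = 1.4,
        reduction_ratio: float = 2.0,
        min_edge_length: int = 10,
        hue_lo: float = 190.0,
        hue_hi: float = 270.0,
        sat_lo: float = 0.25,
        val_lo: float = 0.20,
        min_region_area: int = 50,
        n_dist_bins: int = 8,
        n_angle_bins: int = 8,
        distance_range_mode: str = "per_image",
        fixed_d_max: float = 724.0,
        channel_mapping: dict[str, int] | None = None,
    ):
        self.side = side
        self.sigma = sigma
        self.reduction_ratio = reduction_ratio
        self.min_edge_length = min_edge_length
        self.hue_lo = hue_lo
        self.hue_hi = hue_hi
        self.sat_lo = sat_lo
        self.val_lo = val_lo
        self.min_region_area = min_region_area
        self.n_dist_bins = n_dist_bins
        self.n_angle_bins = n_angle_bins
        self.distance_range_mode = distance_range_mode
        self.fixed_d_max = fixed_d_max
        self.channel_mapping = channel_mapping

    def _make_config(self) -> RunConfig:
        return RunConfig(
            side=self.side,
            sigma=self.sigma,
            reduction_ratio=self.reduction_ratio,
            min_edge_length=self.min_edge_length,
            hsv_range=HSVRange(self.hue_lo, self.hue_hi, self.sat_lo, self.val_lo),
            min_region_area=self.min_region_area,
            n_dist_bins=self.n_dist_bins,
            n_angle_bins=self.n_angle_bins,
            distance_range_mode=self.distance_range_mode,
            fixed_d_max=self.fixed_d_max,
            channel_mapping=self.channel_mapping,
        )

    def fit(self, X: Sequence[Any] | None = None, y: Any = None) -> "ActinDispersion":
        """Validate parameters; no state is learned from the images."""
        self.config_ = self._make_config()  # raises on invalid parameters
        self.n_features_in_ = 1
        return self

    def compute(self, image: Any) -> DispersionResult:
        """Full :class:`DispersionResult` for one micrograph."""
        if not hasattr(self, "config_"):
            self.fit()
        return compute_dispersion(_coerce_image(image), self.config_)

    def transform(self, X: Sequence[Any]) -> np.ndarray:
        """Map images (arrays, paths, or RasterImages) to an (n, 1) dsp column."""
        if not hasattr(self, "config_"):
            self.fit(X)
        return np.array([[self.compute(item).dsp] for item in X])

    def _more_tags(self) -> dict[str, Any]:
        return {"X_types": ["3darray", "string"], "non_deterministic": False}
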