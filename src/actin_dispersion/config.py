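"""Run configuration: every tunable of the pipeline in one record.

A :class:`RunConfig` is serialized into each result row (plus a short
parameter hash) so batch outputs carry their full provenance, and it
round-trips losslessly through YAML.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError, ParameterError
from .nuclei import HSVRange


@dataclass
class RunConfig:
    """All pipeline parameters.

    Attributes
    ----------
    side : working frame side in pixels (images are resized to side x side).
    sigma : Gaussian smoothing scale in pixels before gradient computation.
    reduction_ratio : T in T_min = T_max / T for hysteresis.
    min_edge_length : minimum pixel count of a surviving edge component.
    hsv_range : blue bracket for nucleus detection.
    min_region_area : minimum nucleus area in pixels.
    n_dist_bins, n_angle_bins : 2D histogram grid.
    distance_range_mode : "per_image" (d_max = max observed Davg) or
        "fixed" (use ``fixed_d_max``, for cross-image comparability).
    channel_mapping : optional override of {actin, nuclei} -> channel index.
    seed : RNG seed, used only by fixture generation.
    """

    side: int = 512
    sigma: float = 1.4
    reduction_ratio: float = 2.0
    min_edge_length: int = 10
    hsv_range: HSVRange = field(default_factory=HSVRange)
    min_region_area: int = 50
    n_dist_bins: int = 8
    n_angle_bins: int = 8
    distance_range_mode: str = "per_image"
    fixed_d_max: float = 724.0  # frame diagonal of the 512x512 working frame
    channel_mapping: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distance_range_mode not in ("per_image", "fixed"):
            raise ConfigurationError(
                f"distance_range_mode must be 'per_image' or 'fixed', got {self.distance_range_mode!r}"
            )
        if self.sigma <= 0:
            raise ParameterError(f"sigma must be positive, got {self.sigma}")
        if self.reduction_ratio < 1:
            raise ParameterError(f"reduction_ratio must be >= 1, got {self.reduction_ratio}")

    def to_dict(self) -> dict[str, Any]:
        d = {
            "side": self.side,
            "sigma": self.sigma,
            "reduction_ratio": self.reduction_ratio,
            "min_edge_length": self.min_edge_length,
            "hsv_range": {
                "hue_lo": self.hsv_range.hue_lo,
                "hue_hi": self.hsv_range.hue_hi,
                "sat_lo": self.hsv_range.sat_lo,
                "val_lo": self.hsv_range.val_lo,
            },
            "min_region_area": self.min_region_area,
            "n_dist_bins": self.n_dist_bins,
            "n_angle_bins": self.n_angle_bins,
            "distance_range_mode": self.distance_range_mode,
            "fixed_d_max": self.fixed_d_max,
            "channel_mapping": dict(self.channel_mapping) if self.channel_mapping else None,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        hsv = d.pop("hsv_range", None)
        if isinstance(hsv, dict):
            d["hsv_range"] = HSVRange(**hsv)
        elif hsv is not None:
            d["hsv_range"] = hsv
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def with_overrides(self, **kwargs: Any) -> "RunConfig":
        return replace(self, **kwargs)

    def param_hash(self) -> str:
        """Short stable digest of the full parameter record."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def apply_set(self, expr: str) -> "RunConfig":
        """Apply a ``key=value`` CLI override; values parsed as YAML scalars."""
        if "=" not in expr:
            raise ConfigurationError(f"--set expects key=value, got {expr!r}")
        key, raw = expr.split("=", 1)
        key = key.strip()
        value = yaml.safe_load(raw)
        if key.startswith("hsv_range."):
            sub = key.split(".", 1)[1]
            if sub not in ("hue_lo", "hue_hi", "sat_lo", "val_lo"):
                raise ConfigurationError(f"unknown hsv_range field {sub!r}")
            hsv = {
                "hue_lo": self.hsv_range.hue_lo,
                "hue_hi": self.hsv_range.hue_hi,
                "sat_lo": self.hsv_range.sat_lo,
                "val_lo": self.hsv_range.val_lo,
            }
            hsv[sub] = value
            return self.with_overrides(hsv_range=HSVRange(**hsv))
        if key not in self.__dataclass_fields__:
            raise ConfigurationError(f"unknown config key {key!r}")
        return self.with_overrides(**{key: value})
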