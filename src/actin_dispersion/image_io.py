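"""Micrograph loading and geometric/channel standardization.

Images are carried as :class:`RasterImage`: float pixels in [0, 1]
regardless of the native bit depth, so every downstream threshold works
identically for 8- and 16-bit acquisitions.  Geometry is standardized to
512 x 512 by bilinear interpolation; non-square inputs are stretched and
the original aspect ratio is kept in metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import ConfigurationError, FormatError, ParameterError

STANDARD_SIDE = 512

#: default channel convention for RGB micrographs: phalloidin(actin)=green,
#: DAPI/Hoechst(nuclei)=blue
DEFAULT_CHANNEL_ROLES = {"actin": 1, "nuclei": 2}


@dataclass
class RasterImage:
    """A single- or three-channel raster with float intensities in [0, 1].

    Parameters
    ----------
    pixels
        ``(H, W)`` or ``(H, W, 3)`` float array in ``[0, 1]``.
    bit_depth
        Native bit depth of the source file (8 or 16); informational once
        pixels are normalized.
    channel_roles
        Optional mapping from ``{"actin", "nuclei"}`` to a channel index.
    source_shape
        ``(height, width)`` of the file as read, before any resize.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    channel_roles: dict[str, int] | None = None
    source_shape: tuple[int, int] | None = None
    path: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim not in (2, 3):
            raise FormatError(f"expected 2D or 3D pixel array, got ndim={self.pixels.ndim}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] not in (1, 3):
            raise FormatError(f"unsupported channel count {self.pixels.shape[2]} (need 1 or 3)")
        if self.pixels.ndim == 3 and self.pixels.shape[2] == 1:
            self.pixels = self.pixels[:, :, 0]
        if self.source_shape is None:
            self.source_shape = (self.height, self.width)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else int(self.pixels.shape[2])

    @property
    def aspect_ratio(self) -> float:
        """Width / height of the original file."""
        h, w = self.source_shape
        return w / h


def load_image(path: str | Path) -> RasterImage:
    """Read a TIFF/PNG/JPEG micrograph into a normalized :class:`RasterImage`.

    16-bit data are divided by 65535, 8-bit by 255; float files are assumed
    already in [0, 1] and clipped.  RGBA alpha planes are dropped.

    Raises
    ------
    IOError
        If the file is missing, empty, or not decodable; the message names
        the path.
    FormatError
        If the channel count is neither 1 nor 3.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises plugin-specific errors
        raise IOError(f"cannot read image file {path!s}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] not in (1, 3)):
        raise FormatError(f"unsupported image layout {arr.shape} in {path!s} (need 1 or 3 channels)")

    if arr.dtype == np.uint8:
        bit_depth, scale = 8, 255.0
    elif arr.dtype == np.uint16:
        bit_depth, scale = 16, 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        bit_depth, scale = 8, 1.0
    else:
        bit_depth = 16 if arr.max(initial=0) > 255 else 8
        scale = float(2**bit_depth - 1)
    pixels = np.clip(arr.astype(np.float64) / scale, 0.0, 1.0)
    roles = dict(DEFAULT_CHANNEL_ROLES) if (arr.ndim == 3 and arr.shape[2] == 3) else None
    return RasterImage(pixels, bit_depth=bit_depth, channel_roles=roles, path=str(path))


def standardize(img: RasterImage, side: int = STANDARD_SIDE) -> RasterImage:
    """Resize to ``side x side`` with bilinear interpolation.

    Idempotent: an image already at the target size is returned unchanged
    (same pixel bytes).  Aspect ratio is *not* preserved; the original
    shape stays available as ``source_shape``.
    """
    if side <= 0:
        raise ParameterError(f"side must be positive, got {side}")
    if img.height == side and img.width == side:
        return replace(img, pixels=img.pixels.copy())
    out_shape = (side, side) if img.n_channels == 1 else (side, side, img.n_channels)
    resized = _sk_resize(
        img.pixels, out_shape, order=1, mode="reflect", anti_aliasing=False, preserve_range=True
    )
    return replace(img, pixels=np.clip(resized, 0.0, 1.0))


def extract_channel(img: RasterImage, role: str) -> RasterImage:
    """Return the single-channel view for ``role`` ("actin" or "nuclei")."""
    if role not in ("actin", "nuclei"):
        raise ConfigurationError(f"unknown channel role {role!r}")
    roles = img.channel_roles
    if img.n_channels == 1:
        if roles is not None and roles.get(role) == 0:
            return replace(img, pixels=img.pixels.copy(), channel_roles=None)
        raise ConfigurationError(
            f"cannot extract role {role!r} from a single-channel image without a channel mapping"
        )
    if roles is None:
        roles = DEFAULT_CHANNEL_ROLES
    if role not in roles:
        raise ConfigurationError(f"channel mapping {roles} does not define role {role!r}")
    idx = roles[role]
    if not 0 <= idx < img.n_channels:
        raise ConfigurationError(f"channel index {idx} out of range for {img.n_channels} channels")
    return replace(img, pixels=img.pixels[:, :, idx].copy(), channel_roles=None)
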