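"""Core image containers and grayscale I/O.

An :class:`EnFaceAngiogram` is a single en-face OCT-A projection of one
anatomical slab (superficial plexus, deep plexus or choriocapillaris) of one
eye, stored as normalized float intensity in [0, 1] together with its physical
pixel pitch and the device's signal-strength quality index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .exceptions import OctavascError

LAYERS = ("superficial", "deep", "choriocapillaris")
EYES = ("OD", "OS")

#: Default pixel pitch of a 6 x 6 mm, 1024 x 1024 px macular scan.
DEFAULT_PX_SIZE_UM = 6.0


@dataclass
class EnFaceAngiogram:
    """One en-face OCT-A image of one layer of one eye.

    Parameters
    ----------
    pixels
        2-D float array of normalized intensity in [0, 1].
    px_size_um
        Physical pixel pitch in micrometres (default 6 um/px).
    layer
        Anatomical slab: ``superficial``, ``deep`` or ``choriocapillaris``.
    eye
        ``OD`` (right) or ``OS`` (left).
    quality_index
        Device signal-strength index; scans below the configured minimum
        (default 8) are excluded from analysis.
    """

    pixels: np.ndarray
    px_size_um: float = DEFAULT_PX_SIZE_UM
    layer: str = "superficial"
    eye: str = "OD"
    quality_index: int = 10

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise OctavascError("angiogram must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise OctavascError("angiogram intensities must be finite")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise OctavascError("angiogram intensities must lie in [0, 1]")
        if self.layer not in LAYERS:
            raise OctavascError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.eye not in EYES:
            raise OctavascError(f"unknown eye {self.eye!r}; expected one of {EYES}")
        if self.px_size_um <= 0:
            raise OctavascError("px_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMap:
    """Binary segmentation of an angiogram with provenance of the algorithm."""

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise OctavascError("binary map must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SkeletonMap:
    """1-pixel-wide centerline map derived from a :class:`BinaryMap`."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise OctavascError("skeleton map must be 2-D")


def as_pixels(image) -> np.ndarray:
    """Return the float pixel array of an angiogram, map or bare ndarray."""
    if isinstance(image, (EnFaceAngiogram, BinaryMap, SkeletonMap)):
        return np.asarray(image.pixels)
    return np.asarray(image)


def save_angiogram(path: str | Path, image: EnFaceAngiogram) -> Path:
    """Write an angiogram as 16-bit grayscale TIFF or PNG (by suffix)."""
    path = Path(path)
    data = np.clip(np.round(image.pixels * 65535.0), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".png":
        Image.fromarray(data, mode="I;16").save(path)
    else:
        raise OctavascError(f"unsupported image format {path.suffix!r}")
    return path


def load_angiogram(
    path: str | Path,
    layer: str,
    eye: str = "OD",
    px_size_um: float = DEFAULT_PX_SIZE_UM,
    quality_index: int = 10,
) -> EnFaceAngiogram:
    """Read an 8/16-bit grayscale TIFF/PNG and normalize intensities to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = np.asarray(Image.open(path))
    data = np.asarray(data)
    if data.ndim == 3:  # collapse trivial channel axes
        data = data.mean(axis=-1)
    if data.dtype == np.uint8:
        pixels = data.astype(float) / 255.0
    elif data.dtype == np.uint16:
        pixels = data.astype(float) / 65535.0
    else:
        pixels = data.astype(float)
        hi = pixels.max()
        if hi > 1.0:
            pixels = pixels / hi
    return EnFaceAngiogram(
        pixels=np.clip(pixels, 0.0, 1.0),
        px_size_um=px_size_um,
        layer=layer,
        eye=eye,
        quality_index=quality_index,
    )
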