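"""Skeleton-based vessel metrics for the retinal plexus layers.

Three scale-free metrics are computed from the binarized and skeletonized
en-face image:

* vessel density   — vessel pixels / total pixels (area fraction),
* skeleton density — centerline pixels / total pixels, a length-weighted
  density that down-weights large vessels and emphasizes capillary change,
* vessel diameter index (VDI) — vessel pixels / centerline pixels, a mean
  vessel caliber in pixels (optionally micrometres).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import skeletonize as _thin

from .exceptions import LayerError, QualityError, UndefinedMetricError
from .images import BinaryMap, EnFaceAngiogram, SkeletonMap, as_pixels
from .thresholding import binarize_layer

#: Scans with a device signal-strength index below this are excluded.
MIN_QUALITY_INDEX = 8


@dataclass
class VesselMetrics:
    """Vessel density / skeleton density / VDI triple for one layer of one eye."""

    vessel_density: float
    skeleton_density: float
    vessel_diameter_index: float
    layer: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.skeleton_density <= self.vessel_density <= 1.0:
            raise UndefinedMetricError(
                "expected 0 <= skeleton_density <= vessel_density <= 1, got "
                f"{self.skeleton_density} / {self.vessel_density}"
            )


def skeletonize(mask) -> SkeletonMap:
    """Topology-preserving 8-connectivity thinning to 1-px-wide centerlines."""
    px = as_pixels(mask).astype(bool)
    return SkeletonMap(_thin(px))


def vessel_density(mask) -> float:
    """Fraction of image pixels classified as vessel."""
    px = as_pixels(mask).astype(bool)
    return float(px.sum()) / px.size


def skeleton_density(skel) -> float:
    """Fraction of image pixels on the 1-px vessel centerline map."""
    px = as_pixels(skel).astype(bool)
    return float(px.sum()) / px.size


def vessel_diameter_index(mask, skel, px_size_um: float | None = None) -> float:
    """Mean vessel caliber: vessel-pixel count / skeleton-pixel count.

    Returns pixels by default; pass ``px_size_um`` to convert to micrometres.

    Raises
    ------
    UndefinedMetricError
        If the skeleton is empty (no vessels detected).
    """
    m = as_pixels(mask).astype(bool)
    s = as_pixels(skel).astype(bool)
    n_skel = s.sum()
    if n_skel == 0:
        raise UndefinedMetricError("vessel diameter index undefined: empty skeleton")
    vdi = float(m.sum()) / float(n_skel)
    return vdi * px_size_um if px_size_um is not None else vdi


def compute_vessel_metrics(
    image: EnFaceAngiogram,
    min_quality: int = MIN_QUALITY_INDEX,
) -> VesselMetrics:
    """Full per-layer pipeline: binarize -> skeletonize -> three metrics.

    Only retinal plexus layers are accepted; the choriocapillaris has its own
    reflectivity/flow-void quantification. Images below the signal-strength
    minimum are rejected rather than silently analysed.
    """
    if image.layer not in ("superficial", "deep"):
        raise LayerError(
            f"vessel metrics are defined for retinal plexus layers, not {image.layer!r}"
        )
    if image.quality_index < min_quality:
        raise QualityError(
            f"image rejected, reason: quality (signal strength index "
            f"{image.quality_index} < {min_quality})"
        )
    mask = binarize_layer(image)
    skel = skeletonize(mask)
    return VesselMetrics(
        vessel_density=vessel_density(mask),
        skeleton_density=skeleton_density(skel),
        vessel_diameter_index=vessel_diameter_index(mask, skel),
        layer=image.layer,
    )
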