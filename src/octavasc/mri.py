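"""White-matter lesion burden summaries from a 3-D lesion mask.

Two measures are derived from a supplied binary lesion mask (segmentation
itself is upstream and out of scope):

* NOL — number of lesions, i.e. connected components of the mask
  (26-connectivity by default, matching common lesion-toolbox behaviour),
* WMI — white-matter lesion index, the lesion volume as a percentage of the
  total intracranial volume (sum of white matter, grey matter and CSF):
  ``WMI = lesion_volume / TIV * 100``. WMI is natural-log-transformed for
  the regression analyses; a zero WMI leaves the log undefined and flags the
  participant instead of silently dropping them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .exceptions import OctavascError

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class MriSummary:
    """Per-participant MRI burden: lesion count and normalized lesion volume."""

    nol: int
    lesion_volume_ml: float
    tiv_ml: float
    wmi: float
    log_wmi: float | None

    @property
    def log_wmi_defined(self) -> bool:
        return self.log_wmi is not None


def _validate_binary(mask) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 3:
        raise OctavascError("lesion mask must be a 3-D volume")
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise OctavascError("lesion mask must be binary (values 0/1)")
        arr = arr.astype(bool)
    return arr


def count_lesions(mask, connectivity: int = 26) -> int:
    """Number of connected components of a binary lesion mask."""
    arr = _validate_binary(mask)
    if connectivity not in _CONNECTIVITY_RANK:
        raise OctavascError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    _, n = ndimage.label(arr, structure=structure)
    return int(n)


def compute_wmi(
    mask,
    voxel_dims_mm: tuple[float, float, float],
    tissue_volumes_ml: tuple[float, float, float],
    connectivity: int = 26,
) -> MriSummary:
    """Summarize a lesion mask into NOL and WMI.

    Parameters
    ----------
    mask
        3-D binary lesion mask.
    voxel_dims_mm
        Voxel edge lengths in millimetres.
    tissue_volumes_ml
        (white matter, grey matter, CSF) volumes in millilitres; TIV is their
        sum.
    """
    arr = _validate_binary(mask)
    dims = np.asarray(voxel_dims_mm, dtype=float)
    if dims.shape != (3,) or np.any(dims <= 0):
        raise OctavascError("voxel_dims_mm must be 3 positive edge lengths")
    tissues = np.asarray(tissue_volumes_ml, dtype=float)
    if tissues.shape != (3,) or np.any(tissues <= 0):
        raise OctavascError("all three tissue volumes must be positive")

    voxel_ml = float(np.prod(dims)) / 1000.0  # mm^3 -> mL
    lesion_ml = float(arr.sum()) * voxel_ml
    tiv_ml = float(tissues.sum())
    wmi = lesion_ml / tiv_ml * 100.0
    log_wmi = math.log(wmi) if wmi > 0 else None
    return MriSummary(
        nol=count_lesions(arr, connectivity=connectivity),
        lesion_volume_ml=lesion_ml,
        tiv_ml=tiv_ml,
        wmi=wmi,
        log_wmi=log_wmi,
    )


def load_lesion_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI-1 lesion mask; returns (binary array, voxel dims in mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return _validate_binary(data > 0.5 if data.dtype.kind == "f" else data), zooms


def save_lesion_mask(path: str | Path, mask, voxel_dims_mm) -> Path:
    """Write a binary lesion mask as uint8 NIfTI-1 with voxel dims in the header."""
    arr = _validate_binary(mask).astype(np.uint8)
    affine = np.diag(list(voxel_dims_mm) + [1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(tuple(voxel_dims_mm))
    nib.save(img, str(path))
    return Path(path)
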