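"""Participant-level records and their CSV table representation.

A :class:`ParticipantRecord` bundles one subject's covariates (age, sex,
Fazekas grade, MoCA), per-eye OCT-A metric sets, MRI burden summary, and
screening exclusion flags. The CSV schema is one row per participant with
per-eye metric columns suffixed ``_od`` / ``_os``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import OctavascError
from .mri import MriSummary

#: Per-eye OCT-A metric columns appended by the imaging pipeline.
OCTA_METRICS = (
    "vd_sup", "sd_sup", "vdi_sup",
    "vd_deep", "sd_deep", "vdi_deep",
    "cc_mean", "cc_sd",
    "fv_n", "fv_mean_um2", "fv_slope", "fv_intercept",
)

EXCLUSION_REASONS = ("ocular_disease", "poor_image_quality", "neurologic_abnormality")


@dataclass
class ParticipantRecord:
    """One subject: covariates, per-eye metrics, MRI summary, exclusion flags.

    ``group`` is derived, not stored: a participant is a CSVD case iff their
    Fazekas score is >= 1.
    """

    id: str
    age: float
    sex: str
    fazekas: int
    moca: float | None = None
    eyes: dict = field(default_factory=dict)  # eye -> {metric: value}
    eye_quality: dict = field(default_factory=dict)  # eye -> quality index
    mri: MriSummary | None = None
    exclusion_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.fazekas not in (0, 1, 2, 3):
            raise OctavascError(f"Fazekas score must be 0-3, got {self.fazekas}")
        unknown = set(self.exclusion_flags) - set(EXCLUSION_REASONS)
        if unknown:
            raise OctavascError(f"unknown exclusion flags: {sorted(unknown)}")

    @property
    def group(self) -> str:
        return "case" if self.fazekas >= 1 else "control"

    @property
    def is_excluded(self) -> bool:
        return bool(self.exclusion_flags)


def records_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Flatten records into the documented one-row-per-participant CSV schema."""
    rows = []
    for rec in records:
        row: dict = {
            "id": rec.id,
            "group": rec.group,
            "age": rec.age,
            "sex": rec.sex,
            "fazekas": rec.fazekas,
            "moca": rec.moca,
        }
        if rec.mri is not None:
            row.update(
                nol=rec.mri.nol,
                wmi=rec.mri.wmi,
                log_wmi=rec.mri.log_wmi,
                lesion_volume_ml=rec.mri.lesion_volume_ml,
                tiv_ml=rec.mri.tiv_ml,
            )
        for eye, suffix in (("OD", "od"), ("OS", "os")):
            metrics = rec.eyes.get(eye, {})
            for m in OCTA_METRICS:
                row[f"{m}_{suffix}"] = metrics.get(m, np.nan)
            row[f"quality_{suffix}"] = rec.eye_quality.get(eye, np.nan)
        for reason in EXCLUSION_REASONS:
            row[f"flag_{reason}"] = int(reason in rec.exclusion_flags)
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[ParticipantRecord]:
    """Inverse of :func:`records_to_frame` (tolerates missing optional columns)."""
    records = []
    for _, row in df.iterrows():
        eyes, quality = {}, {}
        for eye, suffix in (("OD", "od"), ("OS", "os")):
            metrics = {}
            for m in OCTA_METRICS:
                col = f"{m}_{suffix}"
                if col in row and pd.notna(row[col]):
                    metrics[m] = float(row[col])
            if metrics:
                eyes[eye] = metrics
            qcol = f"quality_{suffix}"
            if qcol in row and pd.notna(row[qcol]):
                quality[eye] = int(row[qcol])
        mri = None
        if "wmi" in row and pd.notna(row["wmi"]):
            wmi = float(row["wmi"])
            mri = MriSummary(
                nol=int(row["nol"]) if pd.notna(row.get("nol")) else 0,
                lesion_volume_ml=float(row.get("lesion_volume_ml", np.nan)),
                tiv_ml=float(row.get("tiv_ml", np.nan)),
                wmi=wmi,
                log_wmi=float(np.log(wmi)) if wmi > 0 else None,
            )
        flags = {
            reason
            for reason in EXCLUSION_REASONS
            if f"flag_{reason}" in row and row[f"flag_{reason}"] == 1
        }
        records.append(
            ParticipantRecord(
                id=str(row["id"]),
                age=float(row["age"]),
                sex=str(row.get("sex", "f")),
                fazekas=int(row["fazekas"]),
                moca=float(row["moca"]) if pd.notna(row.get("moca")) else None,
                eyes=eyes,
                eye_quality=quality,
                mri=mri,
                exclusion_flags=flags,
            )
        )
    return records
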