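"""Run configuration: a single serializable block of pipeline constants."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .thresholding import PHANSALKAR_DEFAULTS


@dataclass
class RunConfig:
    """All tunable constants of an analysis run.

    The configuration is serializable and its SHA-256 hash is recorded in the
    run manifest so any output file can be traced to the exact settings.
    """

    seed: int = 0
    min_quality_index: int = 8
    px_size_um: float = 6.0
    phansalkar: dict = field(default_factory=lambda: dict(PHANSALKAR_DEFAULTS))
    # one resolvable capillary-scale element (4 px at 6 um/px); single-pixel
    # speckle components otherwise dominate the small end of the size
    # distribution fit
    void_min_size_um2: float = 144.0
    void_connectivity: int = 8
    void_n_bins: int = 10
    lesion_connectivity: int = 26
    rho_eye: float = 0.8
    run_age_matched: bool = True
    run_cases_only: bool = True
    # demo-only sizes: kept modest so the synthetic end-to-end run stays fast
    demo_vessel_shape: tuple = (256, 256)
    demo_choriocap_shape: tuple = (384, 384)
    demo_lesion_grid: tuple = (64, 64, 64)
    demo_image_participants: int = 3

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        flat = {}
        for key, value in data.items():
            if isinstance(value, dict) and key != "phansalkar":
                flat.update(value)
            else:
                flat[key] = value
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in flat.items() if k in known}
        cfg = cls(**kwargs)
        for tup_field in ("demo_vessel_shape", "demo_choriocap_shape", "demo_lesion_grid"):
            setattr(cfg, tup_field, tuple(getattr(cfg, tup_field)))
        return cfg
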