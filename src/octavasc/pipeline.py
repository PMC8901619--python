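"""End-to-end orchestration: images -> metrics -> cohort table -> reports.

Two entry points:

* :func:`run_images` walks a directory of per-eye en-face images named
  ``<participant>_<eye>_<layer>.tif`` (or ``.png``), computes the per-eye
  metrics of each layer, and appends them to a cohort table. Unreadable
  images flag the participant as ``poor_image_quality`` and the run
  continues.
* :func:`run_demo` generates a complete synthetic study — cohort table,
  en-face images for a few participants, lesion volumes — runs the analysis
  and writes the full report bundle. Deterministic given (seed, config).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .choriocap import (
    FlowVoidSet,
    detect_flow_voids,
    fit_void_size_distribution,
    reflectivity_stats,
)
from .config import RunConfig
from .exceptions import InsufficientDataError, OctavascError
from .images import load_angiogram, save_angiogram
from .mri import compute_wmi, save_lesion_mask
from .records import records_from_frame, records_to_frame
from .stats import build_reports
from .vessel import compute_vessel_metrics

logger = logging.getLogger("octavasc")

_LAYER_TOKENS = {"sup": "superficial", "superficial": "superficial",
                 "deep": "deep", "cc": "choriocapillaris",
                 "choriocapillaris": "choriocapillaris"}
_METRIC_PREFIX = {"superficial": "sup", "deep": "deep"}


def _parse_image_name(path: Path):
    stem = path.stem
    parts = stem.rsplit("_", 2)
    if len(parts) != 3:
        raise OctavascError(f"image name {path.name!r} is not <participant>_<eye>_<layer>")
    pid, eye, layer_token = parts
    if eye not in ("OD", "OS"):
        raise OctavascError(f"unknown eye token {eye!r} in {path.name!r}")
    layer = _LAYER_TOKENS.get(layer_token.lower())
    if layer is None:
        raise OctavascError(f"unknown layer token {layer_token!r} in {path.name!r}")
    return pid, eye, layer


def run_images(
    image_dir: str | Path,
    cohort_csv: str | Path,
    config: RunConfig | None = None,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Process a directory of en-face images and augment the cohort table.

    Per-eye columns are appended for each successfully analysed layer; every
    skipped image is logged with its reason, and a participant with an
    unreadable image is flagged ``poor_image_quality``.
    """
    config = config or RunConfig()
    image_dir = Path(image_dir)
    df = pd.read_csv(cohort_csv)
    df["id"] = df["id"].astype(str)
    df = df.set_index("id", drop=False)

    n_ok, n_skipped = 0, 0
    void_sets: dict[str, list[FlowVoidSet]] = {}
    paths = sorted(p for p in image_dir.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png"))
    for path in paths:
        try:
            pid, eye, layer = _parse_image_name(path)
        except OctavascError as err:
            logger.warning("skipping %s: %s", path.name, err)
            n_skipped += 1
            continue
        if pid not in df.index:
            logger.warning("skipping %s: participant %s not in cohort table", path.name, pid)
            n_skipped += 1
            continue
        suffix = eye.lower()
        try:
            image = load_angiogram(path, layer=layer, eye=eye, px_size_um=config.px_size_um)
        except Exception as err:  # unreadable file: flag, continue
            logger.warning("unreadable image %s (%s); flagging %s", path.name, err, pid)
            df.loc[pid, "flag_poor_image_quality"] = 1
            n_skipped += 1
            continue
        qcol = f"quality_{suffix}"
        if qcol in df.columns and pd.notna(df.loc[pid, qcol]):
            image.quality_index = int(df.loc[pid, qcol])
        try:
            if layer in ("superficial", "deep"):
                metrics = compute_vessel_metrics(image, min_quality=config.min_quality_index)
                tag = _METRIC_PREFIX[layer]
                df.loc[pid, f"vd_{tag}_{suffix}"] = metrics.vessel_density
                df.loc[pid, f"sd_{tag}_{suffix}"] = metrics.skeleton_density
                df.loc[pid, f"vdi_{tag}_{suffix}"] = metrics.vessel_diameter_index
            else:
                refl = reflectivity_stats(image)
                df.loc[pid, f"cc_mean_{suffix}"] = refl.mean
                df.loc[pid, f"cc_sd_{suffix}"] = refl.sd
                voids = detect_flow_voids(
                    image,
                    min_size_um2=config.void_min_size_um2,
                    connectivity=config.void_connectivity,
                    phansalkar_params=config.phansalkar,
                )
                df.loc[pid, f"fv_n_{suffix}"] = voids.n_voids
                df.loc[pid, f"fv_mean_um2_{suffix}"] = voids.mean_size_um2
                void_sets.setdefault(pid, []).append(voids)
                try:
                    fit = fit_void_size_distribution(voids, n_bins=config.void_n_bins)
                    df.loc[pid, f"fv_slope_{suffix}"] = fit.slope
                    df.loc[pid, f"fv_intercept_{suffix}"] = fit.intercept
                except InsufficientDataError as err:
                    logger.info("no distribution fit for %s: %s", path.name, err)
            n_ok += 1
        except OctavascError as err:
            logger.warning("skipping %s: %s", path.name, err)
            n_skipped += 1
    logger.info("processed %d images, skipped %d", n_ok, n_skipped)

    df = df.reset_index(drop=True)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def run_demo(
    seed: int = 0,
    config: RunConfig | None = None,
    out_dir: str | Path = "octavasc_demo",
    n_cases: int = 20,
    n_controls: int = 10,
) -> dict:
    """One-command synthetic end-to-end run; returns the written file paths.

    Generates a study-parameterized cohort, writes it as CSV, runs the
    statistical layer into the report bundle, and additionally exercises the
    imaging path: for a few participants it synthesizes per-eye plexus and
    choriocapillaris images plus a lesion volume, analyses them, and writes
    the image-derived metrics next to the table-derived ones.
    """
    config = config or RunConfig(seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    cohort_seed, image_seed, lesion_seed = (int(s) % (2**31) for s in ss.generate_state(3))

    params = synthetic.CohortParams(
        n_cases=n_cases, n_controls=n_controls, rng_seed=cohort_seed
    )
    records = synthetic.generate_cohort(params)
    cohort_df = records_to_frame(records)
    cohort_path = out / "cohort.csv"
    cohort_df.to_csv(cohort_path, index=False)

    # statistical layer with a per-eye void-set reconstruction for the
    # intercept comparison (sampled under the same per-group void model)
    rng_voids = np.random.default_rng(cohort_seed + 1)
    void_sets = {}
    for rec in records:
        icpt = params.void_intercepts[rec.group] + rng_voids.normal(
            0.0, params.void_intercept_sd[rec.group]
        )
        void_sets[rec.id] = [
            FlowVoidSet(
                sizes_px=synthetic.sample_void_sizes(
                    rng_voids, params.void_slope, icpt, params.void_size_range
                ),
                px_size_um=params.px_size_um,
                image_id=f"{rec.id}_{eye}",
            )
            for eye in ("OD", "OS")
        ]
    report = build_reports(records, min_quality=config.min_quality_index, void_sets=void_sets)

    manifest = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_cases": n_cases,
        "n_controls": n_controls,
    }
    paths = report.save(out / "reports", manifest=manifest)
    paths["cohort"] = str(cohort_path)

    # imaging subpipeline on a subset of participants
    image_dir = out / "images"
    image_dir.mkdir(exist_ok=True)
    img_rng = np.random.default_rng(image_seed)
    truth_sidecar = {}
    subset = records[: config.demo_image_participants]
    for i, rec in enumerate(subset):
        for eye in ("OD", "OS"):
            for layer, tag in (("superficial", "sup"), ("deep", "deep")):
                truth = synthetic.generate_vessel_image(
                    seed=int(img_rng.integers(2**31)),
                    shape=tuple(config.demo_vessel_shape),
                    target_fraction=rec.eyes[eye][f"vd_{tag}"],
                    layer=layer,
                )
                truth.image.eye = eye
                path = image_dir / f"{rec.id}_{eye}_{tag}.tif"
                save_angiogram(path, truth.image)
                truth_sidecar[path.name] = {
                    "true_vessel_fraction": truth.true_vessel_fraction,
                    "mean_width_px": truth.mean_width_px,
                }
            cc = synthetic.generate_choriocap_image(
                seed=int(img_rng.integers(2**31)),
                shape=tuple(config.demo_choriocap_shape),
                background_mean=rec.eyes[eye]["cc_mean"],
                intercept=2.6,
            )
            cc.image.eye = eye
            path = image_dir / f"{rec.id}_{eye}_cc.tif"
            save_angiogram(path, cc.image)
            truth_sidecar[path.name] = {
                "n_voids": int(cc.true_void_sizes.size),
                "slope": cc.slope,
                "intercept": cc.intercept,
            }
    (image_dir / "truth.json").write_text(json.dumps(truth_sidecar, indent=2))
    image_df = run_images(image_dir, cohort_path, config=config,
                          out_csv=out / "cohort_image_metrics.csv")
    paths["image_metrics"] = str(out / "cohort_image_metrics.csv")
    paths["images"] = str(image_dir)

    # lesion volumes for the same subset
    mri_dir = out / "mri"
    mri_dir.mkdir(exist_ok=True)
    mri_rows = []
    les_rng = np.random.default_rng(lesion_seed)
    for rec in subset:
        truth = synthetic.generate_lesion_volume(
            seed=int(les_rng.integers(2**31)),
            grid=tuple(config.demo_lesion_grid),
            n_lesions=rec.mri.nol if rec.mri else 10,
        )
        mask_path = mri_dir / f"{rec.id}_lesions.nii"
        save_lesion_mask(mask_path, truth.mask, truth.voxel_dims_mm)
        summary = compute_wmi(
            truth.mask, truth.voxel_dims_mm, truth.tissue_volumes_ml,
            connectivity=config.lesion_connectivity,
        )
        mri_rows.append(
            {
                "id": rec.id,
                "nol": summary.nol,
                "true_n_lesions": truth.true_n_lesions,
                "lesion_volume_ml": summary.lesion_volume_ml,
                "tiv_ml": summary.tiv_ml,
                "wmi": summary.wmi,
                "log_wmi": summary.log_wmi,
                "manifest_hash": config.config_hash(),
            }
        )
    mri_csv = mri_dir / "mri_summaries.csv"
    pd.DataFrame(mri_rows).to_csv(mri_csv, index=False)
    paths["mri"] = str(mri_csv)
    return paths


def run_stats(
    cohort_csv: str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path = "octavasc_reports",
) -> dict:
    """Statistical layer only: cohort CSV in, report bundle out."""
    config = config or RunConfig()
    df = pd.read_csv(cohort_csv)
    records = records_from_frame(df)
    report = build_reports(records, min_quality=config.min_quality_index)
    manifest = {"seed": config.seed, "config_hash": config.config_hash(),
                "config": config.to_dict(), "input": str(cohort_csv)}
    return report.save(out_dir, manifest=manifest)
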