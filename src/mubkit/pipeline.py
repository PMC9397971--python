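"""simulate -> extract -> analyze orchestration with file I/O.

Images travel as 8-bit grayscale PNG with a JSON calibration sidecar
(``row_spacing_mm``, ``col_spacing_mm``, ``plane``, ``side``,
``subject``, ``image_index``) and a ground-truth ROI polygon JSON,
standing in for the manual outlines of the acquisition protocol.
Tables are UTF-8 comma-separated CSV with '.' decimals and empty strings
for missing values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .biomarkers import GLCMSpec, average_triplicate, extract_biomarkers
from .errors import InvalidParameterError, MubkitError, SchemaError
from .geometry import (
    PLANES,
    CalibratedImage,
    rasterize_roi,
    roi_from_ground_truth,
    trim_lateral_margins,
)
from .synthetic import CohortConfig, ImageRecord, iter_cohort_images, simulate_cohort
from .validity import build_report, mub_column

log = logging.getLogger("mubkit")

_SIDE_SHORT = {"asymptomatic": "asympt", "symptomatic": "sympt"}


@dataclass
class PipelineConfig:
    """Run configuration shared by the pipeline commands."""

    out_dir: Path = Path("mubkit_out")
    seed: int = 0
    n_subjects: int = 41
    subgroup_size: int = 20
    images_per_plane: int = 3
    rows: int = 128
    cols: int = 128
    alpha: float = 0.05
    bh_correction: bool = False
    di_variant: str = "group_means"
    glcm_distance: int = 1
    glcm_levels: int = 64
    glcm_kernel: str = "inverse_square"
    trim_longitudinal_mm: float = 10.0
    trim_transverse_mm: float = 5.0

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if not 0 < self.alpha < 1:
            raise InvalidParameterError("alpha must lie in (0, 1)")
        if self.trim_longitudinal_mm <= 0 or self.trim_transverse_mm <= 0:
            raise InvalidParameterError("trim widths must be positive")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") \
                else json.load(fh)
        raw = dict(raw or {})
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(n_subjects=self.n_subjects, seed=self.seed,
                            subgroup_size=min(self.subgroup_size, self.n_subjects),
                            images_per_plane=self.images_per_plane)

    def glcm_spec(self) -> GLCMSpec:
        return GLCMSpec(distance_px=self.glcm_distance, levels=self.glcm_levels,
                        kernel=self.glcm_kernel)

    def trim_width(self, plane: str) -> float:
        return self.trim_longitudinal_mm if plane == "longitudinal" \
            else self.trim_transverse_mm


def _image_stem(rec: ImageRecord) -> str:
    return f"s{rec.subject:03d}_{rec.side}_{rec.plane}_{rec.image_index}"


def cmd_simulate(config: PipelineConfig) -> dict:
    """Render the synthetic cohort to disk: PNG frames, JSON sidecars,
    ground-truth ROI polygons, cohort CSV and a manifest."""
    out = config.out_dir
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    cohort_cfg = config.cohort_config()
    cohort = simulate_cohort(cohort_cfg)
    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)

    files = []
    for rec in iter_cohort_images(cohort_cfg, cohort, config.rows, config.cols):
        stem = _image_stem(rec)
        iio.imwrite(img_dir / f"{stem}.png", rec.image.pixels)
        sidecar = {
            "row_spacing_mm": rec.image.row_spacing_mm,
            "col_spacing_mm": rec.image.col_spacing_mm,
            "plane": rec.plane, "side": rec.image.side,
            "subject": rec.subject, "image_index": rec.image_index,
        }
        (img_dir / f"{stem}.json").write_text(json.dumps(sidecar, sort_keys=True))
        polygon = roi_from_ground_truth(rec.boundaries)
        (img_dir / f"{stem}_roi.json").write_text(
            json.dumps({"polygon": polygon.tolist()}))
        files.append(f"{stem}.png")
    manifest = {"seed": config.seed, "n_subjects": config.n_subjects,
                "rows": config.rows, "cols": config.cols, "images": sorted(files)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("simulated %d subjects, %d images -> %s",
             config.n_subjects, len(files), out)
    return {"cohort_csv": cohort_path, "image_dir": img_dir,
            "n_images": len(files)}


def _load_frame(png_path: Path) -> tuple[CalibratedImage, np.ndarray, dict]:
    sidecar_path = png_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise SchemaError(f"missing calibration sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    roi_path = png_path.with_name(png_path.stem + "_roi.json")
    if not roi_path.exists():
        raise SchemaError(f"missing ROI polygon {roi_path}")
    polygon = np.asarray(json.loads(roi_path.read_text())["polygon"], dtype=float)
    pixels = iio.imread(png_path)
    image = CalibratedImage(pixels=pixels,
                            row_spacing_mm=meta["row_spacing_mm"],
                            col_spacing_mm=meta["col_spacing_mm"],
                            plane=meta["plane"], side=meta["side"],
                            image_index=meta["image_index"])
    return image, polygon, meta


def cmd_extract(config: PipelineConfig) -> dict:
    """Extract biomarkers for every frame and average the triplicates.

    Writes ``mub_long.csv`` (one row per image) and ``mub_wide.csv``
    (one row per subject, columns ``{mub}_{plane}_{side}``).  Corrupt or
    incomplete frames are skipped with a logged warning and counted in
    the returned summary.
    """
    img_dir = config.out_dir / "images"
    spec = config.glcm_spec()
    long_rows, n_failed = [], 0
    for png_path in sorted(img_dir.glob("*.png")):
        try:
            image, polygon, meta = _load_frame(png_path)
            roi = rasterize_roi(polygon, image)
            roi = trim_lateral_margins(roi, image, config.trim_width(image.plane))
            bset = extract_biomarkers(image, roi, spec)
        except SchemaError:
            raise
        except (MubkitError, OSError, ValueError, KeyError) as exc:
            log.warning("skipping %s: %s", png_path.name, exc)
            n_failed += 1
            continue
        long_rows.append({
            "subject": meta["subject"], "side": _SIDE_SHORT[meta["side"]],
            "plane": meta["plane"], "image_index": meta["image_index"],
            "thickness": bset.mean_thickness_mm,
            "echogenicity": bset.echogenicity,
            "homogeneity": bset.homogeneity,
        })
    if not long_rows:
        raise SchemaError(f"no usable frames found under {img_dir}")
    long_df = pd.DataFrame(long_rows)
    long_df.to_csv(config.out_dir / "mub_long.csv", index=False)

    wide = {}
    from .biomarkers import BiomarkerSet  # local to avoid cycle at import time
    for (subject, side, plane), grp in long_df.groupby(["subject", "side", "plane"]):
        sets = [BiomarkerSet(mean_thickness_mm=r.thickness,
                             echogenicity=r.echogenicity,
                             homogeneity=r.homogeneity, plane=plane, side=side)
                for r in grp.itertuples()]
        avg = sets[0] if len(sets) == 1 else average_triplicate(sets)
        row = wide.setdefault(subject, {"subject": subject})
        row[mub_column("thickness", plane, side)] = avg.mean_thickness_mm
        row[mub_column("echogenicity", plane, side)] = avg.echogenicity
        row[mub_column("homogeneity", plane, side)] = avg.homogeneity
    wide_df = pd.DataFrame(sorted(wide.values(), key=lambda r: r["subject"]))
    wide_df.to_csv(config.out_dir / "mub_wide.csv", index=False)
    log.info("extracted %d frames (%d skipped) -> mub_wide.csv",
             len(long_rows), n_failed)
    return {"mub_wide_csv": config.out_dir / "mub_wide.csv",
            "n_frames": len(long_rows), "n_failed": n_failed}


def cmd_analyze(config: PipelineConfig) -> dict:
    """Join extracted biomarkers with the cohort clinical table and emit
    the validity report (paired rows, correlation blocks, summary)."""
    out = config.out_dir
    mub = pd.read_csv(out / "mub_wide.csv")
    cohort = pd.read_csv(out / "cohort.csv")
    unmatched = sorted(set(mub["subject"]).symmetric_difference(cohort["subject"]))
    if unmatched:
        raise SchemaError(f"subjects fail to join between biomarker and "
                          f"cohort tables: {unmatched}")
    merged = cohort.merge(mub, on="subject", validate="one_to_one")
    if merged.empty:
        raise SchemaError("join of biomarker and cohort tables is empty")
    report = build_report(merged, alpha=config.alpha,
                          bh_correction=config.bh_correction)
    report.paired_rows.to_csv(out / "table2.csv", index=False)
    report.sympt_block.to_csv(out / "table3_sympt.csv", index=False)
    report.di_block.to_csv(out / "table3_di.csv", index=False)
    report.group_rows.to_csv(out / "group_compare.csv", index=False)
    summary = {
        "seed": config.seed,
        "alpha": config.alpha,
        "bh_correction": config.bh_correction,
        "n_subjects": int(len(merged)),
        "n_significant": report.n_significant,
        "n_significant_nonnegligible": report.n_significant_nonnegligible,
        "tests_used": report.paired_rows.get("test_used",
                                             pd.Series(dtype=str)).value_counts().to_dict(),
        "notes": report.notes,
        "versions": {"mubkit": __version__, "python": platform.python_version(),
                     "numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    log.info("analysis: %d significant cells (%d non-negligible)",
             report.n_significant, report.n_significant_nonnegligible)
    return {"summary": summary, "report": report}


def extract_simulated_cohort(cohort_cfg: CohortConfig, rows: int = 64,
                             cols: int = 64) -> pd.DataFrame:
    """Simulate a cohort, render every frame in memory, extract the
    biomarkers and return the clinical table joined with the
    triplicate-averaged ``{mub}_{plane}_{side}`` columns."""
    cohort = simulate_cohort(cohort_cfg)
    acc: dict[tuple, list] = {}
    for rec in iter_cohort_images(cohort_cfg, cohort, rows, cols):
        roi = rasterize_roi(roi_from_ground_truth(rec.boundaries), rec.image)
        roi = trim_lateral_margins(roi, rec.image)
        b = extract_biomarkers(rec.image, roi)
        acc.setdefault((rec.subject, rec.side, rec.plane), []).append(
            (b.mean_thickness_mm, b.echogenicity, b.homogeneity))
    rows_out = {}
    for (subject, side, plane), vals in acc.items():
        th, ec, ho = np.mean(vals, axis=0)
        row = rows_out.setdefault(subject, {"subject": subject})
        row[mub_column("thickness", plane, side)] = th
        row[mub_column("echogenicity", plane, side)] = ec
        row[mub_column("homogeneity", plane, side)] = ho
    mub = pd.DataFrame(sorted(rows_out.values(), key=lambda r: r["subject"]))
    return cohort.merge(mub, on="subject", validate="one_to_one")


def cmd_report(config: PipelineConfig) -> dict:
    """Full pipeline: simulate, extract, analyze."""
    cmd_simulate(config)
    cmd_extract(config)
    return cmd_analyze(config)
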