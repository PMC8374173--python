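"""Manifest-driven batch workflows: build a calibration, analyze craters.

These functions tie the library together into the two shell-level jobs:

* :func:`run_calibrate` — walk a standards manifest (one row per droplet
  image), measure every droplet, filter saturated measurements, fit the
  power-law calibration and write the measurement CSV, per-concentration
  summary CSV and calibration JSON;
* :func:`run_analyze` — walk a crater manifest (one row per crater, three
  co-registered images), run the full sizing/quantitation/screening chain
  and write the crater-record CSV;
* :func:`write_calibration_dataset` / :func:`write_crater_dataset` —
  render synthetic datasets to disk in exactly the formats the two jobs
  consume, so a complete round trip needs no real data.

Per-row failures are logged and skipped; a run only fails when nothing
usable remains.  Outputs are sorted and floats written with 9 significant
digits so reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationFit,
    DropletStandard,
    build_calibration,
    load_calibration,
    save_calibration,
)
from .craters import (
    ParticleCraterCalibration,
    analyze_crater,
    load_pc_calibration,
)
from .imaging import blue_channel, read_roi_file, read_rgb_image
from .measure import (
    DEFAULT_ARTIFACT_RATIO,
    DEFAULT_SATURATION_THRESHOLD,
    measure_roi,
)
from .synth import make_calibration_series, make_crater_set, render_scene

__all__ = [
    "RunConfig",
    "run_calibrate",
    "run_analyze",
    "write_calibration_dataset",
    "write_crater_dataset",
]

logger = logging.getLogger("impactquant")

_FLOAT_FMT = "%.9g"


@dataclass
class RunConfig:
    """Run-level settings shared by the workflows.

    ``pixel_size_um_by_objective`` must be supplied from the microscope
    configuration (the pixel scale cannot be inferred from the images);
    manifest rows may override it with an explicit ``pixel_size_um``
    column.
    """

    pixel_size_um_by_objective: dict[str, float] = field(
        default_factory=lambda: {"10x": 1.0, "20x": 0.5}
    )
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD
    artifact_ratio_threshold: float = DEFAULT_ARTIFACT_RATIO
    aggregation: str = "mean-per-concentration"
    projectile_concentration_uM: float = 100.0
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config field(s) {sorted(unknown)}")
        return cls(**doc)

    def pixel_size_for(self, row: pd.Series) -> float:
        if "pixel_size_um" in row and not pd.isna(row["pixel_size_um"]):
            return float(row["pixel_size_um"])
        objective = str(row["objective"])
        try:
            return self.pixel_size_um_by_objective[objective]
        except KeyError:
            raise ValueError(
                f"no pixel size configured for objective {objective!r}"
            ) from None


def _load_manifest(manifest: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(manifest, pd.DataFrame):
        return manifest
    return pd.read_csv(manifest)


def run_calibrate(
    config: RunConfig,
    standards_manifest: str | Path | pd.DataFrame,
    outdir: str | Path,
    objective: str | None = None,
) -> tuple[CalibrationFit, pd.DataFrame]:
    """Measure every standard droplet and fit the picomole calibration.

    Writes ``measurements.csv``, ``summary.csv`` and ``calibration.json``
    to ``outdir`` and returns the fit plus the measurement table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(standards_manifest)
    if objective is None:
        objectives = manifest["objective"].unique()
        if len(objectives) != 1:
            raise ValueError(
                "manifest mixes objectives; pass objective= to choose one"
            )
        objective = str(objectives[0])

    standards: list[DropletStandard] = []
    rows = []
    for idx, row in manifest.iterrows():
        try:
            px = config.pixel_size_for(row)
            planes = read_rgb_image(
                row["image_path"], float(row["exposure_s"]), px, "humid"
            )
            plane = blue_channel(planes)
            rois = read_roi_file(row["roi_file"])
            label = str(row["roi_label"])
            signal = next(
                r for r in rois if r.label == label and r.role == "signal"
            )
            backgrounds = [r for r in rois if r.role == "background"]
            meas = measure_roi(plane, signal, backgrounds)
        except StopIteration:
            logger.warning(
                "row %s skipped: no signal ROI labelled %r in %s",
                idx, row.get("roi_label"), row.get("roi_file"),
            )
            continue
        except Exception as exc:
            logger.warning("row %s skipped: %s", idx, exc)
            continue

        saturated = meas.saturated_fraction > config.saturation_threshold
        conc = float(row["concentration_uM"])
        std = DropletStandard(
            concentration_uM=conc,
            volume_nL=float(row["volume_nL"]),
            replicate_id=int(row["replicate_id"]),
            objective=str(row["objective"]),
            measurement=meas,
        )
        if not saturated:
            standards.append(std)
        else:
            logger.warning(
                "droplet %r excluded from the fit: saturated fraction %.3g "
                "exceeds %.3g",
                meas.roi_label, meas.saturated_fraction, config.saturation_threshold,
            )
        rows.append(
            {
                "roi_label": meas.roi_label,
                "concentration_uM": conc,
                "volume_nL": float(row["volume_nL"]),
                "picomoles": std.picomoles,
                "replicate_id": std.replicate_id,
                "objective": std.objective,
                "humidity_state": "humid",
                "mean_signal": meas.mean_signal,
                "mean_background": meas.mean_background,
                "area_um2": meas.area_um2,
                "exposure_s": meas.exposure_s,
                "integrated_intensity": meas.integrated_intensity,
                "saturated_fraction": meas.saturated_fraction,
                "saturated_flag": saturated,
            }
        )

    if not rows:
        raise RuntimeError("all manifest rows failed; no usable standards")
    measurements = pd.DataFrame(rows).sort_values(
        ["concentration_uM", "replicate_id", "roi_label"], kind="mergesort"
    )
    measurements.to_csv(
        outdir / "measurements.csv", index=False, float_format=_FLOAT_FMT
    )

    fit, summaries = build_calibration(
        standards, objective=objective, aggregation=config.aggregation
    )
    save_calibration(fit, outdir / "calibration.json")

    summary_rows = []
    for conc, summ in summaries.items():
        summary_rows.append(
            {
                "concentration_uM": conc,
                "n": summ.n,
                "mean": summ.mean,
                "median": summ.median,
                "sd": summ.sd,
                "q1": summ.q1,
                "q3": summ.q3,
                "iqr": summ.iqr,
                "lower_fence": summ.lower_fence,
                "upper_fence": summ.upper_fence,
                "n_outliers": len(summ.outliers),
            }
        )
    pd.DataFrame(summary_rows).sort_values("concentration_uM").to_csv(
        outdir / "summary.csv", index=False, float_format=_FLOAT_FMT
    )
    logger.info(
        "calibration (%s, %s): a = %.4g +/- %.2g, b = %.4g +/- %.2g on %d points",
        objective, config.aggregation, fit.a, fit.se_a, fit.b, fit.se_b, fit.n_points,
    )
    return fit, measurements


def run_analyze(
    config: RunConfig,
    crater_manifest: str | Path | pd.DataFrame,
    calibration: str | Path | CalibrationFit,
    pc_calibration: str | Path | ParticleCraterCalibration,
    outdir: str | Path,
) -> pd.DataFrame:
    """Analyze every crater in the manifest and write ``craters.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not isinstance(calibration, CalibrationFit):
        cal_path = Path(calibration)
        if not cal_path.exists():
            raise FileNotFoundError(
                f"calibration file {cal_path} not found; run the calibrate "
                "workflow first"
            )
        calibration = load_calibration(cal_path)
    if not isinstance(pc_calibration, ParticleCraterCalibration):
        pc_calibration = load_pc_calibration(pc_calibration)

    manifest = _load_manifest(crater_manifest)
    records = []
    for idx, row in manifest.iterrows():
        try:
            px = config.pixel_size_for(row)
            objective = str(row["objective"])
            if calibration.objective and objective != calibration.objective:
                logger.warning(
                    "crater %r imaged at %s but calibration is for %s",
                    row["crater_label"], objective, calibration.objective,
                )
            humid = blue_channel(
                read_rgb_image(
                    row["humid_path"], float(row["exposure_s_humid"]), px, "humid"
                )
            )
            dry = blue_channel(
                read_rgb_image(
                    row["dry_path"], float(row["exposure_s_dry"]), px, "dry"
                )
            )
            rois = read_roi_file(row["roi_file"])
            label = str(row["crater_label"])
            crater_roi = next(
                r for r in rois if r.label == label and r.role == "signal"
            )
            backgrounds = [r for r in rois if r.role == "background"]
            rec = analyze_crater(
                crater_roi,
                dry,
                humid,
                backgrounds,
                calibration,
                pc_calibration,
                projectile_concentration_uM=config.projectile_concentration_uM,
                artifact_ratio_threshold=config.artifact_ratio_threshold,
            )
        except StopIteration:
            logger.warning(
                "row %s skipped: no signal ROI labelled %r in %s",
                idx, row.get("crater_label"), row.get("roi_file"),
            )
            continue
        except Exception as exc:
            logger.warning("row %s skipped: %s", idx, exc)
            continue
        records.append(
            {
                "crater_label": rec.crater_label,
                "major_axis_um": rec.major_axis_um,
                "minor_axis_um": rec.minor_axis_um,
                "crater_diameter_um": rec.crater_diameter_um,
                "particle_diameter_um": rec.particle_diameter_um,
                "impactor_pmol": rec.impactor_pmol,
                "crater_pmol": rec.crater_pmol,
                "capture_efficiency_pct": rec.capture_efficiency_pct,
                "artifact_flag": rec.artifact_flag,
                "extrapolated": rec.extrapolated,
                "calibration_fit_id": rec.calibration_fit_id,
            }
        )

    columns = [
        "crater_label", "major_axis_um", "minor_axis_um", "crater_diameter_um",
        "particle_diameter_um", "impactor_pmol", "crater_pmol",
        "capture_efficiency_pct", "artifact_flag", "extrapolated",
        "calibration_fit_id",
    ]
    out = pd.DataFrame(records, columns=columns).sort_values(
        "crater_label", kind="mergesort"
    )
    out.to_csv(outdir / "craters.csv", index=False, float_format=_FLOAT_FMT)
    effs = out["capture_efficiency_pct"].dropna()
    if len(effs):
        logger.info(
            "analyzed %d craters (%d artifacts); capture efficiencies "
            "%.3g-%.3g%%",
            len(out), int(out["artifact_flag"].sum()), effs.min(), effs.max(),
        )
    else:
        logger.info("analyzed %d craters; no efficiency estimates", len(out))
    return out


# ---------------------------------------------------------------------------
# synthetic dataset writers (drop-in replacements for real data)


def write_calibration_dataset(
    outdir: str | Path, seed: int = 0, **series_kwargs
) -> Path:
    """Render a synthetic standard-droplet dataset and its manifest CSV.

    Returns the manifest path; the manifest is directly consumable by
    :func:`run_calibrate`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenes, manifest = make_calibration_series(seed=seed, **series_kwargs)
    image_paths, roi_paths = [], []
    for scene, (_, row) in zip(scenes, manifest.iterrows()):
        stem = str(row["roi_label"])
        paths = render_scene(scene).write(outdir, stem)
        image_paths.append(str(paths["humid"]))
        roi_paths.append(str(paths["rois"]))
    manifest = manifest.assign(image_path=image_paths, roi_file=roi_paths)
    manifest_path = outdir / "standards_manifest.csv"
    manifest.to_csv(manifest_path, index=False, float_format=_FLOAT_FMT)
    return manifest_path


def _brightfield_outline(scene, dep_shape) -> np.ndarray:
    """Mid-gray bright-field companion with a darker rim at the crater edge."""
    yy, xx = np.mgrid[0 : scene.height_px, 0 : scene.width_px]
    theta = math.radians(dep_shape.angle_deg)
    dx = xx - dep_shape.cx
    dy = yy - dep_shape.cy
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    r = np.sqrt((u / dep_shape.a) ** 2 + (v / dep_shape.b) ** 2)
    img = np.full(r.shape, 30000.0)
    img[np.abs(r - 1.0) * min(dep_shape.a, dep_shape.b) < 2.0] = 8000.0
    return img.astype(np.uint16)


def write_crater_dataset(outdir: str | Path, seed: int = 0, **set_kwargs) -> Path:
    """Render a synthetic crater dataset (bright-field/dry/humid triples).

    Returns the crater manifest path consumable by :func:`run_analyze`;
    the ground truth is written alongside as ``truth.csv``.
    """
    from .imaging import ImagePlane, write_rgb_image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenes, truth = make_crater_set(seed=seed, **set_kwargs)
    rows = []
    for scene, (_, t) in zip(scenes, truth.iterrows()):
        stem = str(t["crater_label"])
        rendered = render_scene(scene)
        paths = rendered.write(outdir, stem)
        bf_px = _brightfield_outline(scene, scene.deposits[0].shape)
        bf_plane = ImagePlane(
            bf_px, bit_depth=16, channel="mono",
            exposure_s=1.0, pixel_size_um=scene.pixel_size_um,
            humidity_state="brightfield",
        )
        bf_path = outdir / f"{stem}_brightfield.tif"
        write_rgb_image(bf_path, [bf_plane])
        rows.append(
            {
                "crater_label": stem,
                "brightfield_path": str(bf_path),
                "dry_path": str(paths["dry"]),
                "humid_path": str(paths["humid"]),
                "roi_file": str(paths["rois"]),
                "exposure_s_brightfield": 1.0,
                "exposure_s_dry": scene.exposure_s,
                "exposure_s_humid": scene.exposure_s,
                "objective": t["objective"],
                "pixel_size_um": scene.pixel_size_um,
            }
        )
    manifest_path = outdir / "craters_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False, float_format=_FLOAT_FMT)
    truth.to_csv(outdir / "truth.csv", index=False, float_format=_FLOAT_FMT)
    return manifest_path
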