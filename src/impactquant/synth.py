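"""Synthetic fluorescence scenes with ground-truth manifests.

Renders the two experimental designs end-to-end testable without any real
microscopy data:

* droplet standard series — dried-and-rehumidified droplets of known
  picomole content (concentration x volume), imaged per-concentration at
  the exposure schedule used for real standards (10 s at 10-100 nM, 1 s at
  1 µM, 0.1 s at 10 µM);
* crater scenes — elliptical residue deposits inside crater outlines whose
  size follows a particle-crater calibration in reverse, with a matching
  bright-field outline image.

Each deposit is drawn into the blue channel as a uniform (or
centre-weighted) profile whose total excess count equals

    brightness_per_pmol * picomoles * exposure_s / pixel_size_um**2

so that the measured integrated intensity recovers
``brightness_per_pmol * picomoles`` exactly up to pixelation.
``brightness_per_pmol`` is an arbitrary scene constant: the calibration
workflow must estimate and cancel it, which is precisely what closed-loop
tests verify.  The dry companion image scales every deposit's emission by
``humidity_contrast`` (dried tracer films are only weakly fluorescent);
a deposit given a contrast near 1 emulates a humidity-insensitive
contaminant and must be caught by the artifact screen.

All randomness flows from the scene seed; identical scenes render
bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .calibration import droplet_picomoles
from .craters import ParticleCraterCalibration, impactor_picomoles
from .imaging import EllipseShape, ImagePlane, Roi, write_rgb_image, write_roi_file

__all__ = [
    "Deposit",
    "SynthScene",
    "RenderedScene",
    "render_scene",
    "make_calibration_series",
    "make_crater_set",
    "exposure_for_concentration",
    "droplet_diameter_um",
    "DEFAULT_BRIGHTNESS_PER_PMOL",
    "DEFAULT_HUMIDITY_CONTRAST",
]

#: Scene emission constant, counts*um^2*s^-1 per picomole.  Arbitrary: the
#: calibration fit measures it; its value only sets the count scale.
DEFAULT_BRIGHTNESS_PER_PMOL = 1e10

#: Dry/humid emission ratio of dried tracer films (weakly fluorescent dry).
DEFAULT_HUMIDITY_CONTRAST = 0.02

_SUPERSAMPLE = 4  # subpixel grid per axis for edge anti-aliasing


@dataclass
class Deposit:
    """One fluorescent deposit plus the ROI that will be drawn around it.

    ``shape`` is the ROI outline (droplet rim or crater rim); the emitting
    region is the same ellipse shrunk by ``fill_fraction`` so its
    anti-aliased edge stays inside the ROI and the ROI captures the whole
    photon budget.
    """

    label: str
    shape: EllipseShape
    picomoles: float
    profile: Literal["uniform", "radial-falloff"] = "uniform"
    fill_fraction: float = 0.9
    humidity_contrast: float | None = None  # None -> scene default

    def __post_init__(self) -> None:
        if self.picomoles < 0:
            raise ValueError("picomoles must be >= 0")
        if not 0 < self.fill_fraction <= 1:
            raise ValueError("fill_fraction must lie in (0, 1]")


@dataclass
class SynthScene:
    """Full description of one synthetic image pair."""

    width_px: int = 256
    height_px: int = 256
    bit_depth: int = 16
    pixel_size_um: float = 1.0
    deposits: list[Deposit] = field(default_factory=list)
    background_level: float = 500.0
    noise: Literal["none", "poisson", "gaussian"] = "none"
    gaussian_sd: float = 10.0
    brightness_per_pmol: float = DEFAULT_BRIGHTNESS_PER_PMOL
    humidity_contrast: float = DEFAULT_HUMIDITY_CONTRAST
    exposure_s: float = 1.0
    n_background_rois: int = 5
    seed: int = 0


@dataclass
class RenderedScene:
    """Rendered image pair plus ROIs and the ground-truth manifest."""

    humid: ImagePlane
    dry: ImagePlane
    rois: list[Roi]
    manifest: pd.DataFrame
    scene: SynthScene

    def write(self, outdir: str | Path, stem: str) -> dict[str, Path]:
        """Write humid/dry RGB TIFFs, the ROI JSON and the manifest CSV.

        The red/green channels are written as zeros: the tracer emits only
        in the blue channel.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "humid": outdir / f"{stem}_humid.tif",
            "dry": outdir / f"{stem}_dry.tif",
            "rois": outdir / f"{stem}_rois.json",
            "manifest": outdir / f"{stem}_manifest.csv",
        }
        for key, plane in (("humid", self.humid), ("dry", self.dry)):
            zero = ImagePlane(
                np.zeros_like(plane.pixels),
                bit_depth=plane.bit_depth,
                channel="red",
                exposure_s=plane.exposure_s,
                pixel_size_um=plane.pixel_size_um,
                humidity_state=plane.humidity_state,
            )
            green = replace(zero, channel="green")
            write_rgb_image(paths[key], [zero, green, plane])
        write_roi_file(self.rois, paths["rois"])
        self.manifest.to_csv(paths["manifest"], index=False)
        return paths


def _deposit_excess(
    scene: SynthScene, dep: Deposit
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Excess counts (above background) contributed by one deposit.

    Returns the patch array and the (row, col) slices where it lands.
    Total patch sum equals the deposit's photon budget up to the
    supersampling quadrature.
    """
    sh = dep.shape
    a = sh.a * dep.fill_fraction
    b = sh.b * dep.fill_fraction
    margin = 2.0
    x0 = max(int(math.floor(sh.cx - a - margin)), 0)
    x1 = min(int(math.ceil(sh.cx + a + margin)), scene.width_px - 1)
    y0 = max(int(math.floor(sh.cy - a - margin)), 0)
    y1 = min(int(math.ceil(sh.cy + a + margin)), scene.height_px - 1)
    if sh.cx - a < -0.5 or sh.cx + a > scene.width_px - 0.5 or (
        sh.cy - a < -0.5 or sh.cy + a > scene.height_px - 0.5
    ):
        raise ValueError(f"deposit {dep.label!r} extends outside the canvas")

    s = _SUPERSAMPLE
    sub = (np.arange(s) + 0.5) / s - 0.5
    xs = (np.arange(x0, x1 + 1)[:, None] + sub[None, :]).ravel()
    ys = (np.arange(y0, y1 + 1)[:, None] + sub[None, :]).ravel()
    gx, gy = np.meshgrid(xs, ys)
    theta = math.radians(sh.angle_deg)
    dx = gx - sh.cx
    dy = gy - sh.cy
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    r2 = (u / a) ** 2 + (v / b) ** 2
    if dep.profile == "uniform":
        w = (r2 <= 1.0).astype(float)
    elif dep.profile == "radial-falloff":
        # parabolic dome, unit mean over the ellipse: same total flux
        w = np.where(r2 <= 1.0, 2.0 * (1.0 - r2), 0.0)
    else:
        raise ValueError(f"unknown profile {dep.profile!r}")
    ny, nx = y1 - y0 + 1, x1 - x0 + 1
    coverage = w.reshape(ny, s, nx, s).mean(axis=(1, 3))

    total_counts = (
        scene.brightness_per_pmol
        * dep.picomoles
        * scene.exposure_s
        / scene.pixel_size_um**2
    )
    area_px2 = math.pi * a * b
    patch = coverage * (total_counts / area_px2)
    return patch, (slice(y0, y1 + 1), slice(x0, x1 + 1))


def _quantise(scene: SynthScene, field_counts: np.ndarray, rng) -> np.ndarray:
    max_count = (1 << scene.bit_depth) - 1
    if scene.noise == "poisson":
        img = rng.poisson(np.clip(field_counts, 0, None)).astype(float)
    elif scene.noise == "gaussian":
        img = field_counts + rng.normal(0.0, scene.gaussian_sd, field_counts.shape)
    elif scene.noise == "none":
        img = field_counts
    else:
        raise ValueError(f"unknown noise model {scene.noise!r}")
    img = np.clip(np.rint(img), 0, max_count)
    return img.astype(np.uint8 if scene.bit_depth == 8 else np.uint16)


def _background_rois(scene: SynthScene) -> list[Roi]:
    """Tracer-free patches placed on a deterministic grid away from deposits."""
    half = 6.0
    clearance = 4.0
    rois: list[Roi] = []
    n_grid = 8
    xs = np.linspace(12, scene.width_px - 13, n_grid)
    ys = np.linspace(12, scene.height_px - 13, n_grid)
    for y in ys:
        for x in xs:
            if len(rois) >= scene.n_background_rois:
                return rois
            ok = True
            for dep in scene.deposits:
                d = math.hypot(x - dep.shape.cx, y - dep.shape.cy)
                if d < dep.shape.a + half * 1.5 + clearance:
                    ok = False
                    break
            if ok:
                rois.append(
                    Roi(
                        label=f"bg{len(rois) + 1}",
                        role="background",
                        shape=EllipseShape(cx=x, cy=y, a=half, b=half),
                    )
                )
    if len(rois) < scene.n_background_rois:
        raise ValueError(
            "could not place the requested background ROIs clear of deposits; "
            "enlarge the canvas or reduce n_background_rois"
        )
    return rois


def render_scene(scene: SynthScene) -> RenderedScene:
    """Render the humid/dry image pair, ROIs and truth manifest."""
    field_counts = np.full(
        (scene.height_px, scene.width_px), float(scene.background_level)
    )
    dry_counts = field_counts.copy()
    records = []
    for dep in scene.deposits:
        patch, where = _deposit_excess(scene, dep)
        field_counts[where] += patch
        contrast = (
            scene.humidity_contrast
            if dep.humidity_contrast is None
            else dep.humidity_contrast
        )
        dry_counts[where] += patch * contrast
        records.append(
            {
                "label": dep.label,
                "picomoles": dep.picomoles,
                "center_x_px": dep.shape.cx,
                "center_y_px": dep.shape.cy,
                "major_axis_um": 2 * dep.shape.a * scene.pixel_size_um,
                "minor_axis_um": 2 * dep.shape.b * scene.pixel_size_um,
                "humidity_contrast": contrast,
                "expected_integrated_intensity": scene.brightness_per_pmol
                * dep.picomoles,
            }
        )

    rng = np.random.default_rng(scene.seed)
    humid_px = _quantise(scene, field_counts, rng)
    dry_px = _quantise(scene, dry_counts, rng)
    meta = dict(
        bit_depth=scene.bit_depth,
        channel="blue",
        exposure_s=scene.exposure_s,
        pixel_size_um=scene.pixel_size_um,
    )
    humid = ImagePlane(humid_px, humidity_state="humid", **meta)
    dry = ImagePlane(dry_px, humidity_state="dry", **meta)

    rois = [
        Roi(label=dep.label, role="signal", shape=dep.shape)
        for dep in scene.deposits
    ]
    rois += _background_rois(scene)
    manifest = pd.DataFrame.from_records(
        records,
        columns=[
            "label",
            "picomoles",
            "center_x_px",
            "center_y_px",
            "major_axis_um",
            "minor_axis_um",
            "humidity_contrast",
            "expected_integrated_intensity",
        ],
    )
    return RenderedScene(humid=humid, dry=dry, rois=rois, manifest=manifest, scene=scene)


def exposure_for_concentration(concentration_uM: float) -> float:
    """Exposure schedule of the standard series: long exposures for dilute
    droplets, shortened at 1 and 10 µM to avoid pixel saturation."""
    if concentration_uM <= 0.1:
        return 10.0
    if concentration_uM <= 1.0:
        return 1.0
    return 0.1


def droplet_diameter_um(volume_nL: float) -> float:
    """Spot diameter of a deposited droplet, anchored to a ~500 µm footprint
    at 50 nL and scaled with the cube root of the volume."""
    return 500.0 * (volume_nL / 50.0) ** (1.0 / 3.0)


def make_calibration_series(
    concentrations_uM: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
    volume_nL: float = 50.0,
    replicates: int = 3,
    include_blank: bool = True,
    objective: str = "10x",
    pixel_size_um: float = 1.0,
    noise: Literal["none", "poisson", "gaussian"] = "poisson",
    brightness_per_pmol: float = DEFAULT_BRIGHTNESS_PER_PMOL,
    seed: int = 0,
) -> tuple[list[SynthScene], pd.DataFrame]:
    """Build one scene per standard droplet plus the standards manifest.

    Defaults reproduce the low-replicate design: 10 nM, 100 nM, 1 µM and
    10 µM droplets of 50 nL (three replicates each, plus a blank buffer
    control), imaged at the per-concentration exposure schedule.  The
    24-replicate variant uses 5 nL droplets and ``replicates=24``.
    """
    if sum(c > 0 for c in set(concentrations_uM)) < 2:
        raise ValueError("need at least 2 distinct positive concentrations")
    if any(c < 0 for c in concentrations_uM):
        raise ValueError("concentrations must be >= 0")

    diameter_px = droplet_diameter_um(volume_nL) / pixel_size_um
    pad = 30
    canvas = int(math.ceil(diameter_px)) + 2 * pad
    radius_px = diameter_px / 2.0

    conc_list = list(concentrations_uM) + ([0.0] if include_blank else [])
    scenes: list[SynthScene] = []
    rows = []
    k = 0
    for conc in conc_list:
        n_rep = replicates if conc > 0 else 1
        pmol = droplet_picomoles(conc, volume_nL) if conc > 0 else 0.0
        for rep in range(1, n_rep + 1):
            dep = Deposit(
                label=f"droplet_c{conc:g}_r{rep}",
                shape=EllipseShape(
                    cx=canvas / 2.0, cy=canvas / 2.0, a=radius_px, b=radius_px
                ),
                picomoles=pmol,
                fill_fraction=0.94,
            )
            scene = SynthScene(
                width_px=canvas,
                height_px=canvas,
                pixel_size_um=pixel_size_um,
                deposits=[dep],
                noise=noise,
                brightness_per_pmol=brightness_per_pmol,
                exposure_s=exposure_for_concentration(conc) if conc > 0 else 10.0,
                n_background_rois=5,
                seed=seed + k,
            )
            scenes.append(scene)
            rows.append(
                {
                    "roi_label": dep.label,
                    "concentration_uM": conc,
                    "volume_nL": volume_nL,
                    "replicate_id": rep,
                    "objective": objective,
                    "exposure_s": scene.exposure_s,
                    "pixel_size_um": pixel_size_um,
                    "picomoles": pmol,
                }
            )
            k += 1
    return scenes, pd.DataFrame(rows)


def make_crater_set(
    n_craters: int,
    particle_diameter_range_um: tuple[float, float] = (8.0, 31.0),
    efficiency_range: tuple[float, float] = (0.01, 0.11),
    pc_calibration: ParticleCraterCalibration | None = None,
    concentration_uM: float = 100.0,
    objective: str = "10x",
    pixel_size_um: float = 1.0,
    noise: Literal["none", "poisson", "gaussian"] = "poisson",
    brightness_per_pmol: float = DEFAULT_BRIGHTNESS_PER_PMOL,
    exposure_s: float = 10.0,
    contaminant_every: int = 0,
    seed: int = 0,
) -> tuple[list[SynthScene], pd.DataFrame]:
    """Build single-crater scenes with known particle sizes and efficiencies.

    Per crater: a particle diameter D and a capture efficiency are drawn
    uniformly from the given ranges; the crater outline follows the
    particle-crater calibration run forward (with mild random
    ellipticity), and the residue deposit carries ``efficiency *
    impactor_picomoles(D, C)``.  The defaults put crater diameters in the
    ~16-93 µm range observed on aluminium at 1.7 km/s.  If
    ``contaminant_every`` is n > 0, every n-th crater is rendered as a
    humidity-insensitive contaminant (dry/humid contrast 1) that the
    artifact screen must reject.

    Returns the scenes plus a truth manifest (one row per crater).
    """
    if pc_calibration is None:
        pc_calibration = ParticleCraterCalibration(
            target_material="aluminium", velocity_km_s=1.7, ratio=3.0
        )
    d_lo, d_hi = particle_diameter_range_um
    e_lo, e_hi = efficiency_range
    if not (0 < d_lo <= d_hi):
        raise ValueError("invalid particle diameter range")
    if not (0 < e_lo <= e_hi <= 1):
        raise ValueError("efficiency range must lie within (0, 1]")

    rng = np.random.default_rng(seed)
    scenes: list[SynthScene] = []
    rows = []
    for i in range(n_craters):
        d_particle = float(rng.uniform(d_lo, d_hi))
        eff = float(rng.uniform(e_lo, e_hi))
        d_crater = pc_calibration.crater_from_particle(d_particle)
        aspect = float(rng.uniform(0.85, 1.0))
        major_um = 2.0 * d_crater / (1.0 + aspect)
        minor_um = aspect * major_um
        a_px = major_um / 2.0 / pixel_size_um
        b_px = minor_um / 2.0 / pixel_size_um
        angle = float(rng.uniform(0.0, 180.0))
        canvas = int(math.ceil(2 * a_px)) + 80
        pmol_imp = impactor_picomoles(d_particle, concentration_uM)
        pmol_crater = eff * pmol_imp
        is_contaminant = contaminant_every > 0 and (i + 1) % contaminant_every == 0
        label = f"crater{i + 1:03d}"
        dep = Deposit(
            label=label,
            shape=EllipseShape(
                cx=canvas / 2.0, cy=canvas / 2.0, a=a_px, b=b_px, angle_deg=angle
            ),
            picomoles=pmol_crater,
            fill_fraction=0.9,
            humidity_contrast=1.0 if is_contaminant else None,
        )
        scene = SynthScene(
            width_px=canvas,
            height_px=canvas,
            pixel_size_um=pixel_size_um,
            deposits=[dep],
            noise=noise,
            brightness_per_pmol=brightness_per_pmol,
            exposure_s=exposure_s,
            n_background_rois=3,
            seed=seed + 1000 + i,
        )
        # truth consistency under the picomole/efficiency relations
        assert math.isclose(
            pmol_crater, eff * impactor_picomoles(d_particle, concentration_uM)
        )
        assert math.isclose(
            d_particle, pc_calibration.particle_from_crater(d_crater), rel_tol=1e-9
        )
        scenes.append(scene)
        rows.append(
            {
                "crater_label": label,
                "particle_diameter_um": d_particle,
                "crater_diameter_um": d_crater,
                "major_axis_um": major_um,
                "minor_axis_um": minor_um,
                "efficiency_pct": 100.0 * eff,
                "impactor_pmol": pmol_imp,
                "crater_pmol": pmol_crater,
                "objective": objective,
                "exposure_s": exposure_s,
                "pixel_size_um": pixel_size_um,
                "contaminant": is_contaminant,
            }
        )
    return scenes, pd.DataFrame(rows)
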