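"""Crater sizing and capture-efficiency estimation.

Each impact crater is measured from three co-registered images: a
bright-field image on which the crater outline (ROI) is drawn and the
crater's major/minor axes are obtained by ellipse fitting; a dry
fluorescence image used to screen humidity-insensitive artifacts; and a
humidified fluorescence image from which the captured tracer is
quantified.

The crater diameter is the mean of the fitted major and minor axes.  An
empirical particle-crater calibration (from microsphere impact
experiments on the same target material and velocity) converts crater
diameter to impactor diameter D.  Assuming a spherical ice particle of
tracer concentration C (µM), the impactor carries

    pmol_impactor = C * (pi/6) * D**3 * 1e-9        (D in µm)

which at the standard projectile concentration C = 100 µM reduces to
``(pi/6) * D**3 * 1e-7``.  Capture efficiency is the percentage of that
tracer recovered in the crater.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import CalibrationFit, invert_calibration
from .imaging import ImagePlane, Roi, roi_pixel_mask
from .measure import (
    DEFAULT_ARTIFACT_RATIO,
    artifact_screen,
    measure_roi,
)

__all__ = [
    "ParticleCraterCalibration",
    "CraterRecord",
    "fit_ellipse",
    "crater_diameter",
    "particle_diameter",
    "impactor_picomoles",
    "capture_efficiency",
    "analyze_crater",
    "save_pc_calibration",
    "load_pc_calibration",
]


@dataclass
class ParticleCraterCalibration:
    """Empirical crater-size to particle-size mapping.

    Either a scalar ratio ``k`` (crater diameter = k * particle diameter)
    or a strictly increasing table of (crater_um, particle_um) pairs used
    with linear interpolation.  Calibrations are specific to a target
    material and impact velocity and are always supplied as input, never
    built in.
    """

    target_material: str
    velocity_km_s: float
    ratio: float | None = None
    table: np.ndarray | None = None  # (n, 2): crater_um, particle_um

    def __post_init__(self) -> None:
        if (self.ratio is None) == (self.table is None):
            raise ValueError("supply exactly one of ratio or table")
        if self.ratio is not None and not self.ratio > 0:
            raise ValueError(f"ratio must be > 0, got {self.ratio}")
        if self.table is not None:
            self.table = np.asarray(self.table, dtype=float)
            if self.table.ndim != 2 or self.table.shape[1] != 2 or len(self.table) < 2:
                raise ValueError("table must be an (n>=2, 2) array")
            if np.any(np.diff(self.table[:, 0]) <= 0) or np.any(
                np.diff(self.table[:, 1]) <= 0
            ):
                raise ValueError("table must be strictly increasing in both columns")

    def particle_from_crater(self, crater_diameter_um: float) -> float:
        if self.ratio is not None:
            return crater_diameter_um / self.ratio
        craters = self.table[:, 0]
        if not craters[0] <= crater_diameter_um <= craters[-1]:
            warnings.warn(
                f"crater diameter {crater_diameter_um:.3g} um outside the "
                f"calibration table [{craters[0]:.3g}, {craters[-1]:.3g}]; "
                "clamping to the table edge",
                stacklevel=2,
            )
        return float(np.interp(crater_diameter_um, craters, self.table[:, 1]))

    def crater_from_particle(self, particle_diameter_um: float) -> float:
        """Forward mapping, used when synthesising scenes."""
        if self.ratio is not None:
            return particle_diameter_um * self.ratio
        return float(
            np.interp(particle_diameter_um, self.table[:, 1], self.table[:, 0])
        )


def save_pc_calibration(cal: ParticleCraterCalibration, path) -> None:
    """Write a particle-crater calibration to JSON."""
    import json
    from pathlib import Path

    doc: dict = {
        "target_material": cal.target_material,
        "velocity_km_s": cal.velocity_km_s,
    }
    if cal.ratio is not None:
        doc["ratio"] = cal.ratio
    else:
        doc["table"] = cal.table.tolist()
    Path(path).write_text(json.dumps(doc, indent=1))


def load_pc_calibration(path) -> ParticleCraterCalibration:
    """Read a particle-crater calibration from JSON."""
    import json
    from pathlib import Path

    doc = json.loads(Path(path).read_text())
    for fld in ("target_material", "velocity_km_s"):
        if fld not in doc:
            raise ValueError(
                f"particle-crater calibration {path!r} is missing {fld!r}"
            )
    return ParticleCraterCalibration(
        target_material=doc["target_material"],
        velocity_km_s=float(doc["velocity_km_s"]),
        ratio=float(doc["ratio"]) if "ratio" in doc else None,
        table=np.asarray(doc["table"], dtype=float) if "table" in doc else None,
    )


@dataclass
class CraterRecord:
    """Full per-crater result row."""

    crater_label: str
    major_axis_um: float
    minor_axis_um: float
    crater_diameter_um: float
    particle_diameter_um: float
    impactor_pmol: float
    crater_pmol: float | None
    capture_efficiency_pct: float | None
    artifact_flag: bool
    extrapolated: bool = False
    calibration_fit_id: str = ""


def fit_ellipse(
    points: np.ndarray | None = None, mask: np.ndarray | None = None
) -> tuple[float, float, tuple[float, float], float]:
    """Fit an ellipse to boundary points or a filled binary mask.

    For a mask the result is the equal-moment ellipse: same centroid and
    second central moments as the pixel region (this is what the familiar
    fit-ellipse tools report).  For boundary points a direct least-squares
    conic fit is used.  Returns ``(major_px, minor_px, (cx, cy),
    angle_deg)`` with FULL axis lengths and the major-axis angle in
    degrees, in [0, 180).
    """
    if (points is None) == (mask is None):
        raise ValueError("supply exactly one of points or mask")

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        ys, xs = np.nonzero(mask)
        if xs.size < 5:
            raise ValueError(f"mask has {xs.size} pixels; need at least 5")
        cx, cy = float(xs.mean()), float(ys.mean())
        # second central moments of the pixel region
        cov = np.cov(np.vstack([xs, ys]).astype(float), ddof=0)
        evals, evecs = np.linalg.eigh(cov)
        if evals[0] <= 0:
            raise ValueError("degenerate (collinear) mask")
        # uniform ellipse with semi-axes (p, q) has second moments p^2/4, q^2/4
        minor = 4.0 * math.sqrt(evals[0])
        major = 4.0 * math.sqrt(evals[1])
        vx, vy = evecs[:, 1]
        angle = math.degrees(math.atan2(vy, vx)) % 180.0
        return major, minor, (cx, cy), angle

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y)")
    if len(pts) < 5:
        raise ValueError(f"got {len(pts)} points; an ellipse fit needs at least 5")
    from skimage.measure import EllipseModel

    model = EllipseModel()
    if not model.estimate(pts) or not np.all(np.isfinite(model.params)):
        raise ValueError("ellipse fit failed (degenerate or collinear points)")
    xc, yc, a, b, theta = model.params
    if a < b:
        a, b = b, a
        theta += math.pi / 2.0
    if a <= 0 or b <= 0:
        raise ValueError("ellipse fit produced non-positive axes")
    return (
        2.0 * float(a),
        2.0 * float(b),
        (float(xc), float(yc)),
        math.degrees(theta) % 180.0,
    )


def crater_diameter(major_axis_um: float, minor_axis_um: float) -> float:
    """Effective crater diameter: mean of the fitted major/minor axes."""
    if not (major_axis_um >= minor_axis_um > 0):
        raise ValueError(
            f"need major >= minor > 0, got {major_axis_um}, {minor_axis_um}"
        )
    return 0.5 * (major_axis_um + minor_axis_um)


def particle_diameter(
    crater_diameter_um: float, calibration: ParticleCraterCalibration
) -> float:
    """Impactor diameter from crater diameter via the empirical mapping."""
    if not crater_diameter_um > 0:
        raise ValueError(f"crater diameter must be > 0, got {crater_diameter_um}")
    return calibration.particle_from_crater(crater_diameter_um)


def impactor_picomoles(
    particle_diameter_um: float, concentration_uM: float = 100.0
) -> float:
    """Tracer carried by a spherical impactor of diameter D µm.

    ``C * (pi/6) * D**3 * 1e-9`` pmol; with the standard 100 µM projectile
    this is exactly ``(pi/6) * D**3 * 1e-7``.  Identical to treating the
    sphere volume ``(pi/6) D^3`` µm³ = ``(pi/6) D^3 * 1e-6`` nL as a
    droplet of concentration C.
    """
    if particle_diameter_um < 0:
        raise ValueError("particle diameter must be >= 0")
    if concentration_uM < 0:
        raise ValueError("concentration must be >= 0")
    return concentration_uM * (math.pi / 6.0) * particle_diameter_um**3 * 1e-9


def capture_efficiency(crater_pmol: float, impactor_pmol: float) -> float:
    """Percent of the impactor's tracer recovered in the crater.

    Values above 100 % are physically impossible and signal a calibration
    mismatch; they are reported with a warning rather than clamped.
    """
    if not impactor_pmol > 0:
        raise ValueError(f"impactor_pmol must be > 0, got {impactor_pmol}")
    if crater_pmol < 0:
        raise ValueError(f"crater_pmol must be >= 0, got {crater_pmol}")
    eff = 100.0 * crater_pmol / impactor_pmol
    if eff > 100.0:
        warnings.warn(
            f"capture efficiency {eff:.1f}% exceeds 100%; check the "
            "particle-crater calibration and the intensity calibration",
            stacklevel=2,
        )
    return eff


def analyze_crater(
    crater_roi: Roi,
    dry_plane: ImagePlane,
    humid_plane: ImagePlane,
    background_rois: Sequence[Roi],
    cal_fit: CalibrationFit,
    pc_calibration: ParticleCraterCalibration,
    projectile_concentration_uM: float = 100.0,
    artifact_ratio_threshold: float = DEFAULT_ARTIFACT_RATIO,
) -> CraterRecord:
    """Run the full per-crater chain and return a :class:`CraterRecord`.

    The crater ROI (drawn on the bright-field image, reused on the dry and
    humid images, which are assumed co-registered) is ellipse-fitted to
    get the axes; the humid measurement is converted to picomoles through
    the intensity calibration; the dry measurement screens artifacts.
    Artifact craters keep their geometry but have the efficiency withheld.
    """
    px = humid_plane.pixel_size_um
    mask = roi_pixel_mask(crater_roi, humid_plane.width_px, humid_plane.height_px)
    major_px, minor_px, _center, _angle = fit_ellipse(mask=mask)
    major_um, minor_um = major_px * px, minor_px * px
    d_crater = crater_diameter(major_um, minor_um)
    d_particle = particle_diameter(d_crater, pc_calibration)
    pmol_imp = impactor_picomoles(d_particle, projectile_concentration_uM)

    humid_meas = measure_roi(humid_plane, crater_roi, background_rois)
    dry_meas = measure_roi(dry_plane, crater_roi, background_rois)

    if humid_meas.integrated_intensity <= 0:
        # nothing detectable once humidified: an empty crater
        return CraterRecord(
            crater_label=crater_roi.label,
            major_axis_um=major_um,
            minor_axis_um=minor_um,
            crater_diameter_um=d_crater,
            particle_diameter_um=d_particle,
            impactor_pmol=pmol_imp,
            crater_pmol=0.0,
            capture_efficiency_pct=0.0,
            artifact_flag=False,
        )

    verdict = artifact_screen(dry_meas, humid_meas, artifact_ratio_threshold)
    if verdict == "artifact":
        return CraterRecord(
            crater_label=crater_roi.label,
            major_axis_um=major_um,
            minor_axis_um=minor_um,
            crater_diameter_um=d_crater,
            particle_diameter_um=d_particle,
            impactor_pmol=pmol_imp,
            crater_pmol=None,
            capture_efficiency_pct=None,
            artifact_flag=True,
        )

    pmol_crater, extrapolated = invert_calibration(
        cal_fit, humid_meas.integrated_intensity
    )
    eff = capture_efficiency(pmol_crater, pmol_imp)
    return CraterRecord(
        crater_label=crater_roi.label,
        major_axis_um=major_um,
        minor_axis_um=minor_um,
        crater_diameter_um=d_crater,
        particle_diameter_um=d_particle,
        impactor_pmol=pmol_imp,
        crater_pmol=pmol_crater,
        capture_efficiency_pct=eff,
        artifact_flag=False,
        extrapolated=extrapolated,
        calibration_fit_id=f"{cal_fit.objective}/{cal_fit.aggregation}",
    )
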