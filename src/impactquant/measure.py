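"""Background-corrected integrated intensity and measurement screening.

The core observable is the integrated intensity

    I = (mean_signal - mean_background) * A / s

with ``A`` the geometric ROI area in square micrometres and ``s`` the
exposure time in seconds.  The background term is the unweighted mean of
the per-ROI mean intensities of tracer-free regions near the feature
(mean of means, not pooled pixels), which makes it independent of how
large each background patch is.

Dried Pacific Blue films are only weakly fluorescent; genuine tracer is
therefore near-dark in the dry image and bright once humidified.  The
artifact screen exploits this: residues whose emission survives drying
(dust, autofluorescent debris) are flagged and excluded from capture
estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .imaging import ImagePlane, Roi, roi_area_um2, roi_mean_intensity, roi_pixel_mask

__all__ = [
    "IntensityMeasurement",
    "background_mean",
    "integrated_intensity",
    "saturation_fraction",
    "measure_roi",
    "artifact_screen",
    "DEFAULT_SATURATION_THRESHOLD",
    "DEFAULT_ARTIFACT_RATIO",
]

#: Measurements with more than this fraction of full-scale pixels are
#: flagged unusable in reports.
DEFAULT_SATURATION_THRESHOLD = 0.01

#: Dry/humid intensity ratio above which a residue is called an artifact.
DEFAULT_ARTIFACT_RATIO = 0.5


@dataclass
class IntensityMeasurement:
    """One ROI's quantitation bundle.

    ``integrated_intensity`` is recomputable from the other fields as
    ``(mean_signal - mean_background) * area_um2 / exposure_s``.
    """

    roi_label: str
    mean_signal: float
    mean_background: float
    area_um2: float
    exposure_s: float
    integrated_intensity: float
    saturated_fraction: float
    n_background_rois: int

    def __post_init__(self) -> None:
        if not self.area_um2 > 0:
            raise ValueError("area_um2 must be > 0")
        if not self.exposure_s > 0:
            raise ValueError("exposure_s must be > 0")
        if not 0.0 <= self.saturated_fraction <= 1.0:
            raise ValueError("saturated_fraction must lie in [0, 1]")


def background_mean(plane: ImagePlane, background_rois: Sequence[Roi]) -> float:
    """Average background level: mean of the per-ROI mean intensities."""
    rois = [r for r in background_rois if r.role == "background"]
    if not rois:
        raise ValueError(
            "no background ROIs supplied; draw tracer-free regions near the "
            "feature and pass them with role='background'"
        )
    return float(sum(roi_mean_intensity(plane, r) for r in rois) / len(rois))


def integrated_intensity(
    mean_signal: float,
    mean_background: float,
    area_um2: float,
    exposure_s: float,
) -> float:
    """Background-corrected, area-scaled, exposure-normalised intensity.

    May be negative when the background exceeds the signal; negative values
    are preserved (clamping would bias calibration near the detection
    floor).
    """
    if not area_um2 > 0:
        raise ValueError(f"area_um2 must be > 0, got {area_um2}")
    if not exposure_s > 0:
        raise ValueError(f"exposure_s must be > 0, got {exposure_s}")
    return (mean_signal - mean_background) * area_um2 / exposure_s


def saturation_fraction(plane: ImagePlane, roi: Roi) -> float:
    """Fraction of ROI pixels at full scale (``2**bit_depth - 1``)."""
    mask = roi_pixel_mask(roi, plane.width_px, plane.height_px)
    values = plane.pixels[mask]
    return float((values == plane.max_count).sum() / values.size)


def measure_roi(
    plane: ImagePlane,
    signal_roi: Roi,
    background_rois: Sequence[Roi],
) -> IntensityMeasurement:
    """Full single-ROI measurement on one channel plane."""
    if signal_roi.role != "signal":
        raise ValueError(
            f"ROI {signal_roi.label!r} has role {signal_roi.role!r}; "
            "measure_roi needs a signal ROI"
        )
    mean_sig = roi_mean_intensity(plane, signal_roi)
    mean_bg = background_mean(plane, background_rois)
    area = roi_area_um2(signal_roi, plane.pixel_size_um)
    intensity = integrated_intensity(mean_sig, mean_bg, area, plane.exposure_s)
    if intensity < 0:
        warnings.warn(
            f"ROI {signal_roi.label!r}: background exceeds signal "
            f"(integrated intensity {intensity:.4g}); value reported as-is",
            stacklevel=2,
        )
    return IntensityMeasurement(
        roi_label=signal_roi.label,
        mean_signal=mean_sig,
        mean_background=mean_bg,
        area_um2=area,
        exposure_s=plane.exposure_s,
        integrated_intensity=intensity,
        saturated_fraction=saturation_fraction(plane, signal_roi),
        n_background_rois=sum(1 for r in background_rois if r.role == "background"),
    )


def artifact_screen(
    dry: IntensityMeasurement,
    humid: IntensityMeasurement,
    ratio_threshold: float = DEFAULT_ARTIFACT_RATIO,
) -> str:
    """Classify a residue as ``"genuine"`` or ``"artifact"``.

    Genuine tracer is near-dark in the dry image; an artifact keeps more
    than ``ratio_threshold`` of its humid intensity when dry.  A
    non-positive humid intensity leaves the ratio undefined and is
    classified as artifact with a warning.
    """
    if dry.roi_label != humid.roi_label:
        raise ValueError(
            f"dry/humid label mismatch: {dry.roi_label!r} vs {humid.roi_label!r}"
        )
    if humid.integrated_intensity <= 0:
        warnings.warn(
            f"ROI {humid.roi_label!r}: humid intensity "
            f"{humid.integrated_intensity:.4g} <= 0; dry/humid ratio undefined, "
            "classifying as artifact",
            stacklevel=2,
        )
        return "artifact"
    ratio = dry.integrated_intensity / humid.integrated_intensity
    return "artifact" if ratio > ratio_threshold else "genuine"
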