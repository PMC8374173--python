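"""Picomole calibration: droplet standards, power-law fits, Tukey summaries.

Standard droplets of known concentration ``C`` (µM) and volume ``V`` (nL)
carry ``C * V * 1e-3`` picomoles of tracer.  Plotting integrated intensity
against picomoles over several decades gives a near-linear relation that
is summarised by a power law ``y = a * x**b``, fitted by ordinary least
squares in log-log space (the standard choice for data spanning decades
with multiplicative error; a direct nonlinear fit is available as an
alternative).  Inverting the fit converts a crater's integrated intensity
into picomoles of captured tracer.

Replicates at each concentration are summarised with classic Tukey
boxplot statistics: hinge quartiles and 1.5*IQR fences, with points
outside the fences flagged as outliers (flagged, not removed: by default
outliers stay in the fit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .measure import IntensityMeasurement

__all__ = [
    "DropletStandard",
    "CalibrationFit",
    "ReplicateSummary",
    "droplet_picomoles",
    "fit_power_law",
    "invert_calibration",
    "replicate_summary",
    "build_calibration",
    "save_calibration",
    "load_calibration",
]


def droplet_picomoles(concentration_uM: float, volume_nL: float) -> float:
    """Tracer content of a deposited droplet: ``C * V * 1e-3`` picomoles."""
    if concentration_uM < 0:
        raise ValueError(f"concentration_uM must be >= 0, got {concentration_uM}")
    if not volume_nL > 0:
        raise ValueError(f"volume_nL must be > 0, got {volume_nL}")
    return concentration_uM * volume_nL * 1e-3


@dataclass
class DropletStandard:
    """One measured standard droplet."""

    concentration_uM: float
    volume_nL: float
    replicate_id: int
    objective: str
    measurement: IntensityMeasurement
    picomoles: float = field(init=False)

    def __post_init__(self) -> None:
        self.picomoles = droplet_picomoles(self.concentration_uM, self.volume_nL)


@dataclass
class CalibrationFit:
    """Power law ``y = a * x**b`` with standard errors and valid domain.

    ``a`` has units counts*um^2*s^-1*pmol^-b; ``b`` is dimensionless.
    ``domain_pmol`` is the picomole range spanned by the fitted standards;
    inversion outside it is flagged as extrapolation.
    """

    a: float
    b: float
    se_a: float
    se_b: float
    n_points: int
    domain_pmol: tuple[float, float]
    objective: str = ""
    aggregation: str = ""

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("fitted amplitude a must be > 0")
        if self.n_points < 2:
            raise ValueError("a power-law fit needs at least 2 points")
        lo, hi = self.domain_pmol
        if not lo < hi:
            raise ValueError("domain_pmol must satisfy min < max")

    def predict(self, picomoles: float) -> float:
        return self.a * picomoles**self.b


def fit_power_law(
    points: Sequence[tuple[float, float]],
    method: Literal["loglog-ols", "nls"] = "loglog-ols",
) -> CalibrationFit:
    """Fit ``y = a * x**b`` to (picomoles, integrated intensity) pairs.

    ``loglog-ols`` (default) regresses ln y on ln x: the slope is ``b`` and
    the intercept ``ln a``; ``se_a = a * se(intercept)`` by the delta
    method.  ``nls`` runs unweighted nonlinear least squares on the raw
    scale, seeded from the log-log solution, as a sensitivity check.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (picomoles, intensity) pairs")
    if len(pts) < 2:
        raise ValueError(f"need at least 2 points, got {len(pts)}")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError(
            "all picomole and intensity values must be strictly positive "
            "(the log-log fit is undefined otherwise); filter blanks and "
            "below-detection points first"
        )
    lx, ly = np.log(x), np.log(y)
    if np.ptp(lx) == 0:
        raise ValueError("zero variance in picomoles; need >= 2 distinct x values")

    res = stats.linregress(lx, ly)
    b = float(res.slope)
    a = float(math.exp(res.intercept))
    se_b = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    se_int = float(res.intercept_stderr) if np.isfinite(res.intercept_stderr) else 0.0
    se_a = a * se_int

    if method == "nls":
        (a, b), pcov = optimize.curve_fit(
            lambda xx, aa, bb: aa * xx**bb, x, y, p0=(a, b), maxfev=10000
        )
        perr = np.sqrt(np.diag(pcov))
        se_a, se_b = float(perr[0]), float(perr[1])
        a, b = float(a), float(b)
    elif method != "loglog-ols":
        raise ValueError(f"unknown fitting method {method!r}")

    return CalibrationFit(
        a=a,
        b=b,
        se_a=se_a,
        se_b=se_b,
        n_points=len(pts),
        domain_pmol=(float(x.min()), float(x.max())),
    )


def invert_calibration(
    fit: CalibrationFit, integrated_intensity: float
) -> tuple[float, bool]:
    """Convert an integrated intensity to picomoles: ``(I / a)**(1 / b)``.

    Returns ``(picomoles, extrapolated)`` where the flag marks estimates
    outside the calibrated picomole domain.  Non-positive intensities have
    no estimate (below detection) and raise.
    """
    if not integrated_intensity > 0:
        raise ValueError(
            f"integrated intensity {integrated_intensity:.4g} is not positive; "
            "no picomole estimate (below detection)"
        )
    pmol = (integrated_intensity / fit.a) ** (1.0 / fit.b)
    lo, hi = fit.domain_pmol
    return pmol, not (lo <= pmol <= hi)


@dataclass
class ReplicateSummary:
    """Tukey boxplot statistics for one replicate group."""

    n: int
    mean: float
    median: float
    sd: float
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    outliers: list[float]


def _tukey_hinges(sorted_values: np.ndarray) -> tuple[float, float]:
    """Lower/upper hinges: medians of the two halves, median included in
    both halves when n is odd."""
    n = len(sorted_values)
    half = (n + 1) // 2
    lower = sorted_values[:half]
    upper = sorted_values[n - half :]
    return float(np.median(lower)), float(np.median(upper))


def replicate_summary(values: Sequence[float]) -> ReplicateSummary:
    """Summarise replicate measurements with Tukey hinges and 1.5*IQR fences."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty replicate set")
    srt = np.sort(arr)
    q1, q3 = _tukey_hinges(srt)
    iqr = q3 - q1
    lower_fence = q1 - 1.5 * iqr
    upper_fence = q3 + 1.5 * iqr
    outliers = [float(v) for v in arr if v < lower_fence or v > upper_fence]
    return ReplicateSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        q1=q1,
        q3=q3,
        iqr=iqr,
        lower_fence=lower_fence,
        upper_fence=upper_fence,
        outliers=outliers,
    )


def build_calibration(
    standards: Sequence[DropletStandard],
    objective: str,
    aggregation: Literal["mean-per-concentration", "all-droplets"],
    method: Literal["loglog-ols", "nls"] = "loglog-ols",
) -> tuple[CalibrationFit, dict[float, ReplicateSummary]]:
    """Build a calibration fit from measured droplet standards.

    ``mean-per-concentration`` averages integrated intensity within each
    concentration before fitting (the low-replicate 10x workflow);
    ``all-droplets`` fits every droplet individually (the 24-replicate 20x
    workflow).  Blank controls (zero concentration) are excluded from the
    fit — their logs are undefined — but still summarised.  Tukey outliers
    are flagged in the summaries yet retained in the fit.

    Returns the fit plus a per-concentration ``ReplicateSummary`` mapping.
    """
    if aggregation not in ("mean-per-concentration", "all-droplets"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    use = [s for s in standards if s.objective == objective]
    if not use:
        raise ValueError(f"no standards for objective {objective!r}")

    by_conc: dict[float, list[DropletStandard]] = {}
    for s in use:
        by_conc.setdefault(s.concentration_uM, []).append(s)
    summaries = {
        conc: replicate_summary(
            [s.measurement.integrated_intensity for s in group]
        )
        for conc, group in sorted(by_conc.items())
    }

    points: list[tuple[float, float]] = []
    if aggregation == "mean-per-concentration":
        for conc, group in by_conc.items():
            if conc <= 0:
                continue  # blank control: background check only
            pmol = group[0].picomoles
            mean_i = float(
                np.mean([s.measurement.integrated_intensity for s in group])
            )
            points.append((pmol, mean_i))
    else:
        points = [
            (s.picomoles, s.measurement.integrated_intensity)
            for s in use
            if s.concentration_uM > 0
        ]

    points = [(x, y) for x, y in points if y > 0]
    n_conc = len({x for x, _ in points})
    if n_conc < 2:
        raise ValueError(
            "fewer than 2 usable concentrations after filtering blanks and "
            "non-positive intensities"
        )
    fit = fit_power_law(points, method=method)
    fit.objective = objective
    fit.aggregation = aggregation
    return fit, summaries


def save_calibration(fit: CalibrationFit, path) -> None:
    """Write a calibration fit to its JSON interchange form."""
    import json
    from pathlib import Path

    doc = {
        "a": fit.a,
        "se_a": fit.se_a,
        "b": fit.b,
        "se_b": fit.se_b,
        "n_points": fit.n_points,
        "domain_pmol": list(fit.domain_pmol),
        "objective": fit.objective,
        "aggregation": fit.aggregation,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_calibration(path) -> CalibrationFit:
    """Read a calibration fit from its JSON interchange form."""
    import json
    from pathlib import Path

    doc = json.loads(Path(path).read_text())
    missing = [k for k in ("a", "b", "n_points", "domain_pmol") if k not in doc]
    if missing:
        raise ValueError(f"calibration file {path!r} is missing field(s) {missing}")
    return CalibrationFit(
        a=float(doc["a"]),
        b=float(doc["b"]),
        se_a=float(doc.get("se_a", 0.0)),
        se_b=float(doc.get("se_b", 0.0)),
        n_points=int(doc["n_points"]),
        domain_pmol=tuple(float(v) for v in doc["domain_pmol"]),
        objective=doc.get("objective", ""),
        aggregation=doc.get("aggregation", ""),
    )
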