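"""Spectrophotometric drug quantification.

Linear (Beer-Lambert) calibration curves map absorbance to drug
concentration.  This module fits such curves by ordinary least squares,
inverts them for quantification (flagging extrapolation outside the
validated linear range), bundles several curves per medium with
range-based selection, and screens concentration time series for
stability against a percent-of-initial tolerance band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateCurveError, InvalidInputError

__all__ = [
    "CalibrationCurve",
    "CalibrationSet",
    "InvertedConcentration",
    "StabilityReport",
    "fit_calibration",
    "invert_calibration",
    "stability_screen",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """A straight-line calibration: absorbance = intercept + slope * C.

    Parameters
    ----------
    slope : float
        Absorbance per (mg/mL); must be positive for a usable assay.
    intercept : float
        Absorbance at zero concentration (blank offset).
    r : float
        Pearson correlation coefficient of the regression.
    linear_range : tuple of float
        (min, max) concentration in mg/mL over which linearity was
        established; quantification outside it is flagged.
    wavelength_nm : float, optional
        Detection wavelength, kept as metadata.
    """

    slope: float
    intercept: float
    r: float
    linear_range: tuple[float, float]
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InvalidInputError("calibration slope must be positive")
        lo, hi = self.linear_range
        if not lo < hi:
            raise InvalidInputError("linear_range must satisfy min < max")
        if abs(self.r) > 1 + 1e-12:
            raise InvalidInputError("|r| cannot exceed 1")

    def predict(self, concentration: float) -> float:
        """Absorbance expected at `concentration` (mg/mL)."""
        return self.intercept + self.slope * float(concentration)


class InvertedConcentration(NamedTuple):
    """Concentration obtained by inverting a calibration curve."""

    concentration: float
    within_linear_range: bool


def fit_calibration(
    points: Sequence[tuple[float, float]],
    wavelength_nm: float | None = None,
) -> CalibrationCurve:
    """Fit a calibration line to (concentration mg/mL, absorbance) pairs.

    Ordinary least squares; the linear range is set to the span of the
    supplied concentrations.  Requires at least 3 points with
    non-negative, non-constant concentrations.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise InvalidInputError("need >= 3 (concentration, absorbance) points")
    conc, absorb = pts[:, 0], pts[:, 1]
    if np.any(conc < 0):
        raise InvalidInputError("concentrations must be non-negative")
    if np.ptp(conc) == 0:
        raise InvalidInputError("concentrations have zero variance")
    res = stats.linregress(conc, absorb)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        linear_range=(float(conc.min()), float(conc.max())),
        wavelength_nm=wavelength_nm,
    )


def invert_calibration(
    curve: CalibrationCurve, absorbance: float
) -> InvertedConcentration:
    """Concentration (mg/mL) corresponding to an absorbance reading.

    C = (absorbance - intercept) / slope.  The result carries a flag
    telling whether it falls inside the curve's validated linear range.
    """
    if curve.slope == 0:
        raise DegenerateCurveError("cannot invert a zero-slope curve")
    conc = (float(absorbance) - curve.intercept) / curve.slope
    lo, hi = curve.linear_range
    return InvertedConcentration(conc, lo <= conc <= hi)


@dataclass(frozen=True)
class CalibrationSet:
    """Several calibration curves for one medium, selected by range.

    UV assays commonly validate two lines per solvent over adjacent
    concentration windows.  `quantify` inverts each curve and keeps the
    candidate whose own linear range contains it; when several ranges
    overlap, the curve covering the lower range wins.
    """

    curves: tuple[CalibrationCurve, ...]

    def __post_init__(self) -> None:
        if not self.curves:
            raise InvalidInputError("CalibrationSet needs at least one curve")
        ordered = tuple(sorted(self.curves, key=lambda c: c.linear_range[0]))
        object.__setattr__(self, "curves", ordered)

    def curve_for(self, concentration: float) -> CalibrationCurve:
        """The curve whose linear range contains `concentration`.

        Overlaps resolve to the lower-range curve; a concentration
        outside every range falls back to the nearest range's curve.
        """
        for curve in self.curves:  # sorted by range minimum
            lo, hi = curve.linear_range
            if lo <= concentration <= hi:
                return curve
        return min(
            self.curves,
            key=lambda c: min(
                abs(concentration - c.linear_range[0]),
                abs(concentration - c.linear_range[1]),
            ),
        )

    def quantify(self, absorbance: float) -> InvertedConcentration:
        """Invert the appropriate curve for an absorbance reading."""
        candidates = [invert_calibration(c, absorbance) for c in self.curves]
        for curve, cand in zip(self.curves, candidates):
            lo, hi = curve.linear_range
            if lo <= cand.concentration <= hi:
                return cand
        # No curve claims the reading: report the first (lowest-range)
        # inversion, flagged out of range.
        return candidates[0]


@dataclass(frozen=True)
class StabilityReport:
    """Outcome of screening a concentration series for stability.

    `percent_of_initial` is the series normalised so the first point is
    100; `violations` lists the indices where it leaves the +/- `band`
    percent tolerance around 100.
    """

    times: np.ndarray
    percent_of_initial: np.ndarray
    band: float
    violations: tuple[int, ...] = field(default_factory=tuple)

    @property
    def passed(self) -> bool:
        return not self.violations


def stability_screen(
    times: Sequence[float],
    concentrations: Sequence[float],
    band_percent: float = 15.0,
) -> StabilityReport:
    """Screen a concentration time series against a percent band.

    The series is expressed as percent of the initial concentration
    (first point defined as 100); every timepoint whose deviation from
    100 exceeds `band_percent` in magnitude is reported as a violation.
    The check is per-timepoint, not on the mean.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.shape != c.shape or t.ndim != 1 or t.size < 2:
        raise InvalidInputError("need >= 2 matching time/concentration points")
    if c[0] <= 0:
        raise InvalidInputError("initial concentration must be positive")
    percent = 100.0 * c / c[0]
    bad = np.flatnonzero(np.abs(percent - 100.0) > band_percent)
    return StabilityReport(
        times=t,
        percent_of_initial=percent,
        band=float(band_percent),
        violations=tuple(int(i) for i in bad),
    )
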