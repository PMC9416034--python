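"""Franz diffusion cell permeation analysis.

A vertical Franz cell exposes a tissue membrane of area ``A`` (cm^2) to
a donor solution of concentration ``Cd`` (mg/mL); drug appearing in the
acceptor chamber is sampled over time, each withdrawal being replaced
with fresh fluid to preserve sink conditions.  From the resulting time
courses this module computes the standard biopharmaceutical parameters:

* ``Js``  -- steady-state flux, the slope of cumulative permeated amount
  per unit area (Q/A) versus time in the linear regime, ug/cm^2/h;
* ``t_lag`` -- the x-intercept of that regression (minutes), read here
  as the time needed to establish the steady state;
* ``Kp = Js / Cd`` -- permeability coefficient, cm/h (Cd converted to
  ug/cm^3);
* ``De = Q_T / A`` -- drug entrapped in the tissue per unit area at the
  end of the run, ug/cm^2;
* ``Ac = De / Cd`` -- accumulation parameter, cm.

It also aggregates Kp across donor levels into an intrinsic
permeability, computes enhancement ratios against a reference Kp, and
flags donor levels where the response has stopped rising (membrane
saturation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InvalidInputError, NoSteadyStateError

__all__ = [
    "PermeationExperiment",
    "PermeationResult",
    "SaturationReport",
    "cumulative_amounts",
    "steady_state_flux",
    "permeability_coefficient",
    "intrinsic_permeability",
    "entrapment_density",
    "accumulation_parameter",
    "enhancement_ratio",
    "detect_saturation",
    "analyze_permeation",
]

#: mg/mL -> ug/cm^3 (= ug/mL)
_MG_ML_TO_UG_CM3 = 1000.0

#: Minimum number of points in a steady-state regression window.
MIN_WINDOW_POINTS = 4


@dataclass(frozen=True)
class PermeationExperiment:
    """Per-replicate acceptor concentration time series plus cell setup.

    Parameters
    ----------
    times_h : array, shape (n_times,)
        Sampling times in hours, strictly increasing.
    acceptor_conc_ug_ml : array, shape (n_replicates, n_times)
        Acceptor-chamber concentration at each sampling, ug/mL, as
        measured in the withdrawn aliquot (before replacement).
    v_acceptor_ml, v_sample_ml : float
        Acceptor chamber volume and withdrawn/replaced aliquot volume.
    area_cm2 : float
        Mucosal orifice area available for permeation.
    cd_mg_per_ml : float
        Donor concentration.
    q_t_ug : array, optional, shape (n_replicates,)
        Drug extracted from the tissue at the end of the run, per
        replicate.
    sampling_corrected : bool
        True when `acceptor_conc_ug_ml` is already corrected for the
        dilution caused by sample replacement, in which case
        `cumulative_amounts` skips the correction.
    """

    times_h: np.ndarray
    acceptor_conc_ug_ml: np.ndarray
    cd_mg_per_ml: float
    v_acceptor_ml: float = 15.0
    v_sample_ml: float = 0.5
    area_cm2: float = 0.636
    q_t_ug: np.ndarray | None = None
    sampling_corrected: bool = False

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times_h, dtype=float))
        c = np.atleast_2d(np.asarray(self.acceptor_conc_ug_ml, dtype=float))
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "acceptor_conc_ug_ml", c)
        if t.size < 4:
            raise InvalidInputError("need at least 4 timepoints")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if c.shape[1] != t.size:
            raise InvalidInputError("acceptor_conc shape does not match times")
        if self.v_sample_ml > self.v_acceptor_ml:
            raise InvalidInputError("v_sample cannot exceed v_acceptor")
        if self.area_cm2 <= 0:
            raise InvalidInputError("area must be positive")
        if self.cd_mg_per_ml <= 0:
            raise InvalidInputError("donor concentration must be positive")
        if self.q_t_ug is not None:
            q = np.atleast_1d(np.asarray(self.q_t_ug, dtype=float))
            if q.size != c.shape[0]:
                raise InvalidInputError("q_t_ug must have one entry per replicate")
            object.__setattr__(self, "q_t_ug", q)

    @property
    def n_replicates(self) -> int:
        return self.acceptor_conc_ug_ml.shape[0]


@dataclass(frozen=True)
class PermeationResult:
    """Biopharmaceutical parameters estimated from one experiment.

    ``Kp * Cd`` (Cd in ug/cm^3) equals ``Js`` identically, and
    ``Ac * Cd`` equals ``De`` when tissue data are present; both are
    unit-consistency invariants, not fitted relations.
    """

    js_ug_cm2_h: float
    js_se: float
    t_lag_min: float
    lag_detected: bool
    r2: float
    fit_window: tuple[int, int]
    kp_cm_h: float | None = None
    de_ug_cm2: float | None = None
    de_se: float | None = None
    ac_cm: float | None = None
    replicate_slopes: tuple[float, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "js_ug_cm2_h": self.js_ug_cm2_h,
            "js_se": self.js_se,
            "t_lag_min": self.t_lag_min,
            "lag_detected": self.lag_detected,
            "r2": self.r2,
            "fit_window": list(self.fit_window),
            "kp_cm_h": self.kp_cm_h,
            "de_ug_cm2": self.de_ug_cm2,
            "de_se": self.de_se,
            "ac_cm": self.ac_cm,
            "replicate_slopes": list(self.replicate_slopes),
        }


@dataclass(frozen=True)
class SaturationReport:
    """Donor levels whose response stopped rising proportionally."""

    donor_levels: tuple[float, ...]
    responses: tuple[float, ...]
    saturated_levels: tuple[float, ...]
    threshold: float


def cumulative_amounts(exp: PermeationExperiment) -> np.ndarray:
    """Cumulative permeated amount Q(t) in ug, per replicate.

    Each withdrawn aliquot (``V_sample``) removes drug that must be
    added back to later readings; the standard replacement-dilution
    correction is

        Q(t_n) = V_acceptor * C_n + V_sample * sum_{i<n} C_i.

    With ``sampling_corrected=True`` (or ``V_sample = 0``) this reduces
    to ``Q = V_acceptor * C``.
    """
    c = exp.acceptor_conc_ug_ml
    if np.any(c < 0):
        raise InvalidInputError("acceptor concentrations must be non-negative")
    if exp.sampling_corrected:
        return exp.v_acceptor_ml * c
    prior = np.concatenate(
        [np.zeros((c.shape[0], 1)), np.cumsum(c, axis=1)[:, :-1]], axis=1
    )
    return exp.v_acceptor_ml * c + exp.v_sample_ml * prior


def _window_regression(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and r^2 of y on t (r^2 = 1 for <= 2 points)."""
    res = stats.linregress(t, y)
    r2 = 1.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return float(res.slope), float(res.intercept), r2


def _auto_window(
    t: np.ndarray, y: np.ndarray, min_points: int
) -> tuple[int, int]:
    """Select the steady-state regression window.

    Candidates are every contiguous window whose last point is the
    final timepoint and whose length is at least
    ``max(min_points, ceil(n/2))`` -- the half-length floor keeps the
    selection from chasing short, noise-tilted late windows, which
    would bias the flux upward.  Windows with a non-positive slope are
    discarded; among the rest the one with the highest r^2 wins, with
    r^2 compared at 1e-9 resolution so that numerically tied windows
    resolve toward the longer one.
    """
    n = t.size
    min_len = max(min_points, math.ceil(n / 2))
    best: tuple[float, int, tuple[int, int]] | None = None
    for start in range(0, n - min_len + 1):
        slope, _, r2 = _window_regression(t[start:], y[start:])
        if slope <= 0:
            continue
        key = (round(r2, 9), n - start)
        if best is None or key > (best[0], best[1]):
            best = (key[0], key[1], (start, n))
    if best is None:
        raise NoSteadyStateError("no window with positive slope found")
    return best[2]


def steady_state_flux(
    exp: PermeationExperiment,
    window: tuple[int, int] | None = None,
    min_points: int = MIN_WINDOW_POINTS,
) -> PermeationResult:
    """Estimate Js and t_lag from the linear portion of Q/A versus t.

    The regression is run on the replicate-mean Q/A profile over
    `window` (Python-style half-open index range); when `window` is
    omitted it is auto-selected (see `_auto_window`).  Js is the slope
    in ug/cm^2/h with its SE taken across per-replicate slopes; t_lag
    is the x-intercept converted to minutes, reported as 0 (with
    ``lag_detected=False``) when the intercept is non-negative.
    """
    q = cumulative_amounts(exp)
    qa = q / exp.area_cm2
    qa_mean = qa.mean(axis=0)
    t = exp.times_h
    if window is None:
        window = _auto_window(t, qa_mean, min_points)
    start, stop = window
    if stop - start < 3:
        raise InvalidInputError("fit window must contain at least 3 points")
    tw, yw = t[start:stop], qa_mean[start:stop]
    slope, intercept, r2 = _window_regression(tw, yw)
    if slope <= 0:
        raise NoSteadyStateError("flux slope is not positive over the window")
    rep_slopes = tuple(
        _window_regression(tw, qa[i, start:stop])[0] for i in range(qa.shape[0])
    )
    if len(rep_slopes) > 1:
        js_se = float(np.std(rep_slopes, ddof=1) / math.sqrt(len(rep_slopes)))
    else:
        js_se = 0.0
    # scale-aware zero test: a tiny negative intercept from rounding is
    # not a physical lag
    lag_detected = intercept < -1e-9 * max(1.0, float(np.max(np.abs(yw))))
    t_lag_min = (-intercept / slope) * 60.0 if lag_detected else 0.0
    return PermeationResult(
        js_ug_cm2_h=slope,
        js_se=js_se,
        t_lag_min=t_lag_min,
        lag_detected=lag_detected,
        r2=r2,
        fit_window=(start, stop),
        replicate_slopes=rep_slopes,
    )


def permeability_coefficient(js_ug_cm2_h: float, cd_mg_per_ml: float) -> float:
    """Kp = Js / Cd in cm/h, with Cd converted from mg/mL to ug/cm^3."""
    if cd_mg_per_ml <= 0:
        raise InvalidInputError("donor concentration must be positive")
    return js_ug_cm2_h / (cd_mg_per_ml * _MG_ML_TO_UG_CM3)


def intrinsic_permeability(
    kp_values: Sequence[float],
    selected: Sequence[int] | None = None,
) -> tuple[float, float]:
    """Mean +/- SE of the Kp values at the selected donor levels.

    The permeability coefficient should not depend on donor
    concentration; levels distorted by too little drug or by membrane
    saturation are excluded and the remaining Kp values averaged.
    Returns (mean, SE); SE is 0 for a single value by convention.
    """
    kp = np.asarray(kp_values, dtype=float)
    if selected is not None:
        kp = kp[list(selected)]
    if kp.size == 0:
        raise InvalidInputError("no Kp values selected")
    mean = float(kp.mean())
    se = float(np.std(kp, ddof=1) / math.sqrt(kp.size)) if kp.size > 1 else 0.0
    return mean, se


def entrapment_density(q_t_ug: float, area_cm2: float) -> float:
    """De = Q_T / A in ug/cm^2 (drug retained in the tissue per area)."""
    if area_cm2 <= 0:
        raise InvalidInputError("area must be positive")
    return q_t_ug / area_cm2


def accumulation_parameter(de_ug_cm2: float, cd_mg_per_ml: float) -> float:
    """Ac = De / Cd in cm, with Cd converted from mg/mL to ug/cm^3."""
    if cd_mg_per_ml <= 0:
        raise InvalidInputError("donor concentration must be positive")
    return de_ug_cm2 / (cd_mg_per_ml * _MG_ML_TO_UG_CM3)


def enhancement_ratio(
    kp_formulation: float, kp_reference: float, ndigits: int | None = 1
) -> float:
    """Fold change of a formulation's Kp over a reference Kp."""
    if kp_reference <= 0:
        raise InvalidInputError("reference Kp must be positive")
    ratio = kp_formulation / kp_reference
    return round(ratio, ndigits) if ndigits is not None else ratio


def detect_saturation(
    donor_levels: Sequence[float],
    responses: Sequence[float],
    rel_threshold: float = 0.05,
) -> SaturationReport:
    """Flag donor levels where the response stopped increasing.

    A level is saturated when its response exceeds the previous level's
    by less than `rel_threshold` (relative) despite the higher donor
    concentration -- the signature of membrane saturation.
    """
    levels = np.asarray(donor_levels, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if levels.shape != resp.shape or levels.ndim != 1:
        raise InvalidInputError("levels and responses must match 1-d shapes")
    if np.any(np.diff(levels) <= 0):
        raise InvalidInputError("donor levels must be sorted ascending")
    flagged = [
        float(levels[i])
        for i in range(1, levels.size)
        if resp[i] < (1.0 + rel_threshold) * resp[i - 1]
    ]
    return SaturationReport(
        donor_levels=tuple(float(x) for x in levels),
        responses=tuple(float(x) for x in resp),
        saturated_levels=tuple(flagged),
        threshold=float(rel_threshold),
    )


def analyze_permeation(
    exp: PermeationExperiment,
    window: tuple[int, int] | None = None,
) -> PermeationResult:
    """Full single-experiment analysis: Js, t_lag, Kp and (if tissue
    extracts are present) De and Ac."""
    base = steady_state_flux(exp, window=window)
    kp = permeability_coefficient(base.js_ug_cm2_h, exp.cd_mg_per_ml)
    de = de_se = ac = None
    if exp.q_t_ug is not None:
        de_values = np.array(
            [entrapment_density(q, exp.area_cm2) for q in exp.q_t_ug]
        )
        de = float(de_values.mean())
        de_se = (
            float(np.std(de_values, ddof=1) / math.sqrt(de_values.size))
            if de_values.size > 1
            else 0.0
        )
        ac = accumulation_parameter(de, exp.cd_mg_per_ml)
    return PermeationResult(
        js_ug_cm2_h=base.js_ug_cm2_h,
        js_se=base.js_se,
        t_lag_min=base.t_lag_min,
        lag_detected=base.lag_detected,
        r2=base.r2,
        fit_window=base.fit_window,
        kp_cm_h=kp,
        de_ug_cm2=de,
        de_se=de_se,
        ac_cm=ac,
        replicate_slopes=base.replicate_slopes,
    )
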