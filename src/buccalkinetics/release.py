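"""Drug-release kinetic modelling.

Fits the semi-empirical models routinely applied to dissolution data
(dose fraction D released versus time t in minutes):

* zero order:        D = k*t
* first order:       D = 1 - exp(-k*t)
* Higuchi:           D = k*sqrt(t)
* Korsmeyer-Peppas:  D = k*t^n           (power law)
* Hixson-Crowell:    D = 1 - (1 - k*t)^3
* Peppas-Sahlin:     D = k1*t^m + k2*t^(2m),  m fixed (default 0.43)

Profiles are truncated at 90% released before fitting, models ranked by
r^2, and the Peppas-Sahlin fit decomposed into its Fickian diffusion
(F) and Case II relaxation/erosion (R) contributions:

    F(t) = 1 / (1 + (k2/k1)*t^m),   R/F(t) = (k2/k1)*t^m,

which satisfy F*(1 + R/F) = 1 identically.  The power-law exponent n
diagnoses the transport mechanism (n = 0.5 pure Fickian for a thin
film; n = 1 Case II).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateCurveError, InvalidInputError

__all__ = [
    "MODEL_NAMES",
    "ReleaseProfile",
    "KineticFit",
    "MechanismSeries",
    "TruncationResult",
    "truncate_at_fraction",
    "fit_release_model",
    "fit_all_models",
    "rank_models",
    "mechanism_decomposition",
    "classify_transport",
    "aspect_ratio",
    "evaluate_model",
]

DEFAULT_M_EXPONENT = 0.43

MODEL_NAMES = (
    "zero_order",
    "first_order",
    "higuchi",
    "korsmeyer_peppas",
    "hixson_crowell",
    "peppas_sahlin",
)

_N_FREE_PARAMS = {
    "zero_order": 1,
    "first_order": 1,
    "higuchi": 1,
    "korsmeyer_peppas": 2,
    "hixson_crowell": 1,
    "peppas_sahlin": 2,
}


@dataclass(frozen=True)
class ReleaseProfile:
    """Dose fraction released versus time, with tablet geometry.

    Dose fractions up to 1.05 are tolerated (small analytical
    overshoot) and flagged via `overshoot`; larger values are
    rejected.
    """

    times_min: np.ndarray
    dose_fraction: np.ndarray
    tablet_diameter_cm: float | None = None
    tablet_thickness_mm: float | None = None

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times_min, dtype=float))
        d = np.atleast_1d(np.asarray(self.dose_fraction, dtype=float))
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "dose_fraction", d)
        if t.size == 0:
            raise InvalidInputError("empty release profile")
        if t.shape != d.shape:
            raise InvalidInputError("times and dose fractions must match")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(d < 0) or np.any(d > 1.05):
            raise InvalidInputError("dose fractions must lie in [0, 1.05]")

    @property
    def overshoot(self) -> bool:
        """True when any dose fraction exceeds 1 (analytical overshoot)."""
        return bool(np.any(self.dose_fraction > 1.0))


@dataclass(frozen=True)
class KineticFit:
    """A fitted release model with goodness of fit."""

    model: str
    params: dict[str, float]
    param_se: dict[str, float]
    r2: float
    truncation_time_min: float
    converged: bool
    message: str = ""
    m_exponent: float | None = None

    @property
    def n_free_params(self) -> int:
        return _N_FREE_PARAMS[self.model]

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": dict(self.params),
            "param_se": dict(self.param_se),
            "r2": self.r2,
            "truncation_time_min": self.truncation_time_min,
            "converged": self.converged,
            "message": self.message,
            "m_exponent": self.m_exponent,
        }


@dataclass(frozen=True)
class MechanismSeries:
    """Fickian fraction F and ratio R/F over time for a Peppas-Sahlin fit.

    When k2 < 0 (as matrix tablets with a shrinking relaxational term
    can produce) R/F is negative and F exceeds 1; `outside_unit_range`
    flags that the usual contribution-in-[0,1] reading does not apply.
    """

    times_min: np.ndarray
    fickian_fraction: np.ndarray
    r_over_f: np.ndarray
    outside_unit_range: bool


class TruncationResult(NamedTuple):
    profile: "ReleaseProfile"
    cutoff_reached: bool
    truncation_time_min: float


def truncate_at_fraction(
    profile: ReleaseProfile, cutoff: float = 0.9
) -> TruncationResult:
    """Truncate a profile at a release cutoff (default 90%).

    Keeps every point with D <= cutoff plus the first point exceeding
    it.  When the cutoff is never exceeded the profile is returned
    unchanged with ``cutoff_reached=False``.
    """
    if not 0 < cutoff <= 1:
        raise InvalidInputError("cutoff must lie in (0, 1]")
    d = profile.dose_fraction
    over = np.flatnonzero(d > cutoff)
    if over.size == 0:
        return TruncationResult(profile, False, float(profile.times_min[-1]))
    stop = int(over[0]) + 1  # keep first point beyond the cutoff
    truncated = replace(
        profile,
        times_min=profile.times_min[:stop],
        dose_fraction=d[:stop],
    )
    return TruncationResult(truncated, True, float(truncated.times_min[-1]))


def evaluate_model(
    model: str, t: np.ndarray | float, params: dict[str, float],
    m_exponent: float = DEFAULT_M_EXPONENT,
) -> np.ndarray | float:
    """Evaluate a release model D(t) at times t (minutes)."""
    t = np.asarray(t, dtype=float)
    if model == "zero_order":
        return params["k"] * t
    if model == "first_order":
        return 1.0 - np.exp(-params["k"] * t)
    if model == "higuchi":
        return params["k"] * np.sqrt(t)
    if model == "korsmeyer_peppas":
        return params["k"] * t ** params["n"]
    if model == "hixson_crowell":
        return 1.0 - (1.0 - params["k"] * t) ** 3
    if model == "peppas_sahlin":
        m = params.get("m", m_exponent)
        return params["k1"] * t**m + params["k2"] * t ** (2 * m)
    raise InvalidInputError(f"unknown release model: {model!r}")


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -math.inf
    return 1.0 - ss_res / ss_tot


def _linear_fit(
    design: np.ndarray, d: np.ndarray, names: Sequence[str]
) -> tuple[dict[str, float], dict[str, float]]:
    """Exact least squares for models linear in their parameters,
    with SEs from the unscaled covariance (X'X)^-1 * s^2."""
    coef, _, _, _ = np.linalg.lstsq(design, d, rcond=None)
    resid = d - design @ coef
    dof = max(d.size - design.shape[1], 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return (
        {name: float(c) for name, c in zip(names, coef)},
        {name: float(s) for name, s in zip(names, se)},
    )


def _nonlinear_fit(
    fun: Callable,
    t: np.ndarray,
    d: np.ndarray,
    p0_list: Sequence[Sequence[float]],
    bounds: tuple,
    names: Sequence[str],
) -> tuple[dict[str, float], dict[str, float], bool, str]:
    """Bounded nonlinear least squares with deterministic multi-start."""
    best = None
    last_err = ""
    for p0 in p0_list:
        try:
            popt, pcov = curve_fit(
                fun, t, d, p0=p0, bounds=bounds, maxfev=20000,
                ftol=1e-12, xtol=1e-12, gtol=1e-12,
            )
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            last_err = str(exc)
            continue
        ssr = float(np.sum((d - fun(t, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        nan = {name: math.nan for name in names}
        return nan, dict(nan), False, last_err or "optimizer failed"
    _, popt, pcov = best
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return (
        {name: float(p) for name, p in zip(names, popt)},
        {name: float(s) for name, s in zip(names, se)},
        True,
        "",
    )


def fit_release_model(
    profile: ReleaseProfile,
    model: str,
    m_exponent: float | None = None,
) -> KineticFit:
    """Fit one release model to a (pre-truncated) profile.

    Least squares on D directly (no linearising transform).  Models
    linear in their parameters (zero order, Higuchi, Peppas-Sahlin with
    fixed m) are solved exactly; the rest use bounded nonlinear least
    squares started from five deterministic log-spaced rate guesses.
    Rate constants are constrained positive; the power-law exponent n
    is unconstrained.  Non-convergence is reported via ``converged``,
    never as silent NaN in a "converged" fit.
    """
    if model not in MODEL_NAMES:
        raise InvalidInputError(f"unknown release model: {model!r}")
    t = profile.times_min
    d = profile.dose_fraction
    n_free = _N_FREE_PARAMS[model]
    if t.size < n_free + 2:
        raise InvalidInputError(
            f"{model} needs at least {n_free + 2} points, got {t.size}"
        )
    m = DEFAULT_M_EXPONENT if m_exponent is None else float(m_exponent)
    converged, message = True, ""
    k_starts = np.logspace(-3, 0, 5)

    if model == "zero_order":
        params, se = _linear_fit(t[:, None], d, ["k"])
    elif model == "higuchi":
        params, se = _linear_fit(np.sqrt(t)[:, None], d, ["k"])
    elif model == "peppas_sahlin":
        design = np.column_stack([t**m, t ** (2 * m)])
        params, se = _linear_fit(design, d, ["k1", "k2"])
    elif model == "first_order":
        params, se, converged, message = _nonlinear_fit(
            lambda tt, k: 1.0 - np.exp(-k * tt),
            t, d, [[k] for k in k_starts], (1e-12, np.inf), ["k"],
        )
    elif model == "korsmeyer_peppas":
        params, se, converged, message = _nonlinear_fit(
            lambda tt, k, n: k * tt**n,
            t, d, [[k, 0.5] for k in k_starts],
            ([1e-12, -np.inf], [np.inf, np.inf]), ["k", "n"],
        )
    else:  # hixson_crowell
        params, se, converged, message = _nonlinear_fit(
            lambda tt, k: 1.0 - (1.0 - k * tt) ** 3,
            t, d, [[k / t.max()] for k in k_starts],
            (1e-12, np.inf), ["k"],
        )

    if converged:
        eval_params = dict(params)
        if model == "peppas_sahlin":
            eval_params["m"] = m
        r2 = _r_squared(d, np.asarray(evaluate_model(model, t, eval_params, m)))
    else:
        r2 = -math.inf
    return KineticFit(
        model=model,
        params=params,
        param_se=se,
        r2=r2,
        truncation_time_min=float(t[-1]),
        converged=converged,
        message=message,
        m_exponent=m if model == "peppas_sahlin" else None,
    )


def fit_all_models(
    profile: ReleaseProfile,
    models: Sequence[str] = MODEL_NAMES,
    m_exponent: float | None = None,
    truncation_fraction: float = 0.9,
) -> list[KineticFit]:
    """Truncate a profile at `truncation_fraction` released, then fit
    every requested model.  Returns fits ranked by `rank_models`."""
    truncated = truncate_at_fraction(profile, truncation_fraction).profile
    fits = [fit_release_model(truncated, m, m_exponent) for m in models]
    return rank_models(fits)


def rank_models(fits: Sequence[KineticFit]) -> list[KineticFit]:
    """Rank fits by descending r^2; ties go to the model with fewer
    free parameters; non-converged fits are listed last."""
    converged = [f for f in fits if f.converged]
    failed = [f for f in fits if not f.converged]
    converged.sort(key=lambda f: (-f.r2, f.n_free_params, f.model))
    return converged + failed


def mechanism_decomposition(
    fit: KineticFit, times_min: Sequence[float]
) -> MechanismSeries:
    """Fickian (F) and relaxational (R) contributions of a
    Peppas-Sahlin fit, evaluated at the requested times."""
    if fit.model != "peppas_sahlin":
        raise InvalidInputError("mechanism decomposition needs a peppas_sahlin fit")
    k1, k2 = fit.params["k1"], fit.params["k2"]
    if k1 == 0:
        raise DegenerateCurveError("k1 = 0: Fickian term absent, F undefined")
    m = fit.m_exponent if fit.m_exponent is not None else DEFAULT_M_EXPONENT
    t = np.asarray(times_min, dtype=float)
    r_over_f = (k2 / k1) * t**m
    fickian = 1.0 / (1.0 + r_over_f)
    return MechanismSeries(
        times_min=t,
        fickian_fraction=fickian,
        r_over_f=r_over_f,
        outside_unit_range=bool(k2 < 0),
    )


def classify_transport(n: float, atol: float = 1e-9) -> str:
    """Transport-mechanism label from the power-law exponent n."""
    if not math.isfinite(n):
        raise InvalidInputError("exponent must be finite")
    if abs(n - 0.5) <= atol:
        return "Fickian (Higuchi)"
    if n < 0.5:
        return "sub-Fickian/anomalous (diffusion-dominated)"
    if n < 1.0:
        return "anomalous transport"
    return "Case II or super Case II"


def aspect_ratio(diameter_cm: float, thickness_mm: float) -> float:
    """Tablet diameter/thickness ratio (dimensionless; thickness
    converted from mm to cm)."""
    if diameter_cm <= 0 or thickness_mm <= 0:
        raise InvalidInputError("diameter and thickness must be positive")
    return diameter_cm / (thickness_mm / 10.0)
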