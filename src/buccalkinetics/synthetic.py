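"""Synthetic data generators with known ground truth.

Every analysis stage in this package can be exercised without raw
instrument data: these generators emit Franz-cell permeation
experiments, release profiles and calibration points from stated truth
parameters plus a simple observational noise model (additive Gaussian
on the measured signal, truncated at zero).  Each generator is a pure
function of its spec -- the seed fully determines the output -- so
parameter-recovery tests and simulation studies are reproducible
bit-for-bit.

Defaults mirror the ex vivo / in vitro study conditions the package is
built around: 6 Franz-cell replicates sampled every 30 min for 6 h in a
15 mL acceptor chamber (0.5 mL withdrawals, 0.636 cm^2 orifice), and
release profiles of 13 points up to the 90%-release time with noise on
the dose fraction.  The permeation noise default (0.23 ug/mL) is the
concentration equivalent of the UV assay's absorbance SE (0.009 abs /
39.13 abs per mg/mL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidInputError
from .permeation import PermeationExperiment
from .release import MODEL_NAMES, ReleaseProfile, evaluate_model

__all__ = [
    "PermeationSpec",
    "ReleaseSpec",
    "CalibrationSpec",
    "gen_permeation",
    "gen_release",
    "gen_calibration",
]


def _default_permeation_times() -> np.ndarray:
    # every 30 min for 6 h, first sample at 30 min
    return np.arange(1, 13) * 0.5


def _default_release_times() -> np.ndarray:
    # 13 points up to the 90%-release time of the default power law
    return np.linspace(40.0 / 13.0, 40.0, 13)


@dataclass(frozen=True)
class PermeationSpec:
    """Truth + noise model for one synthetic permeation experiment.

    The cumulative truth is piecewise linear,
    ``Q/A(t) = Js * max(0, t - t_lag)``; when `jmax`/`km` are given the
    flux follows a saturable (Michaelis-type) dependence on the donor
    concentration, ``Js(Cd) = Jmax * Cd / (Km + Cd)``.  Acceptor
    concentrations are obtained by inverting the sampling-with-
    replacement correction, so the generated experiment round-trips
    exactly through `cumulative_amounts` at zero noise.
    """

    seed: int
    js_ug_cm2_h: float | None = 21.0
    t_lag_h: float = 0.5
    cd_mg_per_ml: float = 5.0
    jmax_ug_cm2_h: float | None = None
    km_mg_per_ml: float | None = None
    noise_sd_ug_ml: float = 0.23
    n_replicates: int = 6
    times_h: np.ndarray = field(default_factory=_default_permeation_times)
    v_acceptor_ml: float = 15.0
    v_sample_ml: float = 0.5
    area_cm2: float = 0.636
    de_ug_cm2: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "times_h", np.asarray(self.times_h, dtype=float)
        )
        if self.noise_sd_ug_ml < 0:
            raise InvalidInputError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise InvalidInputError("need at least one replicate")
        saturating = self.jmax_ug_cm2_h is not None or self.km_mg_per_ml is not None
        if saturating and (self.jmax_ug_cm2_h is None or self.km_mg_per_ml is None):
            raise InvalidInputError("saturation needs both jmax and km")
        if not saturating and self.js_ug_cm2_h is None:
            raise InvalidInputError("either js or (jmax, km) must be given")

    @property
    def true_js(self) -> float:
        """Flux implied by the spec at its donor concentration."""
        if self.jmax_ug_cm2_h is not None:
            return (
                self.jmax_ug_cm2_h
                * self.cd_mg_per_ml
                / (self.km_mg_per_ml + self.cd_mg_per_ml)
            )
        return float(self.js_ug_cm2_h)


def gen_permeation(spec: PermeationSpec) -> PermeationExperiment:
    """Generate a synthetic Franz-cell experiment from its spec."""
    rng = np.random.default_rng(spec.seed)
    t = spec.times_h
    qa_truth = spec.true_js * np.clip(t - spec.t_lag_h, 0.0, None)
    q_truth = qa_truth * spec.area_cm2

    # invert Q(t_n) = Va*C_n + Vs*sum_{i<n} C_i for the sampled concentrations
    c_truth = np.empty_like(q_truth)
    running = 0.0
    for i, q in enumerate(q_truth):
        c_truth[i] = (q - spec.v_sample_ml * running) / spec.v_acceptor_ml
        running += c_truth[i]

    conc = np.tile(c_truth, (spec.n_replicates, 1))
    if spec.noise_sd_ug_ml > 0:
        conc = conc + rng.normal(0.0, spec.noise_sd_ug_ml, size=conc.shape)
    conc = np.clip(conc, 0.0, None)

    q_t = None
    if spec.de_ug_cm2 is not None:
        q_t = np.full(spec.n_replicates, spec.de_ug_cm2 * spec.area_cm2)
        if spec.noise_sd_ug_ml > 0:
            q_t = np.clip(
                q_t + rng.normal(0.0, spec.noise_sd_ug_ml, spec.n_replicates),
                0.0,
                None,
            )

    return PermeationExperiment(
        times_h=t,
        acceptor_conc_ug_ml=conc,
        cd_mg_per_ml=spec.cd_mg_per_ml,
        v_acceptor_ml=spec.v_acceptor_ml,
        v_sample_ml=spec.v_sample_ml,
        area_cm2=spec.area_cm2,
        q_t_ug=q_t,
    )


@dataclass(frozen=True)
class ReleaseSpec:
    """Truth + noise model for one synthetic release profile.

    Defaults: a power-law (Korsmeyer-Peppas) truth with the package's
    reference matrix-tablet parameters, sampled at 13 timepoints up to
    the 90%-release time, additive Gaussian noise sd 0.01 on the dose
    fraction.
    """

    seed: int
    model: str = "korsmeyer_peppas"
    params: dict[str, float] = field(
        default_factory=lambda: {"k": 0.25748, "n": 0.34963}
    )
    noise_sd: float = 0.01
    times_min: np.ndarray = field(default_factory=_default_release_times)
    m_exponent: float = 0.43
    tablet_diameter_cm: float | None = 0.65
    tablet_thickness_mm: float | None = 1.05

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "times_min", np.asarray(self.times_min, dtype=float)
        )
        if self.model not in MODEL_NAMES:
            raise InvalidInputError(f"unknown release model: {self.model!r}")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be non-negative")


def gen_release(spec: ReleaseSpec) -> ReleaseProfile:
    """Generate a synthetic release profile from its spec."""
    rng = np.random.default_rng(spec.seed)
    d = np.clip(
        np.asarray(
            evaluate_model(spec.model, spec.times_min, spec.params, spec.m_exponent)
        ),
        0.0,
        1.0,
    )
    if spec.noise_sd > 0:
        d = d + rng.normal(0.0, spec.noise_sd, size=d.shape)
    d = np.clip(d, 0.0, 1.05)
    return ReleaseProfile(
        times_min=spec.times_min,
        dose_fraction=d,
        tablet_diameter_cm=spec.tablet_diameter_cm,
        tablet_thickness_mm=spec.tablet_thickness_mm,
    )


@dataclass(frozen=True)
class CalibrationSpec:
    """Truth + noise model for synthetic calibration points.

    Defaults are the reference UV line in phosphate buffer: absorbance
    = 0.0052 + 39.13 * C over 0.0006-0.0240 mg/mL, with noise sd equal
    to the assay's reported absorbance SE.
    """

    seed: int
    slope: float = 39.13
    intercept: float = 0.0052
    conc_range_mg_ml: tuple[float, float] = (0.0006, 0.0240)
    n_points: int = 8
    noise_sd: float = 0.009

    def __post_init__(self) -> None:
        lo, hi = self.conc_range_mg_ml
        if not lo < hi:
            raise InvalidInputError("degenerate concentration range")
        if self.n_points < 2:
            raise InvalidInputError("need at least 2 calibration points")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be non-negative")


def gen_calibration(spec: CalibrationSpec) -> list[tuple[float, float]]:
    """Generate (concentration, absorbance) calibration points."""
    rng = np.random.default_rng(spec.seed)
    conc = np.linspace(*spec.conc_range_mg_ml, spec.n_points)
    absorb = spec.intercept + spec.slope * conc
    if spec.noise_sd > 0:
        absorb = absorb + rng.normal(0.0, spec.noise_sd, size=absorb.shape)
    return list(zip(conc.tolist(), absorb.tolist()))
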