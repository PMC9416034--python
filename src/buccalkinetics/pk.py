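"""Pharmacokinetics-based tablet sizing.

For a drug whose oral regimen never reaches a steady state, a
transmucosal tablet can be sized so that the absorption rate through
the mucosa balances elimination at the target plasma level:

    Ke   = 0.693 / t_half                 (1/h)
    DR_E = Cmax * Ke                      (ng/mL/h, elimination rate)
    DR_A = DR_E * V_D                     (ug/h, required absorption;
                                           the mL->L and ng->ug factors
                                           cancel numerically)

Given the steady-state flux Js (ug/cm^2/h) measured ex vivo, the
two-face exchange area of a flat tablet of negligible thickness is
2*pi*(d/2)^2, so the tested tablet delivers Js*area ug/h, and the
tablet required to deliver a target DR_A has

    area = DR_A / Js,   diameter = 2*sqrt(area / (2*pi)).

Report values are rounded per pharmaceutical-table convention (areas
and diameters to 2 dp, DR_A to 3 significant figures before sizing)
while raw unrounded values are always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidInputError

__all__ = [
    "HALF_LIFE_CONSTANT",
    "PKParameters",
    "DosageDesign",
    "elimination_constant",
    "elimination_rate",
    "required_absorption_rate",
    "tablet_exchange_area",
    "tested_absorption_rate",
    "required_geometry",
    "design_dosage",
    "round_sig",
]

#: Conventional half-life constant; pharmacokinetic tables round ln 2
#: to 0.693, and the derived rate constants match that convention.
HALF_LIFE_CONSTANT = 0.693


def round_sig(x: float, sig: int) -> float:
    """Round to `sig` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class PKParameters:
    """Single-dose pharmacokinetic parameters.

    Cmax in ng/mL, elimination half-life in hours, apparent volume of
    distribution in litres; Ke is derived as 0.693/t_half (or ln 2 with
    ``exact_ln2=True``).  Optional SEs feed delta-method uncertainty
    propagation through the sizing chain.
    """

    cmax_ng_ml: float
    t_half_h: float
    vd_l: float
    cmax_se: float = 0.0
    t_half_se: float = 0.0
    vd_se: float = 0.0
    exact_ln2: bool = False
    body_reference: str = ""

    def __post_init__(self) -> None:
        if min(self.cmax_ng_ml, self.t_half_h, self.vd_l) <= 0:
            raise InvalidInputError("Cmax, t_half and V_D must be positive")

    @property
    def ke_per_h(self) -> float:
        return elimination_constant(self.t_half_h, exact_ln2=self.exact_ln2)


@dataclass(frozen=True)
class DosageDesign:
    """Outcome of the sizing chain for one formulation.

    `*_report` fields carry the rounded table values; same-named raw
    fields are unrounded.  `required_total_area_cm2 * js = dr_a_target`
    holds on the raw values by construction.
    """

    dr_e_ng_ml_h: float
    dr_a_required_ug_h: float
    dr_a_target_ug_h: float
    js_ug_cm2_h: float
    tested_diameter_cm: float
    tested_area_cm2: float
    tested_area_report_cm2: float
    tested_dr_a_ug_h: float
    tested_dr_a_report_ug_h: float
    required_total_area_cm2: float
    required_area_report_cm2: float
    required_diameter_cm: float
    required_diameter_report_cm: float
    dr_a_se_ug_h: float | None = None
    required_area_se_cm2: float | None = None

    def to_dict(self) -> dict:
        return {
            "dr_e_ng_ml_h": self.dr_e_ng_ml_h,
            "dr_a_required_ug_h": self.dr_a_required_ug_h,
            "dr_a_target_ug_h": self.dr_a_target_ug_h,
            "js_ug_cm2_h": self.js_ug_cm2_h,
            "tested": {
                "diameter_cm": self.tested_diameter_cm,
                "area_cm2": self.tested_area_report_cm2,
                "dr_a_ug_h": self.tested_dr_a_report_ug_h,
            },
            "required": {
                "area_cm2": self.required_area_report_cm2,
                "diameter_cm": self.required_diameter_report_cm,
            },
            "raw": {
                "tested_area_cm2": self.tested_area_cm2,
                "tested_dr_a_ug_h": self.tested_dr_a_ug_h,
                "required_area_cm2": self.required_total_area_cm2,
                "required_diameter_cm": self.required_diameter_cm,
            },
            "dr_a_se_ug_h": self.dr_a_se_ug_h,
            "required_area_se_cm2": self.required_area_se_cm2,
        }


def elimination_constant(t_half_h: float, exact_ln2: bool = False) -> float:
    """First-order elimination constant Ke = 0.693/t_half (1/h)."""
    if t_half_h <= 0:
        raise InvalidInputError("half-life must be positive")
    const = math.log(2.0) if exact_ln2 else HALF_LIFE_CONSTANT
    return const / t_half_h


def elimination_rate(cmax_ng_ml: float, ke_per_h: float) -> float:
    """Drug elimination rate DR_E = Cmax * Ke in ng/(mL*h)."""
    if cmax_ng_ml <= 0 or ke_per_h <= 0:
        raise InvalidInputError("Cmax and Ke must be positive")
    return cmax_ng_ml * ke_per_h


def required_absorption_rate(dr_e_ng_ml_h: float, vd_l: float) -> float:
    """Absorption rate DR_A = DR_E * V_D needed to balance elimination.

    ng/(mL*h) * L = ng/(mL*h) * 1000 mL = 1000 ng/h = 1 ug/h per unit,
    so the product is numerically DR_A in ug/h.
    """
    if dr_e_ng_ml_h <= 0 or vd_l <= 0:
        raise InvalidInputError("DR_E and V_D must be positive")
    return dr_e_ng_ml_h * vd_l


def tablet_exchange_area(diameter_cm: float) -> float:
    """Two-face exchange area 2*pi*(d/2)^2 of a flat tablet (cm^2);
    the lateral surface is neglected (negligible thickness)."""
    if diameter_cm <= 0:
        raise InvalidInputError("diameter must be positive")
    return 2.0 * math.pi * (diameter_cm / 2.0) ** 2


def tested_absorption_rate(js_ug_cm2_h: float, area_cm2: float) -> float:
    """Delivery rate Js * area of a tablet of known exchange area (ug/h)."""
    if js_ug_cm2_h < 0 or area_cm2 <= 0:
        raise InvalidInputError("flux must be non-negative and area positive")
    return js_ug_cm2_h * area_cm2


def required_geometry(
    dr_a_target_ug_h: float, js_ug_cm2_h: float
) -> tuple[float, float]:
    """(total two-face area cm^2, diameter cm) of the tablet delivering
    `dr_a_target_ug_h` at flux `js_ug_cm2_h`."""
    if js_ug_cm2_h <= 0:
        raise InvalidInputError("flux must be positive")
    if dr_a_target_ug_h <= 0:
        raise InvalidInputError("target absorption rate must be positive")
    area = dr_a_target_ug_h / js_ug_cm2_h
    diameter = 2.0 * math.sqrt(area / (2.0 * math.pi))
    return area, diameter


def design_dosage(
    pk: PKParameters,
    js_ug_cm2_h: float,
    tested_diameter_cm: float = 0.65,
    js_se: float = 0.0,
    dr_a_sig_figs: int = 3,
) -> DosageDesign:
    """Full sizing chain Cmax -> Ke -> DR_E -> DR_A -> geometry.

    The target DR_A used for sizing is the required rate rounded to
    `dr_a_sig_figs` significant figures, and the tested tablet's
    delivery rate is computed on its 2-dp-rounded exchange area, both
    matching pharmaceutical-table reporting; raw values are retained.
    First-order (delta-method) uncertainties on DR_A and the required
    area are propagated from the supplied SEs.
    """
    ke = pk.ke_per_h
    dr_e = elimination_rate(pk.cmax_ng_ml, ke)
    dr_a_raw = required_absorption_rate(dr_e, pk.vd_l)
    dr_a_target = round_sig(dr_a_raw, dr_a_sig_figs)

    tested_area = tablet_exchange_area(tested_diameter_cm)
    tested_area_report = round(tested_area, 2)
    tested_dr_a = tested_absorption_rate(js_ug_cm2_h, tested_area)
    tested_dr_a_report = round(
        tested_absorption_rate(js_ug_cm2_h, tested_area_report), 2
    )

    req_area, req_diam = required_geometry(dr_a_target, js_ug_cm2_h)

    # Delta method: DR_A = Cmax * (const/t_half) * V_D is a product, so
    # relative variances add; required area adds the flux term.
    rel_var = (
        (pk.cmax_se / pk.cmax_ng_ml) ** 2
        + (pk.t_half_se / pk.t_half_h) ** 2
        + (pk.vd_se / pk.vd_l) ** 2
    )
    dr_a_se = dr_a_raw * math.sqrt(rel_var)
    area_rel_var = rel_var + (js_se / js_ug_cm2_h) ** 2 if js_ug_cm2_h else rel_var
    area_se = req_area * math.sqrt(area_rel_var)

    return DosageDesign(
        dr_e_ng_ml_h=dr_e,
        dr_a_required_ug_h=dr_a_raw,
        dr_a_target_ug_h=dr_a_target,
        js_ug_cm2_h=js_ug_cm2_h,
        tested_diameter_cm=tested_diameter_cm,
        tested_area_cm2=tested_area,
        tested_area_report_cm2=tested_area_report,
        tested_dr_a_ug_h=tested_dr_a,
        tested_dr_a_report_ug_h=tested_dr_a_report,
        required_total_area_cm2=req_area,
        required_area_report_cm2=round(req_area, 2),
        required_diameter_cm=req_diam,
        required_diameter_report_cm=round(req_diam, 2),
        dr_a_se_ug_h=dr_a_se if rel_var > 0 else None,
        required_area_se_cm2=area_se if area_rel_var > 0 else None,
    )
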