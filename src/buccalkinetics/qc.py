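"""Formulation quality metrics for spray-dried powders and tablets.

Process yield, drug loading (DL%), loading efficiency (LE%), drug per
tablet, and batch-uniformity acceptance on weight/thickness/content
series (pass when SE is within a percent tolerance of the mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "BatchRecord",
    "UniformityResult",
    "process_yield",
    "drug_loading",
    "loading_efficiency",
    "drug_per_tablet",
    "uniformity_check",
    "qc_report",
]


def process_yield(recovered_g: float, starting_g: float) -> float:
    """Spray-drying process yield, 100 * recovered / starting (%).

    A recovery above 105% of the input mass is rejected as physically
    implausible (weighing or transcription error).
    """
    if starting_g <= 0:
        raise InvalidInputError("starting mass must be positive")
    if recovered_g < 0:
        raise InvalidInputError("recovered mass must be non-negative")
    if recovered_g > 1.05 * starting_g:
        raise InvalidInputError("recovered mass exceeds 105% of starting mass")
    return 100.0 * recovered_g / starting_g


def drug_loading(drug_mg: float, powder_mg: float) -> float:
    """DL% = 100 * drug mass / powder mass."""
    if powder_mg <= 0:
        raise InvalidInputError("powder mass must be positive")
    if drug_mg < 0:
        raise InvalidInputError("drug mass must be non-negative")
    return 100.0 * drug_mg / powder_mg


def loading_efficiency(measured_dl: float, theoretical_dl: float) -> float:
    """LE% = 100 * measured DL% / theoretical DL% (recovered vs
    theoretical drug content)."""
    if theoretical_dl <= 0:
        raise InvalidInputError("theoretical drug loading must be positive")
    return 100.0 * measured_dl / theoretical_dl


def drug_per_tablet(dl_percent: float, tablet_weight_mg: float) -> float:
    """Drug content of one tablet (mg) from its weight and DL%."""
    if dl_percent <= 0 or tablet_weight_mg <= 0:
        raise InvalidInputError("DL% and tablet weight must be positive")
    return dl_percent / 100.0 * tablet_weight_mg


@dataclass(frozen=True)
class UniformityResult:
    mean: float
    se: float
    relative_se_percent: float
    tolerance_percent: float
    passed: bool
    statistic: str = "se"


def uniformity_check(
    values: Sequence[float],
    tolerance_percent: float = 10.0,
    use_rsd: bool = False,
) -> UniformityResult:
    """Batch uniformity: pass when SE/mean (percent) is within tolerance.

    ``use_rsd=True`` substitutes the relative standard deviation
    (pharmacopoeial style) for the standard error.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InvalidInputError("uniformity check needs at least 2 values")
    mean = float(v.mean())
    if mean == 0:
        raise InvalidInputError("mean of values is zero")
    sd = float(np.std(v, ddof=1))
    spread = sd if use_rsd else sd / math.sqrt(v.size)
    rel = abs(spread / mean) * 100.0
    return UniformityResult(
        mean=mean,
        se=float(sd / math.sqrt(v.size)),
        relative_se_percent=rel,
        tolerance_percent=float(tolerance_percent),
        passed=rel <= tolerance_percent,
        statistic="rsd" if use_rsd else "se",
    )


@dataclass(frozen=True)
class BatchRecord:
    """One spray-dried batch: composition, masses and tablet series.

    `composition` maps component name to % w/w and must sum to 100; the
    theoretical DL% defaults to the composition's drug entry.
    """

    name: str
    composition: dict[str, float]
    starting_mass_g: float
    recovered_mass_g: float
    measured_dl_percent: float
    measured_dl_se: float = 0.0
    drug_component: str = "drug"
    theoretical_dl_percent: float | None = None
    tablet_weights_mg: tuple[float, ...] = field(default_factory=tuple)
    tablet_thicknesses_mm: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 100.0) > 0.01:
            raise InvalidInputError(
                f"composition sums to {total}, expected 100 +/- 0.01"
            )
        if self.starting_mass_g < 0 or self.recovered_mass_g < 0:
            raise InvalidInputError("masses must be non-negative")
        if self.theoretical_dl_percent is None:
            if self.drug_component not in self.composition:
                raise InvalidInputError(
                    "no theoretical DL%: composition lacks the drug component"
                )
            object.__setattr__(
                self,
                "theoretical_dl_percent",
                float(self.composition[self.drug_component]),
            )


def qc_report(batch: BatchRecord, tolerance_percent: float = 10.0) -> dict:
    """All quality metrics for one batch as a JSON-ready dict."""
    report: dict = {
        "batch": batch.name,
        "yield_percent": process_yield(
            batch.recovered_mass_g, batch.starting_mass_g
        ),
        "dl_percent": batch.measured_dl_percent,
        "dl_se": batch.measured_dl_se,
        "theoretical_dl_percent": batch.theoretical_dl_percent,
        "le_percent": loading_efficiency(
            batch.measured_dl_percent, batch.theoretical_dl_percent
        ),
    }
    if batch.tablet_weights_mg:
        wu = uniformity_check(batch.tablet_weights_mg, tolerance_percent)
        report["tablet_weight"] = wu.__dict__ | {
            "drug_per_tablet_mg": drug_per_tablet(
                batch.measured_dl_percent, wu.mean
            )
        }
    if batch.tablet_thicknesses_mm:
        report["tablet_thickness"] = uniformity_check(
            batch.tablet_thicknesses_mm, tolerance_percent
        ).__dict__
    return report
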