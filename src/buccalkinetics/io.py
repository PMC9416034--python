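"""CSV readers and writers for the analysis modules.

All files are plain UTF-8 CSV with a header row and decimal points:

* calibration: ``concentration,absorbance``
* stability:   ``time_h,concentration``
* permeation:  long format ``replicate,time_h,acceptor_conc_ug_per_ml``
* release:     ``time_min,dose_fraction[,replicate]``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .permeation import PermeationExperiment
from .release import ReleaseProfile

__all__ = [
    "read_calibration_csv",
    "read_stability_csv",
    "read_permeation_csv",
    "read_release_csv",
    "write_permeation_csv",
    "write_release_csv",
    "write_calibration_csv",
]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InvalidInputError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidInputError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def read_calibration_csv(path: str | Path) -> list[tuple[float, float]]:
    df = _read_csv(path, ["concentration", "absorbance"])
    return list(zip(df["concentration"].astype(float), df["absorbance"].astype(float)))


def read_stability_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = _read_csv(path, ["time_h", "concentration"])
    return df["time_h"].to_numpy(float), df["concentration"].to_numpy(float)


def read_permeation_csv(
    path: str | Path,
    cd_mg_per_ml: float,
    v_acceptor_ml: float = 15.0,
    v_sample_ml: float = 0.5,
    area_cm2: float = 0.636,
    q_t_ug: list[float] | None = None,
    sampling_corrected: bool = False,
) -> PermeationExperiment:
    """Assemble a `PermeationExperiment` from a long-format CSV plus
    the cell geometry/donor configuration."""
    df = _read_csv(path, ["replicate", "time_h", "acceptor_conc_ug_per_ml"])
    wide = df.pivot_table(
        index="replicate", columns="time_h", values="acceptor_conc_ug_per_ml"
    ).sort_index(axis=1)
    if wide.isna().any().any():
        raise InvalidInputError(
            f"{path}: replicates do not share a common time grid"
        )
    return PermeationExperiment(
        times_h=wide.columns.to_numpy(float),
        acceptor_conc_ug_ml=wide.to_numpy(float),
        cd_mg_per_ml=cd_mg_per_ml,
        v_acceptor_ml=v_acceptor_ml,
        v_sample_ml=v_sample_ml,
        area_cm2=area_cm2,
        q_t_ug=np.asarray(q_t_ug, float) if q_t_ug is not None else None,
        sampling_corrected=sampling_corrected,
    )


def read_release_csv(
    path: str | Path,
    tablet_diameter_cm: float | None = None,
    tablet_thickness_mm: float | None = None,
) -> ReleaseProfile:
    """Read a release profile; replicate columns are averaged per time."""
    df = _read_csv(path, ["time_min", "dose_fraction"])
    if "replicate" in df.columns:
        df = df.groupby("time_min", as_index=False)["dose_fraction"].mean()
    df = df.sort_values("time_min")
    return ReleaseProfile(
        times_min=df["time_min"].to_numpy(float),
        dose_fraction=df["dose_fraction"].to_numpy(float),
        tablet_diameter_cm=tablet_diameter_cm,
        tablet_thickness_mm=tablet_thickness_mm,
    )


def write_permeation_csv(exp: PermeationExperiment, path: str | Path) -> None:
    rows = [
        {
            "replicate": rep + 1,
            "time_h": float(t),
            "acceptor_conc_ug_per_ml": float(exp.acceptor_conc_ug_ml[rep, j]),
        }
        for rep in range(exp.n_replicates)
        for j, t in enumerate(exp.times_h)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_release_csv(profile: ReleaseProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"time_min": profile.times_min, "dose_fraction": profile.dose_fraction}
    ).to_csv(path, index=False)


def write_calibration_csv(
    points: list[tuple[float, float]], path: str | Path
) -> None:
    pd.DataFrame(points, columns=["concentration", "absorbance"]).to_csv(
        path, index=False
    )
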