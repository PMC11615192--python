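"""Mg/Ca palaeothermometry.

Shell Mg/Ca (mmol mol⁻¹) is converted to calcification temperature with an
exponential calibration Mg/Ca = a·exp(b·T). The default parameters are the
species-specific central-Atlantic calibration a = 0.6 (± 0.16) mmol mol⁻¹,
b = 0.075 (± 0.006) °C⁻¹, so T = ln(Mg/Ca / a) / b.

Where duplicate dissolutions exist for a site, the first-listed (primary)
ratio is the conversion input by default; the replicate contributes to the
uncertainty budget only. A ``mode="mean"`` alternative averages the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationEquation",
    "MgCaMeasurement",
    "REGENBERG_TRILOBUS",
    "mgca_to_temperature",
    "temperature_to_mgca",
    "temperature_uncertainty",
    "select_primary_mgca",
    "convert_table",
]

#: Propagated analytical uncertainty on Mg/Ca (mmol mol⁻¹): ICP-MS precision
#: combined with the spread of replicate dissolutions.
DEFAULT_SIGMA_ANALYTICAL = 0.14

#: Coldest temperature considered plausible for the calibration's domain.
MIN_PLAUSIBLE_T = -2.0


@dataclass(frozen=True)
class CalibrationEquation:
    """Parameters of an exponential Mg/Ca–temperature calibration."""

    name: str = "regenberg-trilobus"
    a: float = 0.6  # pre-exponential, mmol mol⁻¹
    sigma_a: float = 0.16
    b: float = 0.075  # exponent, °C⁻¹
    sigma_b: float = 0.006

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("calibration requires a > 0 and b > 0")


REGENBERG_TRILOBUS = CalibrationEquation()


@dataclass
class MgCaMeasurement:
    """One site's Mg/Ca determination, optionally with a replicate."""

    site_id: int
    mgca: float  # mmol mol⁻¹, primary (first-listed) value
    mgca_replicate: float | None = None
    sigma_analytical: float = DEFAULT_SIGMA_ANALYTICAL
    al_ca: float | None = None
    fe_ca: float | None = None
    mn_ca: float | None = None

    def __post_init__(self) -> None:
        if self.mgca <= 0:
            raise ValueError("mgca must be positive")
        if self.sigma_analytical < 0:
            raise ValueError("sigma_analytical must be non-negative")


def mgca_to_temperature(mgca: float, calibration: CalibrationEquation = REGENBERG_TRILOBUS) -> float:
    """Invert the calibration: T = ln(Mg/Ca / a) / b, in °C."""
    if mgca <= 0:
        raise ValueError("mgca must be positive")
    return math.log(mgca / calibration.a) / calibration.b


def temperature_to_mgca(temperature: float, calibration: CalibrationEquation = REGENBERG_TRILOBUS) -> float:
    """Forward calibration: Mg/Ca = a·exp(b·T), in mmol mol⁻¹."""
    return calibration.a * math.exp(calibration.b * temperature)


def is_plausible(mgca: float, calibration: CalibrationEquation = REGENBERG_TRILOBUS) -> bool:
    """False when the ratio implies a temperature below the plausible minimum."""
    return mgca > calibration.a * math.exp(calibration.b * MIN_PLAUSIBLE_T)


def temperature_uncertainty(
    measurement: MgCaMeasurement | float,
    calibration: CalibrationEquation = REGENBERG_TRILOBUS,
    include_calibration: bool = False,
    sigma_analytical: float | None = None,
) -> float:
    """First-order 1σ temperature uncertainty in °C.

    The analytical term is σ_Mg/Ca / (b · Mg/Ca). With
    ``include_calibration`` the calibration-parameter terms
    σ_a / (b·a) and |ln(Mg/Ca / a)|·σ_b / b are added in quadrature,
    assuming independent errors.
    """
    if isinstance(measurement, MgCaMeasurement):
        mgca = measurement.mgca
        sigma = measurement.sigma_analytical if sigma_analytical is None else sigma_analytical
    else:
        mgca = float(measurement)
        sigma = DEFAULT_SIGMA_ANALYTICAL if sigma_analytical is None else sigma_analytical
    b = calibration.b
    var = (sigma / (b * mgca)) ** 2
    if include_calibration:
        var += (calibration.sigma_a / (b * calibration.a)) ** 2
        var += (abs(math.log(mgca / calibration.a)) * calibration.sigma_b / b) ** 2
    return math.sqrt(var)


def select_primary_mgca(measurement: MgCaMeasurement, mode: str = "primary") -> float:
    """Ratio used for temperature conversion.

    ``"primary"`` (default) returns the first-listed value — the rule
    consistent with the reference temperature column. ``"mean"`` averages
    primary and replicate when a replicate exists.
    """
    if mode == "primary":
        return measurement.mgca
    if mode == "mean":
        if measurement.mgca_replicate is None:
            return measurement.mgca
        return 0.5 * (measurement.mgca + measurement.mgca_replicate)
    raise ValueError(f"unknown mode {mode!r}")


def convert_table(
    geochem: pd.DataFrame,
    calibration: CalibrationEquation = REGENBERG_TRILOBUS,
    mode: str = "primary",
    include_calibration_uncertainty: bool = False,
) -> pd.DataFrame:
    """Convert a geochemistry site table to calcification temperatures.

    Expects canonical columns ``mgca_mmol_mol`` and (optionally)
    ``mgca_replicate_mmol_mol``; returns a table indexed like the input with
    the ratio used, temperature, its 1σ uncertainty and a plausibility flag.
    """
    rows = {}
    for site_id, row in geochem.iterrows():
        m = MgCaMeasurement(
            site_id=int(site_id),
            mgca=float(row["mgca_mmol_mol"]),
            mgca_replicate=(
                float(row["mgca_replicate_mmol_mol"])
                if "mgca_replicate_mmol_mol" in row and pd.notna(row["mgca_replicate_mmol_mol"])
                else None
            ),
        )
        used = select_primary_mgca(m, mode=mode)
        rows[site_id] = {
            "mgca_used_mmol_mol": used,
            "temperature_c": mgca_to_temperature(used, calibration),
            "sigma_temperature_c": temperature_uncertainty(
                m, calibration, include_calibration=include_calibration_uncertainty
            ),
            "plausible": is_plausible(used, calibration),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = geochem.index.name
    return out
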