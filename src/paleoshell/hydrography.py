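"""Seawater state and profile operations.

Potential density anomaly σθ is computed with the EOS-80 one-atmosphere
International Equation of State of Seawater (UNESCO 1983 polynomial) at a
reference pressure of 0 dbar, on the practical salinity scale. The upper
300 m of the water column is the working domain: profile interpolation,
warm-season averaging for extra-tropical sites, and detection of the
subsurface salinity maximum that traces subtropical underwater.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HydroProfile",
    "SalinityMaxHorizon",
    "sigma_theta",
    "interp_profile",
    "warm_season_profile",
    "find_salinity_max",
    "TROPICS_LATITUDE",
]

# Sites poleward of this latitude use warm-season averages; equatorward sites
# use annual means (the species' peak flux is year-round in the tropics but
# concentrated in the warmest months at temperate latitudes).
TROPICS_LATITUDE = 23.0


@dataclass
class HydroProfile:
    """Depth-ordered temperature/salinity nodes for one site and month.

    ``month`` is 1–12 for a monthly climatology or ``"mean"`` for an average;
    ``months_used`` records which months entered an averaged profile.
    """

    site_id: int
    month: int | str
    depths: np.ndarray  # m, strictly increasing
    temperature: np.ndarray  # °C
    salinity: np.ndarray  # practical salinity
    months_used: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.salinity = np.asarray(self.salinity, dtype=float)
        if not (len(self.depths) == len(self.temperature) == len(self.salinity)):
            raise ValueError("depths, temperature and salinity must have equal length")
        if len(self.depths) < 2:
            raise ValueError("profile needs at least 2 depth nodes")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any((self.temperature < -2.0) | (self.temperature > 40.0)):
            raise ValueError("temperature outside [-2, 40] °C")


@dataclass
class SalinityMaxHorizon:
    """Depth horizon of the salinity maximum of a profile."""

    depth: float  # m
    salinity: float
    sigma_theta: float  # kg m⁻³ − 1000
    is_subsurface: bool  # False when the maximum sits at the shallowest node
    tied: bool = False  # more than one node attains the maximum


def sigma_theta(salinity, temperature):
    """Potential density anomaly σθ (kg m⁻³ − 1000), EOS-80 at 0 dbar.

    Accepts scalars or arrays. Valid for practical salinity in [0, 42] and
    temperature in [−2, 40] °C. Reproduces the UNESCO 1983 check values,
    e.g. ρ(S=35, T=5 °C, p=0) = 1027.67547 kg m⁻³.
    """
    S = np.asarray(salinity, dtype=float)
    T = np.asarray(temperature, dtype=float)
    if np.any((S < 0.0) | (S > 42.0)):
        raise ValueError("salinity outside [0, 42]")
    if np.any((T < -2.0) | (T > 40.0)):
        raise ValueError("temperature outside [-2, 40] °C")

    # Density of the Standard Mean Ocean Water reference (pure water limit).
    rho_w = (
        999.842594
        + 6.793952e-2 * T
        - 9.095290e-3 * T**2
        + 1.001685e-4 * T**3
        - 1.120083e-6 * T**4
        + 6.536332e-9 * T**5
    )
    A = (
        8.24493e-1
        - 4.0899e-3 * T
        + 7.6438e-5 * T**2
        - 8.2467e-7 * T**3
        + 5.3875e-9 * T**4
    )
    B = -5.72466e-3 + 1.0227e-4 * T - 1.6546e-6 * T**2
    C = 4.8314e-4
    rho = rho_w + A * S + B * S**1.5 + C * S**2
    out = rho - 1000.0
    return float(out) if out.ndim == 0 else out


def interp_profile(profile: HydroProfile, depth: float) -> tuple[float, float]:
    """Piecewise-linear (temperature, salinity) at ``depth``; exact at nodes.

    Extrapolation outside the node range is refused.
    """
    z = float(depth)
    if z < profile.depths[0] or z > profile.depths[-1]:
        raise ValueError(
            f"extrapolation not allowed: depth {z} m outside "
            f"[{profile.depths[0]}, {profile.depths[-1]}] m"
        )
    t = float(np.interp(z, profile.depths, profile.temperature))
    s = float(np.interp(z, profile.depths, profile.salinity))
    return t, s


def _common_grid(monthly: dict[int, HydroProfile]) -> np.ndarray:
    grids = [monthly[m].depths for m in sorted(monthly)]
    for g in grids[1:]:
        if len(g) != len(grids[0]) or np.any(g != grids[0]):
            raise ValueError("monthly profiles must share a common depth grid")
    return grids[0]


def warm_season_profile(monthly, latitude: float) -> HydroProfile:
    """Seasonally appropriate mean profile for a site.

    Poleward of ±23° latitude the node-wise mean of the three consecutive
    warmest months is used — ranked by shallowest-node (mixed-layer)
    temperature, with wrap-around across the year boundary. Equatorward of
    23° the simple annual mean over all 12 months is returned.
    """
    if not isinstance(monthly, dict):
        monthly = {p.month: p for p in monthly}
    missing = set(range(1, 13)) - set(monthly)
    if missing:
        raise ValueError(f"missing months: {sorted(missing)}")
    depths = _common_grid(monthly)
    site_id = monthly[1].site_id

    if abs(latitude) > TROPICS_LATITUDE:
        sst = np.array([monthly[m].temperature[0] for m in range(1, 13)])
        triples = [((m0 % 12) + 1, (m0 + 1) % 12 + 1, (m0 + 2) % 12 + 1) for m0 in range(12)]
        months = max(triples, key=lambda tr: sum(sst[m - 1] for m in tr))
    else:
        months = tuple(range(1, 13))

    T = np.mean([monthly[m].temperature for m in months], axis=0)
    S = np.mean([monthly[m].salinity for m in months], axis=0)
    return HydroProfile(
        site_id=site_id, month="mean", depths=depths, temperature=T,
        salinity=S, months_used=months,
    )


def find_salinity_max(profile: HydroProfile) -> SalinityMaxHorizon:
    """Locate the salinity maximum of a profile.

    Under piecewise-linear interpolation the maximum sits on a node; ties are
    resolved to the shallowest node (the species is near-surface dwelling)
    and flagged. ``is_subsurface`` is False when the maximum is at the
    shallowest node — the subtropical-gyre case with no salinity inversion.
    """
    s = profile.salinity
    smax = s.max()
    at_max = np.flatnonzero(s == smax)
    idx = int(at_max[0])
    depth = float(profile.depths[idx])
    return SalinityMaxHorizon(
        depth=depth,
        salinity=float(smax),
        sigma_theta=sigma_theta(smax, profile.temperature[idx]),
        is_subsurface=idx != 0,
        tied=len(at_max) > 1,
    )
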