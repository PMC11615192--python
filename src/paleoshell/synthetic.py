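"""Synthetic hydrography, shell-trait populations and voxel phantoms.

Everything here exists so each pipeline stage can be tested against known
ground truth without external data:

- yearly sets of monthly temperature/salinity profiles on the standard
  climatology depth grid (2.5 m, then every 10 m to 200 m, every 20 m to
  300 m), with a mixed layer over a logistic thermocline and an optional
  Gaussian subsurface salinity maximum;
- per-site shell populations whose mean weight responds linearly to a
  salinity driver, with log-normal intra-sample scatter matching the
  relative SDs seen in real transect tables (~8–20%);
- digitised hollow-sphere phantoms with aperture, debris blob and a
  calcite-standard cube, paired with their analytic volumes and surfaces.

All randomness flows from explicit seeds; generators are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hydrography import HydroProfile, interp_profile, warm_season_profile
from .morphometry import SpecimenMorphometry
from .paleothermometry import temperature_to_mgca
from .tomogram import Label, LabelVolume

__all__ = [
    "ARGO_GRID",
    "ProfileScenario",
    "TraitScenario",
    "PhantomTruth",
    "generate_profile_year",
    "generate_shell_sample",
    "generate_phantom",
    "make_transect_scenario",
    "generate_transect",
]

#: Standard climatology depth grid (m): 2.5, every 10 m to 200, every 20 m to 300.
ARGO_GRID = np.array([2.5] + list(range(10, 201, 10)) + list(range(220, 301, 20)), float)

#: Maximum/minimum sieve aperture ratio of the analysed 300–355 μm fraction.
SIEVE_WINDOW_UM = (300.0, 355.0)


@dataclass(frozen=True)
class ProfileScenario:
    """Parameters of a synthetic yearly profile set for one site."""

    sst: float = 26.0  # °C, annual-mean surface temperature
    mixed_layer_depth: float = 40.0  # m
    thermocline_scale: float = 20.0  # m, logistic decay scale
    deep_temp: float = 12.0  # °C at the base of the domain
    surface_salinity: float = 36.0
    s_max_amplitude: float = 0.6  # practical salinity units
    s_max_depth: float = 80.0  # m; 0 puts the maximum at the surface
    s_max_width: float = 30.0  # m, Gaussian width
    seasonal_amplitude: float = 2.0  # °C, SST modulation
    peak_month: int = 9  # warmest month (9 → Aug–Oct warmest triple)
    noise_sd: float = 0.0  # °C / psu node noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mixed_layer_depth <= 0 or self.thermocline_scale <= 0:
            raise ValueError("depth scales must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class TraitScenario:
    """Parameters of a synthetic per-site shell population."""

    n_specimens: int = 50
    salinity: float = 36.0  # driver value for the weight response
    weight_slope: float = 2.2  # μg per practical-salinity unit
    baseline_weight: float = 28.0  # μg at salinity 36
    weight_noise_sd: float = 2.5  # μg per specimen
    mean_silhouette_area: float = 0.132e6  # μm²
    mean_potential_volume: float = 20.5e6  # μm³
    mean_test_fraction: float = 0.40  # of potential volume
    mean_outer_surface_area: float = 0.49e6  # μm²
    relative_sd: dict = field(
        default_factory=lambda: {
            "silhouette_area": 0.11,
            "potential_volume": 0.12,
            "test_volume": 0.16,
            "biovolume": 0.15,
            "outer_surface_area": 0.09,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be at least 1")
        lo, hi = SIEVE_WINDOW_UM
        if lo <= 0 or hi <= lo:
            raise ValueError("invalid sieve window")


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic geometry of the un-apertured hollow-sphere phantom."""

    outer_radius: float
    inner_radius: float
    wall: float
    shell_volume: float  # 4/3·π·(R³ − r³)
    full_volume: float  # 4/3·π·R³
    outer_surface: float  # 4π R²
    inner_surface: float  # 4π r²
    total_surface: float  # 4π (R² + r²)


def _lognormal(rng, mean: float, rel_sd: float, size: int) -> np.ndarray:
    """Log-normal draws with the given arithmetic mean and relative SD."""
    if rel_sd == 0:
        return np.full(size, mean)
    sigma2 = math.log(1.0 + rel_sd**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def generate_profile_year(scenario: ProfileScenario) -> dict[int, HydroProfile]:
    """12 monthly profiles on the standard grid, reproducible under the seed.

    Temperature follows a normalised logistic decay from the monthly SST to
    ``deep_temp`` below the mixed layer; salinity is the surface value plus a
    Gaussian bump centred at ``s_max_depth``. Monthly SST is modulated
    sinusoidally around ``peak_month``.
    """
    rng = np.random.default_rng(scenario.seed)
    z = ARGO_GRID

    def logistic(depth):
        return 1.0 / (1.0 + np.exp((depth - scenario.mixed_layer_depth) / scenario.thermocline_scale))

    shape = logistic(z) / logistic(z[0])  # T(2.5 m) = monthly SST exactly
    s_profile = scenario.surface_salinity + scenario.s_max_amplitude * np.exp(
        -0.5 * ((z - scenario.s_max_depth) / scenario.s_max_width) ** 2
    )
    out: dict[int, HydroProfile] = {}
    for month in range(1, 13):
        sst_m = scenario.sst + scenario.seasonal_amplitude * math.cos(
            2.0 * math.pi * (month - scenario.peak_month) / 12.0
        )
        T = scenario.deep_temp + (sst_m - scenario.deep_temp) * shape
        S = s_profile.copy()
        if scenario.noise_sd > 0:
            T = T + rng.normal(0.0, scenario.noise_sd, z.size)
            S = S + rng.normal(0.0, scenario.noise_sd, z.size)
        out[month] = HydroProfile(
            site_id=0, month=month, depths=z, temperature=T, salinity=S
        )
    return out


def generate_shell_sample(
    scenario: TraitScenario,
) -> tuple[list[SpecimenMorphometry], float]:
    """Specimen population plus its mean weight (μg).

    Weights are linear in the salinity driver (anchored at salinity 36) with
    Gaussian specimen noise; areas and volumes are log-normal with the
    programmed relative SDs. Geometric consistency (test < potential) is
    enforced by drawing the test volume as a fraction of each specimen's
    potential volume.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_specimens
    weights = (
        scenario.baseline_weight
        + scenario.weight_slope * (scenario.salinity - 36.0)
        + rng.normal(0.0, scenario.weight_noise_sd, n)
    )
    rsd = scenario.relative_sd
    sil = _lognormal(rng, scenario.mean_silhouette_area, rsd["silhouette_area"], n)
    pot = _lognormal(rng, scenario.mean_potential_volume, rsd["potential_volume"], n)
    frac = np.clip(
        _lognormal(rng, scenario.mean_test_fraction, rsd["test_volume"], n), 0.05, 0.95
    )
    test = frac * pot
    bio = np.minimum(
        _lognormal(rng, 0.58 * scenario.mean_potential_volume, rsd["biovolume"], n),
        0.99 * (pot - test),
    )
    osa = _lognormal(rng, scenario.mean_outer_surface_area, rsd["outer_surface_area"], n)
    specimens = [
        SpecimenMorphometry(
            silhouette_area=float(sil[i]),
            potential_volume=float(pot[i]),
            test_volume=float(test[i]),
            biovolume=float(bio[i]),
            outer_surface_area=float(osa[i]),
        )
        for i in range(n)
    ]
    return specimens, float(weights.mean())


def generate_phantom(
    outer_radius: float,
    wall: float,
    aperture_radius: float = 0.0,
    voxel_size: float = 1.2,
    debris_fraction: float = 0.0,
    with_standard: bool = True,
    with_intensity: bool = False,
) -> tuple[LabelVolume, PhantomTruth]:
    """Digitised hollow sphere with optional aperture, debris and standard.

    The sphere is centred on the grid; the aperture is a cylindrical opening
    of ``aperture_radius`` punched through the wall along +z. The debris blob
    is a concentric sphere holding ``debris_fraction`` % of the analytic shell
    volume. Analytic truth refers to the un-apertured sphere.
    """
    if wall >= outer_radius:
        raise ValueError("wall must be thinner than outer_radius")
    if aperture_radius >= outer_radius:
        raise ValueError("aperture must be narrower than outer_radius")
    if wall / voxel_size < 5:
        raise ValueError(
            f"voxel_size {voxel_size} too coarse: fewer than 5 voxels across the wall"
        )
    R = outer_radius
    r = outer_radius - wall
    margin = 4 * voxel_size
    half = R + margin
    n = int(np.ceil(2 * half / voxel_size))
    coords = (np.arange(n) + 0.5) * voxel_size - half
    zz, yy, xx = np.meshgrid(coords, coords, coords, indexing="ij")
    d2 = xx**2 + yy**2 + zz**2

    labels = np.zeros((n, n, n), dtype=np.uint8)
    shell = (d2 <= R**2) & (d2 >= r**2)
    lumen = d2 < r**2
    if aperture_radius > 0:
        bore = (xx**2 + yy**2 <= aperture_radius**2) & (zz > 0)
        shell &= ~bore
        lumen &= ~bore
    labels[shell] = int(Label.TEST)
    labels[lumen] = int(Label.LUMEN)

    shell_volume = 4.0 / 3.0 * math.pi * (R**3 - r**3)
    if debris_fraction > 0:
        rd = (3.0 * (debris_fraction / 100.0) * shell_volume / (4.0 * math.pi)) ** (1.0 / 3.0)
        if rd > r / 2.0:
            raise ValueError("debris blob does not fit inside the lumen")
        # blob sits in the lower (−z) half of the lumen, clear of any aperture bore
        dd2 = xx**2 + yy**2 + (zz + r / 2.0) ** 2
        labels[(dd2 < rd**2) & (labels == int(Label.LUMEN))] = int(Label.DEBRIS)
    if with_standard:
        k = max(4, int(round(8.0 / voxel_size)))
        labels[:k, :k, :k] = int(Label.STANDARD)

    intensity = None
    if with_intensity:
        grey = {
            int(Label.BACKGROUND): 100.0,
            int(Label.TEST): 800.0,
            int(Label.LUMEN): 100.0,
            int(Label.DEBRIS): 300.0,
            int(Label.STANDARD): 900.0,
        }
        intensity = np.zeros(labels.shape)
        for lab, g in grey.items():
            intensity[labels == lab] = g

    truth = PhantomTruth(
        outer_radius=R,
        inner_radius=r,
        wall=wall,
        shell_volume=shell_volume,
        full_volume=4.0 / 3.0 * math.pi * R**3,
        outer_surface=4.0 * math.pi * R**2,
        inner_surface=4.0 * math.pi * r**2,
        total_surface=4.0 * math.pi * (R**2 + r**2),
    )
    return LabelVolume(voxels=labels, voxel_size=voxel_size, raw_intensity=intensity), truth


_PRESETS = {
    "gyre-N": (
        ProfileScenario(
            sst=24.0, mixed_layer_depth=80.0, thermocline_scale=25.0, deep_temp=13.0,
            surface_salinity=37.2, s_max_amplitude=0.3, s_max_depth=0.0, s_max_width=40.0,
            seasonal_amplitude=3.0, peak_month=9,
        ),
        TraitScenario(salinity=37.0),
    ),
    "tropics": (
        ProfileScenario(
            sst=26.0, mixed_layer_depth=45.0, thermocline_scale=20.0, deep_temp=12.0,
            surface_salinity=36.0, s_max_amplitude=0.8, s_max_depth=80.0, s_max_width=30.0,
            seasonal_amplitude=1.5, peak_month=9,
        ),
        TraitScenario(salinity=36.2),
    ),
    "equator": (
        ProfileScenario(
            sst=27.0, mixed_layer_depth=22.0, thermocline_scale=12.0, deep_temp=11.0,
            surface_salinity=35.8, s_max_amplitude=0.6, s_max_depth=60.0, s_max_width=25.0,
            seasonal_amplitude=1.0, peak_month=9,
        ),
        TraitScenario(salinity=35.9),
    ),
    "gyre-S": (
        ProfileScenario(
            sst=23.5, mixed_layer_depth=75.0, thermocline_scale=25.0, deep_temp=13.0,
            surface_salinity=36.8, s_max_amplitude=0.3, s_max_depth=0.0, s_max_width=40.0,
            seasonal_amplitude=3.0, peak_month=3,
        ),
        TraitScenario(salinity=36.6),
    ),
}


def make_transect_scenario(preset: str) -> tuple[ProfileScenario, TraitScenario]:
    """Named parameter bundles spanning the gyre / tropics / equator regimes.

    Gyre presets put the salinity maximum at the surface (no subsurface
    maximum); the equator preset has a shallow mixed layer and fresh surface.
    """
    try:
        return _PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")


def _interp_scenarios(latitude: float, seed: int) -> tuple[ProfileScenario, TraitScenario]:
    """Smooth latitude interpolation between the equator and gyre regimes."""
    w = min(abs(latitude) / 31.0, 1.0)  # 0 at the Equator, 1 at the gyre cores
    prof = ProfileScenario(
        sst=27.0 - 3.2 * w,
        mixed_layer_depth=22.0 + 58.0 * w,
        thermocline_scale=12.0 + 13.0 * w,
        deep_temp=11.0 + 2.0 * w,
        surface_salinity=35.8 + 1.3 * w**1.5,
        s_max_amplitude=0.6 - 0.3 * w,
        s_max_depth=max(0.0, 70.0 * (1.0 - 1.15 * w)),
        s_max_width=25.0 + 15.0 * w,
        seasonal_amplitude=1.0 + 2.0 * w,
        peak_month=9 if latitude >= 0 else 3,
        noise_sd=0.05,
        seed=seed,
    )
    traits = TraitScenario(salinity=prof.surface_salinity, seed=seed + 1)
    return prof, traits


def generate_transect(seed: int = 0, n_sites: int = 16) -> dict:
    """A full synthetic transect exercising every pipeline stage.

    Sites span 31° N to 25° S. For each site, monthly profiles are generated,
    a true calcification depth is fixed, the matching temperature is read off
    the seasonally appropriate profile and pushed through the forward
    calibration to make a synthetic Mg/Ca ratio; shell populations respond to
    the salinity at that depth with the programmed weight slope.

    Returns ``sites``, ``geochemistry`` and ``morphometry`` tables in the
    canonical schemas, the ``profiles`` map, and a ``truth`` table holding the
    programmed depths and salinity drivers.
    """
    rng = np.random.default_rng(seed)
    lats = np.linspace(31.0, -25.0, n_sites)
    sites_rows, geochem_rows, morpho_rows, truth_rows = [], [], [], []
    profiles: dict[int, dict[int, HydroProfile]] = {}
    for i, lat in enumerate(lats, start=1):
        site_seed = int(rng.integers(0, 2**31 - 1))
        prof_sc, trait_sc = _interp_scenarios(float(lat), site_seed)
        monthly = generate_profile_year(prof_sc)
        for m in monthly.values():
            m.site_id = i
        profiles[i] = monthly
        seasonal = warm_season_profile(monthly, float(lat))

        z_true = 35.0 + 35.0 * (1.0 - abs(lat) / 31.0) + rng.uniform(-5.0, 5.0)
        t_true, s_true = interp_profile(seasonal, z_true)
        trait_sc = replace(trait_sc, salinity=s_true)
        specimens, mean_weight = generate_shell_sample(trait_sc)

        sites_rows.append(
            {"site_id": i, "label": f"SYN-{i:02d}", "latitude": round(float(lat), 3),
             "longitude": -20.0, "water_depth_m": 3400.0}
        )
        geochem_rows.append(
            {"site_id": i, "shell_weight_ug": mean_weight,
             "mgca_mmol_mol": temperature_to_mgca(t_true)}
        )
        agg = {
            "site_id": i,
            "silhouette_area_um2": float(np.mean([s.silhouette_area for s in specimens])),
            "potential_volume_um3": float(np.mean([s.potential_volume for s in specimens])),
            "test_volume_um3": float(np.mean([s.test_volume for s in specimens])),
            "biovolume_um3": float(np.mean([s.biovolume for s in specimens])),
            "outer_surface_area_um2": float(np.mean([s.outer_surface_area for s in specimens])),
        }
        morpho_rows.append(agg)
        truth_rows.append(
            {"site_id": i, "true_depth_m": z_true, "true_temperature_c": t_true,
             "salinity_driver": s_true}
        )

    def _frame(rows):
        df = pd.DataFrame(rows)
        return df.set_index(df["site_id"].astype(int)).drop(columns="site_id")

    return {
        "sites": _frame(sites_rows),
        "geochemistry": _frame(geochem_rows),
        "morphometry": _frame(morpho_rows),
        "profiles": profiles,
        "truth": _frame(truth_rows),
    }
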