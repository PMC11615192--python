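"""Tabular I/O, unit conventions, configuration and logging shared by all stages.

Canonical units used throughout the package (``UnitPolicy``): depth in m,
weight in μg, areas in μm², volumes in μm³, densities in g cm⁻³ (identical to
μg nl⁻¹), thickness in μm, SA:V in μm⁻¹ and area density ρA in μg μm⁻².
Display units used in input tables (mm² for silhouette and surface areas,
nl for volumes) are converted on ingest; writers keep unit suffixes in the
column names so every emitted table states its units.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .hydrography import HydroProfile

__all__ = [
    "UnitPolicy",
    "SiteRecord",
    "SiteEnvironment",
    "read_site_table",
    "read_morphometry_table",
    "read_profile_set",
    "write_profile_set",
    "write_results",
    "load_reference_tables",
    "load_config",
    "get_logger",
]


class TableFormatError(ValueError):
    """Raised when an input table violates the documented schema."""


@dataclass(frozen=True)
class UnitPolicy:
    """Exact power-of-ten conversion factors between display and canonical units."""

    MM2_TO_UM2: float = 1e6
    NL_TO_UM3: float = 1e6
    # μg / nl is numerically identical to g / cm³; kept for readability.
    UG_PER_NL_TO_G_PER_CM3: float = 1.0


UNITS = UnitPolicy()


@dataclass
class SiteRecord:
    """Location and stratigraphic metadata for one core-top site."""

    site_id: int
    label: str
    latitude: float
    longitude: float
    water_depth: float  # m
    core_depth: float | None = None  # cm
    age_text: str = ""
    stratigraphy: str = ""
    fragmentation_index: float | None = None  # consumed, never computed
    percent_dextral: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        if self.water_depth <= 0:
            raise ValueError("water_depth must be positive")


@dataclass
class SiteEnvironment:
    """Environmental values paired with one site (measured or gridded)."""

    salinity_at_acd: float | None = None
    co3_3d: float | None = None  # μmol kg⁻¹, pre-industrial
    salinity_3d: float | None = None
    sigma_theta_3d: float | None = None  # kg m⁻³ − 1000
    sigma_theta_at_acd: float | None = None

    def __post_init__(self) -> None:
        for name in ("salinity_at_acd", "salinity_3d"):
            v = getattr(self, name)
            if v is not None and not 30.0 <= v <= 40.0:
                raise ValueError(f"{name}={v} outside [30, 40]")
        for name in ("sigma_theta_3d", "sigma_theta_at_acd"):
            v = getattr(self, name)
            if v is not None and not 20.0 <= v <= 30.0:
                raise ValueError(f"{name}={v} outside [20, 30]")
        if self.co3_3d is not None and self.co3_3d <= 0:
            raise ValueError("co3_3d must be positive")


# Numeric columns recognised in merged site tables; anything else is carried
# through untouched as free text.
_SITE_NUMERIC_COLUMNS = (
    "latitude",
    "longitude",
    "water_depth_m",
    "core_depth_cm",
    "shell_weight_ug",
    "mgca_mmol_mol",
    "mgca_replicate_mmol_mol",
    "temperature_c",
    "acd_m",
    "salinity_acd",
    "sigma_theta_acd",
    "co3_3d_umol_kg",
    "salinity_3d",
    "sigma_theta_3d",
    "fragmentation_index",
    "percent_dextral",
)

_MORPHO_DISPLAY_COLUMNS = {
    # display column -> (canonical column, conversion factor)
    "silhouette_area_mm2": ("silhouette_area_um2", UNITS.MM2_TO_UM2),
    "potential_volume_nl": ("potential_volume_um3", UNITS.NL_TO_UM3),
    "test_volume_nl": ("test_volume_um3", UNITS.NL_TO_UM3),
    "biovolume_nl": ("biovolume_um3", UNITS.NL_TO_UM3),
    "outer_surface_area_mm2": ("outer_surface_area_um2", UNITS.MM2_TO_UM2),
    "total_surface_area_mm2": ("total_surface_area_um2", UNITS.MM2_TO_UM2),
}


def _read_csv(path, decimal: str = ".") -> pd.DataFrame:
    df = pd.read_csv(path, decimal=decimal, skipinitialspace=True)
    if df.empty:
        raise TableFormatError(f"{path}: no data rows")
    return df


def _coerce_numeric(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableFormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}, row {row + 2}"
            )
        df[col] = coerced


def _check_unique_sites(df: pd.DataFrame, path) -> None:
    if "site_id" not in df.columns:
        raise TableFormatError(f"{path}: missing required column 'site_id'")
    dup = df["site_id"][df["site_id"].duplicated()]
    if not dup.empty:
        raise TableFormatError(f"{path}: duplicate site_id {sorted(set(dup))}")


def read_site_table(path, decimal: str = ".") -> pd.DataFrame:
    """Read a merged site table (location, weights, geochemistry, environment).

    Values are returned in canonical units, indexed by ``site_id``. Missing
    cells stay ``NaN`` — they are never silently zeroed. ``decimal=","``
    switches the parser to comma-decimal locales.
    """
    df = _read_csv(path, decimal=decimal)
    _check_unique_sites(df, path)
    _coerce_numeric(df, _SITE_NUMERIC_COLUMNS + ("site_id",), path)
    if len(df) < 3:
        raise TableFormatError(f"{path}: at least 3 sites required, got {len(df)}")
    if "latitude" in df.columns and (df["latitude"].abs() > 90).any():
        raise TableFormatError(f"{path}: latitude outside [-90, 90]")
    if "longitude" in df.columns and (df["longitude"].abs() > 180).any():
        raise TableFormatError(f"{path}: longitude outside [-180, 180]")
    return df.set_index(df["site_id"].astype(int)).drop(columns="site_id")


def read_morphometry_table(path, decimal: str = ".") -> pd.DataFrame:
    """Read a per-site morphometry table and convert to canonical μm²/μm³ units."""
    df = _read_csv(path, decimal=decimal)
    _check_unique_sites(df, path)
    numeric = [c for c in df.columns if c not in ("label",)]
    _coerce_numeric(df, numeric, path)
    for display, (canonical, factor) in _MORPHO_DISPLAY_COLUMNS.items():
        if display in df.columns:
            df[canonical] = df[display] * factor
            df = df.drop(columns=display)
    return df.set_index(df["site_id"].astype(int)).drop(columns="site_id")


def read_profile_set(path, decimal: str = ".") -> dict[int, dict[int, HydroProfile]]:
    """Read depth-resolved monthly profiles: site → month → :class:`HydroProfile`.

    Rows may arrive in any order; they are sorted by depth per site/month.
    Duplicate depths and profiles with fewer than two nodes are errors.
    """
    df = _read_csv(path, decimal=decimal)
    required = {"site", "month", "depth_m", "temperature_c", "salinity"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    _coerce_numeric(df, ["site", "month", "depth_m", "temperature_c", "salinity"], path)

    out: dict[int, dict[int, HydroProfile]] = {}
    for (site, month), grp in df.groupby(["site", "month"]):
        grp = grp.sort_values("depth_m")
        depths = grp["depth_m"].to_numpy(float)
        if len(depths) < 2:
            raise TableFormatError(
                f"{path}: site {site} month {month}: fewer than 2 depth nodes"
            )
        if np.any(np.diff(depths) <= 0):
            raise TableFormatError(
                f"{path}: site {site} month {month}: non-monotone (duplicate) depths"
            )
        out.setdefault(int(site), {})[int(month)] = HydroProfile(
            site_id=int(site),
            month=int(month),
            depths=depths,
            temperature=grp["temperature_c"].to_numpy(float),
            salinity=grp["salinity"].to_numpy(float),
        )
    return out


def write_profile_set(profiles: Mapping[int, Mapping[int, HydroProfile]], path) -> None:
    rows = []
    for site in sorted(profiles):
        for month in sorted(profiles[site]):
            p = profiles[site][month]
            for z, t, s in zip(p.depths, p.temperature, p.salinity):
                rows.append((site, month, z, t, s))
    pd.DataFrame(
        rows, columns=["site", "month", "depth_m", "temperature_c", "salinity"]
    ).to_csv(path, index=False)


def _config_hash(config) -> str:
    blob = yaml.safe_dump(config, sort_keys=True) if config is not None else ""
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_results(tables: Mapping[str, pd.DataFrame], outdir, config=None, seed=None) -> Path:
    """Write one CSV per result table plus a run manifest.

    The manifest records the config hash, seed and library versions so a rerun
    with identical config and seed can be verified byte-for-byte against the
    emitted tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        dest = outdir / f"{name}.csv"
        table.to_csv(dest, float_format="%.12g")
        written.append(dest.name)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "tables": sorted(written),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def load_reference_tables() -> dict[str, pd.DataFrame]:
    """Load the packaged 16-site reference tables (already in canonical units).

    Returns ``sites`` (locations/stratigraphy), ``geochemistry`` (weights,
    Mg/Ca, printed temperatures and at-depth environment) and ``morphometry``
    (optical and tomographic shell measurements).
    """
    base = resources.files("paleoshell.data")
    with resources.as_file(base / "sites.csv") as p:
        sites = read_site_table(p)
    with resources.as_file(base / "geochemistry.csv") as p:
        geochem = read_site_table(p)
    with resources.as_file(base / "morphometry.csv") as p:
        morpho = read_morphometry_table(p)
    return {"sites": sites, "geochemistry": geochem, "morphometry": morpho}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise TableFormatError(f"{path}: config must be a YAML mapping")
    return cfg


def get_logger(name: str = "paleoshell") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger
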