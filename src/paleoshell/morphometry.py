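"""Scalar shell traits and site-level aggregation.

All traits are derived from sample means (mean weight / mean area, etc.),
not from means of per-specimen ratios — the convention needed so that a
site-level table of averaged measurements reproduces the published
site-level trait values exactly.

Canonical units: weight μg, areas μm², volumes μm³. Note μg nl⁻¹ ≡ g cm⁻³,
so bulk shell density (weight / potential volume) lands directly in g cm⁻³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpecimenMorphometry",
    "SampleMorphometry",
    "DerivedTraits",
    "equivalent_circular_diameter",
    "area_density",
    "mean_thickness",
    "bulk_shell_density",
    "test_volume_percent",
    "surface_to_volume_ratio",
    "organic_tissue_density",
    "aggregate_sample",
    "derive_site_traits",
]

#: Mean density of near-surface seawater used in the organic-tissue estimate.
SEAWATER_DENSITY_G_CM3 = 1.025


@dataclass
class SpecimenMorphometry:
    """Per-specimen shell measurements in canonical units (μm², μm³)."""

    silhouette_area: float | None = None  # μm², optical
    potential_volume: float | None = None  # μm³, shell + sealed interior
    test_volume: float | None = None  # μm³, calcite only
    biovolume: float | None = None  # μm³, internal cavity (independent measurement)
    outer_surface_area: float | None = None  # μm²
    total_test_surface_area: float | None = None  # μm², inner + outer
    ct_number: float | None = None
    debris_fraction: float | None = None  # % of test volume

    def __post_init__(self) -> None:
        for name in (
            "silhouette_area", "potential_volume", "test_volume",
            "biovolume", "outer_surface_area", "total_test_surface_area",
        ):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if (
            self.test_volume is not None
            and self.potential_volume is not None
            and self.test_volume >= self.potential_volume
        ):
            raise ValueError("test_volume must be smaller than potential_volume")
        if self.debris_fraction is not None and not 0 <= self.debris_fraction <= 100:
            raise ValueError("debris_fraction must lie in [0, 100]")


@dataclass
class SampleMorphometry:
    """Site-level means and intra-sample relative SDs (%)."""

    site_id: int
    mean_weight: float  # μg, from the weighing study
    n_specimens: int
    means: dict[str, float] = field(default_factory=dict)
    relative_sd: dict[str, float] = field(default_factory=dict)


@dataclass
class DerivedTraits:
    """Traits computed from site-level mean measurements."""

    ecd: float | None = None  # μm
    rho_a: float | None = None  # μg μm⁻²
    mean_thickness: float | None = None  # μm
    bsd: float | None = None  # g cm⁻³
    test_percent: float | None = None  # %
    sa_to_v: float | None = None  # μm⁻¹


def equivalent_circular_diameter(area: float) -> float:
    """Diameter (μm) of the circle with the same area (μm²) as the silhouette."""
    if area <= 0:
        raise ValueError("area must be positive")
    return 2.0 * math.sqrt(area / math.pi)


def area_density(weight: float, silhouette_area: float) -> float:
    """Area density ρA = shell weight / silhouette area, μg μm⁻².

    A size-normalisation of shell mass: within a narrow sieve fraction ρA is
    dominated by calcification changes rather than specimen size.
    """
    if weight <= 0 or silhouette_area <= 0:
        raise ValueError("weight and silhouette_area must be positive")
    return weight / silhouette_area


def mean_thickness(test_volume: float, total_test_surface_area: float) -> float:
    """Mean test wall thickness = calcite volume / total (inner+outer) surface, μm.

    For a thin wall, volume ≈ surface × thickness with the surface counted on
    both faces, so V/SA tends to half the wall thickness. The *total*
    segmented surface is required; substituting the outer surface alone would
    roughly double the value.
    """
    if test_volume <= 0 or total_test_surface_area <= 0:
        raise ValueError("test_volume and total_test_surface_area must be positive")
    return test_volume / total_test_surface_area


def bulk_shell_density(weight: float, potential_volume: float) -> float:
    """Bulk shell density BSD = weight / potential specimen volume, g cm⁻³.

    ``weight`` in μg, ``potential_volume`` in μm³; μg nl⁻¹ ≡ g cm⁻³.
    """
    if weight <= 0 or potential_volume <= 0:
        raise ValueError("weight and potential_volume must be positive")
    return weight * 1e6 / potential_volume


def test_volume_percent(test_volume: float, potential_volume: float) -> float:
    """Calcite test volume as % of the potential specimen volume."""
    if test_volume <= 0 or potential_volume <= 0:
        raise ValueError("volumes must be positive")
    if test_volume >= potential_volume:
        raise ValueError("test_volume must be smaller than potential_volume")
    return 100.0 * test_volume / potential_volume


def surface_to_volume_ratio(outer_surface_area: float, potential_volume: float) -> float:
    """SA:V = outer surface area / potential volume, μm⁻¹ (a sphericity index)."""
    if outer_surface_area <= 0 or potential_volume <= 0:
        raise ValueError("outer_surface_area and potential_volume must be positive")
    return outer_surface_area / potential_volume


def organic_tissue_density(
    mean_bsd: float, seawater_density: float = SEAWATER_DENSITY_G_CM3
) -> float:
    """Descriptive organic-tissue density estimate: mean BSD − seawater density.

    A first-order bookkeeping of what the soft parts of a neutrally ballasted
    cell would weigh, not a buoyancy model.
    """
    if mean_bsd <= seawater_density:
        raise ValueError("mean_bsd must exceed seawater_density")
    return mean_bsd - seawater_density


_AGG_FIELDS = (
    "silhouette_area", "potential_volume", "test_volume", "biovolume",
    "outer_surface_area", "total_test_surface_area", "ct_number", "debris_fraction",
)


def aggregate_sample(
    specimens: list[SpecimenMorphometry], weight: float
) -> tuple[SampleMorphometry, DerivedTraits]:
    """Aggregate specimens to site level and derive traits from the means.

    Per-field mean and relative SD (population SD / mean × 100) over the
    specimens that carry the field; derived traits use the aggregated means,
    matching the convention that traits come from averaged measurements.
    """
    if not specimens:
        raise ValueError("at least one specimen required")
    means: dict[str, float] = {}
    rsd: dict[str, float] = {}
    for name in _AGG_FIELDS:
        vals = np.array([getattr(s, name) for s in specimens if getattr(s, name) is not None], float)
        if vals.size == 0:
            continue
        mu = float(vals.mean())
        means[name] = mu
        rsd[name] = float(100.0 * vals.std() / mu) if mu != 0 else 0.0

    sample = SampleMorphometry(
        site_id=0, mean_weight=weight, n_specimens=len(specimens),
        means=means, relative_sd=rsd,
    )
    traits = DerivedTraits()
    if "silhouette_area" in means:
        traits.ecd = equivalent_circular_diameter(means["silhouette_area"])
        traits.rho_a = area_density(weight, means["silhouette_area"])
    if "potential_volume" in means:
        traits.bsd = bulk_shell_density(weight, means["potential_volume"])
        if "test_volume" in means:
            traits.test_percent = test_volume_percent(
                means["test_volume"], means["potential_volume"]
            )
        if "outer_surface_area" in means:
            traits.sa_to_v = surface_to_volume_ratio(
                means["outer_surface_area"], means["potential_volume"]
            )
    if "test_volume" in means and "total_test_surface_area" in means:
        traits.mean_thickness = mean_thickness(
            means["test_volume"], means["total_test_surface_area"]
        )
    return sample, traits


def derive_site_traits(morpho: pd.DataFrame, weights: pd.Series) -> pd.DataFrame:
    """Derived-trait table for a transect.

    ``morpho`` is a canonical-unit morphometry table (μm²/μm³ columns) indexed
    by site; ``weights`` the mean shell weights (μg) on the same index. Traits
    whose inputs are missing for a site are left absent (NaN), never
    approximated — notably ``mean_thickness_um``, which needs the total
    segmented surface area.
    """
    out = pd.DataFrame(index=morpho.index)
    out["shell_weight_ug"] = weights
    sil = morpho.get("silhouette_area_um2")
    pot = morpho.get("potential_volume_um3")
    test = morpho.get("test_volume_um3")
    osa = morpho.get("outer_surface_area_um2")
    tsa = morpho.get("total_surface_area_um2")
    if sil is not None:
        out["ecd_um"] = 2.0 * np.sqrt(sil / np.pi)
        out["rho_a_ug_um2"] = weights / sil
    if pot is not None:
        out["bsd_g_cm3"] = weights * 1e6 / pot
        if test is not None:
            out["test_percent"] = 100.0 * test / pot
        if osa is not None:
            out["sa_to_v_um1"] = osa / pot
    if test is not None and tsa is not None:
        out["mean_thickness_um"] = test / tsa
    return out
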