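import math

import numpy as np
import pytest

from paleoshell.morphometry import (
    SpecimenMorphometry,
    aggregate_sample,
    area_density,
    bulk_shell_density,
    derive_site_traits,
    equivalent_circular_diameter,
    mean_thickness,
    organic_tissue_density,
    surface_to_volume_ratio,
)
from paleoshell.morphometry import test_volume_percent as volume_percent


class TestScalarTraits:
    def test_ecd_of_unit_circle_area(self):
        assert equivalent_circular_diameter(math.pi) == pytest.approx(2.0, abs=1e-12)

    def test_ecd_of_printed_silhouette(self):
        # 0.126 mm² = 1.26e5 μm² → 400.5 μm
        assert equivalent_circular_diameter(0.126e6) == pytest.approx(400.5, abs=0.05)

    def test_ecd_monotone_in_area(self):
        areas = np.linspace(1e4, 2e5, 50)
        ecds = [equivalent_circular_diameter(a) for a in areas]
        assert np.all(np.diff(ecds) > 0)

    def test_area_density_printed_inputs(self):
        # site 1: 31.2 μg over 0.126 mm²
        assert area_density(31.2, 0.126e6) == pytest.approx(2.476e-4, rel=1e-3)

    def test_area_density_scale_invariance_and_errors(self):
        assert area_density(62.4, 0.252e6) == area_density(31.2, 0.126e6)
        with pytest.raises(ValueError):
            area_density(0.0, 0.126e6)

    def test_bulk_shell_density_printed_inputs(self):
        assert bulk_shell_density(31.2, 20.807e6) == pytest.approx(1.500, abs=1e-3)
        assert bulk_shell_density(22.1, 19.264e6) == pytest.approx(1.147, abs=5e-4)
        # weight numerically equal to volume in nl → density 1
        assert bulk_shell_density(20.0, 20.0e6) == pytest.approx(1.0, abs=1e-12)

    def test_test_volume_percent_printed_inputs(self):
        assert volume_percent(6.653e6, 20.480e6) == pytest.approx(32.5, abs=0.05)
        assert volume_percent(11.231e6, 22.374e6) == pytest.approx(50.2, abs=0.05)
        with pytest.raises(ValueError):
            volume_percent(20.0e6, 20.0e6)

    def test_sa_to_v_printed_inputs_and_sphere(self):
        assert surface_to_volume_ratio(0.436e6, 20.807e6) == pytest.approx(0.0210, abs=5e-5)
        # sphere radius R has SA:V = 3/R
        R = 50.0
        assert surface_to_volume_ratio(
            4 * math.pi * R**2, 4 / 3 * math.pi * R**3
        ) == pytest.approx(3.0 / R, abs=1e-12)

    def test_sa_to_v_decreases_with_size_in_a_shape_family(self):
        ratios = [
            surface_to_volume_ratio(4 * math.pi * r**2, 4 / 3 * math.pi * r**3)
            for r in (20.0, 40.0, 80.0)
        ]
        assert np.all(np.diff(ratios) < 0)

    def test_mean_thickness_thin_shell_limit(self):
        # hollow sphere, both faces counted: V/SA → wall/2 as wall/R → 0
        R, wall = 500.0, 2.0
        r = R - wall
        v = 4 / 3 * math.pi * (R**3 - r**3)
        sa = 4 * math.pi * (R**2 + r**2)
        assert mean_thickness(v, sa) == pytest.approx(wall / 2, rel=0.01)
        assert mean_thickness(5.0, 5.0) == 1.0

    def test_organic_tissue_density(self):
        assert organic_tissue_density(1.4) == pytest.approx(0.375, abs=1e-12)
        assert organic_tissue_density(1.5, 1.025) == pytest.approx(0.475, abs=1e-12)
        with pytest.raises(ValueError):
            organic_tissue_density(1.025)

    def test_geometric_consistency_enforced(self):
        with pytest.raises(ValueError, match="smaller than potential"):
            SpecimenMorphometry(test_volume=21e6, potential_volume=20e6)


class TestScaleConsistency:
    def test_doubling_linear_dimensions(self):
        # volumes ×8, areas ×4, SA:V ×0.5
        sa, v = 0.49e6, 20.5e6
        assert surface_to_volume_ratio(4 * sa, 8 * v) == pytest.approx(
            0.5 * surface_to_volume_ratio(sa, v), rel=1e-12
        )
        assert equivalent_circular_diameter(4 * 0.13e6) == pytest.approx(
            2 * equivalent_circular_diameter(0.13e6), rel=1e-12
        )


class TestAggregation:
    def test_single_specimen_zero_spread(self):
        spec = SpecimenMorphometry(silhouette_area=1.3e5, potential_volume=2.0e7, test_volume=8e6)
        sample, traits = aggregate_sample([spec], weight=30.0)
        assert sample.n_specimens == 1
        assert sample.relative_sd["silhouette_area"] == 0.0
        assert traits.bsd == pytest.approx(30.0 * 1e6 / 2.0e7)

    def test_programmed_population_recovered(self):
        rng = np.random.default_rng(5)
        n, mu, rsd = 400, 2.05e7, 0.12
        sigma2 = math.log(1 + rsd**2)
        vols = rng.lognormal(math.log(mu) - sigma2 / 2, math.sqrt(sigma2), n)
        specs = [SpecimenMorphometry(potential_volume=float(v)) for v in vols]
        sample, _ = aggregate_sample(specs, weight=28.0)
        se_mean = rsd * mu / math.sqrt(n)
        assert sample.means["potential_volume"] == pytest.approx(mu, abs=3 * se_mean)
        assert sample.relative_sd["potential_volume"] == pytest.approx(100 * rsd, rel=0.15)

    def test_site_means_reproduce_reference_row(self, ref):
        # feeding a site's printed means back through aggregation is an identity
        row = ref["morphometry"].loc[1]
        spec = SpecimenMorphometry(
            silhouette_area=row["silhouette_area_um2"],
            potential_volume=row["potential_volume_um3"],
            test_volume=row["test_volume_um3"],
            outer_surface_area=row["outer_surface_area_um2"],
        )
        _, traits = aggregate_sample([spec], weight=31.2)
        assert traits.bsd == pytest.approx(1.500, abs=1e-3)
        assert traits.test_percent == pytest.approx(100 * 9.705 / 20.807, abs=1e-9)


class TestSiteTraitTable:
    def test_thickness_absent_without_total_surface(self, ref):
        traits = derive_site_traits(ref["morphometry"], ref["geochemistry"]["shell_weight_ug"])
        assert "mean_thickness_um" not in traits.columns

    def test_transect_means(self, ref):
        traits = derive_site_traits(ref["morphometry"], ref["geochemistry"]["shell_weight_ug"])
        assert traits["bsd_g_cm3"].mean() == pytest.approx(1.40, abs=0.01)
        assert traits["sa_to_v_um1"].mean() == pytest.approx(0.024, abs=0.0005)
        assert traits["test_percent"].mean() == pytest.approx(40.0, abs=1.5)
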