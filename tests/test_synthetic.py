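import numpy as np
import pytest

from paleoshell.hydrography import find_salinity_max, warm_season_profile
from paleoshell.morphometry import aggregate_sample
from paleoshell.stats import ols_fit
from paleoshell.synthetic import (
    ARGO_GRID,
    ProfileScenario,
    TraitScenario,
    generate_phantom,
    generate_profile_year,
    generate_shell_sample,
    generate_transect,
    make_transect_scenario,
)


class TestProfileGenerator:
    def test_standard_grid_spacing(self):
        p = generate_profile_year(ProfileScenario())[1]
        assert p.depths[0] == 2.5
        assert p.depths[-1] == 300.0
        shallow = p.depths[(p.depths >= 10) & (p.depths <= 200)]
        assert np.all(np.diff(shallow) == 10.0)
        deep = p.depths[p.depths >= 200]
        assert np.all(np.diff(deep) == 20.0)

    def test_zero_seasonal_amplitude_gives_identical_months(self):
        year = generate_profile_year(ProfileScenario(seasonal_amplitude=0.0))
        for m in range(2, 13):
            np.testing.assert_allclose(year[m].temperature, year[1].temperature, rtol=1e-12)

    def test_surface_temperature_tracks_monthly_sst(self):
        sc = ProfileScenario(sst=26.0, seasonal_amplitude=2.0, peak_month=9)
        year = generate_profile_year(sc)
        assert year[9].temperature[0] == pytest.approx(28.0, abs=1e-9)
        assert year[3].temperature[0] == pytest.approx(24.0, abs=1e-9)

    def test_programmed_salinity_maximum_recovered(self):
        sc = ProfileScenario(s_max_depth=80.0, s_max_amplitude=0.8, s_max_width=30.0)
        horizon = find_salinity_max(generate_profile_year(sc)[6])
        node_spacing = 10.0
        assert abs(horizon.depth - 80.0) <= node_spacing
        assert horizon.is_subsurface

    def test_bit_reproducible_under_seed(self):
        a = generate_profile_year(ProfileScenario(noise_sd=0.1, seed=42))
        b = generate_profile_year(ProfileScenario(noise_sd=0.1, seed=42))
        c = generate_profile_year(ProfileScenario(noise_sd=0.1, seed=43))
        np.testing.assert_array_equal(a[5].temperature, b[5].temperature)
        assert not np.array_equal(a[5].temperature, c[5].temperature)


class TestShellSampleGenerator:
    def test_zero_noise_weight_linear_in_salinity(self):
        w = []
        for sal in (35.0, 36.0, 37.0):
            _, weight = generate_shell_sample(
                TraitScenario(salinity=sal, weight_noise_sd=0.0, seed=1)
            )
            w.append(weight)
        assert w[1] - w[0] == pytest.approx(2.2, abs=1e-9)
        assert w[2] - w[1] == pytest.approx(2.2, abs=1e-9)

    def test_programmed_relative_sds_recovered(self):
        sc = TraitScenario(n_specimens=50, seed=7)
        specimens, _ = generate_shell_sample(sc)
        sample, _ = aggregate_sample(specimens, weight=28.0)
        for fieldname, rsd in (("silhouette_area", 0.11), ("potential_volume", 0.12)):
            # relative SD of a relative SD estimate ~ rsd/sqrt(2n); allow 2×SE
            se = 100 * rsd / np.sqrt(2 * sc.n_specimens) * 2
            assert sample.relative_sd[fieldname] == pytest.approx(100 * rsd, abs=2 * se)

    def test_geometric_consistency(self):
        specimens, _ = generate_shell_sample(TraitScenario(n_specimens=200, seed=3))
        assert all(s.test_volume < s.potential_volume for s in specimens)
        assert all(s.biovolume + s.test_volume <= s.potential_volume for s in specimens)

    def test_salinity_weight_slope_recovered_across_transect(self):
        rng = np.random.default_rng(17)
        sals = np.linspace(35.5, 37.3, 16)
        weights = [
            generate_shell_sample(
                TraitScenario(salinity=float(s), seed=int(rng.integers(2**31)))
            )[1]
            for s in sals
        ]
        fit = ols_fit(sals, weights)
        assert fit.slope > 0
        assert fit.r_squared > 0.6


class TestPhantomGenerator:
    def test_analytic_truth_values(self):
        _, truth = generate_phantom(50.0, 10.0, voxel_size=1.2)
        assert truth.shell_volume == pytest.approx(4 / 3 * np.pi * (50**3 - 40**3))
        assert truth.shell_volume == pytest.approx(255516.0, rel=1e-4)
        assert truth.total_surface == pytest.approx(4 * np.pi * (50**2 + 40**2))

    def test_no_debris_label_when_fraction_zero(self, hollow_sphere):
        vol, _ = hollow_sphere
        assert not np.any(vol.voxels == 3)

    def test_too_coarse_voxels_rejected(self):
        with pytest.raises(ValueError, match="5 voxels"):
            generate_phantom(50.0, 4.0, voxel_size=1.2)

    def test_closed_meshes_have_spherical_topology(self):
        import trimesh
        from skimage import measure
        from scipy import ndimage

        vol, _ = generate_phantom(40.0, 8.0, voxel_size=1.0, with_standard=False)
        mask = np.pad(vol.voxels == 1, 2).astype(float)
        sm = ndimage.gaussian_filter(mask, 1.0)
        verts, faces, _, _ = measure.marching_cubes(sm, 0.5)
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        parts = mesh.split(only_watertight=True)
        # aperture-free hollow sphere: two closed sphere-like surfaces
        assert len(parts) == 2
        assert all(p.euler_number == 2 for p in parts)


class TestPresets:
    def test_gyre_presets_have_surface_salinity_maximum(self):
        for preset in ("gyre-N", "gyre-S"):
            prof_sc, _ = make_transect_scenario(preset)
            horizon = find_salinity_max(generate_profile_year(prof_sc)[1])
            assert not horizon.is_subsurface

    def test_tropics_preset_has_subsurface_maximum(self):
        prof_sc, _ = make_transect_scenario("tropics")
        horizon = find_salinity_max(generate_profile_year(prof_sc)[1])
        assert horizon.is_subsurface

    def test_equator_preset_shallow_mixed_layer_fresh_surface(self):
        eq, _ = make_transect_scenario("equator")
        gy, _ = make_transect_scenario("gyre-N")
        assert eq.mixed_layer_depth < gy.mixed_layer_depth
        assert eq.surface_salinity < gy.surface_salinity

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            make_transect_scenario("abyss")

    def test_hemisphere_peak_months(self):
        n, _ = make_transect_scenario("gyre-N")
        s, _ = make_transect_scenario("gyre-S")
        warm_n = warm_season_profile(generate_profile_year(n), 30.0)
        warm_s = warm_season_profile(generate_profile_year(s), -25.0)
        assert sorted(warm_n.months_used) == [8, 9, 10]
        assert sorted(warm_s.months_used) == [2, 3, 4]


class TestTransect:
    def test_deterministic_under_seed(self):
        a = generate_transect(seed=5, n_sites=6)
        b = generate_transect(seed=5, n_sites=6)
        assert a["geochemistry"].equals(b["geochemistry"])
        assert a["morphometry"].equals(b["morphometry"])

    def test_tables_conform_to_schemas(self):
        bundle = generate_transect(seed=2, n_sites=5)
        assert list(bundle["sites"].index) == [1, 2, 3, 4, 5]
        assert "mgca_mmol_mol" in bundle["geochemistry"].columns
        assert "potential_volume_um3" in bundle["morphometry"].columns
        assert set(bundle["profiles"][1]) == set(range(1, 13))
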