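import numpy as np
import pytest

from paleoshell.synthetic import generate_phantom
from paleoshell.tomogram import (
    Label,
    LabelVolume,
    component_volumes,
    debris_percent,
    mesh_surface_area,
    normalize_ct_number,
    potential_volume_closing,
    voxel_face_area,
)


def block_volume(n=10, voxel_size=1.0):
    grid = np.zeros((n + 4, n + 4, n + 4), dtype=np.uint8)
    grid[2 : 2 + n, 2 : 2 + n, 2 : 2 + n] = int(Label.TEST)
    return LabelVolume(voxels=grid, voxel_size=voxel_size)


class TestComponentVolumes:
    def test_block_counts_exactly(self):
        vols = component_volumes(block_volume(10, 1.0))
        assert vols[Label.TEST] == pytest.approx(1000.0)

    def test_hollow_sphere_within_2_percent(self, hollow_sphere):
        vol, truth = hollow_sphere
        got = component_volumes(vol)[Label.TEST]
        assert got == pytest.approx(truth.shell_volume, rel=0.02)

    def test_all_background_rejected(self):
        grid = np.zeros((8, 8, 8), dtype=np.uint8)
        with pytest.raises(ValueError, match="empty test label"):
            component_volumes(LabelVolume(voxels=grid))


class TestMeshSurfaceArea:
    def test_solid_sphere_outer_surface(self):
        # wall ≈ radius − few voxels: lumen tiny; compare outer sphere surface
        vol, truth = generate_phantom(40.0, 32.0, voxel_size=1.0, with_standard=False)
        # fill lumen to make the object solid
        vol.voxels[vol.voxels == int(Label.LUMEN)] = int(Label.TEST)
        assert mesh_surface_area(vol) == pytest.approx(truth.outer_surface, rel=0.03)

    def test_hollow_sphere_total_surface(self, hollow_sphere):
        vol, truth = hollow_sphere
        assert mesh_surface_area(vol) == pytest.approx(truth.total_surface, rel=0.03)

    def test_voxel_face_counting_biased_high(self, hollow_sphere):
        vol, truth = hollow_sphere
        ratio = voxel_face_area(vol) / truth.total_surface
        assert 1.4 < ratio < 1.6

    def test_absent_label_rejected(self, hollow_sphere):
        vol, _ = hollow_sphere
        with pytest.raises(ValueError, match="DEBRIS absent"):
            mesh_surface_area(vol, Label.DEBRIS)

    def test_convergence_with_resolution(self):
        errs = []
        for vs in (2.0, 1.0):
            vol, truth = generate_phantom(50.0, 10.0, voxel_size=vs, with_standard=False)
            v = component_volumes(vol)[Label.TEST]
            sa = mesh_surface_area(vol)
            errs.append(
                (abs(v - truth.shell_volume) / truth.shell_volume,
                 abs(sa - truth.total_surface) / truth.total_surface)
            )
        assert errs[0][0] < 0.02 and errs[1][0] < 0.02
        assert errs[0][1] < 0.03 and errs[1][1] < 0.03
        assert errs[1][0] <= errs[0][0]  # volume error shrinks with finer voxels

    def test_thin_shell_thickness_near_half_wall(self):
        vol, truth = generate_phantom(50.0, 6.0, voxel_size=1.0, with_standard=False)
        v = component_volumes(vol)[Label.TEST]
        t = v / mesh_surface_area(vol)
        assert t == pytest.approx(truth.wall / 2.0, rel=0.05)


class TestPotentialVolume:
    def test_sealed_aperture_recovers_full_sphere(self):
        vol, truth = generate_phantom(50.0, 10.0, aperture_radius=10.0, voxel_size=1.2)
        res = potential_volume_closing(vol, closing_radius=15.0)
        assert res.sealed
        assert res.volume == pytest.approx(truth.full_volume, rel=0.02)

    def test_radius_too_small_flags_not_sealed(self):
        vol, truth = generate_phantom(50.0, 10.0, aperture_radius=20.0, voxel_size=1.2)
        res = potential_volume_closing(vol, closing_radius=8.0)
        test_vol = component_volumes(vol)[Label.TEST]
        assert not res.sealed
        assert test_vol <= res.volume < truth.full_volume

    def test_solid_block_is_its_own_volume(self):
        res = potential_volume_closing(block_volume(20, 1.0), closing_radius=3.0)
        assert res.volume == pytest.approx(8000.0, rel=0.05)
        assert not res.sealed  # nothing to seal

    def test_radius_below_voxel_rejected(self, hollow_sphere):
        vol, _ = hollow_sphere
        with pytest.raises(ValueError, match="at least one voxel"):
            potential_volume_closing(vol, closing_radius=0.5)


class TestCTNumber:
    def _volume(self, test_grey):
        grid = np.zeros((12, 12, 12), dtype=np.uint8)
        grid[2:6, 2:6, 2:6] = int(Label.TEST)
        grid[8:11, 8:11, 8:11] = int(Label.STANDARD)
        raw = np.full(grid.shape, 100.0)
        raw[grid == int(Label.TEST)] = test_grey
        raw[grid == int(Label.STANDARD)] = 900.0
        return LabelVolume(voxels=grid, voxel_size=1.0, raw_intensity=raw)

    def test_test_equal_to_standard_maps_to_reference(self):
        assert normalize_ct_number(self._volume(900.0)).mean_ct == pytest.approx(1000.0)

    def test_midpoint_maps_to_half_reference(self):
        assert normalize_ct_number(self._volume(500.0)).mean_ct == pytest.approx(500.0)

    def test_invariant_under_affine_rescaling(self):
        vol = self._volume(650.0)
        base = normalize_ct_number(vol).mean_ct
        vol2 = LabelVolume(
            voxels=vol.voxels, voxel_size=1.0, raw_intensity=3.7 * vol.raw_intensity + 250.0
        )
        assert normalize_ct_number(vol2).mean_ct == pytest.approx(base, abs=1e-9)

    def test_missing_standard_rejected(self):
        grid = np.zeros((8, 8, 8), dtype=np.uint8)
        grid[2:5, 2:5, 2:5] = int(Label.TEST)
        vol = LabelVolume(voxels=grid, voxel_size=1.0, raw_intensity=np.ones(grid.shape))
        with pytest.raises(ValueError, match="no calcite standard"):
            normalize_ct_number(vol)


class TestDebris:
    def test_no_debris_is_zero(self, hollow_sphere):
        vol, _ = hollow_sphere
        assert debris_percent(vol) == 0.0

    def test_programmed_debris_fraction_recovered(self):
        vol, _ = generate_phantom(50.0, 10.0, voxel_size=1.2, debris_fraction=12.0)
        assert debris_percent(vol) == pytest.approx(12.0, abs=0.5)

    def test_debris_equal_to_test_is_100(self):
        grid = np.zeros((10, 10, 10), dtype=np.uint8)
        grid[2:5, 2:5, 2:5] = int(Label.TEST)
        grid[6:9, 6:9, 6:9] = int(Label.DEBRIS)
        assert debris_percent(LabelVolume(voxels=grid)) == pytest.approx(100.0)
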