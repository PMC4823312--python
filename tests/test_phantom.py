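"""Phantom construction: layers, defects, liquid film, sensors, geometry."""

import numpy as np
import pytest

from megfem import (
    DefectSpec, LayerRadii, PhantomConfig,
    SensorArrayConfig, ShiftLine, Tissue, TissueTable, add_liquid_layer,
    build_phantom, carve_defects, compute_shift_eccentricity,
    draw_base_lengths, make_sensor_array,
)
from megfem.phantom import BONE_LABELS

from conftest import make_homogeneous_sphere


@pytest.fixture(scope="module")
def sphere_grid():
    return build_phantom(PhantomConfig(shape="sphere", voxel_size=0.4))


class TestTissueTable:
    def test_default_conductivities(self):
        table = TissueTable()
        expected = {
            Tissue.SCALP: 0.33, Tissue.COMPACT_BONE: 0.004,
            Tissue.CANCELLOUS_BONE: 0.046, Tissue.GRAY_MATTER: 0.23,
            Tissue.WHITE_MATTER: 0.31, Tissue.CSF: 1.79,
            Tissue.BLOOD_VESSEL: 0.78, Tissue.OCULAR_HUMOR: 1.7,
            Tissue.OCULAR_LENS: 0.35, Tissue.AGAR_DEFECT: 1.0,
            Tissue.LIQUID_LAYER: 0.6,
        }
        for label, sigma in expected.items():
            assert table[label] == sigma

    def test_nonpositive_conductivity_rejected(self):
        with pytest.raises(ValueError):
            TissueTable({Tissue.SCALP: 0.0})

    def test_missing_label_raises_with_name(self):
        table = TissueTable({Tissue.SCALP: 0.33})
        with pytest.raises(KeyError, match="GRAY_MATTER"):
            table[Tissue.GRAY_MATTER]

    def test_perturbed_scales_one_tissue(self):
        table = TissueTable().perturbed(Tissue.GRAY_MATTER, 0.2)
        assert table[Tissue.GRAY_MATTER] == pytest.approx(0.276)
        assert table[Tissue.SCALP] == 0.33


class TestBuildPhantom:
    def test_requested_voxel_size_is_exact(self, sphere_grid):
        assert sphere_grid.voxel_size == 0.4

    def test_ray_crosses_layers_in_order(self, sphere_grid):
        # from the center outward along +z: white, gray, compact,
        # cancellous, compact, scalp, liquid
        n = sphere_grid.dims[2]
        iz0 = n // 2
        ix = iy = sphere_grid.dims[0] // 2
        ray = sphere_grid.labels[ix, iy, iz0:]
        seen = [int(l) for l, _ in __import__("itertools").groupby(ray)]
        expected = [Tissue.WHITE_MATTER, Tissue.GRAY_MATTER,
                    Tissue.COMPACT_BONE, Tissue.CANCELLOUS_BONE,
                    Tissue.COMPACT_BONE, Tissue.SCALP, Tissue.LIQUID_LAYER,
                    Tissue.BACKGROUND]
        assert seen == [int(l) for l in expected]

    def test_deterministic(self):
        cfg = PhantomConfig(shape="sphere", voxel_size=0.8)
        a = build_phantom(cfg)
        b = build_phantom(cfg)
        assert np.array_equal(a.labels, b.labels)

    def test_non_nested_radii_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            LayerRadii(scalp=10.0, skull_outer=11.0)

    def test_cancellous_enclosed_by_compact(self, sphere_grid):
        # every face neighbor of a cancellous voxel is bone
        from scipy import ndimage
        canc = sphere_grid.labels == int(Tissue.CANCELLOUS_BONE)
        bone = np.isin(sphere_grid.labels, [int(l) for l in BONE_LABELS])
        structure = ndimage.generate_binary_structure(3, 1)
        dilated = ndimage.binary_dilation(canc, structure=structure)
        assert np.all(bone[dilated & ~canc] | ~(dilated & ~canc)[dilated & ~canc])
        assert np.all(bone[dilated])

    def test_shells_concentric(self, sphere_grid):
        # label shells of the sphere phantom are concentric to within a voxel
        centers = sphere_grid.voxel_centers()
        r = np.linalg.norm(centers, axis=-1)
        radii = PhantomConfig().radii
        for label, lo, hi in [
            (Tissue.SCALP, radii.skull_outer, radii.scalp),
            (Tissue.GRAY_MATTER, radii.white, radii.skull_inner),
        ]:
            sel = sphere_grid.labels == int(label)
            tol = sphere_grid.voxel_size
            assert r[sel].min() > lo - tol
            assert r[sel].max() < hi + tol


class TestCarveDefects:
    def test_carving_relabels_only_bone(self, sphere_grid):
        defect = DefectSpec(center=(0.0, 0.0, 14.0), radius=2.0)
        carved = carve_defects(sphere_grid, [defect])
        changed = carved.labels != sphere_grid.labels
        assert changed.sum() > 0
        assert np.all(np.isin(sphere_grid.labels[changed],
                              [int(l) for l in BONE_LABELS]))
        assert np.all(carved.labels[changed] == int(Tissue.AGAR_DEFECT))

    def test_two_defects_reduce_bone_count(self, sphere_grid):
        defects = [DefectSpec(center=(0.0, 0.0, 14.0), radius=2.0),
                   DefectSpec(center=(-6.0, 0.0, 12.6),
                              axis=(-6.0, 0.0, 12.6), radius=2.0)]
        carved = carve_defects(sphere_grid, defects)
        bone = [int(l) for l in BONE_LABELS]
        assert carved.label_counts()[int(Tissue.AGAR_DEFECT)] > 0
        assert sum(carved.label_counts().get(l, 0) for l in bone) < \
            sum(sphere_grid.label_counts()[l] for l in bone)

    def test_empty_defect_list_is_identity(self, sphere_grid):
        out = carve_defects(sphere_grid, [])
        assert np.array_equal(out.labels, sphere_grid.labels)

    def test_defect_missing_skull_raises(self, sphere_grid):
        lonely = DefectSpec(center=(0.0, 0.0, 40.0), radius=0.5,
                            axis=(1.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="does not intersect"):
            carve_defects(sphere_grid, [lonely])

    def test_oversized_defect_warns(self, sphere_grid):
        huge = DefectSpec(center=(0.0, 0.0, 14.0), radius=12.0)
        with pytest.warns(UserWarning, match="bone voxels"):
            carve_defects(sphere_grid, [huge])


class TestLiquidLayer:
    def test_shell_is_one_voxel_thick(self):
        grid = make_homogeneous_sphere(radius=5.0, voxel=0.5,
                                       label=Tissue.COMPACT_BONE)
        out = add_liquid_layer(grid)
        from scipy import ndimage
        head = grid.labels != int(Tissue.BACKGROUND)
        structure = ndimage.generate_binary_structure(3, 1)
        expected = ndimage.binary_dilation(head, structure=structure) & ~head
        assert np.array_equal(out.labels == int(Tissue.LIQUID_LAYER),
                              expected)

    def test_idempotent(self):
        grid = make_homogeneous_sphere(radius=4.0, voxel=0.5,
                                       label=Tissue.COMPACT_BONE)
        once = add_liquid_layer(grid)
        twice = add_liquid_layer(once)
        assert np.array_equal(once.labels, twice.labels)

    def test_no_background_no_change(self):
        grid = make_homogeneous_sphere(radius=3.0, voxel=0.5,
                                       label=Tissue.COMPACT_BONE)
        grid.labels[grid.labels == int(Tissue.BACKGROUND)] = \
            int(Tissue.SCALP)
        out = add_liquid_layer(grid)
        assert np.array_equal(out.labels, grid.labels)


class TestSensorArray:
    def test_default_array(self):
        arr = make_sensor_array(SensorArrayConfig())
        assert arr.n_channels == 16
        assert np.all(arr.base_lengths == 30.0)
        assert np.allclose(np.linalg.norm(arr.axes, axis=1), 1.0)
        # bottom coils coplanar
        assert np.ptp(arr.positions[:, 2]) == 0.0

    def test_top_coils_at_base_length(self):
        arr = make_sensor_array(SensorArrayConfig())
        assert np.allclose(
            np.linalg.norm(arr.top_positions - arr.positions, axis=1), 30.0)

    def test_nonstandard_channel_count_rejected(self):
        with pytest.raises(ValueError, match="16 channels"):
            SensorArrayConfig(n_channels=9, grid_shape=(3, 3))

    def test_base_length_draw_reproducible(self):
        cfg = SensorArrayConfig()
        a = draw_base_lengths(cfg, seed=7)
        b = draw_base_lengths(cfg, seed=7)
        assert np.array_equal(a, b)
        assert np.all((a >= 28.5) & (a <= 31.5))
        arr = make_sensor_array(cfg).with_base_lengths(a)
        assert np.allclose(arr.base_lengths, a)


class TestShiftEccentricity:
    defect = DefectSpec(center=(2.0, 0.0, 10.0), radius=2.5)
    line = ShiftLine(origin=(-5.0, 0.0, 7.0), direction=(1.0, 0.0, 0.0),
                     n_positions=20)

    def test_zero_at_defect_center_projection(self):
        assert compute_shift_eccentricity(
            (2.0, 0.0, 7.0), self.defect, self.line) == pytest.approx(0.0)

    def test_unity_at_edge_projections(self):
        assert compute_shift_eccentricity(
            (4.5, 0.0, 7.0), self.defect, self.line) == pytest.approx(1.0)
        assert compute_shift_eccentricity(
            (-0.5, 0.0, 7.0), self.defect, self.line) == pytest.approx(-1.0)

    def test_affine_along_line(self):
        # eccentricity is affine in the arc position: equal increments
        xs = np.linspace(-5.0, 5.0, 10)
        eccs = [compute_shift_eccentricity((x, 0.0, 7.0), self.defect,
                                           self.line) for x in xs]
        diffs = np.diff(eccs)
        assert np.allclose(diffs, diffs[0])
        assert compute_shift_eccentricity(
            (3.25, 0.0, 7.0), self.defect, self.line) == pytest.approx(0.5)

    def test_degenerate_defect_raises(self):
        axial = DefectSpec(center=(2.0, 0.0, 10.0), radius=2.5,
                           axis=(1.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="extent"):
            compute_shift_eccentricity((2.0, 0.0, 7.0), axial, self.line)


class TestShiftLine:
    def test_half_step_spacing(self):
        line = ShiftLine(origin=(0, 0, 0), direction=(1, 0, 0),
                         n_positions=9)
        pos = line.positions()
        gaps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        assert np.allclose(gaps, line.half_step, atol=1e-9)
        assert line.full_step == pytest.approx(0.691)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            ShiftLine(origin=(0, 0, 0), direction=(1.0, 1.0, 0.0),
                      n_positions=3)
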