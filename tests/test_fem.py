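"""FEM forward solution: assembly, Venant loads, solves, fields, transfer."""

import numpy as np
import pytest

from megfem import (
    Dipole, LabeledVoxelGrid, SensorArrayConfig, Tissue, TissueTable,
    apply_node_shift, assemble_stiffness, make_sensor_array, primary_signal,
    secondary_signal_direct, venant_load, voxels_to_hexmesh,
)
from megfem.analytic import sphere_potential
from megfem.fem import forward_map, meg_transfer
from megfem.hexmesh import element_volumes

from conftest import make_homogeneous_sphere


def column_mesh(n=2, voxel=0.5, labels=(Tissue.GRAY_MATTER,
                                        Tissue.COMPACT_BONE)):
    arr = np.zeros((1, 1, n), dtype=np.int16)
    for k in range(n):
        arr[0, 0, k] = int(labels[k % len(labels)])
    grid = LabeledVoxelGrid((1, 1, n), voxel, np.zeros(3), arr)
    return grid, voxels_to_hexmesh(grid, TissueTable())


def reference_element_stiffness(h_m: float, sigma: float,
                                corners: np.ndarray) -> np.ndarray:
    """Independent dense-quadrature stiffness of an axis-aligned cube.

    Uses an explicitly written trilinear basis on [-1, 1]^3 and an order-4
    Gauss--Legendre product rule, sharing no code with the implementation.
    """
    signs = 2 * corners - 1                                  # (8, 3) of +-1
    x, w = np.polynomial.legendre.leggauss(4)
    K = np.zeros((8, 8))
    jac = (h_m / 2.0) ** 3
    for ix, wx in zip(x, w):
        for iy, wy in zip(x, w):
            for iz, wz in zip(x, w):
                xi = np.array([ix, iy, iz])
                grad = np.zeros((8, 3))
                for a in range(8):
                    s = signs[a]
                    grad[a] = [
                        s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2]),
                        (1 + s[0] * xi[0]) * s[1] * (1 + s[2] * xi[2]),
                        (1 + s[0] * xi[0]) * (1 + s[1] * xi[1]) * s[2],
                    ]
                grad /= 8.0
                grad *= 2.0 / h_m                            # d xi / dx
                K += wx * wy * wz * jac * sigma * grad @ grad.T
    return K


class TestAssembly:
    def test_row_sums_vanish(self):
        grid = make_homogeneous_sphere(radius=3.0, voxel=0.75)
        mesh = apply_node_shift(voxels_to_hexmesh(grid, TissueTable()),
                                0.49, grid)
        K = assemble_stiffness(mesh).matrix
        rowsum = np.abs(np.asarray(K.sum(axis=1))).max()
        assert rowsum <= 1e-10 * np.abs(K.diagonal()).max()

    def test_symmetry(self):
        grid = make_homogeneous_sphere(radius=3.0, voxel=0.75)
        mesh = voxels_to_hexmesh(grid, TissueTable())
        K = assemble_stiffness(mesh).matrix
        asym = np.abs((K - K.T).toarray()).max()
        assert asym <= 1e-12 * np.abs(K.toarray()).max()

    def test_two_element_column_matches_reference_assembly(self):
        from megfem.hexmesh import HEX_CORNERS
        from megfem.units import MM_TO_M
        grid, mesh = column_mesh()
        K = assemble_stiffness(mesh).matrix.toarray()
        ref = np.zeros_like(K)
        for e in range(2):
            sigma = mesh.element_conductivity[e]
            Ke = reference_element_stiffness(0.5 * MM_TO_M, sigma,
                                             HEX_CORNERS)
            idx = mesh.elements[e]
            ref[np.ix_(idx, idx)] += Ke
        assert np.allclose(K, ref, atol=1e-12 * np.abs(ref).max())

    def test_degenerate_mesh_rejected(self):
        grid, mesh = column_mesh()
        mesh.nodes[0] = mesh.nodes[7] + (mesh.nodes[7] - mesh.nodes[0])
        with pytest.raises(ValueError, match="degenerate"):
            assemble_stiffness(mesh)


@pytest.fixture(scope="module")
def sphere():
    grid = make_homogeneous_sphere(radius=5.0, voxel=0.5)
    return voxels_to_hexmesh(grid, TissueTable())


class TestVenantLoad:
    def test_monopoles_sum_to_zero(self, sphere):
        load = venant_load(sphere, Dipole((0.3, -0.2, 1.0), (130, 40, -20)),
                           warn_nonbrain=False)
        assert abs(load.total()) <= 1e-12 * np.abs(load.values).max()

    def test_first_moment_matches_dipole(self, sphere):
        dip = Dipole((0.3, -0.2, 1.0), (130.0, 40.0, -20.0))
        load = venant_load(sphere, dip, warn_nonbrain=False)
        moment = load.first_moment(dip.pos, sphere.nodes)
        assert np.linalg.norm(moment - dip.mom) <= 0.01 * dip.strength

    def test_zero_moment_gives_zero_load(self, sphere):
        load = venant_load(sphere, Dipole((0.3, -0.2, 1.0), (0, 0, 0)),
                           warn_nonbrain=False)
        assert np.all(load.values == 0.0)

    def test_outside_mesh_rejected(self, sphere):
        with pytest.raises(ValueError, match="outside"):
            venant_load(sphere, Dipole((20.0, 0.0, 0.0), (130, 0, 0)))

    def test_nonbrain_position_warns(self):
        grid = make_homogeneous_sphere(radius=4.0, voxel=0.5,
                                       label=Tissue.SCALP)
        mesh = voxels_to_hexmesh(grid, TissueTable())
        with pytest.warns(UserWarning, match="not inside brain"):
            venant_load(mesh, Dipole((0.0, 0.0, 1.0), (130, 0, 0)))


@pytest.fixture(scope="module")
def system_and_mesh():
    grid = make_homogeneous_sphere(radius=6.0, voxel=0.5)
    mesh = apply_node_shift(voxels_to_hexmesh(grid, TissueTable()),
                            0.49, grid)
    return assemble_stiffness(mesh), mesh


class TestSolvePotential:
    def test_zero_load_zero_potential(self, system_and_mesh):
        system, mesh = system_and_mesh
        assert np.all(system.solve(np.zeros(system.n)) == 0.0)

    def test_linearity(self, system_and_mesh):
        system, mesh = system_and_mesh
        load = venant_load(mesh, Dipole((0, 0, 3.0), (130, 0, 0)),
                           warn_nonbrain=False).to_dense()
        u1 = system.solve(load)
        u2 = system.solve(2.0 * load)
        assert np.allclose(u2, 2.0 * u1, rtol=1e-8,
                           atol=1e-10 * np.abs(u1).max())

    def test_potential_matches_sphere_series(self, system_and_mesh):
        # closed-form (spherical-harmonic) potential of a homogeneous
        # conducting sphere, evaluated on an interior shell clear of both
        # the source singularity and the staircase boundary
        system, mesh = system_and_mesh
        dip = Dipole((0.0, 0.0, 3.0), (130.0, 0.0, 0.0))
        u = system.solve(venant_load(mesh, dip,
                                     warn_nonbrain=False).to_dense())
        r_eff = (3.0 * element_volumes(mesh).sum() / (4 * np.pi)) ** (1 / 3)
        nr = np.linalg.norm(mesh.nodes, axis=1)
        shell = (nr > 4.2) & (nr < 5.4)
        va = sphere_potential(dip, mesh.nodes[shell], r_eff, 0.23,
                              n_terms=150)
        vf = u[shell]
        err = np.linalg.norm((vf - vf.mean()) - (va - va.mean())) \
            / np.linalg.norm(va - va.mean())
        assert err <= 0.05

    def test_pcg_agrees_with_direct(self, system_and_mesh):
        system, mesh = system_and_mesh
        load = venant_load(mesh, Dipole((0, 0, 3.0), (130, 0, 0)),
                           warn_nonbrain=False).to_dense()
        from megfem.fem import StiffnessSystem
        direct = StiffnessSystem(system.matrix, method="direct")
        u_direct = direct.solve(load)
        u_pcg = system.solve(load)
        assert np.linalg.norm(u_pcg - u_direct) <= \
            1e-6 * np.linalg.norm(u_direct)


class TestPrimarySignal:
    array = make_sensor_array(SensorArrayConfig(plane_z=12.0, spacing=5.0))

    def test_linearity_in_moment(self):
        d1 = Dipole((0, 0, 5.0), (60.0, 10.0, 0.0))
        d2 = Dipole((0, 0, 5.0), (120.0, 20.0, 0.0))
        assert np.allclose(primary_signal(d2, self.array).values,
                           2.0 * primary_signal(d1, self.array).values)

    def test_moment_along_coil_axis_line_is_silent(self):
        # dipole directly below a coil with moment along the coil axis:
        # Biot-Savart cross product vanishes on that line
        pos = self.array.positions[5]
        dip = Dipole((pos[0], pos[1], 5.0), (0.0, 0.0, 130.0))
        values = primary_signal(dip, self.array).values
        assert values[5] == pytest.approx(0.0, abs=1e-12)

    def test_coil_disc_quadrature_close_to_point_coil(self):
        dip = Dipole((0, 0, 5.0), (130.0, 0, 0))
        point = primary_signal(dip, self.array).values
        finite = make_sensor_array(
            SensorArrayConfig(plane_z=12.0, spacing=5.0, coil_radius=0.8))
        disc = primary_signal(dip, finite).values
        assert np.linalg.norm(disc - point) < 0.01 * np.linalg.norm(point)

    def test_coincident_coil_rejected(self):
        pos = self.array.positions[0]
        with pytest.raises(ValueError, match="coincides"):
            primary_signal(Dipole(tuple(pos), (130, 0, 0)), self.array)


class TestTransfer:
    def test_transfer_equals_direct_secondary(self, homogeneous_sphere_model):
        model = homogeneous_sphere_model
        rng = np.random.default_rng(42)
        for _ in range(5):
            pos = rng.uniform(-2.5, 2.5, 3)
            mom = rng.uniform(-100, 100, 3)
            load = venant_load(model.mesh, Dipole(tuple(pos), tuple(mom)),
                               warn_nonbrain=False)
            via_transfer = model.transfer.secondary(load)
            direct = secondary_signal_direct(model.system, model.mesh,
                                             model.array, load)
            assert np.linalg.norm(via_transfer - direct) <= \
                1e-6 * np.linalg.norm(direct)

    def test_transfer_reuse_requires_no_solves(self, homogeneous_sphere_model):
        model = homogeneous_sphere_model
        n_before = model.transfer.n_solves
        rng = np.random.default_rng(3)
        for _ in range(10):
            dip = Dipole(tuple(rng.uniform(-2, 2, 3)),
                         tuple(rng.uniform(-50, 50, 3)))
            model.field_map(dip)
        assert model.transfer.n_solves == n_before

    def test_secondary_weaker_than_primary_for_central_dipole(
            self, homogeneous_sphere_model):
        model = homogeneous_sphere_model
        dip = Dipole((0.0, 0.0, 0.5), (130.0, 0.0, 0.0))
        load = venant_load(model.mesh, dip, warn_nonbrain=False)
        sec = model.transfer.secondary(load)
        prim = primary_signal(dip, model.array).values
        assert np.linalg.norm(sec) < np.linalg.norm(prim)


class TestForwardMap:
    def test_linearity_superposition(self, homogeneous_sphere_model):
        model = homogeneous_sphere_model
        rng = np.random.default_rng(11)
        pos = (0.5, -0.5, 2.0)
        moments = rng.uniform(-80, 80, (3, 3))
        total = model.field_map(Dipole(pos, tuple(moments.sum(axis=0))))
        parts = sum(model.field_map(Dipole(pos, tuple(m))).values
                    for m in moments)
        assert np.allclose(total.values, parts,
                           rtol=1e-9, atol=1e-9 * np.abs(parts).max())

    def test_conductivity_scaling_invariance(self):
        # scaling ALL conductivities by alpha leaves the map unchanged:
        # the potential scales by 1/alpha and sigma grad u is invariant
        grid = make_homogeneous_sphere(radius=4.0, voxel=0.5)
        table2 = TissueTable({k: 2.0 * v
                              for k, v in TissueTable().conductivity.items()})
        array = make_sensor_array(SensorArrayConfig(plane_z=8.0, spacing=4.0))
        dip = Dipole((0, 0, 2.0), (130.0, 0, 0))
        maps = []
        for table in (TissueTable(), table2):
            mesh = apply_node_shift(voxels_to_hexmesh(grid, table), 0.49,
                                    grid)
            system = assemble_stiffness(mesh)
            transfer = meg_transfer(system, mesh, array)
            maps.append(forward_map(mesh, array, dip, transfer,
                                    warn_nonbrain=False).values)
        assert np.allclose(maps[0], maps[1], rtol=1e-9)

    def test_in_brain_lookup(self, homogeneous_sphere_model):
        model = homogeneous_sphere_model
        assert model.in_brain((0.0, 0.0, 0.0))
        assert not model.in_brain((0.0, 0.0, 30.0))
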