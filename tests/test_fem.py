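"""Linear-elastic FEM: constitutive law, elements, assembly, loads, solves."""

import numpy as np
import pytest

import limbuskit as lk
from limbuskit.fem import strain_displacement_matrix

from conftest import uniaxial_dofs


def energy_oracle(coords, d_matrix, u):
    """Independent strain-energy oracle for a linear tet.

    Fits the affine deformation from the nodal displacements, forms the
    small-strain tensor, and evaluates U = V/2 εᵀDε — no B matrix involved.
    """
    m = np.hstack([np.ones((4, 1)), coords])
    grad_u = np.linalg.solve(m, u.reshape(4, 3))[1:]  # ∂u_j/∂x_i
    eps = 0.5 * (grad_u + grad_u.T)
    voigt = np.array([eps[0, 0], eps[1, 1], eps[2, 2],
                      2 * eps[0, 1], 2 * eps[1, 2], 2 * eps[0, 2]])
    vol = abs(np.linalg.det(m)) / 6.0
    return 0.5 * vol * voigt @ d_matrix @ voigt


def rigid_body_basis(nodes):
    """3 translations + 3 linearized rotations as global dof vectors."""
    n = len(nodes)
    vecs = []
    for axis in range(3):
        v = np.zeros((n, 3))
        v[:, axis] = 1.0
        vecs.append(v.ravel())
    for axis in range(3):
        omega = np.zeros(3)
        omega[axis] = 1.0
        vecs.append(np.cross(omega, nodes).ravel())
    return vecs


@pytest.fixture()
def tm_material():
    return lk.MaterialModel(young_modulus=162.0, poisson_ratio=0.48)


class TestElasticityMatrix:
    def test_nu_zero_closed_form(self):
        d = lk.elasticity_matrix(lk.MaterialModel(1.0, 0.0))
        assert np.allclose(d, np.diag([1, 1, 1, 0.5, 0.5, 0.5]))

    def test_tm_values_from_lame_constants(self, tm_material):
        lam = 162.0 * 0.48 / (1.48 * 0.04)
        mu = 162.0 / 2.96
        d = lk.elasticity_matrix(tm_material)
        expect = np.zeros((6, 6))
        expect[:3, :3] = lam
        expect[np.arange(3), np.arange(3)] = 2 * mu + lam
        expect[np.arange(3, 6), np.arange(3, 6)] = mu
        assert np.allclose(d, expect)

    @pytest.mark.parametrize("e,nu", [(1.0, 0.3), (162.0, 0.48), (5e3, -0.5)])
    def test_symmetric_positive_definite(self, e, nu):
        d = lk.elasticity_matrix(lk.MaterialModel(e, nu))
        assert np.allclose(d, d.T)
        assert np.linalg.eigvalsh(d).min() > 0

    def test_incompressible_limit_rejected(self):
        with pytest.raises(lk.IncompressibleLimitError):
            lk.MaterialModel(162.0, 0.5)

    def test_invalid_material_rejected(self):
        with pytest.raises(ValueError):
            lk.MaterialModel(-1.0, 0.3)
        with pytest.raises(ValueError):
            lk.MaterialModel(1.0, -1.5)


class TestElementStiffness:
    REF_TET = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])

    def test_rigid_translations_in_null_space(self, tm_material):
        d = lk.elasticity_matrix(tm_material)
        ke = lk.element_stiffness(self.REF_TET, d)
        for axis in range(3):
            t = np.tile(np.eye(3)[axis], 4)
            assert np.allclose(ke @ t, 0.0, atol=1e-10)

    def test_rank_six(self, tm_material):
        d = lk.elasticity_matrix(tm_material)
        ke = lk.element_stiffness(self.REF_TET, d)
        assert np.allclose(ke, ke.T)
        eigs = np.linalg.eigvalsh(ke)
        assert np.sum(np.abs(eigs) < 1e-9 * eigs.max()) == 6

    @pytest.mark.parametrize("seed", range(4))
    def test_energy_matches_deformation_gradient_oracle(self, seed, tm_material):
        rng = np.random.default_rng(seed)
        coords = self.REF_TET + 0.2 * rng.standard_normal((4, 3))
        m = np.hstack([np.ones((4, 1)), coords])
        if np.linalg.det(m) <= 0:
            coords = coords[[0, 2, 1, 3]]
        d = lk.elasticity_matrix(tm_material)
        ke = lk.element_stiffness(coords, d)
        u = rng.standard_normal(12)
        assert 0.5 * u @ ke @ u == pytest.approx(
            energy_oracle(coords, d, u), rel=1e-9)

    def test_stiffness_scales_linearly_with_size(self, tm_material):
        d = lk.elasticity_matrix(tm_material)
        k1 = lk.element_stiffness(self.REF_TET, d)
        k3 = lk.element_stiffness(3.0 * self.REF_TET, d)
        assert np.allclose(k3, 3.0 * k1)

    def test_degenerate_tet_rejected(self, tm_material):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(lk.DegenerateElementError):
            lk.element_stiffness(flat, lk.elasticity_matrix(tm_material))

    def test_b_matrix_constant_strain_exact(self):
        b, vol = strain_displacement_matrix(self.REF_TET)
        assert vol == pytest.approx(1.0 / 6.0)
        # linear field u = (x, 0, 0) -> strain (1, 0, 0, 0, 0, 0)
        u = np.zeros(12)
        u[0::3] = self.REF_TET[:, 0]
        assert np.allclose(b @ u, [1, 0, 0, 0, 0, 0])


class TestAssembly:
    def single_tet_mesh(self):
        return lk.TetMesh(
            nodes=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]),
            tets=np.array([[0, 1, 2, 3]]),
            boundary_tris=np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]]),
            tri_labels=np.zeros(4, dtype=np.int64),
        )

    def test_single_tet_global_equals_element(self, tm_material):
        mesh = self.single_tet_mesh()
        k = lk.assemble(mesh, tm_material).toarray()
        ke = lk.element_stiffness(mesh.nodes * 1e-6,
                                  lk.elasticity_matrix(tm_material))
        assert np.allclose(k, ke)

    def test_exact_symmetry(self, bar_mesh, tm_material):
        k = lk.assemble(bar_mesh, tm_material)
        assert (k - k.T).nnz == 0 or abs(k - k.T).max() == 0.0

    def test_six_rigid_body_modes_before_constraints(self, bar_mesh, tm_material):
        k = lk.assemble(bar_mesh, tm_material)
        scale = np.abs(k).max()
        for v in rigid_body_basis(bar_mesh.nodes * 1e-6):
            assert np.linalg.norm(k @ v) <= 1e-8 * scale * np.linalg.norm(v)
        # a uniform stretch is NOT a rigid mode
        stretch = np.zeros((bar_mesh.n_nodes, 3))
        stretch[:, 2] = bar_mesh.nodes[:, 2] * 1e-6
        assert np.linalg.norm(k @ stretch.ravel()) > 1e-6 * scale


class TestPressureLoad:
    def test_consistent_load_and_total_force(self, bar_mesh):
        p = 60.0
        f = lk.pressure_load(bar_mesh, p, [0, 0, 1])
        a_top_m2 = 20e-6 * 20e-6  # 2×2 voxels of 10 μm pitch
        total = f.reshape(-1, 3).sum(axis=0)
        assert np.allclose(total, [0, 0, -p * a_top_m2], rtol=1e-12)
        # load only on pressure-face nodes
        loaded = np.flatnonzero(np.abs(f.reshape(-1, 3)).sum(axis=1) > 0)
        assert set(loaded) <= set(bar_mesh.nodes_of(lk.FACE_PRESSURE))

    def test_zero_pressure_zero_vector(self, bar_mesh):
        assert not lk.pressure_load(bar_mesh, 0.0, [0, 0, 1]).any()

    def test_unlabeled_mesh_rejected(self, tm_material):
        vol = lk.SegmentedVolume(np.ones((2, 2, 2), bool), 2.0, 2.0)
        mesh = lk.voxel_to_tetmesh(vol)
        with pytest.raises(lk.UnloadedModelError):
            lk.pressure_load(mesh, 10.0, [0, 0, 1])


class TestSolve:
    def test_uniaxial_bar_matches_closed_form(self, bar_mesh, tm_material):
        # free lateral faces + laterally-free base: uniform stress p,
        # tip displacement pL/E regardless of Poisson ratio
        p, length = 16.2, 100.0
        load = lk.LoadCase(p, [0, 0, 1], fixed_dofs=uniaxial_dofs(bar_mesh))
        res = lk.solve(bar_mesh, tm_material, load)
        expect = p * length / tm_material.young_modulus  # 10 μm
        assert res.max_directional_deformation == pytest.approx(
            expect, rel=1e-6)
        tip = np.isclose(bar_mesh.nodes[:, 2], length)
        assert np.allclose(np.abs(res.directional_deformation[tip]),
                           expect, rtol=1e-6)

    def test_fixed_nodes_exactly_zero(self, bar_mesh, tm_material):
        base = bar_mesh.nodes_of(lk.FACE_FIXED)
        res = lk.solve(bar_mesh, tm_material,
                       lk.LoadCase(50.0, [0, 0, 1], fixed_nodes=base))
        assert np.all(res.displacements[base] == 0.0)
        assert res.stats["residual"] <= 1e-8

    def test_zero_pressure_zero_displacement(self, bar_mesh, tm_material):
        res = lk.solve(bar_mesh, tm_material,
                       lk.LoadCase(0.0, [0, 0, 1],
                                   fixed_nodes=bar_mesh.nodes_of(lk.FACE_FIXED)))
        assert not res.displacements.any()

    def test_linearity_in_pressure(self, bar_mesh, tm_material):
        base = bar_mesh.nodes_of(lk.FACE_FIXED)
        u1 = lk.solve(bar_mesh, tm_material,
                      lk.LoadCase(25.0, [0, 0, 1], fixed_nodes=base))
        u2 = lk.solve(bar_mesh, tm_material,
                      lk.LoadCase(50.0, [0, 0, 1], fixed_nodes=base))
        assert np.allclose(u2.displacements, 2.0 * u1.displacements,
                           rtol=1e-10, atol=1e-14)

    def test_displacement_scales_inversely_with_stiffness(self, bar_mesh):
        base = bar_mesh.nodes_of(lk.FACE_FIXED)
        load = lk.LoadCase(40.0, [0, 0, 1], fixed_nodes=base)
        soft = lk.solve(bar_mesh, lk.MaterialModel(162.0, 0.48), load)
        stiff = lk.solve(bar_mesh, lk.MaterialModel(324.0, 0.48), load)
        assert np.allclose(soft.displacements, 2.0 * stiff.displacements,
                           rtol=1e-10, atol=1e-14)

    def test_reactions_balance_applied_load(self, bar_mesh, tm_material):
        p = 60.0
        base = bar_mesh.nodes_of(lk.FACE_FIXED)
        load = lk.LoadCase(p, [0, 0, 1], fixed_nodes=base)
        res = lk.solve(bar_mesh, tm_material, load)
        k = lk.assemble(bar_mesh, tm_material)
        f = lk.pressure_load(bar_mesh, p, load.pressure_normal)
        u_m = (res.displacements * 1e-6).ravel()
        reactions = (k @ u_m - f).reshape(-1, 3)[base].sum(axis=0)
        applied = f.reshape(-1, 3).sum(axis=0)
        assert np.linalg.norm(reactions + applied) <= 1e-8 * np.linalg.norm(applied)

    def test_solution_invariant_under_node_reordering(self, bar_mesh, tm_material):
        rng = np.random.default_rng(11)
        perm = rng.permutation(bar_mesh.n_nodes)
        inv = np.argsort(perm)
        shuffled = lk.TetMesh(
            nodes=bar_mesh.nodes[perm],
            tets=inv[bar_mesh.tets],
            boundary_tris=inv[bar_mesh.boundary_tris],
            tri_labels=bar_mesh.tri_labels.copy(),
        )
        base = bar_mesh.nodes_of(lk.FACE_FIXED)
        res_a = lk.solve(bar_mesh, tm_material,
                         lk.LoadCase(30.0, [0, 0, 1], fixed_nodes=base))
        res_b = lk.solve(shuffled, tm_material,
                         lk.LoadCase(30.0, [0, 0, 1],
                                     fixed_nodes=shuffled.nodes_of(lk.FACE_FIXED)))
        assert np.allclose(res_a.displacements, res_b.displacements[inv][perm][inv],
                           rtol=1e-8, atol=1e-12)
        assert res_a.max_directional_deformation == pytest.approx(
            res_b.max_directional_deformation, rel=1e-8)

    def test_no_constraint_rejected(self, bar_mesh, tm_material):
        with pytest.raises(lk.InsufficientConstraintError):
            lk.solve(bar_mesh, tm_material, lk.LoadCase(10.0, [0, 0, 1]))


class TestPressureSweep:
    def test_default_sweep_is_study_protocol(self, bar_mesh, tm_material):
        results = lk.pressure_sweep(
            bar_mesh, tm_material, pressure_normal=[0, 0, 1],
            fixed_nodes=bar_mesh.nodes_of(lk.FACE_FIXED))
        assert [r.pressure for r in results] == [float(p)
                                                 for p in range(10, 170, 10)]
        maxima = [r.max_directional_deformation for r in results]
        assert np.all(np.diff(maxima) > 0)
        assert maxima[-1] == pytest.approx(16.0 * maxima[0], rel=1e-8)

    def test_report_table(self, bar_mesh, tm_material):
        results = lk.pressure_sweep(
            bar_mesh, tm_material, pressures=(0.0, 60.0),
            pressure_normal=[0, 0, 1],
            fixed_nodes=bar_mesh.nodes_of(lk.FACE_FIXED))
        table = lk.deformation_report(results)
        assert len(table) == 2
        assert table.loc[0, "max_directional_deformation_um"] == 0.0
        assert table.loc[1, "max_directional_deformation_um"] > 0


class TestTrabecularMeshworkModel:
    def test_largest_deformation_on_beam_surface(self, intact_scene,
                                                 intact_config, tm_material):
        # small TM subvolume: beams loaded along the outflow direction (+x),
        # constrained on the scleral side; the peak deformation must sit on
        # the free surface of a slender beam, i.e. on a boundary node
        labels, _ = intact_scene
        (s0, s1), (r0, r1), (c0, c1) = intact_config.tm_roi
        sub = labels.labels[s0:s1, 200:240, c0 + 40: c0 + 80] == lk.TM_BEAM
        vol = lk.SegmentedVolume(sub, intact_config.lateral_pitch,
                                 intact_config.axial_step)
        seed = tuple(np.argwhere(vol.mask)[0])
        vol = lk.region_grow(vol, seed, 26)
        mesh = lk.voxel_to_tetmesh(vol)
        mesh = lk.label_boundaries(
            mesh, [-1, 0, 0], angle_tol_deg=30.0,
            fixed_region=lk.scleral_side_fixed_region(mesh, axis=0))
        res = lk.solve(
            mesh, tm_material,
            lk.LoadCase(60.0, [-1, 0, 0],
                        fixed_nodes=mesh.nodes_of(lk.FACE_FIXED)))
        boundary_nodes = set(np.unique(mesh.boundary_tris))
        assert res.max_node in boundary_nodes
        assert res.max_directional_deformation > 0
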