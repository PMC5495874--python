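"""FEM assembly, Venant loads, AMG-CG solves and transfer-matrix leadfields.

Oracles: exact symbolic element integration (sympy), dense direct solves,
and path equivalence between the transfer-matrix and direct-solve routes.
"""

import numpy as np
import pytest
from scipy import sparse

from emegfem import fem
from emegfem.amg import AMGPreconditioner
from emegfem.mesh import ConductivityTable, assign_conductivities, build_hex_mesh, build_source_space
from emegfem.phantom import DipoleSource, LabeledVoxelGrid, four_shell_spec, make_sensor_array, voxelize_sphere_model


def cube_grid(n, labels_value=1, voxel=1.0):
    labels = np.full((n, n, n), labels_value, dtype=int)
    return LabeledVoxelGrid(labels, voxel, np.zeros(3), {labels_value: "gm"})


def cube_mesh(n, sigma=1.0, voxel=1.0):
    mesh = build_hex_mesh(cube_grid(n, voxel=voxel), 0.0)
    return assign_conductivities(mesh, ConductivityTable({1: sigma}))


@pytest.fixture(scope="module")
def small_phantom():
    """Thick-shell 4 mm sphere with EEG+MEG sensors (module-shared)."""
    spec = four_shell_spec(radii=(60, 52, 46, 42), conductivities=(0.43, 0.0033, 1.79, 0.33))
    grid = voxelize_sphere_model(spec, 4.0, (34, 34, 34))
    mesh = assign_conductivities(build_hex_mesh(grid, 0.33), ConductivityTable(spec.conductivity_table()))
    K = fem.assemble_stiffness(mesh)
    sensors = make_sensor_array(spec, 24, 24, meg_type="magnetometer", baseline=None)
    return spec, mesh, K, sensors


class TestAssembly:
    def test_unit_cube_element_matches_symbolic_integration(self):
        """Single unit-cube element, sigma = I: the 8x8 stiffness equals the
        exact symbolic integral of grad(phi_i) . grad(phi_j)."""
        import sympy as sp

        x, y, z = sp.symbols("x y z")
        from emegfem.mesh import CORNER_OFFSETS

        phis = [
            ((1 - x) if i == 0 else x) * ((1 - y) if j == 0 else y) * ((1 - z) if k == 0 else z)
            for i, j, k in CORNER_OFFSETS
        ]
        exact = np.empty((8, 8))
        for a in range(8):
            ga = [sp.diff(phis[a], v) for v in (x, y, z)]
            for b in range(a, 8):
                gb = [sp.diff(phis[b], v) for v in (x, y, z)]
                val = sp.integrate(
                    sum(u * v for u, v in zip(ga, gb)), (x, 0, 1), (y, 0, 1), (z, 0, 1)
                )
                exact[a, b] = exact[b, a] = float(val)
        # 1 mm voxel in SI meters scales K linearly by h = 1e-3
        mesh = cube_mesh(1)
        Kg = fem.assemble_stiffness(mesh).matrix.toarray() / 1e-3
        e = mesh.elements[0]  # map corner-local ordering to global node ids
        np.testing.assert_allclose(Kg[np.ix_(e, e)], exact, atol=1e-12)

    def test_row_sums_vanish(self, small_phantom):
        _, _, K, _ = small_phantom
        rs = np.asarray(K.matrix.sum(axis=1)).ravel()
        assert np.abs(rs).max() < 1e-10 * np.abs(K.matrix.data).max()

    def test_symmetry(self, small_phantom):
        _, _, K, _ = small_phantom
        d = (K.matrix - K.matrix.T).tocoo()
        assert np.abs(d.data).max() < 1e-12 * np.abs(K.matrix.data).max() if d.nnz else True

    def test_conductivity_scaling_is_exact(self):
        K1 = fem.assemble_stiffness(cube_mesh(3, sigma=1.0)).matrix.toarray()
        K2 = fem.assemble_stiffness(cube_mesh(3, sigma=2.5)).matrix.toarray()
        np.testing.assert_allclose(K2, 2.5 * K1, rtol=1e-13, atol=1e-16 * np.abs(K1).max())

    def test_missing_tensors_rejected(self):
        mesh = build_hex_mesh(cube_grid(2), 0.0)
        with pytest.raises(ValueError, match="tensors"):
            fem.assemble_stiffness(mesh)


class TestVenant:
    def test_loads_sum_to_zero_exactly(self, small_phantom):
        _, mesh, _, _ = small_phantom
        _, Q = fem.venant_loads([5.0, -3.0, 20.0], mesh)
        np.testing.assert_allclose(Q.sum(axis=0), 0.0, atol=1e-12 * np.abs(Q).max())

    def test_first_moment_reproduced_within_one_percent(self, small_phantom):
        _, mesh, _, _ = small_phantom
        rng = np.random.default_rng(5)
        for _ in range(20):
            u = rng.standard_normal(3)
            pos = 30.0 * u / np.linalg.norm(u) * rng.uniform(0.2, 0.9)
            nbrs, Q = fem.venant_loads(pos, mesh)
            dx = (mesh.nodes[nbrs] - pos) * 1e-3
            M = dx.T @ Q  # (3, 3): first moment of each unit-moment load set
            assert np.abs(M - np.eye(3)).max() < 0.01

    def test_on_node_axis_aligned_moment_is_antisymmetric(self):
        """Dipole exactly on a node with an x-moment loads +-x neighbors
        antisymmetrically."""
        mesh = cube_mesh(5)
        node = int(np.argmin(np.linalg.norm(mesh.nodes - np.array([2.5, 2.5, 2.5]), axis=1)))
        pos = mesh.nodes[node]
        nbrs, Q = fem.venant_loads(pos, mesh)
        dx = mesh.nodes[nbrs] - pos
        qx = Q[:, 0]
        # mirror each neighbor across the node in x
        for i, d in enumerate(dx):
            j = int(np.argmin(np.linalg.norm(dx - d * np.array([-1, 1, 1]), axis=1)))
            assert qx[i] == pytest.approx(-qx[j], rel=1e-6, abs=1e-9 * np.abs(qx).max())

    def test_outside_mesh_rejected(self, small_phantom):
        _, mesh, _, _ = small_phantom
        with pytest.raises(ValueError, match="outside"):
            fem.venant_loads([500.0, 0.0, 0.0], mesh)


class TestSolver:
    def test_zero_rhs_gives_zero_solution(self, small_phantom):
        _, _, K, _ = small_phantom
        u = K.solve(np.zeros(K.n_nodes))
        assert np.all(u == 0)

    def test_unbalanced_rhs_rejected(self, small_phantom):
        _, _, K, _ = small_phantom
        rhs = np.zeros(K.n_nodes)
        rhs[10] = 1.0
        with pytest.raises(ValueError, match="charge-balanced"):
            K.solve(rhs)

    def test_agrees_with_dense_direct_solve(self):
        """AMG-CG matches a dense solve on a 5^3 mesh to 1e-8 relative."""
        mesh = cube_mesh(5)
        K = fem.assemble_stiffness(mesh)
        rng = np.random.default_rng(0)
        rhs = rng.standard_normal(K.n_nodes)
        rhs -= rhs.mean()
        u = K.solve(rhs, tol=1e-12)
        Kd = K.matrix.toarray()
        ud = np.linalg.lstsq(Kd, rhs, rcond=None)[0]
        ud -= ud.mean()
        assert np.linalg.norm(u - ud) < 1e-8 * np.linalg.norm(ud)

    def test_solution_invariant_under_node_permutation(self):
        mesh = cube_mesh(4)
        K = fem.assemble_stiffness(mesh)
        rng = np.random.default_rng(1)
        rhs = rng.standard_normal(K.n_nodes)
        rhs -= rhs.mean()
        u = K.solve(rhs, tol=1e-11)
        perm = rng.permutation(K.n_nodes)
        P = sparse.csr_matrix((np.ones(len(perm)), (np.arange(len(perm)), perm)))
        Kp = fem.StiffnessMatrix(matrix=(P @ K.matrix @ P.T).tocsr(), ground_node=0)
        up = Kp.solve(rhs[perm], tol=1e-11)
        assert np.linalg.norm(up - u[perm]) < 1e-8 * np.linalg.norm(u)

    def test_nonconvergence_reports_residual_history(self, small_phantom):
        _, mesh, K, _ = small_phantom
        rhs = np.zeros(K.n_nodes)
        rhs[0], rhs[-1] = 1.0, -1.0
        with pytest.raises(fem.SolverError, match="residual history"):
            K.solve(rhs, tol=1e-13, maxiter=2)

    def test_constant_shift_changes_no_readout(self, small_phantom):
        """Null-space safety: adding a constant to the potentials leaves
        every EEG and MEG read-out unchanged."""
        _, mesh, K, sensors = small_phantom
        rng = np.random.default_rng(2)
        u = rng.standard_normal(K.n_nodes)
        S = fem.meg_secondary_matrix(mesh, sensors)
        T = fem.eeg_transfer(K, sensors, mesh, tol=1e-8)
        snapped = T.snapped_nodes
        read_eeg = u[snapped] - u[snapped].mean()
        read_meg = S @ u
        shifted = u + 123.456
        np.testing.assert_allclose(shifted[snapped] - shifted[snapped].mean(), read_eeg, atol=1e-9)
        np.testing.assert_allclose(S @ shifted, read_meg, rtol=0, atol=1e-12 * np.abs(read_meg).max() + 1e-22)


class TestAmg:
    def test_preconditioner_is_symmetric(self):
        mesh = cube_mesh(6)
        K = fem.assemble_stiffness(mesh)
        A = K.grounded()
        M = AMGPreconditioner(A, max_coarse=50)
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(A.shape[0]), rng.standard_normal(A.shape[0])
        assert x @ M(y) == pytest.approx(y @ M(x), rel=1e-10)

    def test_vcycle_reduces_error(self):
        mesh = cube_mesh(8)
        K = fem.assemble_stiffness(mesh)
        A = K.grounded()
        M = AMGPreconditioner(A, max_coarse=50)
        rng = np.random.default_rng(1)
        x_true = rng.standard_normal(A.shape[0])
        b = A @ x_true
        x = M(b)
        assert np.linalg.norm(b - A @ x) < 0.5 * np.linalg.norm(b)


class TestTransferAndLeadfields:
    def test_transfer_equals_direct_readout_on_toy_mesh(self):
        """T @ rhs reproduces the electrode read-out of the direct solve for
        random load vectors, to 1e-8."""
        spec = four_shell_spec(radii=(14, 12, 10, 8), conductivities=(0.43, 0.0033, 1.79, 0.33))
        grid = voxelize_sphere_model(spec, 2.0, (16, 16, 16))
        mesh = assign_conductivities(build_hex_mesh(grid, 0.0), ConductivityTable(spec.conductivity_table()))
        K = fem.assemble_stiffness(mesh)
        sensors = make_sensor_array(spec, 12, 8, meg_type="magnetometer", baseline=None)
        T = fem.eeg_transfer(K, sensors, mesh, tol=1e-12)
        rng = np.random.default_rng(3)
        for _ in range(3):
            rhs = rng.standard_normal(K.n_nodes)
            rhs -= rhs.mean()
            u = K.solve(rhs, tol=1e-12)
            direct = u[T.snapped_nodes] - u[T.snapped_nodes].mean()
            via_transfer = T.matrix @ rhs
            assert np.abs(via_transfer - direct).max() < 1e-8 * np.abs(direct).max()

    def test_average_reference_rows(self, small_phantom):
        """The electrode read-outs of any potential field sum to zero, i.e.
        the transfer rows sum to zero across sensors."""
        _, mesh, K, sensors = small_phantom
        T = fem.eeg_transfer(K, sensors, mesh, tol=1e-9)
        colsum = T.matrix.sum(axis=0)
        assert np.abs(colsum).max() < 1e-8 * np.abs(T.matrix).max()

    def test_duplicate_electrodes_give_identical_rows(self, small_phantom):
        spec, mesh, K, _ = small_phantom
        from emegfem.phantom import SensorArray

        pos = np.array([[0.0, 0.0, 60.0], [0.0, 0.0, 60.0], [40.0, 0.0, 40.0]])
        sens = SensorArray(
            eeg_positions=pos,
            eeg_labels=["a", "b", "c"],
            meg_centers=np.empty((0, 3)),
            meg_orientations=np.empty((0, 3)),
            meg_labels=[],
        )
        T = fem.eeg_transfer(K, sens, mesh, tol=1e-9)
        np.testing.assert_array_equal(T.matrix[0], T.matrix[1])

    def test_far_electrode_rejected(self, small_phantom):
        spec, mesh, K, _ = small_phantom
        from emegfem.phantom import SensorArray

        sens = SensorArray(
            eeg_positions=np.array([[0.0, 0.0, 100.0]]),
            eeg_labels=["far"],
            meg_centers=np.empty((0, 3)),
            meg_orientations=np.empty((0, 3)),
            meg_labels=[],
        )
        with pytest.raises(ValueError, match="far"):
            fem.eeg_transfer(K, sens, mesh, snap_tolerance=10.0)

    def test_coil_inside_head_rejected(self, small_phantom):
        spec, mesh, K, _ = small_phantom
        from emegfem.phantom import SensorArray

        sens = SensorArray(
            eeg_positions=np.array([[0.0, 0.0, 60.0]]),
            eeg_labels=["e"],
            meg_centers=np.array([[0.0, 0.0, 30.0]]),
            meg_orientations=np.array([[0.0, 0.0, 1.0]]),
            meg_labels=["m"],
        )
        with pytest.raises(ValueError, match="inside"):
            fem.meg_secondary_matrix(mesh, sens)

    def test_leadfield_column_equals_direct_path(self, small_phantom):
        """Transfer-matrix leadfield columns equal the venant -> solve ->
        read-out route for both modalities."""
        spec, mesh, K, sensors = small_phantom
        ss = build_source_space(mesh, gm_label=4, spacing=8.0)
        Te = fem.eeg_transfer(K, sensors, mesh, tol=1e-11)
        Tm = fem.meg_transfer(K, sensors, mesh, tol=1e-11)
        lf = fem.compute_leadfields(K, mesh, ss, sensors, eeg=Te, meg=Tm)
        S = fem.meg_secondary_matrix(mesh, sensors)
        j = len(ss) // 2
        dip = DipoleSource(ss.positions[j], [0.0, 10.0, 0.0])
        direct = fem.direct_leadfield_column(
            K, mesh, sensors, dip, eeg_snapped_nodes=Te.snapped_nodes, meg_secondary=S, tol=1e-11
        )
        col = lf.column_block(j) @ dip.moment
        eeg_rows = lf.row_modality == "eeg"
        assert np.abs(col[eeg_rows] - direct["eeg"]).max() < 1e-7 * np.abs(direct["eeg"]).max()
        assert np.abs(col[~eeg_rows] - direct["meg"]).max() < 1e-7 * np.abs(direct["meg"]).max()

    def test_leadfield_units_sanity_and_linearity(self, small_phantom):
        """1 nA*m tangential source reads out in the sub-microvolt to
        microvolt EEG range; leadfields are exactly linear in the moment."""
        spec, mesh, K, sensors = small_phantom
        ss = build_source_space(mesh, gm_label=4, spacing=8.0)
        Te = fem.eeg_transfer(K, sensors, mesh)
        lf = fem.compute_leadfields(K, mesh, ss, sensors, eeg=Te)
        j = int(np.argmax(np.linalg.norm(ss.positions, axis=1)))
        col = lf.column_block(j) @ np.array([1.0, 0.0, 0.0])
        assert 1e-3 < np.abs(col).max() < 10.0
        np.testing.assert_allclose(lf.column_block(j) @ np.array([2.0, 0, 0]), 2 * col, rtol=1e-14)

    def test_radial_meg_silence_on_sphere(self, small_phantom):
        """A quasi-radial dipole produces < 1% of the MEG power of an
        equal-strength tangential dipole at the same position."""
        spec, mesh, K, sensors = small_phantom
        S = fem.meg_secondary_matrix(mesh, sensors)
        pos = np.array([0.0, 0.0, 26.0])
        rad = fem.direct_leadfield_column(K, mesh, sensors, DipoleSource(pos, [0, 0, 10.0]), meg_secondary=S)
        tan = fem.direct_leadfield_column(K, mesh, sensors, DipoleSource(pos, [10.0, 0, 0]), meg_secondary=S)
        assert np.linalg.norm(rad["meg"]) < 0.01 * np.linalg.norm(tan["meg"])

    def test_gradiometer_is_two_coil_difference(self, small_phantom):
        spec, mesh, K, _ = small_phantom
        mag = make_sensor_array(spec, 8, 16, meg_type="magnetometer", baseline=None)
        grad = make_sensor_array(spec, 8, 16, meg_type="axial_gradiometer", baseline=50.0)
        from emegfem.phantom import SensorArray

        far = SensorArray(
            eeg_positions=mag.eeg_positions,
            eeg_labels=mag.eeg_labels,
            meg_centers=mag.meg_centers + 50.0 * mag.meg_orientations,
            meg_orientations=mag.meg_orientations,
            meg_labels=mag.meg_labels,
            meg_type="magnetometer",
        )
        S_near = fem.meg_secondary_matrix(mesh, mag)
        S_far = fem.meg_secondary_matrix(mesh, far)
        S_grad = fem.meg_secondary_matrix(mesh, grad)
        np.testing.assert_allclose(S_grad, S_near - S_far, atol=1e-18)
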