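"""Voxel hexahedral elasticity: element matrices, assembly, solve, fields."""

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss

from ossify import fem
from ossify.config import LoadCase, Phase
from ossify.geometry import uniform_box_domain

from conftest import homogeneous_materials


# ---------------------------------------------------------------------------
# independent element-stiffness oracle: separately coded trilinear shape
# functions, finite-difference gradients, 3-point Gauss-Legendre quadrature
# ---------------------------------------------------------------------------

def _oracle_element_stiffness(E, nu, h):
    offsets = np.array(
        [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
         (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)], dtype=float
    )

    def shapes(p):
        t = p / h
        vals = np.ones(8)
        for a in range(8):
            for d in range(3):
                vals[a] *= t[d] if offsets[a, d] == 1 else 1 - t[d]
        return vals

    def grads(p, step=1e-6):
        g = np.zeros((8, 3))
        for d in range(3):
            e = np.zeros(3)
            e[d] = step
            g[:, d] = (shapes(p + e) - shapes(p - e)) / (2 * step)
        return g

    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = lam * np.outer([1, 1, 1, 0, 0, 0], [1, 1, 1, 0, 0, 0]) + mu * np.diag(
        [2, 2, 2, 1, 1, 1]
    )
    pts, wts = leggauss(3)
    K = np.zeros((24, 24))
    for i, wi in zip(pts, wts):
        for j, wj in zip(pts, wts):
            for k, wk in zip(pts, wts):
                p = (np.array([i, j, k]) + 1) * h / 2
                g = grads(p)
                B = np.zeros((6, 24))
                for a in range(8):
                    dx, dy, dz = g[a]
                    c = 3 * a
                    B[0, c] = dx
                    B[1, c + 1] = dy
                    B[2, c + 2] = dz
                    B[3, c], B[3, c + 1] = dy, dx
                    B[4, c + 1], B[4, c + 2] = dz, dy
                    B[5, c], B[5, c + 2] = dz, dx
                K += wi * wj * wk * (h / 2) ** 3 * B.T @ C @ B
    return K


class TestElementStiffness:
    def test_symmetric_with_six_rigid_modes(self):
        K = fem.element_stiffness(10.0, 0.3, 0.05)
        assert np.allclose(K, K.T)
        w = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(w) < 1e-10 * w.max()) == 6
        assert w[6] > 0

    def test_matches_independent_oracle(self):
        K = fem.element_stiffness(350.0, 0.3, 0.05)
        K_ref = _oracle_element_stiffness(350.0, 0.3, 0.05)
        assert np.allclose(K, K_ref, rtol=1e-6, atol=1e-6 * np.abs(K_ref).max())

    def test_shared_face_equilibrium(self):
        # two elements sharing a face: rigid translation is in the null space
        dom = uniform_box_domain((2, 1, 1))
        sys_ = fem.assemble_system(dom, homogeneous_materials(dom), coarsening=1)
        t = np.tile(np.eye(3), (sys_.K.shape[0] // 3, 1))
        assert np.abs(sys_.K @ t).max() < 1e-10 * np.abs(sys_.K.data).max()


class TestAssembly:
    def test_cube_matches_dense_scatter_oracle(self):
        dom = uniform_box_domain((4, 4, 4))
        mats = homogeneous_materials(dom, E=2.0, nu=0.3)
        sys_ = fem.assemble_system(dom, mats, coarsening=1)
        Ke = _oracle_element_stiffness(2.0, 0.3, dom.spacing)
        n = sys_.K.shape[0]
        K_ref = np.zeros((n, n))
        for dofs in sys_.edofs:
            K_ref[np.ix_(dofs, dofs)] += Ke
        assert np.allclose(sys_.K.toarray(), K_ref, rtol=1e-6,
                           atol=1e-6 * np.abs(K_ref).max())

    def test_disconnected_region_raises(self):
        dom = uniform_box_domain((2, 2, 5))
        dom.phase[:, :, 2] = Phase.OUTSIDE
        with pytest.raises(fem.SolverError, match="disconnected"):
            fem.assemble_system(dom, homogeneous_materials(dom), coarsening=1)


def _bar_uniaxial(E=0.2, nu=0.167, sigma=0.01, dims=(2, 2, 10)):
    """Solve a homogeneous bar under uniaxial stress with tributary face loads."""
    dom = uniform_box_domain(dims)
    sys_ = fem.assemble_system(dom, homogeneous_materials(dom, E, nu), coarsening=1)
    nnx, nny, nnz = sys_.node_dims
    h = dom.spacing
    F = sigma * (dims[0] * h) * (dims[1] * h)
    w = np.zeros((nnx, nny))
    for ei in range(dims[0]):
        for ej in range(dims[1]):
            w[ei : ei + 2, ej : ej + 2] += 0.25
    w /= w.sum()
    f = np.zeros(sys_.ndofs)
    for i in range(nnx):
        for j in range(nny):
            f[3 * sys_.node_ids(i, j, nnz - 1) + 2] = -F * w[i, j]
    fixed = [3 * sys_.node_ids(i, j, 0) + 2 for i in range(nnx) for j in range(nny)]
    n0 = sys_.node_ids(0, 0, 0)
    n1 = sys_.node_ids(nnx - 1, 0, 0)
    fixed += [3 * n0, 3 * n0 + 1, 3 * n1 + 1]
    disp = fem.solve(sys_, f, np.array(fixed), tol=1e-12)
    return dom, sys_, disp, f


class TestSolve:
    def test_zero_loads_zero_displacement(self):
        dom = uniform_box_domain((2, 2, 4))
        sys_ = fem.assemble_system(dom, homogeneous_materials(dom), coarsening=1)
        disp = fem.solve_displacements(sys_, LoadCase(0.0, 0.0))
        assert np.all(disp.u == 0.0)

    def test_bar_axial_strain_is_sigma_over_E(self):
        dom, sys_, disp, _ = _bar_uniaxial()
        L = dom.dims[2] * dom.spacing
        strain = disp.u[:, :, -1, 2] / L
        assert np.allclose(strain, -0.05, atol=1e-8)

    def test_bar_transverse_strain(self):
        dom, sys_, disp, _ = _bar_uniaxial()
        width = dom.dims[0] * dom.spacing
        mid = dom.dims[2] // 2
        eps_t = (disp.u[-1, 0, mid, 0] - disp.u[0, 0, mid, 0]) / width
        assert eps_t == pytest.approx(0.167 * 0.01 / 0.2, abs=1e-8)  # -nu*sigma/E

    def test_patch_test_reproduces_linear_field(self):
        dom = uniform_box_domain((4, 4, 5))
        sys_ = fem.assemble_system(dom, homogeneous_materials(dom, 5.0, 0.25),
                                   coarsening=1)
        A = np.array([[1.2e-3, 3e-4, -2e-4],
                      [3e-4, -8e-4, 1e-4],
                      [-2e-4, 1e-4, 5e-4]])  # symmetric -> equilibrium field
        nnx, nny, nnz = sys_.node_dims
        h = dom.spacing
        coords = np.stack(
            np.meshgrid(np.arange(nnx) * h, np.arange(nny) * h,
                        np.arange(nnz) * h, indexing="ij"), axis=-1
        )
        u_exact = coords @ A.T
        boundary = np.zeros((nnx, nny, nnz), dtype=bool)
        boundary[[0, -1], :, :] = boundary[:, [0, -1], :] = boundary[:, :, [0, -1]] = True
        nodes = np.flatnonzero(boundary)
        fixed = (3 * nodes[:, None] + np.arange(3)).ravel()
        vals = u_exact.reshape(-1, 3)[nodes].ravel()
        disp = fem.solve(sys_, np.zeros(sys_.ndofs), fixed, fixed_values=vals,
                         tol=1e-13)
        assert np.abs(disp.u - u_exact).max() < 1e-10

    def test_reaction_equilibrium(self, mini_domain):
        from ossify.coupling import _scaffold_material
        from ossify.config import SimConfig

        mats = fem.materials_from_phase(mini_domain, (1000.0, 0.3))
        sys_ = fem.assemble_system(mini_domain, mats, coarsening=4)
        loads = LoadCase(3.7, 1.2)
        f = fem.load_vector(sys_, loads)
        disp = fem.solve_displacements(sys_, loads, tol=1e-8)
        r = fem.reaction_forces(sys_, disp, f)
        comp = disp.fixed_dofs % 3
        assert np.sum(r[comp == 2]) == pytest.approx(loads.compression_load, rel=1e-6)
        assert np.sum(r[comp == 0]) == pytest.approx(-loads.shear_load, rel=1e-6)

    def test_stiffness_monotonicity(self):
        # raising any element's modulus cannot increase the compliance
        rng = np.random.default_rng(3)
        dom = uniform_box_domain((4, 4, 6))
        loads = LoadCase(0.05, 0.02)

        def compliance(E_field):
            mats = fem.MaterialField(E=E_field, nu=np.full(dom.dims, 0.3))
            sys_ = fem.assemble_system(dom, mats, coarsening=1)
            f = fem.load_vector(sys_, loads)
            disp = fem.solve_displacements(sys_, loads, tol=1e-10)
            return f @ disp.flat

    # fixed loads: work done must not increase when any element stiffens
        E0 = np.full(dom.dims, 1.0)
        base = compliance(E0)
        for _ in range(3):
            E1 = E0.copy()
            ijk = tuple(rng.integers(0, s) for s in dom.dims)
            E1[ijk] *= 10.0
            assert compliance(E1) <= base * (1 + 1e-9)


class TestElementFields:
    def test_uniform_hydrostatic_compression(self):
        dom = uniform_box_domain((3, 3, 3))
        sys_ = fem.assemble_system(dom, homogeneous_materials(dom, 2.0, 0.3),
                                   coarsening=1)
        c = 1e-3
        nnx, nny, nnz = sys_.node_dims
        h = dom.spacing
        coords = np.stack(
            np.meshgrid(np.arange(nnx) * h, np.arange(nny) * h,
                        np.arange(nnz) * h, indexing="ij"), axis=-1
        )
        u = (-c * coords).reshape(-1)
        disp = fem.DisplacementField(u=u.reshape(nnx, nny, nnz, 3),
                                     fixed_dofs=np.empty(0, dtype=np.int64),
                                     residual=0.0, residual_history=[])
        stim = fem.element_fields(sys_, disp)
        lam = 2.0 * 0.3 / (1.3 * 0.4)
        mu = 2.0 / 2.6
        p_exact = (3 * lam + 2 * mu) * c  # compression-positive
        assert np.allclose(stim.gamma[sys_.active], -c, atol=1e-12)
        assert np.allclose(stim.p[sys_.active], p_exact, rtol=1e-10)

    def test_pure_shear_has_zero_hydrostatic_stress(self):
        dom = uniform_box_domain((1, 1, 1))
        sys_ = fem.assemble_system(dom, homogeneous_materials(dom, 2.0, 0.3),
                                   coarsening=1)
        u = np.zeros(sys_.node_dims + (3,))
        h = dom.spacing
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    u[i, j, k, 0] = 1e-3 * j * h  # u_x = c*y
        disp = fem.DisplacementField(u=u, fixed_dofs=np.empty(0, dtype=np.int64),
                                     residual=0.0, residual_history=[])
        stim = fem.element_fields(sys_, disp)
        assert stim.p[sys_.active][0] == pytest.approx(0.0, abs=1e-15)

    def test_bar_gamma_and_p(self):
        dom, sys_, disp, _ = _bar_uniaxial()
        stim = fem.element_fields(sys_, disp)
        mid = dom.dims[2] // 2
        assert stim.gamma[1, 1, mid] == pytest.approx(-0.05, abs=1e-8)
        assert stim.p[1, 1, mid] == pytest.approx(0.01 / 3, abs=1e-8)

    def test_mesh_refinement_preserves_stimulus_pattern(self):
        # stiff inclusion in a soft block: coarse and fine solves must agree
        # in spatial pattern (rank correlation) like a mesh-sensitivity study
        from scipy.stats import spearmanr
        from ossify import mechanoregulation as mreg

        dom = uniform_box_domain((12, 12, 16), spacing=0.1)
        E = np.full(dom.dims, 0.2)
        E[4:8, 4:8, 6:10] = 350.0  # scaffold-like inclusion
        mats = fem.MaterialField(E=E, nu=np.full(dom.dims, 0.3))
        loads = LoadCase(0.01, 0.004)
        S = {}
        for k in (2, 1):
            sys_ = fem.assemble_system(dom, mats, coarsening=k)
            disp = fem.solve_displacements(sys_, loads, tol=1e-10)
            stim = fem.element_fields(sys_, disp)
            S[k] = mreg.stimulus(stim.gamma, stim.p)
        # restrict the fine field to the coarse grid by block averaging
        fine = S[1].reshape(6, 2, 6, 2, 8, 2).mean(axis=(1, 3, 5))
        rho = spearmanr(fine.ravel(), S[2].ravel()).statistic
        assert rho > 0.9
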