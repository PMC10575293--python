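"""Linear-elastic finite elements on the voxel grid.

Eight-node trilinear hexahedral elements with 2x2x2 Gauss quadrature, one
element per ``k^3`` voxel block (k = coarsening factor; k=1 puts one element
per voxel).  Because every element is a cube of the same size, the element
stiffness separates into two material-independent geometry matrices scaled by
the Lame constants,

    K_e = h * (lambda_e * K_lam + mu_e * K_mu),

which makes assembly a vectorized scatter of per-element Lame constants.
Element properties are volume averages of the member-voxel properties, with
out-of-domain voxels contributing zero stiffness (boundary softening).

The solved displacement field yields per-element centroid small strains; the
mechanoregulation stimulus consumes the minimal principal strain (gamma, the
algebraically smallest strain eigenvalue, compression negative) and the
hydrostatic stress p = -tr(sigma)/3 (compression positive, MPa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg

from ossify.config import Phase
from ossify.geometry import DomainModel

# local node order: (i,j,k) offsets within the element
_NODE_OFFSETS = np.array(
    [
        (0, 0, 0),
        (1, 0, 0),
        (1, 1, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 0, 1),
        (1, 1, 1),
        (0, 1, 1),
    ],
    dtype=np.int64,
)
_XI_SIGNS = 2.0 * _NODE_OFFSETS - 1.0  # node corners in (-1,1)^3


class SolverError(RuntimeError):
    """FE solve failed; carries the residual history for diagnosis."""

    def __init__(self, msg: str, residuals: list[float] | None = None):
        super().__init__(msg)
        self.residuals = residuals or []


def _b_matrix(xi: float, eta: float, zeta: float) -> np.ndarray:
    """Strain-displacement matrix (6x24) on the bi-unit reference cube (h=1).

    Rows: exx, eyy, ezz, gxy, gyz, gxz (engineering shear).  Derivatives are
    with respect to physical coordinates of a unit cube element, dN/dx =
    2 * dN/dxi.
    """
    dN = np.empty((8, 3))
    for a in range(8):
        sx, sy, sz = _XI_SIGNS[a]
        dN[a] = [
            sx * (1 + sy * eta) * (1 + sz * zeta) / 8.0,
            (1 + sx * xi) * sy * (1 + sz * zeta) / 8.0,
            (1 + sx * xi) * (1 + sy * eta) * sz / 8.0,
        ]
    dN *= 2.0  # reference cube (-1,1) -> unit physical cube
    B = np.zeros((6, 24))
    for a in range(8):
        dx, dy, dz = dN[a]
        c = 3 * a
        B[0, c] = dx
        B[1, c + 1] = dy
        B[2, c + 2] = dz
        B[3, c] = dy
        B[3, c + 1] = dx
        B[4, c + 1] = dz
        B[4, c + 2] = dy
        B[5, c] = dz
        B[5, c + 2] = dx
    return B


def _geometry_matrices() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-cube K_lam, K_mu (24x24) and the centroid B matrix (6x24)."""
    gp = 1.0 / np.sqrt(3.0)
    m = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    d_mu = np.diag([2.0, 2.0, 2.0, 1.0, 1.0, 1.0])
    k_lam = np.zeros((24, 24))
    k_mu = np.zeros((24, 24))
    detj = 1.0 / 8.0  # unit cube
    for sx in (-gp, gp):
        for sy in (-gp, gp):
            for sz in (-gp, gp):
                B = _b_matrix(sx, sy, sz)
                k_lam += detj * B.T @ np.outer(m, m) @ B
                k_mu += detj * B.T @ d_mu @ B
    return k_lam, k_mu, _b_matrix(0.0, 0.0, 0.0)


K_LAM, K_MU, B_CENTER = _geometry_matrices()


def element_stiffness(E: float, nu: float, h: float = 1.0) -> np.ndarray:
    """Stiffness of a single cubic hex8 element of edge h."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    return h * (lam * K_LAM + mu * K_MU)


@dataclass
class MaterialField:
    """Per-voxel Young's modulus (MPa) and Poisson ratio on the full grid."""

    E: np.ndarray
    nu: np.ndarray

    def validate(self, in_domain: np.ndarray) -> None:
        if np.any(self.E[in_domain] <= 0):
            raise ValueError("Young's modulus must be positive in the domain")
        if np.any((self.nu[in_domain] < 0) | (self.nu[in_domain] >= 0.5)):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")


def materials_from_phase(
    domain: DomainModel, scaffold_material: tuple[float, float]
) -> MaterialField:
    """Initial material field: phase-table properties, granulation callus."""
    from ossify.config import PHASE_MATERIALS

    E = np.zeros(domain.dims)
    nu = np.zeros(domain.dims)
    table = dict(PHASE_MATERIALS)
    table[Phase.SCAFFOLD] = scaffold_material
    for ph, (e, n) in table.items():
        m = domain.phase == ph
        E[m] = e
        nu[m] = n
    return MaterialField(E=E, nu=nu)


@dataclass
class LinearSystem:
    """Assembled stiffness operator plus the grid bookkeeping to use it."""

    K: sparse.csr_matrix
    domain: DomainModel
    coarsening: int
    elem_dims: tuple[int, int, int]
    node_dims: tuple[int, int, int]
    active: np.ndarray  # bool, elem_dims
    elem_h: float  # element edge length, mm
    lam: np.ndarray  # per-element Lame lambda (elem_dims)
    mu: np.ndarray
    edofs: np.ndarray = field(repr=False)  # (n_active, 24) dof indices

    @property
    def ndofs(self) -> int:
        return 3 * int(np.prod(self.node_dims))

    def node_ids(self, i, j, k):
        return np.ravel_multi_index((i, j, k), self.node_dims)


def _block_mean(arr: np.ndarray, k: int, edims: tuple[int, int, int]) -> np.ndarray:
    """Mean over k^3 voxel blocks, padding with zeros to a multiple of k."""
    ex, ey, ez = edims
    pad = [(0, ex * k - arr.shape[0]), (0, ey * k - arr.shape[1]), (0, ez * k - arr.shape[2])]
    a = np.pad(arr.astype(float), pad)
    return a.reshape(ex, k, ey, k, ez, k).mean(axis=(1, 3, 5))


def assemble_system(
    domain: DomainModel, materials: MaterialField, coarsening: int = 1
) -> LinearSystem:
    """Assemble the global stiffness matrix over active elements.

    An element is active if any member voxel lies inside the domain; its Lame
    constants are k^3-block means with out-of-domain voxels contributing zero.
    Raises on a disconnected load-bearing region (components of the active
    element graph that cannot reach the constrained proximal face would make
    the constrained system singular).
    """
    k = int(coarsening)
    if k < 1:
        raise ValueError("coarsening must be >= 1")
    in_domain = domain.phase != Phase.OUTSIDE
    materials.validate(in_domain)
    dims = domain.dims
    edims = tuple(int(np.ceil(d / k)) for d in dims)

    E, nu = materials.E, materials.nu
    lam_vox = np.where(in_domain, E * nu / ((1 + nu) * (1 - 2 * nu) + 1e-300), 0.0)
    mu_vox = np.where(in_domain, E / (2 * (1 + nu)), 0.0)
    lam_e = _block_mean(lam_vox, k, edims)
    mu_e = _block_mean(mu_vox, k, edims)
    active = _block_mean(in_domain, k, edims) > 0

    n_comp, labels = _connected_components(active)
    if n_comp > 1:
        sizes = np.bincount(labels[active].ravel())
        raise SolverError(
            f"load-bearing region is disconnected: {n_comp} components of "
            f"sizes {sorted(sizes, reverse=True)}; the stiffness operator is "
            "singular under single-face constraints"
        )

    node_dims = (edims[0] + 1, edims[1] + 1, edims[2] + 1)
    ei, ej, ek = np.nonzero(active)
    # (n, 8) node ids then (n, 24) dof ids
    ni = ei[:, None] + _NODE_OFFSETS[None, :, 0]
    nj = ej[:, None] + _NODE_OFFSETS[None, :, 1]
    nk = ek[:, None] + _NODE_OFFSETS[None, :, 2]
    nodes = np.ravel_multi_index((ni, nj, nk), node_dims)
    edofs = (3 * nodes[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)

    h = domain.spacing * k
    lam_a = lam_e[active]
    mu_a = mu_e[active]
    ndofs = 3 * int(np.prod(node_dims))

    K = sparse.csr_matrix((ndofs, ndofs))
    chunk = 100_000
    for s in range(0, edofs.shape[0], chunk):
        e = slice(s, s + chunk)
        data = h * (
            lam_a[e, None, None] * K_LAM[None] + mu_a[e, None, None] * K_MU[None]
        )
        rows = np.repeat(edofs[e], 24, axis=1).ravel()
        cols = np.tile(edofs[e], (1, 24)).ravel()
        K = K + sparse.coo_matrix(
            (data.ravel(), (rows, cols)), shape=(ndofs, ndofs)
        ).tocsr()
    return LinearSystem(
        K=K,
        domain=domain,
        coarsening=k,
        elem_dims=edims,
        node_dims=node_dims,
        active=active,
        elem_h=h,
        lam=lam_e,
        mu=mu_e,
        edofs=edofs,
    )


def _connected_components(active: np.ndarray) -> tuple[int, np.ndarray]:
    labels, n = ndimage.label(active, structure=ndimage.generate_binary_structure(3, 1))
    return n, labels


def _active_node_mask(system: LinearSystem) -> np.ndarray:
    mask = np.zeros(system.node_dims, dtype=bool)
    nodes = system.edofs[:, ::3] // 3
    mask.ravel()[nodes.ravel()] = True
    return mask


@dataclass
class DisplacementField:
    """Nodal displacements (node_dims + (3,)) with solver diagnostics."""

    u: np.ndarray
    fixed_dofs: np.ndarray
    residual: float
    residual_history: list[float]

    @property
    def flat(self) -> np.ndarray:
        return self.u.reshape(-1)


def solve(
    system: LinearSystem,
    f: np.ndarray,
    fixed_dofs: np.ndarray,
    fixed_values: np.ndarray | None = None,
    tol: float = 1e-8,
    x0: np.ndarray | None = None,
) -> DisplacementField:
    """Solve K u = f with Dirichlet constraints by reduction + Jacobi-CG."""
    ndofs = system.ndofs
    fixed_dofs = np.asarray(fixed_dofs, dtype=np.int64)
    if fixed_dofs.size == 0:
        raise ValueError("constraints must remove all rigid-body modes")
    u = np.zeros(ndofs)
    if fixed_values is not None:
        u[fixed_dofs] = fixed_values

    free = np.ones(ndofs, dtype=bool)
    free[fixed_dofs] = False
    # drop dofs of inactive nodes (zero rows) from the solve
    active_dofs = np.zeros(ndofs, dtype=bool)
    active_dofs[system.edofs.ravel()] = True
    free &= active_dofs
    fidx = np.nonzero(free)[0]

    K = system.K
    b = f[fidx] - K[fidx][:, fixed_dofs] @ u[fixed_dofs]
    Kff = K[fidx][:, fidx]
    diag = Kff.diagonal()
    diag[diag <= 0] = 1.0
    M = sparse.diags(1.0 / diag)
    residuals: list[float] = []
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        u[fidx] = 0.0
        return DisplacementField(
            u=u.reshape(system.node_dims + (3,)),
            fixed_dofs=fixed_dofs,
            residual=0.0,
            residual_history=[],
        )

    it = [0]

    def cb(xk):
        it[0] += 1
        if it[0] % 25 == 0:  # sampled history; a full per-iteration record
            residuals.append(float(np.linalg.norm(b - Kff @ xk) / bnorm))  # doubles cost

    x = x0[fidx] if x0 is not None else None
    rel = np.inf
    rtol = tol * 0.1
    for _ in range(4):  # scipy's stopping rule can overshoot the true residual
        x, info = cg(Kff, b, M=M, rtol=rtol, maxiter=50 * len(fidx), callback=cb, x0=x)
        rel = float(np.linalg.norm(b - Kff @ x) / bnorm)
        if np.isfinite(rel) and rel <= tol:
            break
        rtol *= 0.1
    else:
        raise SolverError(
            f"CG failed to converge (relative residual {rel:.3e})", residuals
        )
    u[fidx] = x
    return DisplacementField(
        u=u.reshape(system.node_dims + (3,)),
        fixed_dofs=fixed_dofs,
        residual=rel,
        residual_history=residuals,
    )


def proximal_fixed_dofs(system: LinearSystem) -> np.ndarray:
    """All DOFs of active nodes on the proximal (z=0) face."""
    mask = _active_node_mask(system)
    ids = np.nonzero(mask[:, :, 0].ravel())[0]
    nnx, nny, nnz = system.node_dims
    i, j = np.unravel_index(ids, (nnx, nny))
    nodes = system.node_ids(i, j, np.zeros_like(i))
    return (3 * nodes[:, None] + np.arange(3)[None, :]).ravel()


def _distal_face_nodes(system: LinearSystem, phase_filter: int | None) -> np.ndarray:
    """Node ids on the distal (max z) face, optionally only where the top
    voxel layer of the supporting element contains the given phase."""
    ez_top = system.elem_dims[2] - 1
    ei, ej, ek = np.nonzero(system.active)
    top = ek == ez_top
    ei, ej = ei[top], ej[top]
    if phase_filter is not None:
        k = system.coarsening
        ph = system.domain.phase[:, :, -1]
        keep = []
        for a, bj in zip(ei, ej):
            block = ph[a * k : (a + 1) * k, bj * k : (bj + 1) * k]
            keep.append(np.any(block == phase_filter))
        sel = np.asarray(keep, dtype=bool)
        ei, ej = ei[sel], ej[sel]
    nk = system.node_dims[2] - 1
    corners = set()
    for a, bj in zip(ei, ej):
        for di in (0, 1):
            for dj in (0, 1):
                corners.add((a + di, bj + dj))
    if not corners:
        return np.empty(0, dtype=np.int64)
    arr = np.array(sorted(corners), dtype=np.int64)
    return system.node_ids(arr[:, 0], arr[:, 1], np.full(len(arr), nk))


def load_vector(system: LinearSystem, loads) -> np.ndarray:
    """Nodal force vector for the compression + shear load case.

    The axial compression is spread uniformly over the distal cortical-face
    nodes (acting in -z); the shear acts in +x spread uniformly over all
    distal end-face nodes.
    """
    f = np.zeros(system.ndofs)
    if loads.compression_load:
        nodes = _distal_face_nodes(system, Phase.CORTICAL_BONE)
        if nodes.size == 0:
            nodes = _distal_face_nodes(system, None)
        f[3 * nodes + 2] -= loads.compression_load / nodes.size
    if loads.shear_load:
        nodes = _distal_face_nodes(system, None)
        f[3 * nodes + 0] += loads.shear_load / nodes.size
    return f


def solve_displacements(
    system: LinearSystem, loads, tol: float = 1e-8, x0: np.ndarray | None = None
) -> DisplacementField:
    """Solve the constrained system for the standard load case."""
    f = load_vector(system, loads)
    fixed = proximal_fixed_dofs(system)
    return solve(system, f, fixed, tol=tol, x0=x0)


def reaction_forces(system: LinearSystem, disp: DisplacementField, f: np.ndarray) -> np.ndarray:
    """Reactions at the constrained DOFs: (K u - f) restricted to fixed dofs."""
    r = system.K @ disp.flat - f
    return r[disp.fixed_dofs]


@dataclass
class StimulusField:
    """Per-element minimal principal strain, hydrostatic stress, stimulus."""

    elem_dims: tuple[int, int, int]
    coarsening: int
    active: np.ndarray
    gamma: np.ndarray  # elem_dims, dimensionless (compression negative)
    p: np.ndarray  # elem_dims, MPa (compression positive)
    S: np.ndarray | None = None  # set by the mechanoregulation module

    def broadcast(self, arr: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
        """Expand a per-element array to the voxel grid (nearest element)."""
        k = self.coarsening
        out = np.repeat(np.repeat(np.repeat(arr, k, axis=0), k, axis=1), k, axis=2)
        return out[: dims[0], : dims[1], : dims[2]]

    def site_values(self, which: str, dims: tuple[int, int, int]) -> np.ndarray:
        return self.broadcast(getattr(self, which), dims)


def element_fields(system: LinearSystem, disp: DisplacementField) -> StimulusField:
    """Centroid small-strain tensor per element -> (gamma, p).

    gamma is the algebraically smallest strain eigenvalue; p = -tr(sigma)/3
    with sigma from the element's (averaged) Lame constants.
    """
    u = disp.flat
    ue = u[system.edofs]  # (n, 24)
    strain = ue @ (B_CENTER.T / system.elem_h)  # (n, 6) engineering
    exx, eyy, ezz, gxy, gyz, gxz = strain.T
    tens = np.empty((len(strain), 3, 3))
    tens[:, 0, 0] = exx
    tens[:, 1, 1] = eyy
    tens[:, 2, 2] = ezz
    tens[:, 0, 1] = tens[:, 1, 0] = gxy / 2
    tens[:, 1, 2] = tens[:, 2, 1] = gyz / 2
    tens[:, 0, 2] = tens[:, 2, 0] = gxz / 2
    eigs = np.linalg.eigvalsh(tens)
    gamma_a = eigs[:, 0]
    lam = system.lam[system.active]
    mu = system.mu[system.active]
    tr = exx + eyy + ezz
    tr_sigma = (3 * lam + 2 * mu) * tr
    p_a = -tr_sigma / 3.0

    gamma = np.zeros(system.elem_dims)
    p = np.zeros(system.elem_dims)
    gamma[system.active] = gamma_a
    p[system.active] = p_a
    return StimulusField(
        elem_dims=system.elem_dims,
        coarsening=system.coarsening,
        active=system.active,
        gamma=gamma,
        p=p,
    )
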