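"""Trilinear hexahedral FEM forward solution for EEG potentials and MEG fields.

The quasi-static EEG forward problem div(sigma grad u) = div j_p is
discretized with piecewise trilinear basis functions on the hexahedral mesh.
Point dipoles become balanced monopole loads on the nodes around the source
(Venant direct approach).  The singular Neumann system is grounded at one
node and solved with conjugate gradients preconditioned by smoothed-
aggregation algebraic multigrid (AMG-CG).

For the many-sources/few-sensors regime the transfer-matrix approach is
used: one solve per sensor row yields a matrix that turns any Venant load
vector into sensor read-outs by a sparse dot product.

MEG fields are the sum of the primary field (Biot-Savart of the impressed
dipole) and the secondary field of the volume currents -sigma grad u,
integrated element-wise with one-point quadrature.

Internally all geometry is converted to SI meters; leadfields are reported
in microvolts (EEG) and femtotesla (MEG) per nA*m of dipole moment.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from .amg import AMGPreconditioner
from .mesh import CORNER_OFFSETS, HexMesh, SourceSpace, shape_gradients
from .phantom import DipoleSource, SensorArray

logger = logging.getLogger(__name__)

__all__ = [
    "StiffnessMatrix",
    "TransferMatrix",
    "LeadfieldSet",
    "VenantConfig",
    "assemble_stiffness",
    "venant_rhs",
    "venant_loads",
    "solve_potential",
    "eeg_transfer",
    "meg_secondary_matrix",
    "meg_transfer",
    "meg_forward",
    "compute_leadfields",
]

MU0_OVER_4PI = 1e-7
_GP = np.array(
    [[sx, sy, sz] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)], float
) / np.sqrt(3.0)


class SolverError(RuntimeError):
    pass


@dataclass
class StiffnessMatrix:
    """FE stiffness matrix with its reference (grounding) constraint.

    The full matrix is symmetric positive semidefinite with the constant
    vector in its nullspace; solving is done on the SPD system obtained by
    grounding ``ground_node``, and solutions are returned mean-zero (the
    read-out convention).
    """

    matrix: sparse.csr_matrix  # full singular system, S*m
    ground_node: int = 0
    reference: str = "mean-zero"

    _grounded: sparse.csr_matrix | None = field(default=None, repr=False)
    _amg: AMGPreconditioner | None = field(default=None, repr=False)
    _keep: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def grounded(self) -> sparse.csr_matrix:
        if self._grounded is None:
            keep = np.ones(self.n_nodes, dtype=bool)
            keep[self.ground_node] = False
            self._keep = keep
            K = self.matrix.tocsc()[:, keep].tocsr()[keep]
            self._grounded = K.tocsr()
        return self._grounded

    def preconditioner(self) -> AMGPreconditioner:
        if self._amg is None:
            self._amg = AMGPreconditioner(self.grounded())
            logger.info(
                "AMG setup: %d levels, grid complexity %.2f",
                self._amg.n_levels,
                self._amg.grid_complexity(),
            )
        return self._amg

    def solve(self, rhs: np.ndarray, tol: float = 1e-9, maxiter: int = 500) -> np.ndarray:
        """AMG-CG solve; returns the mean-zero potential vector (volts)."""
        rhs = np.asarray(rhs, float).ravel()
        total = rhs.sum()
        scale = np.abs(rhs).sum()
        if scale > 0 and abs(total) > 1e-8 * scale:
            raise ValueError(
                f"rhs is not charge-balanced (sum {total:.3e} vs magnitude {scale:.3e})"
            )
        if scale == 0:
            return np.zeros(self.n_nodes)
        Kg = self.grounded()
        b = rhs[self._keep]
        M = self.preconditioner().as_linear_operator()
        hist: list[float] = []

        def cb(xk):
            hist.append(float(np.linalg.norm(b - Kg @ xk)))

        x, info = cg(Kg, b, rtol=tol, atol=0.0, maxiter=maxiter, M=M, callback=cb)
        if info != 0:
            raise SolverError(
                f"AMG-CG did not reach rtol={tol} in {maxiter} iterations; "
                f"residual history tail: {[f'{r:.2e}' for r in hist[-5:]]}"
            )
        u = np.empty(self.n_nodes)
        u[self._keep] = x
        u[self.ground_node] = 0.0
        return u - u.mean()


def _element_operator(mesh: HexMesh):
    """Per-element geometry in meters: corner coords, centroid gradients,
    volumes and centroids (cached on the mesh object)."""
    cache = getattr(mesh, "_fem_cache", None)
    if cache is not None:
        return cache
    X = mesh.corner_coords() * 1e-3  # m
    dN0 = shape_gradients(np.zeros(3))
    J0 = np.einsum("ia,eib->eab", dN0, X)
    detJ0 = np.linalg.det(J0)
    Jinv0 = np.linalg.inv(J0)
    grad0 = np.einsum("ia,eab->eib", dN0, Jinv0)  # (Ne, 8, 3) at centroid
    vol = np.zeros(len(X))
    for gp in _GP:
        dN = shape_gradients(gp)
        J = np.einsum("ia,eib->eab", dN, X)
        vol += np.linalg.det(J)
    centroids = X.mean(axis=1)
    cache = (X, grad0, vol, centroids)
    mesh._fem_cache = cache
    return cache


def assemble_stiffness(mesh: HexMesh, ground_node: int = 0) -> StiffnessMatrix:
    """Assemble K_ab = sum_e int grad(phi_a) . sigma_e grad(phi_b) dV with
    8-point Gauss quadrature per hexahedron."""
    if mesh.element_tensors is None:
        raise ValueError("mesh has no conductivity tensors assigned")
    X = mesh.corner_coords() * 1e-3
    sig = mesh.element_tensors  # S/m
    Ne = mesh.n_elements
    Ke = np.zeros((Ne, 8, 8))
    for gp in _GP:
        dN = shape_gradients(gp)  # (8, 3)
        J = np.einsum("ia,eib->eab", dN, X)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            bad = int(np.argwhere(detJ <= 0)[0, 0])
            raise ValueError(f"singular or inverted geometry in element {bad}")
        Jinv = np.linalg.inv(J)
        G = np.einsum("ia,eab->eib", dN, Jinv)  # (Ne, 8, 3)
        SG = np.einsum("ebc,ejc->ejb", sig, G)
        Ke += np.einsum("eib,ejb,e->eij", G, SG, detJ)
    rows = np.repeat(mesh.elements, 8, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, 8)).ravel()
    K = sparse.coo_matrix((Ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
    K.sum_duplicates()
    return StiffnessMatrix(matrix=K, ground_node=int(ground_node))


@dataclass(frozen=True)
class VenantConfig:
    """Venant direct-approach parameters.

    The monopole loads live on the nodes sharing an element with the node
    nearest the dipole.  They are found by Tikhonov-regularized least
    squares matching the dipole's moments up to second order in the
    node offsets (scaled by ``reference_length``), under a hard zero-total-
    charge constraint.
    """

    moment_order: int = 2
    tikhonov: float = 1e-6
    reference_length: float = 20.0  # mm


def venant_loads(
    position_mm: np.ndarray,
    mesh: HexMesh,
    config: VenantConfig = VenantConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Venant monopole loads for unit moments at a position.

    Returns ``(node_indices, Q)`` where ``Q[:, d]`` are loads in amperes
    reproducing a 1 A*m dipole moment along Cartesian axis ``d``.  Loads sum
    to zero exactly (hard constraint).
    """
    position_mm = np.asarray(position_mm, float)
    if mesh.element_at(position_mm) < 0:
        raise ValueError(f"dipole position {position_mm} is outside the mesh")
    _, nearest = mesh.node_tree().query(position_mm)
    elems = mesh.elements_of_node(int(nearest))
    nbrs = np.unique(mesh.elements[elems].ravel())
    dx = (mesh.nodes[nbrs] - position_mm) * 1e-3  # m
    aref = config.reference_length * 1e-3
    s = dx / aref  # dimensionless offsets
    k = len(nbrs)

    # moment-matching rows (targets for a unit moment along each axis)
    rows = [s.T]  # first moments: sum q_i s_i,d = m_d / aref
    targets = [np.eye(3) / aref]
    if config.moment_order >= 2:
        rows.append((s**2).T)  # pure second moments -> 0
        targets.append(np.zeros((3, 3)))
        mixed = np.stack([s[:, 0] * s[:, 1], s[:, 0] * s[:, 2], s[:, 1] * s[:, 2]])
        rows.append(mixed)  # mixed second moments -> 0
        targets.append(np.zeros((3, 3)))
    A = np.vstack(rows)  # (n_rows, k)
    B = np.vstack(targets)  # (n_rows, 3)

    # hard zero-sum constraint: parametrize loads in the sum-zero subspace
    from scipy.linalg import null_space

    Z = null_space(np.ones((1, k)))  # (k, k-1)
    AZ = A @ Z
    M = AZ.T @ AZ + config.tikhonov * (Z.T @ Z)
    Y = np.linalg.solve(M, AZ.T @ B)
    Q = Z @ Y  # (k, 3), amperes per 1 A*m moment
    Q -= Q.mean(axis=0)  # exact charge balance (removes SVD round-off)
    return nbrs, Q


def venant_rhs(dipole: DipoleSource, mesh: HexMesh, config: VenantConfig = VenantConfig()) -> sparse.csr_matrix:
    """Sparse FE load vector (amperes) for a dipole with moment in nA*m."""
    nbrs, Q = venant_loads(dipole.position, mesh, config)
    loads = Q @ (dipole.moment * 1e-9)
    rhs = sparse.csr_matrix(
        (loads, (nbrs, np.zeros(len(nbrs), dtype=int))), shape=(mesh.n_nodes, 1)
    )
    return rhs


def solve_potential(K: StiffnessMatrix, rhs, tol: float = 1e-9, maxiter: int = 500) -> np.ndarray:
    """Mean-zero node potentials (volts) for a charge-balanced load vector."""
    if sparse.issparse(rhs):
        rhs = np.asarray(rhs.todense()).ravel()
    return K.solve(rhs, tol=tol, maxiter=maxiter)


# ---------------------------------------------------------------------------
# transfer matrices
# ---------------------------------------------------------------------------


@dataclass
class TransferMatrix:
    """Dense sensors x FE-nodes matrix turning load vectors into read-outs."""

    matrix: np.ndarray
    modality: str
    names: list[str]
    snapped_nodes: np.ndarray | None = None  # EEG: electrode collocation nodes


def _boundary_nodes(mesh: HexMesh) -> np.ndarray:
    indptr, _ = mesh.node_element_adjacency()
    return np.flatnonzero(np.diff(indptr) < 8)


def eeg_transfer(
    K: StiffnessMatrix,
    sensors: SensorArray,
    mesh: HexMesh,
    snap_tolerance: float = 10.0,
    tol: float = 1e-9,
    maxiter: int = 500,
) -> TransferMatrix:
    """Average-referenced EEG transfer matrix (one AMG-CG solve per electrode).

    Electrodes are collocated with the nearest mesh-surface node; electrodes
    farther than ``snap_tolerance`` mm from the surface raise an error.
    Row s of the result is the (mean-zero) solution of ``K t = r_s`` with
    ``r_s`` the snapped-electrode-minus-average read-out vector, so
    ``T @ b`` equals the average-referenced electrode potentials of the
    direct solve for any load vector ``b``.
    """
    surf = _boundary_nodes(mesh)
    from scipy.spatial import cKDTree

    tree = cKDTree(mesh.nodes[surf])
    d, idx = tree.query(sensors.eeg_positions)
    if np.any(d > snap_tolerance):
        bad = [
            f"{sensors.eeg_labels[i]} ({d[i]:.1f} mm)"
            for i in np.flatnonzero(d > snap_tolerance)
        ]
        raise ValueError(f"electrodes farther than {snap_tolerance} mm from the surface: {bad}")
    snapped = surf[idx]
    n = len(snapped)
    T = np.empty((n, mesh.n_nodes))
    for i, node in enumerate(snapped):
        r = np.zeros(mesh.n_nodes)
        r[node] += 1.0
        np.add.at(r, snapped, -1.0 / n)
        T[i] = K.solve(r, tol=tol, maxiter=maxiter)
    return TransferMatrix(matrix=T, modality="eeg", names=list(sensors.eeg_labels), snapped_nodes=snapped)


def _coil_rows(mesh: HexMesh, positions: np.ndarray, orientations: np.ndarray) -> np.ndarray:
    """Secondary-field read-out rows: row @ u = n . B_sec(p) in tesla.

    One-point (centroid) quadrature of the volume-current integral
    B_sec(p) = -mu0/4pi * int sigma grad(u) x (p - x)/|p - x|^3 dV.
    """
    if mesh.element_tensors is None:
        raise ValueError("mesh has no conductivity tensors assigned")
    X, grad0, vol, centroids = _element_operator(mesh)
    sig_grad = np.einsum("eab,eib->eia", mesh.element_tensors, grad0)  # (Ne, 8, 3)
    rows = np.zeros((len(positions), mesh.n_nodes))
    for c, (p, ori) in enumerate(zip(positions * 1e-3, orientations)):
        diff = p[None, :] - centroids
        k = diff / np.linalg.norm(diff, axis=1, keepdims=True) ** 3  # (Ne, 3)
        cxk = np.cross(sig_grad, k[:, None, :])  # (Ne, 8, 3)
        contrib = -MU0_OVER_4PI * vol[:, None] * (cxk @ ori)
        np.add.at(rows[c], mesh.elements.ravel(), contrib.ravel())
    return rows


def meg_secondary_matrix(mesh: HexMesh, sensors: SensorArray) -> np.ndarray:
    """Per-channel secondary-field read-out rows (channels x nodes, tesla).

    Magnetometers read ``n . B`` at the coil center; axial gradiometers read
    the difference between the near coil and a second coil displaced by the
    baseline along the coil orientation (near minus far).
    """
    for p in sensors.meg_centers:
        if mesh.element_at(p) >= 0:
            raise ValueError(f"MEG coil at {p} lies inside the head volume")
    rows = _coil_rows(mesh, sensors.meg_centers, sensors.meg_orientations)
    if sensors.meg_type == "axial_gradiometer":
        far = sensors.meg_centers + sensors.baseline * sensors.meg_orientations
        rows = rows - _coil_rows(mesh, far, sensors.meg_orientations)
    return rows


def meg_transfer(
    K: StiffnessMatrix,
    sensors: SensorArray,
    mesh: HexMesh,
    tol: float = 1e-9,
    maxiter: int = 500,
) -> TransferMatrix:
    """MEG transfer matrix: one AMG-CG solve per channel row of the
    secondary-field matrix (the primary field is added at leadfield time)."""
    S = meg_secondary_matrix(mesh, sensors)
    T = np.empty_like(S)
    for c in range(len(S)):
        # S rows are gradient-based read-outs, hence charge-balanced up to
        # round-off; project out the residual constant component
        r = S[c] - S[c].mean()
        T[c] = K.solve(r, tol=tol, maxiter=maxiter)
    return TransferMatrix(matrix=T, modality="meg", names=list(sensors.meg_labels))


def _primary_rows(sensors: SensorArray, position_mm: np.ndarray) -> np.ndarray:
    """(n_channels, 3) primary-field read-out per unit (1 A*m) moment axis."""

    def at(points):
        d = (points - position_mm) * 1e-3
        dn = np.linalg.norm(d, axis=1, keepdims=True) ** 3
        # n . (m x d)/|d|^3 = m . (d x n)/|d|^3
        return MU0_OVER_4PI * np.cross(d, sensors.meg_orientations) / dn

    B = at(sensors.meg_centers)
    if sensors.meg_type == "axial_gradiometer":
        B = B - at(sensors.meg_centers + sensors.baseline * sensors.meg_orientations)
    return B


# ---------------------------------------------------------------------------
# leadfields
# ---------------------------------------------------------------------------


@dataclass
class LeadfieldSet:
    """Row-stacked multimodal gain matrix: sensors x (3 * n_sources).

    Units per column triple (unit Cartesian moments of 1 nA*m): EEG rows in
    microvolts, MEG rows in femtotesla.
    """

    matrix: np.ndarray
    row_modality: np.ndarray  # 'eeg' | 'meg' per row
    row_names: list[str]
    source_positions: np.ndarray  # (n_src, 3) mm
    source_nearest_node: np.ndarray
    spacing: float  # mm, source-space grid spacing
    units: dict = field(default_factory=lambda: {"eeg": "uV/nAm", "meg": "fT/nAm"})

    def __post_init__(self):
        self.row_modality = np.asarray(self.row_modality)
        if self.matrix.shape != (len(self.row_modality), 3 * len(self.source_positions)):
            raise ValueError("leadfield shape mismatch")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("leadfield contains non-finite entries")

    @property
    def n_sources(self) -> int:
        return len(self.source_positions)

    def block(self, modality: str) -> "LeadfieldSet":
        sel = self.row_modality == modality
        return LeadfieldSet(
            matrix=self.matrix[sel],
            row_modality=self.row_modality[sel],
            row_names=[n for n, m in zip(self.row_names, self.row_modality) if m == modality],
            source_positions=self.source_positions,
            source_nearest_node=self.source_nearest_node,
            spacing=self.spacing,
            units=self.units,
        )

    def source_spacing_hint(self) -> float:
        return self.spacing

    def source_space_hash(self) -> str:
        return hashlib.sha256(np.ascontiguousarray(self.source_positions).tobytes()).hexdigest()

    def column_block(self, j: int) -> np.ndarray:
        return self.matrix[:, 3 * j : 3 * j + 3]


def compute_leadfields(
    K: StiffnessMatrix,
    mesh: HexMesh,
    source_space: SourceSpace,
    sensors: SensorArray,
    eeg: TransferMatrix | None = None,
    meg: TransferMatrix | None = None,
    venant: VenantConfig = VenantConfig(),
) -> LeadfieldSet:
    """Assemble the multimodal leadfield from transfer matrices.

    Each source contributes three columns (unit Cartesian moments of
    1 nA*m); EEG and MEG channel blocks are row-stacked, EEG first.
    """
    if len(source_space) == 0:
        raise ValueError("empty source space")
    if eeg is None and meg is None:
        raise ValueError("need at least one transfer matrix")
    blocks, modality, names = [], [], []
    n_src = len(source_space)
    if eeg is not None:
        blocks.append(np.empty((eeg.matrix.shape[0], 3 * n_src)))
        modality += ["eeg"] * eeg.matrix.shape[0]
        names += eeg.names
    if meg is not None:
        blocks.append(np.empty((meg.matrix.shape[0], 3 * n_src)))
        modality += ["meg"] * meg.matrix.shape[0]
        names += meg.names

    for j, pos in enumerate(source_space.positions):
        nbrs, Q = venant_loads(pos, mesh, venant)
        i = 0
        if eeg is not None:
            # volts per A*m -> microvolts per nA*m: 1e6 * 1e-9 = 1e-3
            blocks[i][:, 3 * j : 3 * j + 3] = 1e-3 * (eeg.matrix[:, nbrs] @ Q)
            i += 1
        if meg is not None:
            sec = meg.matrix[:, nbrs] @ Q
            prim = _primary_rows(sensors, pos)
            # tesla per A*m -> femtotesla per nA*m: 1e15 * 1e-9 = 1e6
            blocks[i][:, 3 * j : 3 * j + 3] = 1e6 * (sec + prim)

    return LeadfieldSet(
        matrix=np.vstack(blocks),
        row_modality=np.array(modality),
        row_names=names,
        source_positions=source_space.positions.copy(),
        source_nearest_node=source_space.nearest_node.copy(),
        spacing=source_space.spacing,
    )


def meg_forward(
    K: StiffnessMatrix,
    sensors: SensorArray,
    mesh: HexMesh,
    source_space: SourceSpace,
    tol: float = 1e-9,
) -> LeadfieldSet:
    """MEG-only leadfield (transfer-matrix route); fT per nA*m."""
    T = meg_transfer(K, sensors, mesh, tol=tol)
    return compute_leadfields(K, mesh, source_space, sensors, eeg=None, meg=T)


def direct_leadfield_column(
    K: StiffnessMatrix,
    mesh: HexMesh,
    sensors: SensorArray,
    dipole: DipoleSource,
    eeg_snapped_nodes: np.ndarray | None = None,
    meg_secondary: np.ndarray | None = None,
    tol: float = 1e-9,
) -> dict[str, np.ndarray]:
    """Independent direct-solve route: one full FEM solve for one dipole.

    Returns per-modality sensor vectors (EEG microvolts average-referenced,
    MEG femtotesla).  Used to validate the transfer-matrix path.
    """
    rhs = venant_rhs(dipole, mesh)
    u = solve_potential(K, rhs, tol=tol)
    out: dict[str, np.ndarray] = {}
    if eeg_snapped_nodes is not None:
        v = u[eeg_snapped_nodes]
        out["eeg"] = (v - v.mean()) * 1e6
    if meg_secondary is not None:
        sec = meg_secondary @ u
        prim = _primary_rows(sensors, dipole.position) @ (dipole.moment * 1e-9)
        out["meg"] = (sec + prim) * 1e15
    return out
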