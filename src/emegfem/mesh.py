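"""Geometry-adapted hexahedral meshing and conductivity assignment.

A labeled voxel grid becomes a finite-element mesh with one trilinear
hexahedron per nonzero voxel.  Nodes on tissue interfaces are shifted toward
the local minority-tissue centroid to smooth the staircase boundary
("geometry adaptation"); the shift factor is capped so every element keeps a
positive Jacobian.  Conductivity is attached per element, either as an
isotropic scalar from a tissue table or as an anisotropic tensor derived from
diffusion MRI by a volume-normalized effective-medium rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .phantom import LabeledVoxelGrid, TensorField

logger = logging.getLogger(__name__)

__all__ = [
    "HexMesh",
    "ConductivityTable",
    "SourceSpace",
    "build_hex_mesh",
    "assign_conductivities",
    "map_dti_conductivity",
    "build_source_space",
    "element_volumes",
    "jacobian_dets",
]

#: Local corner ordering of a hexahedron (VTK convention): corners are the
#: voxel corners at offsets (i, j, k) listed in this order.
CORNER_OFFSETS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ]
)

# Gauss 2x2x2 quadrature on [-1, 1]^3, unit weights
_GP = np.array(
    [[sx, sy, sz] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)], float
) / np.sqrt(3.0)


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """(8, 3) reference-coordinate gradients of the trilinear shape functions."""
    signs = 2.0 * CORNER_OFFSETS - 1.0  # corner signs in [-1, 1]^3
    one = 1.0 + signs * xi  # (8, 3)
    g = np.empty((8, 3))
    g[:, 0] = signs[:, 0] * one[:, 1] * one[:, 2] / 8.0
    g[:, 1] = signs[:, 1] * one[:, 0] * one[:, 2] / 8.0
    g[:, 2] = signs[:, 2] * one[:, 0] * one[:, 1] / 8.0
    return g


@dataclass
class HexMesh:
    """Hexahedral FE mesh in mm with per-element conductivity tensors."""

    nodes: np.ndarray  # (n_nodes, 3) mm
    elements: np.ndarray  # (n_elem, 8) node indices, CORNER_OFFSETS order
    element_labels: np.ndarray  # (n_elem,) tissue labels
    voxel_size: float
    origin: np.ndarray  # of the underlying voxel grid
    element_voxels: np.ndarray  # (n_elem, 3) voxel index per element
    grid_shape: tuple[int, int, int]
    label_table: dict[int, str]
    element_tensors: np.ndarray | None = None  # (n_elem, 3, 3) S/m

    _node_tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _node_elems: tuple | None = field(default=None, repr=False, compare=False)
    _voxel_to_elem: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def node_tree(self) -> cKDTree:
        if self._node_tree is None:
            self._node_tree = cKDTree(self.nodes)
        return self._node_tree

    def node_element_adjacency(self):
        """CSR-style (indptr, indices): elements touching each node."""
        if self._node_elems is None:
            elem_ids = np.repeat(np.arange(self.n_elements), 8)
            order = np.argsort(self.elements.ravel(), kind="stable")
            sorted_nodes = self.elements.ravel()[order]
            counts = np.bincount(sorted_nodes, minlength=self.n_nodes)
            indptr = np.concatenate([[0], np.cumsum(counts)])
            self._node_elems = (indptr, elem_ids[order])
        return self._node_elems

    def elements_of_node(self, node: int) -> np.ndarray:
        indptr, indices = self.node_element_adjacency()
        return indices[indptr[node] : indptr[node + 1]]

    def voxel_to_element(self) -> np.ndarray:
        """Dense voxel-index -> element-id lookup (-1 where no element)."""
        if self._voxel_to_elem is None:
            lut = np.full(self.grid_shape, -1, dtype=np.int64)
            lut[tuple(self.element_voxels.T)] = np.arange(self.n_elements)
            self._voxel_to_elem = lut
        return self._voxel_to_elem

    def element_at(self, point) -> int:
        """Element containing a point (by voxel box), or -1."""
        ijk = np.floor((np.asarray(point, float) - self.origin) / self.voxel_size).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= np.array(self.grid_shape)):
            return -1
        return int(self.voxel_to_element()[tuple(ijk)])

    def corner_coords(self) -> np.ndarray:
        """(n_elem, 8, 3) corner coordinates in mm."""
        return self.nodes[self.elements]


def jacobian_dets(mesh: HexMesh) -> np.ndarray:
    """(n_elem, 8) Jacobian determinants at the element corners (mm^3 scale)."""
    X = mesh.corner_coords()
    dets = np.empty((mesh.n_elements, 8))
    for c, off in enumerate(CORNER_OFFSETS):
        dN = shape_gradients(2.0 * off - 1.0)  # evaluate at the corner
        J = np.einsum("ia,eib->eab", dN, X)
        dets[:, c] = np.linalg.det(J)
    return dets


def element_volumes(mesh: HexMesh) -> np.ndarray:
    """Exact trilinear element volumes via 2x2x2 quadrature (mm^3)."""
    X = mesh.corner_coords()
    vol = np.zeros(mesh.n_elements)
    for gp in _GP:
        dN = shape_gradients(gp)
        J = np.einsum("ia,eib->eab", dN, X)
        vol += np.linalg.det(J)
    return vol


def build_hex_mesh(grid: LabeledVoxelGrid, node_shift_factor: float = 0.33) -> HexMesh:
    """One hexahedral element per nonzero voxel, with interface smoothing.

    Every node adjacent to voxels of more than one label (the background
    counts as label 0) is moved by ``node_shift_factor`` of the way toward
    the centroid of the adjacent voxel *centers* carrying the locally rarest
    label.  Ties in the label counts leave the node in place; interior nodes
    (single label all around) are never moved.  Factors up to 0.49 keep all
    corner Jacobians positive, which is asserted.
    """
    if not 0 <= node_shift_factor <= 0.49:
        raise ValueError("node_shift_factor must be in [0, 0.49]")
    labels = grid.labels
    nx, ny, nz = labels.shape
    vox = np.argwhere(labels != 0)
    if len(vox) == 0:
        raise ValueError("grid has no nonzero voxels")
    h = grid.voxel_size

    # global lattice node ids -> compact ids for used nodes
    corner_idx = vox[:, None, :] + CORNER_OFFSETS[None, :, :]  # (Ne, 8, 3)
    flat = np.ravel_multi_index(
        tuple(corner_idx.reshape(-1, 3).T), (nx + 1, ny + 1, nz + 1)
    )
    used, inverse = np.unique(flat, return_inverse=True)
    elements = inverse.reshape(-1, 8)
    lattice = np.column_stack(np.unravel_index(used, (nx + 1, ny + 1, nz + 1)))
    nodes = grid.origin + lattice * h

    if node_shift_factor > 0:
        nodes = _shift_interface_nodes(nodes, lattice, labels, h, grid.origin, node_shift_factor)

    mesh = HexMesh(
        nodes=nodes,
        elements=elements,
        element_labels=labels[tuple(vox.T)].astype(int),
        voxel_size=h,
        origin=grid.origin,
        element_voxels=vox,
        grid_shape=labels.shape,
        label_table=dict(grid.label_table),
    )
    dets = jacobian_dets(mesh)
    if np.any(dets <= 0):
        bad = int(np.argwhere(np.any(dets <= 0, axis=1))[0, 0])
        raise RuntimeError(f"non-positive Jacobian in element {bad} after node shift")
    return mesh


def _shift_interface_nodes(nodes, lattice, labels, h, origin, factor):
    """Move interface nodes toward the rarest adjacent-voxel-label centroid."""
    nx, ny, nz = labels.shape
    n_nodes = len(lattice)
    # adjacent voxels of each lattice node: offsets (-1, 0) in each axis
    adj_label = np.full((n_nodes, 8), -1, dtype=int)  # -1: off-grid
    adj_center = np.zeros((n_nodes, 8, 3))
    for a, off in enumerate(CORNER_OFFSETS - 1):  # offsets in {-1, 0}^3
        vidx = lattice + off
        inside = np.all((vidx >= 0) & (vidx < [nx, ny, nz]), axis=1)
        lab = np.zeros(n_nodes, dtype=int)
        lab[inside] = labels[tuple(vidx[inside].T)]
        adj_label[:, a] = np.where(inside, lab, 0)  # off-grid counts as background
        adj_center[:, a] = origin + (vidx + 0.5) * h

    mixed = ~np.all(adj_label == adj_label[:, :1], axis=1)
    new_nodes = nodes.copy()
    for i in np.flatnonzero(mixed):
        labs = adj_label[i]
        uniq, counts = np.unique(labs, return_counts=True)
        cmin = counts.min()
        rare = uniq[counts == cmin]
        if len(rare) > 1:
            continue  # tied minority: deterministic no-op
        sel = labs == rare[0]
        target = adj_center[i, sel].mean(axis=0)
        new_nodes[i] = nodes[i] + factor * (target - nodes[i])
    return new_nodes


@dataclass(frozen=True)
class ConductivityTable:
    """Tissue label -> isotropic conductivity in S/m."""

    values: dict[int, float]

    def __post_init__(self):
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("conductivities must be > 0")

    def __getitem__(self, label: int) -> float:
        return self.values[label]


def assign_conductivities(mesh: HexMesh, table: ConductivityTable) -> HexMesh:
    """Isotropic per-element tensors sigma * I from a tissue table (in place
    on a shallow copy of the mesh)."""
    present = set(np.unique(mesh.element_labels).tolist())
    missing = sorted(present - set(table.values))
    if missing:
        raise KeyError(f"no conductivity for labels {missing}")
    sig = np.zeros(mesh.n_elements)
    for lab in present:
        sig[mesh.element_labels == lab] = table[lab]
    tensors = sig[:, None, None] * np.eye(3)[None]
    return _with_tensors(mesh, tensors)


def _with_tensors(mesh: HexMesh, tensors: np.ndarray) -> HexMesh:
    import copy

    out = copy.copy(mesh)
    out.element_tensors = tensors
    return out


def map_dti_conductivity(
    mesh: HexMesh,
    dti: TensorField,
    wm_label: int,
    iso_reference: float = 0.14,
    scaling: str = "volume",
) -> HexMesh:
    """Anisotropic WM conductivity tensors from diffusion tensors.

    The conductivity tensor of each WM element shares the eigenvectors of
    the diffusion tensor of the element's voxel.  Eigenvalues are set by the
    effective-medium rule selected with ``scaling``:

    * ``"volume"`` (default): eigenvalues scaled so their product equals
      ``iso_reference**3`` -- the tensor has the same determinant (volume)
      as the isotropic reference, preserving the geometric-mean
      conductivity.
    * ``"linear"``: conductivity eigenvalues directly proportional to the
      diffusion eigenvalues, ``sigma_i = iso_reference * d_i / mean(d)``.

    Non-WM elements keep their existing tensors (which must already be
    assigned).  Non-positive diffusion eigenvalues are clamped to 1e-6 of
    the largest eigenvalue with a logged warning.
    """
    if dti.kind != "diffusion":
        raise ValueError("need a diffusion tensor field")
    if iso_reference <= 0:
        raise ValueError("iso_reference must be > 0")
    if scaling not in ("volume", "linear"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if mesh.element_tensors is None:
        raise ValueError("assign isotropic conductivities before mapping DTI")

    tensors = mesh.element_tensors.copy()
    wm_elems = np.flatnonzero(mesh.element_labels == wm_label)
    if len(wm_elems) == 0:
        return _with_tensors(mesh, tensors)
    D = dti.tensors[tuple(mesh.element_voxels[wm_elems].T)]
    w, V = np.linalg.eigh(D)  # ascending eigenvalues, orthonormal eigenvectors
    bad = w <= 0
    if bad.any():
        logger.warning(
            "clamping %d non-positive diffusion eigenvalues in %d WM elements",
            int(bad.sum()),
            int(np.any(bad, axis=1).sum()),
        )
        floor = 1e-6 * w[:, -1:].clip(min=1e-300)
        w = np.maximum(w, floor)
    if scaling == "volume":
        geo = np.prod(w, axis=1) ** (1.0 / 3.0)
        sig_eig = iso_reference * w / geo[:, None]
    else:
        sig_eig = iso_reference * w / w.mean(axis=1)[:, None]
    tensors[wm_elems] = np.einsum("nik,nk,njk->nij", V, sig_eig, V)
    return _with_tensors(mesh, tensors)


@dataclass
class SourceSpace:
    """Venant-admissible dipole positions inside gray matter."""

    positions: np.ndarray  # (n, 3) mm
    nearest_node: np.ndarray  # (n,) FE node index
    spacing: float  # mm

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")

    def __len__(self) -> int:
        return len(self.positions)


def venant_condition_ok(mesh: HexMesh, node: int, gm_label: int) -> bool:
    """True if every element touching the node is gray matter."""
    elems = mesh.elements_of_node(node)
    return len(elems) > 0 and bool(np.all(mesh.element_labels[elems] == gm_label))


def build_source_space(
    mesh: HexMesh,
    gm_label: int,
    spacing: float = 2.0,
    condition: str = "node",
) -> SourceSpace:
    """Regular-grid source space restricted to gray matter.

    Candidates sit on an axis-aligned grid of the requested spacing, seeded
    at the GM centroid.  With ``condition="node"`` (the strict Venant
    admissibility used by default) a candidate is admitted iff *every*
    element containing its nearest FE node is GM-labeled, which keeps the
    Venant monopole loads of any admitted dipole inside gray matter.
    ``condition="element"`` only requires the candidate's containing element
    to be GM (the laxer variant).
    """
    if spacing < mesh.voxel_size:
        raise ValueError("spacing must be >= voxel size")
    if condition not in ("node", "element"):
        raise ValueError(f"unknown condition {condition!r}")
    gm_elems = mesh.element_labels == gm_label
    if not gm_elems.any():
        raise ValueError(f"mesh has no elements with GM label {gm_label}")
    centers = mesh.origin + (mesh.element_voxels[gm_elems] + 0.5) * mesh.voxel_size
    centroid = centers.mean(axis=0)
    lo = centers.min(axis=0)
    hi = centers.max(axis=0)
    axes = [
        np.concatenate(
            [np.arange(centroid[d], lo[d] - 1e-9, -spacing)[::-1], np.arange(centroid[d] + spacing, hi[d] + 1e-9, spacing)]
        )
        for d in range(3)
    ]
    G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    lut = mesh.voxel_to_element()
    ijk = np.floor((G - mesh.origin) / mesh.voxel_size).astype(int)
    inside = np.all((ijk >= 0) & (ijk < np.array(mesh.grid_shape)), axis=1)
    elem = np.full(len(G), -1, dtype=np.int64)
    elem[inside] = lut[tuple(ijk[inside].T)]
    ok = elem >= 0
    ok[ok] = mesh.element_labels[elem[ok]] == gm_label
    cand = G[ok]
    if len(cand) == 0:
        raise ValueError("no source-space candidates inside GM; thicken the GM compartment")
    _, nearest = mesh.node_tree().query(cand)

    if condition == "node":
        indptr, indices = mesh.node_element_adjacency()
        is_gm_elem = gm_elems
        admit = np.array(
            [bool(np.all(is_gm_elem[indices[indptr[n] : indptr[n + 1]]])) for n in nearest]
        )
    else:
        admit = np.ones(len(cand), dtype=bool)
    if not admit.any():
        raise ValueError(
            "the Venant admissibility condition excludes every candidate; "
            "thicken the GM compartment or coarsen the source grid"
        )
    return SourceSpace(positions=cand[admit], nearest_node=nearest[admit], spacing=float(spacing))
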