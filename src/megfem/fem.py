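"""Finite-element MEG forward solution.

The scalar electric potential of a current dipole in the head is computed
with trilinear isoparametric hexahedral finite elements (pure-Neumann
problem, zero-mean gauge).  The dipole is represented by a Venant load:
balanced monopole sources on the lattice nodes surrounding the source,
matched to the dipole moment.  The magnetic flux density at the gradiometers
splits into the primary (Biot--Savart field of the isolated dipole) and
secondary part (Biot--Savart integral over the ohmic volume currents
``-sigma grad u``); the secondary part is accelerated by per-channel
transfer vectors so that evaluating a new dipole requires no linear solve.

Units: positions mm, moments uAmm, conductivity S/m, output fT (conversions
centralized in :mod:`megfem.units`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as sparse_linalg

from .hexmesh import HEX_CORNERS, HexMesh, mesh_quality
from .phantom import BRAIN_LABELS, SensorArray, Tissue
from .units import MM_TO_M, MU0_OVER_4PI, T_TO_FT, UAMM_TO_AM


@dataclass(frozen=True)
class Dipole:
    """A current dipole: position in mm, moment vector in uAmm."""

    position: tuple[float, float, float]
    moment: tuple[float, float, float]

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)

    @property
    def mom(self) -> np.ndarray:
        return np.asarray(self.moment, dtype=float)

    @property
    def strength(self) -> float:
        """|moment| in uAmm (forward-simulation default is 130 uAmm)."""
        return float(np.linalg.norm(self.mom))


@dataclass
class FieldMap:
    """Per-channel gradiometer flux density in fT for one configuration."""

    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field map contains non-finite values")

    @property
    def n_channels(self) -> int:
        return len(self.values)

    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


# ---------------------------------------------------------------------------
# trilinear shape functions on the unit cube [0, 1]^3
# ---------------------------------------------------------------------------

def _shape_values(xi: np.ndarray) -> np.ndarray:
    """(8,) trilinear shape function values at reference point xi."""
    vals = np.ones(8)
    for d in range(3):
        vals = vals * np.where(HEX_CORNERS[:, d] == 1, xi[d], 1.0 - xi[d])
    return vals


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """(8, 3) reference-coordinate gradients dN/dxi at point xi."""
    grads = np.empty((8, 3))
    for d in range(3):
        g = np.ones(8)
        for e in range(3):
            if e == d:
                g = g * np.where(HEX_CORNERS[:, e] == 1, 1.0, -1.0)
            else:
                g = g * np.where(HEX_CORNERS[:, e] == 1, xi[e], 1.0 - xi[e])
        grads[:, d] = g
    return grads


def _gauss_points():
    """8-point Gauss rule on [0, 1]^3: (xi, weight) pairs, sum w = 1."""
    a = 0.5 - 0.5 / np.sqrt(3.0)
    b = 0.5 + 0.5 / np.sqrt(3.0)
    for x in (a, b):
        for y in (a, b):
            for z in (a, b):
                yield np.array([x, y, z]), 0.125


# ---------------------------------------------------------------------------
# stiffness assembly and solution
# ---------------------------------------------------------------------------

@dataclass
class StiffnessSystem:
    """Assembled FEM operator over node potentials (pure Neumann).

    ``matrix`` is symmetric positive semi-definite with zero row sums; the
    gauge is fixed by returning zero-mean potentials.  ``solve`` guarantees a
    relative residual <= ``tol`` regardless of the method: "pcg" (default)
    runs diagonally preconditioned conjugate gradients on the consistent
    singular system, "direct" uses a cached sparse LU factorization of the
    grounded system.
    """

    matrix: sparse.csr_matrix
    tol: float = 1e-8
    method: str = "pcg"
    _factor: object = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def _reduced(self) -> sparse.csc_matrix:
        # ground node 0 to remove the constant null space
        return self.matrix[1:, :][:, 1:].tocsc()

    def solve(self, load: np.ndarray) -> np.ndarray:
        """Node potentials (V, zero mean) for a balanced load vector (A)."""
        load = np.asarray(load, dtype=float)
        bnorm = np.linalg.norm(load)
        if bnorm == 0.0:
            return np.zeros(self.n)
        target = load
        u = np.zeros(self.n)
        if self.method == "direct":
            if self._factor is None:
                self._factor = sparse_linalg.splu(self._reduced())
            u[1:] = self._factor.solve(load[1:])
        elif self.method == "pcg":
            # consistent singular system: demean the load, precondition
            # with the (SPD) Jacobi diagonal
            b = target = load - load.mean()
            diag = self.matrix.diagonal()
            M = sparse_linalg.LinearOperator(
                self.matrix.shape, lambda x: x / diag)
            x, info = sparse_linalg.cg(
                self.matrix, b, rtol=self.tol * 0.1, atol=0.0,
                maxiter=20000, M=M)
            if info != 0:
                res = np.linalg.norm(self.matrix @ x - b) / bnorm
                raise RuntimeError(
                    f"PCG did not converge (info={info}, relative residual "
                    f"{res:.2e})"
                )
            u = x
        else:
            raise ValueError(f"unknown solver method {self.method!r}")
        residual = np.linalg.norm(self.matrix @ u - target) / bnorm
        if residual > self.tol:
            raise RuntimeError(
                f"solver residual {residual:.2e} exceeds tolerance {self.tol}"
            )
        return u - u.mean()

    def solve_many(self, loads: np.ndarray) -> np.ndarray:
        return np.vstack([self.solve(b) for b in loads])

    def release_factor(self) -> None:
        """Free a cached factorization (it is rebuilt on demand)."""
        self._factor = None


def assemble_stiffness(mesh: HexMesh, tol: float = 1e-8,
                       method: str = "pcg",
                       check_quality: bool = True) -> StiffnessSystem:
    """Assemble the trilinear isoparametric stiffness matrix.

    8-point Gauss quadrature per element; entries in siemens (potentials in
    volts, loads in amperes).
    """
    if check_quality:
        q = mesh_quality(mesh)
        if q.n_degenerate > 0:
            raise ValueError(
                f"mesh has {q.n_degenerate} degenerate elements "
                f"(min corner Jacobian {q.min_jacobian:.3e} mm^3)"
            )
    coords = mesh.nodes[mesh.elements] * MM_TO_M           # (E, 8, 3)
    sigma = mesh.element_conductivity                      # (E,)
    Ke = np.zeros((mesh.n_elements, 8, 8))
    for xi, w in _gauss_points():
        dN = _shape_gradients(xi)                          # (8, 3)
        J = np.einsum("eni,nj->eij", coords, dN)           # (E, 3, 3)
        detJ = np.linalg.det(J)
        invJ = np.linalg.inv(J)
        gradN = np.einsum("nj,eji->eni", dN, invJ)         # (E, 8, 3)
        Ke += (w * sigma * detJ)[:, None, None] * \
            np.einsum("eni,emi->enm", gradN, gradN)
    rows = np.repeat(mesh.elements, 8, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, 8)).ravel()
    K = sparse.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()
    return StiffnessSystem(K, tol=tol, method=method)


# ---------------------------------------------------------------------------
# Venant source load
# ---------------------------------------------------------------------------

@dataclass
class SourceLoad:
    """Sparse balanced monopole load (A) on nodes near a dipole."""

    indices: np.ndarray
    values: np.ndarray
    n: int

    def to_dense(self) -> np.ndarray:
        b = np.zeros(self.n)
        b[self.indices] = self.values
        return b

    def total(self) -> float:
        return float(self.values.sum())

    def first_moment(self, about_mm: np.ndarray,
                     nodes_mm: np.ndarray) -> np.ndarray:
        """Dipole moment (uAmm) of the monopole set about a point."""
        rel = nodes_mm[self.indices] - np.asarray(about_mm, dtype=float)
        return (self.values[:, None] * rel).sum(axis=0) / 1e-6


def venant_load(mesh: HexMesh, dipole: Dipole,
                warn_nonbrain: bool = True) -> SourceLoad:
    """Balanced monopole loads representing the dipole (Venant approach).

    The neighborhood is the node closest to the dipole plus all nodes
    sharing an element with it.  The monopole vector is the minimum-norm
    solution matching the zeroth moment (sum zero, exactly) and the first
    moment about the dipole position (equal to the dipole moment, exactly),
    with coordinates scaled by the voxel size for conditioning.
    """
    pos = dipole.pos
    dist, nearest = mesh.node_tree().query(pos)
    if dist > mesh.voxel_size * np.sqrt(3.0):
        raise ValueError(
            f"dipole at {tuple(pos)} lies outside the mesh "
            f"(nearest node {dist:.2f} mm away)"
        )
    elems = mesh.elements_of_node(int(nearest))
    if warn_nonbrain:
        labels = set(int(l) for l in mesh.element_label[elems])
        if not labels & {int(l) for l in BRAIN_LABELS}:
            warnings.warn(
                f"dipole at {tuple(pos)} is not inside brain tissue "
                f"(adjacent labels: {sorted(Tissue(l).name for l in labels)})",
                stacklevel=2,
            )
    neigh = np.unique(mesh.elements[elems].ravel())

    if np.allclose(dipole.mom, 0.0):
        return SourceLoad(neigh, np.zeros(len(neigh)), mesh.n_nodes)

    a = mesh.voxel_size
    rel = (mesh.nodes[neigh] - pos) / a                     # dimensionless
    C = np.vstack([np.ones(len(neigh)), rel.T])             # (4, K)
    d = np.concatenate([[0.0], dipole.mom / a])             # moment in uAmm
    q, *_ = np.linalg.lstsq(C, d, rcond=None)               # min-norm, uA
    return SourceLoad(neigh, q * 1e-6, mesh.n_nodes)        # A


# ---------------------------------------------------------------------------
# magnetic fields
# ---------------------------------------------------------------------------

def _dipole_field_T(points_m: np.ndarray, pos_m: np.ndarray,
                    moment_Am: np.ndarray) -> np.ndarray:
    """Biot--Savart field (T) of an isolated current dipole at points (m)."""
    R = points_m - pos_m
    dist = np.linalg.norm(R, axis=-1)
    if np.any(dist < 1e-9):
        raise ValueError("field point coincides with the dipole position")
    return MU0_OVER_4PI * np.cross(moment_Am, R) / dist[:, None] ** 3


def _coil_points(centers_mm: np.ndarray, axes: np.ndarray,
                 radius_mm: float | None) -> np.ndarray:
    """(m, q, 3) quadrature points (m) for each coil.

    Point coils use the center; a finite radius uses a 4-point rule on the
    coil disc (points at radius/sqrt(2), exact for quadratic variation).
    """
    centers = centers_mm * MM_TO_M
    if radius_mm is None:
        return centers[:, None, :]
    r = radius_mm * MM_TO_M / np.sqrt(2.0)
    # in-plane orthonormal basis per coil
    ref = np.where(np.abs(axes[:, :1]) < 0.9,
                   np.tile([1.0, 0.0, 0.0], (len(axes), 1)),
                   np.tile([0.0, 1.0, 0.0], (len(axes), 1)))
    u = np.cross(axes, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(axes, u)
    offsets = np.stack([u, v, -u, -v], axis=1) * r          # (m, 4, 3)
    return centers[:, None, :] + offsets


def primary_signal(dipole: Dipole, array: SensorArray) -> FieldMap:
    """Gradiometer map (fT) of the isolated dipole (primary field only).

    Channel value = mean bottom-coil axial field minus mean top-coil axial
    field.
    """
    pos_m = dipole.pos * MM_TO_M
    mom = dipole.mom * UAMM_TO_AM
    values = np.zeros(array.n_channels)
    for coil_set, sign in ((array.positions, 1.0), (array.top_positions, -1.0)):
        pts = _coil_points(coil_set, array.axes, array.coil_radius)
        for q in range(pts.shape[1]):
            B = _dipole_field_T(pts[:, q], pos_m, mom)
            values += sign / pts.shape[1] * np.einsum("mi,mi->m", B, array.axes)
    return FieldMap(values * T_TO_FT,
                    meta={"component": "primary", "dipole": dipole})


def _centroid_geometry(mesh: HexMesh):
    """Element centroids (m), volumes (m^3), centroid gradients (E, 8, 3)."""
    coords = mesh.nodes[mesh.elements] * MM_TO_M
    centroids = coords.mean(axis=1)
    xi = np.array([0.5, 0.5, 0.5])
    dN = _shape_gradients(xi)
    J = np.einsum("eni,nj->eij", coords, dN)
    invJ = np.linalg.inv(J)
    gradN = np.einsum("nj,eji->eni", dN, invJ)              # 1/m
    vol = np.zeros(mesh.n_elements)
    for xig, w in _gauss_points():
        dNg = _shape_gradients(xig)
        Jg = np.einsum("eni,nj->eij", coords, dNg)
        vol += w * np.linalg.det(Jg)
    return centroids, vol, gradN


def _volume_secondary_vectors(mesh: HexMesh,
                              array: SensorArray) -> np.ndarray:
    """Volume-current route: centroid Biot--Savart per element.

    Retained as an independent cross-check of the surface formulation; its
    accuracy degrades near the source singularity, where the volume current
    of the trilinear potential is underresolved.
    """
    centroids, vol, gradN = _centroid_geometry(mesh)
    sigma = mesh.element_conductivity
    coeff = MU0_OVER_4PI * vol * (-sigma) * T_TO_FT          # (E,)
    W = np.zeros((array.n_channels, mesh.n_nodes))
    bot = _coil_points(array.positions, array.axes, array.coil_radius)
    top = _coil_points(array.top_positions, array.axes, array.coil_radius)
    for ch in range(array.n_channels):
        axis = array.axes[ch]
        d = np.zeros((mesh.n_elements, 3))
        for pts, sign in ((bot[ch], 1.0), (top[ch], -1.0)):
            for p in pts:
                R = p - centroids                            # (E, 3)
                dist3 = np.linalg.norm(R, axis=1) ** 3
                # axis . (J x R) = J . (R x axis)
                d += sign / len(pts) * np.cross(R, axis) / dist3[:, None]
        contrib = coeff[:, None] * np.einsum("eni,ei->en", gradN, d)
        np.add.at(W[ch], mesh.elements.ravel(), contrib.ravel())
    return W


#: per axis d: the in-face parameter axes (s, t) such that
#: ds x dt points along +d on an undistorted voxel
_FACE_PARAM_AXES = {0: (1, 2), 1: (2, 0), 2: (0, 1)}


def _face_corner_locals(d: int) -> tuple[np.ndarray, np.ndarray]:
    """Local node indices of the xi_d = 1 and xi_d = 0 faces.

    Each is ordered by the (s, t) parameter corners (0,0), (1,0), (0,1),
    (1,1) with (s, t) the axes of ``_FACE_PARAM_AXES[d]``.
    """
    s_ax, t_ax = _FACE_PARAM_AXES[d]
    out = []
    for val in (1, 0):
        idx = []
        for t in (0, 1):
            for s in (0, 1):
                corner = np.zeros(3, dtype=int)
                corner[d] = val
                corner[s_ax] = s
                corner[t_ax] = t
                idx.append(int(np.nonzero(
                    np.all(HEX_CORNERS == corner, axis=1))[0][0]))
        out.append(np.array(idx))
    return out[0], out[1]


def _conductivity_jump_faces(mesh: HexMesh):
    """Element faces across which the conductivity jumps.

    Returns (face_nodes (F, 4), jump (F,)) where ``face_nodes`` are ordered
    so that the bilinear surface element ds x dt points from the lower- to
    the higher-index neighbor (outward on boundary faces) and
    ``jump = sigma_far - sigma_near`` across that normal.
    """
    if mesh.element_ijk is None:
        raise ValueError("mesh lacks voxel indices (element_ijk)")
    ijk = mesh.element_ijk
    dims = ijk.max(axis=0) + 1
    lookup = np.full(tuple(dims), -1, dtype=np.int64)
    lookup[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = np.arange(mesh.n_elements)
    sigma = mesh.element_conductivity

    faces, jumps = [], []
    for d in range(3):
        hi_face, lo_face = _face_corner_locals(d)
        shifted = ijk.copy()
        shifted[:, d] += 1
        inside = shifted[:, d] < dims[d]
        neighbor = np.full(mesh.n_elements, -1, dtype=np.int64)
        neighbor[inside] = lookup[shifted[inside, 0], shifted[inside, 1],
                                  shifted[inside, 2]]
        sig_nb = np.where(neighbor >= 0, sigma[np.maximum(neighbor, 0)], 0.0)
        # +d faces: interior jumps counted once, plus the +d boundary
        active = sig_nb != sigma
        faces.append(mesh.elements[np.nonzero(active)[0]][:, hi_face])
        jumps.append((sig_nb - sigma)[active])
        # -d boundary faces (no neighbor at -d): outward normal is -d,
        # realized by swapping the (s, t) parameter order
        shifted = ijk.copy()
        shifted[:, d] -= 1
        inside = shifted[:, d] >= 0
        neighbor = np.full(mesh.n_elements, -1, dtype=np.int64)
        neighbor[inside] = lookup[shifted[inside, 0], shifted[inside, 1],
                                  shifted[inside, 2]]
        boundary = neighbor < 0
        flipped = lo_face[[0, 2, 1, 3]]
        faces.append(mesh.elements[np.nonzero(boundary)[0]][:, flipped])
        jumps.append(np.full(int(boundary.sum()), 0.0) - sigma[boundary])
    return np.vstack(faces), np.concatenate(jumps)


def _face_gauss_points():
    """2x2 Gauss rule on the unit face (s, t) in [0, 1]^2."""
    a = 0.5 - 0.5 / np.sqrt(3.0)
    b = 0.5 + 0.5 / np.sqrt(3.0)
    for s in (a, b):
        for t in (a, b):
            yield s, t, 0.25


def secondary_vectors(mesh: HexMesh, array: SensorArray,
                      method: str = "surface") -> np.ndarray:
    """(m, N) matrix W mapping node potentials (V) to secondary signals (fT).

    The default "surface" route uses the piecewise-homogeneous identity:
    the Biot--Savart integral over the volume currents ``-sigma grad u``
    equals a sum over conductivity-jump faces of

        (sigma_far - sigma_near) * integral_S u n x (r - r')/|r - r'|^3 dS,

    which avoids integrating the underresolved singular current around the
    source and evaluates the well-approximated potential on tissue
    interfaces instead.  The "volume" route (element-centroid quadrature of
    the volume currents) is kept as an independent cross-check.
    """
    if method == "volume":
        return _volume_secondary_vectors(mesh, array)
    if method != "surface":
        raise ValueError(f"unknown secondary-field method {method!r}")

    face_nodes, jump = _conductivity_jump_faces(mesh)
    coords = mesh.nodes[face_nodes] * MM_TO_M                # (F, 4, 3)
    W = np.zeros((array.n_channels, mesh.n_nodes))
    bot = _coil_points(array.positions, array.axes, array.coil_radius)
    top = _coil_points(array.top_positions, array.axes, array.coil_radius)
    for s, t, w in _face_gauss_points():
        # bilinear face shape functions, corner order (0,0),(1,0),(0,1),(1,1)
        N = np.array([(1 - s) * (1 - t), s * (1 - t),
                      (1 - s) * t, s * t])
        dNs = np.array([-(1 - t), (1 - t), -t, t])
        dNt = np.array([-(1 - s), -s, (1 - s), s])
        x = np.einsum("n,fni->fi", N, coords)                # (F, 3)
        ts = np.einsum("n,fni->fi", dNs, coords)
        tt = np.einsum("n,fni->fi", dNt, coords)
        m_vec = np.cross(ts, tt)                             # n dS, (F, 3)
        for ch in range(array.n_channels):
            axis = array.axes[ch]
            a_x_m = np.cross(axis, m_vec)                    # (F, 3)
            q = np.zeros(len(face_nodes))
            for pts, sign in ((bot[ch], 1.0), (top[ch], -1.0)):
                for p in pts:
                    R = p - x
                    dist3 = np.linalg.norm(R, axis=1) ** 3
                    # axis . (n x G) = G . (axis x n)
                    q += sign / len(pts) * \
                        np.einsum("fi,fi->f", a_x_m, R) / dist3
            contrib = (MU0_OVER_4PI * T_TO_FT * w * jump * q)[:, None] \
                * N[None, :]
            np.add.at(W[ch], face_nodes.ravel(), contrib.ravel())
    return W


@dataclass
class TransferSet:
    """Per-channel transfer vectors: secondary signal = T @ load.

    Reusable for every dipole in one head model; no further linear solves
    are needed once constructed.
    """

    T: np.ndarray                # (m, N), fT per A
    n_solves: int = 0            # solves spent building (diagnostic)

    @property
    def n_channels(self) -> int:
        return self.T.shape[0]

    def secondary(self, load: SourceLoad) -> np.ndarray:
        return self.T[:, load.indices] @ load.values


def meg_transfer(system: StiffnessSystem, mesh: HexMesh,
                 array: SensorArray) -> TransferSet:
    """Precompute transfer vectors t_i with K t_i = w_i per channel.

    For any balanced load b, ``t_i . b`` equals the directly computed
    secondary signal ``w_i . K^+ b`` (symmetry of K).
    """
    W = secondary_vectors(mesh, array)
    # project out the constant null space: the signal w . u is unchanged
    # for zero-mean potentials, and the Neumann system becomes consistent
    W = W - W.mean(axis=1, keepdims=True)
    T = np.vstack([system.solve(w) for w in W])
    return TransferSet(T, n_solves=len(W))


def secondary_signal_direct(system: StiffnessSystem, mesh: HexMesh,
                            array: SensorArray, load: SourceLoad) -> np.ndarray:
    """Reference path: solve the potential, then integrate volume currents."""
    u = system.solve(load.to_dense())
    return secondary_vectors(mesh, array) @ u


def forward_map(mesh: HexMesh, array: SensorArray, dipole: Dipole,
                transfer: TransferSet,
                warn_nonbrain: bool = True) -> FieldMap:
    """Full MEG gradiometer map (fT): primary plus secondary field."""
    load = venant_load(mesh, dipole, warn_nonbrain=warn_nonbrain)
    primary = primary_signal(dipole, array)
    values = primary.values + transfer.secondary(load)
    return FieldMap(values, meta={"component": "total", "dipole": dipole})


class ForwardModel:
    """A head model ready for repeated forward evaluations.

    Bundles the mesh, sensor array, assembled stiffness system and transfer
    set; exposes the per-dipole forward map and the 3-column lead field used
    by the dipole fit.  ``grid`` (optional) provides the brain-compartment
    test for source positions.
    """

    def __init__(self, mesh: HexMesh, array: SensorArray, grid=None,
                 tol: float = 1e-8, method: str = "pcg",
                 model_id: str = ""):
        self.mesh = mesh
        self.array = array
        self.grid = grid
        self.model_id = model_id
        self.system = assemble_stiffness(mesh, tol=tol, method=method)
        self.transfer = meg_transfer(self.system, mesh, array)
        # the factorization (potentially GBs) is only needed to build the
        # transfer set; per-dipole forward evaluation is factor-free
        self.system.release_factor()

    def field_map(self, dipole: Dipole,
                  warn_nonbrain: bool = False) -> FieldMap:
        fmap = forward_map(self.mesh, self.array, dipole, self.transfer,
                           warn_nonbrain=warn_nonbrain)
        fmap.meta["model_id"] = self.model_id
        return fmap

    def lead_field(self, position: np.ndarray) -> np.ndarray:
        """(m, 3) map values per unit moment (1 uAmm) along x, y, z."""
        cols = []
        for axis in np.eye(3):
            d = Dipole(tuple(position), tuple(axis))
            cols.append(self.field_map(d).values)
        return np.column_stack(cols)

    def in_brain(self, position: np.ndarray) -> bool:
        if self.grid is not None:
            return int(self.grid.label_at(position)) in \
                {int(l) for l in BRAIN_LABELS}
        dist, nearest = self.mesh.node_tree().query(np.asarray(position))
        if dist > self.mesh.voxel_size * np.sqrt(3.0):
            return False
        elems = self.mesh.elements_of_node(int(nearest))
        return bool(set(int(l) for l in self.mesh.element_label[elems])
                    & {int(l) for l in BRAIN_LABELS})
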