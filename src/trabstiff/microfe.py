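"""Voxel micro-finite-element compression of trabecular bone.

Every bone voxel of the segmented ROI becomes one 8-node trilinear hexahedral
element (hex8 / C3D8) at the native voxel size — no resizing or smoothing.
The model is linear elastic with a single material (default Young's modulus
24.5 GPa, Poisson's ratio 0.3); the bottom face of the cylinder is fixed and
an axial displacement of 5% of the segment height (strain 0.05) is applied to
the top.  Apparent stiffness k is the summed axial reaction on the fixation
divided by the applied displacement; it is normalized by the theoretical
stiffness k' = E*A/L of the equivalent solid cylinder, giving the
dimensionless stiffness index k/k'.

Units are mm-N-GPa: 1 GPa = 10^3 N/mm^2, so stiffness comes out in N/mm.

Two boundary-condition modes are provided, one flag apart:

* ``bonded`` — all three displacement components of the bottom face fixed
  (platen bonded to the cut surface), the top face driven axially with
  lateral components free.
* ``frictionless`` — only axial components constrained on both faces, plus a
  minimal set of lateral pins per load-bearing component to suppress
  rigid-body motion.  The analytic oracles (solid cylinder k/k' = 1, parallel
  rods k/k' = BV/TV) hold exactly in this mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg

from .image_io import BinaryROI

__all__ = [
    "Material",
    "HexMesh",
    "BoundaryConditions",
    "FESolution",
    "StiffnessResult",
    "NoLoadPathError",
    "build_mesh",
    "element_stiffness",
    "assemble_stiffness",
    "make_boundary_conditions",
    "solve",
    "stiffness_index",
    "export_inp",
    "read_inp",
]


class NoLoadPathError(RuntimeError):
    """No face-connected bone component spans the bottom and top planes."""


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic bone tissue properties."""

    E: float = 24.5    # Young's modulus, GPa
    nu: float = 0.3    # Poisson's ratio

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError("E must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ValueError("nu must be in (-1, 0.5)")

    @property
    def e_mpa(self) -> float:
        return self.E * 1.0e3


@dataclass
class HexMesh:
    """Voxel-conforming hex8 mesh (all elements identical cubes)."""

    nodes: np.ndarray             # (nn, 3) coordinates in mm, columns (x, y, z)
    elements: np.ndarray          # (ne, 8) 0-based node ids, C3D8 ordering
    edge: float                   # element edge length = voxel size, mm
    removed_fraction: float       # share of bone voxels dropped by filtering
    element_component: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def height(self) -> float:
        return float(self.nodes[:, 2].max() - self.nodes[:, 2].min())

    def bottom_nodes(self) -> np.ndarray:
        z = self.nodes[:, 2]
        return np.flatnonzero(np.isclose(z, z.min()))

    def top_nodes(self) -> np.ndarray:
        z = self.nodes[:, 2]
        return np.flatnonzero(np.isclose(z, z.max()))


@dataclass
class BoundaryConditions:
    """Prescribed displacement set for uniaxial compression."""

    mode: str                     # 'bonded' | 'frictionless'
    dofs: np.ndarray              # constrained global dof indices
    values: np.ndarray            # prescribed displacement per dof, mm
    fixed_set: np.ndarray         # bottom-face node ids
    driven_set: np.ndarray        # top-face node ids
    delta_d: float                # magnitude of the applied displacement, mm
    strain: float


@dataclass
class FESolution:
    """Converged displacement field with nodal forces at the constraints."""

    displacements: np.ndarray     # (nn, 3), mm
    forces: np.ndarray            # (nn, 3) K@u, meaningful at constrained dofs, N
    residual: float               # relative residual of the reduced system
    bcs: BoundaryConditions

    def reaction_sum_bottom(self) -> float:
        """Total axial reaction force on the fixation, N (signed)."""
        return float(self.forces[self.bcs.fixed_set, 2].sum())

    def force_sum_top(self) -> float:
        """Total axial force transmitted through the driven face, N."""
        return float(self.forces[self.bcs.driven_set, 2].sum())


@dataclass(frozen=True)
class StiffnessResult:
    """Apparent stiffness, equivalent-solid stiffness, and their ratio."""

    k: float                      # N/mm
    k_prime: float                # N/mm
    index: float                  # k / k'
    diameter_mm: float
    height_mm: float


# ---------------------------------------------------------------------------
# meshing


def build_mesh(roi: BinaryROI) -> HexMesh:
    """One cube element per bone voxel, keeping only load-bearing bone.

    Face-connected (6-connectivity) components that touch both the bottom
    and the top plane of the segment are retained — every such component is a
    parallel load path; the rest (floating or corner-hinged fragments, which
    would make the stiffness matrix singular) are dropped and the removed
    volume fraction is recorded.
    """
    mask = roi.mask
    total = int(mask.sum())
    if total == 0:
        raise NoLoadPathError("empty mask")
    labels, n = ndi.label(mask, structure=ndi.generate_binary_structure(3, 1))
    bottom_labels = set(np.unique(labels[0])) - {0}
    top_labels = set(np.unique(labels[-1])) - {0}
    spanning = sorted(bottom_labels & top_labels)
    if not spanning:
        raise NoLoadPathError(
            "no load path: no face-connected component spans bottom to top"
        )
    keep = np.isin(labels, spanning)
    removed_fraction = 1.0 - keep.sum() / total

    a = roi.voxel_size
    nz, ny, nx = mask.shape
    iz, iy, ix = np.nonzero(keep)
    # lattice node ids on the (nz+1, ny+1, nx+1) corner grid
    def nid(z, y, x):
        return (z * (ny + 1) + y) * (nx + 1) + x

    conn = np.stack([
        nid(iz, iy, ix), nid(iz, iy, ix + 1),
        nid(iz, iy + 1, ix + 1), nid(iz, iy + 1, ix),
        nid(iz + 1, iy, ix), nid(iz + 1, iy, ix + 1),
        nid(iz + 1, iy + 1, ix + 1), nid(iz + 1, iy + 1, ix),
    ], axis=1)
    used, conn = np.unique(conn, return_inverse=True)
    conn = conn.reshape(-1, 8)
    gz, rem = np.divmod(used, (ny + 1) * (nx + 1))
    gy, gx = np.divmod(rem, nx + 1)
    nodes = np.stack([gx * a, gy * a, gz * a], axis=1).astype(float)
    elem_comp = labels[iz, iy, ix]
    # renumber components densely
    _, elem_comp = np.unique(elem_comp, return_inverse=True)
    return HexMesh(nodes, conn, a, float(removed_fraction), elem_comp)


# ---------------------------------------------------------------------------
# element and global stiffness


def _hex8_shape_gradients(xi: np.ndarray) -> np.ndarray:
    """Gradients of the 8 trilinear shape functions at natural point xi."""
    s = np.array([
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ], dtype=float)
    g = np.empty((8, 3))
    for i in range(8):
        si = s[i]
        g[i, 0] = si[0] * (1 + si[1] * xi[1]) * (1 + si[2] * xi[2]) / 8.0
        g[i, 1] = si[1] * (1 + si[0] * xi[0]) * (1 + si[2] * xi[2]) / 8.0
        g[i, 2] = si[2] * (1 + si[0] * xi[0]) * (1 + si[1] * xi[1]) / 8.0
    return g


def _elastic_matrix(e_mpa: float, nu: float) -> np.ndarray:
    lam = e_mpa * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e_mpa / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def element_stiffness(material: Material, edge: float,
                      n_gauss: int = 2) -> np.ndarray:
    """24x24 stiffness matrix of a cube hex8 element.

    Trilinear shape functions with n_gauss^3 Gauss quadrature (default
    2x2x2, exact for the trilinear element).  Dof order is node-major
    (ux, uy, uz).  The matrix is symmetric positive semi-definite with the
    six rigid-body zero-energy modes.
    """
    if material.nu >= 0.5:
        raise ValueError("nu = 0.5 is incompressible: stiffness matrix singular")
    D = _elastic_matrix(material.e_mpa, material.nu)
    pts, wts = np.polynomial.legendre.leggauss(n_gauss)
    jac = edge / 2.0
    detJ = jac**3
    K = np.zeros((24, 24))
    for p, wp in zip(pts, wts):
        for q, wq in zip(pts, wts):
            for r, wr in zip(pts, wts):
                g = _hex8_shape_gradients(np.array([p, q, r])) / jac
                B = np.zeros((6, 24))
                for i in range(8):
                    dx, dy, dz = g[i]
                    B[0, 3 * i] = dx
                    B[1, 3 * i + 1] = dy
                    B[2, 3 * i + 2] = dz
                    B[3, 3 * i] = dy
                    B[3, 3 * i + 1] = dx
                    B[4, 3 * i + 1] = dz
                    B[4, 3 * i + 2] = dy
                    B[5, 3 * i] = dz
                    B[5, 3 * i + 2] = dx
                K += wp * wq * wr * detJ * (B.T @ D @ B)
    return 0.5 * (K + K.T)


def assemble_stiffness(mesh: HexMesh, material: Material) -> sparse.csr_array:
    """Global stiffness matrix in CSR form.

    All elements are identical cubes, so the canonical element matrix is
    computed once and scattered over the connectivity.
    """
    ke = element_stiffness(material, mesh.edge)
    ne = mesh.n_elements
    edof = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(ne, 24)
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()
    vals = np.tile(ke.ravel(), ne)
    ndof = 3 * mesh.n_nodes
    K = sparse.coo_array((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K


# ---------------------------------------------------------------------------
# boundary conditions


def make_boundary_conditions(mesh: HexMesh, strain: float = 0.05,
                             mode: str = "bonded") -> BoundaryConditions:
    """Uniaxial compression: bottom fixed, top driven down by strain*height."""
    if mode not in ("bonded", "frictionless"):
        raise ValueError(f"unknown mode: {mode!r}")
    bottom, top = mesh.bottom_nodes(), mesh.top_nodes()
    if bottom.size == 0 or top.size == 0:
        raise NoLoadPathError("mesh has no bottom or top face nodes")
    height = mesh.height
    delta_d = strain * height
    dofs: list[int] = []
    vals: list[float] = []
    if mode == "bonded":
        for n in bottom:
            dofs += [3 * n, 3 * n + 1, 3 * n + 2]
            vals += [0.0, 0.0, 0.0]
    else:
        dofs += [3 * n + 2 for n in bottom]
        vals += [0.0] * bottom.size
        dofs, vals = _add_rigid_body_pins(mesh, bottom, dofs, vals)
    dofs += [3 * n + 2 for n in top]
    vals += [-delta_d] * top.size
    return BoundaryConditions(
        mode=mode,
        dofs=np.asarray(dofs, dtype=np.int64),
        values=np.asarray(vals, dtype=float),
        fixed_set=bottom,
        driven_set=top,
        delta_d=delta_d,
        strain=strain,
    )


def _node_components(mesh: HexMesh) -> np.ndarray:
    comp = np.full(mesh.n_nodes, -1, dtype=np.int64)
    if mesh.element_component is None:
        comp[:] = 0
        return comp
    for c in np.unique(mesh.element_component):
        nodes = np.unique(mesh.elements[mesh.element_component == c])
        comp[nodes] = c
    return comp


def _add_rigid_body_pins(mesh: HexMesh, bottom: np.ndarray,
                         dofs: list[int], vals: list[float]):
    """Pin lateral rigid-body modes of each load-bearing component.

    Per component: one bottom node gets ux = uy = 0 (translation), and a
    second bottom node at a different x gets uy = 0 (rotation about the
    axis); the pins are compatible with a homogeneous uniaxial strain field
    anchored at the first node, so they add no parasitic stress there.
    """
    comp = _node_components(mesh)
    for c in np.unique(comp[bottom]):
        cb = bottom[comp[bottom] == c]
        order = np.lexsort((mesh.nodes[cb, 0], mesh.nodes[cb, 1]))
        first = cb[order[0]]
        dofs += [3 * first, 3 * first + 1]
        vals += [0.0, 0.0]
        x0, y0 = mesh.nodes[first, 0], mesh.nodes[first, 1]
        diff_x = cb[mesh.nodes[cb, 0] != x0]
        if diff_x.size:
            second = diff_x[np.argmax(np.abs(mesh.nodes[diff_x, 0] - x0))]
            dofs.append(3 * second + 1)
            vals.append(0.0)
        else:
            diff_y = cb[mesh.nodes[cb, 1] != y0]
            if diff_y.size:
                second = diff_y[np.argmax(np.abs(mesh.nodes[diff_y, 1] - y0))]
                dofs.append(3 * second)
                vals.append(0.0)
    return dofs, vals


# ---------------------------------------------------------------------------
# solution


def solve(mesh: HexMesh, material: Material, bcs: BoundaryConditions,
          tol: float = 1.0e-8, max_iter: int = 20000) -> FESolution:
    """Solve the constrained linear system by preconditioned conjugate
    gradients (Jacobi preconditioner) and recover constrained-node forces.

    Deterministic for fixed inputs; raises on non-convergence.
    """
    K = assemble_stiffness(mesh, material)
    ndof = K.shape[0]
    cdofs = bcs.dofs
    free = np.setdiff1d(np.arange(ndof), cdofs, assume_unique=False)
    u = np.zeros(ndof)
    u[cdofs] = bcs.values
    rhs = -(K @ u)[free]
    Kff = K[free][:, free]
    if np.linalg.norm(rhs) == 0.0:
        uf = np.zeros(free.size)
        res = 0.0
    else:
        diag = Kff.diagonal()
        if np.any(diag <= 0):
            raise RuntimeError(
                "singular system: free dof with non-positive diagonal "
                "(floating node not attached to any element?)"
            )
        inv_diag = 1.0 / diag
        M = LinearOperator(Kff.shape, matvec=lambda x: inv_diag * x)
        uf, info = cg(Kff, rhs, rtol=tol, maxiter=max_iter, M=M)
        if info > 0:
            raise RuntimeError(f"CG failed to converge in {info} iterations")
        res = float(np.linalg.norm(Kff @ uf - rhs) / np.linalg.norm(rhs))
    u[free] = uf
    forces = K @ u
    return FESolution(
        displacements=u.reshape(-1, 3),
        forces=forces.reshape(-1, 3),
        residual=res,
        bcs=bcs,
    )


def stiffness_index(solution: FESolution, diameter_mm: float,
                    material: Material) -> StiffnessResult:
    """k = |sum of axial reactions on the fixation| / delta_d; k' = E*A/L for
    the equivalent solid cylinder (nominal circle area pi*D^2/4, segment
    height L); index = k/k'."""
    bcs = solution.bcs
    if bcs.delta_d == 0:
        raise ValueError("zero prescribed displacement: stiffness undefined")
    height = abs(bcs.delta_d) / bcs.strain
    k = abs(solution.reaction_sum_bottom()) / abs(bcs.delta_d)
    area = np.pi * diameter_mm**2 / 4.0
    k_prime = material.e_mpa * area / height
    return StiffnessResult(k, k_prime, k / k_prime, diameter_mm, height)


# ---------------------------------------------------------------------------
# ABAQUS-dialect export


def export_inp(mesh: HexMesh, material: Material,
               bcs: BoundaryConditions | None = None) -> str:
    """ABAQUS-dialect input deck: nodes, C3D8 elements, material, and (if
    given) the compression boundary conditions in a static step."""
    out = StringIO()
    out.write("*HEADING\ntrabstiff voxel hex8 mesh\n")
    out.write("*NODE\n")
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        out.write(f"{i}, {x:.9g}, {y:.9g}, {z:.9g}\n")
    out.write("*ELEMENT, TYPE=C3D8, ELSET=BONE\n")
    for i, el in enumerate(mesh.elements + 1, start=1):
        out.write(f"{i}, " + ", ".join(str(n) for n in el) + "\n")
    out.write("*SOLID SECTION, ELSET=BONE, MATERIAL=BONE\n")
    out.write("*MATERIAL, NAME=BONE\n*ELASTIC\n")
    out.write(f"{material.e_mpa:.9g}, {material.nu:.9g}\n")
    if bcs is not None:
        out.write("*NSET, NSET=BOTTOM\n")
        out.write(_id_lines(bcs.fixed_set + 1))
        out.write("*NSET, NSET=TOP\n")
        out.write(_id_lines(bcs.driven_set + 1))
        out.write("*STEP\n*STATIC\n*BOUNDARY\n")
        if bcs.mode == "bonded":
            out.write("BOTTOM, 1, 3, 0.\n")
        else:
            out.write("BOTTOM, 3, 3, 0.\n")
        out.write(f"TOP, 3, 3, {-bcs.delta_d:.9g}\n")
        out.write("*END STEP\n")
    return out.getvalue()


def _id_lines(ids: np.ndarray, per_line: int = 12) -> str:
    lines = []
    for i in range(0, len(ids), per_line):
        lines.append(", ".join(str(n) for n in ids[i:i + per_line]))
    return "\n".join(lines) + "\n"


def read_inp(text: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse nodes and C3D8 connectivity back from an exported deck."""
    nodes: list[list[float]] = []
    elements: list[list[int]] = []
    section = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("*"):
            u = line.upper()
            if u.startswith("*NODE"):
                section = "node"
            elif u.startswith("*ELEMENT") and "C3D8" in u:
                section = "element"
            else:
                section = None
            continue
        parts = [p.strip() for p in line.split(",") if p.strip()]
        if section == "node":
            nodes.append([float(p) for p in parts[1:4]])
        elif section == "element":
            elements.append([int(p) - 1 for p in parts[1:9]])
    return np.asarray(nodes, dtype=float), np.asarray(elements, dtype=np.int64)
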