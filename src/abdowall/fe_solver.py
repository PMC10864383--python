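"""Small-strain isotropic linear-elastic FE solver on linear tetrahedra.

The constitutive model is linear isotropic elasticity, sigma = C(E, nu) eps,
with region-wise constant material properties.  Elements are displacement
based constant-strain tetrahedra (single-point integration); the
intra-abdominal pressure is applied as a dead, consistent nodal load on the
undeformed inner surface; fixed boundaries are handled by exact row/column
elimination, so constrained DOFs are satisfied to machine precision.

Units: mm, MPa, N.  Pressures cross the public interfaces in kPa (the
physiological convention) and are converted to MPa once, here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import yaml

from .mesh_core import LabeledTetMesh, LabelError, triangle_areas, triangle_normals, tet_volumes

__all__ = [
    "AssemblyError",
    "ConstraintError",
    "ConvergenceError",
    "MaterialTable",
    "LoadCase",
    "DisplacementField",
    "default_materials",
    "transition_modulus",
    "assemble_stiffness",
    "pressure_load",
    "solve",
    "strain_energy",
    "node_dofs",
    "ConstrainedOperator",
]

MUSCLE_POISSON = 0.49
WOUND_POISSON = 0.40


class AssemblyError(ValueError):
    """Element-level assembly failure (e.g. non-positive volume)."""


class ConstraintError(ValueError):
    """The constrained system is singular (rigid-body modes remain)."""


class ConvergenceError(RuntimeError):
    """The iterative solver failed to reach the requested residual."""


# --------------------------------------------------------------------------
# materials
# --------------------------------------------------------------------------

def transition_modulus(e_regular: float, e_sheath: float) -> float:
    """Halfway rule for the thin zone between regular muscle and its
    aponeurotic sheath: the arithmetic mean, rounded to 0.1 MPa."""
    return round((e_regular + e_sheath) / 2.0, 1)


@dataclass
class MaterialTable:
    """Map region label -> (elastic modulus E in MPa, Poisson ratio nu)."""

    entries: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, (e, nu) in self.entries.items():
            if e <= 0:
                raise ValueError(f"{label}: elastic modulus must be positive")
            if not 0.0 <= nu < 0.5:
                raise ValueError(f"{label}: Poisson ratio must be in [0, 0.5)")

    def __getitem__(self, label: str) -> tuple[float, float]:
        if label not in self.entries:
            raise LabelError(f"no material for region {label!r}")
        return self.entries[label]

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def modulus(self, label: str) -> float:
        return self[label][0]

    def with_entry(self, label: str, e: float, nu: float | None = None) -> "MaterialTable":
        """New table with one entry added/replaced (wounds default to
        nu = 0.40)."""
        if nu is None:
            nu = WOUND_POISSON if label.startswith("wound:") else MUSCLE_POISSON
        entries = dict(self.entries)
        entries[label] = (float(e), float(nu))
        return MaterialTable(entries)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: [float(e), float(nu)] for k, (e, nu) in self.entries.items()}
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MaterialTable":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls({str(k): (float(v[0]), float(v[1])) for k, v in data.items()})


#: Regular-muscle and aponeurotic-sheath moduli (MPa) of the lateral stack.
_LATERAL_E = {"EO": (1.0, 5.6), "IO": (0.65, 5.6), "TR": (1.03, 5.6)}


def default_materials(extra: dict[str, tuple[float, float]] | None = None) -> MaterialTable:
    """Literature-based tissue moduli (MPa) with nu = 0.49 for muscle.

    Linea alba 72; rectus abdominis 0.52; lateral muscles: regular 1 / 0.65
    / 1.03 (EO / IO / TR), aponeurotic sheath 5.6 for all three, transition
    zones at the halfway modulus (3.3 / 3.1 / 3.3).
    """
    entries: dict[str, tuple[float, float]] = {"LA": (72.0, MUSCLE_POISSON)}
    for side in ("left", "right"):
        entries[f"RA_{side}"] = (0.52, MUSCLE_POISSON)
        for muscle, (e_reg, e_sheath) in _LATERAL_E.items():
            entries[f"{muscle}_regular_{side}"] = (e_reg, MUSCLE_POISSON)
            entries[f"{muscle}_aponeurotic_{side}"] = (e_sheath, MUSCLE_POISSON)
            entries[f"{muscle}_transition_{side}"] = (
                transition_modulus(e_reg, e_sheath), MUSCLE_POISSON,
            )
    if extra:
        entries.update(extra)
    return MaterialTable(entries)


# --------------------------------------------------------------------------
# load case / result containers
# --------------------------------------------------------------------------

@dataclass
class LoadCase:
    """Uniform pressure on a boundary patch with a fixed (clamped) patch."""

    P_a: float  # intra-abdominal pressure, kPa
    pressure_patch: str = "inner_surface"
    fixed_patch: str = "fixed_edge"

    def __post_init__(self) -> None:
        if self.P_a < 0:
            raise ValueError("P_a must be non-negative")


@dataclass
class DisplacementField:
    """Per-node displacements (mm) from one linear solve."""

    u: np.ndarray  # (n_nodes, 3)
    load_case: LoadCase | None
    residual: float  # relative residual of the constrained system
    mesh: LabeledTetMesh | None = None

    def deformed_coords(self, coords: np.ndarray | None = None) -> np.ndarray:
        base = self.mesh.node_coords if coords is None else coords
        return base + self.u


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def _element_matrices(coords: np.ndarray, tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients (m, 4, 3) and volumes (m,) of all tets."""
    v = coords[tets]
    d = v[:, 1:] - v[:, :1]  # (m, 3, 3) edge matrix
    vol = np.linalg.det(d) / 6.0
    if np.any(vol <= 0):
        bad = np.flatnonzero(vol <= 0)
        raise AssemblyError(
            f"non-positive element volumes at tets {bad[:10].tolist()}"
        )
    dinv = np.linalg.inv(d)  # rows of dinv.T are grads of lambda_1..3
    g = np.empty((len(tets), 4, 3))
    g[:, 1:, :] = np.transpose(dinv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    return g, vol


def _b_matrices(g: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (m, 6, 12), engineering shear rows
    (eps_xx, eps_yy, eps_zz, gam_xy, gam_yz, gam_zx)."""
    m = g.shape[0]
    b = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = g[:, a, 0], g[:, a, 1], g[:, a, 2]
        c = 3 * a
        b[:, 0, c + 0] = gx
        b[:, 1, c + 1] = gy
        b[:, 2, c + 2] = gz
        b[:, 3, c + 0] = gy
        b[:, 3, c + 1] = gx
        b[:, 4, c + 1] = gz
        b[:, 4, c + 2] = gy
        b[:, 5, c + 0] = gz
        b[:, 5, c + 2] = gx
    return b


def _elastic_moduli(mesh: LabeledTetMesh, materials: MaterialTable) -> tuple[np.ndarray, np.ndarray]:
    labels = mesh.region_label
    cache: dict[str, tuple[float, float]] = {}
    e = np.empty(len(labels))
    nu = np.empty(len(labels))
    for i, lab in enumerate(labels):
        if lab not in cache:
            cache[lab] = materials[lab]
        e[i], nu[i] = cache[lab]
    return e, nu


def assemble_stiffness(
    mesh: LabeledTetMesh, materials: MaterialTable
) -> sp.csr_matrix:
    """Global stiffness operator (3 n_nodes square, symmetric PSD).

    Each element contributes vol * B^T C B with the isotropic elasticity
    matrix C built from its region's (E, nu).  The result is symmetrized to
    remove floating-point asymmetry from the triple product.
    """
    g, vol = _element_matrices(mesh.node_coords, mesh.tets)
    b = _b_matrices(g)
    e, nu = _elastic_moduli(mesh, materials)

    lam = e * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e / (2 * (1 + nu))
    c = np.zeros((len(e), 6, 6))
    c[:, :3, :3] = lam[:, None, None]
    idx = np.arange(3)
    c[:, idx, idx] += 2 * mu[:, None]
    c[:, idx + 3, idx + 3] = mu[:, None]

    ke = np.einsum("mki,mkl,mlj,m->mij", b, c, b, vol, optimize=True)

    dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    k = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return (k + k.T) * 0.5


def pressure_load(mesh: LabeledTetMesh, patch: str, P_a: float) -> np.ndarray:
    """Consistent nodal forces (N) of a uniform pressure on a boundary patch.

    ``P_a`` is in kPa; positive values push against the patch's outward
    normal (i.e. a pressure inside the cavity pushing the wall outward).
    Each triangle's force p*A is split equally among its three nodes.
    """
    tris = mesh.patch(patch).triangles
    p_mpa = P_a * 1e-3
    areas = triangle_areas(mesh.node_coords, tris)
    normals = triangle_normals(mesh.node_coords, tris)
    force = -p_mpa * areas[:, None] * normals  # traction opposes outward n
    f = np.zeros((mesh.n_nodes, 3))
    for k in range(3):
        np.add.at(f, tris[:, k], force / 3.0)
    return f.ravel()


# --------------------------------------------------------------------------
# constrained solve
# --------------------------------------------------------------------------

class ConstrainedOperator:
    """Stiffness with Dirichlet DOFs eliminated; factorization reusable
    across load vectors (one factorization per material assignment, one
    triangular solve per pressure level)."""

    def __init__(
        self, k: sp.csr_matrix, fixed_dofs: np.ndarray, method: str = "direct",
        rtol: float = 1e-8,
    ) -> None:
        n = k.shape[0]
        fixed = np.unique(np.asarray(fixed_dofs, dtype=np.int64))
        if fixed.size == 0:
            raise ConstraintError("no constrained DOFs: system is singular")
        free = np.setdiff1d(np.arange(n), fixed, assume_unique=True)
        self.k = k
        self.fixed = fixed
        self.free = free
        self.method = method
        self.rtol = rtol
        self.k_ff = k[np.ix_(free, free)].tocsc()
        self.k_fc = k[np.ix_(free, fixed)]
        self._lu = None
        if method == "direct":
            try:
                # SPD system: symmetric-mode minimum-degree ordering gives
                # far less fill than the default unsymmetric COLAMD
                self._lu = spla.splu(
                    self.k_ff, permc_spec="MMD_AT_PLUS_A",
                    options=dict(SymmetricMode=True, DiagPivotThresh=0.0),
                )
            except RuntimeError as exc:  # singular factor
                raise ConstraintError(f"constrained system singular: {exc}")

    def solve(self, f: np.ndarray, fixed_values: np.ndarray | None = None) -> tuple[np.ndarray, float]:
        """Solve for the full DOF vector; returns (u, relative residual)."""
        n = self.k.shape[0]
        u = np.zeros(n)
        if fixed_values is not None:
            u[self.fixed] = fixed_values
        rhs = f[self.free] - (self.k_fc @ u[self.fixed])
        if self._lu is not None:
            u[self.free] = self._lu.solve(rhs)
        else:
            x, info = spla.cg(self.k_ff, rhs, rtol=self.rtol, maxiter=20000)
            if info != 0:
                res = np.linalg.norm(self.k_ff @ x - rhs) / max(
                    np.linalg.norm(rhs), 1e-300
                )
                raise ConvergenceError(
                    f"CG did not converge (info={info}, residual={res:.3e})"
                )
            u[self.free] = x
        scale = max(float(np.linalg.norm(rhs)), 1e-300)
        res = float(np.linalg.norm(self.k_ff @ u[self.free] - rhs)) / scale
        return u, res


def node_dofs(nodes: np.ndarray, components: tuple[int, ...] = (0, 1, 2)) -> np.ndarray:
    """Global DOF ids for the given components of the given nodes."""
    nodes = np.asarray(nodes, dtype=np.int64)
    return (3 * nodes[:, None] + np.array(components)[None, :]).ravel()


def solve(
    mesh: LabeledTetMesh,
    materials: MaterialTable,
    load_case: LoadCase | None = None,
    *,
    load: np.ndarray | None = None,
    fixed_dofs: np.ndarray | None = None,
    fixed_values: np.ndarray | None = None,
    method: str = "direct",
    rtol: float = 1e-8,
) -> DisplacementField:
    """One linear elastostatic solve.

    With a :class:`LoadCase`, the pressure is applied on the case's pressure
    patch and all DOFs of the fixed patch are clamped to zero.  Benchmarks
    and tests may instead pass an explicit ``load`` vector and/or
    ``fixed_dofs`` (optionally with non-zero ``fixed_values``, e.g. an
    affine patch-test boundary).  ``method`` is ``"direct"`` (sparse LU) or
    ``"cg"`` (conjugate gradients at relative residual ``rtol``).
    """
    if load_case is not None:
        if load is None:
            load = pressure_load(mesh, load_case.pressure_patch, load_case.P_a)
        if fixed_dofs is None:
            nodes = np.unique(mesh.patch(load_case.fixed_patch).triangles)
            fixed_dofs = node_dofs(nodes)
    if load is None:
        load = np.zeros(3 * mesh.n_nodes)
    if fixed_dofs is None or len(np.atleast_1d(fixed_dofs)) == 0:
        raise ConstraintError("solve requires a nonempty fixed DOF set")

    k = assemble_stiffness(mesh, materials)
    op = ConstrainedOperator(k, fixed_dofs, method=method, rtol=rtol)
    u, res = op.solve(np.asarray(load, dtype=float).ravel(), fixed_values)
    return DisplacementField(u.reshape(-1, 3), load_case, res, mesh)


def strain_energy(k: sp.csr_matrix, u: np.ndarray) -> float:
    """Energy (half) norm 0.5 u^T K u of a displacement field."""
    v = np.asarray(u, dtype=float).ravel()
    return float(0.5 * v @ (k @ v))
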