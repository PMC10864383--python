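"""Labeled tetrahedral meshes: data model, I/O, measures and statistics.

The package works on volume meshes of linear tetrahedra in which every
element carries a symbolic region label (a tissue name such as ``"LA"`` or
``"EO_regular_left"``, or a wound region ``"wound:A6"``) and the mesh
boundary is partitioned into named triangle patches (``inner_surface``,
``outer_surface``, ``fixed_edge``).  All coordinates are millimetres;
areas are mm^2 and volumes mm^3.

Supported on-disk dialects are Gmsh ``.msh`` v4.1 ASCII (labels stored as
physical names) and VTK ``.vtu`` ASCII (labels stored as integer cell data
with a YAML sidecar table ``<file>.labels.yaml``).  Surface patches can be
exported to ``.vtp`` for visualization.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp
import yaml

__all__ = [
    "MeshValidationError",
    "LabelError",
    "FormatError",
    "LabeledTetMesh",
    "SurfacePatch",
    "MeshStats",
    "tet_volumes",
    "triangle_areas",
    "surface_area",
    "region_volume",
    "compute_mesh_stats",
    "read_mesh",
    "write_mesh",
    "write_surface_vtp",
]


class MeshValidationError(ValueError):
    """The mesh violates a structural invariant (e.g. degenerate elements)."""


class LabelError(ValueError):
    """Region labels are missing, unknown or inconsistent."""


class FormatError(ValueError):
    """Unsupported or malformed mesh file format."""


# --------------------------------------------------------------------------
# geometric primitives
# --------------------------------------------------------------------------

def tet_volumes(coords: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for the package's orientation
    convention ``det[v1-v0, v2-v0, v3-v0] > 0``)."""
    v = coords[tets]
    return np.einsum(
        "ij,ij->i",
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
        v[:, 3] - v[:, 0],
    ) / 6.0


def triangle_areas(coords: np.ndarray, tris: np.ndarray) -> np.ndarray:
    v = coords[tris]
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    return 0.5 * np.linalg.norm(n, axis=1)


def triangle_normals(coords: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Unit normals following the triangle winding (right-hand rule)."""
    v = coords[tris]
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    if np.any(norms <= 0):
        raise MeshValidationError("degenerate boundary triangle (zero area)")
    return n / norms


# faces of a tet (v0,v1,v2,v3), wound outward for positive-volume tets
_TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])


def boundary_faces_of(tets: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary triangles of a tet set (faces used once)."""
    faces = tets[:, _TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


# --------------------------------------------------------------------------
# data model
# --------------------------------------------------------------------------

@dataclass
class LabeledTetMesh:
    """Tetrahedral volume mesh with per-element region labels.

    Attributes
    ----------
    node_coords : (n_nodes, 3) float array, mm
    tets : (n_tets, 4) int array, 0-based node indices, positively oriented
    region_label : (n_tets,) array of str
    boundary_patches : name -> (k, 3) int array of outward-oriented boundary
        triangles.  Patches need not cover the whole boundary but must be
        subsets of it.
    provenance : optional generator metadata (set by ``geometry_synth``);
        carries the wall config and wound specs that produced the mesh.
    """

    node_coords: np.ndarray
    tets: np.ndarray
    region_label: np.ndarray
    boundary_patches: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict | None = None

    # -- construction -------------------------------------------------------

    @classmethod
    def create(
        cls,
        node_coords: np.ndarray,
        tets: np.ndarray,
        region_label: Iterable[str],
        boundary_patches: Mapping[str, np.ndarray] | None = None,
        provenance: dict | None = None,
    ) -> "LabeledTetMesh":
        """Validate, repair orientation, orient patches outward and build.

        Raises
        ------
        LabelError
            if labels are missing or the label array length mismatches.
        MeshValidationError
            for degenerate tets, invalid indices or patch triangles that are
            not boundary faces.
        """
        coords = np.asarray(node_coords, dtype=float)
        tets = np.array(tets, dtype=np.int64)
        labels = np.asarray(list(region_label), dtype=object)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise MeshValidationError("node_coords must be (n, 3)")
        if tets.ndim != 2 or tets.shape[1] != 4:
            raise MeshValidationError("tets must be (m, 4)")
        if labels.shape[0] != tets.shape[0]:
            raise LabelError(
                f"{tets.shape[0]} tets but {labels.shape[0]} region labels"
            )
        if tets.size and (tets.min() < 0 or tets.max() >= coords.shape[0]):
            raise MeshValidationError("tet node index out of range")

        vols = tet_volumes(coords, tets)
        flip = vols < 0
        if np.any(flip):
            tets[flip] = tets[flip][:, [0, 1, 3, 2]]
            vols = np.abs(vols)
        scale = max(float(np.ptp(coords)), 1.0)
        degenerate = np.flatnonzero(vols <= 1e-14 * scale**3)
        if degenerate.size:
            raise MeshValidationError(
                f"degenerate (zero-volume) tets: {degenerate[:20].tolist()}"
                + ("..." if degenerate.size > 20 else "")
            )

        mesh = cls(coords, tets, labels, {}, provenance)
        if boundary_patches:
            bset = {tuple(f) for f in np.sort(mesh.boundary_faces(), axis=1)}
            oriented = {
                tuple(sorted(f)): tuple(f) for f in mesh.boundary_faces()
            }
            for name, tris in boundary_patches.items():
                tris = np.asarray(tris, dtype=np.int64)
                out = np.empty_like(tris)
                for k, t in enumerate(tris):
                    key = tuple(sorted(t.tolist()))
                    if key not in bset:
                        raise MeshValidationError(
                            f"patch {name!r} triangle {t.tolist()} is not a "
                            "boundary face"
                        )
                    out[k] = oriented[key]
                mesh.boundary_patches[name] = out
        return mesh

    # -- derived quantities -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    def labels(self) -> list[str]:
        return sorted(set(self.region_label.tolist()))

    def region_tets(self, label: str) -> np.ndarray:
        mask = self.region_label == label
        if not mask.any():
            raise LabelError(f"unknown region label {label!r}")
        return self.tets[mask]

    def boundary_faces(self) -> np.ndarray:
        """Outward-oriented triangles of the whole mesh boundary (cached)."""
        if not hasattr(self, "_bfaces"):
            self._bfaces = boundary_faces_of(self.tets)
        return self._bfaces

    def patch(self, name: str) -> "SurfacePatch":
        if name not in self.boundary_patches:
            raise KeyError(f"unknown boundary patch {name!r}")
        return SurfacePatch(self.boundary_patches[name], self)


@dataclass
class SurfacePatch:
    """A set of mesh triangles treated as a surface.

    Hosts the measurements done on surfaces: areas and the edge graph on
    which graph geodesics are computed.  The patch stores connectivity only;
    coordinates (undeformed or deformed) are supplied per measurement so the
    same patch serves both configurations.
    """

    triangles: np.ndarray
    parent_mesh: LabeledTetMesh | None = None

    @property
    def nodes(self) -> np.ndarray:
        """Sorted unique node ids used by the patch."""
        return np.unique(self.triangles)

    def edges(self) -> np.ndarray:
        """Unique undirected edges (pairs of global node ids)."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def edge_graph(self, coords: np.ndarray) -> tuple[np.ndarray, sp.csr_matrix]:
        """Weighted adjacency of the patch edges at the given coordinates.

        Returns ``(node_ids, graph)`` where ``graph`` is a symmetric CSR
        matrix over the patch-local node ordering ``node_ids`` and weights
        are edge lengths in mm (all strictly positive).
        """
        ids = self.nodes
        local = {int(g): i for i, g in enumerate(ids)}
        e = self.edges()
        w = np.linalg.norm(coords[e[:, 0]] - coords[e[:, 1]], axis=1)
        if np.any(w <= 0):
            raise MeshValidationError("zero-length edge in surface patch")
        i = np.fromiter((local[int(a)] for a in e[:, 0]), int, len(e))
        j = np.fromiter((local[int(b)] for b in e[:, 1]), int, len(e))
        g = sp.coo_matrix((w, (i, j)), shape=(len(ids), len(ids)))
        g = g + g.T
        return ids, g.tocsr()


@dataclass
class MeshStats:
    """Counts and mean element measures, globally and per wound region."""

    n_nodes: int
    n_surface_triangles: int
    n_tets: int
    mean_triangle_area: float  # mm^2, over the mesh boundary triangles
    mean_tet_volume: float  # mm^3
    total_volume: float  # mm^3
    total_boundary_area: float  # mm^2
    region_volumes: dict[str, float] = field(default_factory=dict)
    wound_mean_tet_volume: dict[str, float] = field(default_factory=dict)
    wound_mean_triangle_area: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_surface_triangles": self.n_surface_triangles,
            "n_tets": self.n_tets,
            "mean_triangle_area_mm2": self.mean_triangle_area,
            "mean_tet_volume_mm3": self.mean_tet_volume,
            "total_volume_mm3": self.total_volume,
            "total_boundary_area_mm2": self.total_boundary_area,
            "region_volumes_mm3": dict(self.region_volumes),
            "wound_mean_tet_volume_mm3": dict(self.wound_mean_tet_volume),
            "wound_mean_triangle_area_mm2": dict(self.wound_mean_triangle_area),
        }


# --------------------------------------------------------------------------
# measures
# --------------------------------------------------------------------------

def surface_area(patch: SurfacePatch | np.ndarray, coords: np.ndarray) -> float:
    """Total triangle area of a surface patch at the supplied coordinates."""
    tris = patch.triangles if isinstance(patch, SurfacePatch) else patch
    if len(tris) == 0:
        raise MeshValidationError("empty surface patch")
    return float(triangle_areas(coords, np.asarray(tris)).sum())


def region_volume(mesh: LabeledTetMesh, label: str, coords: np.ndarray | None = None) -> float:
    """Volume of one labeled region at the supplied (default undeformed)
    coordinates.  Signed volumes are summed, so a deformed configuration is
    integrated consistently even if individual elements distort."""
    coords = mesh.node_coords if coords is None else coords
    return float(tet_volumes(coords, mesh.region_tets(label)).sum())


def compute_mesh_stats(mesh: LabeledTetMesh) -> MeshStats:
    """Counts and mean measures, with wound regions reported separately.

    The boundary-triangle statistics count the triangles on the exterior
    boundary of the whole mesh; per-wound triangle statistics count the
    triangles on the closed boundary of each wound region (lids + lateral
    surface).
    """
    vols = tet_volumes(mesh.node_coords, mesh.tets)
    bfaces = mesh.boundary_faces()
    areas = triangle_areas(mesh.node_coords, bfaces)

    region_vols: dict[str, float] = {}
    wound_vol: dict[str, float] = {}
    wound_area: dict[str, float] = {}
    for lab in mesh.labels():
        mask = mesh.region_label == lab
        region_vols[lab] = float(vols[mask].sum())
        if lab.startswith("wound:"):
            wound_vol[lab] = float(vols[mask].mean())
            wtris = boundary_faces_of(mesh.tets[mask])
            wound_area[lab] = float(
                triangle_areas(mesh.node_coords, wtris).mean()
            )
    return MeshStats(
        n_nodes=mesh.n_nodes,
        n_surface_triangles=len(bfaces),
        n_tets=mesh.n_tets,
        mean_triangle_area=float(areas.mean()),
        mean_tet_volume=float(vols.mean()),
        total_volume=float(vols.sum()),
        total_boundary_area=float(areas.sum()),
        region_volumes=region_vols,
        wound_mean_tet_volume=wound_vol,
        wound_mean_triangle_area=wound_area,
    )


# --------------------------------------------------------------------------
# I/O: Gmsh .msh v4.1 ASCII
# --------------------------------------------------------------------------

def _label_tables(mesh: LabeledTetMesh) -> tuple[dict[str, int], dict[str, int]]:
    regions = {lab: i + 1 for i, lab in enumerate(mesh.labels())}
    patches = {
        name: len(regions) + i + 1
        for i, name in enumerate(sorted(mesh.boundary_patches))
    }
    return regions, patches


def _write_msh(mesh: LabeledTetMesh, path: Path) -> None:
    regions, patches = _label_tables(mesh)
    out = io.StringIO()
    out.write("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")

    out.write("$PhysicalNames\n")
    out.write(f"{len(regions) + len(patches)}\n")
    for name, tag in patches.items():
        out.write(f'2 {tag} "{name}"\n')
    for name, tag in regions.items():
        out.write(f'3 {tag} "{name}"\n')
    out.write("$EndPhysicalNames\n")

    lo = mesh.node_coords.min(axis=0) if mesh.n_nodes else np.zeros(3)
    hi = mesh.node_coords.max(axis=0) if mesh.n_nodes else np.zeros(3)
    bbox = " ".join(f"{v:.17g}" for v in np.r_[lo, hi])
    out.write("$Entities\n")
    out.write(f"0 0 {len(patches)} {len(regions)}\n")
    for tag in patches.values():
        out.write(f"{tag} {bbox} 1 {tag} 0\n")
    for tag in regions.values():
        out.write(f"{tag} {bbox} 1 {tag} 0\n")
    out.write("$EndEntities\n")

    first_vol = next(iter(regions.values()))
    out.write("$Nodes\n")
    out.write(f"1 {mesh.n_nodes} 1 {mesh.n_nodes}\n")
    out.write(f"3 {first_vol} 0 {mesh.n_nodes}\n")
    for i in range(mesh.n_nodes):
        out.write(f"{i + 1}\n")
    for p in mesh.node_coords:
        out.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    out.write("$EndNodes\n")

    # Element tags encode the original element order (triangles first, then
    # tets in mesh order), so readers can reconstruct it exactly even though
    # the format groups elements by entity.
    n_tris = sum(len(t) for t in mesh.boundary_patches.values())
    blocks: list[tuple[int, int, int, np.ndarray, np.ndarray]] = []
    eid = 1
    for name, tag in patches.items():
        conn = mesh.boundary_patches[name]
        blocks.append((2, tag, 2, conn, np.arange(eid, eid + len(conn))))
        eid += len(conn)
    for name, tag in regions.items():
        mask = mesh.region_label == name
        tags = n_tris + 1 + np.flatnonzero(mask)
        blocks.append((3, tag, 4, mesh.tets[mask], tags))
    n_elem = sum(len(b[3]) for b in blocks)
    out.write("$Elements\n")
    out.write(f"{len(blocks)} {n_elem} 1 {n_elem}\n")
    for dim, tag, etype, conn, tags in blocks:
        out.write(f"{dim} {tag} {etype} {len(conn)}\n")
        for t, row in zip(tags, conn):
            out.write(f"{t} " + " ".join(str(v + 1) for v in row) + "\n")
    out.write("$EndElements\n")
    path.write_text(out.getvalue())


def _read_msh(path: Path) -> LabeledTetMesh:
    lines = path.read_text().splitlines()
    sections: dict[str, list[str]] = {}
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            j = i + 1
            body = []
            while j < len(lines) and lines[j].strip() != f"$End{name}":
                body.append(lines[j])
                j += 1
            sections[name] = body
            i = j + 1
        else:
            i += 1

    if "PhysicalNames" not in sections:
        raise LabelError(f"{path}: no $PhysicalNames section (region labels required)")
    phys: dict[tuple[int, int], str] = {}
    for line in sections["PhysicalNames"][1:]:
        parts = line.strip().split(maxsplit=2)
        if len(parts) < 3:
            continue
        dim, tag = int(parts[0]), int(parts[1])
        phys[(dim, tag)] = parts[2].strip().strip('"')

    # entity tag -> physical tag
    ent_phys: dict[tuple[int, int], int] = {}
    body = sections["Entities"]
    counts = [int(v) for v in body[0].split()]
    row = 1
    for dim, n in zip((0, 1, 2, 3), counts):
        for _ in range(n):
            parts = body[row].split()
            row += 1
            tag = int(parts[0])
            off = 4 if dim == 0 else 7
            nphys = int(parts[off])
            if nphys:
                ent_phys[(dim, tag)] = int(parts[off + 1])

    body = sections["Nodes"]
    header = [int(v) for v in body[0].split()]
    n_blocks, n_nodes = header[0], header[1]
    tag2idx: dict[int, int] = {}
    coords = np.zeros((n_nodes, 3))
    row, filled = 1, 0
    for _ in range(n_blocks):
        _, _, _, cnt = (int(v) for v in body[row].split())
        row += 1
        tags = [int(body[row + k].split()[0]) for k in range(cnt)]
        row += cnt
        for k, t in enumerate(tags):
            tag2idx[t] = filled + k
            coords[filled + k] = [float(v) for v in body[row + k].split()[:3]]
        row += cnt
        filled += cnt

    tets: list[tuple[int, list[int], str]] = []  # (element tag, nodes, label)
    tris_by_patch: dict[str, list[list[int]]] = {}
    body = sections["Elements"]
    n_blocks = int(body[0].split()[0])
    row = 1
    for _ in range(n_blocks):
        dim, ent, etype, cnt = (int(v) for v in body[row].split())
        row += 1
        label = None
        if (dim, ent) in ent_phys:
            label = phys.get((dim, ent_phys[(dim, ent)]))
        for k in range(cnt):
            parts = [int(v) for v in body[row + k].split()]
            nodes = [tag2idx[t] for t in parts[1:]]
            if etype == 4:
                if label is None:
                    raise LabelError(f"{path}: tetrahedra without a region label")
                tets.append((parts[0], nodes, label))
            elif etype == 2 and label is not None:
                tris_by_patch.setdefault(label, []).append(nodes)
        row += cnt
    if not tets:
        raise FormatError(f"{path}: no tetrahedra found")
    tets.sort(key=lambda t: t[0])  # restore original element order
    patches = {k: np.array(v) for k, v in tris_by_patch.items()}
    return LabeledTetMesh.create(
        coords, np.array([t[1] for t in tets]), [t[2] for t in tets], patches
    )


# --------------------------------------------------------------------------
# I/O: VTK .vtu ASCII (+ YAML label sidecar)
# --------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".labels.yaml")


def _write_vtu(mesh: LabeledTetMesh, path: Path) -> None:
    regions, patches = _label_tables(mesh)
    tris = [mesh.boundary_patches[n] for n in sorted(mesh.boundary_patches)]
    tri_ids = np.concatenate(
        [np.full(len(t), patches[n]) for n, t in zip(sorted(mesh.boundary_patches), tris)]
    ) if tris else np.zeros(0, dtype=int)
    tris = np.vstack(tris) if tris else np.zeros((0, 3), dtype=int)

    tet_ids = np.array([regions[lab] for lab in mesh.region_label])
    n_cells = mesh.n_tets + len(tris)

    conn = np.concatenate([tris.ravel(), mesh.tets.ravel()])
    offs = np.concatenate([
        np.arange(1, len(tris) + 1) * 3,
        len(tris) * 3 + np.arange(1, mesh.n_tets + 1) * 4,
    ])
    types = np.concatenate([np.full(len(tris), 5), np.full(mesh.n_tets, 10)])
    ids = np.concatenate([tri_ids, tet_ids])

    def arr(tag: str, data: Iterable, dtype: str, ncomp: int | None = None) -> str:
        comp = f' NumberOfComponents="{ncomp}"' if ncomp else ""
        body = " ".join(str(v) for v in data)
        return (
            f'<DataArray type="{dtype}" Name="{tag}"{comp} format="ascii">\n'
            f"{body}\n</DataArray>\n"
        )

    pts = " ".join(f"{v:.17g}" for v in mesh.node_coords.ravel())
    xml = io.StringIO()
    xml.write('<?xml version="1.0"?>\n')
    xml.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
    xml.write("<UnstructuredGrid>\n")
    xml.write(f'<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{n_cells}">\n')
    xml.write("<Points>\n")
    xml.write(f'<DataArray type="Float64" NumberOfComponents="3" format="ascii">\n{pts}\n</DataArray>\n')
    xml.write("</Points>\n<Cells>\n")
    xml.write(arr("connectivity", conn, "Int64"))
    xml.write(arr("offsets", offs, "Int64"))
    xml.write(arr("types", types, "UInt8"))
    xml.write("</Cells>\n<CellData>\n")
    xml.write(arr("label_id", ids, "Int64"))
    xml.write("</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")
    path.write_text(xml.getvalue())

    sidecar = {
        "regions": {int(tag): name for name, tag in regions.items()},
        "patches": {int(tag): name for name, tag in patches.items()},
    }
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar))


def _read_vtu(path: Path) -> LabeledTetMesh:
    side = _sidecar_path(path)
    if not side.exists():
        raise LabelError(f"{path}: label sidecar {side.name} not found")
    tables = yaml.safe_load(side.read_text())
    regions = {int(k): str(v) for k, v in (tables.get("regions") or {}).items()}
    patch_names = {int(k): str(v) for k, v in (tables.get("patches") or {}).items()}

    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise FormatError(f"{path}: no <Piece> element")

    def parse_floats(text: str) -> np.ndarray:
        return np.array((text or "").split(), dtype=float)

    def data(name: str, parent: str) -> np.ndarray:
        for da in piece.find(parent).iter("DataArray"):
            if parent == "Points" or da.get("Name") == name:
                return parse_floats(da.text)
        raise FormatError(f"{path}: missing array {name!r}")

    coords = data("", "Points").reshape(-1, 3)
    conn = data("connectivity", "Cells").astype(int)
    offs = data("offsets", "Cells").astype(int)
    types = data("types", "Cells").astype(int)
    cd = piece.find("CellData")
    if cd is None:
        raise LabelError(f"{path}: no CellData (label_id required)")
    ids = None
    for da in cd.iter("DataArray"):
        if da.get("Name") == "label_id":
            ids = parse_floats(da.text).astype(int)
    if ids is None:
        raise LabelError(f"{path}: no label_id cell array")

    starts = np.concatenate([[0], offs[:-1]])
    tets, tet_labels = [], []
    tris_by_patch: dict[str, list[list[int]]] = {}
    for ctype, s, e, lid in zip(types, starts, offs, ids):
        nodes = conn[s:e].tolist()
        if ctype == 10:
            if lid not in regions:
                raise LabelError(f"{path}: tet label id {lid} not in sidecar")
            tets.append(nodes)
            tet_labels.append(regions[lid])
        elif ctype == 5:
            name = patch_names.get(lid)
            if name is not None:
                tris_by_patch.setdefault(name, []).append(nodes)
    if not tets:
        raise FormatError(f"{path}: no tetrahedra found")
    patches = {k: np.array(v) for k, v in tris_by_patch.items()}
    return LabeledTetMesh.create(coords, np.array(tets), tet_labels, patches)


# --------------------------------------------------------------------------
# public I/O surface
# --------------------------------------------------------------------------

_FORMATS = {"msh": (_read_msh, _write_msh), "vtu": (_read_vtu, _write_vtu)}


def _resolve_format(path: Path, fmt: str | None) -> str:
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise FormatError(
            f"unsupported mesh format {fmt!r}; supported: {sorted(_FORMATS)}"
        )
    return fmt


def read_mesh(path: str | Path, format: str | None = None) -> LabeledTetMesh:
    """Read a labeled tet mesh (Gmsh .msh v4 ASCII or VTK .vtu ASCII).

    Orientation is repaired (inverted tets flipped to positive volume);
    degenerate elements and missing labels raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    reader, _ = _FORMATS[_resolve_format(path, format)]
    return reader(path)


def write_mesh(mesh: LabeledTetMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh; ``read_mesh(write_mesh(m))`` round-trips connectivity
    and labels exactly and coordinates to full double precision."""
    path = Path(path)
    _, writer = _FORMATS[_resolve_format(path, format)]
    writer(mesh, path)


def write_surface_vtp(
    tris: np.ndarray, coords: np.ndarray, path: str | Path,
    point_data: Mapping[str, np.ndarray] | None = None,
) -> None:
    """Export a triangle surface (with optional per-node vectors, e.g. a
    displacement field) as VTK .vtp for visualization."""
    tris = np.asarray(tris)
    ids = np.unique(tris)
    local = np.full(coords.shape[0] if len(coords) else 0, -1, dtype=int)
    local[ids] = np.arange(len(ids))
    pts = coords[ids]
    conn = local[tris].ravel()
    offs = np.arange(1, len(tris) + 1) * 3

    xml = io.StringIO()
    xml.write('<?xml version="1.0"?>\n')
    xml.write('<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">\n')
    xml.write("<PolyData>\n")
    xml.write(
        f'<Piece NumberOfPoints="{len(pts)}" NumberOfVerts="0" NumberOfLines="0" '
        f'NumberOfStrips="0" NumberOfPolys="{len(tris)}">\n'
    )
    xml.write("<Points>\n")
    xml.write('<DataArray type="Float64" NumberOfComponents="3" format="ascii">\n')
    xml.write(" ".join(f"{v:.17g}" for v in pts.ravel()))
    xml.write("\n</DataArray>\n</Points>\n")
    if point_data:
        xml.write("<PointData>\n")
        for name, vals in point_data.items():
            vals = np.asarray(vals)[ids]
            ncomp = vals.shape[1] if vals.ndim == 2 else 1
            xml.write(
                f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">\n'
            )
            xml.write(" ".join(f"{v:.17g}" for v in vals.ravel()))
            xml.write("\n</DataArray>\n")
        xml.write("</PointData>\n")
    xml.write("<Polys>\n")
    xml.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
    xml.write(" ".join(str(v) for v in conn))
    xml.write("\n</DataArray>\n")
    xml.write('<DataArray type="Int64" Name="offsets" format="ascii">\n')
    xml.write(" ".join(str(v) for v in offs))
    xml.write("\n</DataArray>\n</Polys>\n</Piece>\n</PolyData>\n</VTKFile>\n")
    Path(path).write_text(xml.getvalue())
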