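"""Wound deformation characterization: tortuosity and geodesic compression.

A surgical wound is an elliptic cylinder through the wall with two end lids
(on the inner and outer wall surfaces) and a lateral surface.  Its
deformation is quantified by pairing every node on the rim of one lid with
the Euclidean-nearest node on the rim of the opposite lid and tracking, for
the full pair set, the mean Euclidean distance d and the mean graph-geodesic
distance D (shortest path over the lateral-surface edge graph):

* mean tortuosity        tau = D / d          (surface undulation)
* tortuosity change      dtau = 100 (tau_f - tau_0) / tau_0   [%]
* geodesic deformation   G_d = D_f / D_0      (< 1: depth compression)

together with the wound's boundary surface area (both lids + lateral
surface) and region volume in the undeformed and deformed configurations.

The pairing is established once on the undeformed geometry and reused for
the deformed one, so pairs stay comparable.  Every node of *both* rims acts
as an "i" node (the symmetric convention); ties in the nearest-node search
break to the smallest node index.  Because the generator meshes the lateral
surface in structured generatrix rings, the undeformed graph geodesic is a
straight rim-to-rim polyline and tau_0 is 1 up to the small graph slack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.csgraph as csgraph

from .mesh_core import (
    LabeledTetMesh,
    SurfacePatch,
    boundary_faces_of,
    surface_area,
    tet_volumes,
)

__all__ = [
    "TopologyError",
    "RimPairing",
    "WoundDeformationReport",
    "extract_wound_rims",
    "pair_rims",
    "geodesic_distance",
    "rim_distances",
    "deformation_report",
]


class TopologyError(ValueError):
    """The wound region does not have the expected cylinder topology."""


# --------------------------------------------------------------------------
# rim extraction
# --------------------------------------------------------------------------

def _edge_set(tris: np.ndarray) -> set[tuple[int, int]]:
    e = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    e = np.sort(e, axis=1)
    return {tuple(row) for row in e.tolist()}


def _single_loop(edges: set[tuple[int, int]], wound_id: str, which: str) -> np.ndarray:
    """Check the edges form one closed loop; return its node set."""
    from collections import defaultdict

    adj: dict[int, list[int]] = defaultdict(list)
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    nodes = sorted(adj)
    if not nodes:
        raise TopologyError(f"wound {wound_id}: empty {which} rim")
    if any(len(adj[n]) != 2 for n in nodes):
        raise TopologyError(
            f"wound {wound_id}: {which} rim is not a simple closed loop"
        )
    seen = {nodes[0]}
    frontier = [nodes[0]]
    while frontier:
        n = frontier.pop()
        for m in adj[n]:
            if m not in seen:
                seen.add(m)
                frontier.append(m)
    if len(seen) != len(nodes):
        raise TopologyError(
            f"wound {wound_id}: {which} rim has multiple loops"
        )
    return np.array(nodes, dtype=np.int64)


def extract_wound_rims(
    mesh: LabeledTetMesh, wound_id: str
) -> tuple[SurfacePatch, np.ndarray, np.ndarray]:
    """Lateral surface and the two rim node loops of a through-wall wound.

    The wound region's closed boundary is split into the outer lid (faces on
    the mesh ``outer_surface``), the inner lid (on ``inner_surface``) and
    the lateral surface (interior faces).  Rims are the node loops shared
    between the lateral surface and each lid.

    Returns ``(lateral_patch, inner_rim_nodes, outer_rim_nodes)``.
    """
    label = wound_id if wound_id.startswith("wound:") else f"wound:{wound_id}"
    wtets = mesh.region_tets(label)
    wfaces = boundary_faces_of(wtets)

    def face_keys(tris: np.ndarray) -> set[tuple[int, ...]]:
        return {tuple(row) for row in np.sort(tris, axis=1).tolist()}

    outer = face_keys(mesh.boundary_patches.get("outer_surface", np.zeros((0, 3), int)))
    inner = face_keys(mesh.boundary_patches.get("inner_surface", np.zeros((0, 3), int)))
    keys = [tuple(row) for row in np.sort(wfaces, axis=1).tolist()]
    is_outer = np.array([k in outer for k in keys])
    is_inner = np.array([k in inner for k in keys])
    lateral = wfaces[~(is_outer | is_inner)]
    lid_outer = wfaces[is_outer]
    lid_inner = wfaces[is_inner]
    if len(lid_outer) == 0 or len(lid_inner) == 0:
        raise TopologyError(
            f"wound {wound_id}: lids not found on both wall surfaces "
            "(only through-wall wounds are supported)"
        )
    if len(lateral) == 0:
        raise TopologyError(f"wound {wound_id}: no lateral surface")

    lat_edges = _edge_set(lateral)
    rim_outer = _single_loop(lat_edges & _edge_set(lid_outer), wound_id, "outer")
    rim_inner = _single_loop(lat_edges & _edge_set(lid_inner), wound_id, "inner")
    return SurfacePatch(lateral, mesh), rim_inner, rim_outer


# --------------------------------------------------------------------------
# pairing and distances
# --------------------------------------------------------------------------

@dataclass
class RimPairing:
    """Nearest-opposite-rim pairing established on the undeformed geometry.

    ``pairs`` holds one row (i, j) per rim node of *both* lids; ``d0`` and
    ``D0`` are the undeformed Euclidean and graph-geodesic distances (mm).
    """

    pairs: np.ndarray  # (n, 2) node ids
    d0: np.ndarray
    D0: np.ndarray

    def __post_init__(self) -> None:
        bad = self.D0 < self.d0 - 1e-9
        if np.any(bad):
            raise ValueError(
                "geodesic shorter than Euclidean distance for pairs "
                f"{np.flatnonzero(bad)[:5].tolist()}"
            )


def _nearest_opposite(
    src: np.ndarray, dst: np.ndarray, coords: np.ndarray
) -> np.ndarray:
    """For each node in src, the Euclidean-nearest node of dst (ties to the
    smallest node index; dst is sorted so argmin picks it)."""
    d = np.linalg.norm(
        coords[src][:, None, :] - coords[dst][None, :, :], axis=2
    )
    return dst[np.argmin(d, axis=1)]


def rim_distances(
    lateral: SurfacePatch,
    pairs: np.ndarray,
    coords: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean and graph-geodesic distances of rim pairs at ``coords``.

    The geodesic is the shortest path over the lateral-surface edge graph
    with edge lengths measured at the supplied coordinates (Dijkstra, all
    sources batched).
    """
    ids, graph = lateral.edge_graph(coords)
    lookup = {int(g): i for i, g in enumerate(ids)}
    try:
        src_local = np.array([lookup[int(i)] for i in pairs[:, 0]])
        dst_local = np.array([lookup[int(j)] for j in pairs[:, 1]])
    except KeyError as exc:
        raise ValueError(f"pair node {exc} not on the lateral surface")
    uniq, inv = np.unique(src_local, return_inverse=True)
    dmat = csgraph.dijkstra(graph, directed=False, indices=uniq)
    geo = dmat[inv, dst_local]
    if np.any(~np.isfinite(geo)):
        raise ValueError("disconnected rim pair on the lateral surface")
    euc = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return euc, geo


def geodesic_distance(
    lateral: SurfacePatch, i: int, j: int, coords: np.ndarray
) -> float:
    """Shortest-path length (mm) between two patch nodes along the edge
    graph at the supplied coordinates."""
    _, geo = rim_distances(lateral, np.array([[i, j]]), coords)
    return float(geo[0])


def pair_rims(
    lateral: SurfacePatch,
    rim_a: np.ndarray,
    rim_b: np.ndarray,
    coords: np.ndarray,
) -> RimPairing:
    """Pair every node of both rims with its nearest opposite-rim node and
    record undeformed Euclidean/geodesic distances."""
    rim_a = np.sort(np.asarray(rim_a, dtype=np.int64))
    rim_b = np.sort(np.asarray(rim_b, dtype=np.int64))
    if rim_a.size == 0 or rim_b.size == 0:
        raise ValueError("empty rim")
    pa = np.stack([rim_a, _nearest_opposite(rim_a, rim_b, coords)], axis=1)
    pb = np.stack([rim_b, _nearest_opposite(rim_b, rim_a, coords)], axis=1)
    pairs = np.vstack([pa, pb])
    d0, g0 = rim_distances(lateral, pairs, coords)
    return RimPairing(pairs, d0, g0)


# --------------------------------------------------------------------------
# deformation report
# --------------------------------------------------------------------------

@dataclass
class WoundDeformationReport:
    """All shape-change statistics of one wound in one load case."""

    wound_id: str
    d0_mean: float
    D0_mean: float
    df_mean: float
    Df_mean: float
    tau0: float
    tauf: float
    delta_tau_pct: float
    G_d: float
    area0: float
    areaf: float
    vol0: float
    volf: float
    P_a_kPa: float | None = None
    E_w_MPa: float | None = None

    @property
    def d_area_pct(self) -> float:
        return 100.0 * (self.areaf - self.area0) / self.area0

    @property
    def d_vol_pct(self) -> float:
        return 100.0 * (self.volf - self.vol0) / self.vol0

    def row(self) -> dict:
        """Flat record for CSV/JSON export."""
        return {
            "wound_id": self.wound_id,
            "P_a_kPa": self.P_a_kPa,
            "E_w_MPa": self.E_w_MPa,
            "G_d": self.G_d,
            "delta_tau_pct": self.delta_tau_pct,
            "area0_mm2": self.area0,
            "areaf_mm2": self.areaf,
            "vol0_mm3": self.vol0,
            "volf_mm3": self.volf,
            "d_area_pct": self.d_area_pct,
            "d_vol_pct": self.d_vol_pct,
        }


def deformation_report(
    mesh: LabeledTetMesh,
    wound_id: str,
    pairing: RimPairing,
    coords0: np.ndarray,
    coords_f: np.ndarray,
    *,
    lateral: SurfacePatch | None = None,
    P_a_kPa: float | None = None,
    E_w_MPa: float | None = None,
) -> WoundDeformationReport:
    """Compare a wound between two configurations using a fixed pairing.

    ``coords0``/``coords_f`` are full node coordinate arrays (the deformed
    one typically ``mesh.node_coords + u``).  The pairing must have been
    built on ``coords0`` for this wound.
    """
    for c in (coords0, coords_f):
        if c.shape != mesh.node_coords.shape:
            raise ValueError("coordinate array does not match the mesh")
    if lateral is None:
        lateral, _, _ = extract_wound_rims(mesh, wound_id)

    d0, g0 = rim_distances(lateral, pairing.pairs, coords0)
    df, gf = rim_distances(lateral, pairing.pairs, coords_f)
    d0m, g0m, dfm, gfm = (float(x.mean()) for x in (d0, g0, df, gf))
    tau0 = g0m / d0m
    tauf = gfm / dfm

    label = wound_id if wound_id.startswith("wound:") else f"wound:{wound_id}"
    wtets = mesh.region_tets(label)
    wfaces = boundary_faces_of(wtets)
    return WoundDeformationReport(
        wound_id=wound_id.removeprefix("wound:"),
        d0_mean=d0m,
        D0_mean=g0m,
        df_mean=dfm,
        Df_mean=gfm,
        tau0=tau0,
        tauf=tauf,
        delta_tau_pct=100.0 * (tauf - tau0) / tau0,
        G_d=gfm / g0m,
        area0=surface_area(wfaces, coords0),
        areaf=surface_area(wfaces, coords_f),
        vol0=float(tet_volumes(coords0, wtets).sum()),
        volf=float(tet_volumes(coords_f, wtets).sum()),
        P_a_kPa=P_a_kPa,
        E_w_MPa=E_w_MPa,
    )
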