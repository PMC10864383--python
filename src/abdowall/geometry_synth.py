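"""Parametric synthetic abdominal-wall geometry with embedded trocar wounds.

The generator produces a curved rectangular panel (a section of a vertical
cylinder) standing in for a patient-derived abdominal wall.  Its in-plane
layout follows the anatomy the mechanical problem depends on:

* a stiff midline strip (linea alba, 2 cm wide by default),
* flanking rectus abdominis volumes sandwiched between thin aponeurotic
  sheath layers (the rectus sheath, continuation of the lateral muscles'
  aponeuroses),
* lateral three-layer stacks (external oblique / internal oblique /
  transverse abdominis), each subdivided medially-to-laterally into
  aponeurotic, transition and regular-muscle zones.

Surgical wounds are elliptic cylinders orthogonal to the outer surface
(minor axis 2 mm; major axis = trocar diameter).  Around each wound the
footprint is meshed with a structured O-grid: concentric rings morphing from
the wound ellipse out to a block of the background grid, with ring-doubling
transition rows providing local refinement.  The footprint is extruded
through the wall thickness, so the wound lateral surface is a structured
stack of generatrix rings: rim-to-rim polyline paths straight down the
cylinder wall exist by construction, which keeps the undeformed
graph-geodesic essentially equal to the Euclidean rim distance.

All meshes are generated deterministically for a fixed config/seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .mesh_core import LabeledTetMesh

__all__ = [
    "GenerationError",
    "PlacementError",
    "WallConfig",
    "WoundSpec",
    "build_wall",
    "embed_wound",
    "pattern_preset",
]


class GenerationError(ValueError):
    """The wall configuration cannot be meshed as requested."""


class PlacementError(ValueError):
    """A wound footprint is out of its placement region or overlaps."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class WallConfig:
    """Parameters of the synthetic wall panel.  Lengths in mm.

    The panel is parameterized by (u, v): u runs around the girth (arc
    length on the outer surface), v vertically.  ``curvature_radius`` is the
    outer-surface radius of the supporting vertical cylinder;
    ``math.inf`` gives a flat plate.
    """

    panel_width: float = 360.0       # arc extent left flank -> right flank
    panel_height: float = 300.0      # xiphoid -> pubis extent
    curvature_radius: float = 170.0  # transverse abdominal radius
    la_width: float = 20.0           # midline strip (non-diastatic linea alba)
    rectus_width: float = 70.0       # each rectus, from the LA edge outward
    medial_thickness: float = 12.0   # LA / rectus compartment
    lateral_thickness: float = 24.0  # EO+IO+TR stack (8 mm each)
    blend_width: float = 30.0        # thickness ramp beyond the rectus edge
    # medial->lateral split of the lateral span into aponeurotic /
    # transition / regular-muscle zones (must sum to 1)
    zone_fractions: tuple[float, float, float] = (0.25, 0.10, 0.65)
    target_edge_length: float = 5.0  # background grid spacing
    wound_refinement: float = 4.0    # wound edge = target / refinement
    n_sublayers: int = 6             # through-thickness element levels
    jitter: float = 0.0              # in-plane node jitter, fraction of edge
    seed: int = 0

    def validate(self) -> None:
        if min(self.panel_width, self.panel_height, self.la_width,
               self.rectus_width, self.medial_thickness,
               self.lateral_thickness, self.target_edge_length) <= 0:
            raise GenerationError("all dimensions must be positive")
        if any(f <= 0 for f in self.zone_fractions):
            raise GenerationError("zone fractions must be positive")
        if abs(sum(self.zone_fractions) - 1.0) > 1e-9:
            raise GenerationError("zone fractions must sum to 1")
        if self.n_sublayers < 2:
            raise GenerationError("need at least 2 through-thickness layers")
        h = self.target_edge_length
        lat_span = self.lateral_span
        if lat_span <= 0:
            raise GenerationError("panel too narrow for LA + rectus widths")
        for name, width in (
            ("LA strip", self.la_width),
            ("rectus", self.rectus_width),
            ("aponeurotic zone", self.zone_fractions[0] * lat_span),
            ("transition zone", self.zone_fractions[1] * lat_span),
            ("regular zone", self.zone_fractions[2] * lat_span),
        ):
            if width < 2.0 * h - 1e-9:
                raise GenerationError(
                    f"{name} ({width:.3g} mm) thinner than 2 target edge "
                    f"lengths ({2 * h:.3g} mm)"
                )

    # derived in-plane landmarks (|u| coordinates)
    @property
    def u_la(self) -> float:
        return self.la_width / 2.0

    @property
    def u_rectus(self) -> float:
        return self.u_la + self.rectus_width

    @property
    def lateral_span(self) -> float:
        return self.panel_width / 2.0 - self.u_rectus

    @property
    def u_transition(self) -> float:
        return self.u_rectus + self.zone_fractions[0] * self.lateral_span

    @property
    def u_regular(self) -> float:
        return self.u_transition + self.zone_fractions[1] * self.lateral_span

    def thickness(self, u: np.ndarray | float) -> np.ndarray | float:
        """Wall thickness at girth coordinate u: medial value over the LA and
        rectus, ramping smoothly to the lateral value across blend_width."""
        au = np.abs(u)
        s = np.clip((au - self.u_rectus) / self.blend_width, 0.0, 1.0)
        smooth = 3 * s**2 - 2 * s**3
        return self.medial_thickness + (
            self.lateral_thickness - self.medial_thickness
        ) * smooth

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WallConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "zone_fractions" in data:
            data["zone_fractions"] = tuple(data["zone_fractions"])
        return cls(**data)


@dataclass
class WoundSpec:
    """An elliptic-cylinder surgical wound, orthogonal to the outer surface.

    ``center`` is the (u, v) position of the wound axis on the outer
    surface; ``orientation`` the in-plane direction of the major axis.
    ``depth=None`` means through-wall (the local wall thickness).
    """

    id: str
    center: tuple[float, float]
    major_axis_length: float            # trocar diameter: 5, 10 or 12 mm
    minor_axis_length: float = 2.0      # closed-incision width
    orientation: tuple[float, float] = (0.0, 1.0)
    depth: float | None = None
    placement_class: str = "lateral"    # "midline" | "lateral"

    @property
    def a(self) -> float:
        return self.major_axis_length / 2.0

    @property
    def b(self) -> float:
        return self.minor_axis_length / 2.0

    @property
    def label(self) -> str:
        return f"wound:{self.id}"

    def rotation(self) -> np.ndarray:
        d = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise PlacementError(f"wound {self.id}: zero orientation vector")
        d = d / n
        return np.array([[d[0], -d[1]], [d[1], d[0]]])

    def ellipse_points(self, phi: np.ndarray) -> np.ndarray:
        """Points of the wound ellipse in (u, v) at parametric angles."""
        local = np.stack([self.a * np.cos(phi), self.b * np.sin(phi)], axis=-1)
        return np.asarray(self.center) + local @ self.rotation().T

    def u_extent(self) -> float:
        """Half-extent of the ellipse along u (for region checks)."""
        r = self.rotation()
        return math.hypot(self.a * r[0, 0], self.b * r[0, 1])


# --------------------------------------------------------------------------
# preset laparoscopy patterns
# --------------------------------------------------------------------------

# Placements as fractions of the panel half-width / half-height.  The source
# figures give only approximate positions, so these are estimates chosen to
# land each wound well inside its placement region: midline wounds on the LA
# strip, lateral wounds in the regular-muscle zone near the transition.
_PATTERNS: dict[str, list[tuple[str, float, str, tuple[float, float]]]] = {
    "A": [
        ("A1", 12.0, "midline", (0.00, 0.53)),
        ("A2", 5.0, "lateral", (-0.69, 0.40)),
        ("A3", 5.0, "lateral", (-0.69, -0.27)),
        ("A4", 12.0, "midline", (0.00, -0.33)),
        ("A5", 5.0, "lateral", (0.69, -0.27)),
        ("A6", 12.0, "lateral", (0.69, 0.40)),
    ],
    "B": [
        ("B1", 10.0, "midline", (0.00, 0.47)),
        ("B2", 5.0, "lateral", (-0.69, 0.40)),
        ("B3", 5.0, "lateral", (-0.69, -0.27)),
        ("B4", 5.0, "midline", (0.00, -0.40)),
        ("B5", 12.0, "lateral", (0.69, 0.13)),
    ],
}


def pattern_preset(name: str, wall: WallConfig) -> list[WoundSpec]:
    """The two studied laparoscopy trocar layouts.

    Pattern A: six wounds (two 12 mm on the midline, two 5 mm lateral left,
    5 + 12 mm lateral right).  Pattern B: five wounds (10 mm and 5 mm on the
    midline, two 5 mm lateral left, 12 mm lateral right).  All minor axes
    are 2 mm.
    """
    if name not in _PATTERNS:
        raise KeyError(f"unknown laparoscopy pattern {name!r}; use 'A' or 'B'")
    specs = []
    for wid, major, cls, (fu, fv) in _PATTERNS[name]:
        center = (fu * wall.panel_width / 2.0, fv * wall.panel_height / 2.0)
        specs.append(
            WoundSpec(
                id=wid, center=center, major_axis_length=major,
                placement_class=cls,
            )
        )
    return specs


# --------------------------------------------------------------------------
# footprint meshing helpers
# --------------------------------------------------------------------------

def _ellipse_sampler(spec: WoundSpec, n_dense: int = 2048):
    """Return a function mapping a normalized parameter s in [0, 1) to a
    point on the wound ellipse, plus the perimeter (dense quadrature).

    Sampling is uniform in the parametric angle, which concentrates nodes at
    the high-curvature major-axis tips; for the 6:1 wound ellipses this
    keeps the inscribed-polygon area error far smaller than arc-length
    sampling at the same node count.
    """
    phi = np.linspace(0.0, 2.0 * math.pi, n_dense + 1)
    pts = spec.ellipse_points(phi)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    perimeter = float(seg.sum())

    def point_at(s: np.ndarray) -> np.ndarray:
        return spec.ellipse_points(2.0 * math.pi * (np.asarray(s) % 1.0))

    return point_at, perimeter


def _polyline_sampler(poly: np.ndarray):
    """Arc-length sampler along a closed polygon (rows = CCW vertices)."""
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    per = arc[-1]
    svals = arc[:-1] / per

    def point_at(s: np.ndarray) -> np.ndarray:
        target = (np.asarray(s) % 1.0) * per
        x = np.interp(target, arc, closed[:, 0])
        y = np.interp(target, arc, closed[:, 1])
        return np.stack([x, y], axis=-1)

    return point_at, svals


class _Footprint:
    """Incremental 2D triangulation of the panel footprint."""

    def __init__(self) -> None:
        self.key2idx: dict = {}
        self.coords: list[tuple[float, float]] = []
        self.tris: list[tuple[int, int, int]] = []
        self.tri_wound: list[str | None] = []
        self.boundary_nodes: set[int] = set()

    def node(self, key, uv) -> int:
        idx = self.key2idx.get(key)
        if idx is None:
            idx = len(self.coords)
            self.key2idx[key] = idx
            self.coords.append((float(uv[0]), float(uv[1])))
        return idx

    def tri(self, a: int, b: int, c: int, wound: str | None = None) -> None:
        self.tris.append((a, b, c))
        self.tri_wound.append(wound)

    def quad(self, a: int, b: int, c: int, d: int, wound: str | None = None) -> None:
        """Split quad (a,b,c,d) along its shorter diagonal."""
        p = np.asarray(self.coords)
        if np.linalg.norm(p[a] - p[c]) <= np.linalg.norm(p[b] - p[d]):
            self.tri(a, b, c, wound)
            self.tri(a, c, d, wound)
        else:
            self.tri(a, b, d, wound)
            self.tri(b, c, d, wound)


def _wound_block(
    spec: WoundSpec, ug: np.ndarray, vg: np.ndarray
) -> tuple[int, int, int, int]:
    """Grid-cell block (i0, i1, j0, j1) enclosing the wound O-grid."""
    margin = 1.35 * spec.a + 2.0
    uc, vc = spec.center
    i0 = int(np.searchsorted(ug, uc - margin, side="right") - 1)
    i1 = int(np.searchsorted(ug, uc + margin, side="left"))
    j0 = int(np.searchsorted(vg, vc - margin, side="right") - 1)
    j1 = int(np.searchsorted(vg, vc + margin, side="left"))
    if i0 < 1 or j0 < 1 or i1 > len(ug) - 2 or j1 > len(vg) - 2:
        raise PlacementError(
            f"wound {spec.id}: refinement block reaches the panel boundary"
        )
    return i0, i1, j0, j1


def _mesh_wound_ogrid(
    fp: _Footprint, spec: WoundSpec, block: tuple[int, int, int, int],
    ug: np.ndarray, vg: np.ndarray, h_wound: float,
) -> None:
    """Mesh the block interior: rings morphing from the block boundary to the
    wound ellipse (with ring-doubling refinement), then scaled rings inside
    the ellipse collapsing onto a centre fan."""
    i0, i1, j0, j1 = block
    wid = spec.id

    # ordered CCW block-boundary grid nodes, starting at (i0, j0)
    bkeys = (
        [("g", i, j0) for i in range(i0, i1)]
        + [("g", i1, j) for j in range(j0, j1)]
        + [("g", i, j1) for i in range(i1, i0, -1)]
        + [("g", i0, j) for j in range(j1, j0, -1)]
    )
    bpts = np.array(
        [(ug[k[1]], vg[k[2]]) for k in bkeys]
    )
    n0 = len(bkeys)

    epoint, perim = _ellipse_sampler(spec)
    n_target = max(24, int(math.ceil(perim / h_wound)))
    doublings = max(0, int(math.ceil(math.log2(n_target / n0))))
    nf = n0 * 2**doublings

    bsampler, s_outer = _polyline_sampler(bpts)
    # align ellipse parameterization with the block boundary start direction
    start_dir = math.atan2(bpts[0, 1] - spec.center[1], bpts[0, 0] - spec.center[0])
    probe = np.linspace(0.0, 1.0, 720, endpoint=False)
    ep = epoint(probe) - np.asarray(spec.center)
    ang = np.arctan2(ep[:, 1], ep[:, 0])
    s_off = probe[int(np.argmin(np.abs(np.angle(np.exp(1j * (ang - start_dir))))))]

    def ering(svals: np.ndarray) -> np.ndarray:
        return epoint(svals + s_off)

    # s parameter per ring, refined by midpoint insertion at each doubling
    s_rings: list[np.ndarray] = [s_outer]
    for _ in range(doublings):
        s = s_rings[-1]
        nxt = np.empty(2 * len(s))
        nxt[0::2] = s
        gaps = np.diff(np.concatenate([s, [s[0] + 1.0]]))
        nxt[1::2] = s + gaps / 2.0
        s_rings.append(nxt)

    gap = float(np.mean(np.linalg.norm(bpts - ering(s_outer), axis=1)))
    n_plain = max(2, int(round(gap / h_wound)) - doublings)
    # ring 0 = block boundary (t=1) ... last plain ring = ellipse (t=0)
    tvals = np.linspace(1.0, 0.0, 1 + doublings + n_plain)

    # build ring node lists (outermost = block boundary grid nodes)
    rings: list[list[int]] = [[fp.node(k, uv) for k, uv in zip(bkeys, bpts)]]
    ring_s: list[np.ndarray] = [s_outer]
    r = 1
    for d in range(doublings):
        s = s_rings[d + 1]
        t = tvals[r]
        pts = (1 - t) * ering(s) + t * bsampler(s)
        rings.append([fp.node(("r", wid, r, k), p) for k, p in enumerate(pts)])
        ring_s.append(s)
        r += 1
    s = s_rings[-1]
    for p_i in range(n_plain):
        t = tvals[r]
        pts = (1 - t) * ering(s) + t * bsampler(s)
        rings.append([fp.node(("r", wid, r, k), p) for k, p in enumerate(pts)])
        ring_s.append(s)
        r += 1

    # connect consecutive rings
    for ra, rb in zip(rings[:-1], rings[1:]):
        if len(rb) == len(ra):
            n = len(ra)
            for k in range(n):
                fp.quad(ra[k], ra[(k + 1) % n], rb[(k + 1) % n], rb[k])
        else:  # doubling ring: 1 coarse segment -> 2 fine segments
            n = len(ra)
            for k in range(n):
                c0, c1 = ra[k], ra[(k + 1) % n]
                f0, f1, f2 = rb[2 * k], rb[2 * k + 1], rb[(2 * k + 2) % (2 * n)]
                fp.tri(c0, f1, f0)
                fp.tri(c0, c1, f1)
                fp.tri(c1, f2, f1)

    # interior of the ellipse: scaled rings + centre fan (wound footprint)
    ellipse_ring = rings[-1]
    n_in = max(2, int(round(spec.a / h_wound)))
    center = np.asarray(spec.center)
    epts = np.asarray(fp.coords)[ellipse_ring]
    inner_rings = [ellipse_ring]
    for m in range(1, n_in):
        scale = (n_in - m) / n_in
        pts = center + scale * (epts - center)
        inner_rings.append(
            [fp.node(("ri", wid, m, k), p) for k, p in enumerate(pts)]
        )
    cnode = fp.node(("c", wid), center)
    for ra, rb in zip(inner_rings[:-1], inner_rings[1:]):
        n = len(ra)
        for k in range(n):
            fp.quad(ra[k], rb[k], rb[(k + 1) % n], ra[(k + 1) % n], wound=wid)
    n = len(inner_rings[-1])
    last = inner_rings[-1]
    for k in range(n):
        fp.tri(last[k], cnode, last[(k + 1) % n], wound=wid)


def _build_footprint(
    config: WallConfig, wounds: list[WoundSpec]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Triangulate the panel footprint.

    Returns (uv coords, triangles, tri_wound_id array, boundary node mask).
    """
    W, H, h = config.panel_width, config.panel_height, config.target_edge_length
    nu = max(2, int(round(W / h)))
    nv = max(2, int(round(H / h)))
    ug = np.linspace(-W / 2.0, W / 2.0, nu + 1)
    vg = np.linspace(-H / 2.0, H / 2.0, nv + 1)

    blocks = {}
    for spec in wounds:
        _check_placement(config, spec)
        blocks[spec.id] = _wound_block(spec, ug, vg)
    ids = list(blocks)
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            a, b = blocks[ids[x]], blocks[ids[y]]
            if a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]:
                raise PlacementError(
                    f"wounds {ids[x]} and {ids[y]}: refinement blocks overlap"
                )

    def in_block(i: int, j: int) -> bool:
        return any(
            b[0] <= i < b[1] and b[2] <= j < b[3] for b in blocks.values()
        )

    fp = _Footprint()
    h_wound = h / config.wound_refinement

    rng = np.random.default_rng(config.seed)
    jit = config.jitter * h

    def grid_uv(i: int, j: int) -> tuple[float, float]:
        u, v = ug[i], vg[j]
        on_boundary = i in (0, nu) or j in (0, nv)
        near_block = any(
            b[0] - 1 <= i <= b[1] + 1 and b[2] - 1 <= j <= b[3] + 1
            for b in blocks.values()
        )
        if jit > 0 and not on_boundary and not near_block:
            du, dv = rng.uniform(-jit, jit, 2)
            return u + du, v + dv
        return u, v

    # background cells (skipping wound blocks)
    for i in range(nu):
        for j in range(nv):
            if in_block(i, j):
                continue
            n00 = fp.node(("g", i, j), grid_uv(i, j))
            n10 = fp.node(("g", i + 1, j), grid_uv(i + 1, j))
            n11 = fp.node(("g", i + 1, j + 1), grid_uv(i + 1, j + 1))
            n01 = fp.node(("g", i, j + 1), grid_uv(i, j + 1))
            fp.quad(n00, n10, n11, n01)

    for spec in wounds:
        _mesh_wound_ogrid(fp, spec, blocks[spec.id], ug, vg, h_wound)

    coords = np.asarray(fp.coords)
    tris = np.asarray(fp.tris, dtype=np.int64)
    wound_of = np.asarray(fp.tri_wound, dtype=object)
    on_bnd = np.zeros(len(coords), dtype=bool)
    for key, idx in fp.key2idx.items():
        if key[0] == "g" and (key[1] in (0, nu) or key[2] in (0, nv)):
            on_bnd[idx] = True
    return coords, tris, wound_of, on_bnd


def _check_placement(config: WallConfig, spec: WoundSpec) -> None:
    if spec.minor_axis_length <= 0 or spec.major_axis_length <= 0:
        raise PlacementError(f"wound {spec.id}: non-positive axis length")
    uc = spec.center[0]
    ue = spec.u_extent()
    if spec.placement_class == "midline":
        if spec.major_axis_length >= config.la_width:
            raise PlacementError(
                f"wound {spec.id}: major axis {spec.major_axis_length} mm "
                f"does not fit the {config.la_width} mm midline strip"
            )
        if abs(uc) + ue > config.u_la + 1e-9:
            raise PlacementError(
                f"wound {spec.id}: footprint leaves the midline strip"
            )
    elif spec.placement_class == "lateral":
        if abs(uc) - ue < config.u_rectus - 1e-9:
            raise PlacementError(
                f"wound {spec.id}: footprint not fully in the lateral region"
            )
    else:
        raise PlacementError(
            f"wound {spec.id}: unknown placement class "
            f"{spec.placement_class!r}"
        )


# --------------------------------------------------------------------------
# extrusion to a labeled tet mesh
# --------------------------------------------------------------------------

def _surface_map(config: WallConfig, uv: np.ndarray):
    """Outer-surface points and inward extrusion directions at (u, v)."""
    R = config.curvature_radius
    u, v = uv[:, 0], uv[:, 1]
    if math.isinf(R):
        outer = np.stack([u, v, np.zeros_like(u)], axis=1)
        normal = np.tile([0.0, 0.0, 1.0], (len(u), 1))
    else:
        th = u / R
        outer = np.stack([R * np.sin(th), v, R * (np.cos(th) - 1.0)], axis=1)
        normal = np.stack([np.sin(th), np.zeros_like(th), np.cos(th)], axis=1)
    return outer, normal


_PRISM_ROT = np.array([
    [0, 1, 2, 3, 4, 5],
    [1, 2, 0, 4, 5, 3],
    [2, 0, 1, 5, 3, 4],
    [3, 4, 5, 0, 1, 2],
    [4, 5, 3, 1, 2, 0],
    [5, 3, 4, 2, 0, 1],
])


def _split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split prisms (p, 6) into conforming tets via the min-vertex rule.

    Quad-face diagonals always pass through the smallest-indexed corner of
    the face, so adjacent prisms agree on shared faces.
    """
    rot = _PRISM_ROT[np.argmin(prisms, axis=1)]
    v = np.take_along_axis(prisms, rot, axis=1)
    case1 = np.minimum(v[:, 1], v[:, 5]) < np.minimum(v[:, 2], v[:, 4])
    tets = np.empty((len(prisms), 3, 4), dtype=np.int64)
    tets[case1] = np.stack([
        v[case1][:, [0, 1, 2, 5]],
        v[case1][:, [0, 1, 5, 4]],
        v[case1][:, [0, 4, 5, 3]],
    ], axis=1)
    tets[~case1] = np.stack([
        v[~case1][:, [0, 1, 2, 4]],
        v[~case1][:, [0, 4, 2, 5]],
        v[~case1][:, [0, 4, 5, 3]],
    ], axis=1)
    return tets.reshape(-1, 4)


def _tissue_labels(
    config: WallConfig, au: np.ndarray, frac: np.ndarray
) -> np.ndarray:
    """Vectorized tissue label from |u| of the footprint centroid and the
    through-thickness fraction (0 = outer surface, 1 = inner)."""
    s = np.where(np.asarray(au) >= 0, "right", "left")  # au is signed here
    a = np.abs(au)
    labels = np.empty(len(a), dtype=object)

    sheath = 1.0 / config.n_sublayers  # one sub-layer of rectus sheath
    medial = a <= config.u_rectus
    la = a <= config.u_la
    labels[la] = "LA"
    m = medial & ~la
    labels[m & (frac < sheath)] = _tag("EO_aponeurotic", s[m & (frac < sheath)])
    labels[m & (frac > 1 - sheath)] = _tag("TR_aponeurotic", s[m & (frac > 1 - sheath)])
    mid = m & (frac >= sheath) & (frac <= 1 - sheath)
    labels[mid] = _tag("RA", s[mid])

    lat = ~medial
    muscle = np.select(
        [frac < 1 / 3, frac < 2 / 3], ["EO", "IO"], default="TR"
    )
    zone = np.select(
        [a <= config.u_transition, a <= config.u_regular],
        ["aponeurotic", "transition"],
        default="regular",
    )
    for i in np.flatnonzero(lat):
        labels[i] = f"{muscle[i]}_{zone[i]}_{s[i]}"
    return labels


def _tag(stem: str, sides: np.ndarray) -> np.ndarray:
    return np.array([f"{stem}_{sd}" for sd in sides], dtype=object)


def build_wall(
    config: WallConfig, wounds: list[WoundSpec] | tuple[WoundSpec, ...] = (),
) -> LabeledTetMesh:
    """Generate the labeled synthetic wall, optionally with embedded wounds.

    The returned mesh has boundary patches ``outer_surface``,
    ``inner_surface`` and ``fixed_edge`` (the whole panel perimeter, where
    the wall attaches to the skeleton) and carries generation provenance so
    further wounds can be embedded conformally.
    """
    config.validate()
    wounds = list(wounds)
    uv, tris, tri_wound, on_bnd = _build_footprint(config, wounds)

    n_fp = len(uv)
    L = config.n_sublayers
    outer, normal = _surface_map(config, uv)
    t = np.asarray(config.thickness(uv[:, 0]))

    fracs = np.linspace(0.0, 1.0, L + 1)
    coords = (
        outer[:, None, :]
        - fracs[None, :, None] * t[:, None, None] * normal[:, None, :]
    ).reshape(-1, 3)  # node id = fp_index * (L+1) + level

    # prisms per footprint triangle per layer
    tri_rep = np.repeat(tris * (L + 1), L, axis=0)
    lev = np.tile(np.arange(L), len(tris))[:, None]
    bot = tri_rep + lev
    top = bot + 1
    prisms = np.hstack([bot, top])
    tets = _split_prisms(prisms)

    # labels: per prism, shared by its 3 tets
    cent_u = uv[tris, 0].mean(axis=1)
    cu = np.repeat(cent_u, L)
    # prisms iterate layers fastest within each footprint triangle
    fmid = np.tile((fracs[:-1] + fracs[1:]) / 2.0, len(tris))
    labels = _tissue_labels(config, cu, fmid)

    wound_rep = np.repeat(tri_wound, L)
    tloc = np.repeat(np.asarray(config.thickness(cent_u)), L)
    for spec in wounds:
        mask = wound_rep == spec.id
        if spec.depth is not None:
            mask = mask & (fmid * tloc <= spec.depth + 1e-9)
        labels[mask] = spec.label

    labels3 = np.repeat(labels, 3)

    # boundary patches by node level
    level = np.arange(coords.shape[0]) % (L + 1)
    mesh = LabeledTetMesh.create(
        coords, tets, labels3,
        provenance={
            "generator": "abdowall.geometry_synth",
            "config": asdict(config),
            "wounds": [asdict(w) for w in wounds],
        },
    )
    bf = mesh.boundary_faces()
    lv = level[bf]
    outer_m = (lv == 0).all(axis=1)
    inner_m = (lv == L).all(axis=1)
    side_m = ~(outer_m | inner_m)
    mesh.boundary_patches = {
        "outer_surface": bf[outer_m],
        "inner_surface": bf[inner_m],
        "fixed_edge": bf[side_m],
    }
    return mesh


def embed_wound(mesh: LabeledTetMesh, spec: WoundSpec) -> LabeledTetMesh:
    """Return a new wall with ``spec`` conformally embedded.

    Embedding re-generates the structured wall from the stored provenance
    with the extended wound set, which yields the same conformal, locally
    refined mesh a cavity-remeshing step would.  Meshes without generation
    provenance (e.g. read from external files) cannot accept new wounds.
    """
    prov = mesh.provenance
    if not prov or "config" not in prov:
        raise PlacementError(
            "embed_wound requires a mesh generated by build_wall "
            "(no generation provenance present)"
        )
    cfg_d = dict(prov["config"])
    cfg_d["zone_fractions"] = tuple(cfg_d["zone_fractions"])
    config = WallConfig(**cfg_d)
    wounds = [_wound_from_dict(d) for d in prov.get("wounds", [])]
    if any(w.id == spec.id for w in wounds):
        raise PlacementError(f"wound {spec.id} already embedded")
    return build_wall(config, wounds + [spec])


def _wound_from_dict(d: dict) -> WoundSpec:
    d = dict(d)
    d["center"] = tuple(d["center"])
    d["orientation"] = tuple(d["orientation"])
    return WoundSpec(**d)
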