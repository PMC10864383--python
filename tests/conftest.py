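"""Shared fixtures and small mesh builders for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from abdowall.geometry_synth import (
    WallConfig,
    WoundSpec,
    build_wall,
    _split_prisms,
)
from abdowall.mesh_core import LabeledTetMesh


def slab_mesh(
    nx: int, ny: int, nz: int,
    size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    label: str = "slab",
    labeler=None,
) -> LabeledTetMesh:
    """Structured box mesh (each cell = 2 prisms = 6 tets) with boundary
    patches for the six box faces (xmin, xmax, ymin, ymax, zmin, zmax)."""
    xs = np.linspace(0, size[0], nx + 1)
    ys = np.linspace(0, size[1], ny + 1)
    zs = np.linspace(0, size[2], nz + 1)

    def idx(i: int, j: int, k: int) -> int:
        return (i * (ny + 1) + j) * (nz + 1) + k

    coords = np.array([[x, y, z] for x in xs for y in ys for z in zs])
    prisms = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = [
                    idx(i, j, k), idx(i + 1, j, k), idx(i + 1, j + 1, k),
                    idx(i, j + 1, k), idx(i, j, k + 1), idx(i + 1, j, k + 1),
                    idx(i + 1, j + 1, k + 1), idx(i, j + 1, k + 1),
                ]
                prisms.append([c[0], c[1], c[2], c[4], c[5], c[6]])
                prisms.append([c[0], c[2], c[3], c[4], c[6], c[7]])
    tets = _split_prisms(np.array(prisms))
    if labeler is None:
        labels = [label] * len(tets)
    else:
        cents = coords[tets].mean(axis=1)
        labels = [labeler(c) for c in cents]
    mesh = LabeledTetMesh.create(coords, tets, labels)

    bf = mesh.boundary_faces()
    c = coords
    eps = 1e-9
    patches = {
        "xmin": bf[(c[bf][:, :, 0] < eps).all(axis=1)],
        "xmax": bf[(c[bf][:, :, 0] > size[0] - eps).all(axis=1)],
        "ymin": bf[(c[bf][:, :, 1] < eps).all(axis=1)],
        "ymax": bf[(c[bf][:, :, 1] > size[1] - eps).all(axis=1)],
        "zmin": bf[(c[bf][:, :, 2] < eps).all(axis=1)],
        "zmax": bf[(c[bf][:, :, 2] > size[2] - eps).all(axis=1)],
    }
    mesh.boundary_patches = {k: v for k, v in patches.items() if len(v)}
    return mesh


def octant_shell_mesh(
    k: int = 8, nr: int = 6, r1: float = 10.0, r2: float = 20.0
) -> LabeledTetMesh:
    """One octant of a thick spherical shell (symmetry planes = coordinate
    planes), with an ``inner`` boundary patch on the r = r1 surface."""
    verts: dict[tuple[int, int], int] = {}
    pts: list[np.ndarray] = []

    def vid(i: int, j: int) -> int:
        key = (i, j)
        if key not in verts:
            p = np.array([i, j, k - i - j], dtype=float)
            v = p / np.linalg.norm(p)
            verts[key] = len(pts)
            pts.append(v)
        return verts[key]

    tris = []
    for i in range(k):
        for j in range(k - i):
            tris.append([vid(i, j), vid(i + 1, j), vid(i, j + 1)])
            if i + j < k - 1:
                tris.append([vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)])
    surf = np.array(pts)
    tris = np.array(tris)
    rs = np.linspace(r1, r2, nr + 1)
    coords = (surf[:, None, :] * rs[None, :, None]).reshape(-1, 3)
    bot = tris * (nr + 1)
    prisms = np.vstack([np.hstack([bot + l, bot + l + 1]) for l in range(nr)])
    tets = _split_prisms(prisms)
    mesh = LabeledTetMesh.create(coords, tets, ["shell"] * len(tets))
    bf = mesh.boundary_faces()
    r = np.linalg.norm(coords, axis=1)
    mesh.boundary_patches = {"inner": bf[(r[bf] < r1 + 1e-9).all(axis=1)]}
    return mesh


def flat_wall_config(**overrides) -> WallConfig:
    """A small flat wall used throughout the unit tests: fast to mesh and
    solve, with every tissue region still present."""
    base = dict(
        panel_width=200.0,
        panel_height=160.0,
        curvature_radius=math.inf,
        la_width=20.0,
        rectus_width=30.0,
        zone_fractions=(1 / 3, 1 / 3, 1 / 3),
        blend_width=10.0,
        medial_thickness=12.0,
        lateral_thickness=24.0,
        target_edge_length=10.0,
    )
    base.update(overrides)
    return WallConfig(**base)


MIDLINE_WOUND = WoundSpec(
    id="W1", center=(0.0, 20.0), major_axis_length=12.0,
    placement_class="midline",
)
LATERAL_WOUND = WoundSpec(
    id="W2", center=(-70.0, -20.0), major_axis_length=5.0,
    placement_class="lateral",
)


@pytest.fixture(scope="session")
def flat_wall():
    """Flat test wall with one midline and one lateral wound."""
    return build_wall(flat_wall_config(), [MIDLINE_WOUND, LATERAL_WOUND])


@pytest.fixture(scope="session")
def flat_wall_plain():
    """Flat test wall without wounds."""
    return build_wall(flat_wall_config())
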