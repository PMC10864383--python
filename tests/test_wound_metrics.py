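"""Rim pairing, graph geodesics and the deformation statistics."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from abdowall.mesh_core import SurfacePatch
from abdowall.wound_metrics import (
    RimPairing,
    TopologyError,
    deformation_report,
    extract_wound_rims,
    geodesic_distance,
    pair_rims,
    rim_distances,
)


@pytest.fixture(scope="module")
def wound_patches(flat_wall):
    out = {}
    for wid in ("W1", "W2"):
        lat, rin, rout = extract_wound_rims(flat_wall, wid)
        out[wid] = (lat, rin, rout, pair_rims(lat, rin, rout,
                                              flat_wall.node_coords))
    return out


# --------------------------------------------------------------------------
# rim extraction
# --------------------------------------------------------------------------

def test_two_closed_rims_per_wound(flat_wall, wound_patches):
    cfg_layers = flat_wall.provenance["config"]["n_sublayers"]
    for wid, (lat, rin, rout, _) in wound_patches.items():
        assert len(rin) == len(rout)  # same structured ring resolution
        # lateral surface is a tube: rings x layers, two triangles per quad
        assert len(lat.triangles) == 2 * len(rin) * cfg_layers


def test_wound_boundary_partition(flat_wall, wound_patches):
    from abdowall.mesh_core import boundary_faces_of, surface_area

    for wid, (lat, *_rest) in wound_patches.items():
        wtets = flat_wall.region_tets(f"wound:{wid}")
        total = surface_area(boundary_faces_of(wtets), flat_wall.node_coords)
        lat_area = surface_area(lat, flat_wall.node_coords)
        lids = total - lat_area
        assert lids > 0
        # lids ~ 2 x ellipse area; lateral ~ perimeter x depth
        a = {"W1": 6.0, "W2": 2.5}[wid]
        assert lids == pytest.approx(2 * math.pi * a * 1.0, rel=0.03)


def test_non_wound_label_raises(flat_wall):
    with pytest.raises(Exception):
        extract_wound_rims(flat_wall, "nonexistent")


def test_partial_depth_wound_rejected():
    from conftest import flat_wall_config
    from abdowall.geometry_synth import WoundSpec, build_wall

    spec = WoundSpec(id="P", center=(-70.0, 0.0), major_axis_length=5.0,
                     depth=10.0, placement_class="lateral")
    mesh = build_wall(flat_wall_config(), [spec])
    with pytest.raises(TopologyError, match="through-wall"):
        extract_wound_rims(mesh, "P")


# --------------------------------------------------------------------------
# pairing
# --------------------------------------------------------------------------

def test_pairing_covers_both_rims(flat_wall, wound_patches):
    for wid, (lat, rin, rout, pairing) in wound_patches.items():
        assert len(pairing.pairs) == len(rin) + len(rout)
        firsts = set(pairing.pairs[:, 0].tolist())
        assert firsts == set(rin.tolist()) | set(rout.tolist())


def test_aligned_rims_pair_vertically(flat_wall, wound_patches):
    """On the flat wall the wound is a straight cylinder: every rim node
    pairs with the node directly opposite, at distance = wall thickness."""
    depth = {"W1": 12.0, "W2": 24.0}
    for wid, (lat, rin, rout, pairing) in wound_patches.items():
        c = flat_wall.node_coords
        np.testing.assert_allclose(pairing.d0, depth[wid], rtol=1e-9)
        # paired nodes share (x, y)
        dxy = c[pairing.pairs[:, 0], :2] - c[pairing.pairs[:, 1], :2]
        assert np.abs(dxy).max() < 1e-9


def test_pairing_independent_of_rim_ordering(flat_wall, wound_patches):
    lat, rin, rout, pairing = wound_patches["W2"]
    rng = np.random.default_rng(0)
    shuffled = pair_rims(lat, rng.permutation(rin), rng.permutation(rout),
                         flat_wall.node_coords)
    np.testing.assert_array_equal(shuffled.pairs, pairing.pairs)


def test_geodesic_never_below_euclidean(flat_wall, wound_patches):
    for wid, (lat, rin, rout, pairing) in wound_patches.items():
        assert (pairing.D0 >= pairing.d0 - 1e-9).all()
    with pytest.raises(ValueError, match="geodesic shorter"):
        RimPairing(np.array([[0, 1]]), np.array([2.0]), np.array([1.0]))


# --------------------------------------------------------------------------
# geodesics
# --------------------------------------------------------------------------

def _square_patch(with_diagonal: bool) -> tuple[SurfacePatch, np.ndarray]:
    coords = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.0]]
    )
    if with_diagonal:
        tris = np.array([[0, 1, 2], [0, 2, 3]])
    else:
        tris = np.array([[0, 1, 3], [1, 2, 3]])
    return SurfacePatch(tris), coords


def test_geodesic_on_unit_square():
    patch, coords = _square_patch(with_diagonal=True)
    assert geodesic_distance(patch, 0, 2, coords) == pytest.approx(
        math.sqrt(2), rel=1e-12
    )
    patch, coords = _square_patch(with_diagonal=False)
    assert geodesic_distance(patch, 0, 2, coords) == pytest.approx(
        2.0, rel=1e-12
    )


def _floyd_warshall(n: int, edges: list[tuple[int, int, float]]) -> np.ndarray:
    """Brute-force all-pairs shortest path, independent of scipy."""
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i, j, w in edges:
        d[i, j] = min(d[i, j], w)
        d[j, i] = min(d[j, i], w)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def test_geodesic_matches_brute_force_oracle(flat_wall, wound_patches):
    """Dijkstra over the lateral edge graph equals an exhaustive
    Floyd-Warshall on the same graph, exactly."""
    lat, rin, rout, _ = wound_patches["W2"]
    ids = lat.nodes
    local = {int(g): i for i, g in enumerate(ids)}
    coords = flat_wall.node_coords
    edges = [
        (local[int(a)], local[int(b)],
         float(np.linalg.norm(coords[a] - coords[b])))
        for a, b in lat.edges()
    ]
    dist = _floyd_warshall(len(ids), edges)

    rng = np.random.default_rng(42)
    picks = rng.choice(len(ids), size=(20, 2))
    pairs = np.stack([ids[picks[:, 0]], ids[picks[:, 1]]], axis=1)
    same = pairs[:, 0] == pairs[:, 1]
    pairs = pairs[~same]
    _, geo = rim_distances(lat, pairs, coords)
    expected = dist[
        [local[int(i)] for i in pairs[:, 0]],
        [local[int(j)] for j in pairs[:, 1]],
    ]
    # same shortest paths; tolerance covers summation-order rounding only
    np.testing.assert_allclose(geo, expected, rtol=1e-12)


def test_disconnected_pair_raises():
    coords = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 0], [6, 5, 0], [5, 6, 0.0]]
    )
    patch = SurfacePatch(np.array([[0, 1, 2], [3, 4, 5]]))
    with pytest.raises(ValueError, match="disconnected"):
        geodesic_distance(patch, 0, 4, coords)


# --------------------------------------------------------------------------
# deformation report
# --------------------------------------------------------------------------

def test_identity_configuration_reports_zero_change(flat_wall, wound_patches):
    lat, _, _, pairing = wound_patches["W1"]
    rep = deformation_report(
        flat_wall, "W1", pairing, flat_wall.node_coords,
        flat_wall.node_coords, lateral=lat,
    )
    assert rep.delta_tau_pct == 0.0
    assert rep.G_d == 1.0
    assert rep.d_area_pct == 0.0
    assert rep.d_vol_pct == 0.0


def test_rigid_motion_leaves_report_unchanged(flat_wall, wound_patches):
    lat, _, _, pairing = wound_patches["W2"]
    rot = Rotation.from_rotvec([0.4, -0.2, 0.7]).as_matrix()
    moved = flat_wall.node_coords @ rot.T + np.array([10.0, -5.0, 3.0])
    rep = deformation_report(
        flat_wall, "W2", pairing, flat_wall.node_coords, moved, lateral=lat,
    )
    assert rep.G_d == pytest.approx(1.0, abs=1e-10)
    assert rep.delta_tau_pct == pytest.approx(0.0, abs=1e-10)
    assert rep.d_area_pct == pytest.approx(0.0, abs=1e-10)
    assert rep.d_vol_pct == pytest.approx(0.0, abs=1e-10)


@pytest.mark.parametrize("k", [0.9, 0.97, 1.05])
def test_axial_compression_gives_gd_equal_k(flat_wall, wound_patches, k):
    """Scaling the through-wall axis by k compresses every geodesic path by
    exactly k on the straight flat-wall cylinder: G_d = k, dtau = 0."""
    lat, _, _, pairing = wound_patches["W1"]
    scaled = flat_wall.node_coords.copy()
    scaled[:, 2] *= k
    rep = deformation_report(
        flat_wall, "W1", pairing, flat_wall.node_coords, scaled, lateral=lat,
    )
    assert rep.G_d == pytest.approx(k, abs=1e-6)
    assert rep.delta_tau_pct == pytest.approx(0.0, abs=1e-6)


def test_report_internal_consistency(flat_wall, wound_patches):
    lat, _, _, pairing = wound_patches["W2"]
    squeezed = flat_wall.node_coords * np.array([1.01, 0.99, 0.98])
    rep = deformation_report(
        flat_wall, "W2", pairing, flat_wall.node_coords, squeezed, lateral=lat,
    )
    assert rep.G_d == pytest.approx(rep.Df_mean / rep.D0_mean, rel=1e-12)
    assert rep.tau0 == pytest.approx(rep.D0_mean / rep.d0_mean, rel=1e-12)
    assert rep.delta_tau_pct == pytest.approx(
        100 * (rep.tauf - rep.tau0) / rep.tau0, rel=1e-12
    )
    assert rep.d_area_pct == pytest.approx(
        100 * (rep.areaf - rep.area0) / rep.area0, rel=1e-10
    )
    row = rep.row()
    assert set(row) == {
        "wound_id", "P_a_kPa", "E_w_MPa", "G_d", "delta_tau_pct",
        "area0_mm2", "areaf_mm2", "vol0_mm3", "volf_mm3",
        "d_area_pct", "d_vol_pct",
    }


def test_coordinate_mismatch_raises(flat_wall, wound_patches):
    lat, _, _, pairing = wound_patches["W1"]
    with pytest.raises(ValueError, match="does not match"):
        deformation_report(
            flat_wall, "W1", pairing, flat_wall.node_coords,
            flat_wall.node_coords[:10], lateral=lat,
        )
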