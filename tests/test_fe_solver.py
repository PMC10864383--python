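"""Linear-tet elasticity: assembly, loads, constraints and benchmarks."""

import math

import numpy as np
import pytest

from abdowall.fe_solver import (
    ConstraintError,
    LoadCase,
    MaterialTable,
    assemble_stiffness,
    default_materials,
    node_dofs,
    pressure_load,
    solve,
    strain_energy,
    transition_modulus,
)
from abdowall.mesh_core import LabeledTetMesh, LabelError

from conftest import octant_shell_mesh, slab_mesh


# --------------------------------------------------------------------------
# materials
# --------------------------------------------------------------------------

def test_default_material_table():
    mats = default_materials()
    assert mats.modulus("LA") == 72.0
    assert mats.modulus("RA_left") == 0.52
    assert mats.modulus("EO_regular_right") == 1.0
    assert mats.modulus("IO_regular_left") == 0.65
    assert mats.modulus("TR_regular_left") == 1.03
    for m in ("EO", "IO", "TR"):
        assert mats.modulus(f"{m}_aponeurotic_left") == 5.6
    # transition moduli follow the halfway rule
    assert mats.modulus("EO_transition_left") == 3.3
    assert mats.modulus("IO_transition_left") == 3.1
    assert mats.modulus("TR_transition_left") == 3.3
    assert transition_modulus(1.0, 5.6) == 3.3
    assert all(nu == 0.49 for _, nu in mats.entries.values())


def test_material_validation():
    with pytest.raises(ValueError):
        MaterialTable({"a": (-1.0, 0.3)})
    with pytest.raises(ValueError):
        MaterialTable({"a": (1.0, 0.5)})
    with pytest.raises(LabelError):
        MaterialTable({"a": (1.0, 0.3)})["b"]


def test_material_yaml_round_trip(tmp_path):
    mats = default_materials().with_entry("wound:A1", 0.1)
    mats.to_yaml(tmp_path / "m.yaml")
    back = MaterialTable.from_yaml(tmp_path / "m.yaml")
    assert back.entries == mats.entries
    assert back["wound:A1"] == (0.1, 0.40)


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def test_single_tet_has_six_rigid_modes():
    coords = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]
    )
    mesh = LabeledTetMesh.create(coords, [[0, 1, 2, 3]], ["t"])
    k = assemble_stiffness(mesh, MaterialTable({"t": (1.0, 0.3)})).toarray()
    w = np.linalg.eigvalsh(k)
    assert (np.abs(w[:6]) < 1e-12 * w[-1]).all()
    assert (w[6:] > 1e-8 * w[-1]).all()


def test_stiffness_linear_in_modulus():
    mesh = slab_mesh(2, 2, 2)
    k1 = assemble_stiffness(mesh, MaterialTable({"slab": (1.0, 0.3)}))
    k2 = assemble_stiffness(mesh, MaterialTable({"slab": (2.0, 0.3)}))
    assert abs(k2 - 2.0 * k1).max() <= 1e-12 * abs(k1).max()


def test_stiffness_symmetric():
    mesh = slab_mesh(2, 3, 2, size=(1.0, 1.3, 0.7))
    k = assemble_stiffness(mesh, MaterialTable({"slab": (2.5, 0.45)}))
    assert abs(k - k.T).max() <= 1e-12 * abs(k).max()


def test_missing_material_raises():
    mesh = slab_mesh(1, 1, 1)
    with pytest.raises(LabelError):
        assemble_stiffness(mesh, MaterialTable({"other": (1.0, 0.3)}))


# --------------------------------------------------------------------------
# pressure loads
# --------------------------------------------------------------------------

def test_flat_patch_total_force():
    """1 cm^2 patch under 20 kPa carries 2 N total normal force."""
    mesh = slab_mesh(2, 2, 2, size=(10.0, 10.0, 5.0))
    f = pressure_load(mesh, "zmax", 20.0).reshape(-1, 3)
    total = f.sum(axis=0)
    assert total[2] == pytest.approx(-2.0, rel=1e-12)  # pushes into the slab
    assert abs(total[:2]).max() < 1e-14


def test_zero_pressure_zero_load():
    mesh = slab_mesh(1, 1, 1)
    assert not pressure_load(mesh, "zmin", 0.0).any()


def test_closed_surface_forces_balance():
    mesh = octant_shell_mesh(4, 2)
    mesh.boundary_patches["all"] = mesh.boundary_faces()
    f = pressure_load(mesh, "all", 20.0).reshape(-1, 3)
    scale = np.abs(f).sum()
    assert np.abs(f.sum(axis=0)).max() < 1e-10 * scale


# --------------------------------------------------------------------------
# solves and analytic benchmarks
# --------------------------------------------------------------------------

def test_uniaxial_bar_strain():
    """End traction sigma on a bar of modulus E gives strain sigma/E."""
    mesh = slab_mesh(2, 2, 8, size=(1.0, 1.0, 10.0))
    f = pressure_load(mesh, "zmax", -20.0)  # 0.02 MPa tension
    fixed = node_dofs(np.unique(mesh.boundary_patches["zmin"]))
    disp = solve(mesh, MaterialTable({"slab": (1.0, 0.0)}), load=f,
                 fixed_dofs=fixed)
    z = mesh.node_coords[:, 2]
    top = disp.u[z > 10 - 1e-9, 2]
    np.testing.assert_allclose(top, 0.2, rtol=1e-10)
    # fixed nodes exactly zero
    assert not disp.u[z < 1e-9].any()


def test_patch_test_reproduces_affine_field():
    """Linear tets reproduce any affine displacement exactly."""
    mesh = slab_mesh(3, 3, 3)
    grad = np.array(
        [[0.01, 0.002, 0.003], [0.004, -0.005, 0.006], [0.001, 0.002, -0.003]]
    )
    bnodes = np.unique(mesh.boundary_faces())
    disp = solve(
        mesh, MaterialTable({"slab": (1.0, 0.3)}),
        fixed_dofs=node_dofs(bnodes),
        fixed_values=(mesh.node_coords[bnodes] @ grad.T).ravel(),
    )
    exact = mesh.node_coords @ grad.T
    assert np.abs(disp.u - exact).max() < 1e-12


def _lame_radial(r, r1=10.0, r2=20.0, e=1.0, nu=0.3, p=0.02):
    return p * r1**3 / (e * (r2**3 - r1**3)) * (
        (1 - 2 * nu) * r + (1 + nu) * r2**3 / (2 * r**2)
    )


def _sphere_inner_displacement(k: int, nr: int) -> float:
    mesh = octant_shell_mesh(k, nr)
    c = mesh.node_coords
    fixed = np.concatenate([
        node_dofs(np.flatnonzero(np.abs(c[:, 0]) < 1e-9), (0,)),
        node_dofs(np.flatnonzero(np.abs(c[:, 1]) < 1e-9), (1,)),
        node_dofs(np.flatnonzero(np.abs(c[:, 2]) < 1e-9), (2,)),
    ])
    f = pressure_load(mesh, "inner", 20.0)
    disp = solve(mesh, MaterialTable({"shell": (1.0, 0.3)}), load=f,
                 fixed_dofs=fixed)
    r = np.linalg.norm(c, axis=1)
    ur = np.einsum("ij,ij->i", disp.u, c / r[:, None])
    return float(ur[r < 10 + 1e-9].mean())


def test_pressurized_sphere_matches_lame():
    got = _sphere_inner_displacement(10, 8)
    assert got == pytest.approx(_lame_radial(10.0), rel=0.05)


def test_sphere_mesh_convergence():
    """Probe displacement changes < 2% between refinement levels."""
    u1 = _sphere_inner_displacement(12, 9)
    u2 = _sphere_inner_displacement(24, 18)
    assert abs(u2 / u1 - 1.0) < 0.02


def test_linearity_in_pressure(flat_wall):
    mats = default_materials()
    for lab in flat_wall.labels():
        if lab.startswith("wound:"):
            mats = mats.with_entry(lab, 1.0)
    d1 = solve(flat_wall, mats, LoadCase(P_a=10.0))
    d2 = solve(flat_wall, mats, LoadCase(P_a=20.0))
    assert np.abs(d2.u - 2.0 * d1.u).max() <= 1e-8 * np.abs(d2.u).max()


def test_zero_pressure_zero_displacement(flat_wall):
    mats = default_materials()
    for lab in flat_wall.labels():
        if lab.startswith("wound:"):
            mats = mats.with_entry(lab, 1.0)
    disp = solve(flat_wall, mats, LoadCase(P_a=0.0))
    assert not disp.u.any()


def test_monotone_stiffening_of_wound(flat_wall):
    """Raising the wound modulus never increases the compliance (energy
    norm) of the pressure solution."""
    energies = []
    load = pressure_load(flat_wall, "inner_surface", 20.0)
    fixed = node_dofs(np.unique(flat_wall.patch("fixed_edge").triangles))
    for e_w in (0.1, 1.0, 10.0, 100.0):
        mats = default_materials()
        for lab in flat_wall.labels():
            if lab.startswith("wound:"):
                mats = mats.with_entry(lab, e_w)
        k = assemble_stiffness(flat_wall, mats)
        disp = solve(flat_wall, mats, load=load, fixed_dofs=fixed)
        energies.append(strain_energy(k, disp.u))
    assert all(a >= b * (1 - 1e-10) for a, b in zip(energies, energies[1:]))


def test_unconstrained_system_raises():
    mesh = slab_mesh(1, 1, 1)
    with pytest.raises(ConstraintError):
        solve(mesh, MaterialTable({"slab": (1.0, 0.3)}),
              load=np.zeros(3 * mesh.n_nodes), fixed_dofs=np.array([], int))


def test_cg_agrees_with_direct():
    mesh = slab_mesh(3, 3, 3, size=(10.0, 10.0, 10.0))
    mats = MaterialTable({"slab": (1.0, 0.3)})
    f = pressure_load(mesh, "zmax", 5.0)
    fixed = node_dofs(np.unique(mesh.boundary_patches["zmin"]))
    d_direct = solve(mesh, mats, load=f, fixed_dofs=fixed)
    d_cg = solve(mesh, mats, load=f, fixed_dofs=fixed, method="cg", rtol=1e-10)
    assert np.abs(d_cg.u - d_direct.u).max() < 1e-6 * np.abs(d_direct.u).max()
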