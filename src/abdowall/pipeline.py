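"""Experiment driver: reference case, one-at-a-time softening and sweeps.

A plan fixes a laparoscopy pattern on a wall configuration, a set of
intra-abdominal pressure levels and a wound-stiffness policy:

* ``reference`` — every wound healed: its modulus equals the volume-weighted
  mean modulus of the muscle tissue surrounding it;
* ``soften_one`` — like reference, but one wound set to a given E_w;
* ``sweep`` — one wound swept over a list of E_w values (others reference).

Each (stiffness assignment x pressure) pair is one linear FE solve; the
stiffness operator is factorized once per assignment and reused across the
pressure levels (the load scales, the operator does not).  Every solve
yields one deformation report row per wound.  Runs are deterministic for a
fixed plan and seed; with the direct solver the emitted report reproduces
bitwise.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .fe_solver import (
    ConstrainedOperator,
    LoadCase,
    MaterialTable,
    assemble_stiffness,
    default_materials,
    node_dofs,
    pressure_load,
    WOUND_POISSON,
)
from .geometry_synth import WallConfig, WoundSpec, build_wall, pattern_preset
from .mesh_core import LabeledTetMesh, compute_mesh_stats
from .wound_metrics import deformation_report, extract_wound_rims, pair_rims

__all__ = [
    "ExperimentPlan",
    "StiffnessPolicy",
    "reference_stiffness",
    "run_plan",
    "format_table",
    "REPORT_COLUMNS",
]

log = logging.getLogger("abdowall")

#: Physiological pressure sweep: five uniform levels across the IAP range of
#: daily activities.
DEFAULT_PRESSURES_KPA = (4.0, 8.0, 12.0, 16.0, 20.0)

#: Studied wound-stiffness range (MPa).
E_W_RANGE = (0.1, 10000.0)

REPORT_COLUMNS = [
    "wound_id", "P_a_kPa", "E_w_MPa", "G_d", "delta_tau_pct",
    "area0_mm2", "areaf_mm2", "vol0_mm3", "volf_mm3",
    "d_area_pct", "d_vol_pct",
]


@dataclass
class StiffnessPolicy:
    """Exactly one of the three wound-stiffness strategies."""

    kind: str = "reference"  # reference | soften_one | sweep
    wound_id: str | None = None
    E_w: float | None = None
    E_w_list: tuple[float, ...] = ()

    def validate(self) -> None:
        lo, hi = E_W_RANGE
        if self.kind == "reference":
            return
        if self.wound_id is None:
            raise ValueError(f"policy {self.kind!r} needs a wound id")
        values = [self.E_w] if self.kind == "soften_one" else list(self.E_w_list)
        if self.kind == "soften_one" and self.E_w is None:
            raise ValueError("soften_one needs E_w")
        if self.kind == "sweep" and not self.E_w_list:
            raise ValueError("sweep needs a non-empty E_w list")
        if self.kind not in ("soften_one", "sweep"):
            raise ValueError(f"unknown stiffness policy {self.kind!r}")
        for v in values:
            if not lo <= float(v) <= hi:
                raise ValueError(
                    f"E_w={v} MPa outside the studied range [{lo}, {hi}]"
                )


@dataclass
class ExperimentPlan:
    pattern: str = "A"
    wall: WallConfig = field(default_factory=WallConfig)
    pressures_kPa: tuple[float, ...] = DEFAULT_PRESSURES_KPA
    policy: StiffnessPolicy = field(default_factory=StiffnessPolicy)
    out_dir: str | None = None
    seed: int = 0
    write_fields: bool = False

    def validate(self) -> None:
        self.policy.validate()
        if any(p < 0 for p in self.pressures_kPa):
            raise ValueError("pressures must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentPlan":
        data = yaml.safe_load(Path(path).read_text()) or {}
        wall = WallConfig(**{
            **data.get("wall", {}),
            **({"zone_fractions": tuple(data["wall"]["zone_fractions"])}
               if "zone_fractions" in data.get("wall", {}) else {}),
        })
        policy = StiffnessPolicy(**{
            **data.get("policy", {}),
            **({"E_w_list": tuple(data["policy"]["E_w_list"])}
               if "E_w_list" in data.get("policy", {}) else {}),
        })
        return cls(
            pattern=data.get("pattern", "A"),
            wall=wall,
            pressures_kPa=tuple(data.get("pressures_kPa", DEFAULT_PRESSURES_KPA)),
            policy=policy,
            out_dir=data.get("out_dir"),
            seed=int(data.get("seed", 0)),
            write_fields=bool(data.get("write_fields", False)),
        )


def reference_stiffness(
    mesh: LabeledTetMesh, materials: MaterialTable, wound_id: str
) -> float:
    """Healed-wound modulus: volume-weighted mean E of the non-wound tissue
    elements sharing at least one node with the wound region."""
    from .mesh_core import tet_volumes

    label = wound_id if wound_id.startswith("wound:") else f"wound:{wound_id}"
    wnodes = np.unique(mesh.region_tets(label))
    touch = np.isin(mesh.tets, wnodes).any(axis=1)
    is_wound = np.array(
        [str(lab).startswith("wound:") for lab in mesh.region_label]
    )
    nb = touch & ~is_wound
    if not nb.any():
        raise ValueError(f"wound {wound_id} has no tissue neighbors")
    vols = tet_volumes(mesh.node_coords, mesh.tets[nb])
    e = np.array([materials.modulus(lab) for lab in mesh.region_label[nb]])
    return float(np.average(e, weights=vols))


def _assignments(
    plan: ExperimentPlan, wound_ids: list[str], ref_e: dict[str, float]
) -> list[dict[str, float]]:
    pol = plan.policy
    base = dict(ref_e)
    if pol.kind == "reference":
        return [base]
    if pol.kind == "soften_one":
        a = dict(base)
        a[pol.wound_id] = float(pol.E_w)
        return [a]
    out = []
    for e_w in pol.E_w_list:
        a = dict(base)
        a[pol.wound_id] = float(e_w)
        out.append(a)
    return out


def run_plan(
    plan: ExperimentPlan,
    mesh: LabeledTetMesh | None = None,
    base_materials: MaterialTable | None = None,
) -> tuple[list[dict], dict]:
    """Execute a plan; returns (report rows, run manifest).

    A pre-built mesh (with the plan's pattern embedded) may be supplied to
    share one mesh across several plans; otherwise the wall is generated
    from the plan's config and pattern.  When ``plan.out_dir`` is set, the
    rows are written as ``report.csv``/``report.json`` and the manifest as
    ``manifest.json`` (partial results are flushed after every solve).
    """
    plan.validate()
    t_start = time.perf_counter()
    wall = plan.wall
    if wall.seed != plan.seed:
        wall = WallConfig(**{**asdict(wall), "seed": plan.seed})

    if mesh is None:
        specs = pattern_preset(plan.pattern, wall)
        log.info("generating wall (pattern %s, %d wounds)", plan.pattern, len(specs))
        mesh = build_wall(wall, specs)
    wound_ids = sorted(
        lab.removeprefix("wound:")
        for lab in mesh.labels() if lab.startswith("wound:")
    )
    if plan.policy.wound_id is not None and plan.policy.wound_id not in wound_ids:
        raise KeyError(f"policy wound {plan.policy.wound_id!r} not in mesh")
    stats = compute_mesh_stats(mesh)
    log.info("mesh: %d nodes, %d tets", stats.n_nodes, stats.n_tets)

    materials = base_materials or default_materials()
    ref_e = {
        wid: reference_stiffness(mesh, materials, wid) for wid in wound_ids
    }
    log.info("reference wound moduli (MPa): %s",
             {k: round(v, 3) for k, v in ref_e.items()})

    fixed = node_dofs(np.unique(mesh.patch("fixed_edge").triangles))
    unit_load = pressure_load(mesh, "inner_surface", 1.0)

    rims = {}
    pairings = {}
    for wid in wound_ids:
        lat, rin, rout = extract_wound_rims(mesh, wid)
        rims[wid] = lat
        pairings[wid] = pair_rims(lat, rin, rout, mesh.node_coords)

    out_dir = Path(plan.out_dir) if plan.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    plan_doc = {
        "pattern": plan.pattern,
        "wall": asdict(wall),
        "pressures_kPa": list(plan.pressures_kPa),
        "policy": asdict(plan.policy),
        "seed": plan.seed,
    }
    manifest: dict = {
        "plan": plan_doc,
        "config_hash": hashlib.sha256(
            yaml.safe_dump(plan_doc, sort_keys=True).encode()
        ).hexdigest(),
        "mesh_stats": stats.as_dict(),
        "reference_E_MPa": ref_e,
        "assignments": [],
        "solves": [],
    }

    rows: list[dict] = []
    for a_idx, assign in enumerate(_assignments(plan, wound_ids, ref_e)):
        mats = materials
        for wid, e_w in assign.items():
            mats = mats.with_entry(f"wound:{wid}", e_w, WOUND_POISSON)
        manifest["assignments"].append(
            {"index": a_idx, "wound_E_MPa": dict(assign)}
        )
        t0 = time.perf_counter()
        k = assemble_stiffness(mesh, mats)
        op = ConstrainedOperator(k, fixed)
        t_fact = time.perf_counter() - t0
        log.info("assignment %d: assembled+factorized in %.1f s", a_idx, t_fact)

        for p_kpa in plan.pressures_kPa:
            t0 = time.perf_counter()
            u, res = op.solve(unit_load * p_kpa)
            coords_f = mesh.node_coords + u.reshape(-1, 3)
            for wid in wound_ids:
                rep = deformation_report(
                    mesh, wid, pairings[wid], mesh.node_coords, coords_f,
                    lateral=rims[wid], P_a_kPa=p_kpa,
                    E_w_MPa=assign[wid],
                )
                rows.append(rep.row())
            manifest["solves"].append({
                "assignment": a_idx,
                "P_a_kPa": p_kpa,
                "residual": res,
                "seconds": round(time.perf_counter() - t0, 3),
            })
            log.info("  P_a=%g kPa: residual %.2e (%.1f s)",
                     p_kpa, res, time.perf_counter() - t0)
            if out_dir:
                _flush(out_dir, rows, manifest)
            if out_dir and plan.write_fields:
                from .mesh_core import write_surface_vtp

                tag = f"a{a_idx}_p{p_kpa:g}"
                write_surface_vtp(
                    mesh.boundary_patches["outer_surface"], mesh.node_coords,
                    out_dir / f"outer_{tag}.vtp",
                    point_data={"displacement": u.reshape(-1, 3)},
                )

    manifest["total_seconds"] = round(time.perf_counter() - t_start, 3)
    if out_dir:
        _flush(out_dir, rows, manifest)
    return rows, manifest


def _flush(out_dir: Path, rows: list[dict], manifest: dict) -> None:
    with (out_dir / "report.csv").open("w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS)
        w.writeheader()
        for r in rows:
            w.writerow({k: _fmt(r[k]) for k in REPORT_COLUMNS})
    (out_dir / "report.json").write_text(json.dumps(rows, indent=1))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _fmt(v) -> str:
    return f"{v:.17g}" if isinstance(v, float) else str(v)


def format_table(rows: list[dict]) -> str:
    """Human-readable shape-change table (G_d and the tortuosity change
    rounded to 2 decimals, mirroring how such results are usually printed)."""
    lines = [f"{'wound':>6} {'P_a kPa':>8} {'E_w MPa':>9} {'G_d':>6} {'dtau %':>7}"]
    for r in rows:
        lines.append(
            f"{r['wound_id']:>6} {r['P_a_kPa']:>8g} {r['E_w_MPa']:>9.3g} "
            f"{r['G_d']:>6.2f} {r['delta_tau_pct']:>7.2f}"
        )
    return "\n".join(lines)
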