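# abdowall

Finite-element analysis of **trocar-site surgical wound mechanics** in a
layered abdominal-wall model under intra-abdominal pressure (IAP).

After laparoscopic surgery, the small wounds left by the trocars (5–12 mm
ports) are a known site of incisional hernia.  Whether a wound is at
mechanical risk depends on where it sits — embedded in the stiff midline
linea alba, or laterally in the oblique muscle stacks — and on how stiff
the regrown scar tissue is.  `abdowall` is a virtual-simulation toolkit for
exactly that question, aimed at computational biomechanics researchers: it
generates a parametric synthetic abdominal wall (a curved layered panel
with a 2 cm linea alba, rectus compartments wrapped in their aponeurotic
sheath, and three-layer lateral muscle stacks), embeds elliptic-cylinder
wounds with locally refined conformal meshes, solves the linear-elastic
response to a uniform IAP on the inner surface with the wall clamped at its
perimeter, and quantifies wound shape change.

## Model and statistics

Tissues follow small-strain isotropic linear elasticity, **σ = C(E, ν) ε**,
with literature moduli (MPa): linea alba 72, rectus 0.52, external /
internal oblique and transverse muscle 1.0 / 0.65 / 1.03, aponeurotic
sheath 5.6, transition zones at the halfway modulus; muscle ν = 0.49,
wound ν = 0.40.  The wound modulus E_w is the experiment variable
(0.1–10 000 MPa; "reference" = volume-weighted mean modulus of the
surrounding tissue, i.e. a healed scar).  Elements are linear tetrahedra;
pressure is a consistent dead load; Dirichlet conditions are eliminated
exactly.

Each through-wall wound is characterized by pairing every rim node of its
two lids with the nearest node on the opposite rim and tracking mean
Euclidean (d̄) and lateral-surface geodesic (D̄) rim distances:

* tortuosity τ̄ = D̄ / d̄ and its change Δτ = 100 (τ̄_f − τ̄₀)/τ̄₀ [%],
* geodesic deformation Ḡ_d = D̄_f / D̄₀ (< 1 ⇒ the wound lost depth),
* wound boundary area and volume changes between configurations.

## Worked example

```python
from abdowall import (WallConfig, build_wall, pattern_preset,
                      ExperimentPlan, StiffnessPolicy, run_plan, format_table)

plan = ExperimentPlan(
    pattern="A",                      # 6-trocar laparoscopy layout
    wall=WallConfig(),                # default 360 x 300 mm curved panel
    pressures_kPa=(20.0,),            # peak physiological IAP
    policy=StiffnessPolicy("soften_one", "A4", 0.1),  # soft midline scar
)
rows, manifest = run_plan(plan)
print(format_table(rows))
```

```
 wound  P_a kPa   E_w MPa    G_d  dtau %
    A1       20        72   1.01    0.00
    A2       20     0.893   0.94    0.01
    A3       20     0.893   0.94    0.01
    A4       20       0.1   1.00    0.00
    A5       20     0.893   0.94    0.03
    A6       20     0.893   0.94    0.02
```

Reading the table: the softened midline wound A4 (E_w = 0.1 MPa, embedded
in the 72 MPa linea alba) keeps its depth (Ḡ_d = 1.00) and does not
undulate (Δτ = 0.00) even though the midline itself bulges outward by
roughly a centimetre — the stiff strip shields it.  The lateral wounds
(healed, E_w ≈ 0.9 MPa) lose ~6 % of their depth as the pressurized wall
thins.  Full-precision rows (areas, volumes, relative changes) are in
`rows` / `report.csv`; `manifest` records mesh statistics, reference
moduli and solver residuals.

The same workflow is scriptable from the shell:

```bash
abdowall generate --pattern A --out wall.msh
abdowall solve --mesh wall.msh --pressure 20 --out deformed.vtp
abdowall run --plan plan.yaml --out runs/
abdowall report --runs runs/
```

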