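# Methods

## Problem and model

`abdowall` studies how laparoscopic trocar wounds deform when the abdominal
wall is loaded by intra-abdominal pressure (IAP), and how that deformation
depends on where the trocar was placed (on the stiff midline linea alba vs
laterally, in the oblique muscle stacks) and on the stiffness of the
regrown scar tissue.  The mechanical model is deliberately simple and
linear:

* **Kinematics/constitutive law.** Small-strain isotropic linear
  elasticity, sigma = C(E, nu) : eps, with region-wise constant moduli.
  Soft tissue is in reality fibrous, anisotropic and hyperelastic; the
  linear isotropic model is adopted because strain levels at physiological
  IAP stay modest and the questions asked (relative deformation of wounds
  at different sites and stiffnesses) are comparative.
* **Elements.** Displacement-based linear (constant-strain) tetrahedra.
  At nu = 0.49 these elements exhibit volumetric locking, i.e. they
  overestimate stiffness for nearly incompressible tissue; all results in
  this package should be read with that systematic bias in mind.  An
  element-level "selective reduced integration" option would be a no-op for
  single-point tetrahedra and is intentionally not offered; mitigating
  locking properly would require a different element technology.
* **Loads and boundary conditions.** The IAP is a dead, consistent nodal
  load on the undeformed inner surface (no follower-load update — the
  analysis is a single linear solve).  The whole panel perimeter is clamped
  (zero displacement), emulating the attachment of the wall muscles to the
  skeleton.  Dirichlet conditions are imposed by exact row/column
  elimination, so fixed DOFs are zero to machine precision.
* **Solver.** Sparse LU (SuperLU in symmetric mode with minimum-degree
  ordering) by default; one factorization per material assignment, one
  triangular solve per pressure level.  A conjugate-gradient fallback with
  relative residual 1e-8 exists for memory-constrained cases.  Relative
  residuals are recorded in the run manifest.

Units: mm, MPa, N internally; pressures cross public interfaces in kPa.

## Synthetic geometry

The patient-derived geometry of the original imaging-based models is not
reproducible from published information, so the package generates a
parametric stand-in: a curved rectangular panel (section of a vertical
cylinder) whose in-plane layout captures the features the mechanics depends
on — the stiffness layout and the layer stacking:

* a 20 mm stiff midline strip (non-diastatic linea alba, E = 72 MPa),
* rectus abdominis volumes (E = 0.52 MPa) flanking it, sandwiched between
  thin aponeurotic sheath layers (the rectus sheath, E = 5.6 MPa) that
  continue the lateral aponeuroses over the rectus,
* lateral three-layer stacks (external oblique 1.0, internal oblique 0.65,
  transverse 1.03 MPa), each divided medially-to-laterally into
  aponeurotic (5.6 MPa), transition and regular zones.  Transition moduli
  follow the halfway rule, (E_regular + E_sheath)/2 rounded to 0.1 MPa:
  3.3 / 3.1 / 3.3 MPa.

Muscle Poisson ratio is 0.49; wound (scar) tissue has nu = 0.40 and a
modulus E_w that is the experiment variable (0.1–10 000 MPa; the
"reference" or healed value is the volume-weighted mean modulus of the
tissue elements touching the wound).

Default panel dimensions were chosen once, on anatomical grounds: 360 mm of
girth arc x 300 mm height on a 170 mm outer radius; 12 mm wall thickness in
the midline/rectus region (2 mm sheath + 8 mm rectus + 2 mm sheath)
ramping to 24 mm laterally (8 mm per muscle layer); lateral zone split
25 % aponeurotic / 10 % transition / 65 % regular.  Wounds are elliptic
cylinders orthogonal to the outer surface, minor axis 2 mm (a closed
incision), major axis equal to the trocar diameter (5, 10 or 12 mm),
running through the full wall thickness.  Two preset trocar layouts are
provided: pattern A (two 12 mm midline wounds A1/A4, 5 mm lateral pairs
A2/A3 and A5, and a 12 mm lateral A6) and pattern B (10 mm and 5 mm midline
B1/B4, 5 mm lateral B2/B3, 12 mm lateral B5).  Absolute trocar coordinates
are not published; the presets store placements as panel fractions chosen
to land midline wounds on the strip and lateral wounds in the
regular-muscle zone near the transition, and they are documented as
estimates.

### Meshing

The footprint is meshed by a structured background grid; around each wound
an O-grid block is carved out: concentric rings morph from the wound
ellipse to the block boundary, with ring-doubling rows providing local
refinement (wound-edge target = background edge / `wound_refinement`).
Ellipse rings are sampled uniformly in the parametric angle, which
concentrates nodes at the sharp major-axis tips and keeps the
inscribed-polygon area error ~1 % at the default ring counts.  The
footprint is extruded through the thickness (6 sub-layers by default, two
per lateral muscle layer, aligning layer interfaces with element levels);
prisms are split into tetrahedra with the min-vertex diagonal rule, which
is conforming by construction.  Region labels are assigned per element from
the footprint position and thickness fraction of its prism.

Two meshing choices matter for the metrics:

* the wound lateral surface is a structured stack of generatrix rings, so a
  straight rim-to-rim polyline exists in the edge graph and the undeformed
  tortuosity is 1 up to floating-point error (an unstructured lateral mesh
  would inflate it spuriously);
* wound embedding is implemented as conformal re-generation from the
  stored wall provenance (equivalent to cavity remeshing, but deterministic
  and structured); meshes imported from files without provenance cannot
  accept new wounds.

Generation is deterministic for a fixed config and seed (the seed only
feeds the optional node jitter, off by default).  Degenerate (zero-volume)
elements are an error, never silently dropped.

## Wound deformation metrics

Each through-wall wound has two lid rims (where its lateral surface meets
the outer/inner wall surfaces).  Every rim node of **both** lids is paired
with the Euclidean-nearest node of the opposite rim (ties to the smallest
node index); whether one or both rims should be iterated is ambiguous in
the source methodology, and the symmetric convention was chosen because it
is deterministic and lid-agnostic.  The pairing is established on the
undeformed geometry and reused for the deformed one.  For the pair set we
track mean Euclidean distance d and mean geodesic distance D, where the
geodesic is the shortest path over the lateral-surface edge graph
(Dijkstra) at the current coordinates — a graph approximation of the true
polyhedral geodesic that is tight here because of the structured lateral
meshing (measured undeformed slack < 1e-3).  Derived statistics:

* tau = D/d (tortuosity), dtau = 100 (tau_f - tau_0)/tau_0,
* G_d = D_f / D_0 (geodesic deformation; < 1 means the wound lost depth),
* wound boundary surface area (both lids + lateral surface — the
  convention including the lids is used because it matches the magnitude of
  the quoted wound areas; it can be changed by measuring patches
  separately) and wound region volume, in both configurations.

## Experiments

An experiment plan = pattern x wall config x pressure list x stiffness
policy.  Pressures default to five uniform levels over 4–20 kPa (the
physiological IAP range of daily activities).  Policies: `reference` (all
wounds healed), `soften_one` (one wound at a given E_w, rest healed),
`sweep` (one wound over an E_w list).  Every (assignment, pressure) pair is
one linear solve; no superposition shortcuts are taken across material
changes.  Reports are emitted as CSV/JSON rows (full precision) plus a
rounded human-readable table; the manifest records the config hash, mesh
statistics, reference moduli, residuals and timings.  With the direct
solver, identical plans reproduce reports bitwise.

## Problem sizes

The default wall meshes to ~245 k tetrahedra (~48 k nodes, ~145 k free
DOFs); one factorization takes ~30 s and ~1.7 GB on one CPU, and the full
acceptance computation (reference + two soften-one cases + a 6-stiffness x
5-pressure sweep) runs in a few minutes.  The unit-test wall is a 200 x
160 mm flat panel (~20 k tets) that keeps every region present at a few
seconds per solve.  Analytic benchmarks (patch test, uniaxial bar, Lamé
thick-walled sphere on an octant shell with symmetry boundary conditions)
run in seconds.

## What the synthetic geometry does and does not show

Passing tests demonstrate that the solver is correct on analytic problems,
that the metrics satisfy their exact identities (rigid-motion invariance,
G_d = k under imposed axial compression, geodesic = brute-force shortest
path), and that the central qualitative contrast of the study reproduces
on the synthetic panel: a midline wound embedded in the stiff strip barely
deforms (G_d rounds to 1.00, dtau to 0.00) while travelling outward with
the wall, whereas lateral wounds lose depth and — when soft — gain
substantial volume, the more so the softer the scar and the higher the
IAP (soft lateral wound: up to +18 % volume at 20 kPa on the default
panel, with volume strictly increasing over the pressure sweep for
E_w <= 2 MPa).

They do **not** show quantitative agreement with a patient-specific
anatomy, and two systematic effects are worth spelling out.

*Compliance of the panel.*  The panel is singly curved, clamped only at
its perimeter, and has idealized uniform layers; the real wall is doubly
curved with broad bony attachments.  Under 20 kPa the synthetic lateral
wall therefore compresses roughly twice as much as an imaging-derived
geometry: soft lateral wounds here show G_d ~ 0.94 where ~0.96–0.97 is
reported for patient-based models.  The direction and ordering of effects
agree; absolute magnitudes are larger.

*Second-order kinematics artifact.*  Areas and volumes are integrated
exactly on the linearly-displaced coordinates.  A linearized rigid
rotation by angle theta is not volume-preserving — it inflates the exact
volume at O(theta^2) — so once local rotations reach ~0.05–0.1 rad this
artifact contributes a spurious ~0.1–0.5 % change.  It is irrelevant for
soft wounds (whose real changes are 10–100x bigger) but dominates the
near-zero changes of very stiff scars: on the default panel a 2000 MPa
wound shows |area change| up to ~0.4 % and a small positive volume change
where its true elastic deformation is of order 0.01 %.  At the smaller
deflections of a stiffer anatomy the artifact stays well below these
values.  Removing it would require geometrically nonlinear kinematics,
which is outside this package's (deliberately linear) scope.

Known further limitations: no geometric nonlinearity (the outward travel
of the midline at 20 kPa is of the order of a centimetre, where a
finite-displacement analysis would stiffen the response), no contact, no
active muscle tone, no anisotropy, no suture/prosthesis modelling, no
umbilicus feature, and volumetric locking of linear tetrahedra at
nu = 0.49.
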