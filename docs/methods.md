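# Methods

This note documents the models, discretizations and design choices behind
`bladdereit`, and what the synthetic phantom experiments do and do not
demonstrate.

## Physical setting

A cuboid tank (180 × 150 × 100 mm) stands in for the lower abdomen. An
8 × 8 array of circular electrodes (4 mm diameter, 8 mm gaps, so a 12 mm
pitch spanning 84 × 84 mm) sits centred on the top face; a single larger
back electrode on the bottom centre is the signal ground. A 10 mA current
is injected through each array electrode in turn and returns through the
back electrode; voltages are read from the 63 non-driven array electrodes,
giving 64 × 63 = 4032 measurements per acquisition frame. The background
medium is 0.1 S/m; the anomaly ("urine in the bladder") is saline at
0.892 S/m, i.e. an 8.9:1 conductive contrast, placed with its top face
15 mm below the electrode plane (the agar cover layer of the physical
phantom). All conductivities are real-valued magnitudes at the 200 kHz
working frequency; no dispersion is modelled.

## Forward model

The complete electrode model (CEM) is discretized with linear (P1)
tetrahedra. Each electrode l has a contact impedance z_l (default
0.01 Ω·m², configurable) and carries a prescribed net current; the
discrete system couples node potentials with electrode potentials and is
symmetric. Grounding the back electrode both fixes the potential and
absorbs the return current, so current conservation holds to solver
precision (verified to 1e-8·I in tests). Reciprocity (drive i / measure j
= drive j / measure i) is inherited from the symmetry of the system and
verified to 1e-6.

The mesh is a structured lattice split into six tetrahedra per hexahedron
(Kuhn subdivision): deterministic, conforming, and exactly volume-
conserving. In-plane gridlines pass through every electrode centre at
half the array pitch (6 mm) or finer, which guarantees each electrode is
resolved by at least the faces incident to its centre node (≥ 3, usually
6) without local remeshing, and that adjacent electrode patches never
share a face. The discrete electrode patch is therefore somewhat larger
than the physical 12.6 mm² disc at coarse settings; difference imaging is
insensitive to this common-mode geometry, and the contact impedance is
kept at its nominal value. Vertical spacing is graded toward the
electrode plane where current density (and sensitivity) is highest.

Three mesh presets are provided: `coarse` (~9k tets, tests and
diagnostics), `desk` (~32k tets, the interactive default), and `paper`
(~75k tets / ~14k nodes, matching the scale of the reference experiment's
79,307-element discretization). The end-to-end study runs on `paper`:
the boundary-surface localization error is O(h), and at `desk` density
the extra discretization bias on a 64 mL object is roughly +40% of its
volume, which would swamp the quantities being studied.

The Jacobian J (4032 × n_elements, volts per S/m) is computed by the
adjoint-field identity. Because every drive and measurement pattern here
is a pair (array electrode, ground), the 64 unit-current fields supply
both the direct and adjoint fields:

    J[(i, j), e] = −I · V_e · ∇w_i|_e · ∇w_j|_e ,

with w_l the unit-current potential field of electrode l. The sign
convention matches difference imaging with δx = x_p − x, so J δx ≈ V_p − V
and a conductive inclusion appears as negative δx. Columns agree with a
finite-difference re-simulation to < 0.03% on test meshes (1% asserted).

## Difference imaging

One-step linearized reconstruction from dv = F(x_p) − V:

* Tikhonov: δx = (JᵀJ + λI)⁻¹ Jᵀ dv
* NOSER: δx = (JᵀJ + ε·diag(JᵀJ))⁻¹ Jᵀ dv, 0 < ε < 1
* combined (default): δx = (JᵀJ + λI + ε·diag(JᵀJ))⁻¹ Jᵀ dv

Defaults: λ = 10⁻³·trace(JᵀJ)/n (scale-aware) and ε = 0.05. Parameter
scans on the synthetic phantom (clean and noisy) showed this λ sits on
the only stable plateau: a decade smaller amplifies ringing until the
anomaly merges with background structure, a few times larger smears the
image until localization is lost; larger ε degrades depth localization.
No explicit inverse is ever formed. For n ≤ 4032 the normal matrix is
Cholesky-factorized directly; for larger meshes the algebraically
identical dual form δx = D⁻¹Jᵀ(I + J D⁻¹Jᵀ)⁻¹ dv (D the diagonal
penalty) is factorized in measurement space, so cost and memory are
independent of mesh size beyond one copy of J. Both branches agree with
a dense brute-force oracle to 1e-8. A first-difference penalty operator
over face-adjacent element pairs is available for standard-form-breaking
experiments (dense path only); the pipeline does not use it.

Condition numbers of the regularized systems are computed exactly
(dense eigendecomposition up to n = 4000; above that, Lanczos extremes
with exact shift-invert through the dual Cholesky — the combined matrix
is handled as the NOSER matrix plus λI, whose spectrum shifts exactly).
The qualitative hierarchy cond(J) > Tikhonov > NOSER > combined holds in
the conditioning regime λ < ε·min diag(JᵀJ); at reconstruction defaults
λ dominates the deep-element NOSER weights and the Tikhonov/NOSER order
inverts. Both facts are asserted in the test suite.

## Boundary-surface extraction

The reconstructed per-element |δx| is interpolated to nodes
(volume-weighted incident average), differentiated (gradient:
volume-weighted P1 element gradients; Laplacian: Galerkin stiffness with
lumped mass, whose null space contains all linear fields), and searched
for steplike edges — the 3D Marr–Hildreth criterion: Laplacian zero
crossing with gradient magnitude above a threshold T.

* T defaults to the 90th percentile of interior-node ‖∇f‖ ("auto");
  detection is therefore invariant to positive rescaling of the image.
* A tet edge is "intersected" when ‖∇f(P₁)‖+‖∇f(P₂)‖ ≥ 2T and the nodal
  Laplacians have opposite signs (zero counts as positive). A tet is an
  edge element when ≥ 3 of its 6 edges are intersected.
* Pseudo-edge removal discards face-adjacency components smaller than 10
  elements; survivors, collected per horizontal slab (2× mean edge
  length thick), seed a region-growing pass that appends face neighbours
  with ≥ 2 intersected edges until a fixed point.
* The closed shell is then triangulated by marching tetrahedra on the
  Laplacian zero level. Crossing points are interpolated once per global
  mesh edge, so adjacent patches share vertices bit-exactly and the
  surface is crack-free; triangles are oriented along the Laplacian
  gradient (outward from the negative core). Crossing parameters are
  clamped to [1e-6, 1−1e-6] against degenerate triangles.

One robustification was required beyond element-wise detection: the set
{∇²f < 0} in a noisy image percolates through the near-zero background,
so the anomaly core is defined as the connected node set with ∇²f < 0
**and** |f| ≥ 0.25·max|f|, keeping only components touched by the
retained edge elements. On a genuine steplike edge the image still holds
roughly half its peak at the inflection, so the amplitude floor (half of
the half-amplitude level) only severs spurious background bridges; for
idealized Gaussian blobs, whose inflection amplitude is e^{−3/2} ≈ 0.22
of peak, a lower floor can be passed explicitly. Triangulating the
entire shell of the selected cores also repairs pinholes where a shell
tet narrowly failed the gradient criterion; the result is watertight
whenever the core does not touch the domain boundary.

## Quantification

The tank is gridded at 1 mm; the default grid is 180 × 150 × 80 =
2,160,000 cubes of 10⁻³ mL spanning z ∈ [5, 85] mm — 80 mm of depth
ending at the underside of the 15 mm cover layer, which contains every
anomaly placement. Grid nodes are classified against the extracted
surface by scanline ray parity per vertical column, with four
deterministic sub-nanometre diagonal jitters OR-combined and an explicit
on-surface tolerance, so nodes lying exactly on axis-aligned facets
count as enclosed. This convention makes the analytic ground-truth
cuboids come out exactly (a 40 mm cube flags 41³ nodes → 40³ valid cubes
→ 64.000 mL).

A cube is "valid" when ≥ 4 of its 8 vertices are enclosed and those
vertices are not all on one cube face. The coplanarity exclusion is part
of the rule and biases curved shapes low by about one face layer of
boundary cubes (−1.7% on an r = 25 mm sphere at 1 mm spacing; node
classification itself is within 1% of the analytic volume).

Anomaly position is the |δx|-weighted centroid of the half-amplitude
set (elements with |δx| ≥ 0.5·max|δx|; the fraction is configurable).
Position error is the signed per-axis offset from the true centre as a
percentage of the tank extent; volume error is the signed relative
error against the nominal inclusion volume.

## Synthetic study and noise

The simulated filling series reproduces the physical protocol: three
inclusions (4×4×4, 5×5×5, 8×8×5 cm → 64, 125, 320 mL), centred in-plane
with tops 15 mm below the array. The reference frame is the clean
forward computation F(x_p) (as in difference imaging practice); the
inclusion frame plays the role of the physical measurement and carries
additive Gaussian noise at 40 dB SNR, defined against the frame RMS
(the data-vector convention). All randomness flows from a single seed;
per-model noise seeds are spawned deterministically from it.

What the phantom does **not** emulate: electrode placement and contact
drift between reference and measurement, frequency-dependent saline/agar
dispersion, electronics nonlinearity and correlated interference, and
anatomical (non-cuboid) geometry. Passing tests therefore demonstrate
the internal consistency and numerical fidelity of the pipeline under
ideal difference-imaging conditions, not clinical performance.

## Accuracy observed, and known limitations

With clean data at the `paper` mesh preset the end-to-end volume errors
of the three models are about +23%, +18% and −17%: the intrinsic
accuracy of quantifying a one-step linearized reconstruction of an
8.9:1 contrast through its Laplacian-inflection shell at this depth and
aperture. The reconstruction is a smooth blob rather than a plateau
with sharp flanks, so the inflection surface — exact for an ideal
blurred step — lands where regularization puts it, not at a
blur-independent location.

At 40 dB frame SNR the solver's noise-only image response has the same
magnitude as the signal image (image SNR ≈ 1 near the electrode plane at
every (λ, ε) setting scanned), so the extracted shell inflates or picks
up near-array structure; worst-case volume error across the series is
then of order +50 to +140% depending on the noise realization. In-plane
position errors remain small throughout (≤ ~6% of the tank extent), and
the z-axis error is consistently +20 to +26% toward the array — the
centre of mass is pulled up by the depth-decaying sensitivity, the same
tendency the physical experiments report. Volume figures at this noise
level should be read as qualitative; reliable volumetry would need
higher measurement SNR (or frame averaging) than the simulated
single-frame protocol provides.

Other limitations: single-step linear reconstruction only (no iterative
Gauss–Newton); isotropic real conductivity; the valid-cube rule's
curvature bias noted above; watertightness is guaranteed only for
anomaly cores interior to the mesh (cores touching the boundary produce
an open shell, which classification handles by parity but reports).
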