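# Methods

## Model

`cleftsim` simulates the action-potential (AP) upstroke in a pair of
cylindrical cardiomyocytes (radius `R_ID` = 11 um, length `L` = 100 um)
abutting longitudinally at their intercalated discs (ID), embedded in a
grounded extracellular bath box of 300 x 55 x 55 um. The quasi-static
charge-conservation equations

    -div(sigma_i grad V_i) = 0     (intracellular, sigma_i = 3.333 mS/cm)
    -div(sigma_e grad V_e) = 0     (extracellular,  sigma_e = 6.666 mS/cm)

are coupled across each membrane by the current-density balance
`I_m = C_m dV_m/dt + I_ion`, with `V_m = V_i - V_e` at coincident
membrane points.

The ID cleft, tens of nanometres wide versus tens of micrometres of
cell, is not meshed as a volume. Instead the two junctional membranes
and the cleft are collapsed onto a single 2D disc manifold at x = 0
carrying three co-located potentials: `V_i1`, `V_i2` and the cleft
`V_e`. On that manifold:

* tangential cleft current obeys a 2D Poisson equation with sheet
  conductance `w * f_sigma * sigma_cleft`, where the local cleft width
  `w` and conductivity factor `f_sigma` are piecewise-constant fields
  (plaque: 2 nm and 0.1; perinexus: `w_peri`; elsewhere: `w_cleft`);
* both membranes inject `I_ion + C_m dV_m/dt` into the cleft;
* gap junctions couple `V_i1` to `V_i2` through a per-area conductance
  `sigma_gap = G_gap / A_region`, assembled as a mass-matrix bridge
  `[[M, -M], [-M, M]]` (uniform configuration: spread over the ID
  outside the Na+ cluster footprint; close/remote: concentrated in the
  plaque). The Schur-reduced two-terminal conductance equals the
  configured `G_gap` exactly because the field is normalized by the
  realized mesh area.
* cleft `V_e` is continuous with the bath along the junction curve J
  (the disc rim), where the cleft layer shares nodes with the volume
  mesh.

Membrane kinetics are deliberately minimal, resolving only the upstroke:
the fast Na+ current `I_Na = F * gbar_Na m^3 h j (V_m - E_Na)` with the
published Luo-Rudy 1991 alpha/beta rate expressions (see
`lr91_rates.py` for provenance), and a linear K+ leak
`I_K = gbar_K (V_m - E_K)` that pins the resting potential at
E_K = -85 mV. Half of each cell's Na+ channels sit on its two ID-facing
discs (`P` = 0.5), concentrated entirely inside a central cluster of
radius `R_ID`/16; scaling factors `F_ID = P A_cell / A_ID = 5.05` and
`F_lat = (1-P) A_cell / A_lat = 0.555` keep the total channel count
constant. The in-cluster multiplier is renormalized by the realized
(meshed) cluster area so total conductance is conserved to better than
1 % at any resolution.

## Spatial discretization

P1 (piecewise-linear) tetrahedra in the volumes and P1 triangles on the
ID manifold and membranes. The stiffness matrix is
`K = K_nc + K_c + K_gap`; membrane coupling uses the signed incidence
operator `U` (+1 intracellular node, -1 extracellular node per membrane
pair), the consistent membrane mass matrix `G` and `Q = C_m G`.

Meshes are generated deterministically (no external mesher): a
ring-graded triangulation of the ID disc, refined around the
cluster/plaque/perinexus zone (default radial spacing 0.17 um inside the
cluster, 0.58 um in the feature zone out to 4 um, coarsening to 3.4 um
at the rim) is prism-extruded along the cell axis with geometrically
growing layers (0.5 um at the ID), and the bath is built from an
annulus-to-box section extruded alongside. Prisms are split into
tetrahedra with a face-local minimum-index rule, which makes all
sub-meshes conform — including the lateral membrane triangulations of
the intra- and extracellular sides, which match exactly. An automated
audit checks face conformity, layer coincidence and the absence of
duplicate cleft nodes. Identical parameters yield byte-identical meshes,
and all ID configurations and cleft widths share one mesh, so
configuration comparisons are free of meshing artefacts.

The same machinery builds an explicit-cleft variant (cells displaced by
`w`, cleft meshed as a thin tetrahedral layer). It is not used for
production runs; it is the independent validation model: on a miniature
passive pair (R = 2 um, L = 6 um, w = 100 nm, subthreshold current
step) the two formulations agree on the patch potentials and the
mid-cleft `V_e` to within ~1 % (tested at 2 %).

## Time integration

The semi-implicit alpha/beta scheme (alpha + beta = 1): the constant
matrix `K_N + (1/(dt beta)) U_N Q U_N^T` is factorized once per run
(sparse LU of the SPD matrix, reused at every step) and the membrane
potential is advanced by `V_m <- (1/beta) U^T V - (alpha/beta) V_m`.
alpha = beta = 0.5 (Crank-Nicolson) is the default; alpha = 0, beta = 1
gives backward Euler. Gates are integrated with Rush-Larsen, exact for
rates frozen within a step.

Two numerical choices matter in practice:

* **Consistent membrane potential for the kinetics.** The raw
  recursion variable `V_m` of the alpha/beta update carries an
  oscillatory reconstruction mode with amplification factor
  `-alpha/beta` (undamped at Crank-Nicolson). It is harmless for the
  field solve but destructive when sampled by the nonlinear gating at
  conductances with `C_m/g` far below dt — exactly the situation in
  the Na+ cluster, whose local maximal conductance is ~3 x 10^4
  mS/cm^2. Gates and ionic currents are therefore evaluated at the
  consistent, smooth value `U^T V` of the last solved field (the
  alpha/beta average `alpha V_m(t-dt) + beta V_m(t)`), in which the
  oscillating component cancels. Recorded samples are timestamped at
  `t_n + beta dt`, the instant that field represents.
* **Implicit linear leak.** The K+ current is linear, so it is folded
  into the constant left-hand side, where it is evaluated exactly at
  the scheme's time-centred potential. This keeps the passive problem
  genuinely second-order for Crank-Nicolson (measured order 2.0;
  backward Euler measures 1.0) and leaves only the Na+ current
  explicit.

Initialization: `V_i` = -85 mV, `V_e` = 0, gates at their -85 mV steady
state; with E_K = -85 mV this is an equilibrium (rest drift < 0.5 mV
over 10 ms, tested).

## Protocols and readouts

The standard protocol is a current clamp of 11.5 nA for 0.5 ms on a
spherical patch region (radius 2 um, centred on the axis 10 um from the
outer end) inside cell 1, with a zero-current clamp on cell 2's patch;
the current is distributed over the patch nodes by lumped weight, and
the patch potential is their weighted mean. The box faces perpendicular
to the cell axis are grounded; the four lateral faces are zero-flux.

Readouts: patch `V_i` of both cells; ID and bulk (lateral + outer)
surface-integrated `I_Na` per cell, weighted by the piecewise-constant
density field so cluster current is not smeared; minimum cleft `V_e`;
optional full-field snapshots; potential profiles along the ID diameter
through the cluster and plaque centres. The upstroke delay is measured
between 0 mV crossings of the two patch potentials with linear
interpolation; `I_Na` peaks are reported at the discrete output sample
of the extremum. The post-junctional response is classified as an
action potential (0 mV crossing), subthreshold (> 2 mV above rest — the
cutoff separating clear partial depolarizations from numerical drift),
or no effect.

## Resolution presets and run sizes

The `coarse` preset (about 10,000 nodes, dt = 0.0005 ms, 10 ms runs at
output stride 0.01 ms) is used for sweeps, tests and the acceptance
script; each scenario takes tens of seconds on one CPU. Runs
terminate early once the outcome is resolved: 2.5 ms after both
upstrokes, or after 3 ms of electrical quiescence (all regional
`I_Na` < 0.05 nA, stimulus long over, cleft potential collapsed) —
states from which no further excitation is possible in this model.
`medium`/`fine` presets refine all target edge lengths by 1.3x per
level; the high-fidelity time step is 0.0001 ms. Sensitivity at the
transition scenarios (the strongest test of resolution): halving dt
changes the 60 nm / 1 % coupling delay by < 1 %; one refinement level
changes it by a few percent without changing any classification in the
10-100 nm sweep.

## What the model does and does not represent

The simulations reproduce ephaptic interaction mechanisms —
self-activation and self-attenuation through the cleft potential,
outward pre-junctional "Na+ transfer", modulation by perinexal width —
in an idealized geometry: straight cylindrical cells, a flat circular
ID, a single centred Na+ cluster and a single plaque. Not represented:
tortuous ID morphology, multiple plaques, Ca2+ and late Na+ currents,
ion-concentration dynamics (fixed Nernst potentials), repolarization
currents beyond the linear leak (APs here decay passively after the
upstroke), and anisotropic conductivities. Passing tests therefore
support the collapsed-cleft formulation and its numerics, not
quantitative predictions for real tissue.

## Limitations

* The coarse preset slightly under-resolves the cleft potential well at
  wide clefts; transition widths (e.g. the exact boundary of the
  transmitting band) carry a one-grid-step uncertainty.
* The explicit Na+ current limits dt through accuracy (not stability,
  which the consistent-potential evaluation restores); dt = 0.0005 ms
  was verified against 0.0001 ms on the delay scenarios.
* The sparse LU factor-once/solve-many kernel is single-threaded;
  wall time scales roughly linearly with node count times steps.
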