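# Methods

`mcaspol` simulates mass-conserved activator–substrate (MCAS) models of
Rho-GTPase cell polarity and measures how multiple polarity peaks resolve:
one peak absorbing the others (competition), unequal peaks persisting
(coexistence), or peaks converging to equal size (equalization).  A
companion 3D module simulates fluorescence recovery after photobleaching
(FRAP) in a two-lobed (mother–bud) cell to quantify how a constricted neck
retards diffusional exchange.

## Models

All four models conserve total protein: every reaction interconverts
species within a conserved pool, and the solver audits the weighted totals
at run time.

**Minimal model** (dimensionless).  A membrane-bound activator `u`
(GTP-GTPase) and a fast cytosolic substrate `v` (GDP-GTPase):

    du/dt = a u^2 v − b u + Dm ∇²u
    dv/dt = −a u^2 v + b u + Dc ∇²v

with `a = b = 1`, `Dm = 0.01`, `Dc = 1`.  The quadratic activation term is
the implicit positive feedback; `u + v` is conserved.

**Indirect-substrate model.**  Adds a cytosolic intermediate `v_i`
produced from the activator (`u → v_i`, rate `c = 0.01`) that matures into
substrate (`v_i → v`, rate `d = 1`), with its own diffusivity `Dvi`
(default 1).  The indirect return path is what allows a *smaller* peak to
out-recruit a larger one, because `v_i` is exported from peaks in
proportion to their activator content and re-delivered everywhere.

**Mechanistic yeast circuit** (µM, s, µm).  Six species: GTP-Cdc42
(`Cdc42T`), membrane and cytosolic GDP-Cdc42, a scaffold–GEF complex
("BemGEF") in cytosolic, membrane, and Cdc42-bound (`BemGEF42`) forms.
Positive feedback: `BemGEF42` activates neighbouring Cdc42, and GTP-Cdc42
recruits more BemGEF.  Cytosolic species enter the conserved totals with
weight `1/η` (`η = 0.01`, the membrane-to-cytosol volume ratio).  The
complexes `BemGEF42` (and, with negative feedback, `BemGEF*42`) carry both
a Cdc42 and a GEF and therefore appear in both conservation pools.

**Negative-feedback variant.**  Adds ultrasensitive multi-site GEF
phosphorylation: membrane complexes phosphorylate unphosphorylated
complexes at rate `k8(X)·BemGEF42_t·BemGEF42` with
`k8 = k8max X^6/(k8h^6 + X^6)`, and cytosolic phosphorylated GEF is
reactivated at `k9(Y)·BemGEF*_c`.  The Hill arguments are configurable
because the source formulas are ambiguous; defaults are

* `X = BemGEF42_t` (total membrane GTPase–GEF complex).  At a 1x polarity
  peak this reaches ≈ 6 µM against `k8h = 10` µM, so phosphorylation
  switches on steeply between 1x and 2x protein amounts — the behaviour an
  ultrasensitive switch is presumably for.
* `Y = BemGEF*_m` (phosphorylated membrane GEF, ≈ 0.02 µM at a peak,
  commensurate with `k9h = 0.003` µM).  The alternative reading
  `Y = BemGEF*_c` evaluates to ~10⁻⁵ µM ≪ `k9h`, which silences
  dephosphorylation entirely and turns the feedback into a one-way sink;
  we therefore treat it as a transcription artefact, while keeping it
  selectable.

**Protein amounts.**  Amounts are stated in "1x" units.  For the
dimensionless models 1x means a uniform substrate concentration of 2.  For
the mechanistic models 1x means cytosolic pools of 5.0 µM Cdc42 and
0.017 µM BemGEF (the true normalization is not derivable from the rate
tables; these values are exposed in `assays.UNIT_CONCENTRATIONS`).

## Numerics

The integrator is IMEX finite differences on cell-centered 1D/2D grids:
diffusion is backward Euler on a flux-form Laplacian (cached sparse LU per
diffusivity and step size), so inter-cell fluxes cancel exactly and
conserved totals drift only at solver round-off (≤ 10⁻⁸ relative is
enforced; ≲ 10⁻¹² typical).  The reaction term is advanced explicitly for
the dimensionless models.  For the mechanistic models the membrane-binding
kinetics are stiff (`k4a·Cdc42T` exceeds 10³ s⁻¹ at a polarized peak,
capping an explicit step at ~3×10⁻⁴ s), so their reaction sub-step is
solved by backward-Euler Newton with analytic per-cell Jacobians; backward
Euler preserves the linear conservation invariants exactly, and the fixed
point of either scheme is the same semi-discrete steady state.

Step size adapts by step doubling on the reaction term: each step is taken
once at `dt` and again as two half-steps, and accepted when the per-species
relative discrepancy is below `rel_tol` (default 10⁻⁴); the step halves on
rejection and doubles when the error falls below a quarter of the
tolerance, with hysteresis against ping-ponging at a stability boundary.
On the implicit path each species' error scale is floored at 5% of its
conservation group's weighted mass scale (divided by the species' weight):
trace species such as cytosolic BemGEF sit three orders of magnitude below
the membrane pools and are re-slaved to them every step, so measuring
their error against their own maximum throttles the step ~100-fold without
changing any observable (validated against a strict-tolerance explicit
reference: basal cytosolic Cdc42 to 0.06%, basal cytosolic BemGEF to a few
percent during transients and exactly at steady state).

Boundary conditions are periodic or reflecting (no-flux); internal no-flux
walls perpendicular to x insulate subdomains by deleting the coupling
across a wall interface, so removing a wall restores the original operator
exactly.

## Assay protocols

**Single-peak preparation.**  Each insulated subsystem starts with all
protein in the cytosolic pools plus a Gaussian activator bump (amplitude
5× the scaled unit substrate concentration) at the subsystem edge, plus
seeded multiplicative noise (1%) on the cytosolic fields; totals are then
renormalized exactly.  The finite-amplitude seed is essential: below the
Turing threshold the patterned state is excitable and unreachable from
small noise, while far above it noise nucleates many peaks whose
coarsening is astronomically slow, so a noise-only protocol cannot deliver
the required one-peak state.  The seed sits at the boundary because the
boundary-attached half-peak is the stable attractor (interior peaks drift
slowly toward a wall).  Relaxation runs to `max |du/dt| < 10⁻⁶ ×` field
scale or a fixed horizon (400 time units dimensionless, 200 s
mechanistic); basal levels converge to ~10⁻⁷ well before the mesa front
fully equilibrates.

**Domains.**  The 1D domain is `L = 5` (subsystems of 2.5) at 500 grid
points.  The subsystem mass scale is the one genuinely free knob in the
dimensionless models, and it was set once by two phenomenological anchors:
a 1x subsystem must sit below the activator saturation point (so 0.6x vs
1x peaks compete) while 2x–4x subsystems are saturated (so they coexist),
and the indirect model's basal-substrate minimum must fall near 1x (so
0.6x:0.9x competes while 0.8x:1.2x equalizes).  Mechanistic runs use a
4.43 µm square (100×100 points by default; tests use coarser grids), with
the negative-feedback two-peak assays on proportionally smaller subsystems
— each insulated subsystem must hold exactly one peak, and the
negative-feedback circuit's intrinsic peak spacing shrinks with protein
amount, which is a precondition of the protocol rather than a tuning of
its outcome.

**Competition assay.**  Two subsystems are prepared at their stated
amounts, mirrored so their peaks face away from the shared interface,
joined at `t = 0`, and integrated to `t_max = 2000` while tracking each
peak's share of total activator mass (Cdc42T for the mechanistic models)
through watershed partition at inter-peak minima, with identity propagated
by activator-mass-weighted region overlap.  Early termination applies once
a winner exceeds 99.5% or both peaks have settled within 0.5% of equality.

**Outcome rules** (evaluated on the tracked fractions): *competition* —
one share reaches ≥ 99%; *equalization* — both shares settle within ±1
percentage point of 50%; *coexistence* — shares remain within ±1 point of
their starting values throughout; *peaks split* — the detected peak count
exceeds the initial count; *homogeneous* — the activator range falls below
10⁻³ of its mean.  A run still drifting at `t_max` is labeled coexistence
with a `censored` flag; censored cells carry no settled label.

**Competition time** is the interpolated interval between the winner's
share crossing 70% and 99%.

**Basal levels and the outcome predictor.**  The basal substrate level of
a peak is read at the point of its watershed region farthest from the peak
(the subsystem edge for an insulated single peak).  The predictor computes
Δv = basal v at the larger-amount peak minus the smaller one: substrate
higher at the *smaller* peak flows toward the larger one (competition);
higher at the *larger* peak feeds the smaller one (equalization); |Δv|
below a 10⁻⁴ band predicts coexistence.  In the phase-diagram sweep the
prediction is validated against the dynamical label on cells that are
neither boundary (|Δv| < 2×band) nor censored.  Known failure mode: in the
near-classical-Turing regime (indirect-substrate mobility ≫ substrate
mobility) equalization arises from shared local kinetics rather than
substrate flux, and the sign of Δv is no longer informative; coarse sweeps
should avoid placing cells directly on regime boundaries, which the sweep
cannot resolve anyway.

## Simulated FRAP

**Geometry.**  The cell is the union of a 6 µm diameter sphere (mother)
and a prolate ellipsoid (daughter, length 6 µm) overlapped so the waist is
exactly the requested neck diameter (2 µm by default); the overlap offset
has a closed form.  The default daughter width is 3 µm so a genuine
constriction exists; the narrow 2 µm-wide daughter is available as a
configuration.  The interior is a voxel mask; diffusion uses a flux-form
7-point Laplacian with dropped exterior faces (zero normal flux) and
implicit Euler with a fixed 10 ms step and one cached factorization, so
total intensity is conserved to round-off.

**Protocol.**  A 1 µm diameter cylinder through the mother centroid is set
to zero intensity; "images" are z-sums (mimicking non-deconvolved
widefield stacks); ROI traces are means over 3 µm diameter circles at the
bleach site and at two sites equidistant (3 µm) from it along the
mother–daughter axis, one within the mother and one just across the neck.
Both relaxation traces are fit with `a·e^(−kt) + c` (the five-parameter
two-term variant is available but parameter-degenerate on 15-frame traces
and agrees with the single exponential to ~2%), and the neck slowdown is
`1 − k_daughter/k_mother`.  Acquisition mimics the bench assay: 15
post-bleach frames at 0.35 s.  The effective cytosolic diffusivity is
1 µm²/s, chosen so the simulated mother-site half-time (~0.6 s) sits on
the ~1 s scale the experimental acquisition was designed around; the
absolute rates scale with D but the daughter/mother ratio is insensitive
to it at matched sampling.  A voxel-refinement study (0.25 → 0.125 µm)
shows the slowdown converging from below (11.8% → 17.8% → 20.2%);
production runs use ≤ 0.15 µm voxels.

The ROI-ratio readout mixes local redistribution kinetics with the
inter-compartment mode, so it is *not* monotone in neck diameter when the
ROI anatomy changes with the geometry.  The monotone statistic is the
equalization rate of the two compartment means
(`compartment_equilibration_rate`), which decreases strictly as the neck
narrows.

**Exponential fits.**  Traces are normalized as
`(I_raw − I_background)/(I_unbleached − I_background)`.  Fits are
trust-region nonlinear least squares with deterministic initial guesses
(asymptote from the trace tail, rate from a log-linear regression on the
deviation; the two-term model seeds its slow component from the residual
of a first single-exponential pass).  95% confidence intervals use the
t-distribution with `n − p` degrees of freedom; at noise σ = 0.02 and 15
samples the interval covers the true rate in ≈ 93% of replicates.
Half-times are `ln 2 / k`.

## Synthetic data

The generator module provides: the canonical parameter tables and named
assay presets (packaged YAML); homogeneous fields with seeded
multiplicative substrate noise and exactly renormalized totals; scripted
piecewise-linear competition traces realizing every outcome label
(classifier ground truth); and exponential FRAP traces with recorded true
parameters and seeded Gaussian noise.  All stochastic entry points take an
explicit seed.  What these fixtures do not emulate: microscopy noise
statistics, photobleaching during acquisition, optics, or cell-to-cell
parameter variability — passing tests certify the algorithms, not
instrument realism.

## Problem sizes

Default production sizes are 500 points (1D) and 100×100 (2D mechanistic).
The test suite runs the same protocols at reduced sizes chosen once for
desk-scale runs: 2D mechanistic assays at 16×16 on the 4.43 µm square,
the outcome sweep at 250 points, FRAP checks at 0.25 µm voxels with the
headline neck-slowdown number at 0.15 µm.  The phenomenology asserted
(conservation, monotone competition times, saturation shapes, outcome
switching, predictor consistency, ~20% neck slowdown) is stable under
halving any of these resolutions.

## Known limitations

* Outcome labels near regime boundaries depend on the `t_max = 2000`
  observation window; slowly equalizing runs are reported as censored
  coexistence rather than extrapolated.
* The mechanistic "1x" normalization is a modelling choice; regime
  boundaries (saturation onset, splitting threshold) shift with it, and
  only their ordering and existence are asserted.
* The negative-feedback model's Hill-function arguments follow the
  scale-consistency argument above; the alternative readings are exposed
  but not exercised by the tests.
* Under the package's normalization the negative-feedback circuit shows
  competition at low protein amounts and peak splitting (or homogeneous
  decay) at high amounts, but no clean two-equal-peak window in between:
  the basal active-GEF level falls monotonically with amount over the
  single-peak range, and the phosphorylated GEF pool — the circuit's
  indirect substrate, which does rise with amount — is too dilute for its
  return flux to compete.  A normalization placing cytosolic
  phosphorylated GEF near its dephosphorylation constant would strengthen
  that pathway; locating such a window is an open exercise.  Equalization
  is demonstrated in full by the indirect-substrate model, which isolates
  the same mechanism.
* 3D FRAP is diffusion-only: no reversible photophysics, no acquisition
  bleaching, no point-spread function.
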