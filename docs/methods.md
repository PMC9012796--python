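# Methods

## System and scope

`pipacsim` models aerosol drug deposition in a benchtop stand-in for the
insufflated peritoneal cavity: a rigid box of 185 × 135 × 152 mm filled
with CO₂ at 12 mmHg (1600 Pa; ρ = 1.977 kg m⁻³, ν = 7.44 × 10⁻⁶ m² s⁻¹),
with a high-pressure nebulizer nozzle (orifice 200 µm) at the center of the
top face pointing straight down, and four 20 × 20 mm tissue plates: A on
the bottom directly under the nozzle, B on the bottom near the −x wall, C
at mid-height on the −x wall, D on the top face offset from the nozzle.
The coordinate frame is right-handed with gravity along −z and the origin
at the bottom-center; practical units (mL s⁻¹, µm, mmHg, kV) are converted
to SI exactly once at the interface.

The package tracks individual droplets (Lagrangian, one droplet per
simulated parcel) through analytic gas-velocity fields and an optionally
solved electrostatic field, detects wall adhesion, and reduces the
deposit pattern to the observables used in bench experiments.

## Droplet dynamics

Each droplet obeys

m_p du_p/dt = m_p (u − u_p)/τ_p + m_p g + q E,  τ_p = ρ_p d_p²/(18 µ),

with Stokes drag toward the local gas velocity u, gravity
(g = 9.81 m s⁻² exactly; buoyancy neglected, ρ_p/ρ_gas ≈ 540 so the
correction is <0.2 %), and the electrostatic force qE. Droplet Reynolds
numbers at the relevant relative speeds are small enough that the linear
drag law is retained throughout; the standard particle Reynolds number
ρ_gas |u−u_p| d_p/µ is reported as a diagnostic (an alternative
droplet-density form without the length scale is exposed for reference but
not used). The Weber number ρ_p|u−u_p|²d_p/σ is reported as a breakup
diagnostic only — breakup, coalescence, evaporation and condensation are
not modelled (cold, dry CO₂ at room temperature makes the latter two
negligible over a 30-minute run).

**Integrator.** With u and E frozen over a step, the equation of motion is
linear with exact solution u_p(t+Δt) = u_∞ + (u_p − u_∞)e^(−Δt/τ_p),
u_∞ = u + τ_p(g + qE/m_p), and a matching closed form for position. The
integrator applies this exponential update, so it is unconditionally
stable and exact for constant forcing; this matters because τ_p spans
3.6 µs (1 µm) to 10 ms (50 µm) and any explicit scheme would need Δt ≲ τ_p.
The only integration error is the spatial variation of u and E across one
step, controlled by limiting each droplet's displacement per step to 2 mm
(default `max_displacement`), with Δt clamped to [10⁻⁷ s, 1 s] when a field
or jet is active and up to 5 s for uniform forcing (where the update is
exact for any Δt). Step sizes are per-droplet: one-way coupling makes
trajectories independent, so the ensemble is advanced asynchronously in
vectorized batches.

**Wall adhesion.** A droplet deposits when the distance from its center to
any wall drops below its diameter (the adhesion rule implemented
literally, diameter not radius). The terminal step is refined by bisection
(48 iterations) on the closed-form trajectory, locating the contact point
to well below 1 µm. Deposits are attributed to the nearest wall and, where
applicable, to a tissue plate footprint; deposited droplets never move
again. Droplets still airborne at the end of the run (practically only
≤1 µm sizes) are reported as airborne, never force-deposited, and counts
satisfy injected = deposited + airborne at all times.

## Injection model

The nozzle exit speed is u₀ = Q/A_O (15.92 m s⁻¹ at 0.5 mL s⁻¹).
Emission times are uniform over the window volume/Q (40 s for the standard
20 mL dose); each parcel starts at the nozzle tip, which protrudes 5 mm
into the cavity along the nozzle axis — emitting exactly on the boundary
would trigger the adhesion rule immediately, and a real nebulizer tip does
protrude through its access port.

Initial directions are sampled uniformly over the solid-angle cap of half
the spray cone angle (unbiased cone fill), giving an axisymmetric spray.
The cone angle follows a saturating law α(Q) = α_max − c·e^(−kQ) with
defaults α_max = 71°, c = 65°, k = 8.45 s mL⁻¹, calibrated to the measured
anchor of ≈70° at the clinical 0.5–0.6 mL s⁻¹ and rising steeply from
narrow cones at low flow; the coefficients of the published experimental
curve fit are stored as data but are not usable as a default because they
do not reproduce the ~70° anchor under any plain reading.

Droplet sizes are monodisperse by default (the clinical baseline is a
fixed 30 µm), with a lognormal alternative parameterized by the
volume-median diameter D(v,0.5) and geometric SD (default 1.5); lognormal
number-distribution medians are derived from D(v,0.5) via the Hatch–Choate
relation so the sampled volume median converges to the specified value.
The measured D(v,0.5)–flow-rate calibration (48, 40, 35, 29, 28, 28 µm at
0.4–0.9 mL s⁻¹) is embedded as a lookup with linear interpolation between
knots; extrapolation outside the calibrated range is refused. The impaction
parameter d_p²·Q is provided as the standard lumped predictor of inertial
deposition.

## Gas phase

The insufflation flow is not solved; two analytic fields stand in for it.
The default is quiescent gas (the cavity is sealed and pressurized, and
the nebulized liquid adds negligible gas volume). The alternative is a
classical self-similar round jet along the nozzle axis: centerline speed
u₀·B·d_N/s with B = 6.0, Gaussian radial profile of half-width 0.1·s,
capped at u₀ in the potential core. Both satisfy one-way coupling — the
instantaneous airborne volume fraction φ = Σv_i/V of any simulated
ensemble is far below the 10⁻⁶ dilute threshold (the simulator computes φ
as an upper bound before each run and refuses denser ensembles as
unsupported physics; each run also logs its peak airborne φ).

This substitution is the model's main simplification: the real insufflated
cavity carries a recirculating flow driven by the jet's impingement, which
spreads 30 µm droplets across several regions. Under quiescent gas,
droplets ≥5 µm sediment ballistically and deposit almost entirely in the
dorsal region. Consequently the package verifies deposition *trends*
(ordering statements between conditions) rather than the region
percentages a full CFD solution produces.

## Electrostatics (ePIPAC)

The brush electrode is modelled as a 3 mm sphere at fixed potential,
positioned by default on the nozzle axis at 0.6·H (the brush hangs below
the nebulizer tip); the four tissue plates are grounded return electrodes,
and the plexiglass walls are insulating. The Laplace equation is
discretized on a regular lattice (default 48 nodes per axis) with a
symmetric finite-volume 7-point stencil — half-width boundary cells make
the face-flux matrix symmetric under the zero-normal-gradient walls — and
solved with Jacobi-preconditioned conjugate gradients to a 10⁻⁸ relative
residual. E = −∇φ by central differences, interpolated trilinearly at
droplet positions. The problem is linear in the supply voltage, so voltage
sweeps solve once at a reference potential and rescale.

**Polarity and charge.** Droplets carry a negative charge; precipitation
toward *grounded* surfaces then requires a negative electrode potential
(the force qE points away from a like-signed electrode), so a configured
supply voltage of, say, 6.5 kV is applied as −6.5 kV. The default charge
per droplet is −5 × 10⁻¹⁴ C, the corona-charging (Pauthenier) scale for a
30 µm droplet in the ~10⁶ V m⁻¹ field adjacent to the brush — a
conservative cloud-average, two orders of magnitude below the Rayleigh
stability limit (~10⁻¹² C for 30 µm). At this charge the electric force is
several times gravity over most of the cavity at 6.5 kV, which is the
regime in which precipitation visibly redistributes deposition, as
observed on the bench. Space charge, corona dynamics and induced-charge
(image) attraction are neglected: the field is electrostatic and acts
one-way on the droplets.

Because the model lacks space charge and corona-current limits, the
electrostatic effect scales strictly linearly with supply voltage: the
simulated homogeneity keeps improving through 9 kV instead of saturating
at 6.5 kV as the bench experiments do. The deposition pattern would become
voltage-independent only in the field-line-following limit qE ≫ m_p g,
which lies above the supply range at a physical droplet charge. This is a
known, documented limitation.

## Deposition observables

- **Region fractions**: the cavity is divided into four equal-thickness
  horizontal slabs, region 1 (dorsal, bottom) to region 4 (ventral, top),
  with lower-inclusive boundaries. Fractions are percentages of *injected*
  droplets, so runs with different airborne remainders stay comparable;
  the airborne remainder is reported separately and the five numbers sum
  to 100 %.
- **Plate staining**: deposits on a plate are stamped as discs of
  `footprint_scale` × d_p/2 radius onto a raster of 50 µm cells; the
  stained percentage is covered cells / total cells. This emulates the
  photographic thresholding workflow used on real tissue samples. The
  spread factor defaults to 10 — a deposited droplet wets a stain much
  larger than its airborne diameter — and is an explicit calibration knob,
  since no measured spread factor exists for this system.
- **Homogeneity index**: 1 − CV/√3 over the four region fractions, clipped
  to [0, 1]: 1 for perfectly even deposition, 0 when one region takes
  everything (CV of a single-occupied 4-vector is √3). It is permutation-
  and scale-invariant. Runs with no deposits at all report NaN.

## Liquids

Embedded carrier presets: black ink (ρ = 1070 kg m⁻³, µ = 2.1 mPa s),
saline (1005, 1.0), Icodextrin 4 % (1016, 1.88) and 7.5 % (1028, 2.24).
Solution densities are nominal values for these aqueous preparations;
surface tensions (0.05–0.072 N m⁻¹) enter only the Weber diagnostic. In a
one-way coupled transport model the carrier viscosity itself has no
dynamical channel once the droplet size is fixed (drag involves the *gas*
viscosity); carriers differ in transport only through droplet density.
The experimentally observed viscosity effect on deposition operates partly
through atomization, which is outside scope, so simulated carrier
contrasts at fixed 30 µm size are small or degenerate by construction.

## Study conditions and problem sizes

Parameter studies mirror the benchtop grids: diameters {1, 5, 10, 30,
50} µm, flow rates 0.4–0.9 mL s⁻¹, viscosities {1.0, 1.88, 2.24} mPa s,
voltages {0, 4, 5, 6, 6.5, 7, 8, 9} kV, all at the 0.5 mL s⁻¹ / 30 µm /
20 mL / 30 min baseline unless swept. Each run tracks 10,000 parcels —
each parcel one physical droplet; the true count (~10⁹) is statistically
unnecessary — and trend checks use 5 independent seeds per condition (the
exploratory `analysis/` drivers use 5,000 parcels × 3 seeds, which leaves
region-fraction standard errors well under 1 percentage point). Sweeps are
deterministic given their seed lists, and cells can be cached by a content
hash of their configuration so interrupted sweeps resume.

## What the synthetic ensembles do and do not show

The injection generator reproduces the *configured* nebulizer: exact exit
speed, uniform emission in time, axisymmetric cone fill, and the specified
size distribution. It does not emulate primary atomization (ligament
breakup), size–angle correlations, or swirl. Tests passing on these
ensembles therefore validate the transport, field and scoring machinery
under the stated injection model — they do not certify the spray physics
of a real nebulizer, nor deposition patterns that depend on the
recirculating insufflation flow (see Gas phase above).

## Numerical choices, degenerate inputs, determinism

- Exponential integrator; per-droplet Δt from the 2 mm displacement bound;
  48-iteration bisection for wall contact; droplets cannot cross a wall
  undetected because the adhesion shell (one diameter) is crossed first
  and the bisection brackets the first entry into it.
- Laplace solver: resolution ≥ 16 nodes per axis enforced, default 48
  (64 used in verification against the parallel-plate closed form, which
  it reproduces to round-off); CG tolerance 10⁻⁸, non-convergence raises
  with the residual. An electrode smaller than one cell snaps to the
  nearest node so the Dirichlet set is never empty.
- Degenerate inputs: zero parcels yields an empty schedule with a warning;
  a zero cone angle collapses to axial injection; monodisperse ensembles
  have exactly zero size variance; all-zero region fractions are rejected
  by the homogeneity index (NaN at the report level); out-of-range PSD
  medians (outside the 0.5–900 µm sizing-instrument window) are rejected.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  configurations and seeds reproduce byte-identical exported tables.

## Known limitations

1. No recirculating insufflation flow: region percentages for mid-size
   droplets concentrate in region 1 instead of spreading 60/30/10/0-style;
   only cross-condition orderings are meaningful.
2. No space charge or corona current: the electrostatic effect does not
   saturate with voltage inside the supply range.
3. Carrier viscosity acts only through droplet density at fixed size.
4. The cone-angle law is calibrated to a single measured anchor; its
   low-flow branch is qualitative.
5. Tissue is geometrically passive: no uptake, no surface flow, and the
   staining raster's spread factor is a declared calibration knob.
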