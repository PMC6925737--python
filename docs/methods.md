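# Methods

## Model overview

`ciliaflow` simulates mucociliary clearance in a two-dimensional periodic
channel.  The airway surface liquid is modelled as two layers separated by a
virtual elastic membrane: a Newtonian periciliary liquid (PCL) in which an
array of elastic cilia beats, and a viscoelastic mucus layer (ML) above it.
The momentum equation is solved everywhere by a single D2Q9
lattice-Boltzmann (BGK) solver with a spatially varying relaxation time; the
membrane only partitions material properties, it is not an internal boundary
condition.  Components:

* **Fluid** — incompressible Navier–Stokes via D2Q9 BGK with Guo forcing
  (body-force term with the half-force velocity correction in the
  macroscopic update).  Channel boundaries: periodic left/right, halfway
  bounce-back (no-slip) bottom, specular reflection (free-slip) top.  A
  wall-node non-equilibrium-extrapolation variant (`noslip_neq`) and
  velocity-inlet / outflow columns exist for the validation benchmark.
* **Mucus rheology** — Oldroyd-B: the solvent part enters the LBM
  viscosity; the elastic stress obeys the upper-convected Maxwell law with
  relaxation time λ, advanced with first-order upwind advection and an
  implicit treatment of the relaxation/source terms (stable for any λ,
  with the exact quasi-Newtonian limit).  Its divergence (tapered by the
  layer indicator) is a body force.
  The solvent fraction in the ML is Rv = 0.975; the PCL is purely
  Newtonian with 1/40 of the ML total viscosity.
* **Structures** — cilia and the membrane are node-spring fibers
  (stretching stiffness Ks = 2.0, bending stiffness Kb = 1.0, node spacing
  ≈ 1 lattice unit).  Bending uses the variational form of the discrete
  bending energy, which encodes the moment-free/shear-free free-end
  conditions; cilium roots are position-clamped to the bottom wall.  Each
  cilium is dragged by a prescribed-motion *virtual cilium* through penalty
  springs (Ksl = 1.0).
* **Coupling** — the immersed-boundary method with the 4-point Peskin
  kernel (3-point Roma and 2-point hat kernels are available); forward
  Euler advection of Lagrangian points with the interpolated velocity.
* **Particles** — rigid discs advanced by Newton's equations; the
  surface-traction integral is realized by direct-forcing momentum
  exchange at surface Lagrangian points, plus a quadratic short-range
  repulsion (cutoff 2 lattice units) against walls, cilia, and other
  particles.  Neutrally buoyant by default, so the gravity/buoyancy term
  vanishes identically.
* **Measurement** — passive tracepoints seeded mid-ML; the mean ML speed
  is the tracer-mean unwrapped x-displacement over a 3-beat-period window,
  converted to μm/s through the physical lattice spacing and beat period.

## Beat waveform

The beat posture is generated from a tangent-angle profile, so every
posture has the exact cilium arclength L.  The cycle splits into an
*effective stroke* (fraction `asymmetry` = 0.35 of the period) in which the
straight cilium pivots about its root from −A to +A (A = `amplitude`,
radians from the vertical), and a *recovery stroke* in which the root angle
returns while a curvature wave curls the distal part over, returning the
cilium with a low tip; the curl
is an absolute folding angle (default 2.5 rad), not a multiple of the
sweep amplitude — a real cilium folds over during recovery regardless of
how wide it sweeps.  The tip path encloses a nonzero area — the geometric
requirement for net pumping at low Reynolds number.  Cilium k in the array carries the phase offset
k·Δφ, which forms a metachronal wave travelling opposite to the transport
direction (antiplectic coordination) for Δφ > 0.

The amplitude A is not a free choice: following the study's own procedure
it is *regulated* so that the reference case (spacing 0.55 L, phase
difference 0.02 T) transports the ML at ≈ 42 μm/s
(`calibrate_amplitude`, secant iteration on short runs).  The calibrated
values are stored in `ciliaflow.reference` and re-derived by the
acceptance script at run time.

## Scales and nondimensional mapping

The solver always runs with Δx = Δt = 1.  Mapping conventions (the source
literature for this model family leaves them open; they are logged with
every run):

* 1 lattice unit = `dx_um` micrometres.  The *reference* (measurement)
  resolution is dx = 0.2 μm with 20 000 steps per beat period; the
  *screening* resolution used for parameter sweeps and the particle study
  is dx = 0.4 μm with 5 000 steps per period.  The default
  steps-per-period scales as 1/dx² so lattice forces (hence the fiber
  strain budget) are resolution-consistent.
* Re = U_tip·L/ν_ML with U_tip the cycle-mean virtual-tip speed and ν_ML
  the total ML kinematic viscosity; We = λ·f (relaxation time in beat
  periods); the beat frequency 20 Hz fixes the physical time of a step.
* A floor on the PCL lattice viscosity (ν_PCL ≥ 0.1, i.e. τ_PCL ≥ 0.8)
  keeps the fiber–fluid coupling damped *and* keeps the beat quasi-steady
  (Womersley number α² = 2πL²/(T·ν_PCL) ≈ 2 or below).  The quasi-steady
  regime matters physically: at low viscosity the oscillatory flow
  rectifies inertially and the metachronal wave transports mucus far more
  efficiently per unit beat amplitude than Stokes flow does, which would
  push the amplitude regulation toward unrealistically small sweep angles.
  When the floor binds, the effective Reynolds number drops *below* the
  configured 0.05 — deeper into the Stokes regime, where transport per
  beat is insensitive to Re — and the realized value is reported in the
  run summary.

## Numerical stabilization of the fiber coupling

Massless fibers coupled explicitly through the IB kernel ring unstably on
their stiff spring modes when the surrounding viscosity is small.  Two
measures keep the scheme stable without altering equilibria or the slow
beat dynamics:

* **IMEX stiff-force filter.**  The full nonlinear fiber force F(X)
  (tension, bending, penalty) is evaluated exactly, then the spread force
  is `F + A(X̃−X)` with `(I − mA)(X̃−X) = mF(X)`, where A collects the
  linearized stiff operators (bending matrix, penalty identity, stretching
  Laplacian) and m ≈ 0.4 is the per-step mobility of a Lagrangian node
  under the 4-point kernel.  At force equilibrium the spread force is
  exact; stiff modes relax monotonically instead of ringing.  The
  cilium operator is a prefactored dense inverse (≈15 nodes); the
  membrane operator is circulant and applied by FFT.
* **Spring–damper tether.**  The driving force carries a velocity-matching
  term η(V_Y − U) with η = 0.5 (V_Y = virtual-node velocity, U =
  fiber-node velocity of the previous step), the standard feedback-forcing
  damper; its time-mean vanishes once the cilium tracks the virtual one
  (tracking error ≤ 0.4% of L in the reference run).
* The beat starts through a one-period smoothstep ramp from the straight
  resting posture, avoiding the acoustic transient of an impulsive start;
  strain and tracking diagnostics are recorded after the ramp.

## Validation benchmark

The coupled LBM + Oldroyd-B solver is validated against the fully
developed viscoelastic plane Poiseuille flow (120×40 grid, u_max = 0.1,
Re = 4, Rv = 0.9, We ∈ {0.01, 1}), comparing the mid-channel velocity and
streamwise-conformation profiles with their closed forms (parabola and
1 + 32λ²u²(L_y−2y)²/L_y⁴; stress is converted to conformation through
A = I + (λ/η_E)σ).  The fully developed state is driven by the exact
equivalent body force in a periodic channel: at these parameters a
velocity-inlet/outflow channel would need an ~18% density drop — an LBM
compressibility artifact that has nothing to do with the physics being
validated.  Walls use the non-equilibrium-extrapolation rows (the
bounce-back slip error at τ = 3.2 is several per cent); the remaining
uniform O((τ−½)²) slip offset does not affect the shear rate, so the
conformation profile is reproduced essentially exactly, and the velocity
profile to ≈1.2% L2.  The stress in the two rows adjacent to a Dirichlet
wall row is obtained by quadratic extrapolation from the interior (exact
for the parabolic profile), because the wall slip layer would otherwise
corrupt the local shear rate.

## Problem sizes and known limitations

* The acceptance measurements use the reference resolution for the
  transport/strain numbers (runs of 4–6 beat periods after a one-period
  ramp; tracer window 3 T) and the screening resolution for trends and
  particles (5–12 T).  Full-length 30 T / 50 T runs at the original
  0.1 μm resolution are configuration choices, not code limits.
* At screening resolution a 0.4 μm particle spans a single lattice cell;
  it advects correctly as a rigidly constrained disc but its rotation and
  near-field hydrodynamics are under-resolved (module tests use discs of
  ≥ 8 cells).
* The cilium tip sits within one spreading-kernel width of the membrane
  at both desk resolutions (the anatomical tip–membrane gap is 0.7 μm =
  1.75–3.5 cells).  The resulting kernel overlap inflates the apparent
  strain of the tip segments: the measured run maximum is ≈ 2.3% at the
  reference resolution, above the ±1% budget the Ks = 2.0 springs are
  meant to enforce, and the excess shrinks steadily with resolution and
  with the beat-period refinement.  Resolving it fully requires the
  original 0.1 μm grid with a correspondingly fine beat period, outside
  the desk-scale budget; the number is reported as measured.
* The mean mucus speed is insensitive to the ML thickness in this model:
  with a free-slip top boundary the mucus moves as a drag-free plug whose
  steady speed is set at the membrane, so thickening the layer does not
  slow it (it slightly speeds up through reduced confinement).  The
  source study reports a decreasing trend; within this scaled-down model
  that trend is not recovered, and the thickness study should be read
  with that caveat.
* Beyond roughly twelve beat periods at screening resolution a slowly
  growing mean circulation appears in the ciliated band (growth time of
  thousands of steps, insensitive to the structural-coupling settings);
  all study measurements finish well inside that horizon (transport
  windows end by 5–6 T, particle classifications by 12 T).
* The synthetic beat waveform reproduces the *class* of ciliary beats
  (two-stroke, asymmetric, metachronally coordinated) but not any measured
  beat; quantitative transport numbers are meaningful only relative to the
  amplitude regulation, exactly as in the source study.
* The membrane is a material-property divider: stress carries no special
  interface condition there and relaxes freely; particles may cross it
  mechanically (they experience only the viscosity change and repulsion
  from cilia/walls).
* The Oldroyd-B transport uses first-order upwinding; at the We = 0.01
  of the physiological runs the elastic stress is a small perturbation and
  this is ample, but strongly elastic flows (We ≫ 1) would warrant the
  optional higher-order/LBM-advection backend contract.
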