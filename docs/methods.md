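# Methods

## Physical model

Blood is treated as an incompressible Newtonian fluid (ρ = 1060 kg/m³,
μ = 0.0035 Pa·s — a standard large-artery approximation) driven through a
two-dimensional channel model of the left ventricular outflow tract (LVOT),
a 27 mm bileaflet mechanical valve, the sinus of Valsalva and the ascending
aorta. The study grid crosses three clinical variables:

| variable | values | meaning |
|---|---|---|
| LVOT hydraulic diameter | 27, 25, 23, 21, 19 mm | tunnel subaortic stenosis severity; 19 mm removes ≈50 % of the circular cross-sectional area |
| one-leaflet restriction | 0, 50, 100 % | dysfunction of a single leaflet = 0/25/50 % of total valve area |
| mean cardiac output | 3, 5, 7 L/min | low / normal / high flow at a fixed 70 bpm, systole 0.3 s |

That is 45 cases, 15 per cardiac output. Leaflets are rigid and fixed
within a beat (no opening/closing dynamics, no fluid–structure interaction,
no hinge micro-flow): only the forward systolic flow through an already-open
(or stuck) valve is simulated, which is the regime the Doppler surrogates
probe.

### Geometry

The domain is a straight channel (x streamwise, y cross-stream) rasterized
onto a uniform Cartesian grid as a stair-step solid mask:

* **LVOT tunnel** — width equal to the case's hydraulic diameter from the
  inlet to the valve housing (default 50 mm long). The tunnel *is* the
  subaortic stenosis; for 27 mm there is no narrowing. The inlet therefore
  opens exactly one LVOT diameter.
* **Valve housing** — a 3 mm axial ring with inner width 23 mm (2 mm ring
  depth per side), carrying two 12 mm × 2 mm rigid leaflets pivoted at
  hinges ±5 mm off the centerline, with the pivot 0.4 of the leaflet length
  from its wall-side end. Open position 85° from the valve plane, closed
  25°; a partially restricted leaflet interpolates linearly. The fully
  closed leaflet seals its side against the housing ring, converting the
  three-orifice pattern (one central, two lateral) into two orifices.
* **Sinus** — a smooth half-sine symmetric bulge (default 4 mm deep over
  25 mm).
* **Aorta** — straight 27 mm channel (default 80 mm) to the outlet.

The affected leaflet is the upper (+y) one by convention; a healthy mask is
exactly mirror-symmetric cell-by-cell. Leaflets are rasterized as thick
segments (rectangle envelope, flat caps): a cell is solid iff its center
lies inside the envelope. The default rasterized leaflet thickness (2 mm)
is the thinnest feature the default grids resolve (the validator requires
thickness ≥ 2·spacing). Fluid pockets sealed off from the inlet–outlet
channel (e.g. corners behind a closed leaflet) are solidified so the
pressure problem stays well-posed. Hinge offset, pivot fraction, ring
depth and sinus profile are representative published dimensions for a
27 mm bileaflet prosthesis and are fully configurable; the acceptance
surface does not depend on their exact values.

### Inflow and the 2D ↔ 3D mapping

The systolic inflow is a half-sine pulse: Q(t) = Qpeak·sin(πt/τ) during the
0.3 s systole and zero through diastole, with Qpeak = CO·(T/τ)·(π/2) so the
cycle mean is exactly the prescribed cardiac output (for 5 L/min:
Qpeak ≈ 22.4 L/min ≈ 374 cm³/s). Cardiac output is a 3D-equivalent volume
rate; it is mapped to the 2D model through the circular LVOT cross-section:
the inlet carries a plug (uniform) velocity U = Q/(πD²/4) across the tunnel
opening, and the 2D simulation transports that velocity scale. EOA uses
the 3D-equivalent peak systolic flow, which keeps the healthy-valve EOA at
its clinical ≈2.7–3 cm² scale; using the cycle-mean flow instead would
shrink every EOA by the systolic duty factor and put even healthy valves
in the "dysfunction" range.

At 70 bpm with the 13.5 mm valve radius and the blood properties above,
the standard Womersley number R·sqrt(ω/ν) evaluates to ≈20; peak Reynolds
numbers across the grid span roughly 4·10³–1.4·10⁴.

## Numerical scheme

A Chorin-type fractional-step method on a staggered (MAC) grid:

* **Momentum** — explicit first-order upwind convection and explicit
  diffusion. Tangential no-slip at a wall half a cell from a velocity face
  is imposed with reflected ghost values; wall-coincident normal faces are
  held at zero.
* **Projection** — the pressure Poisson equation is assembled once per
  geometry over the fluid cells (Neumann at walls and the velocity inlet,
  Dirichlet gauge pressure 0 at the outlet) and solved by sparse LU
  factorization. The post-projection discrete divergence is at round-off
  (~10⁻¹²/s), far below the configured tolerance, at every step, and
  cycle-integrated inlet and outlet fluxes agree to machine precision.
  The configuration retains an inner-iteration cap for an iterative
  fallback; the direct solve never uses it.
* **Time stepping** — adaptive sub-steps bounded by the convective CFL
  limit (default 0.8), the explicit-diffusion limit (safety 0.45) and the
  0.5 ms output step; snapshots are sampled every 5 ms. The flow starts
  from rest and runs a configurable number of cycles (default 5); the
  periodicity metric is the relative L2 velocity difference between the
  last two cycles at matching phases, reported as a warning above 5 %,
  never an error.
* **Verification** — steady plane Poiseuille (centerline/mean ratio 1.5,
  achieved to ~0.04 % on a 64-cell channel; error order ≥ 1 under
  refinement) and oscillatory channel flow at Womersley number 5 against
  the exact cosh closed form (RMS profile error ≈0.3 %, limit 5 %). The
  closed form itself is cross-checked against an independent eigenfunction
  series to 10⁻⁸.

### Turbulence closure

An optional standard Wilcox-form k–ω model (α = 5/9, β = 3/40, β* = 9/100,
σ = σ* = 1/2) with ν_t = k/ω, a ten-fold production limiter, inlet k from
5 % turbulent intensity of the instantaneous inlet speed, and the rough-wall
ω asymptote 6ν/(β d²) at d = half a cell in solid-adjacent cells. Negative
k after an explicit update is floored to zero and counted. Under
homogeneous constant shear S the ω equation has a stable fixed point
ω* = S·sqrt(α/β) at which the eddy viscosity per unit turbulent kinetic
energy satisfies ν_t·S/k = sqrt(β/α) (k itself grows exponentially, as
expected for unbounded homogeneous shear); the implementation reproduces
this algebraic production–dissipation balance to better than 1 %. Laminar
mode (the default for the case runs and tests) carries no turbulence state,
and the modelled turbulent shear stress ρ·ν_t·(∂u/∂y + ∂v/∂x) is then
identically zero. Turbulent-stress magnitudes from the k–ω mode are
qualitative: the wall treatment on a stair-step mask and the 2D setting do
not support quantitative Reynolds-stress claims.

## Doppler surrogates

* **Vpeak** — maximum speed over the downstream (sinus + aorta) fluid cells
  across the systolic snapshots of the final cycle.
* **V_LVOT** — maximum speed in an echo-like sample volume: a ±2 mm axial
  band of LVOT cells one diameter upstream of the valve plane.
* **TPGmean** — trapezoidal time average of the simplified Bernoulli
  gradient 4V(t)² (mmHg, V in m/s) over the systolic window of the
  downstream peak-speed trace.
* **DVI** = V_LVOT/Vpeak (unclamped); **EOA** = Qpeak/Vpeak in cm².

Peak detection is deterministic: ties break to the earliest time, then the
lowest cell index, so results are invariant to snapshot ordering.

## Diagnostic accuracy

Each case is flagged against the guideline thresholds with inclusive
comparisons (≥/≤; boundary equality is positive). Ground truth comes from
the prescribed leaflet restriction under two groupings — *mild-to-severe*
(50 % and 100 % positive) and *moderate-to-severe* (100 % only), so the
moderate positives are a subset of the mild ones. Sensitivity and
specificity are exact confusion-matrix fractions; reported tables round to
integer percent while the machine-readable output keeps the exact values.
Per-diameter summaries use the sample (n−1) standard deviation and order
diameters descending.

## Synthetic data

The generator serves two roles. (1) The half-sine waveform stands in for a
measured pulsatile inflow: it matches the mean output, heart rate and
systole duration but not the fine shape of a physiological flow curve (no
diastolic baseline, no dicrotic features); analysis windows are
configurable. (2) `synthetic_jet_field` builds smooth velocity snapshots
whose downstream and LVOT maxima are exactly the prescribed values, so the
Doppler and accuracy stages are testable to 10⁻⁹ without the solver.
Passing those tests demonstrates the metric plumbing is exact; it says
nothing about how well the solver fields approximate real valve flow —
that is what the analytic benchmarks and the qualitative trend checks
cover.

## Problem sizes used by the tests and the acceptance script

The default test/acceptance configuration is a deliberately coarse version
of the study: grid spacing h = 0.9 mm (~5000–7000 fluid cells), two cardiac
cycles with the final cycle analyzed, laminar mode, and a sub-grid of cases
(2 diameters × 2 dysfunction levels × 2–3 cardiac outputs). One
periodicity-focused test runs five cycles. At this scale each case takes a
few seconds and the qualitative physics is stable: three comparable valve
jets for a healthy valve, two orifices with the flux diverted to the
functioning side for a stuck leaflet, Vpeak increasing with stenosis,
dysfunction and flow, DVI and EOA nearly flow-independent (spread well
under 15 %), EOA decreasing with dysfunction and peak vorticity growing
with stenosis severity.

## Known limitations

* 2D, coarse, first-order upwind: simulated Vpeak magnitudes run ~10–20 %
  below the values a body-fitted 3D (or fine 2D) model produces for the
  same conditions; orderings and ratios are robust, absolute magnitudes
  are indicative. At the coarse default resolution the most extreme
  healthy case (19 mm, 7 L/min) can graze the 3 m/s threshold.
* Fixed leaflets: opening/closing transients, leaflet flutter and
  regurgitant (diastolic leakage) flow are out of scope.
* The stair-step mask resolves leaflets of ≥2 cells thickness only; hinge
  micro-gaps and the housing's true profile are not represented.
* The k–ω implementation targets its unit contracts (decay, equilibrium
  balance, boundedness), not quantitative turbulence statistics at
  Re ≈ 10⁴ in 2D.
* Tunnel stenosis only, symmetric about the centerline; discrete
  (membranous) subaortic ridges and dynamic (beat-varying) obstruction are
  not modelled.
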