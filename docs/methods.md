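# Methods

This note documents the models and numerical choices behind `batwake`, what
the synthetic data generator does and does not emulate, and the limits of
what the validation suite demonstrates.

## Coordinates, units, constants

Right-handed SI coordinates shared by all modules: x streamwise (positive
downstream), y spanwise (positive starboard), z up. The measurement plane is
a transverse (y–z) plane, so the vorticity component available from in-plane
derivatives is the streamwise one, ω<sub>x</sub> = ∂w/∂y − ∂v/∂z — the
component that carries the lift signal of trailing vortices. Defaults follow
the acquisition this package targets: frame rate f_L = 640 Hz, air density
ρ = 1.2 kg/m³, in-plane vector pitch 0.0024 m on a ~0.30 × 0.20 m window
(126 × 84 vectors), light sheet 0.10 m behind the animal, g = 9.81 m/s².

## Synthetic wakes (module `synthetic`)

A wake is a list of closed polyline vortex filaments, each with a signed
circulation Γ (right-hand rule along the vertex order) and a Lamb–Oseen core
radius r_c. Induced velocity is the straight-segment Biot–Savart kernel
multiplied by the Lamb–Oseen regularization 1 − exp(−d²/r_c²), d being the
perpendicular distance to the segment's carrier line. This choice gives
closed-form oracles: an infinite straight filament has tangential speed
Γ/(2πr)(1 − e^{−r²/r_c²}) and peak vorticity Γ/(πr_c²); a closed loop has
vertical impulse ρΓA_z on its signed horizontal projected area. Collinear
subdivision of straight legs is a no-op for this kernel, so long legs use
few segments; circles use 128 vertices (area error ~0.04 %).

Advection is rigid translation at the tunnel speed U (frozen flow);
self-induced deformation between shedding and measurement is neglected,
consistent with the short convection time from animal to sheet at the
speeds of interest. Sampling a plane produces frames with optional Gaussian
velocity noise, a fixed count round(f·N) of spurious vectors drawn uniformly
within ±5U (guaranteeing detectability at the default outlier threshold),
and masked holes; one seeded generator makes sequences bit-reproducible.

Scenario presets:

* `single_ring` — one horizontal circular loop (impulse oracle ρΓπR²).
* `trailing_pair` — two long streamwise counter-rotating filaments ±Γ;
  each is closed by a return leg 1.5 m outside the window so Kelvin's
  theorem holds while the window sees an ideal lifting pair (momentary
  force oracle ρUΓb).
* `cruise_wingbeat` — per-wingbeat tip + root loop pairs: a lift-carrying
  tip loop (span 0.22 m) with a weaker counter-rotating root loop
  (span 0.06 m, 30 % of tip circulation) inside it, one pair per wingbeat
  cell of streamwise length U/f_wb, with margin cells so the plane always
  sits inside a wake train. When Γ is not given it is tuned so the wake
  impulse per wingbeat equals m·g·T exactly — full weight support by
  construction, making percent recovery a parameter-recovery test.
* `reversed_loop` — a small loop of negative circulation (upwash inside)
  above a normal-sense start-vortex loop: the configuration shed at the
  upstroke/downstroke transition, giving momentary negative weight support
  when it crosses the plane.

The study species' actual circulations and core radii are not published;
the defaults (Γ ≈ 0.1–0.5 m²/s, r_c = 8–20 mm, 11 Hz wingbeat, 9 g mass,
flight speeds 1–5 m/s) are plausible magnitudes for a small bat, chosen
once and not fitted to anything downstream.

What the generator does **not** emulate: leading-edge vortices, wake
self-deformation and instabilities, turbulence, correlated PIV noise,
peak-locking, or out-of-plane loss-of-pairs. Passing tests therefore show
the *estimators* are correct and robust to idealized measurement defects,
not that real recordings meet these assumptions.

## Vector validation and repair (module `preprocess`)

Detection is a single-pass normalized median test on the 3×3 neighborhood
(center excluded, valid neighbors only, minimum 3): a vector is rejected
when any component satisfies |value − median| > k·(1.4826·MAD + ε), with
MAD the median absolute deviation of the neighbors about their median and
ε a frame-global noise floor (the median of the local scales). Default
k = 2. The MAD (rather than an rms) keeps the local scale finite under
clustered outliers, and the scale factor 1.4826 makes it estimate the noise
sd consistently; together they hold false rejections of clean Gaussian
vectors below 1 % while gross outliers (several U against noise of ~0.01 U)
remain trivially detectable — measured on seeded frames: recall 100 %,
false positives ≤ 0.5 %. With a raw neighborhood rms and no floor the same
multiplier rejects ~5 % of clean vectors, which is why the robust scale was
chosen.

Repair replaces flagged vectors by the median of their valid neighbors;
masked holes (and flagged cells with < 3 valid neighbors) are filled by
Delaunay-linear interpolation from valid data, nearest-neighbor outside the
hull. Unflagged vectors pass through bit-exact. Frames under 50 % valid are
refused — the sequence should be discarded, not patched.

## Pseudo-3D reconstruction (module `reconstruct`)

Frames stack at out-of-plane spacing U/f_L, earliest frame farthest
downstream, so the frozen-flow identity ∂/∂x = −(1/U)∂/∂t holds on the
grid (a flip flag reverses the axis for flight-direction visualization).
Resampling to an isotropic 0.0024 m grid uses separable not-a-knot cubic
splines along each axis (exact for cubic polynomials, including near the
boundary). Smoothing is a 5×5×5 sampled Gaussian, σ = 0.65 voxels
(the conventional default of the smoothing routine this mirrors; exposed in
config), normalized to unit sum, nearest-edge replication at boundaries.
The stack is a pseudo-volume — three-component planes, not an instantaneous
volume — and is used for visualization and structure analysis only.

## Differential quantities (module `fields`)

All derivatives are second-order central differences (one-sided at edges),
matching the resolution of PIV data; Q = ½(‖Ω‖² − ‖S‖²) is computed as
−½ tr(A²). Closed-form checks: solid-body rotation at rate Ω gives
ω_x = 2Ω and Q = Ω² to machine precision (linear fields are exact under
central differences); pure shear gives Q = 0; the Lamb–Oseen peak vorticity
is recovered within 0.5 % at 10 cells per core radius.

## Weight support (module `forces`)

The momentary vertical force crossing the plane is
F = 2ρU Σ_{y>y₀} ω_x·(y−y₀)·dy·dz: the spanwise first moment of streamwise
vorticity over one semi-span, doubled (the window covers more than half the
span but not all of it; an option integrates both semi-planes without
doubling). Multiplying each frame's F by 1/f_L and summing is identical to
the per-voxel impulse formulation — the streamwise voxel depth is U/f_L —
and dividing a wingbeat's impulse by its duration gives the mean force;
percent weight support is 100·F̄/(m g). Momentary forces are computed on
raw repaired frames rather than the smoothed volume, avoiding smoothing
bias in the moment integral (configurable by passing volume-derived frames
instead).

The body symmetry plane y₀ is found automatically by minimizing a
normalized antisymmetry mismatch of ω_x (its value is 0 for a perfectly
mirror-antisymmetric wake, ~1 for uncorrelated halves), with a manual
override honored verbatim; a boundary minimum raises an error instead of
returning a spurious plane. Wingbeat intervals come from the first
significant autocorrelation peak of the force series (parabolic sub-frame
refinement), with boundaries anchored at the steepest rising edge of the
period-folded force profile; user intervals always win. The acceptance
filter keeps sequences with 80 % ≤ support ≤ 120 %, boundaries inclusive
(the inclusive choice is a convention; it is configurable).

Validation: a transported ring recovers its analytic impulse within 0.1 %
at the default grid; the tuned cruise wake reads 98–102 % support across
ten noise seeds, so the ±20 % filter keeps 10/10.

## Vortex structures (module `structures`)

Structures are 26-connected components of {Q > threshold}, components below
8 voxels discarded as noise, labels ordered by size. Default thresholds
2500 s⁻² (wake overview) and 2000 s⁻² (body-wake detail) are absolute
values in SI units and configurable, since Q magnitudes depend on smoothing
and grid conventions. Circulation is integrated over the dominant
cross-section: the slice, normal to the coordinate axis best aligned with
the voxel cloud's principal direction, holding the most member voxels; the
integration disk is padded to 3× the footprint's equivalent radius because
vortex cores extend below any Q threshold (a Lamb–Oseen core thresholded
at Q = 2500 contains well under 100 % of Γ). Well-separated synthetic
filaments recover Γ within 0.2 %; the 5 % test tolerance leaves room for
core overlap in denser wakes. Induced-flow sense (upwash/downwash) is the
sign of the mean vertical velocity over member voxels. The color-axis limit
for vertical-speed maps is mean(|w|) + 3·sd(w) over the volume.

Structure counting per interval is centroid-in-slab; no tracking, splitting
or merging across slabs is attempted — counts, not identities, are the
deliverable.

## Problem sizes and determinism

Default validation sizes: 126 × 84 vectors per frame, sequences of 30–116
frames, volumes up to ~300 × 126 × 84 voxels after resampling; the full
test suite runs in about two minutes and the acceptance script in under
two minutes on one CPU. For the multi-wingbeat benchmark, Biot–Savart
segments farther than 0.6 m from the plane are culled during sampling; far
segments induce only a smooth quasi-uniform field whose in-plane
derivatives are negligible, so vorticity-derived quantities are unaffected
(the option defaults off, and the exactness test samples without it).
Every stochastic path takes an explicit seed; identical seeds give
bit-identical sequences.

## Known limitations

* The Trefftz-type estimator assumes the wake's lift-carrying vorticity
  crosses the imaged window; vortices shed outside it (or dissipated below
  noise) bias support low — which is exactly what the ±20 % filter screens.
* Frozen-flow stacking misrepresents strongly deforming or slowly
  convecting wakes (low U, strong self-induction).
* The automatic body-center and wingbeat segmentation assume a roughly
  bilaterally symmetric, periodic wake; maneuvering flight needs manual
  values.
* Q-threshold structure counts depend on threshold and smoothing; they are
  reproducible given a configuration but are not an absolute taxonomy of
  the wake.
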