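# Methods

This note records the models, conventions and design choices behind
platelight, and what its synthetic-data tests do and do not demonstrate.

## Plate geometry

All supported formats sit on the ANSI/SLAS footprint (127.76 × 85.48 mm).
The 96-well (8×12, 9.0 mm pitch) and 384-well (16×24, 4.5 mm pitch)
constants are the SLAS standard values; 24-well (4×6, 19.3 mm) and 12-well
(3×4, 26.01 mm) pitches are vendor-typical, with A1 offsets centering the
grid on the footprint. The constants table is validated at construction:
twice the A1 offset plus the grid span must match the footprint within
2 mm on each axis.

Well-to-machine mapping is translation plus per-axis sign only
(`PlateCalibration`): the stage is assumed leveled and the plate nest
square to the axes, so rotation is not modeled. Which corner the stage
homes to varies between builds, hence both axis signs are free.
Coordinates are computed in full precision and printed to 3 decimals; the
motion hardware class being modeled positions to 0.1 mm, which is the
tolerance used when checking replayed motion.

## Dosimetry

The beam is a uniform ("top-hat") disc: the only beam datum such rigs
measure routinely is a diameter, and power densities are quoted as
power/area. Gaussian profiles, lens NA and thermal drift are out of scope.
Units follow photodynamic-therapy convention: irradiance *E* in mW cm⁻²,
dose *H* = *E·t*/1000 in J cm⁻².

Calibration tables are strictly tabulated, piecewise-linear, and never
extrapolated — the quantity being set is the light dose delivered to a
sample, so an out-of-range request fails loudly rather than guessing. The
shipped example tables (current → 10–1200 mW, beam 10 mm at 10 mm below
the lens growing to 24 mm at the far position, attenuator 1–100%
transmittance) span the ranges typical of this hardware class; they are
synthetic fixtures, not measurements of any specific device.

Step resolution accepts exactly one consistent specification of
(*E*, *H*, *t*) — irradiance plus time or dose, or power plus time — and
returns a state satisfying *H* = *E·t*/1000 and *E* = *P*/*A*
simultaneously to 1e-9 relative; over- or under-specified targets are
errors. When an attenuator is configured, coarse power is set by drive
current (smallest calibrated knot at or above the requirement) and
fine-tuned multiplicatively by transmittance; without one, current is
found by inverse interpolation directly.

The iris rule matches the aperture to min(beam diameter, well opening),
clamped to the 1.9–36.0 mm hardware range, and flags possible
neighbor-spill whenever the beam is wider than the well pitch — relevant
because unilluminated neighbors serve as on-plate dark controls.

## Protocol engine and device simulator

Exposure timing is embedded in the emitted G-code as a `G4` dwell rather
than a host-side sleep, so a plan's timing is part of the deterministic
program text and can be verified by replay. Laser gating uses the spindle
convention of engraver firmware (`M3 S…`/`M5`); the `S` word carries the
commanded output power in mW. How a given build wires its laser enable is
not inferable from the hardware class, so the gating dialect is isolated
in one function.

Ordering policies: `as-given`, `serpentine` (row-major boustrophedon, the
default — near-minimal travel for rectangular selections without a
solver), and `nearest-neighbor` (greedy from the machine origin, with a
fallback to the given order if greedy happens to be longer, so the policy
is never worse than not using it). Dose accounting is commanded-value:
the modeled hardware is open-loop with no photodiode feedback, so a
completed step's delivered dose equals its commanded dose by definition,
and anything else is recorded as error/aborted. The temperature setpoint
is protocol metadata only; plate heating is controlled by a separate
instrument.

The simulator implements exactly the command subset the engine emits
(G21, G90, G0/G1, G4, M3/M5, `?` status) with in-band `ok`/`error:N`
responses, instantaneous motion, scripted fault injection by command
ordinal, and an optional response latency for exercising host timeouts.
It is a test double, not a firmware clone: `$`-settings, jogging and
acceleration planning are out of scope.

## Release analysis

CR% is computed per reading from per-group controls and left unclamped;
out-of-range values set a flag so that bad controls remain visible in
output rather than being silently truncated. F₀ comes from cold controls
at the matching timepoint (pooling all of a group's cold controls when a
timepoint has none of its own); whether background should be per-timepoint
or per-plate is an assay-design ambiguity, and the per-matching-time
choice is recorded in the curve metadata by construction. Dark-control
wells are summarized into their own curves (dose 0) and never mixed into
illuminated ones.

The saturation model CR(*H*) = CR_max·(1 − e^(−k·H)) is a convenience
summary of screen output, not a mechanistic claim. When one formulation is
measured at several irradiances, its points are pooled into a single curve
in dose before fitting (`pool_curves`): in a dose-driven model CR depends
on *H* alone, and pooling is what identifies the plateau when a
low-irradiance series never reaches it — a 100 mW cm⁻² series capped at
25 J cm⁻² constrains CR_max poorly on its own.

## Singlet-oxygen quantum yield

The relative slope method compares integrated 1220–1350 nm emission
(trapezoidal integration with interpolated window edges) regressed on
absorbance at the excitation wavelength. Slopes are ordinary least squares
**with intercept** by default, because scattering and detector background
produce offsets in real series; a through-origin mode is available when
background is known to be zero. Matching of excitation wavelength and
detector gain between sample and reference is asserted by experiment
metadata, not enforced spectroscopically. Uncertainty on
Φ = Φ_ref·S_s/S_ref is first-order propagation of the two slope standard
errors; Φ > 1 is reported as computed with a warning flag.

With four-point series (the realistic design) the intercept-included slope
standard error has only two residual degrees of freedom, so a ±2·se
interval undercovers relative to its Gaussian nominal (the t₂ quantile
effect). The se-calibration property test therefore uses an eight-point
series at the same 2% noise, where coverage of ±2·se is ≥ 90%; the
four-point default is tested for accuracy of the estimate itself (mean
recovery well within 2% over 200 replicates).

## Synthetic data

The release generator emulates the design of a photorelease screen: two
compounds at three loadings, two irradiances (450 and 100 mW cm⁻²),
timepoints from 5 to 300 s, triplicate samples, and per-timepoint cold,
Triton and shielded dark-control wells, each (formulation, irradiance)
group on its own virtual 96-well plate. Truth is first-order in dose;
release ceilings default to 0.9 for oxygenated presets and 0.2 for
oxygen-depleted ones (photorelease screens of this type see most of the
cargo released aerobically and a 10–20% residual band anaerobically), with
a fast (k = 0.5 per J cm⁻²) and a slow (k = 0.02) compound spanning the
saturating and non-saturating regimes. Noise is additive Gaussian with sd
equal to 2% of the F₁₀₀−F₀ dynamic range — plate-reader noise at these
signal levels is approximately constant-variance — and identical seeds
give byte-identical files.

The quantum-yield generator draws series whose noise-free slopes give the
requested true Φ exactly; intensity noise is additive Gaussian at 2% of
the series' top intensity by default.

What the generators deliberately do **not** model: fluorescence
inner-filter and self-quenching nonlinearity, heteroscedastic or drifting
plate-reader noise, liposome physics (pore formation, lipid-oxidation
chemistry), evaporation, well-to-well optical crosstalk, and DLS traces.
Passing recovery tests therefore demonstrates correctness of the analysis
arithmetic and estimator calibration under the stated noise model, not
robustness to these real-data effects.

## Problem sizes and statistical checks

The recovery check runs 100 generator seeds of the full default screen
(12 formulation×irradiance groups, 432 wells each) and asks that at least
95% of pooled kinetic fits land within 3 fitted standard errors of truth.
The threshold is a coverage criterion, not an all-pass one, by design:
even a perfectly calibrated estimator lands outside ±3·se about 0.3% of
the time, so demanding every one of ~600 fits inside would fail a correct
implementation with appreciable probability; ≥ 95% against a 99.7%
nominal leaves headroom for the mild small-sample behavior of nonlinear
fit standard errors. Quantum-yield recovery averages 200 seeded
replicates. Motion correctness replays 1,000 random protocols (400 in the
acceptance script) across all four plate formats and all three ordering
policies, requiring the simulator to accept every emitted line and the
final position to match the last planned well center within 0.1 mm.
Round-trip identities (dose↔time, irradiance↔power) are checked to 1e-9
relative on thousands of random positive inputs, and the OLS slope is
checked against an independent normal-equations solve at 1e-10 relative
on 1,000 random series.

## Known limitations

- No real serial transport is bundled; `execute()` takes any object with
  the `send(line) → response` channel contract, and users wrap their own
  port.
- Only the GRBL command subset the engine emits is simulated.
- The kinetic fit assumes homoscedastic errors on mean CR points; weighted
  fits are not implemented.
- Calibration tables are 1-D; cross-dependencies (e.g. beam diameter
  changing with iris setting) are not modeled — the iris is treated as a
  hard aperture applied after the beam table.
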