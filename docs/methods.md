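# Methods

## Model and geometry

Forces are modelled in the sphere–plate Derjaguin geometry: a silica colloid
probe of radius r = 5 µm (default) against a flat coated substrate, both
carrying the sample of interest. The separation D is surface-to-surface in
nm; repulsion is positive. The net interaction is classical DLVO:

* electrostatic double layer (EDL): `F_EDL = κ r Z exp(−κD)`, valid in the
  weak-overlap superposition regime (D ≳ 1/κ), with
  `κ = sqrt(2F²c₀/(εε₀RT))` and `Z = 64π εε₀ (RT/F)² tanh²(Fψ_δ/4RT)`;
* unretarded van der Waals (VDW): `F_VDW = −A_H r/(6D²)`.

Assumptions worth keeping in mind: 1:1 electrolyte, constant-potential
surfaces treated through the effective Stern potential ψ_δ, no retardation
screening of A_H, and no short-range non-DLVO forces (hydration, steric,
bridging). Short-range deviations are deliberately excluded by the tail
policy rather than modelled.

The Hamaker constant can also be computed from dielectric data via the
standard two-term Lifshitz expression (zero-frequency dielectric term plus a
dispersion term over visible refractive indices, UV absorption frequency
ν_e = 3×10¹⁵ Hz by default). The printed-form ambiguity of this formula in
parts of the literature is resolved by requiring the symmetric-media
reduction `A = (3/4)kT[(ε₁−ε₃)/(ε₁+ε₃)]² +
(3hν_e/16√2)(n₁²−n₃²)²/(n₁²+n₃²)^{3/2}` to hold exactly, which the test
suite asserts. Note that this textbook two-term evaluation with generic
cellulose constants (ε ≈ 6, n ≈ 1.56) gives ≈1.4×10⁻²⁰ J, a factor ~4 above
the full-spectrum literature value 3.6×10⁻²¹ J used as the fitting default —
the expected gap between the simple formula (no electrolyte screening of the
zero-frequency term, single UV relaxation) and a proper spectral
calculation; the package therefore treats the literature value as the
operative A_H and the calculator as an order-of-magnitude tool.

## Fitting procedure

Per curve: select the approach (extend) trace, zero the baseline against the
farthest 20 % of distances, and select the large-distance tail. The tail
starts at `d_min = 2/κ_init` (κ_init from a coarse two-point log-slope
estimate) and keeps the contiguous run of points with force above
`min_force = 1×10⁻² nN`; both are configurable. The default `min_force` is
about five times a typical instrument force noise sd (2×10⁻³ nN), which keeps
the log transform's small-signal bias negligible.

The fit itself regresses ln F on D (OLS via statsmodels); κ = −slope,
Z = exp(intercept)/(κr). One refinement: because A_H is known and fixed (it
is never a free parameter), the VDW term is added back before taking the
log — `ln(F + A_H r/6D²)` is *exactly* affine in D under the forward model,
so noiseless curves are recovered to machine precision regardless of where
the tail window sits. With `hamaker=0` the code reduces to the classical
neglect-VDW tail fit; the difference matters only where the EDL tail has
decayed to within an order of magnitude of the VDW term. Standard errors
come from the OLS covariance (delta method for Z). The fixed-κ re-fit
estimates only the intercept of `ln F + κD`, so κ is reproduced exactly and
cross-sample Z comparisons are not confounded by per-curve κ scatter.

The limit distance — the separation where the force profile goes flat — is
operationalized as the largest D with |dF/dD| equal to a slope threshold,
default 1.8×10⁻³ nN/nm. The threshold is a reporting convention, not
physics, and is exposed in the config; the default reproduces the reference
pair series' reported limit distances within their error bands. Analytic
mode solves the criterion on the fitted profile by bracketed root-finding
(geometric scan for the outermost crossing, then Brent); empirical mode
applies a Savitzky–Golay slope (window 11, order 2) to the measured curve
and scans outward-in. Degenerate cases (Z = 0, threshold out of range) raise
with the searched interval named.

Replicate aggregation reports arithmetic mean ± sample sd (ddof = 1) per
pair label; sd rather than sem is the default because the spread across
substrate locations, not the mean's precision, is the quantity of interest
for particle-spacing arguments.

## Adsorption, phase separation, rheology

Sauerbrey mass uses Δm = −C·mean(Δf)/ν over a user-chosen equilibrium
window, C = 17.7 ng/(cm²·Hz) for a 5 MHz crystal. This is a rigid-film
relation; viscoelastic (dissipation-based) corrections are out of scope. The
specific-adsorption conversion divides by the coating areal mass; the
default 7.77 µg/cm² is *inferred* (back-solved from a published 676 ng/cm² →
87 mg/g conversion pair) and should be overridden whenever the sensor
loading is known.

Critical concentrations are read off the anisotropic-fraction series with
tolerance tol = 0.02 (appearance and completeness are judged by eye in
practice, so exact 0/1 thresholds would be brittle): C_a is the lowest
tested concentration with fraction > tol, C_i the lowest with fraction ≥
1 − tol, each reported as a one-sided bound when the transition is not
bracketed by the tested grid.

Gel classification requires G′ > G″ at every sampled frequency; otherwise
the state is liquid-like and the G′/G″ crossover frequency is interpolated
log-log. The steady-shear classifier segments log viscosity vs log rate into
three continuous linear pieces (grid search over breakpoints, least
squares); slopes (steep, shallow, steep) with the middle above −0.2 and the
outer pieces below −0.4 read as the liquid-crystal three-region signature.
The slope cuts are operational definitions of "very weak thinning" vs
"shear thinning" and are configurable. Both classifiers are invariant to
vertical scaling, as they must be. The kinetic-arrest flag is the boolean
composition: gelation concentration ≤ C_a means the network freezes before
chiral ordering, predicting a colorless film.

## Synthetic data

Generators emulate the instruments so the whole pipeline runs without
downloads; all are deterministic per (spec, seed) via numpy Generator
streams, with suite-level child seeds spawned from one master seed.

* Force curves: forward DLVO plus a single-exponential contact artifact
  (amplitude 0.5 nN, decay 5 nm) standing in for the unmodelled short-range
  steric/adhesion contribution, plus additive Gaussian noise (sd 2×10⁻³ nN);
  200 points over a 2–200 nm ramp, matching a typical colloid-probe
  acquisition. The default campaign is 100 repeats at 10 locations per pair
  for the seven reference pairs shipped in `data/reference_pairs.tsv`.
* QCM traces: baseline, exponential adsorption transient (τ = 150 s), rinse
  step releasing a set fraction, final plateau whose Sauerbrey mass is the
  requested value; Δf noise sd 0.2 Hz.
* Phase series: fraction 0 below C_a, a 0.05 onset band at C_a ramping
  linearly to 1 at C_i, clipped Gaussian noise. The onset band models the
  thin first anisotropic layer that makes C_a visible on a coarse grid.
* Rheology: parametric power-law moduli/viscosity with the named qualitative
  structure (gel, crossover, three-region, Newtonian-then-thinning, simple
  power law) and 1 % lognormal jitter.

What the generators do **not** emulate: instrument drift and hysteresis,
cantilever hydrodynamic drag, vendor raw formats, tactoid kinetics, and any
coupling between the strands (e.g. adsorption actually changing ζ). Passing
tests therefore demonstrate that the estimators are correct and robust under
the stated noise models, not that they are proof against every artifact of
real instruments.

## Problem sizes and numerical choices

Default analyses run in seconds: per-curve fits are closed-form OLS on ≤200
points; the Monte-Carlo bias checks use 100 replicates per pair (seeded,
master seed 20230415); the classifier round-trips use 100 seeded trials; the
optics property sweep uses 10⁴ points. Root-finding tolerances are
xtol = 1e-10 nm; read/write round-trips hold to 1e-9 relative (floats are
written with 12 significant digits); duplicate distances are averaged on
load and curves re-sorted ascending.

## Known limitations

* Constant-charge vs constant-potential boundary corrections and retarded
  VDW are not implemented; at high κD or small D the model is nominal.
* The log-linear estimator is consistent but not efficient under additive
  force noise (noise becomes heteroscedastic after the log); bias at the
  default settings is ≪1 % for κ, but a weighted or nonlinear refinement
  would be the next step if sub-percent Z accuracy mattered.
* The limit distance depends on an arbitrary slope threshold; only
  comparisons at a fixed threshold are meaningful.
* The stacking relation P = (360/α)·d applied at molecular-scale α and d
  gives a molecular-scale pitch estimate (~195 nm for α = 7°, d = 3.8 nm),
  which underestimates film-scale pitch; it is a mechanism diagnostic, not a
  quantitative pitch predictor, and the package treats it as such.
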