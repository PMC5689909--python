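# Methods

## Model overview

The simulator is one-dimensional and deterministic.  Its observable is
the dose rate at a point of water-equivalent depth *w* as a function of
time over one rotation of a range modulation wheel.  While wheel step
*k* (water-equivalent pull-back *p_k*, dwell fraction *τ_k*, beam
current factor *b_k*) is in the beam, the instantaneous dose rate is

D′(w, t) = b_k · D(w; R − p_k),

where D(·; R) is the pristine Bragg curve of range R.  Profiles are
binned every 0.25 ms over the 100 ms period; the bin straddling a step
boundary takes the time-weighted mix.  Integrating the profile over a
cycle reproduces the static SOBP dose Σ_k τ_k b_k D(w; R − p_k) exactly
(a conserved quantity used as a cross-check in the tests).

## Pristine Bragg curve

Depth dose follows the Bortfeld-style analytic form: the
continuous-slowing-down term (R₀ − z)^(1/p−1) with p = 1.77,
α = 0.0022 cm·MeV⁻ᵖ, a fluence-reduction/buildup term with
β = 0.012 cm⁻¹, γ = 0.6 and a low-energy contamination fraction
ε = 0.1, convolved with a Gaussian of width σ.  Near the peak
(−20 ≤ ζ ≤ 10, ζ = (z − R₀)/σ) the convolution is evaluated in closed
form with parabolic cylinder functions; deeper in the plateau the
unconvolved form is used (the convolution is an identity there to
better than 10⁻⁴) and beyond ζ > 10 the dose is exactly zero.  The
implementation was validated against brute-force numerical convolution
of the power-law term.

Peaks are parametrized by their clinical range (distal depth at 90% of
the peak maximum); the internal R₀ is solved by fixed-point iteration so
the realized distal-90% depth matches the requested range to 2·10⁻⁵ cm.

**Range-spread width σ.**  Default σ = 2.0% of the range.  This is the
*total* width of the delivered peak: range straggling in water
(≈1.1–1.2% of range) combined in quadrature with the range width
contributed by the energy spread of the incident beam and scattering in
the modulation hardware.  The choice matters because the wheel has 24
equally spaced steps: with a substantially narrower peak
(σ ≲ 1.5% of range) no non-negative weighting of 24 peaks can keep the
summed plateau ripple at the clinical ±2% level, while 2.0% yields
≤1% ripple for all three study beams.  σ is configurable per peak.

**Pull-backs preserve σ.**  A pulled-back layer traverses the same
total material (wheel step plus water), so its accumulated straggling
matches the unmodulated beam; `shifted_peak` therefore reduces the
range and carries σ over unchanged.

## Wheel design

Step pull-backs are equally spaced over [0, M] (M = modulation width);
dwell fractions are solved by non-negative least squares against a flat
unit target on a 0.01 cm grid.  The flat-target grid spans from just
below the shallowest layer's peak position up to the deepest layer's
peak position: both extreme layers' Bragg peaks must be inside the
constrained region, otherwise the least-squares solution raises an
uncontrolled horn just outside it.  Flatness is then *checked* on the
conventional plateau window [R − M + 0.5 cm, R − 0.5 cm]; the solve
fails loudly, naming the achieved ripple, if it exceeds 2%.

Because the clinical landmarks — range = distal 90% of maximum,
modulation = proximal 98% to distal 90% — are emergent properties of
the summed curve, the designer iterates its internal range and span
targets (up to four passes) until the realized landmarks match the
prescription; the realized accuracy is ≲0.1 mm in range and ≲1 mm in
modulation width for the three study beams.  BCM refinement is a second
non-negative least-squares pass over the same objective expressed as
multiplicative per-step corrections; for a beam whose dwell solution is
already optimal it returns unit factors, and it never worsens the
max-deviation flatness metric (it falls back to the unrefined beam if
the candidate does).

Steps are laid out in time in order of increasing pull-back with the
full-range step starting at t = 0, making the dose burst seen by a deep
detector contiguous at the start of the cycle.  The physical wheel
interleaves repeated tracks per revolution; one effective track per
100 ms period is modeled.  Beam-spot transit across step boundaries is
instantaneous, and scoring is at a point rather than a finite voxel.

## Phantoms and WEPL

Absorbers are homogeneous slab stacks (thickness, relative stopping
power) or 1-D voxel lines of CT numbers.  CT numbers convert to
relative stopping power through a piecewise-linear calibration with
nodes (−1000, 0.001), (0, 1.0), (100, 1.10), clamped at the ends — a
soft-tissue slope of 0.001 RSP/HU, so a 20 HU shift maps to 0.02 RSP.
WEPL is the line integral of RSP from the entrance surface with partial
voxels pro-rated linearly; the inverse map is exact on
piecewise-constant RSP.  The synthetic "patient CT" stand-in is a voxel
line of Gaussian HU (mean 40, σ 20, 1 mm voxels) with no air cavities.

Because scoring depends on depth only through WEPL, a constant-HU-0
voxel line is *exactly* equivalent to a unit-RSP slab (mirroring a
plastic versus CT-of-plastic comparison), and HU noise perturbs only
the depth → WEPL map, not the σ_rms(WEPL) relation itself.  Real
lateral heterogeneity (range mixing) is outside this 1-D model — see
Limitations.

## Synthetic diode sessions

Each diode trace is a nearest-bin upsampling of the profile at 100 kHz
over 19 consecutive cycles.  Noise model (all parameters configurable):

- multiplicative Gaussian, CV 2% per sample (gain/counting noise);
- additive Gaussian floor, σ = 0.5% of the trace maximum
  (preamp/digitizer baseline), with the result clipped at zero as in a
  unipolar digitizer;
- per-cycle Gaussian trigger jitter, σ = 0.1 ms.

Values were chosen as plausible for a diode + preamplifier + digitizer
chain; they are not fitted to any measured data.  Randomness is
reproducible: per-trace streams are spawned from the session seed keyed
by (diode index, depth index).  The measurement depth schedule mimics a
physical session: 30 depths across the calibration region with ~2 mm
increments near the distal end and coarser spacing proximally.

## σ_rms statistics

Profiles are treated as point-mass weight distributions over their
bin-center (or sample) times: σ_rms is the weighted standard deviation,
skewness and excess kurtosis the standardized third and fourth moments
(normal = 0).  All are invariant under amplitude scaling, so absolute
detector response never enters.  A single-occupied-bin signal is
reported as degenerate with σ_rms = 0.  Note that with the point-mass
convention a uniform signal over n bins has
σ_rms = (T/√12)·√(1 − 1/n²), i.e. the continuous closed form up to a
~3·10⁻⁶ discrete-grid correction at n = 400.

Measured cycles are preprocessed before the moments are taken:

1. samples are averaged into 0.25 ms bins; bins below 2% of the cycle
   maximum are declared empty (suppressing the rectified noise floor,
   which otherwise biases σ_rms upward by ~1 ms);
2. the cycle is circularly re-anchored at the end of the longest empty
   gap, so trigger jitter cannot wrap a sliver of the dose burst across
   the cycle boundary (which would corrupt σ_rms by milliseconds).

On noise-free, jitter-free signals whose support starts at the trigger
this is an exact no-op; the residual systematic on noisy sessions is
≤0.025 ms (≲0.05 mm of WEPL).  Noise-free calibration profiles use the
plain linear convention directly.

## Calibration fit and inversion

The calibration window runs from 2 cm inside the proximal edge of the
plateau (proximal-98% point of the cycle-integrated dose) to 2 cm
inside the depth of maximum dose, extended where necessary so it always
contains the expected detector region (prescribed range − 1 cm
± 0.5 cm); in practice the upper edge is range − 0.5 cm.  A degree-4
polynomial is fitted by least squares to σ_rms versus WEPL on this
window (≥6 points required so the adjusted R² = 1 − (1−R²)(n−1)/(n−5)
has a residual degree of freedom), and rejected if not strictly
monotone there.  Inversion brackets the unique root with brentq
(tolerance 10⁻⁴ cm), allowing up to 0.3 cm of monotone extrapolation at
each window edge so an observation at exactly the boundary does not
fail on the fit's edge residual; standard errors propagate by the
first-order delta method.  Deviation reports give mean, SD and max of
the *absolute* estimate−truth difference in millimetres.

The fit is oriented σ_rms(WEPL), as the physics dictates
(monotone-decreasing width with depth), with numerical inversion rather
than fitting WEPL(σ_rms) directly.

## Range-mixing flag

Dose arriving over paths of different WEPLs (lateral heterogeneity)
distorts the cycle-profile shape beyond what its width implies.  The
flag compares observed skewness and excess kurtosis against the
reference-scan values interpolated at the WEPL inferred from σ_rms,
scored in units of the local variability of the reference moments over
±0.25 cm (floored at 0.01); a score above 3 — or a degenerate or
out-of-range profile — raises the flag.  A 50/50 mixture of profiles
1 cm apart near the distal end scores far above threshold; the flag is
screening-quality only and no quantitative unmixing is attempted.

## Numerical choices

- Depth grids: 0.01 cm scoring/fitting increment; time bins 0.25 ms;
  sampling 100 kHz (25 samples per bin).
- NNLS (scipy) for weights and BCM: deterministic, non-negative by
  construction; exactly-zero-weight steps are dropped from the wheel.
- Quartic fitted in the plain power basis (well-conditioned in float64
  for WEPL ≤ 21 cm); coefficients are stored ascending (c₀…c₄).
- All randomness flows from explicit integer seeds through
  numpy SeedSequence spawning; fixed seeds give byte-identical outputs.

## Problem sizes

Default study conditions are the full stated geometry: 12 diodes × 19
cycles × 100 kHz, 0.01 cm calibration scans (600–1800 profiles per
beam), 30-depth sessions, and five seeds for the stochastic recovery
checks.  The acceptance script simulates 45 noisy single-depth sessions
(three beams × five seeds × three depths near the range) in about half
a minute on one CPU.

## Limitations

- No particle transport: nuclear halo, secondary particles, scatter
  tails, lateral profiles and energy spectra are absent; the pristine
  curve is an analytic idealization normalized per layer.
- 1-D only: range mixing can be *flagged* on synthetic mixtures but not
  simulated from genuinely heterogeneous geometry, and the CT stand-in
  is a noise model, not anatomy. Passing tests demonstrate internal
  consistency of the simulate → calibrate → infer loop under the stated
  noise model, not agreement with measured beam data.
- The noise model omits diode energy dependence, amplifier dynamics and
  digitizer quantization.
- The wheel is one effective track with equally spaced pull-backs; real
  wheel-track geometry (interleaved tracks, gating for intermediate
  modulations) is not modeled.
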