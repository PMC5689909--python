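# rmwcal

Time-resolved scout-beam simulation and water-equivalent path length
(WEPL) calibration for passively scattered proton therapy range
verification.

## The problem

In passively scattered proton delivery, a rotating range modulation
wheel (RMW) time-multiplexes pristine Bragg peaks of successively
pulled-back ranges to synthesize a spread-out Bragg peak (SOBP).
Because the wheel rotates at a fixed period (100 ms here), the dose rate
at a point inside the SOBP varies over one wheel cycle in a way that is
unique to that point's depth: a detector deep in the plateau receives
dose only while the thinnest wheel steps are in the beam, a shallow
detector receives dose through most of the cycle.  A small silicon
diode implanted or placed in the patient therefore encodes its own WEPL
in the *shape* of its signal versus time — not in its amplitude.

The practical procedure uses a low-dose (4 cGy) "scout" SOBP whose range
deliberately overshoots the predicted detector WEPL by 1 cm so the
detector sits on the plateau.  The per-cycle dose-rate distribution is
reduced to its rms temporal width σ_rms, which decreases strictly
monotonically with WEPL across the plateau; a fourth-order polynomial
fit

σ_rms(w) = c₀ + c₁ w + c₂ w² + c₃ w³ + c₄ w⁴

is the continuous calibration curve, and its numerical inversion maps a
measured mean σ_rms (over 12 diodes × 19 wheel cycles, sampled at
100 kHz) to a WEPL estimate.  This package implements the whole chain as
a deterministic desk-scale simulator plus a synthetic measurement
generator, for three clinically representative scout beams
(range/modulation 10/9.9, 15/14 and 21/18 cm):

- analytic pristine Bragg peaks (Bortfeld-style power-law + Gaussian
  range-spread form, parametrized by the clinical distal-90% range);
- wheel-step dwell weights solved by non-negative least squares for a
  ±2% flat plateau, with beam-current-modulation (BCM) refinement;
- dose-rate profiles per wheel cycle every 0.25 ms on a 0.01 cm depth
  grid, through homogeneous slab phantoms or 1-D CT-number voxel lines
  (piecewise-linear HU → relative stopping power conversion);
- synthetic diode voltage traces with multiplicative, additive-floor
  and trigger-jitter noise;
- σ_rms / skewness / kurtosis statistics, window selection, quartic
  fitting with adjusted R², inversion with delta-method standard
  errors, deviation reports, and a skewness/kurtosis-based flag for
  range-mixed signals.

## Worked example

```python
import rmwcal as rc

# scout beam for a detector predicted at 9 cm WEPL: range 10, mod 9.9
beam = rc.refine_bcm(rc.design_scout_beam(9.0, 9.9, nominal_energy_mev=168.0))
curve = rc.sobp_depth_dose(beam)
print(f"plateau flatness: {100*rc.plateau_flatness(beam):.2f}%")
print(f"distal-90% range: {rc.distal_range(curve):.3f} cm")
print(f"modulation width (98%->90%): {rc.modulation_width(curve):.3f} cm")

water = rc.water_phantom(40.0)
scan, window, cal = rc.calibrate_beam(beam, water)
print(f"calibration window: [{window[0]:.2f}, {window[1]:.2f}] cm WEPL")
print(f"adjusted R^2: {cal.adjusted_r2:.5f}")

res = rc.recover_wepls(beam, water, cal, [9.0, 9.25, 9.5],
                       noise=rc.NoiseModel(), seed=1)
print(res[["true_wepl_cm", "sigma_ms", "est_wepl_cm", "error_mm"]])
```

prints

```
plateau flatness: 0.70%
distal-90% range: 9.999 cm
modulation width (98%->90%): 9.999 cm
calibration window: [2.10, 9.50] cm WEPL
adjusted R^2: 0.99998
 true_wepl_cm  sigma_ms  est_wepl_cm  error_mm
         9.00   14.6787       9.0045    0.0447
         9.25   13.5869       9.2407   -0.0929
         9.50   12.1573       9.5254    0.2543
```

The SOBP lands within a fraction of a millimetre of the prescribed
10 cm range and 9.9 cm modulation with a plateau flat to 0.7%.  The
quartic calibration explains the noiseless σ_rms(WEPL) relation to
adjusted R² ≈ 1, and inverting noisy synthetic sessions (12 diodes × 19
cycles) recovers the detector WEPL to within ~0.3 mm in the region
within 1 cm of the beam range where the detector is expected to lie.

A CLI mirrors the workflow: `rmwcal design-beam`, `scan`,
`simulate-session`, `calibrate`, `infer`, `report` and `demo`
(see `rmwcal --help`).

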