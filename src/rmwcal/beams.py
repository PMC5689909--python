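"""Scout SOBP construction: wheel geometry, step weights, BCM refinement.

A scout beam is a low-dose spread-out Bragg peak (SOBP) whose range
deliberately overshoots the predicted detector WEPL by 1 cm, so that the
detector sits on the flat plateau.  The SOBP is synthesized by a range
modulation wheel: an ordered set of absorber steps, each pulling the
pristine peak back by a fixed water-equivalent thickness and occupying a
fraction of the 100 ms rotation period (the dwell fraction).  Dwell
fractions are solved by non-negative least squares so the summed depth
dose is flat to within a tolerance over the plateau; a beam-current
modulation (BCM) factor per step can refine the flatness further.

Clinical range and modulation conventions: range is the depth of the
distal 90%-of-maximum point; modulation width is the distance from the
proximal 98% point to the distal 90% point.  Because these landmarks are
emergent properties of the summed curve, the designer iterates the
internal range and pull-back span targets until the realized landmarks
match the prescription.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import nnls

from .bragg import DepthDoseCurve, PristinePeak, distal_range, shifted_peak

__all__ = [
    "WheelStep",
    "ModulatorWheel",
    "ScoutBeam",
    "design_scout_beam",
    "solve_step_weights",
    "sobp_depth_dose",
    "modulation_width",
    "proximal_edge",
    "plateau_flatness",
    "refine_bcm",
]

DEFAULT_N_STEPS = 24
PLATEAU_MARGIN_CM = 0.5
FLATNESS_TOL = 0.02
DEPTH_GRID_CM = 0.01


@dataclass(frozen=True)
class WheelStep:
    index: int
    pullback_cm: float
    dwell_fraction: float
    bcm_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.pullback_cm < 0:
            raise ValueError("pullback_cm must be >= 0")
        if not (0.0 < self.dwell_fraction <= 1.0):
            raise ValueError("dwell_fraction must be in (0, 1]")
        if self.bcm_factor < 0:
            raise ValueError("bcm_factor must be >= 0")


@dataclass
class ModulatorWheel:
    """Ordered wheel steps covering one rotation period.

    Steps are laid out in time in order of increasing pull-back, with the
    zero-pull-back (full-range) step starting at t = 0 of the cycle, so
    the dose burst seen by a deep detector is contiguous at cycle start.
    """

    steps: list[WheelStep]
    period_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.period_ms <= 0:
            raise ValueError("period_ms must be positive")
        if not self.steps:
            raise ValueError("wheel needs at least one step")
        total = sum(s.dwell_fraction for s in self.steps)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"dwell fractions must sum to 1, got {total!r}")
        pulls = [s.pullback_cm for s in self.steps]
        if len(pulls) > 1 and not all(b > a for a, b in zip(pulls, pulls[1:])):
            raise ValueError("pullback_cm must be strictly increasing with index")

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def pullbacks_cm(self) -> np.ndarray:
        return np.array([s.pullback_cm for s in self.steps])

    @property
    def dwell_fractions(self) -> np.ndarray:
        return np.array([s.dwell_fraction for s in self.steps])

    @property
    def bcm_factors(self) -> np.ndarray:
        return np.array([s.bcm_factor for s in self.steps])

    def step_boundaries_ms(self) -> np.ndarray:
        """Cumulative time boundaries of the steps, length n_steps + 1."""
        return np.concatenate([[0.0], np.cumsum(self.dwell_fractions)]) * self.period_ms


@dataclass
class ScoutBeam:
    """A scout SOBP: prescription plus the wheel that realizes it."""

    prescribed_range_cm: float
    modulation_cm: float
    wheel: ModulatorWheel
    base_peak: PristinePeak
    nominal_energy_mev: float | None = None  # metadata label only
    dose_rate_gy_per_min: float = 2.0
    scout_dose_cgy: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 < self.modulation_cm <= self.prescribed_range_cm):
            raise ValueError("require 0 < modulation_cm <= prescribed_range_cm")

    @property
    def beam_id(self) -> str:
        return f"R{self.prescribed_range_cm:g}M{self.modulation_cm:g}"

    @property
    def step_peaks(self) -> list[PristinePeak]:
        if not hasattr(self, "_step_peaks"):
            self._step_peaks = [
                self.base_peak if s.pullback_cm == 0.0
                else shifted_peak(self.base_peak, s.pullback_cm)
                for s in self.wheel.steps
            ]
        return self._step_peaks

    def step_doses(self, z) -> np.ndarray:
        """Per-step relative dose at depth(s) z: shape (n_steps, len(z))."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        return np.vstack([pk.dose(z) for pk in self.step_peaks])

    def plateau_window_cm(self, margin_cm: float = PLATEAU_MARGIN_CM) -> tuple[float, float]:
        lo = self.prescribed_range_cm - self.modulation_cm + margin_cm
        hi = self.prescribed_range_cm - margin_cm
        return lo, hi

    def to_json(self, path) -> None:
        payload = {
            "prescribed_range_cm": self.prescribed_range_cm,
            "modulation_cm": self.modulation_cm,
            "nominal_energy_mev": self.nominal_energy_mev,
            "dose_rate_gy_per_min": self.dose_rate_gy_per_min,
            "scout_dose_cgy": self.scout_dose_cgy,
            "base_peak": {
                "range_cm": self.base_peak.range_cm,
                "straggling_sigma_cm": self.base_peak.straggling_sigma_cm,
            },
            "wheel": {
                "period_ms": self.wheel.period_ms,
                "steps": [
                    {
                        "index": s.index,
                        "pullback_cm": s.pullback_cm,
                        "dwell_fraction": s.dwell_fraction,
                        "bcm_factor": s.bcm_factor,
                    }
                    for s in self.wheel.steps
                ],
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ScoutBeam":
        with open(path) as fh:
            d = json.load(fh)
        wheel = ModulatorWheel(
            steps=[WheelStep(**s) for s in d["wheel"]["steps"]],
            period_ms=d["wheel"]["period_ms"],
        )
        return cls(
            prescribed_range_cm=d["prescribed_range_cm"],
            modulation_cm=d["modulation_cm"],
            wheel=wheel,
            base_peak=PristinePeak(**d["base_peak"]),
            nominal_energy_mev=d.get("nominal_energy_mev"),
            dose_rate_gy_per_min=d.get("dose_rate_gy_per_min", 2.0),
            scout_dose_cgy=d.get("scout_dose_cgy", 4.0),
        )


def _fit_window(base: PristinePeak, span_cm: float) -> tuple[float, float]:
    """Flat-target grid bounds for the weight solve.

    Both extreme layers' Bragg-peak positions must lie inside the
    flat-target grid: leaving either outside lets the least-squares
    solution raise an uncontrolled horn there.  The grid therefore runs
    from just below the shallowest layer's peak (its maximum sits about
    one straggling width proximal of the plateau edge) up to the deepest
    layer's peak position.
    """
    sigma = base.straggling_sigma_cm
    lo = max(base.range_cm - span_cm - max(0.25, 1.5 * sigma), 0.02)
    return lo, base.depth_of_max_cm


def _weights_for(
    base_peak: PristinePeak,
    pullbacks: np.ndarray,
    window: tuple[float, float],
    grid_cm: float,
) -> np.ndarray:
    """Non-negative least-squares dwell weights for a flat plateau."""
    lo, hi = window
    zg = np.arange(lo, hi + 1e-9, grid_cm)
    peaks = [
        base_peak if pb == 0.0 else shifted_peak(base_peak, pb) for pb in pullbacks
    ]
    a = np.column_stack([pk.dose(zg) for pk in peaks])
    w, _ = nnls(a, np.ones(zg.size))
    if w.sum() <= 0:
        raise RuntimeError("weight solve produced all-zero weights")
    return w / w.sum()


def solve_step_weights(
    range_cm: float,
    modulation_cm: float,
    n_steps: int = DEFAULT_N_STEPS,
    *,
    straggling_sigma_cm: float | None = None,
    plateau_margin_cm: float = PLATEAU_MARGIN_CM,
    flatness_tol: float = FLATNESS_TOL,
    grid_cm: float = DEPTH_GRID_CM,
) -> ModulatorWheel:
    """Build a wheel whose summed SOBP is flat over the plateau.

    Step pull-backs are equally spaced in [0, modulation_cm]; dwell
    fractions are solved by NNLS against a flat target on the plateau
    window (``plateau_margin_cm`` inside each edge).  Raises if the
    achieved flatness exceeds ``flatness_tol``.
    """
    if n_steps == 1:
        return ModulatorWheel(steps=[WheelStep(0, 0.0, 1.0)])
    if n_steps < 5:
        raise ValueError("n_steps must be 1 (degenerate) or >= 5")
    if not (0.0 < modulation_cm < range_cm):
        raise ValueError("require 0 < modulation_cm < range_cm")
    base = PristinePeak(range_cm, straggling_sigma_cm)
    pulls = np.linspace(0.0, modulation_cm, n_steps)
    window = (range_cm - modulation_cm + plateau_margin_cm, range_cm - plateau_margin_cm)
    if window[0] >= window[1]:
        raise ValueError("plateau window is empty; modulation too small")
    w = _weights_for(base, pulls, _fit_window(base, modulation_cm), grid_cm)
    keep = w > 0
    # NNLS may zero out a step entirely; dwell fractions must be positive,
    # so zero-weight steps are dropped from the wheel.
    steps = [
        WheelStep(index=i, pullback_cm=float(pb), dwell_fraction=float(wk))
        for i, (pb, wk) in enumerate(zip(pulls[keep], w[keep]))
    ]
    wheel = ModulatorWheel(steps=steps)
    flat = _flatness_of(base, wheel, window, grid_cm)
    if flat > flatness_tol:
        raise RuntimeError(
            f"flatness infeasible with {n_steps} steps: achieved "
            f"{flat:.3%} > {flatness_tol:.1%}"
        )
    return wheel


def _flatness_of(
    base: PristinePeak,
    wheel: ModulatorWheel,
    window: tuple[float, float],
    grid_cm: float = DEPTH_GRID_CM,
) -> float:
    zg = np.arange(window[0], window[1] + 1e-9, grid_cm)
    peaks = [
        base if s.pullback_cm == 0.0 else shifted_peak(base, s.pullback_cm)
        for s in wheel.steps
    ]
    a = np.column_stack([pk.dose(zg) for pk in peaks])
    d = a @ (wheel.dwell_fractions * wheel.bcm_factors)
    return float(np.abs(d / d.mean() - 1.0).max())


def sobp_depth_dose(
    beam: ScoutBeam,
    depths=None,
    *,
    normalize: bool = True,
    grid_cm: float = DEPTH_GRID_CM,
) -> DepthDoseCurve:
    """Summed SOBP depth dose, Σ_k dwell_k · bcm_k · dose_k(z).

    With ``normalize=True`` the curve is scaled so the plateau mean is 1;
    otherwise raw pristine-peak units (peak max of each layer = 1).
    """
    if depths is None:
        depths = np.arange(0.0, beam.prescribed_range_cm + 1.5 + 1e-9, grid_cm)
    depths = np.atleast_1d(np.asarray(depths, dtype=float))
    weights = beam.wheel.dwell_fractions * beam.wheel.bcm_factors
    doses = weights @ beam.step_doses(depths)
    if normalize:
        lo, hi = beam.plateau_window_cm()
        sel = (depths >= lo) & (depths <= hi)
        if sel.any():
            ref = doses[sel].mean()
        else:  # curve evaluated away from the plateau; normalize globally
            ref = doses.max()
        doses = doses / ref
    return DepthDoseCurve(depths, doses)


def proximal_edge(curve: DepthDoseCurve, fraction: float = 0.98) -> float:
    """Shallowest depth reaching ``fraction`` of the curve maximum.

    Located on the proximal rising edge by linear interpolation.  If the
    curve already starts at/above the level, the first grid depth is
    returned.
    """
    z, d = curve.depths_cm, curve.doses
    level = fraction * d.max()
    above = np.nonzero(d >= level)[0]
    if above.size == 0:
        raise ValueError("curve never reaches the proximal level")
    k = above[0]
    if k == 0:
        return float(z[0])
    z1, z2, d1, d2 = z[k - 1], z[k], d[k - 1], d[k]
    return float(z1 + (level - d1) * (z2 - z1) / (d2 - d1))


def modulation_width(curve: DepthDoseCurve) -> float:
    """Modulation width: proximal-98% depth to distal-90% depth (cm)."""
    d90 = distal_range(curve, 0.90)
    p98 = proximal_edge(curve, 0.98)
    if p98 >= d90:
        raise ValueError("modulation exceeds range: no proximal 98% crossing")
    return d90 - p98


def plateau_flatness(beam: ScoutBeam, margin_cm: float = PLATEAU_MARGIN_CM) -> float:
    """Max relative deviation from the plateau mean, |dose/mean - 1|."""
    window = beam.plateau_window_cm(margin_cm)
    return _flatness_of(beam.base_peak, beam.wheel, window)


def design_scout_beam(
    predicted_detector_wepl_cm: float,
    modulation_cm: float,
    n_steps: int = DEFAULT_N_STEPS,
    *,
    overshoot_cm: float = 1.0,
    nominal_energy_mev: float | None = None,
    straggling_sigma_cm: float | None = None,
    range_tol_cm: float = 0.05,
    modulation_tol_cm: float = 0.1,
    max_iter: int = 4,
) -> ScoutBeam:
    """Design a scout beam overshooting the predicted detector WEPL by 1 cm.

    The internal range and pull-back span targets are iterated (up to
    ``max_iter`` passes) until the realized distal-90% range and
    98%-to-90% modulation width of the summed SOBP match the prescription
    within tolerance; the span is capped so the most pulled-back layer
    keeps a positive residual range.
    """
    if predicted_detector_wepl_cm <= 0:
        raise ValueError("predicted_detector_wepl_cm must be positive")
    prescribed = predicted_detector_wepl_cm + overshoot_cm
    if not (0.0 < modulation_cm <= prescribed):
        raise ValueError(
            f"modulation {modulation_cm} cm exceeds resulting range {prescribed} cm"
        )

    range_target = prescribed
    span_target = min(modulation_cm, prescribed - 0.1)
    beam = None
    for _ in range(max_iter):
        wheel = solve_step_weights(
            range_target,
            span_target,
            n_steps,
            straggling_sigma_cm=straggling_sigma_cm,
        )
        base = PristinePeak(range_target, straggling_sigma_cm)
        beam = ScoutBeam(
            prescribed_range_cm=prescribed,
            modulation_cm=modulation_cm,
            wheel=wheel,
            base_peak=base,
            nominal_energy_mev=nominal_energy_mev,
        )
        curve = sobp_depth_dose(beam)
        d90 = distal_range(curve, 0.90)
        mw = modulation_width(curve)
        dr = prescribed - d90
        dm = modulation_cm - mw
        if abs(dr) <= range_tol_cm and abs(dm) <= modulation_tol_cm:
            break
        range_target += dr
        span_target = float(np.clip(span_target + dm, 0.5, range_target - 0.1))
    return beam


def refine_bcm(beam: ScoutBeam, grid_cm: float = DEPTH_GRID_CM) -> ScoutBeam:
    """Refine per-step beam-current factors to minimize plateau deviation.

    A second non-negative least-squares pass solves for effective step
    weights; the BCM factor is the multiplicative correction relative to
    the dwell fractions (which are fixed by the wheel geometry).  The fit
    window is the one implied by the wheel itself (base-peak range and
    pull-back span), i.e. the same objective the dwell solve used, so a
    beam whose dwell fractions are already optimal gets unit factors.  If
    the candidate correction does not improve the max-deviation flatness
    metric, the beam is returned unchanged.
    """
    span = float(beam.wheel.pullbacks_cm.max())
    window = _fit_window(beam.base_peak, span)
    pulls = beam.wheel.pullbacks_cm
    v = _weights_for(beam.base_peak, pulls, window, grid_cm)
    dwell = beam.wheel.dwell_fractions
    bcm = np.where(dwell > 0, v / dwell, 0.0)
    # normalize so total beam weight is preserved
    bcm = bcm / (dwell @ bcm)
    candidate_steps = [
        replace(s, bcm_factor=float(b)) for s, b in zip(beam.wheel.steps, bcm)
    ]
    candidate = replace(
        beam, wheel=ModulatorWheel(steps=candidate_steps, period_ms=beam.wheel.period_ms)
    )
    if plateau_flatness(candidate) <= plateau_flatness(beam):
        return candidate
    return replace(beam)
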