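"""Time-resolved dose-rate scoring over one modulator-wheel cycle.

The central simulated observable: the dose rate at a scoring point as a
function of time over one 100 ms wheel rotation, binned every 0.25 ms.
While a wheel step is in the beam, the instantaneous dose rate at a point
of water-equivalent depth ``w`` is proportional to
``bcm_k * pristine_dose(w, peak_k)``; the profile is therefore piecewise
constant per step, with the bin straddling a step boundary taking the
time-weighted mix.  Scoring is noise-free and deterministic —
measurement-like stochasticity belongs to the synthetic diode generator.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beams import ScoutBeam
from .phantoms import Phantom, wepl_at

__all__ = [
    "DoseRateProfile",
    "CalibrationScan",
    "step_bin_matrix",
    "score_profile",
    "scan_depths",
]

DEFAULT_BIN_WIDTH_MS = 0.25


@dataclass
class DoseRateProfile:
    """Dose rate per time bin over one wheel period at a given WEPL."""

    bin_width_ms: float
    dose_rate: np.ndarray  # arbitrary units, one value per time bin
    wepl_cm: float
    beam_id: str = ""
    period_ms: float = 100.0

    def __post_init__(self) -> None:
        self.dose_rate = np.asarray(self.dose_rate, dtype=float)
        n = self.dose_rate.size
        if abs(n * self.bin_width_ms - self.period_ms) > 1e-9:
            raise ValueError("n_bins * bin_width_ms must equal period_ms")
        if (self.dose_rate < 0).any():
            raise ValueError("dose rate must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.dose_rate.size

    @property
    def times_ms(self) -> np.ndarray:
        """Bin-center times."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ms

    def integral(self) -> float:
        """Time-integrated dose over one cycle (rate × bin width summed)."""
        return float(self.dose_rate.sum() * self.bin_width_ms)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# wepl_cm={self.wepl_cm} beam_id={self.beam_id} "
                     f"bin_width_ms={self.bin_width_ms}\n")
            fh.write("time_ms,dose_rate\n")
            for t, r in zip(self.times_ms, self.dose_rate):
                fh.write(f"{t},{r}\n")


def step_bin_matrix(
    wheel, bin_width_ms: float = DEFAULT_BIN_WIDTH_MS
) -> np.ndarray:
    """Fraction of each time bin occupied by each wheel step.

    Shape (n_bins, n_steps); row sums are 1.  Steps occupy contiguous
    spans of the cycle in wheel order starting at t = 0.
    """
    period = wheel.period_ms
    n_bins = int(round(period / bin_width_ms))
    if abs(n_bins * bin_width_ms - period) > 1e-9:
        raise ValueError("bin_width_ms must divide the wheel period")
    bounds = wheel.step_boundaries_ms()
    edges = np.arange(n_bins + 1) * bin_width_ms
    lo = np.maximum(edges[:-1, None], bounds[None, :-1])
    hi = np.minimum(edges[1:, None], bounds[None, 1:])
    return np.clip(hi - lo, 0.0, None) / bin_width_ms


def score_profile(
    beam: ScoutBeam,
    phantom: Phantom,
    geometric_depth_cm: float,
    bin_width_ms: float = DEFAULT_BIN_WIDTH_MS,
) -> DoseRateProfile:
    """Dose-rate profile per wheel cycle at a point in the phantom."""
    w = wepl_at(phantom, geometric_depth_cm)  # raises beyond phantom
    m = step_bin_matrix(beam.wheel, bin_width_ms)
    dose = beam.step_doses(w)[:, 0]
    rate = m @ (beam.wheel.bcm_factors * dose)
    return DoseRateProfile(
        bin_width_ms=bin_width_ms,
        dose_rate=rate,
        wepl_cm=float(w),
        beam_id=beam.beam_id,
        period_ms=beam.wheel.period_ms,
    )


@dataclass
class CalibrationScan:
    """Dose-rate profiles on a dense depth grid through the plateau."""

    depth_grid_cm: np.ndarray
    wepl_grid_cm: np.ndarray
    rates: np.ndarray  # shape (n_depths, n_bins)
    bin_width_ms: float
    beam_id: str = ""
    period_ms: float = 100.0

    def __post_init__(self) -> None:
        self.depth_grid_cm = np.asarray(self.depth_grid_cm, dtype=float)
        self.wepl_grid_cm = np.asarray(self.wepl_grid_cm, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if not (np.diff(self.depth_grid_cm) > 0).all():
            raise ValueError("depth grid must be strictly increasing")
        if self.rates.shape[0] != self.depth_grid_cm.size:
            raise ValueError("one profile row per depth required")

    def __len__(self) -> int:
        return self.depth_grid_cm.size

    @property
    def times_ms(self) -> np.ndarray:
        return (np.arange(self.rates.shape[1]) + 0.5) * self.bin_width_ms

    def profile(self, i: int) -> DoseRateProfile:
        return DoseRateProfile(
            bin_width_ms=self.bin_width_ms,
            dose_rate=self.rates[i],
            wepl_cm=float(self.wepl_grid_cm[i]),
            beam_id=self.beam_id,
            period_ms=self.period_ms,
        )

    @property
    def profiles(self) -> list[DoseRateProfile]:
        return [self.profile(i) for i in range(len(self))]

    def integrated_dose(self) -> np.ndarray:
        """Per-depth cycle-integrated dose (equals static SOBP × period)."""
        return self.rates.sum(axis=1) * self.bin_width_ms

    def to_csv(self, path) -> None:
        """Wide CSV: one column per depth, one row per time bin."""
        with open(path, "w") as fh:
            fh.write(f"# beam_id={self.beam_id} bin_width_ms={self.bin_width_ms}\n")
            fh.write("time_ms," + ",".join(f"{d:g}" for d in self.depth_grid_cm) + "\n")
            for i, t in enumerate(self.times_ms):
                fh.write(f"{t}," + ",".join(f"{r:.9g}" for r in self.rates[:, i]) + "\n")


def scan_depths(
    beam: ScoutBeam,
    phantom: Phantom,
    depth_window: tuple[float, float],
    spacing_cm: float = 0.01,
    bin_width_ms: float = DEFAULT_BIN_WIDTH_MS,
) -> CalibrationScan:
    """Score profiles on a regular geometric-depth grid.

    The grid runs from ``depth_window[0]`` to ``depth_window[1]``
    inclusive (within floating tolerance) in steps of ``spacing_cm``.
    """
    lo, hi = depth_window
    if hi < lo:
        raise ValueError("empty depth window")
    depths = np.arange(lo, hi + spacing_cm * 0.5, spacing_cm)
    if depths.size == 0:
        raise ValueError("empty depth window")
    wepls = np.atleast_1d(wepl_at(phantom, depths))
    m = step_bin_matrix(beam.wheel, bin_width_ms)
    dose = beam.step_doses(wepls)  # (n_steps, n_depths)
    rates = (m @ (beam.wheel.bcm_factors[:, None] * dose)).T
    return CalibrationScan(
        depth_grid_cm=depths,
        wepl_grid_cm=wepls,
        rates=rates,
        bin_width_ms=bin_width_ms,
        beam_id=beam.beam_id,
        period_ms=beam.wheel.period_ms,
    )
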