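"""Synthetic diode measurement generator.

Emulates the acquisition chain of a time-resolved diode dosimetry
session: each diode's voltage is sampled at 100 kHz over 19 consecutive
wheel cycles, with the signal proportional to the dose rate at the
diode's depth.  The proportionality constant is arbitrary — all
downstream statistics are amplitude-invariant — so voltages are emitted
in dose-rate units.

The noise model is deliberately simple: multiplicative Gaussian noise per
sample (electronics gain fluctuations and counting noise), an additive
Gaussian floor scaled to the trace maximum (preamp/digitizer baseline),
and a per-cycle Gaussian trigger jitter (uncertainty of the wheel-phase
trigger derived from the beam-current monitor).  Voltages are clipped at
zero, as a unipolar digitizer would.

All randomness is reproducible: sub-streams are spawned from the session
seed keyed by (diode index, depth index), so any single trace can be
regenerated bit-exactly in isolation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beams import ScoutBeam
from .phantoms import Phantom, wepl_at
from .scoring import DoseRateProfile, score_profile

__all__ = [
    "NoiseModel",
    "DiodeTrace",
    "MeasurementSession",
    "synthesize_trace",
    "generate_session",
    "depth_schedule",
]

DEFAULT_SAMPLE_RATE_HZ = 100_000
DEFAULT_N_CYCLES = 19
DEFAULT_N_DIODES = 12


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise description.

    relative_sigma: multiplicative Gaussian coefficient of variation.
    floor_sigma: additive Gaussian sigma as a fraction of the trace max.
    trigger_jitter_ms: per-cycle Gaussian sigma of the trigger phase.
    """

    relative_sigma: float = 0.02
    floor_sigma: float = 0.005
    trigger_jitter_ms: float = 0.1

    def __post_init__(self) -> None:
        if min(self.relative_sigma, self.floor_sigma, self.trigger_jitter_ms) < 0:
            raise ValueError("noise parameters must be non-negative")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(relative_sigma=0.0, floor_sigma=0.0, trigger_jitter_ms=0.0)


@dataclass
class DiodeTrace:
    """Sampled voltage signal of one diode over consecutive wheel cycles."""

    sample_rate_hz: float
    n_cycles: int
    voltages: np.ndarray
    diode_id: int
    true_wepl_cm: float
    seed: int
    period_ms: float = 100.0

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        expected = self.n_cycles * self.samples_per_cycle
        if self.voltages.size != expected:
            raise ValueError(
                f"trace length {self.voltages.size} != n_cycles x period x rate "
                f"= {expected}"
            )
        if (self.voltages < 0).any():
            raise ValueError("voltages must be non-negative")

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.period_ms / 1000.0 * self.sample_rate_hz))

    @property
    def sample_times_ms(self) -> np.ndarray:
        """Within-cycle sample times (one cycle)."""
        return np.arange(self.samples_per_cycle) * (1000.0 / self.sample_rate_hz)

    def cycles(self) -> np.ndarray:
        """Voltages reshaped to (n_cycles, samples_per_cycle)."""
        return self.voltages.reshape(self.n_cycles, self.samples_per_cycle)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# diode_id={self.diode_id} true_wepl_cm={self.true_wepl_cm} "
                f"sample_rate_hz={self.sample_rate_hz} n_cycles={self.n_cycles}\n"
            )
            fh.write("time_s,voltage\n")
            dt = 1.0 / self.sample_rate_hz
            for i, v in enumerate(self.voltages):
                fh.write(f"{i * dt:.6f},{v:.8g}\n")


def _cycle_matrix(
    profile: DoseRateProfile,
    noise: NoiseModel,
    n_cycles: int,
    sample_rate_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_cycles, samples_per_cycle) noisy realizations of the profile."""
    period = profile.period_ms
    spc = period / 1000.0 * sample_rate_hz
    if abs(spc - round(spc)) > 1e-9:
        raise ValueError(
            "sample_rate incompatible with bin structure: non-integer "
            "samples per cycle"
        )
    spc = int(round(spc))
    t = np.arange(spc) * (1000.0 / sample_rate_hz)
    jitter = (
        rng.normal(0.0, noise.trigger_jitter_ms, n_cycles)
        if noise.trigger_jitter_ms > 0
        else np.zeros(n_cycles)
    )
    phase = (t[None, :] + jitter[:, None]) % period
    idx = np.minimum(
        (phase / profile.bin_width_ms).astype(np.intp), profile.n_bins - 1
    )
    v = profile.dose_rate[idx]
    if noise.relative_sigma > 0:
        v = v * (1.0 + rng.normal(0.0, noise.relative_sigma, v.shape))
    if noise.floor_sigma > 0:
        v = v + rng.normal(0.0, noise.floor_sigma * profile.dose_rate.max(), v.shape)
    return np.clip(v, 0.0, None)


def _trace_rng(seed: int, diode: int, depth_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(diode, depth_index))
    return np.random.default_rng(ss)


def synthesize_trace(
    profile: DoseRateProfile,
    noise: NoiseModel | None = None,
    n_cycles: int = DEFAULT_N_CYCLES,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    seed: int = 0,
    diode_id: int = 0,
    depth_index: int = 0,
) -> DiodeTrace:
    """Sample a diode voltage trace from a dose-rate profile.

    Each cycle is a nearest-bin upsampling of the profile at the sample's
    cycle phase, with independent noise and trigger jitter per cycle.
    Reproducible for a fixed (seed, diode_id, depth_index).
    """
    if noise is None:
        noise = NoiseModel()
    rng = _trace_rng(seed, diode_id, depth_index)
    cycles = _cycle_matrix(profile, noise, n_cycles, sample_rate_hz, rng)
    return DiodeTrace(
        sample_rate_hz=sample_rate_hz,
        n_cycles=n_cycles,
        voltages=cycles.ravel(),
        diode_id=diode_id,
        true_wepl_cm=profile.wepl_cm,
        seed=seed,
        period_ms=profile.period_ms,
    )


@dataclass
class MeasurementSession:
    """All traces of one calibration session: n_diodes × n_depths."""

    traces: list[DiodeTrace]
    depths_cm: np.ndarray
    beam_id: str
    n_diodes: int = DEFAULT_N_DIODES

    def __post_init__(self) -> None:
        self.depths_cm = np.asarray(self.depths_cm, dtype=float)
        if not (np.diff(self.depths_cm) > 0).all():
            raise ValueError("depths must be strictly increasing")
        if len(self.traces) != self.n_diodes * self.depths_cm.size:
            raise ValueError("expected n_diodes x n_depths traces")

    @property
    def n_depths(self) -> int:
        return self.depths_cm.size

    def traces_at(self, depth_index: int) -> list[DiodeTrace]:
        k = self.n_diodes
        return self.traces[depth_index * k : (depth_index + 1) * k]


def generate_session(
    beam: ScoutBeam,
    phantom: Phantom,
    depths_cm,
    noise: NoiseModel | None = None,
    seed: int = 0,
    n_diodes: int = DEFAULT_N_DIODES,
    n_cycles: int = DEFAULT_N_CYCLES,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
) -> MeasurementSession:
    """Simulate a full calibration session at the given geometric depths."""
    depths = np.atleast_1d(np.asarray(depths_cm, dtype=float))
    wepls = np.atleast_1d(wepl_at(phantom, depths))
    if (wepls >= beam.prescribed_range_cm).any():
        raise ValueError("measurement depth beyond the prescribed range")
    traces: list[DiodeTrace] = []
    for pi, depth in enumerate(depths):
        prof = score_profile(beam, phantom, float(depth))
        for di in range(n_diodes):
            traces.append(
                synthesize_trace(
                    prof,
                    noise,
                    n_cycles=n_cycles,
                    sample_rate_hz=sample_rate_hz,
                    seed=seed,
                    diode_id=di,
                    depth_index=pi,
                )
            )
    return MeasurementSession(
        traces=traces, depths_cm=depths, beam_id=beam.beam_id, n_diodes=n_diodes
    )


def depth_schedule(
    beam: ScoutBeam,
    n_depths: int = 30,
    *,
    proximal_margin_cm: float = 2.0,
    distal_offset_cm: float = 0.5,
    fine_span_cm: float = 3.0,
    fine_step_cm: float = 0.2,
) -> np.ndarray:
    """Measurement depth schedule across the plateau (in WEPL of water).

    Mimics a physical session: ~2 mm increments near the distal end of
    the plateau (where the detector is expected), coarser spacing
    proximally, ``n_depths`` points in total inside the calibration
    region.
    """
    r = beam.prescribed_range_cm
    lo = r - beam.modulation_cm + proximal_margin_cm
    hi = r - distal_offset_cm
    if hi <= lo:
        raise ValueError("plateau too short for a measurement schedule")
    fine_lo = max(hi - fine_span_cm, lo)
    fine = np.arange(hi, fine_lo - 1e-9, -fine_step_cm)[::-1]
    n_coarse = max(n_depths - fine.size, 0)
    if n_coarse:
        coarse = np.linspace(lo, fine_lo, n_coarse, endpoint=False)
        sched = np.concatenate([coarse, fine])
    else:
        sched = fine[-n_depths:]
    return np.round(sched, 6)
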