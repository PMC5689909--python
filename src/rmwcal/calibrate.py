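"""WEPL calibration statistics: rms width, quartic fit, inversion.

The physics behind the method: a detector deep in the SOBP plateau is
reached only by the least pulled-back wheel steps, so it sees dose during
a short part of the cycle; a shallow detector sees dose during most of
it.  The rms width of the dose-rate-versus-time distribution over one
cycle is therefore a strictly decreasing function of detector WEPL on
the plateau, and a fourth-order polynomial fit of sigma_rms against WEPL
gives a continuous, invertible calibration curve.

Temporal moments use the point-mass convention: the signal is a weight
distribution over its sample (or bin-center) times; no per-bin width
correction is applied.  All statistics are invariant under scaling of
the signal amplitude, so the absolute detector response never enters.

Measured per-cycle segments are preprocessed before the moments are
taken: samples are averaged into profile-width bins, bins below a small
fraction of the cycle maximum are declared empty (suppressing the
rectified noise floor), and the cycle is circularly re-anchored at the
end of the longest empty gap.  On noise-free, jitter-free signals whose
support starts at the trigger this preprocessing is an exact no-op; with
trigger jitter it prevents a sliver of the dose burst from wrapping
around the cycle boundary and corrupting the width.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .beams import ScoutBeam
from .scoring import CalibrationScan, DoseRateProfile
from .synth import DiodeTrace, MeasurementSession

__all__ = [
    "RmsWidthStat",
    "CalibrationCurve",
    "WeplEstimate",
    "DeviationStats",
    "rms_width",
    "trace_cycle_stats",
    "session_sigma",
    "select_window",
    "fit_calibration",
    "infer_wepl",
    "deviation_stats",
    "range_mixing_flag",
]

BASELINE_THRESHOLD = 0.02  # fraction of cycle max below which a bin is empty


@dataclass(frozen=True)
class RmsWidthStat:
    """Weighted temporal moments of a dose-rate distribution."""

    sigma_rms_ms: float
    skewness: float
    excess_kurtosis: float
    degenerate: bool = False  # single-bin (point mass) signal


@dataclass
class CalibrationCurve:
    """Fourth-order polynomial sigma_rms(WEPL) with validity window."""

    coefficients: np.ndarray  # c0..c4, ascending powers
    wepl_window_cm: tuple[float, float]
    adjusted_r2: float
    residual_sd_ms: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != 5:
            raise ValueError("expected five polynomial coefficients c0..c4")
        lo, hi = self.wepl_window_cm
        if hi <= lo:
            raise ValueError("wepl window must be non-empty")

    def __call__(self, wepl_cm) -> np.ndarray | float:
        return np.polynomial.polynomial.polyval(wepl_cm, self.coefficients)

    def derivative(self, wepl_cm) -> np.ndarray | float:
        dc = np.polynomial.polynomial.polyder(self.coefficients)
        return np.polynomial.polynomial.polyval(wepl_cm, dc)

    def to_json_dict(self) -> dict:
        return {
            "coefficients": list(self.coefficients),
            "wepl_window_cm": list(self.wepl_window_cm),
            "adjusted_r2": self.adjusted_r2,
            "residual_sd_ms": self.residual_sd_ms,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            wepl_window_cm=tuple(d["wepl_window_cm"]),
            adjusted_r2=d["adjusted_r2"],
            residual_sd_ms=d["residual_sd_ms"],
        )


@dataclass(frozen=True)
class WeplEstimate:
    wepl_cm: float
    se_cm: float
    n_obs: int


@dataclass(frozen=True)
class DeviationStats:
    mean_mm: float
    sd_mm: float
    max_mm: float


def _weighted_moments(times: np.ndarray, weights: np.ndarray) -> RmsWidthStat:
    s = weights.sum()
    if s <= 0:
        raise ValueError("no signal: all-zero weights")
    if np.count_nonzero(weights) == 1:
        return RmsWidthStat(0.0, 0.0, 0.0, degenerate=True)
    tbar = (weights * times).sum() / s
    dt = times - tbar
    m2 = (weights * dt**2).sum() / s
    sigma = np.sqrt(m2)
    if sigma == 0.0:
        return RmsWidthStat(0.0, 0.0, 0.0, degenerate=True)
    m3 = (weights * dt**3).sum() / s
    m4 = (weights * dt**4).sum() / s
    return RmsWidthStat(
        sigma_rms_ms=float(sigma),
        skewness=float(m3 / sigma**3),
        excess_kurtosis=float(m4 / sigma**4 - 3.0),
    )


def _gap_cut_index(empty: np.ndarray) -> int | None:
    """Index of the first bin after the longest circular run of empty bins.

    Returns None when no bin is empty (no re-anchoring possible).
    """
    n = empty.size
    if not empty.any():
        return None
    if empty.all():
        return 0
    ext = np.concatenate([empty, empty]).astype(np.int8)
    # run-length encode the doubled mask
    change = np.flatnonzero(np.diff(ext)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [2 * n]])
    best_len, best_end = -1, 0
    for a, b in zip(starts, ends):
        if ext[a] and (b - a) > best_len and b >= n:
            best_len, best_end = b - a, b
    if best_len >= n:
        return 0
    return int(best_end % n)


def _cycle_stat(
    times: np.ndarray,
    volts: np.ndarray,
    period_ms: float,
    bin_width_ms: float,
    threshold: float,
) -> RmsWidthStat:
    """Moments of one measured cycle with gap re-anchoring."""
    nsb = int(round(bin_width_ms / (times[1] - times[0])))
    if nsb < 1 or times.size % nsb:
        nsb = 1
    if nsb > 1:
        bin_means = volts.reshape(-1, nsb).mean(axis=1)
    else:
        bin_means = volts
    empty = bin_means < threshold * bin_means.max()
    cut = _gap_cut_index(empty)
    v = np.where(np.repeat(empty, nsb)[: volts.size], 0.0, volts)
    if cut is None:
        t = times
    else:
        t = (times - cut * bin_width_ms) % period_ms
    return _weighted_moments(t, v)


def rms_width(signal: DoseRateProfile | tuple) -> RmsWidthStat:
    """Rms width (and higher standardized moments) of a dose-rate profile.

    Accepts a DoseRateProfile or a ``(times, weights)`` pair.  Treats the
    signal as a point-mass weight distribution over its times.
    """
    if isinstance(signal, DoseRateProfile):
        return _weighted_moments(signal.times_ms, signal.dose_rate)
    times, weights = signal
    return _weighted_moments(
        np.asarray(times, dtype=float), np.asarray(weights, dtype=float)
    )


def trace_cycle_stats(
    trace: DiodeTrace,
    bin_width_ms: float = 0.25,
    threshold: float = BASELINE_THRESHOLD,
) -> list[RmsWidthStat]:
    """Per-cycle moments of a diode trace (one stat per wheel cycle)."""
    if trace.n_cycles < 1:
        raise ValueError("trace shorter than one cycle")
    t = trace.sample_times_ms
    return [
        _cycle_stat(t, cyc, trace.period_ms, bin_width_ms, threshold)
        for cyc in trace.cycles()
    ]


def session_sigma(
    session: MeasurementSession,
    bin_width_ms: float = 0.25,
    threshold: float = BASELINE_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-depth mean sigma_rms and standard error over diodes × cycles.

    Returns ``(summary, records)``: ``summary`` has one row per depth
    (true_wepl_cm, sigma_ms, se_ms, n_obs); ``records`` has one row per
    (depth, diode, cycle) observation.
    """
    rec: list[tuple] = []
    for pi in range(session.n_depths):
        for tr in session.traces_at(pi):
            for ci, st in enumerate(trace_cycle_stats(tr, bin_width_ms, threshold)):
                rec.append(
                    (pi, float(session.depths_cm[pi]), tr.true_wepl_cm,
                     tr.diode_id, ci, st.sigma_rms_ms, st.skewness,
                     st.excess_kurtosis)
                )
    records = pd.DataFrame(
        rec,
        columns=[
            "depth_index", "depth_cm", "true_wepl_cm", "diode_id", "cycle",
            "sigma_rms_ms", "skewness", "excess_kurtosis",
        ],
    )
    g = records.groupby("depth_index")["sigma_rms_ms"]
    summary = pd.DataFrame(
        {
            "depth_cm": records.groupby("depth_index")["depth_cm"].first(),
            "true_wepl_cm": records.groupby("depth_index")["true_wepl_cm"].first(),
            "sigma_ms": g.mean(),
            "se_ms": g.sem(),
            "n_obs": g.size(),
        }
    )
    return summary, records


def select_window(
    scan: CalibrationScan,
    beam: ScoutBeam,
    inner_margin_cm: float = 2.0,
    detector_margin_cm: float = 0.5,
) -> tuple[float, float]:
    """Calibration WEPL window from the scanned plateau landmarks.

    The lower edge sits ``inner_margin_cm`` inside the proximal edge of
    the plateau (the proximal 98% point); the upper edge sits
    ``inner_margin_cm`` inside the depth of maximum dose, extended if
    necessary so the window always contains the expected detector region
    ``prescribed_range - 1 cm ± detector_margin_cm``.
    """
    dose = scan.integrated_dose()
    wepl = scan.wepl_grid_cm
    i_max = int(dose.argmax())
    level = 0.98 * dose[i_max]
    above = np.nonzero(dose >= level)[0]
    k = above[0]
    if k == 0:
        prox = float(wepl[0])
    else:
        w1, w2, d1, d2 = wepl[k - 1], wepl[k], dose[k - 1], dose[k]
        prox = float(w1 + (level - d1) * (w2 - w1) / (d2 - d1))
    lo = prox + inner_margin_cm
    detector_hi = beam.prescribed_range_cm - 1.0 + detector_margin_cm
    hi = max(float(wepl[i_max]) - inner_margin_cm, detector_hi)
    hi = min(hi, float(wepl[-1]))
    if lo >= hi:
        raise ValueError(
            f"empty calibration window: modulation too small "
            f"(proximal edge {prox:.2f} cm, lo {lo:.2f} >= hi {hi:.2f})"
        )
    return lo, hi


def fit_calibration(
    wepls,
    sigmas,
    window: tuple[float, float] | None = None,
) -> CalibrationCurve:
    """Least-squares degree-4 polynomial fit of sigma_rms versus WEPL.

    Requires at least six points (five coefficients plus one residual
    degree of freedom for the adjusted R²) and a fit that is strictly
    monotone on the window, otherwise the curve would not be invertible.
    """
    w = np.asarray(wepls, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    if window is not None:
        keep = (w >= window[0]) & (w <= window[1])
        w, s = w[keep], s[keep]
    n = w.size
    if n <= 5:
        raise ValueError(f"insufficient dof: need >= 6 points, got {n}")
    coef = np.polynomial.polynomial.polyfit(w, s, 4)
    fitted = np.polynomial.polynomial.polyval(w, coef)
    res = s - fitted
    sse = float((res**2).sum())
    sst = float(((s - s.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 5)
    win = window if window is not None else (float(w.min()), float(w.max()))
    dense = np.linspace(win[0], win[1], 512)
    deriv = np.polynomial.polynomial.polyval(
        dense, np.polynomial.polynomial.polyder(coef)
    )
    if not ((deriv < 0).all() or (deriv > 0).all()):
        raise ValueError("calibration not invertible: fit non-monotone on window")
    return CalibrationCurve(
        coefficients=coef,
        wepl_window_cm=win,
        adjusted_r2=float(adj),
        residual_sd_ms=float(res.std(ddof=0)),
    )


def infer_wepl(
    curve: CalibrationCurve,
    sigma_ms: float,
    se_ms: float = 0.0,
    n_obs: int = 1,
    xtol_cm: float = 1e-4,
    edge_pad_cm: float = 0.3,
) -> WeplEstimate:
    """Invert the calibration polynomial for an observed mean sigma_rms.

    The unique root of sigma(w) = observed is bracketed on the monotone
    window; the standard error is propagated to WEPL by the first-order
    delta method using the polynomial derivative.  Observations falling
    just outside the fitted range (within ``edge_pad_cm`` of monotone
    extrapolation at either window edge) are still inverted, so a
    detector sitting exactly at a window boundary does not fail on the
    fit's edge residual.
    """
    lo, hi = curve.wepl_window_cm
    # extend each edge while the polynomial stays monotone
    for _ in range(6):
        pad = edge_pad_cm / 6.0
        if np.sign(curve.derivative(hi + pad)) == np.sign(curve.derivative(hi)):
            hi += pad
        if np.sign(curve.derivative(lo - pad)) == np.sign(curve.derivative(lo)) and lo - pad > 0:
            lo -= pad
    flo, fhi = float(curve(lo)) - sigma_ms, float(curve(hi)) - sigma_ms
    if flo * fhi > 0:
        raise ValueError(
            f"out of calibration range: sigma {sigma_ms:.3f} ms not attained "
            f"on window [{lo:.2f}, {hi:.2f}] cm"
        )
    w = brentq(lambda x: float(curve(x)) - sigma_ms, lo, hi, xtol=xtol_cm)
    slope = float(curve.derivative(w))
    se_cm = abs(se_ms / slope) if slope != 0 else float("inf")
    return WeplEstimate(wepl_cm=float(w), se_cm=float(se_cm), n_obs=n_obs)


def deviation_stats(estimates, true_wepls) -> DeviationStats:
    """Mean / SD / max of absolute WEPL deviation, in millimetres."""
    est = np.asarray(
        [e.wepl_cm if isinstance(e, WeplEstimate) else e for e in estimates],
        dtype=float,
    )
    tru = np.asarray(true_wepls, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimates and truths must have matching length")
    dev_mm = np.abs(est - tru) * 10.0
    return DeviationStats(
        mean_mm=float(dev_mm.mean()),
        sd_mm=float(dev_mm.std(ddof=0)),
        max_mm=float(dev_mm.max()),
    )


def _reference_moments(scan: CalibrationScan) -> pd.DataFrame:
    stats = [rms_width(scan.profile(i)) for i in range(len(scan))]
    return pd.DataFrame(
        {
            "wepl_cm": scan.wepl_grid_cm,
            "sigma_ms": [s.sigma_rms_ms for s in stats],
            "skewness": [s.skewness for s in stats],
            "excess_kurtosis": [s.excess_kurtosis for s in stats],
        }
    )


def range_mixing_flag(
    stat: RmsWidthStat,
    curve: CalibrationCurve,
    reference_scan: CalibrationScan,
    z_threshold: float = 3.0,
    local_halfwidth_cm: float = 0.25,
    moment_floor: float = 0.01,
) -> tuple[bool, float, str]:
    """Flag a profile whose shape is inconsistent with a single WEPL.

    Range mixing — dose arriving over paths of different WEPLs — distorts
    the cycle profile's shape beyond what its rms width implies.  The
    observed skewness and excess kurtosis are compared against the
    reference scan values at the WEPL inferred from sigma_rms; the score
    is the larger deviation in units of the local variability of the
    reference moments (floored at ``moment_floor``).

    Returns (flagged, score, reason).
    """
    if stat.degenerate:
        return True, float("inf"), "degenerate"
    try:
        est = infer_wepl(curve, stat.sigma_rms_ms)
    except ValueError:
        return True, float("inf"), "out of calibration range"
    ref = _reference_moments(reference_scan)
    w = est.wepl_cm
    near = ref[np.abs(ref["wepl_cm"] - w) <= local_halfwidth_cm]
    if near.empty:
        near = ref.iloc[(ref["wepl_cm"] - w).abs().argsort()[:5]]
    ref_sk = float(np.interp(w, ref["wepl_cm"], ref["skewness"]))
    ref_ku = float(np.interp(w, ref["wepl_cm"], ref["excess_kurtosis"]))
    scale_sk = max(float(near["skewness"].max() - near["skewness"].min()), moment_floor)
    scale_ku = max(
        float(near["excess_kurtosis"].max() - near["excess_kurtosis"].min()),
        moment_floor,
    )
    z_sk = abs(stat.skewness - ref_sk) / scale_sk
    z_ku = abs(stat.excess_kurtosis - ref_ku) / scale_ku
    score = max(z_sk, z_ku)
    if score > z_threshold:
        which = "skewness" if z_sk >= z_ku else "kurtosis"
        return True, float(score), f"{which} deviates from reference"
    return False, float(score), "consistent with reference"
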