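"""Analytical one-dimensional pristine Bragg peak depth-dose model.

A pristine proton depth-dose curve in water is represented by the
Bortfeld-style analytic form: a power-law continuous-slowing-down term
``(R0 - z)^(1/p - 1)`` plus a fluence-reduction term, convolved with a
Gaussian of width ``sigma`` that lumps range straggling and the energy
spread of the incident beam.  Near the peak the convolution has a closed
form in parabolic cylinder functions ``D_v``; deep in the entrance plateau
the unconvolved form is used, and beyond the distal falloff the dose is
exactly zero.

Peaks are parametrized clinically, by their distal-90% range in water
(the depth on the falling edge where dose drops to 90% of the peak
maximum), not by the internal CSDA range ``R0``; the constructor solves
for ``R0`` so that the realized distal-90% depth equals ``range_cm``.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property, lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import gamma as _gamma
from scipy.special import pbdv

__all__ = [
    "PristinePeak",
    "DepthDoseCurve",
    "pristine_dose",
    "distal_range",
    "shifted_peak",
    "DEFAULT_STRAGGLING_FRACTION",
]

# Bragg-Kleeman exponent and coefficient for protons in water, plus the
# fluence-reduction (beta), dose-buildup (gamma) and low-energy
# contamination (epsilon) parameters of the analytic depth-dose form.
_P = 1.77
_ALPHA = 0.0022  # cm MeV^-p
_BETA = 0.012    # 1/cm
_GAMMA_COEF = 0.6
_EPS = 0.1

#: Default Gaussian range-spread as a fraction of the distal-90% range.
#: Covers range straggling (~1.2% of range) combined in quadrature with
#: the range width contributed by the energy spread of the incident beam.
DEFAULT_STRAGGLING_FRACTION = 0.020


def _raw_dose(z: np.ndarray, r0: float, sigma: float) -> np.ndarray:
    """Unnormalized analytic depth dose at depths ``z`` (cm).

    Piecewise evaluation: unconvolved power-law form for
    ``zeta = (z - r0)/sigma < -20`` (where the Gaussian convolution is an
    identity to better than 1e-4), the parabolic-cylinder closed form for
    ``-20 <= zeta <= 10``, and zero beyond.
    """
    z = np.asarray(z, dtype=float)
    zeta = (z - r0) / sigma
    out = np.zeros_like(z)

    plateau = zeta < -20.0
    if plateau.any():
        u = r0 - z[plateau]
        out[plateau] = (
            u ** (1.0 / _P - 1.0)
            + (_BETA + _GAMMA_COEF * _BETA * _P + _EPS * _P / r0) * u ** (1.0 / _P)
        ) / (_P * _ALPHA ** (1.0 / _P) * (1.0 + _BETA * r0))

    near = (zeta >= -20.0) & (zeta <= 10.0)
    if near.any():
        zz = zeta[near]
        pref = (
            np.exp(-(zz**2) / 4.0)
            * sigma ** (1.0 / _P)
            * _gamma(1.0 / _P)
            / (np.sqrt(2.0 * np.pi) * _P * _ALPHA ** (1.0 / _P) * (1.0 + _BETA * r0))
        )
        term = pbdv(-1.0 / _P, zz)[0] / sigma + (
            _BETA / _P + _GAMMA_COEF * _BETA + _EPS / r0
        ) * pbdv(-1.0 / _P - 1.0, zz)[0]
        out[near] = pref * term
    return out


def _raw_landmarks(r0: float, sigma: float) -> tuple[float, float, float]:
    """(peak max, distal-90% depth, depth of max) of the unnormalized curve."""
    z = np.linspace(max(r0 - 5.0 * sigma, 0.0), r0 + 5.0 * sigma, 801)
    d = _raw_dose(z, r0, sigma)
    i = int(d.argmax())
    peak = d[i]
    tail = d[i:]
    below = np.nonzero(tail <= 0.9 * peak)[0]
    j = i + below[0]
    z1, z2, d1, d2 = z[j - 1], z[j], d[j - 1], d[j]
    d90 = z1 + (0.9 * peak - d1) * (z2 - z1) / (d2 - d1)
    return peak, d90, float(z[i])


@lru_cache(maxsize=4096)
def _solve_model(range_cm: float, sigma: float) -> tuple[float, float, float]:
    """Solve for the internal r0 whose distal-90% depth equals range_cm.

    The distal-90% depth shifts one-to-one with r0 to excellent
    approximation, so a fixed-point iteration converges in a few steps;
    brentq is the fallback if it stalls.
    """
    r0 = range_cm
    for _ in range(8):
        peak_max, d90, zmax = _raw_landmarks(r0, sigma)
        err = d90 - range_cm
        if abs(err) < 2e-5:
            return r0, peak_max, zmax
        r0 -= err
    lo = max(range_cm - 4.0 * sigma, 0.25 * range_cm)
    hi = range_cm + 2.0 * sigma
    r0 = brentq(lambda r: _raw_landmarks(r, sigma)[1] - range_cm, lo, hi, xtol=2e-5)
    peak_max, _, zmax = _raw_landmarks(r0, sigma)
    return r0, peak_max, zmax


@dataclass
class PristinePeak:
    """A single-energy-layer Bragg peak in water.

    Parameters
    ----------
    range_cm:
        Clinical range: depth of the distal 90%-of-maximum point (cm).
    straggling_sigma_cm:
        Gaussian range-spread width (cm).  Defaults to
        ``DEFAULT_STRAGGLING_FRACTION * range_cm``.
    """

    range_cm: float
    straggling_sigma_cm: float | None = None

    def __post_init__(self) -> None:
        if self.range_cm <= 0:
            raise ValueError(f"range_cm must be positive, got {self.range_cm}")
        if self.straggling_sigma_cm is None:
            self.straggling_sigma_cm = DEFAULT_STRAGGLING_FRACTION * self.range_cm
        if self.straggling_sigma_cm <= 0:
            raise ValueError("straggling_sigma_cm must be positive")

    @cached_property
    def _model(self) -> tuple[float, float, float]:
        """(r0, peak_max, depth_of_max) of the solved analytic curve."""
        return _solve_model(float(self.range_cm), float(self.straggling_sigma_cm))

    @property
    def depth_of_max_cm(self) -> float:
        """Depth of the Bragg-peak maximum (slightly proximal of range_cm)."""
        return self._model[2]

    @property
    def entrance_plateau_ratio(self) -> float:
        """Entrance dose relative to the peak maximum, dose(0)/dose(peak)."""
        return float(self.dose(0.0))

    def dose(self, z) -> np.ndarray | float:
        """Relative dose at depth(s) ``z`` (cm), normalized to peak max = 1."""
        scalar = np.isscalar(z)
        z = np.atleast_1d(np.asarray(z, dtype=float))
        if (z < 0).any():
            raise ValueError("depth must be non-negative")
        r0, peak_max, _ = self._model
        d = _raw_dose(z, r0, self.straggling_sigma_cm) / peak_max
        return float(d[0]) if scalar else d


def pristine_dose(z, peak: PristinePeak):
    """Relative dose of ``peak`` at depth(s) ``z`` in cm (peak maximum = 1)."""
    return peak.dose(z)


def shifted_peak(peak: PristinePeak, pullback_cm: float) -> PristinePeak:
    """Peak with its range reduced by a water-equivalent pull-back.

    The range-spread width is carried over unchanged: the pulled-back beam
    traverses the same total material (wheel step plus water), so its
    accumulated straggling matches the unmodulated beam.
    """
    if pullback_cm < 0:
        raise ValueError("pullback_cm must be non-negative")
    if pullback_cm >= peak.range_cm:
        raise ValueError(
            f"pullback {pullback_cm} cm >= peak range {peak.range_cm} cm"
        )
    return PristinePeak(
        range_cm=peak.range_cm - pullback_cm,
        straggling_sigma_cm=peak.straggling_sigma_cm,
    )


@dataclass
class DepthDoseCurve:
    """Sampled relative depth-dose curve on a strictly increasing grid."""

    depths_cm: np.ndarray
    doses: np.ndarray

    def __post_init__(self) -> None:
        self.depths_cm = np.asarray(self.depths_cm, dtype=float)
        self.doses = np.asarray(self.doses, dtype=float)
        if self.depths_cm.shape != self.doses.shape or self.depths_cm.ndim != 1:
            raise ValueError("depths_cm and doses must be 1-D and equal length")
        if self.depths_cm.size < 1:
            raise ValueError("curve needs at least one sample")
        if not (np.diff(self.depths_cm) > 0).all():
            raise ValueError("depths_cm must be strictly increasing")
        if (self.doses < 0).any():
            raise ValueError("doses must be non-negative")

    def dose_at(self, z) -> np.ndarray | float:
        return np.interp(z, self.depths_cm, self.doses)

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.depths_cm, self.doses])
        np.savetxt(path, arr, delimiter=",", header="depth_cm,dose", comments="")

    @classmethod
    def from_csv(cls, path) -> "DepthDoseCurve":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(arr[:, 0], arr[:, 1])


def distal_range(curve: DepthDoseCurve, fraction: float = 0.90) -> float:
    """Deepest depth where dose falls to ``fraction`` of the curve maximum.

    The crossing is located on the distal falling edge by linear
    interpolation between grid points.  ``fraction=1.0`` returns the depth
    of maximum.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    z, d = curve.depths_cm, curve.doses
    i_max = int(d.argmax())
    if fraction == 1.0:
        return float(z[i_max])
    level = fraction * d[i_max]
    tail = d[i_max:]
    above = np.nonzero(tail >= level)[0]
    j = i_max + above[-1]  # deepest point still at/above the level
    if j + 1 >= z.size:
        raise ValueError("no distal crossing: curve never falls below level")
    z1, z2, d1, d2 = z[j], z[j + 1], d[j], d[j + 1]
    return float(z1 + (level - d1) * (z2 - z1) / (d2 - d1))
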