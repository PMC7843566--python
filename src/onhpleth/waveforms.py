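"""Parametric cardiac-pulse waveform families for phantom generation.

The pulsatile absorption of ONH tissue over one heartbeat rises quickly
during systole and decays slowly in diastole. Two parametric families with
exactly known (amplitude, time-to-peak, FWHM, duration) are provided:

``triangle``
    Piecewise-linear: rise 0 -> amplitude over [0, time_to_peak], linear fall
    back to 0 at t_end, flat 0 until duration. Closed-form geometry gives
    FWHM = t_end / 2, so t_end = 2 * fwhm; feasible iff
    time_to_peak / 2 < fwhm <= duration / 2.

``gamma``
    Gamma-variate a(t) = A * (t/tp)**alpha * exp(alpha * (1 - t/tp)), the
    standard smooth model of an indicator-dilution / pulse curve, peaking at
    tp. The shape exponent alpha is solved numerically so the half-maximum
    width equals the requested FWHM.

Both start at 0 %A at t = 0 and attain the peak amplitude exactly at
time_to_peak, mirroring the definitions the parameter extractors invert.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq


class InfeasibleWaveform(ValueError):
    """Raised when (time_to_peak, fwhm, duration) cannot be realized."""


@dataclass(frozen=True)
class WaveformSpec:
    """Target pulse descriptors, in the units the extractors report.

    amplitude : peak absorption in %A (> 0)
    time_to_peak : s, time of the maximum from pulse start
    fwhm : s, full width at half the peak amplitude
    duration : s, beat length (start of one heartbeat to the next)
    shape : "triangle" or "gamma"
    """

    amplitude: float
    time_to_peak: float
    fwhm: float
    duration: float
    shape: str = "triangle"

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise InfeasibleWaveform("amplitude > 0 violated")
        if not 0 < self.time_to_peak < self.duration:
            raise InfeasibleWaveform("0 < time_to_peak < duration violated")
        if not 0 < self.fwhm < self.duration:
            raise InfeasibleWaveform("0 < fwhm < duration violated")
        if self.shape not in ("triangle", "gamma"):
            raise InfeasibleWaveform(f"unknown waveform family {self.shape!r}")
        if self.shape == "triangle":
            t_end = 2.0 * self.fwhm
            if self.fwhm <= self.time_to_peak / 2.0:
                raise InfeasibleWaveform(
                    "triangle family requires fwhm > time_to_peak / 2 "
                    "(descending limb must cross half maximum after the peak)"
                )
            if t_end > self.duration + 1e-12:
                raise InfeasibleWaveform(
                    "triangle family requires 2 * fwhm <= duration "
                    "(fall must return to baseline within the beat)"
                )
        else:
            # alpha solvable and descending half-max crossing inside the beat
            alpha = _gamma_alpha(self.time_to_peak, self.fwhm)
            _, t_down = _gamma_half_crossings(alpha, self.time_to_peak)
            if t_down >= self.duration:
                raise InfeasibleWaveform(
                    "gamma family: half-maximum descent would occur after the "
                    "beat ends; reduce fwhm or increase duration"
                )


def _gamma_log_shape(u: np.ndarray | float) -> np.ndarray | float:
    # log of the unit-amplitude gamma-variate in normalized time u = t / tp
    with np.errstate(divide="ignore"):
        return np.where(u > 0, np.log(np.maximum(u, 1e-300)) + 1.0 - u, -np.inf)


def _gamma_half_crossings(alpha: float, tp: float) -> tuple[float, float]:
    """Times where the gamma-variate crosses half maximum, by root finding."""
    c = np.log(0.5) / alpha  # solve log(u) + 1 - u = c on each side of u = 1
    f = lambda u: np.log(u) + 1.0 - u - c
    lo = 0.5 * np.exp(c - 1.0)  # f(lo) = -log(2) - lo < 0 for any c < 0
    u_up = brentq(f, lo, 1.0)
    hi = 2.0
    while f(hi) > 0:
        hi *= 2.0
    u_down = brentq(f, 1.0, hi)
    return u_up * tp, u_down * tp


def _gamma_alpha(tp: float, fwhm: float) -> float:
    """Shape exponent giving the requested FWHM at peak time tp."""

    def width_err(log_alpha: float) -> float:
        t_up, t_down = _gamma_half_crossings(np.exp(log_alpha), tp)
        return (t_down - t_up) - fwhm

    lo, hi = np.log(1e-3), np.log(1e6)
    if width_err(lo) < 0 or width_err(hi) > 0:
        raise InfeasibleWaveform(
            "gamma family: no shape exponent yields the requested fwhm "
            "for this time_to_peak"
        )
    return float(np.exp(brentq(width_err, lo, hi, xtol=1e-12)))


def evaluate_waveform(spec: WaveformSpec, t: np.ndarray) -> np.ndarray:
    """Continuous waveform value in %A at times ``t`` (seconds from beat start)."""
    t = np.asarray(t, dtype=float)
    a = np.zeros_like(t)
    if spec.shape == "triangle":
        t_end = 2.0 * spec.fwhm
        rising = (t >= 0) & (t <= spec.time_to_peak)
        falling = (t > spec.time_to_peak) & (t < t_end)
        a[rising] = spec.amplitude * t[rising] / spec.time_to_peak
        a[falling] = spec.amplitude * (t_end - t[falling]) / (t_end - spec.time_to_peak)
    else:
        alpha = _gamma_alpha(spec.time_to_peak, spec.fwhm)
        inside = (t > 0) & (t < spec.duration)
        u = t[inside] / spec.time_to_peak
        a[inside] = spec.amplitude * np.exp(alpha * _gamma_log_shape(u))
    return a


def generate_pulse_waveform(spec: WaveformSpec, fps: float) -> np.ndarray:
    """Sample one beat at the frame grid t = n / fps, n = 0 .. round(duration*fps)-1.

    The returned trace starts at 0 %A, returns toward 0 by the end of the
    beat, and carries the spec amplitude exactly: the sample nearest the
    apex is placed at the apex value (otherwise a peak falling between
    grid points would make every downstream amplitude-recovery check
    measure the sampling grid instead of the pipeline).
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    n = int(round(spec.duration * fps))
    if n < 2:
        raise InfeasibleWaveform("duration shorter than two frame periods at this fps")
    samples = evaluate_waveform(spec, np.arange(n) / fps)
    k_peak = int(round(spec.time_to_peak * fps))
    if 0 < k_peak < n:
        samples[k_peak] = spec.amplitude
    return samples


def tile_pulses(one_beat: np.ndarray, n_frames: int) -> np.ndarray:
    """Repeat a single-beat trace to cover ``n_frames`` frames."""
    reps = int(np.ceil(n_frames / len(one_beat)))
    return np.tile(one_beat, reps)[:n_frames]
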