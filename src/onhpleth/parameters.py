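"""The five waveform descriptors of an averaged pulse.

peak amplitude (%A)    maximum of the averaged pulse (ties: earliest sample)
steepness (%A/s)       systolic filling speed; default: rise from 30% to 70%
                       of peak amplitude divided by the elapsed time, with
                       three alternate estimators (min-max, 47-53%, maximum
                       numerical derivative)
time-to-peak (s, %)    time of the maximum from the beat start, also as a
                       percentage of pulse duration
FWHM (s, %)            full width at half the peak amplitude, also as %
pulse duration (s)     mean duration of the contributing beats

Threshold crossings are located by linear interpolation between samples:
at 25 frames/s, nearest-sample quantization (±0.02 s) would be coarse
against the population SDs of the timing parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pulses import AveragedPulse
from .waveforms import WaveformSpec, evaluate_waveform

STEEPNESS_VARIANTS = ("rise_30_70", "min_max", "rise_47_53", "max_derivative")


class InvalidPulse(ValueError):
    """The averaged pulse does not look like a heartbeat."""


@dataclass(frozen=True)
class PulseParameters:
    peak_amplitude: float
    steepness: float
    steepness_variant: str
    time_to_peak_s: float
    time_to_peak_pct: float
    fwhm_s: float
    fwhm_pct: float
    duration_s: float
    n_pulses: int = 0

    def as_row(self) -> dict:
        return {
            "peak_amplitude": self.peak_amplitude,
            "steepness": self.steepness,
            "ttp_s": self.time_to_peak_s,
            "ttp_pct": self.time_to_peak_pct,
            "fwhm_s": self.fwhm_s,
            "fwhm_pct": self.fwhm_pct,
            "duration_s": self.duration_s,
            "steepness_variant": self.steepness_variant,
            "n_pulses": self.n_pulses,
        }


def _peak_index(pulse: AveragedPulse) -> int:
    idx = int(np.argmax(pulse.values))  # argmax takes the earliest tie
    if pulse.values[idx] <= 0:
        raise InvalidPulse("pulse maximum is not positive")
    if idx == 0:
        raise InvalidPulse("pulse peaks at its first sample")
    return idx


def _cross_up(t: np.ndarray, v: np.ndarray, level: float, stop: int) -> float:
    """Time of the first upward crossing of ``level`` at or before ``stop``."""
    for i in range(1, stop + 1):
        if v[i - 1] < level <= v[i]:
            frac = (level - v[i - 1]) / (v[i] - v[i - 1])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    raise InvalidPulse(
        f"no upward crossing of {level:.3g} %A on the ascending limb "
        "(non-monotone or truncated rise)"
    )


def _cross_down(t: np.ndarray, v: np.ndarray, level: float, start: int) -> float:
    """Time of the first downward crossing of ``level`` after ``start``."""
    for i in range(start + 1, len(v)):
        if v[i - 1] >= level > v[i]:
            frac = (v[i - 1] - level) / (v[i - 1] - v[i])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    raise InvalidPulse(
        f"pulse never falls back below {level:.3g} %A "
        "(beat boundary problem: pulse ends above half maximum)"
    )


def peak_amplitude(pulse: AveragedPulse) -> float:
    return float(pulse.values[_peak_index(pulse)])


def time_to_peak(pulse: AveragedPulse) -> tuple[float, float]:
    idx = _peak_index(pulse)
    t = float(pulse.time_s[idx])
    return t, 100.0 * t / pulse.duration_s


def steepness(pulse: AveragedPulse, variant: str = "rise_30_70") -> float:
    if variant not in STEEPNESS_VARIANTS:
        raise ValueError(f"unknown steepness variant {variant!r}")
    amp = peak_amplitude(pulse)
    idx = _peak_index(pulse)
    t, v = pulse.time_s, pulse.values
    if variant == "min_max":
        return amp / float(t[idx])
    if variant == "max_derivative":
        dt = t[1] - t[0]
        dv = (v[2:] - v[:-2]) / (2.0 * dt)
        return float(dv.max())
    lo, hi = (0.30, 0.70) if variant == "rise_30_70" else (0.47, 0.53)
    t_lo = _cross_up(t, v, lo * amp, idx)
    t_hi = _cross_up(t, v, hi * amp, idx)
    if t_hi <= t_lo:
        raise InvalidPulse("ascending-limb crossings out of order")
    return (hi - lo) * amp / (t_hi - t_lo)


def fwhm(pulse: AveragedPulse) -> tuple[float, float]:
    amp = peak_amplitude(pulse)
    idx = _peak_index(pulse)
    half = 0.5 * amp
    t_up = _cross_up(pulse.time_s, pulse.values, half, idx)
    t_down = _cross_down(pulse.time_s, pulse.values, half, idx)
    width = t_down - t_up
    return float(width), 100.0 * width / pulse.duration_s


def pulse_duration(pulse: AveragedPulse) -> float:
    return float(pulse.duration_s)


def extract_parameters(pulse: AveragedPulse, variant: str = "rise_30_70") -> PulseParameters:
    """All five descriptors of one averaged pulse."""
    amp = peak_amplitude(pulse)
    ttp_s, ttp_pct = time_to_peak(pulse)
    fwhm_s, fwhm_pct = fwhm(pulse)
    return PulseParameters(
        peak_amplitude=amp,
        steepness=steepness(pulse, variant),
        steepness_variant=variant,
        time_to_peak_s=ttp_s,
        time_to_peak_pct=ttp_pct,
        fwhm_s=fwhm_s,
        fwhm_pct=fwhm_pct,
        duration_s=pulse_duration(pulse),
        n_pulses=pulse.n_pulses,
    )


def pulse_from_waveform(spec: WaveformSpec, fps: float) -> AveragedPulse:
    """Sample one beat of a parametric waveform as an AveragedPulse.

    Samples run t = k / fps for k = 0 .. round(duration * fps) inclusive,
    so the trace spans the full beat [0, duration] and the implied sample
    spacing of the AveragedPulse equals 1 / fps exactly. Used to close the
    generator -> extractor loop.
    """
    n = int(round(spec.duration * fps))
    t = np.arange(n + 1) / fps
    vals = evaluate_waveform(spec, t)
    k_peak = int(round(spec.time_to_peak * fps))
    if 0 < k_peak < n:
        vals[k_peak] = spec.amplitude  # apex carried by the nearest sample
    return AveragedPulse(
        values=vals,
        sd=np.zeros_like(vals),
        fps=fps,
        n_pulses=1,
        duration_s=n / fps,
    )
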