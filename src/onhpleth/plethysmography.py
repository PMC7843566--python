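"""Plethysmographic signal: ROI intensity, trend, and %A absorption.

The ROI-mean grey level I(n) of a registered sequence is divided by a
slowly varying trend I_avg(n); the relative absorption

    A(n) = 1 - I(n) / I_avg(n)

rises when blood volume (and hence light absorption) rises. Multiplying by
100 gives the analysis trace a_pct in %A; adding 100 gives the
display-convention trace, where 105 means absorption 5% above the trend.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import ROIMask
from .video import FrameFlag, VideoSequence


@dataclass
class PlethSignal:
    i_raw: np.ndarray
    i_trend: np.ndarray
    a_pct: np.ndarray
    display_100: np.ndarray
    fps: float
    frame_flags: list[FrameFlag]

    def __post_init__(self) -> None:
        n = len(self.i_raw)
        if not (len(self.i_trend) == len(self.a_pct) == len(self.display_100) == len(self.frame_flags) == n):
            raise ValueError("all traces must share one length")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.i_raw)) / self.fps

    def flagged(self) -> np.ndarray:
        return np.array([f != FrameFlag.OK for f in self.frame_flags])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "frame": np.arange(len(self.i_raw)),
                "time_s": self.time_s,
                "i_raw": self.i_raw,
                "i_trend": self.i_trend,
                "a_pct": self.a_pct,
                "flag": [f.value for f in self.frame_flags],
            }
        ).to_csv(path, index=False)


def extract_intensity_signal(video: VideoSequence, roi: ROIMask) -> tuple[np.ndarray, list[FrameFlag]]:
    """Mean grey level over ROI pixels per frame, skipping out-of-field pixels.

    A frame whose ROI is entirely out of field gets NaN and an edge_loss flag.
    """
    if not roi.mask.any():
        raise ValueError("ROI is empty")
    flags = list(video.flags)
    i_raw = np.empty(video.n_frames)
    for n in range(video.n_frames):
        sel = roi.mask & video.frame_valid(n)
        if not sel.any():
            i_raw[n] = np.nan
            flags[n] = FrameFlag.EDGE_LOSS
        else:
            i_raw[n] = video.frames[n][sel].mean()
    return i_raw, flags


def estimate_trend(
    i_raw: np.ndarray,
    fps: float,
    window_s: float = 1.5,
    flags: list[FrameFlag] | None = None,
) -> np.ndarray:
    """Centred moving-average trend, reflect-padded, excluding flagged frames.

    The window (default 1.5 s, at least one plausible pulse period) is
    rounded to an odd number of frames so the average stays centred.
    """
    i_raw = np.asarray(i_raw, dtype=float)
    win = int(round(window_s * fps))
    if win % 2 == 0:
        win += 1
    if len(i_raw) < win:
        raise ValueError(f"signal shorter ({len(i_raw)}) than the trend window ({win} frames)")
    good = np.isfinite(i_raw)
    if flags is not None:
        good &= np.array([f == FrameFlag.OK for f in flags])
    if not good.any():
        raise ValueError("all frames flagged: no data to estimate a trend from")

    vals = np.where(good, i_raw, 0.0)
    wts = good.astype(float)
    half = win // 2
    vals_p = np.pad(vals, half, mode="reflect")
    wts_p = np.pad(wts, half, mode="reflect")
    kernel = np.ones(win)
    num = np.convolve(vals_p, kernel, mode="valid")
    den = np.convolve(wts_p, kernel, mode="valid")
    if (den == 0).any():
        raise ValueError("a trend window contains no usable frames")
    trend = num / den
    if (trend <= 0).any():
        raise ValueError("non-positive trend value: pathological input signal")
    return trend


def estimate_beat_period(i_raw: np.ndarray, fps: float, window_s: float = 1.5) -> float | None:
    """Beat period (s) from the autocorrelation of the detrended intensity.

    A coarse moving-average detrend removes drift, then the first
    autocorrelation peak in the plausible beat range 0.33-2.0 s is taken.
    Returns None when no credible periodicity is found.
    """
    i_raw = np.asarray(i_raw, dtype=float)
    good = np.isfinite(i_raw)
    if good.sum() < int(2.0 * fps):
        return None
    x = i_raw.copy()
    x[~good] = np.nanmean(i_raw)
    try:
        x = x - estimate_trend(x, fps, window_s=window_s)
    except ValueError:
        return None
    x = x - x.mean()
    if np.allclose(x, 0):
        return None
    ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
    ac = ac / ac[0]
    lo = max(int(round(0.33 * fps)), 1)
    hi = min(int(round(2.0 * fps)), len(ac) - 1)
    if hi <= lo:
        return None
    k = lo + int(np.argmax(ac[lo : hi + 1]))
    if ac[k] < 0.2:  # no credible periodicity
        return None
    return k / fps


def compute_pleth_signal(i_raw: np.ndarray, i_trend: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """a_pct(n) = (1 - i_raw/i_trend) * 100 and its 100-referenced display trace."""
    i_raw = np.asarray(i_raw, dtype=float)
    i_trend = np.asarray(i_trend, dtype=float)
    if i_raw.shape != i_trend.shape:
        raise ValueError("raw and trend traces must share one length")
    if (i_trend <= 0).any():
        raise ValueError("trend must be strictly positive")
    a_pct = (1.0 - i_raw / i_trend) * 100.0
    return a_pct, 100.0 + a_pct


def pleth_signal(
    video: VideoSequence,
    roi: ROIMask,
    window_s: float | None = None,
) -> PlethSignal:
    """Full chain: ROI intensity -> trend -> %A absorption signal.

    With ``window_s=None`` the trend window is chosen adaptively as two
    detected beat periods: a centred moving average over an integer number
    of beats nulls the pulse fundamental exactly, so trend correction
    removes drift without distorting the beat amplitude. A fixed window
    (e.g. the 1.5 s fallback used when no periodicity is detectable)
    leaks a heart-rate-dependent fraction of the pulse into the trend.
    """
    i_raw, flags = extract_intensity_signal(video, roi)
    if window_s is None:
        period = estimate_beat_period(i_raw, video.fps)
        window_s = 2.0 * period if period is not None else 1.5
        window_s = min(window_s, (len(i_raw) - 1) / video.fps)
    i_trend = estimate_trend(i_raw, video.fps, window_s=window_s, flags=flags)
    filled = np.where(np.isfinite(i_raw), i_raw, i_trend)
    a_pct, display = compute_pleth_signal(filled, i_trend)
    return PlethSignal(
        i_raw=i_raw,
        i_trend=i_trend,
        a_pct=a_pct,
        display_100=display,
        fps=video.fps,
        frame_flags=flags,
    )
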