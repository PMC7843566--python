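"""Heartbeat detection, pulse selection, and the averaged pulse.

A pulse (one heartbeat) runs from one labelled local minimum of the %A
signal to the next. Labels come either from a manual label file — the
primary path, mirroring masked manual inspection of each recording — or
from automated screening that rejects beats spanning flagged frames or
with outlying duration/amplitude. Selected beats are re-referenced to
their starting value, resampled to a common length, and averaged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .plethysmography import PlethSignal
from .video import FrameFlag

MIN_PULSE_S = 0.33  # shortest plausible beat (≈ 180 bpm)
MAX_PULSE_S = 2.0  # longest plausible beat (= 30 bpm)


@dataclass
class PulseLabelSet:
    """Start-of-heartbeat minima and the beat intervals built from them.

    ``pairs`` lists the (start_frame, end_frame) of each selected beat;
    for manual labels these are simply consecutive minima. Label files
    must not carry any diagnosis field (labelling is masked to grouping).
    """

    minima_frames: list[int]
    fps: float
    source: str = "manual"
    sequence_id: str = ""
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = list(self.minima_frames)
        if len(m) < 2:
            raise ValueError("at least 2 labelled minima (1 pulse) required")
        if any(b <= a for a, b in zip(m, m[1:])):
            raise ValueError("labelled minima must be strictly increasing")
        if not self.pairs:
            for a, b in zip(m, m[1:]):
                gap_s = (b - a) / self.fps
                if not MIN_PULSE_S <= gap_s <= MAX_PULSE_S:
                    raise ValueError(
                        f"inter-minimum gap {gap_s:.2f} s outside the plausible "
                        f"beat range [{MIN_PULSE_S}, {MAX_PULSE_S}] s"
                    )
            self.pairs = list(zip(m, m[1:]))

    @property
    def n_pulses(self) -> int:
        return len(self.pairs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "sequence_id": self.sequence_id,
                    "fps": self.fps,
                    "minima_frames": list(self.minima_frames),
                    "source": self.source,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PulseLabelSet":
        rec = json.loads(Path(path).read_text())
        if "diagnosis" in rec or "group" in rec:
            raise ValueError(
                "label files must not carry diagnosis/group information "
                "(pulse selection is masked to grouping)"
            )
        return cls(
            minima_frames=[int(i) for i in rec["minima_frames"]],
            fps=float(rec["fps"]),
            source=rec.get("source", "manual"),
            sequence_id=rec.get("sequence_id", ""),
        )


@dataclass
class AveragedPulse:
    """Mean +/- SD waveform of the selected beats, starting at 0 %A.

    ``values`` spans [0, duration_s]; sample k sits at
    t_k = k * duration_s / (len(values) - 1).
    """

    values: np.ndarray
    sd: np.ndarray
    fps: float
    n_pulses: int
    duration_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if len(self.values) != len(self.sd):
            raise ValueError("values and sd must share one length")
        if abs(self.values[0]) > 1e-9:
            raise ValueError("averaged pulse must start at 0 (start-point reference)")

    @property
    def time_s(self) -> np.ndarray:
        return np.linspace(0.0, self.duration_s, len(self.values))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "sample": np.arange(len(self.values)),
                "time_s": self.time_s,
                "value_pctA": self.values,
                "sd_pctA": self.sd,
            }
        ).to_csv(path, index=False)


def detect_minima(
    sig: PlethSignal,
    min_separation_s: float = MIN_PULSE_S,
    prominence_fraction: float = 0.3,
    flag_margin: int = 2,
) -> list[int]:
    """Candidate heartbeat-start minima of the %A trace.

    Two passes: a distance-only pass estimates the median pulse amplitude,
    then minima are re-detected requiring prominence of at least
    ``prominence_fraction`` of that amplitude. Minima within
    ``flag_margin`` frames of a flagged frame are discarded.
    """
    a = sig.a_pct
    if len(a) < sig.fps:
        raise ValueError("signal shorter than 1 s")
    distance = max(int(round(min_separation_s * sig.fps)), 1)
    rough, _ = find_peaks(-a, distance=distance)
    if len(rough) >= 2:
        amps = [a[s:e + 1].max() - a[s] for s, e in zip(rough, rough[1:])]
        prominence = prominence_fraction * float(np.median(amps))
    else:
        prominence = None
    if prominence and prominence > 0:
        minima, _ = find_peaks(-a, distance=distance, prominence=prominence)
    else:
        minima = rough
    flagged = np.flatnonzero(sig.flagged())
    keep = [
        int(m)
        for m in minima
        if not len(flagged) or np.abs(flagged - m).min() > flag_margin
    ]
    return keep


def select_pulses(
    minima: list[int],
    sig: PlethSignal,
    labels: PulseLabelSet | None = None,
    duration_tolerance: float = 0.25,
    amplitude_tolerance: float = 0.50,
    min_pulses: int = 2,
) -> PulseLabelSet:
    """Keep reliable beats; manual labels pass through after validation.

    Automated screening drops a beat if it spans a flagged frame, if its
    duration deviates from the median by more than ``duration_tolerance``,
    or if its peak amplitude deviates by more than ``amplitude_tolerance``.
    """
    if labels is not None:
        if abs(labels.fps - sig.fps) > 1e-9:
            raise ValueError("label fps does not match the signal fps")
        last = max(e for _, e in labels.pairs)
        if last >= len(sig.a_pct):
            raise ValueError("labelled minima exceed the signal length")
        return labels

    if len(minima) < 2:
        raise ValueError("fewer than 2 candidate minima: no pulse to select")
    flagged = sig.flagged()
    a = sig.a_pct
    cand = list(zip(minima, minima[1:]))
    durations = np.array([e - s for s, e in cand], dtype=float)
    amps = np.array([a[s:e + 1].max() - a[s] for s, e in cand])
    med_d = np.median(durations)
    med_a = np.median(amps)

    kept: list[tuple[int, int]] = []
    rejected: list[str] = []
    for (s, e), d, amp in zip(cand, durations, amps):
        gap_s = d / sig.fps
        if flagged[s:e + 1].any():
            rejected.append(f"pulse {s}-{e}: flagged frame inside")
        elif not MIN_PULSE_S <= gap_s <= MAX_PULSE_S:
            rejected.append(f"pulse {s}-{e}: implausible duration {gap_s:.2f} s")
        elif abs(d - med_d) > duration_tolerance * med_d:
            rejected.append(f"pulse {s}-{e}: duration outlier ({d:.0f} vs median {med_d:.0f} frames)")
        elif abs(amp - med_a) > amplitude_tolerance * med_a:
            rejected.append(f"pulse {s}-{e}: amplitude outlier ({amp:.2f} vs median {med_a:.2f} %A)")
        else:
            kept.append((s, e))
    if len(kept) < min_pulses:
        raise RuntimeError(
            f"only {len(kept)} reliable pulse(s), need >= {min_pulses}. "
            "Rejections: " + ("; ".join(rejected) if rejected else "none")
        )
    starts = sorted({s for s, _ in kept} | {kept[-1][1]})
    return PulseLabelSet(
        minima_frames=starts, fps=sig.fps, source="auto", pairs=kept
    )


def average_pulses(
    sig: PlethSignal,
    labels: PulseLabelSet,
    min_pulses: int = 2,
    mode: str = "resample",
) -> AveragedPulse:
    """Average the selected beats into one mean +/- SD waveform.

    Each beat is re-referenced by subtracting its first sample, then
    resampled by linear interpolation to the rounded median beat length
    (``mode="truncate"`` instead cuts all beats to the shortest).
    ``duration_s`` is the mean of the individual beat durations. SD is the
    sample standard deviation (ddof=1) across beats; all 0 for one beat.
    """
    if labels.n_pulses < min_pulses:
        raise ValueError(f"{labels.n_pulses} pulse(s) selected, need >= {min_pulses}")
    a = sig.a_pct
    beats = []
    lengths = []
    for s, e in labels.pairs:
        seg = a[s:e + 1] - a[s]
        beats.append(seg)
        lengths.append(e - s)
    lengths = np.array(lengths, dtype=float)

    if mode == "truncate":
        L = int(lengths.min())
        stack = np.stack([b[: L + 1] for b in beats])
    elif mode == "resample":
        L = int(round(float(np.median(lengths))))
        grid = np.linspace(0.0, 1.0, L + 1)
        stack = np.stack(
            [np.interp(grid, np.linspace(0.0, 1.0, len(b)), b) for b in beats]
        )
    else:
        raise ValueError("mode must be 'resample' or 'truncate'")

    values = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(beats) > 1 else np.zeros_like(values)
    values = values - values[0]  # start-point reference survives averaging
    return AveragedPulse(
        values=values,
        sd=sd,
        fps=sig.fps,
        n_pulses=len(beats),
        duration_s=float(lengths.mean() / sig.fps),
    )


def pulse_rate(labels: PulseLabelSet, fps: float) -> float:
    """Beats per minute from the mean inter-minimum interval."""
    gaps = np.array([e - s for s, e in labels.pairs], dtype=float) / fps
    return 60.0 / float(gaps.mean())
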