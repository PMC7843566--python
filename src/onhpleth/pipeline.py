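"""End-to-end runs: registration through parameter extraction.

``run_pipeline`` executes the nine processing steps on in-memory objects;
``analyze`` wraps it with file I/O and a provenance record so a run can be
reproduced from its outputs alone. ``batch`` maps ``analyze`` over a
manifest of sequences and reduces to one row per subject.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .parameters import PulseParameters, extract_parameters
from .plethysmography import PlethSignal, pleth_signal
from .pulses import AveragedPulse, PulseLabelSet, average_pulses, detect_minima, pulse_rate, select_pulses
from .registration import MotionTrace, register_sequence
from .segmentation import (
    MaskKind,
    MaskProvenance,
    ROIMask,
    average_frames,
    dilate_vessels,
    make_onh_roi,
    segment_onh,
    segment_vessels,
)
from .video import VideoSequence, read_video, write_video

log = logging.getLogger("onhpleth")


@dataclass
class PipelineResult:
    registered: VideoSequence
    trace: MotionTrace
    averaged_image: np.ndarray
    onh: ROIMask
    vessels_dilated: ROIMask
    roi: ROIMask
    signal: PlethSignal
    labels: PulseLabelSet
    pulse: AveragedPulse
    params: PulseParameters
    pulse_rate_bpm: float
    warnings: list[str] = field(default_factory=list)

    def parameter_row(self) -> dict:
        return self.params.as_row() | {"pulse_rate_bpm": self.pulse_rate_bpm}


def run_pipeline(
    video: VideoSequence,
    onh_mask: ROIMask | None = None,
    vessel_mask: ROIMask | None = None,
    labels: PulseLabelSet | None = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Steps 1-9 on one sequence; masks and labels may be supplied or derived."""
    cfg = config or RunConfig()
    warnings: list[str] = []
    t0 = time.perf_counter()

    registered, trace = register_sequence(
        video,
        max_rotation_deg=cfg.max_rotation_deg,
        confidence_threshold=cfg.confidence_threshold,
    )
    log.info("registration: %.2f s", time.perf_counter() - t0)

    avg = average_frames(registered)
    if onh_mask is None and not cfg.allow_auto_onh:
        raise ValueError("no manual ONH mask given and automatic segmentation is disabled")
    onh = segment_onh(avg, manual_mask=onh_mask, threshold_quantile=cfg.onh_threshold_quantile)
    vessels = vessel_mask if vessel_mask is not None else segment_vessels(avg)
    if vessels.kind != MaskKind.VESSELS_DILATED:
        vessels_dil = dilate_vessels(vessels, diameter_px=cfg.dilation_diameter_px)
    else:
        vessels_dil = vessels
    roi = make_onh_roi(onh, vessels_dil, min_pixels=cfg.roi_min_pixels)

    sig = pleth_signal(registered, roi, window_s=cfg.trend_window_s)

    if cfg.selection_mode == "manual" and labels is None:
        raise ValueError("selection_mode is 'manual' but no label file was given")
    minima = detect_minima(sig) if labels is None else []
    chosen = select_pulses(
        minima,
        sig,
        labels=labels,
        duration_tolerance=cfg.duration_tolerance,
        amplitude_tolerance=cfg.amplitude_tolerance,
        min_pulses=cfg.min_pulses,
    )
    if chosen.n_pulses > cfg.max_pulses:
        warnings.append(
            f"{chosen.n_pulses} pulses selected; keeping the {cfg.max_pulses} "
            "with duration closest to the median"
        )
        durs = np.array([e - s for s, e in chosen.pairs], dtype=float)
        order = np.argsort(np.abs(durs - np.median(durs)), kind="stable")[: cfg.max_pulses]
        pairs = [chosen.pairs[i] for i in sorted(order)]
        starts = sorted({s for s, _ in pairs} | {pairs[-1][1]})
        chosen = PulseLabelSet(minima_frames=starts, fps=sig.fps, source=chosen.source, pairs=pairs)

    pulse = average_pulses(sig, chosen, min_pulses=cfg.min_pulses, mode=cfg.averaging_mode)
    params = extract_parameters(pulse, variant=cfg.steepness_variant)
    return PipelineResult(
        registered=registered,
        trace=trace,
        averaged_image=avg,
        onh=onh,
        vessels_dilated=vessels_dil,
        roi=roi,
        signal=sig,
        labels=chosen,
        pulse=pulse,
        params=params,
        pulse_rate_bpm=pulse_rate(chosen, sig.fps),
        warnings=warnings,
    )


def analyze(
    video_path: str | Path,
    onh_mask_path: str | Path | None = None,
    vessel_mask_path: str | Path | None = None,
    labels_path: str | Path | None = None,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    sequence_id: str | None = None,
) -> dict:
    """File-level run: read inputs, run the pipeline, write all outputs."""
    cfg = config or RunConfig()
    video = read_video(video_path, fps=cfg.fps)
    onh = (
        ROIMask.read_png(onh_mask_path, MaskKind.ONH, MaskProvenance.MANUAL)
        if onh_mask_path
        else None
    )
    vessels = (
        ROIMask.read_png(vessel_mask_path, MaskKind.VESSELS, MaskProvenance.MANUAL)
        if vessel_mask_path
        else None
    )
    labels = PulseLabelSet.from_json(labels_path) if labels_path else None
    result = run_pipeline(video, onh_mask=onh, vessel_mask=vessels, labels=labels, config=cfg)

    seq_id = sequence_id or Path(video_path).stem
    row = {"sequence_id": seq_id} | result.parameter_row()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_video(out / f"{seq_id}_registered.tif", result.registered)
        result.trace.to_csv(out / f"{seq_id}_motion.csv", flags=result.registered.flags)
        result.onh.write_png(out / f"{seq_id}_onh.png")
        result.vessels_dilated.write_png(out / f"{seq_id}_vessels_dilated.png")
        result.roi.write_png(out / f"{seq_id}_roi.png")
        result.signal.to_csv(out / f"{seq_id}_signal.csv")
        result.pulse.to_csv(out / f"{seq_id}_pulse.csv")
        pd.DataFrame([row]).to_csv(out / f"{seq_id}_parameters.csv", index=False)
        provenance = {
            "sequence_id": seq_id,
            "inputs": {
                "video": str(video_path),
                "onh_mask": str(onh_mask_path) if onh_mask_path else None,
                "vessel_mask": str(vessel_mask_path) if vessel_mask_path else None,
                "labels": str(labels_path) if labels_path else None,
            },
            "config": cfg.to_dict(),
            "versions": {"onhpleth": __version__, "python": platform.python_version()},
            "warnings": result.warnings,
        }
        (out / f"{seq_id}_provenance.json").write_text(json.dumps(provenance, indent=2))
    return row


def batch(manifest_path: str | Path, config: RunConfig | None = None, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run ``analyze`` per manifest row, one output row per subject.

    Manifest columns: subject_id, group, video, and optional onh_mask,
    vessel_mask, labels. When a subject has several sequences, the
    sequence with the most accepted pulses is kept (``sequence_policy``).
    Per-row failures are logged and do not stop the run.
    """
    cfg = config or RunConfig()
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        raise ValueError("empty manifest")
    base = Path(manifest_path).parent
    rows = []
    failures = []
    for i, rec in manifest.iterrows():
        try:
            def _p(col):
                return base / rec[col] if col in rec and isinstance(rec[col], str) else None

            row = analyze(
                base / rec["video"],
                onh_mask_path=_p("onh_mask"),
                vessel_mask_path=_p("vessel_mask"),
                labels_path=_p("labels"),
                config=cfg,
                out_dir=out_dir,
                sequence_id=f"{rec['subject_id']}_{i}",
            )
            row["subject_id"] = rec["subject_id"]
            if "group" in rec:
                row["group"] = rec["group"]
            rows.append(row)
        except Exception as exc:  # error containment: log and continue
            log.error("manifest row %d (%s) failed: %s", i, rec.get("subject_id", "?"), exc)
            failures.append({"row": i, "subject_id": rec.get("subject_id"), "error": str(exc)})
    if not rows:
        raise RuntimeError(f"all {len(manifest)} manifest rows failed")
    table = pd.DataFrame(rows)
    # sequence policy: keep the sequence with the most accepted pulses
    if cfg.sequence_policy == "most_pulses":
        table = (
            table.sort_values("n_pulses", ascending=False, kind="stable")
            .groupby("subject_id", as_index=False, sort=False)
            .first()
        )
    table.attrs["failures"] = failures
    return table
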