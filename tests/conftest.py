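"""Shared fixtures: phantoms and signals generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from onhpleth.config import RunConfig
from onhpleth.phantom import (
    MotionArtifactSpec,
    ScenePhantom,
    default_vessel_tree,
    render_video,
)
from onhpleth.plethysmography import PlethSignal
from onhpleth.segmentation import MaskKind, MaskProvenance, ROIMask
from onhpleth.video import FrameFlag
from onhpleth.waveforms import WaveformSpec, generate_pulse_waveform, tile_pulses

FPS = 25.0


@pytest.fixture(scope="session")
def waveform_spec() -> WaveformSpec:
    """The reference triangle beat: 5 %A, systole 0.30 s, FWHM 0.50 s, 1.0 s."""
    return WaveformSpec(amplitude=5.0, time_to_peak=0.3, fwhm=0.5, duration=1.0)


@pytest.fixture(scope="session")
def phantom_scene() -> ScenePhantom:
    return ScenePhantom(vessel_tree=default_vessel_tree())


@pytest.fixture(scope="session")
def still_video(phantom_scene, waveform_spec):
    """Motion- and noise-free 250-frame phantom with the reference beat."""
    beat = generate_pulse_waveform(waveform_spec, FPS)
    wave = tile_pulses(beat, 250)
    return render_video(phantom_scene, wave, MotionArtifactSpec.still(250), fps=FPS)


@pytest.fixture(scope="session")
def moving_video(phantom_scene, waveform_spec):
    """The end-to-end recovery phantom: +-4 px drift, mild sensor noise."""
    beat = generate_pulse_waveform(waveform_spec, FPS)
    wave = tile_pulses(beat, 250)
    art = MotionArtifactSpec.sinusoidal(250, FPS, amp_px=4.0, noise_sd=1.0, seed=7)
    return render_video(phantom_scene, wave, art, fps=FPS)


@pytest.fixture(scope="session")
def pipeline_config() -> RunConfig:
    # the 100x100 phantom disc is smaller than a real high-resolution ONH
    return RunConfig(roi_min_pixels=400)


@pytest.fixture()
def true_roi(phantom_scene):
    from onhpleth.segmentation import dilate_vessels

    vessels = ROIMask(phantom_scene.vessel_mask(), MaskKind.VESSELS, MaskProvenance.MANUAL)
    roi = phantom_scene.onh_mask() & ~dilate_vessels(vessels).mask
    return ROIMask(roi, MaskKind.ONH_TISSUE_ROI, MaskProvenance.MERGED)


def make_signal(a_pct: np.ndarray, fps: float = FPS, flags=None) -> PlethSignal:
    """Wrap a bare %A trace as a PlethSignal (unit trend, raw implied)."""
    a_pct = np.asarray(a_pct, dtype=float)
    trend = np.full_like(a_pct, 100.0)
    raw = trend * (1.0 - a_pct / 100.0)
    return PlethSignal(
        i_raw=raw,
        i_trend=trend,
        a_pct=a_pct,
        display_100=100.0 + a_pct,
        fps=fps,
        frame_flags=list(flags) if flags is not None else [FrameFlag.OK] * len(a_pct),
    )
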