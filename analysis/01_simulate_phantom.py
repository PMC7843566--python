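"""Render the reference fundus phantoms with known injected pulse.

Writes a motion-free and a moving (+-4 px drift, mild noise) 10-s phantom
video at 25 frames/s, plus ground truth (injected waveform, motion trace,
true masks), under results/phantom/. The injected beat is the reference
triangle: 5 %A amplitude, 0.30 s systolic rise, 0.50 s FWHM, 1.0 s beat.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "phantom"

from onhpleth.phantom import MotionArtifactSpec, ScenePhantom, default_vessel_tree, render_video
from onhpleth.segmentation import MaskKind, MaskProvenance, ROIMask
from onhpleth.video import write_video
from onhpleth.waveforms import WaveformSpec, generate_pulse_waveform, tile_pulses

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
FPS, N_FRAMES = 25.0, 250


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = WaveformSpec(amplitude=5.0, time_to_peak=0.3, fwhm=0.5, duration=1.0)
    wave = tile_pulses(generate_pulse_waveform(spec, FPS), N_FRAMES)
    phantom = ScenePhantom(vessel_tree=default_vessel_tree())

    runs = {
        "still": MotionArtifactSpec.still(N_FRAMES),
        "moving": MotionArtifactSpec.sinusoidal(N_FRAMES, FPS, amp_px=4.0, noise_sd=1.0, seed=SEED),
    }
    for name, art in runs.items():
        video, truth = render_video(phantom, wave, art, fps=FPS)
        write_video(OUT / f"{name}.tif", video)
        truth.to_json(OUT / f"{name}_truth.json")
        for mask, kind, fname in (
            (truth.onh_mask, MaskKind.ONH, "onh"),
            (truth.vessel_mask, MaskKind.VESSELS, "vessels"),
            (truth.tissue_mask, MaskKind.ONH_TISSUE_ROI, "tissue"),
        ):
            ROIMask(mask, kind, MaskProvenance.AUTOMATIC).write_png(OUT / f"{name}_{fname}.png")
        print(f"{name}: {video.n_frames} frames, grey range "
              f"{video.frames.min():.0f}-{video.frames.max():.0f}, "
              f"injected peak {wave.max():.1f} %A")
    print(f"wrote phantoms to {OUT}")


if __name__ == "__main__":
    main()
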