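"""Synthetic fundus-video phantoms with a known injected pulse.

The phantom emulates what the analysis pipeline sees in a real recording:
a bright ONH disc carrying a darker large-vessel tree on a textured
background, a multiplicative cardiac absorption modulation of a few %A on
the ONH tissue, rigid inter-frame eye motion, blink and motion-blur
artifact frames, and additive sensor noise. Because absorption is injected
multiplicatively on a static scene — exactly the model the plethysmographic
signal A(n) = 1 - I(n)/I_avg(n) inverts — the ground truth of every
downstream stage is known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk, line as draw_line
from skimage.morphology import dilation, disk as disk_footprint

from .transform import apply_rigid
from .video import VideoSequence


@dataclass
class ScenePhantom:
    """Static retinal scene: disc, vessel tree, background texture.

    vessel_tree is a list of ((r0, c0), (r1, c1), width_px) polyline segments.
    Absorption fractions are in [0, 1); tissue_absorption_gain scales the
    injected waveform on ONH tissue pixels (1.0 = waveform applied as-is).
    """

    frame_shape: tuple[int, int] = (100, 100)
    onh_center: tuple[int, int] = (50, 50)
    onh_radius: int = 35
    vessel_tree: list[tuple[tuple[int, int], tuple[int, int], int]] = field(default_factory=list)
    background_level: float = 120.0
    onh_brightness_gain: float = 1.4
    vessel_absorption: float = 0.45
    tissue_absorption_gain: float = 1.0
    texture_amplitude: float = 0.03
    texture_seed: int = 0
    modulation_apron_px: int = 4
    modulation_soft_sigma: float = 2.0

    def __post_init__(self) -> None:
        r, c = self.onh_center
        if (
            r - self.onh_radius < 0
            or c - self.onh_radius < 0
            or r + self.onh_radius >= self.frame_shape[0]
            or c + self.onh_radius >= self.frame_shape[1]
        ):
            raise ValueError("ONH disc must lie fully inside the frame")
        for seg in self.vessel_tree:
            if seg[2] < 1:
                raise ValueError("vessel widths must be >= 1 px")
        for frac in (self.vessel_absorption, self.tissue_absorption_gain):
            if not 0 <= frac <= 1:
                raise ValueError("absorption fractions must be in [0, 1]")

    def onh_mask(self) -> np.ndarray:
        m = np.zeros(self.frame_shape, dtype=bool)
        rr, cc = draw_disk(self.onh_center, self.onh_radius, shape=self.frame_shape)
        m[rr, cc] = True
        return m

    def vessel_mask(self) -> np.ndarray:
        m = np.zeros(self.frame_shape, dtype=bool)
        for (r0, c0), (r1, c1), width in self.vessel_tree:
            rr, cc = draw_line(r0, c0, r1, c1)
            keep = (rr >= 0) & (rr < self.frame_shape[0]) & (cc >= 0) & (cc < self.frame_shape[1])
            m[rr[keep], cc[keep]] = True
        radius = max(int(round((max(s[2] for s in self.vessel_tree) - 1) / 2)), 0) if self.vessel_tree else 0
        if radius > 0:
            m = dilation(m, disk_footprint(radius))
        return m

    def tissue_mask(self) -> np.ndarray:
        """Pixels whose intensity is modulated by the pulse: ONH minus vessels."""
        return self.onh_mask() & ~self.vessel_mask()

    def modulation_gain(self) -> np.ndarray:
        """Per-pixel pulsatile gain in [0, 1].

        Full gain on ONH tissue with a smooth apron extending a few pixels
        past the disc contour (perfused tissue does not stop pulsating at a
        drawn boundary; a hard step there would be a rendering artifact that
        bleeds into boundary ROI pixels under subpixel motion). Large
        vessels carry no tissue modulation.
        """
        if self.modulation_apron_px > 0:
            support = dilation(self.onh_mask(), disk_footprint(self.modulation_apron_px))
            gain = gaussian_filter(support.astype(float), self.modulation_soft_sigma)
            gain = np.clip(gain, 0.0, 1.0)
        else:
            gain = self.onh_mask().astype(float)
        gain[self.vessel_mask()] = 0.0
        return gain * self.tissue_absorption_gain

    def static_scene(self) -> np.ndarray:
        rng = np.random.default_rng(self.texture_seed)
        texture = gaussian_filter(rng.standard_normal(self.frame_shape), sigma=4)
        texture = 1.0 + self.texture_amplitude * texture / max(texture.std(), 1e-12)
        scene = self.background_level * texture
        scene[self.onh_mask()] *= self.onh_brightness_gain
        scene[self.vessel_mask()] *= 1.0 - self.vessel_absorption
        return scene


@dataclass
class MotionArtifactSpec:
    """Per-frame rigid motion plus artifact frames and sensor noise."""

    dx: np.ndarray
    dy: np.ndarray
    theta: np.ndarray
    blink_frames: frozenset[int] = frozenset()
    blur_frames: frozenset[int] = frozenset()
    noise_sd: float = 0.0
    blur_sigma: float = 3.0
    blink_gain: float = 2.5
    seed: int = 0

    @classmethod
    def still(cls, n_frames: int, noise_sd: float = 0.0, seed: int = 0) -> "MotionArtifactSpec":
        z = np.zeros(n_frames)
        return cls(dx=z, dy=z.copy(), theta=z.copy(), noise_sd=noise_sd, seed=seed)

    @classmethod
    def sinusoidal(
        cls,
        n_frames: int,
        fps: float,
        amp_px: float = 4.0,
        freq_hz: float = 0.35,
        amp_deg: float = 0.0,
        noise_sd: float = 0.0,
        seed: int = 0,
    ) -> "MotionArtifactSpec":
        """Slow sinusoidal drift emulating fixational eye movement."""
        t = np.arange(n_frames) / fps
        return cls(
            dx=amp_px * np.sin(2 * np.pi * freq_hz * t),
            dy=amp_px * np.sin(2 * np.pi * freq_hz * t + 1.1),
            theta=amp_deg * np.sin(2 * np.pi * freq_hz * t + 2.2),
            noise_sd=noise_sd,
            seed=seed,
        )

    def validate(self, n_frames: int) -> None:
        if not (len(self.dx) == len(self.dy) == len(self.theta) == n_frames):
            raise ValueError("motion trace must have one (dx, dy, theta) entry per frame")
        for idx in self.blink_frames | self.blur_frames:
            if not 0 <= idx < n_frames:
                raise ValueError("blink/blur frame indices must lie within the sequence")


@dataclass
class GroundTruth:
    """What the renderer injected, for validating pipeline recovery."""

    waveform_pct: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    theta: np.ndarray
    onh_mask: np.ndarray
    vessel_mask: np.ndarray
    tissue_mask: np.ndarray
    blink_frames: frozenset[int]
    blur_frames: frozenset[int]

    def mask_in_reference(self, mask: np.ndarray, reference_index: int) -> np.ndarray:
        """Place a scene-coordinate mask into a registration's reference frame.

        Registered sequences live in the coordinates of their reference
        frame, which itself sits at that frame's motion offset — exactly
        where a manual mask drawn on the registered averaged image would
        live. Rotation of the reference frame is neglected (masks are
        tolerant to the sub-degree rotations simulated here).
        """
        from scipy.ndimage import shift as nd_shift

        dy, dx = self.dy[reference_index], self.dx[reference_index]
        return nd_shift(mask.astype(float), (dy, dx), order=0, cval=0.0) > 0.5

    def to_json(self, path: str | Path) -> None:
        rec = {
            "waveform_pct": self.waveform_pct.tolist(),
            "dx": self.dx.tolist(),
            "dy": self.dy.tolist(),
            "theta": self.theta.tolist(),
            "blink_frames": sorted(self.blink_frames),
            "blur_frames": sorted(self.blur_frames),
        }
        Path(path).write_text(json.dumps(rec))


def render_video(
    phantom: ScenePhantom,
    waveform_pct: np.ndarray,
    art: MotionArtifactSpec,
    fps: float = 25.0,
) -> tuple[VideoSequence, GroundTruth]:
    """Render a phantom video with the waveform injected on ONH tissue.

    Frame n before motion and noise is
    ``scene(p) * (1 - tissue_absorption_gain * a(n) / 100)`` on tissue
    pixels and ``scene(p)`` elsewhere; rigid motion is then applied, blink
    frames are overwritten with a near-saturated uniform level, blur frames
    are Gaussian-smoothed, and seeded Gaussian noise is added last.
    """
    waveform_pct = np.asarray(waveform_pct, dtype=float)
    n_frames = len(waveform_pct)
    art.validate(n_frames)

    scene = phantom.static_scene()
    gain = phantom.modulation_gain()
    rng = np.random.default_rng(art.seed)
    blink_level = art.blink_gain * phantom.background_level

    # The camera frame is a window onto a larger retina: render on a
    # reflect-padded scene and crop, so motion brings plausible content
    # into view instead of an artificial dark border.
    max_shift = max(np.abs(art.dx).max(), np.abs(art.dy).max(), 0.0)
    rot_slack = np.deg2rad(np.abs(art.theta).max()) * max(phantom.frame_shape) / 2.0
    pad = int(np.ceil(max_shift + rot_slack)) + 2
    scene_p = np.pad(scene, pad, mode="reflect")
    gain_p = np.pad(gain, pad, mode="constant", constant_values=0.0)
    crop = (slice(pad, pad + phantom.frame_shape[0]), slice(pad, pad + phantom.frame_shape[1]))

    frames = np.empty((n_frames,) + phantom.frame_shape)
    for n in range(n_frames):
        frame = scene_p * (1.0 - gain_p * waveform_pct[n] / 100.0)
        if art.dx[n] or art.dy[n] or art.theta[n]:
            frame = apply_rigid(frame, art.dx[n], art.dy[n], art.theta[n])
        frame = frame[crop]
        if n in art.blink_frames:
            frame = np.full(phantom.frame_shape, blink_level)
        elif n in art.blur_frames:
            frame = gaussian_filter(frame, sigma=art.blur_sigma)
        frames[n] = frame
    if art.noise_sd > 0:
        frames += rng.normal(0.0, art.noise_sd, size=frames.shape)

    video = VideoSequence(frames=frames, fps=fps)
    truth = GroundTruth(
        waveform_pct=waveform_pct,
        dx=np.asarray(art.dx, dtype=float),
        dy=np.asarray(art.dy, dtype=float),
        theta=np.asarray(art.theta, dtype=float),
        onh_mask=phantom.onh_mask(),
        vessel_mask=phantom.vessel_mask(),
        tissue_mask=phantom.tissue_mask(),
        blink_frames=frozenset(art.blink_frames),
        blur_frames=frozenset(art.blur_frames),
    )
    return video, truth


def default_vessel_tree(shape: tuple[int, int] = (100, 100)) -> list[tuple[tuple[int, int], tuple[int, int], int]]:
    """A simple branching tree crossing the disc, 3 px trunks."""
    r, c = shape[0] // 2, shape[1] // 2
    return [
        ((2, c - 6), (r, c), 3),
        ((r, c), (shape[0] - 3, c + 8), 3),
        ((r, c), (r + 12, 4), 2),
        ((r - 14, c - 2), (r - 30, c - 18), 2),
    ]
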