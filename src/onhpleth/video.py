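"""Video container and lossless I/O.

Fundus video sequences are short (~10 s at 25 frames/s), grayscale, and carry
per-frame quality flags that downstream stages (registration, pulse
selection) must honour. Sub-percent intensity signals do not survive lossy
codecs, so only lossless multi-page TIFF is read and written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import tifffile


class FrameFlag(str, Enum):
    OK = "ok"
    BLINK = "blink"
    BLUR = "blur"
    EDGE_LOSS = "edge_loss"


@dataclass
class VideoSequence:
    """Ordered stack of equally-timed grayscale frames.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Grayscale frames, float64 grey levels.
    fps : float
        Frame rate in frames per second.
    flags : list of FrameFlag
        Per-frame quality flag; defaults to all OK.
    valid : ndarray of bool, optional
        Per-frame per-pixel validity (False where a pixel fell outside the
        field of view after registration). ``None`` means all valid.
    """

    frames: np.ndarray
    fps: float
    flags: list[FrameFlag] = field(default_factory=list)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) stack")
        if self.n_frames < 2:
            raise ValueError("a video sequence needs at least 2 frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not self.flags:
            self.flags = [FrameFlag.OK] * self.n_frames
        if len(self.flags) != self.n_frames:
            raise ValueError("one quality flag per frame required")
        if self.valid is not None and self.valid.shape != self.frames.shape:
            raise ValueError("validity mask must match frame stack shape")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def ok_indices(self) -> np.ndarray:
        return np.array([i for i, f in enumerate(self.flags) if f == FrameFlag.OK], dtype=int)

    def frame_valid(self, n: int) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.frame_shape, dtype=bool)
        return self.valid[n]


def write_video(path: str | Path, video: VideoSequence, dtype: str = "uint16") -> None:
    """Write a sequence as multi-page grayscale TIFF (8 or 16 bit)."""
    if dtype not in ("uint8", "uint16"):
        raise ValueError("dtype must be 'uint8' or 'uint16'")
    info = np.iinfo(np.dtype(dtype))
    data = np.clip(np.round(video.frames), info.min, info.max).astype(dtype)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        metadata={"fps": video.fps, "wavelength_nm": 575},
    )


def read_video(path: str | Path, fps: float = 25.0) -> VideoSequence:
    """Read a multi-page TIFF video. AVI and other containers are rejected."""
    path = Path(path)
    if path.suffix.lower() in (".avi", ".mp4", ".mov", ".mkv"):
        raise ValueError(
            f"unsupported container {path.suffix!r}: compressed or codec-based video "
            "corrupts sub-percent intensity signals; convert to multi-page TIFF"
        )
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta = tif.shaped_metadata or tif.imagej_metadata
        if isinstance(meta, (list, tuple)) and meta:
            meta = meta[0]
        if isinstance(meta, dict) and "fps" in meta:
            fps = float(meta["fps"])
    if frames.ndim == 2:
        frames = frames[None]
    return VideoSequence(frames=frames.astype(np.float64), fps=fps)
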