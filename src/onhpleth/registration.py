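"""Rigid frame-to-frame registration and artifact flagging.

Eye movements during the ~10 s acquisition shift and rotate the retina on
the sensor; they must be removed before any per-pixel intensity averaging.
Translation is estimated by subpixel phase correlation; rotation by a
coarse grid search over derotation angles scored by masked normalized
cross-correlation, refined with a one-dimensional parabola fit through the
best score and its neighbours. Frames distorted by blinks (eyelid
reflection saturates the sensor) or motion/defocus blur are flagged — not
dropped — so pulse selection can avoid them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import sobel
from skimage.registration import phase_cross_correlation
from skimage.transform import warp

from .transform import apply_rigid, invert_rigid, rigid_tf
from .video import FrameFlag, VideoSequence


@dataclass
class MotionTrace:
    """Estimated per-frame rigid motion relative to the reference frame."""

    dx: np.ndarray
    dy: np.ndarray
    theta: np.ndarray
    confidence: np.ndarray
    reference_index: int

    def to_csv(self, path: str | Path, flags: list[FrameFlag] | None = None) -> None:
        df = pd.DataFrame(
            {
                "frame": np.arange(len(self.dx)),
                "dx_px": self.dx,
                "dy_px": self.dy,
                "theta_deg": self.theta,
                "confidence": self.confidence,
                "flag": [f.value for f in flags] if flags else ["ok"] * len(self.dx),
            }
        )
        df.to_csv(path, index=False)


def flag_artifacts(
    video: VideoSequence,
    blink_quantile: float = 0.98,
    blur_fraction: float = 0.5,
) -> list[FrameFlag]:
    """Classify frames as ok / blink / blur.

    blink: frame mean grey exceeds the ``blink_quantile`` quantile of the
    sequence's temporal-median frame (a frame dominated by eyelid
    reflection is brighter than almost every normal pixel; the median
    frame is insensitive to the blink frames themselves).
    blur: frame gradient energy below ``blur_fraction`` of the sequence
    median gradient energy.
    """
    sat_level = np.quantile(np.median(video.frames, axis=0), blink_quantile)
    means = video.frames.mean(axis=(1, 2))
    blink = means > sat_level

    grad_energy = np.empty(video.n_frames)
    for n in range(video.n_frames):
        gx = sobel(video.frames[n], axis=1)
        gy = sobel(video.frames[n], axis=0)
        grad_energy[n] = np.mean(gx * gx + gy * gy)
    ref_energy = np.median(grad_energy[~blink]) if (~blink).any() else np.median(grad_energy)
    blur = grad_energy < blur_fraction * ref_energy

    flags = []
    for n in range(video.n_frames):
        if blink[n]:
            flags.append(FrameFlag.BLINK)
        elif blur[n]:
            flags.append(FrameFlag.BLUR)
        else:
            flags.append(FrameFlag.OK)
    return flags


def _masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    if mask.sum() < 16:
        return 0.0
    av = a[mask] - a[mask].mean()
    bv = b[mask] - b[mask].mean()
    denom = np.sqrt((av * av).sum() * (bv * bv).sum())
    if denom == 0:
        return 0.0
    return float((av * bv).sum() / denom)


def _valid_mask(shape: tuple[int, int], dx: float, dy: float, theta: float, margin: int = 2) -> np.ndarray:
    ones = np.ones(shape)
    w = apply_rigid(ones, dx, dy, theta, order=1, cval=0.0)
    m = w > 0.999
    if margin:
        m[:margin] = m[-margin:] = False
        m[:, :margin] = m[:, -margin:] = False
    return m


def _translation_correction(reference: np.ndarray, moving: np.ndarray, upsample: int) -> tuple[float, float]:
    shift, _, _ = phase_cross_correlation(reference, moving, upsample_factor=upsample, normalization=None)
    # shift is the (row, col) displacement to apply to `moving` to align it
    return float(shift[1]), float(shift[0])  # (tx, ty) in (col, row)


def estimate_rigid(
    moving: np.ndarray,
    reference: np.ndarray,
    max_rotation_deg: float = 3.0,
    rotation_step_deg: float = 0.5,
    upsample: int = 50,
    rotation_skip_ncc: float = 0.995,
) -> tuple[float, float, float, float]:
    """Estimate the rigid motion (dx, dy, theta) of ``moving`` vs ``reference``.

    Returns ``(dx, dy, theta_deg, confidence)`` such that applying the
    inverse transform to ``moving`` aligns it with ``reference``.
    Confidence is the masked normalized cross-correlation after alignment,
    clipped to [0, 1]; constant frames get the identity with confidence 0.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError("frames must share one shape")
    if np.ptp(moving) == 0 or np.ptp(reference) == 0:
        return 0.0, 0.0, 0.0, 0.0

    def score(theta_c: float) -> tuple[float, tuple[float, float, float]]:
        derot = apply_rigid(moving, 0.0, 0.0, theta_c, mode="reflect") if theta_c else moving
        tx, ty = _translation_correction(reference, derot, upsample)
        corrected = apply_rigid(moving, tx, ty, theta_c, mode="reflect")
        mask = _valid_mask(moving.shape, tx, ty, theta_c)
        return _masked_ncc(reference, corrected, mask), (tx, ty, theta_c)

    ncc0, corr0 = score(0.0)
    best_ncc, best_corr = ncc0, corr0
    if max_rotation_deg > 0 and ncc0 < rotation_skip_ncc:
        thetas = np.arange(-max_rotation_deg, max_rotation_deg + 1e-9, rotation_step_deg)
        nccs = np.empty(len(thetas))
        corrs = []
        for i, th in enumerate(thetas):
            nccs[i], corr = score(float(th))
            corrs.append(corr)
        k = int(np.argmax(nccs))
        best_ncc, best_corr = nccs[k], corrs[k]
        # refine inside the bracket around the coarse winner
        lo = float(thetas[max(k - 1, 0)])
        hi = float(thetas[min(k + 1, len(thetas) - 1)])
        if hi > lo:
            from scipy.optimize import minimize_scalar

            res = minimize_scalar(
                lambda th: -score(float(th))[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 0.01},
            )
            ncc_r, corr_r = score(float(res.x))
            if ncc_r > best_ncc:
                best_ncc, best_corr = ncc_r, corr_r
        if ncc0 >= best_ncc:
            best_ncc, best_corr = ncc0, corr0

    tx, ty, theta_c = best_corr
    dx, dy, theta = invert_rigid(tx, ty, theta_c, moving.shape)
    return dx, dy, theta, float(np.clip(best_ncc, 0.0, 1.0))


def register_sequence(
    video: VideoSequence,
    max_rotation_deg: float = 3.0,
    confidence_threshold: float = 0.3,
    flag_first: bool = True,
    **kwargs,
) -> tuple[VideoSequence, MotionTrace]:
    """Resample every frame into the reference frame's coordinates.

    The reference is the temporally middle ok-flagged frame. Blink frames
    (near-constant, unregistrable) keep the identity transform; frames
    whose post-alignment correlation falls below ``confidence_threshold``
    are flagged ``edge_loss``. Out-of-field pixels introduced by the
    resampling are recorded in the output's validity mask.
    """
    flags = flag_artifacts(video) if flag_first else list(video.flags)
    ok = [i for i, f in enumerate(flags) if f == FrameFlag.OK]
    if not ok:
        raise RuntimeError(
            "registration impossible: no ok-flagged frame to use as reference "
            f"(flags: {[f.value for f in flags[:10]]} ...)"
        )
    ref_idx = ok[len(ok) // 2]
    reference = video.frames[ref_idx]

    n = video.n_frames
    dx = np.zeros(n)
    dy = np.zeros(n)
    theta = np.zeros(n)
    conf = np.zeros(n)
    out = np.empty_like(video.frames)
    valid = np.zeros(video.frames.shape, dtype=bool)

    for i in range(n):
        if i == ref_idx:
            out[i] = reference
            valid[i] = True
            conf[i] = 1.0
            continue
        if flags[i] == FrameFlag.BLINK:
            out[i] = video.frames[i]
            valid[i] = True
            continue
        dxi, dyi, thi, ci = estimate_rigid(
            video.frames[i], reference, max_rotation_deg=max_rotation_deg, **kwargs
        )
        dx[i], dy[i], theta[i], conf[i] = dxi, dyi, thi, ci
        # correction = inverse of the estimated motion; out-of-field pixels
        # are reflect-filled (plausible content, avoids a moving dark band
        # that would bias any later re-registration) but marked invalid
        tf = rigid_tf(dxi, dyi, thi, reference.shape)
        out[i] = warp(video.frames[i], tf, order=1, mode="reflect", preserve_range=True)
        valid[i] = warp(np.ones_like(reference), tf, order=1, mode="constant", cval=0.0) > 0.999
        if flags[i] == FrameFlag.OK and ci < confidence_threshold:
            flags[i] = FrameFlag.EDGE_LOSS

    registered = VideoSequence(frames=out, fps=video.fps, flags=flags, valid=valid)
    trace = MotionTrace(dx=dx, dy=dy, theta=theta, confidence=conf, reference_index=ref_idx)
    return registered, trace
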