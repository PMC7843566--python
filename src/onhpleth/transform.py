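"""Rigid (shift + rotation about frame centre) transforms on frames.

One shared convention for phantom rendering and registration: the forward
transform rotates the frame content by ``theta_deg`` counter-clockwise about
the frame centre and then shifts it by ``(dx, dy)`` pixels (columns, rows).
"""

from __future__ import annotations

import numpy as np
from skimage.transform import SimilarityTransform, warp


def rigid_tf(dx: float, dy: float, theta_deg: float, shape: tuple[int, int]) -> SimilarityTransform:
    """Forward similarity transform in image (x=col, y=row) coordinates."""
    centre = np.array([(shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0])
    to_origin = SimilarityTransform(translation=-centre)
    rotate = SimilarityTransform(rotation=np.deg2rad(theta_deg))
    back = SimilarityTransform(translation=centre + np.array([dx, dy]))
    return to_origin + rotate + back


def apply_rigid(
    img: np.ndarray,
    dx: float,
    dy: float,
    theta_deg: float,
    order: int = 1,
    mode: str = "constant",
    cval: float = 0.0,
) -> np.ndarray:
    """Move frame content by the forward rigid transform (bilinear by default)."""
    tf = rigid_tf(dx, dy, theta_deg, img.shape)
    return warp(img, tf.inverse, order=order, mode=mode, cval=cval, preserve_range=True)


def invert_rigid(dx: float, dy: float, theta_deg: float, shape: tuple[int, int]) -> tuple[float, float, float]:
    """Parameters of the inverse transform in the same (dx, dy, theta) form."""
    inv = rigid_tf(dx, dy, theta_deg, shape).inverse
    theta_inv = -theta_deg
    # residual translation after removing the centred rotation
    base = rigid_tf(0.0, 0.0, theta_inv, shape)
    delta = inv.params[:2, 2] - base.params[:2, 2]
    return float(delta[0]), float(delta[1]), float(theta_inv)
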