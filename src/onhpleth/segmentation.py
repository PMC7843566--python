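"""ONH-tissue ROI construction: averaging, masks, dilation, merging.

The analysis region is the microvascular tissue of the optic nerve head:
the ONH disc mask minus the large-vessel tree dilated by a small circular
element (vessel walls move and pulse, so their close surroundings are
excluded too). ONH segmentation is manual-first — a supplied mask is
validated and used as-is — with an automatic intensity-threshold fallback;
vessels are found by multiscale ridge filtering with hysteresis
thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.filters import apply_hysteresis_threshold, sato
import imageio.v3 as iio

from .video import VideoSequence


class MaskKind(str, Enum):
    ONH = "onh"
    VESSELS = "vessels"
    VESSELS_DILATED = "vessels_dilated"
    ONH_TISSUE_ROI = "onh_tissue_roi"


class MaskProvenance(str, Enum):
    MANUAL = "manual"
    AUTOMATIC = "automatic"
    MERGED = "merged"


@dataclass
class ROIMask:
    mask: np.ndarray
    kind: MaskKind
    provenance: MaskProvenance

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def write_png(self, path: str | Path) -> None:
        iio.imwrite(path, (self.mask * 255).astype(np.uint8))

    @classmethod
    def read_png(cls, path: str | Path, kind: MaskKind, provenance: MaskProvenance = MaskProvenance.MANUAL) -> "ROIMask":
        img = np.asarray(iio.imread(path))
        if img.ndim == 3:
            img = img[..., 0]
        return cls(mask=img > 127, kind=kind, provenance=provenance)


def average_frames(video: VideoSequence) -> np.ndarray:
    """Pixel-wise mean over ok-flagged frames, ignoring out-of-field pixels."""
    ok = video.ok_indices()
    if len(ok) == 0:
        raise RuntimeError("cannot average: no ok-flagged frames")
    acc = np.zeros(video.frame_shape)
    cnt = np.zeros(video.frame_shape)
    for n in ok:
        v = video.frame_valid(n)
        acc[v] += video.frames[n][v]
        cnt[v] += 1
    never_seen = cnt == 0
    cnt[never_seen] = 1
    avg = acc / cnt
    avg[never_seen] = np.nan
    return avg


def segment_onh(
    avg: np.ndarray,
    manual_mask: ROIMask | None = None,
    threshold_quantile: float = 0.90,
) -> ROIMask:
    """ONH disc mask: validate a manual mask, or threshold the averaged image.

    The automatic fallback thresholds at a brightness quantile (the disc is
    the brightest large structure), keeps the largest connected component,
    and takes its convex hull.
    """
    if manual_mask is not None:
        m = manual_mask.mask
        if m.shape != avg.shape:
            raise ValueError("manual ONH mask shape does not match the image")
        if not m.any():
            raise ValueError("manual ONH mask is empty")
        filled = ndi.binary_fill_holes(m)
        _, n_comp = ndi.label(filled)
        if n_comp != 1:
            raise ValueError(f"manual ONH mask must be a single blob, found {n_comp} components")
        return ROIMask(mask=m, kind=MaskKind.ONH, provenance=MaskProvenance.MANUAL)

    finite = np.nan_to_num(avg, nan=np.nanmin(avg))
    thr = np.quantile(finite, threshold_quantile)
    rough = finite > thr
    # bridge texture valleys so the disc survives as one component
    rough = morphology.closing(rough, morphology.disk(2))
    labels, n_comp = ndi.label(rough)
    if n_comp == 0:
        raise ValueError("automatic ONH segmentation found no bright region")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
    keep = labels == (1 + int(np.argmax(sizes)))
    hull = morphology.convex_hull_image(keep)
    return ROIMask(mask=hull, kind=MaskKind.ONH, provenance=MaskProvenance.AUTOMATIC)


def segment_vessels(
    avg: np.ndarray,
    sigmas=(1.0, 2.0, 3.0),
    low_fraction: float = 0.25,
    high_fraction: float = 0.55,
    min_contrast: float = 0.15,
    tophat_radius: int = 4,
    min_size: int = 20,
) -> ROIMask:
    """Vessel mask from multiscale ridge (vesselness) filtering.

    Vessels are thin, strongly absorbing (dark) elongated structures. The
    Sato tubeness filter (black ridges) provides the line response; it is
    gated by a morphological black top-hat so that only genuinely thin
    dark structures with a local dip of at least ``min_contrast`` of the
    dynamic range count — the edge of a large dark region (e.g. the fundus
    outside the bright disc) excites a ridge filter but not the top-hat.
    Hysteresis thresholding at fractions of the gated response maximum
    binarizes; speckle below ``min_size`` pixels is dropped. May
    legitimately return an empty mask on vessel-free images.
    """
    img = np.nan_to_num(avg, nan=float(np.nanmean(avg)))
    empty = ROIMask(np.zeros(img.shape, dtype=bool), MaskKind.VESSELS, MaskProvenance.AUTOMATIC)
    if np.ptp(img) == 0:
        return empty
    norm = (img - img.min()) / np.ptp(img)
    tophat = morphology.black_tophat(norm, morphology.disk(tophat_radius))
    gate = tophat > min_contrast
    if not gate.any():
        return empty
    response = sato(norm, sigmas=sigmas, black_ridges=True, mode="reflect") * gate
    peak = response.max()
    if peak <= 0:
        return empty
    binary = apply_hysteresis_threshold(response, low_fraction * peak, high_fraction * peak)
    labels, n_comp = ndi.label(binary)
    if n_comp:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
        keep = np.flatnonzero(sizes >= min_size) + 1
        binary = np.isin(labels, keep)
    return ROIMask(mask=binary, kind=MaskKind.VESSELS, provenance=MaskProvenance.AUTOMATIC)


def dilate_vessels(vessels: ROIMask, diameter_px: int = 5) -> ROIMask:
    """Dilate the vessel mask with a circular element of the given diameter."""
    if diameter_px < 1 or diameter_px % 2 == 0:
        raise ValueError("dilation diameter must be a positive odd pixel count")
    footprint = morphology.disk((diameter_px - 1) // 2)
    return ROIMask(
        mask=morphology.dilation(vessels.mask, footprint),
        kind=MaskKind.VESSELS_DILATED,
        provenance=vessels.provenance,
    )


def make_onh_roi(onh: ROIMask, vessels_dilated: ROIMask, min_pixels: int = 500) -> ROIMask:
    """ONH tissue ROI = ONH mask minus the dilated vessel mask."""
    if onh.mask.shape != vessels_dilated.mask.shape:
        raise ValueError("masks must share one shape")
    roi = onh.mask & ~vessels_dilated.mask
    if roi.sum() < min_pixels:
        raise RuntimeError(
            f"ONH tissue ROI has only {int(roi.sum())} pixels (< {min_pixels}); "
            "the aggregated signal would be noise-dominated"
        )
    return ROIMask(mask=roi, kind=MaskKind.ONH_TISSUE_ROI, provenance=MaskProvenance.MERGED)
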