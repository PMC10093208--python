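"""Per-frame mitochondrion segmentation and object filtering.

Binary masks are produced per channel (Otsu or fixed threshold); objects are
defined on the union of the two channel masks so that one object identity
carries both the green and the red measurement.  Surviving objects must pass
three filters: area bounds, minimum mean intensity, and an ROI-boundary rule
that removes objects truncated by the edge of the analysis region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "BinaryMask",
    "LabeledObjects",
    "SegmentationParams",
    "binarize_channel",
    "label_and_filter",
    "segment_frame",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholding and object-filter settings.

    ``roi`` is ``(row0, col0, row1, col1)`` with exclusive upper bounds; when
    ``None`` it defaults to the full frame inset by ``border_margin`` pixels.
    ``min_mean_intensity = 0`` adds no intensity filter beyond the threshold
    itself (mask pixels already sit at or above it).
    """

    threshold_method: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: float | None = None
    min_area: int = 4  # px
    max_area: int = 10**6  # px
    min_mean_intensity: float = 0.0
    roi: tuple[int, int, int, int] | None = None
    border_margin: int = 2  # px

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required with method='fixed'")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.max_area <= self.min_area:
            raise ValueError("max_area must exceed min_area")
        if self.border_margin < 0:
            raise ValueError("border_margin must be >= 0")

    def roi_slice(self, shape: tuple[int, int]) -> tuple[int, int, int, int]:
        if self.roi is not None:
            r0, c0, r1, c1 = self.roi
            if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
                raise ValueError("roi must lie within the image")
            return r0, c0, r1, c1
        m = self.border_margin
        if 2 * m >= min(shape):
            raise ValueError("border_margin leaves no ROI")
        return m, m, shape[0] - m, shape[1] - m


@dataclass
class BinaryMask:
    """Thresholding result; ``degenerate`` flags a constant image under Otsu."""

    mask: np.ndarray
    threshold: float
    degenerate: bool = False


@dataclass
class LabeledObjects:
    """Filtered connected components of one frame.

    Labels are positive and contiguous (1..K); every surviving label passed
    the area, intensity and ROI-boundary filters.
    """

    frame_index: int
    labels: np.ndarray  # (H, W) int, 0 = background
    channel: Literal["green", "red", "union"] = "union"

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def pixel_sets(self) -> dict[int, np.ndarray]:
        """Label -> (n, 2) array of (row, col) pixel coordinates."""
        out: dict[int, np.ndarray] = {}
        for lab in range(1, self.n_objects + 1):
            out[lab] = np.argwhere(self.labels == lab)
        return out

    def centroids(self, pixel_size: float = 1.0) -> dict[int, np.ndarray]:
        """Label -> centroid in physical units ((y, x), µm if pixel_size in µm)."""
        return {
            p.label: np.asarray(p.centroid) * pixel_size
            for p in regionprops(self.labels)
        }


def binarize_channel(frame: np.ndarray, params: SegmentationParams) -> BinaryMask:
    """Threshold one channel frame into a foreground mask.

    A pixel is foreground iff its intensity is >= the threshold.  A constant
    image under Otsu has no between-class structure: the result is an empty
    mask flagged ``degenerate``.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("frame is empty")
    if params.threshold_method == "fixed":
        thr = float(params.fixed_threshold)  # type: ignore[arg-type]
    else:
        if np.ptp(frame) == 0:
            return BinaryMask(np.zeros(frame.shape, bool), float(frame.flat[0]), True)
        thr = float(threshold_otsu(frame))
    return BinaryMask(frame >= thr, thr, False)


def label_and_filter(
    mask: np.ndarray,
    frame: np.ndarray,
    params: SegmentationParams,
    frame_index: int = 0,
    channel: Literal["green", "red", "union"] = "union",
) -> LabeledObjects:
    """Label 8-connected components and apply the three object filters.

    Removes components whose area falls outside ``[min_area, max_area]``,
    whose mean intensity in ``frame`` is below ``min_mean_intensity``, or
    which are truncated by the ROI boundary (any pixel outside the ROI or
    4-adjacent to a pixel outside it).  Survivors are renumbered 1..K in
    scan order.
    """
    mask = np.asarray(mask, bool)
    frame = np.asarray(frame)
    if mask.shape != frame.shape:
        raise ValueError("mask and frame shapes differ")
    r0, c0, r1, c1 = params.roi_slice(mask.shape)
    inside = np.zeros(mask.shape, bool)
    inside[r0:r1, c0:c1] = True
    # ROI interior = inside pixels with all 4-neighbours also inside
    interior = inside.copy()
    interior[r0, c0:c1] = False
    interior[r1 - 1, c0:c1] = False
    interior[r0:r1, c0] = False
    interior[r0:r1, c1 - 1] = False

    raw = cc_label(mask, connectivity=2)  # 8-connectivity
    out = np.zeros_like(raw)
    nxt = 1
    for p in regionprops(raw, intensity_image=frame):
        if not (params.min_area <= p.area <= params.max_area):
            continue
        if p.intensity_mean < params.min_mean_intensity:
            continue
        rr, cc = p.coords[:, 0], p.coords[:, 1]
        if not interior[rr, cc].all():
            continue
        out[rr, cc] = nxt
        nxt += 1
    return LabeledObjects(frame_index, out, channel)


def segment_frame(
    green: np.ndarray,
    red: np.ndarray,
    params: SegmentationParams,
    frame_index: int = 0,
) -> LabeledObjects:
    """Segment one dual-channel frame on the union of both channel masks.

    Each channel is thresholded independently; the union of the two masks
    defines object identity, so green and red means are later measured over
    the same pixels.  Intensity filtering uses the green channel.
    """
    g = binarize_channel(green, params)
    r = binarize_channel(red, params)
    union = g.mask | r.mask
    return label_and_filter(union, green, params, frame_index, channel="union")
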