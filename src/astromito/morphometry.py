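"""Per-mitochondrion morphometry and redox-state measurement.

All shape parameters are measured on a single object's binary mask (taken from
the first frame of a sequence):

* ``area`` — mask pixel count scaled by the pixel area (µm²).
* ``length`` — geodesic length of the skeleton's longest path plus one object
  width.  The medial axis of an elongated object stops about one half-width
  short of each tip, so adding the width restores tip-to-tip length.  Objects
  too small to skeletonize fall back to the fitted-ellipse major axis.
* ``width`` — twice the mean distance-transform value along the skeleton:
  the classic ridge width, near-unbiased for curved and branched shapes.
* ``elongation`` — length / width, exactly.
* ``n_branches`` — number of skeleton segments between endpoints/junctions.
* ``redox_ratio`` — mean red / mean green intensity within the mask, after
  optional background subtraction; reports the oxidation history of the
  MitoTimer biosensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.measure import regionprops
from skimage.morphology import skeletonize

__all__ = [
    "CellRecord",
    "MitoFeatures",
    "UndefinedValueError",
    "count_branches",
    "elongation_factor",
    "measure_frame",
    "measure_object",
    "redox_ratio",
    "skeleton_longest_path",
    "summarize_cell",
]

SUMMARY_PARAMS = ("area", "length", "elongation", "n_branches", "redox_ratio")


class UndefinedValueError(ValueError):
    """A measurement is mathematically undefined for the given input."""


@dataclass
class MitoFeatures:
    """Morphology and photometry of one mitochondrion (first frame)."""

    cell_id: str
    timepoint: str
    object_id: int
    area: float  # µm²
    length: float  # µm
    width: float  # µm
    elongation: float  # length / width
    n_branches: int
    mean_green: float
    mean_red: float
    redox_ratio: float | None  # None when mean_green <= 0 (excluded object)
    centroid: tuple[float, float]  # (y, x) µm


@dataclass
class CellRecord:
    """Cell-level summary over its measured mitochondria.

    ``qc_pass`` requires at least ``qc_min`` mitochondria (default 50),
    matching the quality gate used for per-cell MitoTimer statistics.
    """

    cell_id: str
    condition: str
    timepoint: str
    n_mitochondria: int
    means: dict[str, float]
    medians: dict[str, float]
    qc_pass: bool


# ---------------------------------------------------------------------------
# skeleton utilities

_SQRT2 = math.sqrt(2.0)


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """8-connected pixel graph of a skeleton; edge weights 1 or sqrt(2)."""
    g = nx.Graph()
    coords = np.argwhere(skel)
    pix = {tuple(c) for c in map(tuple, coords)}
    for y, x in pix:
        g.add_node((y, x))
    for y, x in pix:
        for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
            n = (y + dy, x + dx)
            if n in pix:
                g.add_edge((y, x), n, weight=1.0 if dy * dx == 0 else _SQRT2)
    return g


def skeleton_longest_path(mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Longest geodesic path length (px) along the mask's skeleton.

    Returns ``(length_px, skeleton)``.  Exact on tree-shaped skeletons
    (the diameter over endpoint pairs); cycles are handled by falling back
    to all nodes as candidate endpoints.
    """
    skel = skeletonize(np.asarray(mask, bool))
    g = _skeleton_graph(skel)
    if g.number_of_nodes() <= 1:
        return 0.0, skel
    best = 0.0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        ends = [n for n in sub if sub.degree(n) <= 1] or list(sub.nodes)[:1]
        # double-sweep: farthest node from an arbitrary endpoint, then again
        for _ in range(2):
            dist = nx.single_source_dijkstra_path_length(sub, ends[0])
            far, d = max(dist.items(), key=lambda kv: kv[1])
            ends = [far]
            best = max(best, d)
    return best, skel


def count_branches(mask: np.ndarray) -> int:
    """Number of skeleton segments between endpoints/junctions.

    A junction-free skeleton (straight or curved filament, or a single
    pixel) counts as one branch; a Y-shaped skeleton counts three.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("object mask is empty")
    skel = skeletonize(mask)
    g = _skeleton_graph(skel)
    if g.number_of_nodes() == 0:
        return 1
    junctions = [n for n in g if g.degree(n) >= 3]
    if not junctions:
        return 1
    pruned = g.copy()
    pruned.remove_nodes_from(junctions)
    n = sum(1 for _ in nx.connected_components(pruned))
    return max(n, 1)


# ---------------------------------------------------------------------------
# scalar measures


def elongation_factor(length: float, width: float) -> float:
    """Length-to-width ratio; >= 1 for any sensible elongated object."""
    if width <= 0:
        raise UndefinedValueError("width must be > 0")
    return length / width


def redox_ratio(mean_red: float, mean_green: float) -> float:
    """Mean red (555 nm) over mean green (488 nm) intensity."""
    if mean_green <= 0:
        raise UndefinedValueError("mean_green must be > 0")
    return mean_red / mean_green


# ---------------------------------------------------------------------------
# object and frame measurement


def measure_object(
    mask: np.ndarray,
    green: np.ndarray,
    red: np.ndarray,
    pixel_size: float,
    cell_id: str = "cell0",
    timepoint: str = "BL",
    object_id: int = 1,
    background: tuple[float, float] = (0.0, 0.0),
) -> MitoFeatures:
    """Measure one object's morphology and channel intensities.

    ``background`` is a per-channel (green, red) offset subtracted from the
    mean intensities before the ratio is formed; the ratio of an object whose
    background-corrected green mean is <= 0 is undefined and stored as None
    (such objects are excluded from ratio summaries rather than imputed).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("object mask is empty")
    if mask.shape != green.shape or mask.shape != red.shape:
        raise ValueError("mask and frames must share a shape")
    npx = int(mask.sum())
    area = npx * pixel_size**2

    mean_green = float(green[mask].mean()) - background[0]
    mean_red = float(red[mask].mean()) - background[1]
    ratio = mean_red / mean_green if mean_green > 0 else None

    n_br = count_branches(mask)
    skel_len_px, skel = skeleton_longest_path(mask)
    if npx >= 9 and skel_len_px >= 2.0:
        edt = distance_transform_edt(mask)
        width_px = max(2.0 * float(edt[skel].mean()), 1.0)
        length_px = skel_len_px + width_px
    else:
        props = regionprops(mask.astype(np.uint8))[0]
        length_px = max(props.axis_major_length, 1.0)
        width_px = max(props.axis_minor_length, 1.0)
    length = length_px * pixel_size
    width = width_px * pixel_size
    yc, xc = np.argwhere(mask).mean(axis=0)
    return MitoFeatures(
        cell_id=cell_id,
        timepoint=timepoint,
        object_id=object_id,
        area=area,
        length=length,
        width=width,
        elongation=length / width,
        n_branches=n_br,
        mean_green=mean_green,
        mean_red=mean_red,
        redox_ratio=ratio,
        centroid=(float(yc) * pixel_size, float(xc) * pixel_size),
    )


def estimate_background(frame: np.ndarray) -> float:
    """Median-based background estimate (objects cover a minority of pixels)."""
    return float(np.median(frame))


def measure_frame(
    labeled,
    green: np.ndarray,
    red: np.ndarray,
    pixel_size: float,
    cell_id: str = "cell0",
    timepoint: str = "BL",
    background_subtract: bool = True,
) -> list[MitoFeatures]:
    """Measure every labeled object of one frame."""
    bg = (
        (estimate_background(green), estimate_background(red))
        if background_subtract
        else (0.0, 0.0)
    )
    out = []
    for lab in range(1, labeled.n_objects + 1):
        out.append(
            measure_object(
                labeled.labels == lab,
                green,
                red,
                pixel_size,
                cell_id=cell_id,
                timepoint=timepoint,
                object_id=lab,
                background=bg,
            )
        )
    return out


# ---------------------------------------------------------------------------
# cell-level aggregation


def summarize_cell(
    features: Sequence[MitoFeatures],
    qc_min: int = 50,
    condition: str = "control",
) -> CellRecord:
    """Aggregate per-object features to one cell record (mean and median).

    Objects with an undefined redox ratio contribute to every summary except
    the ratio's.  ``qc_pass`` is true iff the cell holds at least ``qc_min``
    mitochondria.
    """
    if not features:
        raise ValueError("no features to summarize")
    cell_ids = {f.cell_id for f in features}
    tps = {f.timepoint for f in features}
    if len(cell_ids) > 1 or len(tps) > 1:
        raise ValueError("features must share cell_id and timepoint")
    means: dict[str, float] = {}
    medians: dict[str, float] = {}
    for p in SUMMARY_PARAMS:
        if p == "redox_ratio":
            vals = [f.redox_ratio for f in features if f.redox_ratio is not None]
        else:
            vals = [getattr(f, p) for f in features]
        if vals:
            means[p] = float(np.mean(vals))
            medians[p] = float(np.median(vals))
        else:
            means[p] = math.nan
            medians[p] = math.nan
    n = len(features)
    return CellRecord(
        cell_id=next(iter(cell_ids)),
        condition=condition,
        timepoint=next(iter(tps)),
        n_mitochondria=n,
        means=means,
        medians=medians,
        qc_pass=n >= qc_min,
    )
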