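"""End-to-end analysis of a dual-channel sequence into cell-level parameters.

One :class:`~astromito.simulate.FrameStack` (one cell at one timepoint) is
turned into:

* first-frame morphometry (area, length, elongation, branch count, redox
  ratio) aggregated over the cell's mitochondria,
* full-sequence tracking with displacement and speed over tracks that span
  the entire sequence,
* the fusion/fission event rate per particle from successive object counts,

yielding the tidy per-cell parameter rows consumed by the change-score
module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import EventEstimate, Track, estimate_event_rate, link_tracks, track_metrics
from .morphometry import CellRecord, MitoFeatures, measure_frame, summarize_cell
from .segment import LabeledObjects, SegmentationParams, segment_frame
from .simulate import FrameStack

__all__ = ["CellResult", "analyze_stack", "analyze_experiment", "cell_values_table"]


@dataclass
class CellResult:
    """All measurements of one cell at one timepoint."""

    cell_id: str
    condition: str
    timepoint: str
    features: list[MitoFeatures]
    record: CellRecord
    tracks: list[Track]
    full_tracks: list[Track]
    events: EventEstimate
    per_frame_objects: list[LabeledObjects]

    def parameter_values(self) -> dict[str, float]:
        """Cell-level value per scored parameter (means over mitochondria/tracks)."""
        vals = dict(self.record.means)
        vals.pop("width", None)
        disp_speed = [
            track_metrics(t, self._frame_interval) for t in self.full_tracks
        ]
        if disp_speed:
            vals["displacement"] = float(np.mean([d for d, _ in disp_speed]))
            vals["speed"] = float(np.mean([s for _, s in disp_speed]))
        else:
            vals["displacement"] = float("nan")
            vals["speed"] = float("nan")
        vals["event_rate"] = self.events.event_rate_per_particle
        return vals

    _frame_interval: float = 1.0


def analyze_stack(
    stack: FrameStack,
    seg_params: SegmentationParams | None = None,
    gating_radius: float = 1.0,
    qc_min: int = 50,
    background_subtract: bool = True,
) -> CellResult:
    """Run segmentation, morphometry, tracking and event-rate estimation."""
    params = seg_params or SegmentationParams()
    cfg = stack.config
    per_frame: list[LabeledObjects] = [
        segment_frame(stack.green[t], stack.red[t], params, frame_index=t)
        for t in range(stack.n_frames)
    ]
    features = measure_frame(
        per_frame[0],
        stack.green[0],
        stack.red[0],
        cfg.pixel_size,
        cell_id=stack.cell_id,
        timepoint=stack.timepoint,
        background_subtract=background_subtract,
    )
    record = summarize_cell(features, qc_min=qc_min, condition=stack.condition)
    tracks = link_tracks(per_frame, cfg.pixel_size, gating_radius=gating_radius)
    full = [t for t in tracks if t.spans(stack.n_frames)]
    counts = [lo.n_objects for lo in per_frame]
    events = estimate_event_rate(counts)
    res = CellResult(
        cell_id=stack.cell_id,
        condition=stack.condition,
        timepoint=stack.timepoint,
        features=features,
        record=record,
        tracks=tracks,
        full_tracks=full,
        events=events,
        per_frame_objects=per_frame,
    )
    res._frame_interval = cfg.frame_interval
    return res


def cell_values_table(results: Iterable[CellResult]) -> pd.DataFrame:
    """Tidy (cell_id, condition, timepoint, parameter, value) rows."""
    rows = []
    for r in results:
        for param, value in r.parameter_values().items():
            rows.append(
                {
                    "cell_id": r.cell_id,
                    "condition": r.condition,
                    "timepoint": r.timepoint,
                    "parameter": param,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def analyze_experiment(
    stacks: Sequence[FrameStack],
    seg_params: SegmentationParams | None = None,
    gating_radius: float = 1.0,
    qc_min: int = 50,
) -> tuple[list[CellResult], pd.DataFrame]:
    """Analyze many stacks and return results plus the tidy value table."""
    results = [
        analyze_stack(s, seg_params=seg_params, gating_radius=gating_radius, qc_min=qc_min)
        for s in stacks
    ]
    return results, cell_values_table(results)
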