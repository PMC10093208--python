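"""Mitochondrial dynamics: tracking, motility metrics and event rates.

Objects are linked frame to frame by optimal bipartite assignment on centroid
distance (gated), tracks spanning the whole sequence yield displacement and
speed, and the fusion/fission activity of a sequence is estimated from the
successive object counts normalized to the mean object count — the event rate
per particle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "EventEstimate",
    "Track",
    "estimate_event_rate",
    "link_tracks",
    "track_metrics",
]


@dataclass
class Track:
    """One linked trajectory: ordered (frame, object label, centroid µm)."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    object_ids: list[int] = field(default_factory=list)
    centroids: list[np.ndarray] = field(default_factory=list)  # (y, x) µm

    def append(self, frame: int, object_id: int, centroid: np.ndarray) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("frames must be strictly increasing")
        self.frames.append(frame)
        self.object_ids.append(object_id)
        self.centroids.append(np.asarray(centroid, float))

    @property
    def n_obs(self) -> int:
        return len(self.frames)

    def spans(self, n_frames: int) -> bool:
        return self.n_obs == n_frames

    @property
    def displacement(self) -> float:
        """Distance (µm) between the track's beginning and end."""
        if self.n_obs < 2:
            raise ValueError("displacement undefined for < 2 observations")
        return float(np.linalg.norm(self.centroids[-1] - self.centroids[0]))

    @property
    def path_length(self) -> float:
        steps = np.diff(np.asarray(self.centroids), axis=0)
        return float(np.linalg.norm(steps, axis=1).sum())


def link_tracks(
    frames_objects: Sequence,
    pixel_size: float,
    gating_radius: float = 1.0,
) -> list[Track]:
    """Link per-frame labeled objects into tracks.

    ``frames_objects`` is a sequence of :class:`~astromito.segment.LabeledObjects`
    (one per frame, in order).  Assignment between consecutive frames
    minimizes total centroid displacement (optimal bipartite matching) with
    links longer than ``gating_radius`` (µm) forbidden.  Unmatched objects
    terminate or start tracks; an empty frame terminates all open tracks.
    """
    if len(frames_objects) < 2:
        raise ValueError("need at least 2 frames to link")
    if gating_radius <= 0:
        raise ValueError("gating_radius must be > 0")

    tracks: list[Track] = []
    open_tracks: dict[int, Track] = {}  # keyed by current object label
    next_id = 0

    def _centroids(lo) -> tuple[list[int], np.ndarray]:
        cen = lo.centroids(pixel_size)
        labs = sorted(cen)
        pts = np.array([cen[lab] for lab in labs]) if labs else np.empty((0, 2))
        return labs, pts

    labs_prev, pts_prev = _centroids(frames_objects[0])
    for lab, pt in zip(labs_prev, pts_prev):
        tr = Track(next_id)
        tr.append(0, lab, pt)
        open_tracks[lab] = tr
        next_id += 1

    for t in range(1, len(frames_objects)):
        labs_new, pts_new = _centroids(frames_objects[t])
        assigned_new: dict[int, Track] = {}
        if labs_prev and labs_new:
            d = np.linalg.norm(
                pts_prev[:, None, :] - pts_new[None, :, :], axis=2
            )
            big = gating_radius * 1e6 + d.max() + 1.0
            cost = np.where(d <= gating_radius, d, big)
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if d[i, j] <= gating_radius:
                    tr = open_tracks[labs_prev[i]]
                    tr.append(t, labs_new[j], pts_new[j])
                    assigned_new[labs_new[j]] = tr
        # terminated tracks move to the output; unmatched new objects start
        for lab in labs_prev:
            tr = open_tracks[lab]
            if tr.frames[-1] != t:
                tracks.append(tr)
        open_tracks = assigned_new
        for j, lab in enumerate(labs_new):
            if lab not in open_tracks:
                tr = Track(next_id)
                tr.append(t, lab, pts_new[j])
                open_tracks[lab] = tr
                next_id += 1
        labs_prev, pts_prev = labs_new, pts_new

    tracks.extend(open_tracks.values())
    tracks.sort(key=lambda tr: tr.track_id)
    return tracks


def track_metrics(track: Track, frame_interval: float) -> tuple[float, float]:
    """(displacement µm, average speed µm/s) of one track.

    Displacement is first-to-last centroid distance; speed is the mean step
    length per frame interval (path length over elapsed time).
    """
    if track.n_obs < 2:
        raise ValueError("metrics undefined for single-observation tracks")
    duration = (track.frames[-1] - track.frames[0]) * frame_interval
    return track.displacement, track.path_length / duration


@dataclass
class EventEstimate:
    """Fusion/fission activity inferred from per-frame object counts.

    ``n_events`` is the sum of absolute successive count changes; dividing by
    the mean object count gives the event rate per particle.  Count drops are
    fusion candidates, rises fission candidates.
    """

    counts: np.ndarray
    mean_count: float
    n_events: int
    n_fusion_candidates: int
    n_fission_candidates: int
    event_rate_per_particle: float
    degenerate: bool = False  # mean_count == 0


def estimate_event_rate(counts: Sequence[int]) -> EventEstimate:
    """Estimate the per-particle fusion/fission event rate from object counts."""
    counts = np.asarray(counts, float)
    if counts.size == 0:
        raise ValueError("counts is empty")
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    diffs = np.diff(counts)
    n_events = int(np.abs(diffs).sum())
    n_fusion = int(-diffs[diffs < 0].sum())
    n_fission = int(diffs[diffs > 0].sum())
    mean_count = float(counts.mean())
    if mean_count > 0:
        rate = n_events / mean_count
        degenerate = False
    else:
        rate = 0.0
        degenerate = True
    return EventEstimate(
        counts=counts,
        mean_count=mean_count,
        n_events=n_events,
        n_fusion_candidates=n_fusion,
        n_fission_candidates=n_fission,
        event_rate_per_particle=rate,
        degenerate=degenerate,
    )
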