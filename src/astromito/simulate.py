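"""Synthetic dual-channel MitoTimer time-lapse generator with ground truth.

Generates fields of elongated (optionally branched) mitochondria rendered as
capsules convolved with a Gaussian PSF, in two correlated intensity channels
(red = ratio x green before noise), with Brownian + drift motion, scheduled or
stochastic fusion/fission events, Poisson shot noise, Gaussian read noise and
16-bit quantization.  Every rendered parameter is recorded in a
:class:`MitoGroundTruth` so downstream segmentation, morphometry, tracking and
scoring can be tested by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "AcquisitionConfig",
    "FieldParams",
    "FrameStack",
    "LognormalComponent",
    "MitoEvent",
    "MitoGroundTruth",
    "MitoTruth",
    "ParticleSample",
    "simulate_field",
    "simulate_particle_sample",
    "simulate_timepoint_series",
]

Timepoint = Literal["BL", "6h", "24h"]
TIMEPOINTS: tuple[str, ...] = ("BL", "6h", "24h")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Imaging geometry and timing.

    Defaults follow the acquisition regime used for astrocytic MitoTimer
    imaging: 16-bit sequences at 1 frame/s for 60 s.  The pixel pitch is a
    generator choice (high-magnification oil objective scale), not a claim.
    """

    pixel_size: float = 0.07  # µm per pixel
    frame_interval: float = 1.0  # s
    n_frames: int = 60
    image_shape: tuple[int, int] = (512, 512)  # (rows, cols) px
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if min(self.image_shape) < 64:
            raise ValueError("image dimensions must be >= 64 px")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")

    @property
    def max_dn(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval


@dataclass(frozen=True)
class MitoEvent:
    """One scheduled fusion or fission.

    ``frame`` is the first frame at which the change is visible, so the
    object count changes between ``frame - 1`` and ``frame``.
    """

    frame: int
    kind: Literal["fusion", "fission"]
    participants: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("fusion", "fission"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        n = len(self.participants)
        if self.kind == "fusion" and n != 2:
            raise ValueError("fusion needs exactly 2 participants")
        if self.kind == "fission" and n != 1:
            raise ValueError("fission needs exactly 1 participant")


@dataclass(frozen=True)
class FieldParams:
    """Population parameters of one simulated field (= one cell).

    Size/intensity distributions are lognormal, given as (median, sigma of
    the natural log).  Multiplying a median by ``s`` therefore shifts the
    population log-mean by exactly ``log s``, which is what the change-score
    recovery experiments rely on.
    """

    n_mitochondria: int = 80
    length_um: tuple[float, float] = (2.0, 0.30)  # tip-to-tip median, log-sd
    width_um: tuple[float, float] = (0.45, 0.10)
    green_intensity: tuple[float, float] = (300.0, 0.25)  # DN above background
    redox_ratio: tuple[float, float] = (1.0, 0.15)  # red/green median, log-sd
    branch_prob: float = 0.25
    branch_count_range: tuple[int, int] = (3, 4)  # >=3: a 2-arm elbow has no skeleton junction
    drift_velocity: tuple[float, float] = (0.0, 0.0)  # (vy, vx) µm/s, shared
    diffusion: float = 0.005  # µm²/s per object
    event_rate: float = 0.0  # events / particle / frame (Poisson)
    event_schedule: tuple[MitoEvent, ...] | None = None
    background: float = 100.0  # DN
    psf_sigma_px: float = 1.5
    shot_noise: bool = True
    read_noise: float = 2.0  # DN
    quantize: bool | None = None  # None -> quantize iff any noise is on
    max_overlap_fraction: float = 0.30
    min_separation_um: float = 0.4  # surface-to-surface gap at placement
    border_margin_um: float = 1.5  # keep initial centroids off the edge

    def __post_init__(self) -> None:
        if self.n_mitochondria < 1:
            raise ValueError("n_mitochondria must be >= 1")
        for name in ("length_um", "width_um", "green_intensity", "redox_ratio"):
            med, sd = getattr(self, name)
            if med <= 0 or sd < 0:
                raise ValueError(f"{name} needs positive median, sd >= 0")
        if not 0 <= self.branch_prob <= 1:
            raise ValueError("branch_prob in [0, 1]")
        if self.diffusion < 0 or self.event_rate < 0 or self.read_noise < 0:
            raise ValueError("diffusion, event_rate, read_noise must be >= 0")

    @property
    def noisy(self) -> bool:
        return self.shot_noise or self.read_noise > 0

    @property
    def do_quantize(self) -> bool:
        return self.noisy if self.quantize is None else self.quantize


@dataclass
class FrameStack:
    """One cell's dual-channel image sequence plus acquisition metadata."""

    green: np.ndarray  # (T, H, W)
    red: np.ndarray  # (T, H, W)
    config: AcquisitionConfig
    cell_id: str = "cell0"
    condition: str = "control"
    timepoint: str = "BL"

    def __post_init__(self) -> None:
        if self.green.shape != self.red.shape:
            raise ValueError("green and red stacks must share a shape")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        if self.green.min() < 0 or self.green.max() > self.config.max_dn:
            raise ValueError("green intensities outside [0, 2^bit_depth - 1]")
        if self.red.min() < 0 or self.red.max() > self.config.max_dn:
            raise ValueError("red intensities outside [0, 2^bit_depth - 1]")

    @property
    def n_frames(self) -> int:
        return self.green.shape[0]


@dataclass(frozen=True)
class MitoTruth:
    """True parameters of one initial mitochondrion."""

    id: int
    centroid_um: tuple[float, float]  # (y, x)
    length_um: float  # longest tip-to-tip path
    width_um: float
    orientation: float  # rad
    n_branches: int
    green_intensity: float  # amplitude, DN
    red_intensity: float  # = ratio * green
    redox_ratio: float


@dataclass
class MitoGroundTruth:
    """Simulator-side truth for one field: shapes, photometry, motion, events."""

    mitochondria: list[MitoTruth]
    drift_velocity: tuple[float, float]
    diffusion: float
    events: list[MitoEvent]
    live_counts: np.ndarray  # (T,) objects present per frame
    trajectories: dict[int, tuple[int, np.ndarray]]  # id -> (first frame, (n,2) µm)
    params: FieldParams
    config: AcquisitionConfig

    @property
    def n_initial(self) -> int:
        return len(self.mitochondria)

    def scheduled_count_changes(self) -> int:
        """Sum over frames of |count(t+1) - count(t)| implied by the schedule."""
        return int(np.abs(np.diff(self.live_counts)).sum())

    def true_cell_means(self) -> dict[str, float]:
        """Population means of the per-object truth (initial objects)."""
        m = self.mitochondria
        return {
            "length": float(np.mean([t.length_um for t in m])),
            "width": float(np.mean([t.width_um for t in m])),
            "elongation": float(np.mean([t.length_um / t.width_um for t in m])),
            "n_branches": float(np.mean([t.n_branches for t in m])),
            "redox_ratio": float(np.mean([t.redox_ratio for t in m])),
        }


# ---------------------------------------------------------------------------
# internal geometry


@dataclass
class _Capsule:
    # endpoints relative to the mito anchor, µm (y, x)
    p0: np.ndarray
    p1: np.ndarray
    radius: float  # µm

    def translated(self, delta: np.ndarray) -> "_Capsule":
        return _Capsule(self.p0 + delta, self.p1 + delta, self.radius)


@dataclass
class _Mito:
    id: int
    anchor: np.ndarray  # current position, µm (y, x)
    capsules: list[_Capsule]
    amp_green: float
    ratio: float
    alive: bool = True
    # fused-in partners; rendered with their own amplitude/ratio so the
    # merged object's integrated intensity is the exact sum of its parents'
    merged: list["_Mito"] = field(default_factory=list)

    def endpoints(self) -> np.ndarray:
        pts = []
        for c in self.capsules:
            pts.append(c.p0)
            pts.append(c.p1)
        return np.asarray(pts)

    def tip(self) -> np.ndarray:
        """Relative endpoint farthest from the anchor."""
        pts = self.endpoints()
        return pts[np.argmax(np.linalg.norm(pts, axis=1))]


def _unit(theta: float) -> np.ndarray:
    return np.array([math.sin(theta), math.cos(theta)])  # (dy, dx)


def _seg_seg_dist(p0, p1, q0, q1) -> float:
    """Minimum distance between two segments in the plane."""
    def _pt_seg(pt, a, b):
        v = b - a
        vv = float(v @ v)
        if vv == 0.0:
            return float(np.linalg.norm(pt - a))
        t = np.clip(float((pt - a) @ v) / vv, 0.0, 1.0)
        return float(np.linalg.norm(pt - (a + t * v)))

    d1 = p1 - p0
    d2 = q1 - q0
    r = p0 - q0
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    if a == 0.0 and e == 0.0:
        return float(np.linalg.norm(r))
    denom = a * e - float(d1 @ d2) ** 2
    if denom > 1e-12:
        c = float(d1 @ r)
        b = float(d1 @ d2)
        s = np.clip((b * f - c * e) / denom, 0.0, 1.0)
        t = np.clip((b * s + f) / e, 0.0, 1.0) if e > 0 else 0.0
        cand = float(np.linalg.norm((p0 + s * d1) - (q0 + t * d2)))
    else:
        cand = np.inf  # (near-)parallel: endpoint checks below suffice
    return min(
        cand,
        _pt_seg(p0, q0, q1),
        _pt_seg(p1, q0, q1),
        _pt_seg(q0, p0, p1),
        _pt_seg(q1, p0, p1),
    )


def _mito_clearance(a: _Mito, b: _Mito) -> float:
    """Surface-to-surface distance between two mitochondria (µm)."""
    best = np.inf
    for ca in a.capsules:
        for cb in b.capsules:
            d = _seg_seg_dist(
                a.anchor + ca.p0, a.anchor + ca.p1,
                b.anchor + cb.p0, b.anchor + cb.p1,
            )
            best = min(best, d - ca.radius - cb.radius)
    return best


def _sample_mito(
    rng: np.random.Generator, params: FieldParams, config: AcquisitionConfig, mid: int
) -> tuple[_Mito, MitoTruth]:
    h_um = config.image_shape[0] * config.pixel_size
    w_um = config.image_shape[1] * config.pixel_size
    m = params.border_margin_um
    anchor = np.array(
        [rng.uniform(m, h_um - m), rng.uniform(m, w_um - m)]
    )
    length = params.length_um[0] * math.exp(rng.normal(0.0, params.length_um[1]))
    width = params.width_um[0] * math.exp(rng.normal(0.0, params.width_um[1]))
    width = min(width, 0.9 * length)  # capsules need length > width
    r = width / 2.0
    amp = params.green_intensity[0] * math.exp(
        rng.normal(0.0, params.green_intensity[1])
    )
    ratio = params.redox_ratio[0] * math.exp(rng.normal(0.0, params.redox_ratio[1]))
    theta = rng.uniform(0.0, math.pi)

    branched = rng.random() < params.branch_prob
    if branched:
        lo, hi = params.branch_count_range
        n_br = int(rng.integers(lo, hi + 1))
    else:
        n_br = 1

    capsules: list[_Capsule] = []
    if n_br == 1:
        half = max(length - width, 0.1 * length) / 2.0  # centerline half-length
        u = _unit(theta)
        capsules.append(_Capsule(-half * u, half * u, r))
        true_len = 2 * half + width
    else:
        # arms share an endpoint at the anchor; angles spread so the skeleton
        # resolves each arm
        arm_c = max(length - width, 0.3 * length) / 2.0  # centerline per arm
        arm_c = max(arm_c, 1.5 * width)
        base = theta
        step = 2 * math.pi / n_br
        arm_lens = []
        for k in range(n_br):
            ang = base + k * step + rng.normal(0.0, 0.08)
            c = arm_c * math.exp(rng.normal(0.0, 0.15))
            capsules.append(_Capsule(np.zeros(2), c * _unit(ang), r))
            arm_lens.append(c)
        arm_lens.sort()
        true_len = arm_lens[-1] + arm_lens[-2] + width
    mito = _Mito(mid, anchor, capsules, amp, ratio)
    truth = MitoTruth(
        id=mid,
        centroid_um=(float(anchor[0]), float(anchor[1])),
        length_um=float(true_len),
        width_um=float(width),
        orientation=float(theta),
        n_branches=n_br,
        green_intensity=float(amp),
        red_intensity=float(ratio * amp),
        redox_ratio=float(ratio),
    )
    return mito, truth


def _render_capsule(
    img: np.ndarray, p0: np.ndarray, p1: np.ndarray, r_px: float, amp: float
) -> None:
    """Add an antialiased capsule (px coordinates, (y, x)) to ``img``."""
    h, w = img.shape
    lo = np.floor(np.minimum(p0, p1) - r_px - 1.5).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + r_px + 1.5).astype(int)
    y0, x0 = np.maximum(lo, 0)
    y1, x1 = np.minimum(hi + 1, (h, w))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = _dist_to_segment(yy, xx, p0, p1)
    cov = np.clip(r_px - d + 0.5, 0.0, 1.0)
    img[y0:y1, x0:x1] += amp * cov


def _dist_to_segment(yy, xx, p0, p1):
    v = p1 - p0
    vv = float(v @ v)
    dy = yy - p0[0]
    dx = xx - p0[1]
    if vv == 0.0:
        return np.hypot(dy, dx)
    t = np.clip((dy * v[0] + dx * v[1]) / vv, 0.0, 1.0)
    return np.hypot(dy - t * v[0], dx - t * v[1])


def _render_field(
    mitos: Sequence[_Mito], config: AcquisitionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free signal images (green, red) for the current state."""
    h, w = config.image_shape
    ps = config.pixel_size
    green = np.zeros((h, w))
    red = np.zeros((h, w))
    for m in mitos:
        if not m.alive:
            continue
        for c in m.capsules:
            p0 = (m.anchor + c.p0) / ps
            p1 = (m.anchor + c.p1) / ps
            r_px = c.radius / ps
            _render_capsule(green, p0, p1, r_px, m.amp_green)
            _render_capsule(red, p0, p1, r_px, m.amp_green * m.ratio)
    return green, red


def _object_mask(m: _Mito, config: AcquisitionConfig) -> np.ndarray:
    h, w = config.image_shape
    ps = config.pixel_size
    mask = np.zeros((h, w), bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for c in m.capsules:
        p0 = (m.anchor + c.p0) / ps
        p1 = (m.anchor + c.p1) / ps
        mask |= _dist_to_segment(yy, xx, p0, p1) <= c.radius / ps
    return mask


def _check_overlap(
    mitos: Sequence[_Mito], config: AcquisitionConfig, max_fraction: float
) -> None:
    total = 0
    paint = np.zeros(config.image_shape, np.int32)
    for m in mitos:
        mk = _object_mask(m, config)
        total += int(mk.sum())
        paint += mk
    if total == 0:
        return
    overlap = int(paint[paint > 1].sum() - (paint > 1).sum())
    frac = overlap / total
    if frac > max_fraction:
        raise ValueError(
            f"initial object overlap {frac:.1%} exceeds "
            f"{max_fraction:.0%}; reduce density or field size"
        )


# ---------------------------------------------------------------------------
# events


def _fuse(mitos: dict[int, _Mito], a_id: int, b_id: int) -> None:
    """Merge b into a, keeping each capsule's own amplitude via sub-mitos."""
    a, b = mitos[a_id], mitos[b_id]
    tip = a.tip()
    b_pts = b.endpoints()
    e = b_pts[np.argmin(np.linalg.norm(b_pts, axis=1))]
    shift = tip - e
    b.anchor = a.anchor.copy()
    b.capsules = [c.translated(shift) for c in b.capsules]
    b.alive = False
    a.merged.append(b)


def _split(
    mitos: dict[int, _Mito], a_id: int, new_id: int, gap_um: float
) -> _Mito:
    a = mitos[a_id]
    if len(a.capsules) >= 2:
        # detach the last arm; shift it along its own axis so the
        # surface-to-surface clearance from the junction is gap_um
        cap = a.capsules.pop()
        center = (cap.p0 + cap.p1) / 2.0
        v = cap.p1 - cap.p0
        n = float(np.linalg.norm(v))
        u = v / n if n > 0 else np.array([0.0, 1.0])
        shift = (gap_um + 2.0 * cap.radius) * u
        child_caps = [
            _Capsule(cap.p0 - center + shift, cap.p1 - center + shift, cap.radius)
        ]
        child = _Mito(new_id, a.anchor + center, child_caps, a.amp_green, a.ratio)
    else:
        # halve the capsule and translate the halves apart along the axis so
        # the surface-to-surface gap is gap_um regardless of object length
        cap = a.capsules[0]
        mid = (cap.p0 + cap.p1) / 2.0
        v = cap.p1 - cap.p0
        n = float(np.linalg.norm(v))
        u = v / n if n > 0 else np.array([0.0, 1.0])
        s = (gap_um + 2.0 * cap.radius) / 2.0
        a.capsules = [_Capsule(cap.p0 - s * u, mid - s * u, cap.radius)]
        child_caps = [_Capsule(s * u, cap.p1 - mid + s * u, cap.radius)]
        child = _Mito(new_id, a.anchor + mid, child_caps, a.amp_green, a.ratio)
    return child


# ---------------------------------------------------------------------------
# public operations


def simulate_field(
    config: AcquisitionConfig,
    params: FieldParams,
    seed: int | np.random.SeedSequence,
    cell_id: str = "cell0",
    condition: str = "control",
    timepoint: str = "BL",
) -> tuple[FrameStack, MitoGroundTruth]:
    """Render one dual-channel sequence and its ground truth.

    Identical ``(config, params, seed)`` yield bit-identical output.
    """
    rng = np.random.default_rng(seed)
    T = config.n_frames
    dt = config.frame_interval

    mitos: dict[int, _Mito] = {}
    truths: list[MitoTruth] = []
    h_um = config.image_shape[0] * config.pixel_size
    w_um = config.image_shape[1] * config.pixel_size
    margin = params.border_margin_um
    for i in range(params.n_mitochondria):
        m, t = _sample_mito(rng, params, config, i)
        if params.min_separation_um > 0:
            placed = False
            for _ in range(300):
                if all(
                    _mito_clearance(m, other) >= params.min_separation_um
                    for other in mitos.values()
                ):
                    placed = True
                    break
                m.anchor = np.array(
                    [rng.uniform(margin, h_um - margin),
                     rng.uniform(margin, w_um - margin)]
                )
            if not placed:
                raise ValueError(
                    "mitochondrion density too high: cannot place "
                    f"object {i} with {params.min_separation_um} um clearance"
                )
            t = replace(
                t, centroid_um=(float(m.anchor[0]), float(m.anchor[1]))
            )
        mitos[i] = m
        truths.append(t)
    next_id = params.n_mitochondria

    _check_overlap(list(mitos.values()), config, params.max_overlap_fraction)

    schedule: list[MitoEvent] = []
    if params.event_schedule is not None:
        known = set(mitos)
        for ev in params.event_schedule:
            if not 1 <= ev.frame <= T - 1:
                raise ValueError(f"event frame {ev.frame} outside [1, {T - 1}]")
            for pid in ev.participants:
                if pid not in known:
                    raise ValueError(f"event references unknown mitochondrion {pid}")
        schedule = sorted(params.event_schedule, key=lambda e: e.frame)

    green = np.zeros((T, *config.image_shape))
    red = np.zeros((T, *config.image_shape))
    live_counts = np.zeros(T, int)
    traj: dict[int, list[tuple[int, float, float]]] = {
        i: [] for i in mitos
    }
    executed: list[MitoEvent] = []
    drift = np.asarray(params.drift_velocity, float)
    step_sd = math.sqrt(2.0 * params.diffusion * dt)

    sched_idx = 0
    for t in range(T):
        if t > 0:
            # motion first, then events becoming visible at frame t
            for m in mitos.values():
                if m.alive:
                    m.anchor = m.anchor + drift * dt + rng.normal(0.0, step_sd, 2)
            live_ids = [i for i, m in mitos.items() if m.alive]
            events_now: list[MitoEvent] = []
            while sched_idx < len(schedule) and schedule[sched_idx].frame == t:
                events_now.append(schedule[sched_idx])
                sched_idx += 1
            if params.event_rate > 0:
                k = rng.poisson(params.event_rate * len(live_ids))
                for _ in range(k):
                    live_ids = [i for i, m in mitos.items() if m.alive]
                    if len(live_ids) >= 2 and rng.random() < 0.5:
                        a, b = rng.choice(live_ids, 2, replace=False)
                        events_now.append(MitoEvent(t, "fusion", (int(a), int(b))))
                    elif live_ids:
                        a = int(rng.choice(live_ids))
                        events_now.append(MitoEvent(t, "fission", (a,)))
            for ev in events_now:
                if ev.kind == "fusion":
                    a, b = ev.participants
                    if not (mitos[a].alive and mitos[b].alive) or a == b:
                        raise ValueError(f"fusion participants {a},{b} not both alive")
                    _fuse(mitos, a, b)
                else:
                    (a,) = ev.participants
                    if not mitos[a].alive:
                        raise ValueError(f"fission participant {a} not alive")
                    child = _split(mitos, a, next_id, gap_um=0.45)
                    mitos[next_id] = child
                    traj[next_id] = []
                    next_id += 1
                executed.append(ev)

        live = [m for m in mitos.values() if m.alive]
        live_counts[t] = len(live)
        for m in live:
            traj[m.id].append((t, float(m.anchor[0]), float(m.anchor[1])))
        render_set: list[_Mito] = []
        for m in live:
            render_set.append(m)
            render_set.extend(
                _Mito(m.id, m.anchor, sub.capsules, sub.amp_green, sub.ratio)
                for sub in m.merged  # type: ignore[attr-defined]
            )
        g, r = _render_field(render_set, config)
        if params.psf_sigma_px > 0:
            g = gaussian_filter(g, params.psf_sigma_px)
            r = gaussian_filter(r, params.psf_sigma_px)
        g = g + params.background
        r = r + params.background
        if params.shot_noise:
            g = rng.poisson(g).astype(float)
            r = rng.poisson(r).astype(float)
        if params.read_noise > 0:
            g = g + rng.normal(0.0, params.read_noise, g.shape)
            r = r + rng.normal(0.0, params.read_noise, r.shape)
        if params.do_quantize:
            g = np.clip(np.rint(g), 0, config.max_dn)
            r = np.clip(np.rint(r), 0, config.max_dn)
        else:
            g = np.clip(g, 0, config.max_dn)
            r = np.clip(r, 0, config.max_dn)
        green[t] = g
        red[t] = r

    stack = FrameStack(green, red, config, cell_id, condition, timepoint)
    gt = MitoGroundTruth(
        mitochondria=truths,
        drift_velocity=(float(drift[0]), float(drift[1])),
        diffusion=params.diffusion,
        events=executed,
        live_counts=live_counts,
        trajectories={
            i: (obs[0][0], np.array([(y, x) for _, y, x in obs]))
            for i, obs in traj.items()
            if obs
        },
        params=params,
        config=config,
    )
    return stack, gt


_SHIFTABLE = {
    "redox_ratio",
    "length",
    "width",
    "green_intensity",
    "event_rate",
    "diffusion",
    "drift_speed",
    "branch_prob",
}


def _shift_params(params: FieldParams, shifts: Mapping[str, float]) -> FieldParams:
    kw: dict = {}
    for name, s in shifts.items():
        if name not in _SHIFTABLE:
            raise ValueError(f"unknown effect parameter {name!r}")
        if s <= 0:
            raise ValueError("effect shifts must be > 0")
        if name == "redox_ratio":
            med, sd = params.redox_ratio
            kw["redox_ratio"] = (med * s, sd)
        elif name == "length":
            med, sd = params.length_um
            kw["length_um"] = (med * s, sd)
        elif name == "width":
            med, sd = params.width_um
            kw["width_um"] = (med * s, sd)
        elif name == "green_intensity":
            med, sd = params.green_intensity
            kw["green_intensity"] = (med * s, sd)
        elif name == "event_rate":
            kw["event_rate"] = params.event_rate * s
        elif name == "diffusion":
            kw["diffusion"] = params.diffusion * s
        elif name == "drift_speed":
            vy, vx = params.drift_velocity
            kw["drift_velocity"] = (vy * s, vx * s)
        elif name == "branch_prob":
            kw["branch_prob"] = min(params.branch_prob * s, 1.0)
    return replace(params, **kw)


def simulate_timepoint_series(
    config: AcquisitionConfig,
    baseline_params: FieldParams,
    effect_spec: Mapping[str, Mapping[str, float]],
    seed: int | np.random.SeedSequence,
    cell_id: str = "cell0",
    condition: str = "control",
    timepoints: Sequence[str] = TIMEPOINTS,
) -> list[tuple[FrameStack, MitoGroundTruth]]:
    """Simulate one cell at BL / 6h / 24h with multiplicative parameter shifts.

    ``effect_spec`` maps a parameter name (e.g. ``"redox_ratio"``) to
    per-timepoint shifts, e.g. ``{"redox_ratio": {"6h": 1.2, "24h": 1.5}}``.
    The true log change score of a shifted parameter at timepoint ``tp``
    equals ``log(shift)`` by construction.
    """
    for name, per_tp in effect_spec.items():
        for tp, s in per_tp.items():
            if tp not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {tp!r}")
            if s <= 0:
                raise ValueError("effect shifts must be > 0")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    children = ss.spawn(len(timepoints))
    out = []
    for tp, child in zip(timepoints, children):
        if tp not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {tp!r}")
        shifts = {
            name: per_tp[tp]
            for name, per_tp in effect_spec.items()
            if tp in per_tp
        }
        p = _shift_params(baseline_params, shifts) if shifts else baseline_params
        out.append(
            simulate_field(config, p, child, cell_id=cell_id,
                           condition=condition, timepoint=tp)
        )
    return out


# ---------------------------------------------------------------------------
# particle sizes (NTA-style)


@dataclass(frozen=True)
class LognormalComponent:
    """One mixture component of a particle-diameter distribution (nm)."""

    median_nm: float
    sigma_log: float
    weight: float


@dataclass
class ParticleSample:
    """Diameters (nm) of one nanoparticle-tracking-style measurement."""

    diameters: np.ndarray
    label: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, float)
        if self.diameters.size and self.diameters.min() <= 0:
            raise ValueError("diameters must be > 0")


def simulate_particle_sample(
    n: int,
    mixture: Sequence[LognormalComponent],
    seed: int | np.random.SeedSequence,
    label: str = "",
    condition: str = "",
) -> ParticleSample:
    """Draw ``n`` particle diameters from a lognormal mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not mixture:
        raise ValueError("mixture must have at least one component")
    w = np.array([c.weight for c in mixture], float)
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("component weights must be >= 0 and sum to 1")
    for c in mixture:
        if c.median_nm <= 0 or c.sigma_log < 0:
            raise ValueError("components need median_nm > 0 and sigma_log >= 0")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(mixture), size=n, p=w)
    med = np.array([c.median_nm for c in mixture])
    sig = np.array([c.sigma_log for c in mixture])
    d = med[comp] * np.exp(rng.normal(0.0, 1.0, n) * sig[comp])
    return ParticleSample(d, label=label, condition=condition)
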