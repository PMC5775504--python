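"""Seeded generators for tracks, residence times, and mask movies.

Every generator is deterministic under a fixed seed and emits ground truth
for each planted quantity so downstream metrics can be scored without
re-derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spot_survival import InteractionRecord
from .trackcore import DEFAULT_FRAME_INTERVAL, MaskSeries, SpotGrid, Track

__all__ = [
    "TwoStateParams",
    "GroundTruth",
    "simulate_two_state_track",
    "simulate_brownian_track",
    "simulate_residence_times",
    "simulate_spot_engagement_track",
    "render_mask_movie",
]

STATE_SYNAPSE = "synapse"
STATE_KINAPSE = "kinapse"


@dataclass
class TwoStateParams:
    """Parameters of the two-state (confined-dwell / persistent-walk) model.

    The planted stable-dwell fraction is
    ``dwell_synapse / (dwell_synapse + dwell_kinapse)``; dwell means are the
    stationary weights, so starting each track from the stationary state
    mixture makes the expected per-frame label fraction equal that value.

    Confined-state dwells are exponential.  Motile-state dwells are
    *shifted* exponential: ``min_dwell_kinapse`` plus an exponential with
    the remaining mean.  The offset guarantees that a motile bout relocates
    the cell beyond the confinement-detection length scale, so that
    successive confined zones are resolved as separate periods rather than
    merging into one large (and hence unstable-looking) zone.
    """

    speed_kinapse: float = 8.0  # μm/min
    persistence_time: float = 240.0  # s, heading decorrelation time
    confinement_radius: float = 2.0  # μm
    dwell_synapse: float = 600.0  # mean s in the confined state
    dwell_kinapse: float = 300.0  # mean s in the motile state
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    n_frames: int = 240
    seed: int = 0
    d_synapse: float = 0.06  # μm²/s, jitter inside the confined zone (large
    # enough that short-lag MSD reflects the zone size, keeping confinement
    # statistically detectable even on fully confined tracks)
    min_dwell_kinapse: float = 150.0  # s, offset of the motile dwell

    def __post_init__(self) -> None:
        for name in (
            "speed_kinapse",
            "persistence_time",
            "confinement_radius",
            "dwell_synapse",
            "dwell_kinapse",
            "frame_interval",
            "d_synapse",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.dwell_synapse, self.dwell_kinapse) < self.frame_interval:
            raise ValueError("dwell means must be >= frame_interval")
        if self.min_dwell_kinapse < 0 or self.min_dwell_kinapse >= self.dwell_kinapse:
            raise ValueError("min_dwell_kinapse must lie in [0, dwell_kinapse)")

    @property
    def stable_fraction(self) -> float:
        return self.dwell_synapse / (self.dwell_synapse + self.dwell_kinapse)


@dataclass
class GroundTruth:
    """Planted truth accompanying a synthetic track."""

    state: np.ndarray  # per-frame labels, aligned 1:1 with track frames
    stable_fraction: float
    attach_frame: int | None = None
    exit_frame: int | None = None
    spot_id: int | None = None
    half_life_h: float | None = None
    extra: dict = field(default_factory=dict)


def _make_track(cell_id: str, positions: np.ndarray, frame_interval: float,
                channels: dict | None = None) -> Track:
    n = len(positions)
    frames = np.arange(n)
    return Track(
        cell_id=cell_id,
        frames=frames,
        times=frames * frame_interval,
        positions=positions,
        channels=channels or {},
        frame_interval=frame_interval,
    )


def _reflect_into_disk(point: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Fold a point radially back inside the disk (repeated if necessary)."""
    for _ in range(16):
        r = np.linalg.norm(point - center)
        if r <= radius:
            return point
        point = center + (point - center) * (2 * radius - r) / r
        if r >= 2 * radius:  # fell through the far side: clamp
            point = center + (point - center) / max(np.linalg.norm(point - center), 1e-12) * radius
    return point


def simulate_two_state_track(params: TwoStateParams) -> tuple[Track, GroundTruth]:
    """Alternating dwells of confined and persistent motion.

    The motile state is a persistent random walk: the heading performs
    rotational diffusion with decorrelation time ``persistence_time`` while
    the step length is ``speed_kinapse * frame_interval``.  The confined
    state is a reflected Brownian walk (coefficient ``d_synapse``) within
    ``confinement_radius`` of the state's entry point.  The first state and
    its residual dwell are drawn from the stationary mixture (exponential
    dwells are memoryless), so the expected label fraction equals
    ``params.stable_fraction``.
    """
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval
    n = params.n_frames

    def draw_dwell(synapse: bool) -> float:
        if synapse:
            return rng.exponential(params.dwell_synapse)
        return params.min_dwell_kinapse + rng.exponential(
            params.dwell_kinapse - params.min_dwell_kinapse
        )

    # stationary initial state; the exponential residual-dwell draw is exact
    # for the confined state and a close approximation for the shifted
    # exponential of the motile state
    in_synapse = rng.random() < params.stable_fraction
    dwell_left = rng.exponential(params.dwell_synapse if in_synapse else params.dwell_kinapse)

    positions = np.zeros((n, 2))
    labels = np.empty(n, dtype=object)
    heading = rng.uniform(0, 2 * np.pi)
    sigma_h = np.sqrt(2 * dt / params.persistence_time)
    step_kin = params.speed_kinapse / 60.0 * dt  # μm per frame
    sigma_syn = np.sqrt(2 * params.d_synapse * dt)
    anchor = positions[0].copy()
    labels[0] = STATE_SYNAPSE if in_synapse else STATE_KINAPSE

    for i in range(1, n):
        dwell_left -= dt
        if dwell_left <= 0:
            in_synapse = not in_synapse
            dwell_left = draw_dwell(in_synapse)
            if in_synapse:
                anchor = positions[i - 1].copy()
        if in_synapse:
            step = rng.normal(0.0, sigma_syn, size=2)
            positions[i] = _reflect_into_disk(
                positions[i - 1] + step, anchor, params.confinement_radius
            )
        else:
            heading = heading + rng.normal(0.0, sigma_h)
            positions[i] = positions[i - 1] + step_kin * np.array(
                [np.cos(heading), np.sin(heading)]
            )
        labels[i] = STATE_SYNAPSE if in_synapse else STATE_KINAPSE

    track = _make_track(f"twostate-{params.seed}", positions, dt)
    truth = GroundTruth(
        state=labels.astype(str),
        stable_fraction=float(np.mean(labels == STATE_SYNAPSE)),
    )
    return track, truth


def simulate_brownian_track(
    D: float,
    n_frames: int,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    seed: int = 0,
    cell_id: str | None = None,
) -> Track:
    """Pure Brownian null track: i.i.d. Gaussian steps, per-axis variance 2·D·Δt."""
    if D < 0:
        raise ValueError("D must be non-negative")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2 * D * frame_interval), size=(n_frames - 1, 2))
    positions = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return _make_track(cell_id or f"brownian-{seed}", positions, frame_interval)


def simulate_residence_times(
    half_life_h: float,
    n_cells: int,
    horizon_h: float,
    seed: int = 0,
) -> list[InteractionRecord]:
    """Exponential spot-residence times with rate ln(2)/half_life.

    All cells attach at t = 0; lifetimes reaching the horizon are censored
    there.  Record times are seconds.
    """
    if half_life_h <= 0:
        raise ValueError("half_life must be positive")
    rng = np.random.default_rng(seed)
    lifetimes_h = rng.exponential(scale=half_life_h / np.log(2), size=n_cells)
    records = []
    for i, life in enumerate(lifetimes_h):
        censored = life >= horizon_h
        records.append(
            InteractionRecord(
                cell_id=f"cell-{i:04d}",
                spot_id=0,
                attach_time=0.0,
                exit_time=float(min(life, horizon_h) * 3600.0),
                censored=bool(censored),
            )
        )
    return records


def simulate_spot_engagement_track(
    grid: SpotGrid,
    spot_id: int,
    approach_speed: float = 12.0,  # μm/min
    arrest_frames: int = 60,
    n_frames: int = 120,
    start_distance: float = 20.0,  # μm from the spot centre
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    confinement_radius: float = 2.0,
    d_arrest: float = 0.002,  # μm²/s
    calcium_amplitude: float = 1.0,
    calcium_noise: float = 0.0,
    seed: int = 0,
) -> tuple[Track, GroundTruth]:
    """A cell approaching a spot, arresting on it, then departing.

    The cell moves ballistically toward the spot centre at
    ``approach_speed``, arrests (confined Brownian jitter) exactly when it
    reaches the centre, stays for ``arrest_frames`` frames, then departs
    ballistically.  A ``calcium_ratio`` channel steps from 1 to
    ``1 + calcium_amplitude`` during the arrest (plus optional Gaussian
    noise), and a ``cell_area`` channel steps from 80 to 150 μm².

    Ground truth carries the planted attach and exit frames.
    """
    rng = np.random.default_rng(seed)
    dt = frame_interval
    step = approach_speed / 60.0 * dt
    center = grid.centers[spot_id]
    n_approach = int(np.ceil(start_distance / step))
    attach_frame = n_approach
    exit_frame = attach_frame + arrest_frames
    if exit_frame >= n_frames:
        raise ValueError("n_frames too small for the requested approach + arrest")

    direction = np.array([1.0, 0.0])
    positions = np.zeros((n_frames, 2))
    pos = center - direction * start_distance
    sigma = np.sqrt(2 * d_arrest * dt)
    labels = np.empty(n_frames, dtype=object)
    for i in range(n_frames):
        if i < attach_frame:
            remaining = np.linalg.norm(center - pos)
            pos = pos + direction * min(step, remaining)
            labels[i] = "approach"
        elif i < exit_frame:
            pos = _reflect_into_disk(pos + rng.normal(0, sigma, 2), center, confinement_radius)
            labels[i] = "arrested"
        else:
            pos = pos + direction * step
            labels[i] = "departed"
        positions[i] = pos

    arrested = (np.arange(n_frames) >= attach_frame) & (np.arange(n_frames) < exit_frame)
    calcium = 1.0 + calcium_amplitude * arrested.astype(float)
    if calcium_noise > 0:
        calcium = calcium + rng.normal(0, calcium_noise, n_frames)
    area = 80.0 + 70.0 * arrested.astype(float)
    track = _make_track(f"engage-{seed}", positions, dt,
                        channels={"calcium_ratio": calcium, "cell_area": area})
    truth = GroundTruth(
        state=labels.astype(str),
        stable_fraction=float(arrested.mean()),
        attach_frame=attach_frame,
        exit_frame=exit_frame,
        spot_id=spot_id,
        extra={"calcium_amplitude": calcium_amplitude},
    )
    return track, truth


def render_mask_movie(
    track: Track,
    cell_radius: float,
    pixel_size: float,
    extent: Sequence[float],
) -> MaskSeries:
    """Disk-shaped cell masks rasterized by pixel-center inclusion.

    ``extent`` is ``(x0, y0, x1, y1)`` in μm.  Pixel (0, 0) is centred at
    ``(x0, y0)``.  Frames whose disk is clipped by the extent are flagged in
    the returned series' ``clipped`` attribute (a boolean array, attached
    dynamically).
    """
    if cell_radius <= pixel_size:
        raise ValueError("cell_radius must exceed pixel_size")
    x0, y0, x1, y1 = (float(v) for v in extent)
    w = int(np.floor((x1 - x0) / pixel_size)) + 1
    h = int(np.floor((y1 - y0) / pixel_size)) + 1
    xs = x0 + pixel_size * np.arange(w)
    ys = y0 + pixel_size * np.arange(h)
    xx, yy = np.meshgrid(xs, ys)
    n = len(track)
    masks = np.zeros((n, h, w), dtype=bool)
    clipped = np.zeros(n, dtype=bool)
    for i, (cx, cy) in enumerate(track.positions):
        masks[i] = (xx - cx) ** 2 + (yy - cy) ** 2 <= cell_radius**2
        if (cx - cell_radius < x0 or cx + cell_radius > x1
                or cy - cell_radius < y0 or cy + cell_radius > y1):
            clipped[i] = True
    series = MaskSeries(frames=track.frames.copy(), masks=masks,
                        pixel_size=pixel_size, origin=(x0, y0))
    series.clipped = clipped
    return series
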