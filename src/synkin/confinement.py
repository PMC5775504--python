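"""Transient-confinement detection and synapse/kinapse classification.

The per-frame confinement score ``L`` is a monotone decreasing transform of
``psi``, the estimated probability that the spatial restriction observed in a
window around the frame would arise by chance under free diffusion.  For a
window of duration ``t`` (s) in which the maximum displacement from the
window's first position is ``R`` (μm), and a track-level short-lag diffusion
coefficient ``D`` (μm²/s), the Simson-type stay-probability relation gives

    log10(psi) = 0.2048 - 2.5117 * D * t / R**2

clipped to (0, 1], and

    L = max(0, -ln(psi) - 1)

so that the demarcation threshold ``L > 3`` corresponds to
``psi < e**-4 ≈ 0.018``.  Maximal runs of frames with ``L`` above threshold
lasting at least ``min_duration`` frames become confinement periods; a period
is called *stable* (synapse-like) when its positional spread ``R**2 / t`` is
below ``spread_threshold`` (μm²/frame), with ``t`` in frames.  The positional
stability index of a track is the fraction of its frames inside stable
periods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .trackcore import MotionStats, Track, smoothed_speed

__all__ = [
    "SIMSON_INTERCEPT",
    "SIMSON_SLOPE",
    "DEFAULT_WINDOWS",
    "DEFAULT_L_THRESHOLD",
    "DEFAULT_SPREAD_THRESHOLD",
    "DEFAULT_MIN_DURATION",
    "ConfinementProfile",
    "ConfinedPeriod",
    "TrackClassification",
    "TrackConfinementResult",
    "estimate_diffusion",
    "confinement_score",
    "demarcate_confined_periods",
    "classify_stability",
    "positional_stability_index",
    "psi_to_score",
    "score_to_psi",
    "analyze_track",
]

SIMSON_INTERCEPT = 0.2048
SIMSON_SLOPE = 2.5117

DEFAULT_WINDOWS = (10, 15, 20, 25, 30)
DEFAULT_L_THRESHOLD = 3.0
DEFAULT_SPREAD_THRESHOLD = 0.666  # μm²/frame
DEFAULT_MIN_DURATION = 10  # frames
DEFAULT_L_MAX = 10.0
D_FLOOR = 1e-6  # μm²/s
DEFAULT_MAX_LAG = 2  # frames; short lags dodge confinement-saturation bias


@dataclass
class ConfinementProfile:
    """Per-frame confinement score and chance probability.

    ``L`` and ``psi`` are linked by the fixed transform
    ``L = max(0, -ln(psi) - 1)``; ``psi`` stored here is the value implied by
    the window-averaged ``L`` (``psi = exp(-(L + 1))`` where ``L > 0``,
    else 1).
    """

    L: np.ndarray
    psi: np.ndarray
    window_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if np.any(self.L < 0):
            raise ValueError("L must be non-negative")
        if np.any((self.psi <= 0) | (self.psi > 1)):
            raise ValueError("psi must lie in (0, 1]")


@dataclass
class ConfinedPeriod:
    """One maximal above-threshold run of frames.

    ``start`` and ``end`` are inclusive positional indices into the track
    arrays; ``t`` is the duration in frames (``end - start + 1``); ``R`` is
    the diameter of the confined zone (maximum pairwise displacement, μm);
    ``spread = R**2 / t`` in μm²/frame.
    """

    start: int
    end: int
    t: int
    R: float
    spread: float
    stable: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end must be >= start")
        if self.R < 0:
            raise ValueError("R must be non-negative")


@dataclass
class TrackClassification:
    """Per-frame state labels and the positional stability index."""

    state: np.ndarray  # per-frame: "stable_synapse" | "motile_kinapse"
    psi_index: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.psi_index <= 1.0:
            raise ValueError("psi_index must lie in [0, 1]")


@dataclass
class TrackConfinementResult:
    """Full output of :func:`analyze_track` for one track."""

    cell_id: str
    motion: MotionStats
    profile: ConfinementProfile
    periods: list[ConfinedPeriod]
    classification: TrackClassification

    @property
    def psi_index(self) -> float:
        return self.classification.psi_index

    @property
    def stable_periods(self) -> list[ConfinedPeriod]:
        return [p for p in self.periods if p.stable]


def psi_to_score(psi: np.ndarray | float) -> np.ndarray | float:
    """Fixed monotone transform ``L = max(0, -ln(psi) - 1)``."""
    return np.maximum(0.0, -np.log(psi) - 1.0)


def score_to_psi(L: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`psi_to_score` on its strictly decreasing branch."""
    return np.minimum(1.0, np.exp(-(np.asarray(L, dtype=float) + 1.0)))


def estimate_diffusion(track: Track, max_lag: int = DEFAULT_MAX_LAG, d_floor: float = D_FLOOR) -> MotionStats:
    """Short-lag diffusion coefficient from a through-origin MSD fit.

    MSD(τ) is computed over frame lags 1..``max_lag`` (using only frame pairs
    actually present, so gaps are respected) and fitted as ``MSD = 4 D τ``
    by weighted least squares through the origin with weights ``1/τ²``
    (MSD variance grows with lag, so this equals the mean of the per-lag
    estimates ``MSD(τ) / 4τ``).  ``D`` is floored at ``d_floor`` so that
    stationary tracks stay usable downstream.
    """
    n = len(track)
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2")
    if n <= max_lag:
        raise ValueError(f"track too short ({n} frames) for max_lag={max_lag}")
    frames = track.frames
    msds: list[float] = []
    lag_times: list[float] = []
    for tau in range(1, max_lag + 1):
        target = frames + tau
        idx = np.searchsorted(frames, target)
        ok = idx < n
        ok[ok] &= frames[idx[ok]] == target[ok]
        if not ok.any():
            continue
        disp = track.positions[idx[ok]] - track.positions[ok]
        msds.append(float(np.mean(np.sum(disp**2, axis=1))))
        lag_times.append(tau * track.frame_interval)
    if not msds:
        raise ValueError("no usable frame pairs for MSD")
    t = np.asarray(lag_times)
    m = np.asarray(msds)
    D = float(np.mean(m / (4.0 * t)))
    D = max(D, d_floor)
    inst = track.step_displacements() / track.step_dt() * 60.0
    return MotionStats(D=D, mean_speed=float(inst.mean()), smoothed_speed=smoothed_speed(track))


def _window_max_from_start(positions: np.ndarray, w: int) -> np.ndarray:
    """Maximum displacement from the first position of every length-w window."""
    win = sliding_window_view(positions, (w, 2)).reshape(-1, w, 2)
    diff = win - win[:, :1, :]
    d2 = np.einsum("nik,nik->ni", diff, diff)
    return np.sqrt(d2.max(axis=1))


def confinement_score(
    track: Track,
    motion: MotionStats | None = None,
    windows: Sequence[int] = DEFAULT_WINDOWS,
    l_max: float = DEFAULT_L_MAX,
) -> ConfinementProfile:
    """Per-frame confinement score averaged over several window lengths.

    For each window length the window is centred on the frame (left-biased
    for even lengths).  Frames for which a given window does not fit
    contribute 0 for that window; a frame covered by no window gets
    ``L = 0``.  ``psi`` is floored at ``exp(-(l_max + 1))`` (handles the
    all-identical-positions case, where ``R = 0``), capping ``L`` at
    ``l_max``.
    """
    n = len(track)
    windows = tuple(int(w) for w in windows)
    if any(w < 3 for w in windows):
        raise ValueError("window lengths must be >= 3 frames")
    if any(w > n for w in windows):
        raise ValueError(f"window lengths must be <= track length ({n})")
    if motion is None:
        motion = estimate_diffusion(track)
    psi_floor = float(np.exp(-(l_max + 1.0)))

    L_sum = np.zeros(n)
    for w in windows:
        r_max = _window_max_from_start(track.positions, w)  # per window start
        starts = np.arange(n - w + 1)
        t_w = track.times[starts + w - 1] - track.times[starts]
        r2 = r_max**2
        with np.errstate(divide="ignore"):
            log10_psi = SIMSON_INTERCEPT - SIMSON_SLOPE * motion.D * t_w / r2
        psi = np.power(10.0, log10_psi)
        psi = np.clip(psi, psi_floor, 1.0)
        L_w = psi_to_score(psi)
        centers = starts + (w - 1) // 2
        L_sum[centers] += L_w
    L = L_sum / len(windows)
    psi = np.where(L > 0, score_to_psi(L), 1.0)
    return ConfinementProfile(L=L, psi=psi, window_lengths=windows)


def demarcate_confined_periods(
    profile: ConfinementProfile,
    track: Track,
    l_threshold: float = DEFAULT_L_THRESHOLD,
    min_duration: int = DEFAULT_MIN_DURATION,
) -> list[ConfinedPeriod]:
    """Maximal runs of frames with ``L > l_threshold`` of sufficient length.

    Returns non-overlapping :class:`ConfinedPeriod` objects with the zone
    diameter ``R`` and duration ``t`` (frames) computed over each run.
    Stability flags are unset; apply :func:`classify_stability`.
    """
    above = profile.L > l_threshold
    if len(above) != len(track):
        raise ValueError("profile not aligned to track")
    periods: list[ConfinedPeriod] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        end = int(stop - 1)
        t = end - start + 1
        if t < min_duration:
            continue
        seg = track.positions[start : end + 1]
        diff = seg[:, None, :] - seg[None, :, :]
        R = float(np.sqrt(np.einsum("ijk,ijk->ij", diff, diff).max()))
        periods.append(ConfinedPeriod(start=int(start), end=end, t=t, R=R, spread=R**2 / t))
    return periods


def classify_stability(
    periods: list[ConfinedPeriod],
    spread_threshold: float = DEFAULT_SPREAD_THRESHOLD,
) -> list[ConfinedPeriod]:
    """Flag each period stable iff ``spread < spread_threshold`` (in place)."""
    for p in periods:
        p.stable = bool(p.spread < spread_threshold)
    return periods


def positional_stability_index(
    track: Track, periods: Sequence[ConfinedPeriod]
) -> TrackClassification:
    """Label frames inside stable periods and compute the stable fraction."""
    n = len(track)
    stable_mask = np.zeros(n, dtype=bool)
    for p in periods:
        if p.start < 0 or p.end >= n:
            raise ValueError("period outside track bounds")
        if p.stable:
            stable_mask[p.start : p.end + 1] = True
    state = np.where(stable_mask, "stable_synapse", "motile_kinapse")
    return TrackClassification(state=state, psi_index=float(stable_mask.mean()))


def analyze_track(
    track: Track,
    windows: Sequence[int] = DEFAULT_WINDOWS,
    l_threshold: float = DEFAULT_L_THRESHOLD,
    min_duration: int = DEFAULT_MIN_DURATION,
    spread_threshold: float = DEFAULT_SPREAD_THRESHOLD,
    l_max: float = DEFAULT_L_MAX,
    max_lag: int = DEFAULT_MAX_LAG,
) -> TrackConfinementResult:
    """Run the full per-track pipeline: D → L → periods → stability → index.

    Window lengths longer than the track are dropped; at least one window
    must remain.
    """
    usable = tuple(w for w in windows if w <= len(track))
    if not usable:
        raise ValueError(f"track {track.cell_id!r} shorter than every window length")
    motion = estimate_diffusion(track, max_lag=max_lag)
    profile = confinement_score(track, motion, windows=usable, l_max=l_max)
    periods = demarcate_confined_periods(profile, track, l_threshold, min_duration)
    classify_stability(periods, spread_threshold)
    classification = positional_stability_index(track, periods)
    return TrackConfinementResult(
        cell_id=track.cell_id,
        motion=motion,
        profile=profile,
        periods=periods,
        classification=classification,
    )
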