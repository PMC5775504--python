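"""Spot occupancy, arrest detection, virtual synchronization, and survival.

Interaction times inside :class:`InteractionRecord` are seconds (same unit as
track times); survival fitting works in hours, the unit in which half-lives
are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .trackcore import SpotGrid, Track, smoothed_speed

__all__ = [
    "DEFAULT_SPEED_THRESHOLD",
    "DEFAULT_DWELL",
    "DEFAULT_HYSTERESIS",
    "DEFAULT_BIN_H",
    "InteractionRecord",
    "SurvivalFit",
    "AlignedProfile",
    "assign_occupancy",
    "detect_arrest",
    "virtual_synchronize",
    "fit_survival",
    "fit_survival_curve",
]

DEFAULT_SPEED_THRESHOLD = 2.0  # μm/min
DEFAULT_DWELL = 10  # frames
DEFAULT_HYSTERESIS = 2.0  # μm beyond spot radius
DEFAULT_BIN_H = 0.25  # 15 min

NO_SPOT = -1


@dataclass
class InteractionRecord:
    """One cell's initial arrest on a spot and its (possibly censored) exit.

    ``exit_time`` carries the observation horizon when ``censored`` is True.
    Later attachments to any spot after the initial exit are counted in
    ``re_engagements`` but excluded from survival analysis by contract.
    """

    cell_id: str
    spot_id: int
    attach_time: float  # s
    exit_time: float  # s; censoring horizon when censored
    censored: bool
    re_engagements: int = 0

    def __post_init__(self) -> None:
        if not self.censored and self.exit_time <= self.attach_time:
            raise ValueError("exit_time must exceed attach_time for uncensored records")

    @property
    def residence_s(self) -> float:
        return self.exit_time - self.attach_time


@dataclass
class SurvivalFit:
    """Log-linear fit of the percent-remaining curve.

    ``half_life = ln(2) / |slope|`` (hours); ``slope`` is the OLS slope of
    ``ln(percent_remaining)`` against time in hours (non-positive for a
    decaying population).  ``half_life`` is ``inf`` (with ``no_decay`` set)
    when no exits occur over the horizon.
    """

    times: np.ndarray  # h
    percent_remaining: np.ndarray
    ln_percent: np.ndarray
    slope: float  # 1/h
    intercept: float
    r_squared: float
    half_life: float  # h
    n_records: int
    no_decay: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.percent_remaining) > 1e-9):
            raise ValueError("percent_remaining must be non-increasing")


@dataclass
class AlignedProfile:
    """Per-cell traces of one channel re-indexed to time since arrest."""

    channel: str
    relative_times: np.ndarray  # s, zero at arrest
    traces: np.ndarray  # (n_cells, n_times), NaN where a cell has no sample
    mean: np.ndarray  # NaN where no cell contributes
    n_cells: int


def assign_occupancy(track: Track, grid: SpotGrid) -> np.ndarray:
    """Per-frame spot id (or -1) by the within-radius rule.

    A frame is assigned to spot *s* iff the centroid lies within the spot
    radius of *s*'s centre; with ``spacing >= diameter`` at most one spot can
    claim a point.
    """
    diff = track.positions[:, None, :] - grid.centers[None, :, :]
    d = np.sqrt(np.einsum("nsk,nsk->ns", diff, diff))
    nearest = d.argmin(axis=1)
    inside = d[np.arange(len(track)), nearest] <= grid.radius
    return np.where(inside, nearest, NO_SPOT)


def _first_run_start(ok: np.ndarray, dwell: int, from_idx: int = 0) -> int | None:
    """Index of the first run of >= dwell consecutive True at/after from_idx."""
    run = 0
    for i in range(from_idx, len(ok)):
        run = run + 1 if ok[i] else 0
        if run >= dwell:
            return i - dwell + 1
    return None


def detect_arrest(
    track: Track,
    grid: SpotGrid,
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
    dwell: int = DEFAULT_DWELL,
    hysteresis: float = DEFAULT_HYSTERESIS,
) -> list[InteractionRecord]:
    """Detect the initial arrest of a track on a spot and its exit.

    Attachment starts at the first frame of a run of at least ``dwell``
    frames during which the centroid occupies one spot and the smoothed speed
    is below ``speed_threshold`` (μm/min).  The exit is the first subsequent
    frame at which the centroid is beyond the spot radius plus ``hysteresis``
    (μm) sustained for ``dwell`` frames; if the movie ends first the record
    is censored at the last frame time.  Arrests after the initial exit are
    tallied as ``re_engagements`` on the same record.

    Returns a list with zero or one record.
    """
    occ = assign_occupancy(track, grid)
    speed = smoothed_speed(track)
    slow = speed < speed_threshold

    def arrest_start(from_idx: int) -> tuple[int, int] | None:
        run = 0
        spot = NO_SPOT
        for i in range(from_idx, len(track)):
            if occ[i] != NO_SPOT and slow[i] and (run == 0 or occ[i] == spot):
                spot = occ[i]
                run += 1
            else:
                run = 1 if (occ[i] != NO_SPOT and slow[i]) else 0
                spot = occ[i] if run else NO_SPOT
            if run >= dwell:
                return i - dwell + 1, spot
        return None

    first = arrest_start(0)
    if first is None:
        return []
    attach_idx, spot_id = first
    center = grid.centers[spot_id]
    dist = np.linalg.norm(track.positions - center, axis=1)
    outside = dist > grid.radius + hysteresis
    exit_idx = _first_run_start(outside, dwell, from_idx=attach_idx + 1)
    if exit_idx is None:
        record = InteractionRecord(
            cell_id=track.cell_id,
            spot_id=int(spot_id),
            attach_time=float(track.times[attach_idx]),
            exit_time=float(track.times[-1]),
            censored=True,
        )
        return [record]
    record = InteractionRecord(
        cell_id=track.cell_id,
        spot_id=int(spot_id),
        attach_time=float(track.times[attach_idx]),
        exit_time=float(track.times[exit_idx]),
        censored=False,
    )
    # count later attachments (to any spot) as re-engagements only
    nxt = arrest_start(exit_idx)
    while nxt is not None:
        record.re_engagements += 1
        start, spot = nxt
        dist2 = np.linalg.norm(track.positions - grid.centers[spot], axis=1)
        out2 = dist2 > grid.radius + hysteresis
        leave = _first_run_start(out2, dwell, from_idx=start + 1)
        if leave is None:
            break
        nxt = arrest_start(leave)
    return [record]


def virtual_synchronize(
    tracks: Sequence[Track],
    records: Sequence[InteractionRecord],
    channel: str,
    window: float = 300.0,
) -> AlignedProfile:
    """Align a per-frame channel across cells at their arrest times.

    ``channel`` may name any track channel or the special value ``"speed"``
    (smoothed speed, μm/min).  Traces are re-indexed to time since arrest on
    a common grid spanning ±``window`` seconds at the frame interval of the
    first contributing track; the mean is the unweighted average over cells
    contributing at each relative time.
    """
    if not records:
        raise ValueError("nothing to align: no arrest records")
    by_id = {t.cell_id: t for t in tracks}
    fi = by_id[records[0].cell_id].frame_interval
    n_side = int(round(window / fi))
    rel = fi * np.arange(-n_side, n_side + 1)
    traces = np.full((len(records), len(rel)), np.nan)
    for row, rec in enumerate(records):
        tr = by_id[rec.cell_id]
        series = smoothed_speed(tr) if channel == "speed" else tr.channels[channel]
        t_rel = tr.times - rec.attach_time
        # nearest-frame matching onto the common grid
        idx = np.searchsorted(t_rel, rel)
        for j, target in enumerate(rel):
            best, err = None, fi / 2
            for k in (idx[j] - 1, idx[j]):
                if 0 <= k < len(t_rel) and abs(t_rel[k] - target) < err:
                    best, err = k, abs(t_rel[k] - target)
            if best is not None:
                traces[row, j] = series[best]
    counts = (~np.isnan(traces)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        sums = np.nansum(traces, axis=0)
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return AlignedProfile(
        channel=channel, relative_times=rel, traces=traces, mean=mean, n_cells=len(records)
    )


def survival_curve(
    records: Sequence[InteractionRecord],
    bin_h: float = DEFAULT_BIN_H,
    horizon_h: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Percent of initially arrested cells still on their spot per time bin.

    Censored cells count as remaining up to their censoring time and then
    drop out of the tally denominator.  Returns (times_h, percent), with
    percent defined wherever the denominator is positive.
    """
    attach = np.array([r.attach_time for r in records]) / 3600.0
    end = np.array([r.exit_time for r in records]) / 3600.0
    dur = end - attach
    cens = np.array([r.censored for r in records], dtype=bool)
    if horizon_h is None:
        horizon_h = float(dur.max())
    n_bins = int(np.floor(horizon_h / bin_h + 1e-9)) + 1
    times = bin_h * np.arange(n_bins)
    pct = np.full(n_bins, np.nan)
    for i, t in enumerate(times):
        in_obs = ~cens | (dur >= t - 1e-12)
        denom = int(in_obs.sum())
        if denom == 0:
            continue
        remaining = int((in_obs & (cens | (dur > t))).sum())
        pct[i] = 100.0 * remaining / denom
    return times, pct


def fit_survival_curve(times_h: np.ndarray, percent: np.ndarray, n_records: int = 0) -> SurvivalFit:
    """OLS fit of ln(percent) vs time over bins with at least one remaining cell."""
    times_h = np.asarray(times_h, dtype=float)
    percent = np.asarray(percent, dtype=float)
    usable = np.isfinite(percent) & (percent > 0)
    if usable.sum() < 2:
        raise ValueError("fewer than 2 usable bins: fit refused")
    ln_pct = np.where(usable, np.log(percent, where=usable, out=np.full_like(percent, np.nan)), np.nan)
    if np.allclose(percent[usable], percent[usable][0]):
        return SurvivalFit(
            times=times_h,
            percent_remaining=percent,
            ln_percent=ln_pct,
            slope=0.0,
            intercept=float(ln_pct[usable][0]),
            r_squared=1.0,
            half_life=np.inf,
            n_records=n_records,
            no_decay=True,
        )
    res = stats.linregress(times_h[usable], ln_pct[usable])
    slope = float(res.slope)
    half_life = np.inf if slope == 0 else float(np.log(2) / abs(slope))
    return SurvivalFit(
        times=times_h,
        percent_remaining=percent,
        ln_percent=ln_pct,
        slope=slope,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        half_life=half_life,
        n_records=n_records,
        no_decay=slope == 0,
    )


def fit_survival(
    records: Sequence[InteractionRecord],
    bin_h: float = DEFAULT_BIN_H,
    horizon_h: float | None = None,
) -> SurvivalFit:
    """First-order exit kinetics: half-life from the ln-percent slope.

    Requires at least 5 records.  All-censored cohorts yield a flat curve
    and ``half_life = inf`` with the ``no_decay`` flag set.
    """
    if len(records) < 5:
        raise ValueError("need >= 5 interaction records")
    times, pct = survival_curve(records, bin_h=bin_h, horizon_h=horizon_h)
    return fit_survival_curve(times, pct, n_records=len(records))
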