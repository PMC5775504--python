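"""Core data types and I/O for centroid tracks, mask movies, and spot grids.

Conventions
-----------
* Positions are continuous coordinates in micrometres (μm) in a right-handed
  x/y plane.
* Times are seconds; speeds are reported in μm/min.
* Pixel rasters are 0-based ``(row, col)`` arrays; :class:`MaskSeries` stores
  the world coordinate of the *centre* of pixel ``(0, 0)`` so that the centre
  of pixel ``(r, c)`` is ``origin + (c * pixel_size, r * pixel_size)``.
* Frame gaps are preserved, never interpolated; time differences used by
  downstream computations are true time differences.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_FRAME_INTERVAL",
    "TRACK_COLUMNS",
    "Track",
    "MotionStats",
    "MaskSeries",
    "SpotGrid",
    "build_spot_grid",
    "read_tracks",
    "write_tracks",
    "read_mask_series",
    "write_mask_series",
    "smoothed_speed",
]

#: Default imaging cadence in seconds (20 frames = 10 min).
DEFAULT_FRAME_INTERVAL = 30.0

#: Required columns of a track table.
TRACK_COLUMNS = ("cell_id", "frame", "time_s", "x_um", "y_um")


@dataclass
class Track:
    """One cell's time-ordered 2D centroid positions plus optional channels.

    Parameters
    ----------
    cell_id :
        Opaque identifier of the cell.
    frames :
        Integer frame indices, 0-based, strictly increasing.  Gaps are
        allowed and preserved.
    times :
        Seconds, strictly increasing, consistent with
        ``(frames - frames[0]) * frame_interval``.
    positions :
        ``(n, 2)`` array of x/y centroid coordinates in μm.
    channels :
        Named per-frame scalar series (e.g. ``calcium_ratio``,
        ``cell_area``), each the same length as ``frames``.
    frame_interval :
        Seconds per frame.
    """

    cell_id: str
    frames: np.ndarray
    times: np.ndarray
    positions: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    frame_interval: float = DEFAULT_FRAME_INTERVAL

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        n = len(self.frames)
        if self.positions.shape != (n, 2):
            raise ValueError(
                f"track {self.cell_id!r}: positions must have shape ({n}, 2), "
                f"got {self.positions.shape}"
            )
        if self.times.shape != (n,):
            raise ValueError(f"track {self.cell_id!r}: times/frames length mismatch")
        if n > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError(f"track {self.cell_id!r}: frames must be strictly increasing")
        if np.any(self.times < 0) or (n > 1 and not np.all(np.diff(self.times) > 0)):
            raise ValueError(
                f"track {self.cell_id!r}: times must be non-negative and strictly increasing"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError(f"track {self.cell_id!r}: non-finite positions")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        expected = (self.frames - self.frames[0]) * self.frame_interval
        if not np.allclose(self.times - self.times[0], expected,
                           atol=1e-6 + 1e-3 * self.frame_interval):
            raise ValueError(
                f"track {self.cell_id!r}: times inconsistent with "
                f"frames * frame_interval ({self.frame_interval} s)"
            )
        for name, series in self.channels.items():
            if series.shape != (n,):
                raise ValueError(
                    f"track {self.cell_id!r}: channel {name!r} length "
                    f"{series.shape} != number of frames {n}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Elapsed time in seconds from first to last frame."""
        return float(self.times[-1] - self.times[0])

    def step_displacements(self) -> np.ndarray:
        """Euclidean displacement (μm) of each successive step, length n-1."""
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def step_dt(self) -> np.ndarray:
        """True time difference (s) of each successive step, length n-1."""
        return np.diff(self.times)


@dataclass
class MotionStats:
    """Per-track motion summary.

    Attributes
    ----------
    D :
        Short-lag diffusion coefficient, μm²/s (non-negative; floored at a
        small epsilon for stationary tracks).
    mean_speed :
        Mean instantaneous speed, μm/min.
    smoothed_speed :
        Per-frame smoothed speed series, μm/min, same length as the track.
    """

    D: float
    mean_speed: float
    smoothed_speed: np.ndarray

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be non-negative")


@dataclass
class MaskSeries:
    """Per-frame binary cell masks sharing one raster shape.

    ``origin`` is the world (x, y) coordinate in μm of the centre of pixel
    ``(0, 0)``; pixel ``(r, c)`` is centred at
    ``(origin[0] + c * pixel_size, origin[1] + r * pixel_size)``.
    """

    frames: np.ndarray
    masks: np.ndarray  # (n, H, W) bool
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be a (n_frames, H, W) stack")
        if len(self.frames) != self.masks.shape[0]:
            raise ValueError("frames/masks length mismatch")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def __len__(self) -> int:
        return self.masks.shape[0]

    @property
    def empty(self) -> np.ndarray:
        """Boolean flag per frame: True where the mask has no foreground."""
        return ~self.masks.any(axis=(1, 2))

    def areas(self) -> np.ndarray:
        """Foreground area per frame in μm²."""
        return self.masks.sum(axis=(1, 2)) * self.pixel_size**2


@dataclass
class SpotGrid:
    """Square lattice of disk-shaped stimulatory spots.

    ``centers`` is an ``(n, 2)`` array of spot centres (μm); the spot id of
    row ``i`` is ``i`` (row-major over the lattice, deterministic).
    """

    spot_diameter: float
    spacing: float
    extent: tuple[float, float, float, float]  # (x0, y0, x1, y1) μm
    centers: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.spacing < self.spot_diameter:
            raise ValueError("spacing must be >= spot_diameter")

    @property
    def radius(self) -> float:
        return self.spot_diameter / 2.0

    @property
    def n_spots(self) -> int:
        return len(self.centers)

    def contains(self, point: Sequence[float], spot_id: int) -> bool:
        """True iff ``point`` lies within the disk of spot ``spot_id``."""
        return float(np.linalg.norm(np.asarray(point, float) - self.centers[spot_id])) <= self.radius

    def to_json(self, path: str | Path) -> None:
        payload = {
            "diameter_um": self.spot_diameter,
            "spacing_um": self.spacing,
            "extent_um": list(self.extent),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpotGrid":
        payload = json.loads(Path(path).read_text())
        return build_spot_grid(
            payload["diameter_um"], payload["spacing_um"], tuple(payload["extent_um"])
        )


def build_spot_grid(
    diameter: float,
    spacing: float,
    extent: Sequence[float],
) -> SpotGrid:
    """Construct a :class:`SpotGrid` of disk spots on a square lattice.

    Parameters
    ----------
    diameter :
        Spot diameter in μm (must be positive and <= spacing).
    spacing :
        Centre-to-centre spacing in μm.
    extent :
        Either ``(width, height)`` (lower-left corner at the world origin) or
        ``(x0, y0, x1, y1)`` in μm.  Centres are placed at
        ``(x0 + i * spacing, y0 + j * spacing)`` for every lattice point
        inside the extent.

    Notes
    -----
    If the extent is smaller than one spacing in either direction the result
    is a single-spot grid and a warning is emitted.
    """
    if not 0 < diameter <= spacing:
        raise ValueError("require spacing >= diameter > 0")
    extent = tuple(float(v) for v in extent)
    if len(extent) == 2:
        extent = (0.0, 0.0, extent[0], extent[1])
    elif len(extent) != 4:
        raise ValueError("extent must be (w, h) or (x0, y0, x1, y1)")
    x0, y0, x1, y1 = extent
    if x1 <= x0 or y1 <= y0:
        raise ValueError("extent must have positive width and height")
    nx = int(np.floor((x1 - x0) / spacing)) + 1
    ny = int(np.floor((y1 - y0) / spacing)) + 1
    if nx == 1 and ny == 1:
        warnings.warn("extent smaller than one spacing: single-spot grid", stacklevel=2)
    xs = x0 + spacing * np.arange(nx)
    ys = y0 + spacing * np.arange(ny)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    return SpotGrid(spot_diameter=diameter, spacing=spacing, extent=extent, centers=centers)


# ---------------------------------------------------------------------------
# Track table I/O
# ---------------------------------------------------------------------------

def read_tracks(path: str | Path, frame_interval: float | None = None) -> list[Track]:
    """Read a tidy track table (CSV) into a list of :class:`Track`.

    The file must contain the columns ``cell_id, frame, time_s, x_um, y_um``;
    any additional numeric column is attached as a named channel.  Rows may
    be unordered; they are sorted by frame per cell.  Duplicate
    ``(cell_id, frame)`` rows and non-numeric coordinates are rejected with
    the offending row numbers.

    ``frame_interval`` is inferred per track from the data when not given
    (falling back to :data:`DEFAULT_FRAME_INTERVAL` for single-frame tracks).
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table {path} missing columns: {missing}")

    numeric_cols = [c for c in df.columns if c != "cell_id"]
    coerced = df[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = coerced[["frame", "time_s", "x_um", "y_um"]].isna().any(axis=1)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"non-numeric coordinates in rows {rows}")
    df[numeric_cols] = coerced

    dup = df.duplicated(subset=["cell_id", "frame"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        raise ValueError(f"duplicate (cell_id, frame) rows: {rows}")

    channel_cols = [c for c in df.columns if c not in TRACK_COLUMNS]
    tracks: list[Track] = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy(dtype=int)
        times = sub["time_s"].to_numpy(dtype=float)
        if frame_interval is not None:
            fi = frame_interval
        elif len(sub) > 1:
            fi = float(np.median(np.diff(times) / np.diff(frames)))
        else:
            fi = DEFAULT_FRAME_INTERVAL
        tracks.append(
            Track(
                cell_id=str(cell_id),
                frames=frames,
                times=times,
                positions=sub[["x_um", "y_um"]].to_numpy(dtype=float),
                channels={c: sub[c].to_numpy(dtype=float) for c in channel_cols},
                frame_interval=fi,
            )
        )
    return tracks


def tracks_to_frame(tracks: Iterable[Track]) -> pd.DataFrame:
    """Flatten tracks into one tidy DataFrame (inverse of :func:`read_tracks`)."""
    parts = []
    for t in tracks:
        d = {
            "cell_id": t.cell_id,
            "frame": t.frames,
            "time_s": t.times,
            "x_um": t.positions[:, 0],
            "y_um": t.positions[:, 1],
        }
        d.update(t.channels)
        parts.append(pd.DataFrame(d))
    if not parts:
        return pd.DataFrame(columns=list(TRACK_COLUMNS))
    return pd.concat(parts, ignore_index=True)


def write_tracks(tracks: Iterable[Track], path: str | Path) -> None:
    """Write tracks to CSV; lossless round trip with :func:`read_tracks`."""
    tracks_to_frame(tracks).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Mask I/O (multi-page TIFF + JSON sidecar)
# ---------------------------------------------------------------------------

def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_mask_series(series: MaskSeries, path: str | Path) -> None:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, series.masks.astype(np.uint8))
    meta = {
        "frames": series.frames.tolist(),
        "pixel_size_um": series.pixel_size,
        "origin_um": list(series.origin),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_mask_series(path: str | Path) -> MaskSeries:
    import tifffile

    path = Path(path)
    masks = tifffile.imread(path).astype(bool)
    if masks.ndim == 2:
        masks = masks[None]
    meta = json.loads(_sidecar_path(path).read_text())
    return MaskSeries(
        frames=np.asarray(meta["frames"], dtype=int),
        masks=masks,
        pixel_size=float(meta["pixel_size_um"]),
        origin=tuple(meta["origin_um"]),
    )


# ---------------------------------------------------------------------------
# Speed
# ---------------------------------------------------------------------------

def smoothed_speed(track: Track) -> np.ndarray:
    """Per-frame smoothed speed in μm/min.

    The instantaneous speed of each step is displacement over true Δt.  The
    value at a frame is the mean instantaneous speed over the window of up to
    two steps before and two steps after that frame, truncated at track ends.
    """
    n = len(track)
    if n < 2:
        raise ValueError("no displacement defined for a single-point track")
    inst = track.step_displacements() / track.step_dt() * 60.0  # μm/min
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - 2)
        hi = min(n - 1, i + 2)  # steps lo..hi-1 touch frames lo..hi
        out[i] = inst[lo:hi].mean()
    return out
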