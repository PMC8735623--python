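"""Trajectory analytics for migrating cells.

Speed and directional persistence are computed from nucleus-centroid
trajectories the way they are in confocal/2-photon invasion assays: each
track's instantaneous velocities ``v_k = (p_{k+1} - p_k) / dt_k`` are
averaged to a per-track mean speed, and the directional persistence of a
track is the mean cosine of the angle between consecutive instantaneous
velocities,

    I(v_1, ..., v_l) = 1/(l-1) * sum_{k=1}^{l-1} cos(v_k, v_{k+1}),

with ``l`` the number of instantaneous velocities.  Per-track values are
averaged (unweighted) into a group persistence index in [-1, 1], where 1
is perfectly straight motion and -1 perfect reversal.  Tracks shorter
than a minimum duration (15 positions by default) are discarded, and
tracks are gated into anatomical zones by their mean x/y position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

__all__ = [
    "Trajectory",
    "VelocitySeries",
    "ZoneDefinition",
    "MigrationSummary",
    "instantaneous_velocities",
    "mean_track_speed",
    "trajectory_persistence",
    "filter_by_duration",
    "assign_zone",
    "rotate_tracks",
    "group_summary",
    "crossing_time",
    "estimate_alignment_time",
]

#: Relative frame-interval jitter tolerated by Trajectory validation.
#: Movies in this kind of assay are acquired every 39-41 s, i.e. a few
#: percent of wobble around the nominal interval.
FRAME_JITTER_TOL = 0.05


@dataclass
class Trajectory:
    """One nucleus's time-ordered positions.

    Attributes
    ----------
    track_id
        Identifier of the track.
    times
        Acquisition times in seconds, strictly increasing and uniformly
        spaced up to :data:`FRAME_JITTER_TOL` relative jitter.
    positions
        ``(n, d)`` array of coordinates in micrometres, ``d`` in (2, 3).
    """

    track_id: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] not in (2, 3):
            raise ConfigError(
                f"track {self.track_id}: positions must be (n, 2) or (n, 3)"
            )
        n = self.positions.shape[0]
        if n < 2 or self.times.shape != (n,):
            raise ConfigError(
                f"track {self.track_id}: need >= 2 positions with matching times"
            )
        if not np.all(np.isfinite(self.positions)) or not np.all(
            np.isfinite(self.times)
        ):
            raise ConfigError(f"track {self.track_id}: non-finite coordinates")
        dts = np.diff(self.times)
        if np.any(dts <= 0):
            raise ConfigError(f"track {self.track_id}: times not strictly increasing")
        dt = dts.mean()
        if np.any(np.abs(dts - dt) / dt >= FRAME_JITTER_TOL):
            raise ConfigError(
                f"track {self.track_id}: frame interval jitter exceeds "
                f"{FRAME_JITTER_TOL:.0%} of the mean interval"
            )

    @property
    def n_positions(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]


@dataclass
class VelocitySeries:
    """Instantaneous velocities of a single track, in um/min."""

    vectors: np.ndarray  # (l, d)
    speeds: np.ndarray  # (l,)

    @property
    def l(self) -> int:  # noqa: E743 - matches the field's usual symbol
        return self.vectors.shape[0]


@dataclass
class ZoneDefinition:
    """Axis-aligned rectangular gating zone with half-open intervals.

    A point (x, y) is inside iff ``x_range[0] <= x < x_range[1]`` and
    ``y_range[0] <= y < y_range[1]``.
    """

    name: str
    x_range: tuple[float, float]
    y_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.x_range[0] < self.x_range[1] and self.y_range[0] < self.y_range[1]):
            raise ConfigError(f"zone {self.name}: min must be < max on both axes")

    def contains(self, x: float, y: float) -> bool:
        return (
            self.x_range[0] <= x < self.x_range[1]
            and self.y_range[0] <= y < self.y_range[1]
        )

    def overlaps(self, other: "ZoneDefinition") -> bool:
        return (
            self.x_range[0] < other.x_range[1]
            and other.x_range[0] < self.x_range[1]
            and self.y_range[0] < other.y_range[1]
            and other.y_range[0] < self.y_range[1]
        )


@dataclass
class MigrationSummary:
    """Group-level migration statistics."""

    group: str
    n_tracks: int
    mean_speed: float  # um/min
    persistence_index: float  # in [-1, 1]
    track_speeds: np.ndarray = field(repr=False)
    track_persistence: np.ndarray = field(repr=False)


def instantaneous_velocities(traj: Trajectory) -> VelocitySeries:
    """Per-step velocities ``(p_{k+1} - p_k) / dt_k`` converted to um/min.

    Frame-interval jitter is handled by dividing each displacement by its
    own interval rather than by a nominal dt.
    """
    dts = np.diff(traj.times)[:, None]  # seconds
    vectors = np.diff(traj.positions, axis=0) / dts * 60.0
    speeds = np.linalg.norm(vectors, axis=1)
    return VelocitySeries(vectors=vectors, speeds=speeds)


def mean_track_speed(vs: VelocitySeries) -> float:
    """Arithmetic mean of the instantaneous speeds, um/min."""
    if vs.l < 1:
        raise ConfigError("empty velocity series")
    return float(vs.speeds.mean())


def trajectory_persistence(vs: VelocitySeries) -> float:
    """Mean cosine between consecutive instantaneous velocities.

    Pairs in which either velocity has zero magnitude have an undefined
    angle and are excluded from both numerator and denominator (a pausing
    cell should not bias the index toward 0).  Returns NaN — the
    undefined-result signal, distinct from an exception — when no valid
    pair remains.
    """
    if vs.l < 2:
        raise ConfigError("persistence needs at least 2 instantaneous velocities")
    a, b = vs.vectors[:-1], vs.vectors[1:]
    na, nb = vs.speeds[:-1], vs.speeds[1:]
    valid = (na > 0) & (nb > 0)
    if not np.any(valid):
        return math.nan
    cos = np.einsum("ij,ij->i", a[valid], b[valid]) / (na[valid] * nb[valid])
    return float(np.clip(cos, -1.0, 1.0).mean())


def filter_by_duration(
    trajectories: list[Trajectory], min_frames: int = 15
) -> list[Trajectory]:
    """Keep trajectories with at least ``min_frames`` positions (inclusive)."""
    return [t for t in trajectories if t.n_positions >= min_frames]


def assign_zone(
    traj: Trajectory, zones: list[ZoneDefinition]
) -> str | None:
    """Zone containing the track's mean (x, y) position, or None.

    Raises
    ------
    ConfigError
        If more than one zone contains the mean position (overlapping
        zone configuration).
    """
    mx, my = traj.positions[:, 0].mean(), traj.positions[:, 1].mean()
    hits = [z.name for z in zones if z.contains(mx, my)]
    if len(hits) > 1:
        raise ConfigError(f"zones {hits} overlap at mean position ({mx}, {my})")
    return hits[0] if hits else None


def rotate_tracks(
    trajectories: list[Trajectory], angle: float
) -> list[Trajectory]:
    """Rigid rotation of x/y about the origin by ``angle`` radians.

    Used to align movies with the embryonic AP axis; z (if present) is
    untouched.  All downstream speed/persistence statistics are invariant.
    """
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    out = []
    for t in trajectories:
        pos = t.positions.copy()
        pos[:, :2] = pos[:, :2] @ rot.T
        out.append(Trajectory(track_id=t.track_id, times=t.times.copy(), positions=pos))
    return out


def group_summary(trajectories: list[Trajectory], label: str) -> MigrationSummary:
    """Group mean speed and persistence index.

    ``mean_speed`` is the unweighted mean over tracks of each track's mean
    instantaneous speed; ``persistence_index`` is the unweighted mean of
    per-track persistence, excluding tracks whose persistence is undefined
    (NaN).
    """
    if not trajectories:
        raise ConfigError("no trajectories to summarize")
    speeds, pers = [], []
    for t in trajectories:
        vs = instantaneous_velocities(t)
        speeds.append(mean_track_speed(vs))
        if vs.l >= 2:
            pers.append(trajectory_persistence(vs))
        else:
            pers.append(math.nan)
    speeds = np.asarray(speeds)
    pers = np.asarray(pers)
    defined = pers[~np.isnan(pers)]
    if defined.size == 0:
        raise ConfigError("no track with defined persistence")
    return MigrationSummary(
        group=label,
        n_tracks=len(trajectories),
        mean_speed=float(speeds.mean()),
        persistence_index=float(defined.mean()),
        track_speeds=speeds,
        track_persistence=pers,
    )


def crossing_time(
    trajectories: list[Trajectory],
    boundary_x: float,
    start_time: float = 0.0,
) -> float | None:
    """Minutes from ``start_time`` until the first track crosses ``boundary_x``.

    The boundary is a vertical line in AP-aligned coordinates.  Each
    track's invasion direction is defined by its initial side of the
    boundary (first frame with non-zero signed distance); the crossing is
    the first frame on the opposite side.  Event times have frame
    resolution — no interpolation between frames.  Returns None — the
    no-crossing signal — if no track ever crosses.
    """
    best: float | None = None
    for t in trajectories:
        s = np.sign(t.positions[:, 0] - boundary_x)
        nz = np.nonzero(s)[0]
        if nz.size == 0:
            continue
        s0 = s[nz[0]]
        crossed = np.nonzero((s != 0) & (s != s0))[0]
        if crossed.size:
            tc = float(t.times[crossed[0]])
            if best is None or tc < best:
                best = tc
    if best is None:
        return None
    return (best - start_time) / 60.0


def estimate_alignment_time(
    trajectories: list[Trajectory],
    boundary_x: float,
    min_tracks: int = 3,
    within_um: float = 10.0,
) -> float | None:
    """Heuristic start event for :func:`crossing_time` (off by default).

    Returns the earliest time (seconds) at which at least ``min_tracks``
    tracks sit within ``within_um`` of the boundary — a stand-in for the
    human-annotated moment when cells align in an arc at the tissue edge.
    """
    counts: dict[float, int] = {}
    for t in trajectories:
        near = np.abs(t.positions[:, 0] - boundary_x) <= within_um
        for tt in t.times[near]:
            counts[float(tt)] = counts.get(float(tt), 0) + 1
    hits = sorted(tt for tt, c in counts.items() if c >= min_tracks)
    return hits[0] if hits else None
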