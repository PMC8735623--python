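"""Readers and writers for the pipeline's delimited-text formats.

All tabular formats are plain CSV (comma separator, dot decimal, header
mandatory).  Files written by macroquant start with a provenance comment
line carrying the package version, the seed and a config hash; readers
skip ``#`` comment lines.  Column layouts:

* tracks:    ``track_id,frame,t_s,x_um,y_um[,z_um]``
* profiles:  ``profile_id,pos_um,ch_membrane,ch_reporter``
* intensity: ``embryo_id,group,batch,mean_intensity``
  (an optional ``roi_id`` column makes it an ROI-level table)
* shapes:    ``cell_id,group,frame,max_length_um,max_width_um``
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .errors import ConfigError, ParseError
from .linescan import LineProfile
from .tracks import Trajectory, ZoneDefinition

__all__ = [
    "provenance_header",
    "read_tracks_csv",
    "write_tracks_csv",
    "read_profiles_csv",
    "write_profiles_csv",
    "read_intensity_csv",
    "write_table",
    "read_shapes_csv",
    "read_tiff_plane",
    "render_profile_tiff",
    "load_config",
    "zones_from_config",
]


def provenance_header(seed: int | None = None, config: dict | None = None) -> str:
    """Deterministic provenance comment (no timestamp, so identical runs
    produce byte-identical files)."""
    parts = [f"macroquant v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        digest = hashlib.sha1(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        parts.append(f"config_sha1={digest}")
    return "# " + " | ".join(parts)


def _write_with_header(df: pd.DataFrame, path, seed=None, config=None, sep=",") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, config=config) + "\n")
        df.to_csv(fh, index=False, sep=sep)


def write_table(df: pd.DataFrame, path, seed=None, config=None, sep=",") -> None:
    """Write any result table with a provenance header (TSV if sep='\\t')."""
    _write_with_header(df, path, seed=seed, config=config, sep=sep)


def _read_csv(path, required: set[str], sep=",") -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#", sep=sep)
    except Exception as err:  # malformed file
        raise ParseError(f"{path}: {err}") from err
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


# -- tracks -----------------------------------------------------------------


def read_tracks_csv(path) -> list[Trajectory]:
    """Read trajectories, grouped by track_id and sorted by frame."""
    df = _read_csv(path, {"track_id", "frame", "t_s", "x_um", "y_um"})
    has_z = "z_um" in df.columns
    coord_cols = ["x_um", "y_um"] + (["z_um"] if has_z else [])
    bad = df[coord_cols + ["t_s"]].isna().any(axis=1)
    if bad.any():
        row = int(df.index[bad][0]) + 2  # +1 header +1 one-based
        raise ParseError(f"{path}: NaN coordinate near line {row}")
    out = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise ParseError(f"{path}: track {tid!r} has non-monotone frames")
        try:
            out.append(
                Trajectory(
                    track_id=str(tid),
                    times=sub["t_s"].to_numpy(dtype=float),
                    positions=sub[coord_cols].to_numpy(dtype=float),
                )
            )
        except ConfigError as err:
            raise ParseError(f"{path}: {err}") from err
    return out


def write_tracks_csv(trajectories: list[Trajectory], path, seed=None, config=None) -> None:
    rows = []
    for t in trajectories:
        for k in range(t.n_positions):
            row = dict(
                track_id=t.track_id,
                frame=k,
                t_s=t.times[k],
                x_um=t.positions[k, 0],
                y_um=t.positions[k, 1],
            )
            if t.dim == 3:
                row["z_um"] = t.positions[k, 2]
            rows.append(row)
    _write_with_header(pd.DataFrame(rows), path, seed=seed, config=config)


# -- profiles ---------------------------------------------------------------


def read_profiles_csv(path) -> list[LineProfile]:
    """Read line profiles; enforces uniform spacing within 1e-6 um."""
    df = _read_csv(path, {"profile_id", "pos_um", "ch_membrane", "ch_reporter"})
    out = []
    for pid, sub in df.groupby("profile_id", sort=True):
        sub = sub.sort_values("pos_um")
        pos = sub["pos_um"].to_numpy(dtype=float)
        steps = np.diff(pos)
        if steps.size == 0:
            raise ParseError(f"{path}: profile {pid!r} has a single sample")
        dx = float(np.median(steps))
        if np.any(np.abs(steps - dx) > 1e-6):
            raise ParseError(f"{path}: profile {pid!r} is not uniformly spaced")
        try:
            out.append(
                LineProfile(
                    positions=pos,
                    ch_membrane=sub["ch_membrane"].to_numpy(dtype=float),
                    ch_reporter=sub["ch_reporter"].to_numpy(dtype=float),
                    dx=dx,
                    inside_to_outside=True,
                    profile_id=str(pid),
                )
            )
        except ConfigError as err:
            raise ParseError(f"{path}: profile {pid!r}: {err}") from err
    return out


def write_profiles_csv(profiles: list[LineProfile], path, seed=None, config=None) -> None:
    frames = []
    for i, p in enumerate(profiles):
        q = p.oriented()
        frames.append(
            pd.DataFrame(
                dict(
                    profile_id=q.profile_id or str(i),
                    pos_um=q.positions,
                    ch_membrane=q.ch_membrane,
                    ch_reporter=q.ch_reporter,
                )
            )
        )
    _write_with_header(pd.concat(frames, ignore_index=True), path, seed=seed, config=config)


# -- intensities and shapes -------------------------------------------------


def read_intensity_csv(path) -> pd.DataFrame:
    df = _read_csv(path, {"embryo_id", "group", "batch", "mean_intensity"})
    if df["mean_intensity"].isna().any() or df["mean_intensity"].lt(0).any():
        raise ParseError(f"{path}: intensities must be non-negative numbers")
    return df


def read_shapes_csv(path) -> pd.DataFrame:
    df = _read_csv(path, {"cell_id", "group", "max_length_um", "max_width_um"})
    if (df["max_length_um"].le(0) | df["max_width_um"].le(0)).any():
        raise ParseError(f"{path}: lengths and widths must be positive")
    return df


# -- images -----------------------------------------------------------------


def read_tiff_plane(path, channel: int = 0, z: int = 0) -> np.ndarray:
    """Read one 2D plane from a TIFF: (H,W), (C,H,W) or (Z,C,H,W) layouts."""
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 2:
        if channel != 0 or z != 0:
            raise ConfigError("2D image has a single plane (channel=z=0)")
        return arr
    if arr.ndim == 3:
        if z != 0:
            raise ConfigError("3D image interpreted as (C, H, W); z must be 0")
        if not 0 <= channel < arr.shape[0]:
            raise ConfigError(f"channel {channel} out of range {arr.shape[0]}")
        return arr[channel]
    if arr.ndim == 4:
        if not 0 <= z < arr.shape[0]:
            raise ConfigError(f"z {z} out of range {arr.shape[0]}")
        if not 0 <= channel < arr.shape[1]:
            raise ConfigError(f"channel {channel} out of range {arr.shape[1]}")
        return arr[z, channel]
    raise ParseError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")


def render_profile_tiff(config, path, height: int = 32) -> None:
    """Render a synthetic 2-channel plane from a profile model.

    Column ``j`` of the image carries the model value at position
    ``j * dx`` in both channels (constant along rows), giving a small
    fixture on which a horizontal line extraction reproduces the
    generated profile.  Channel 0 = membrane marker, channel 1 = reporter.
    """
    from .synthetic import _clean_channels  # local import avoids a cycle

    membrane, reporter = _clean_channels(config)
    img = np.stack(
        [
            np.tile(membrane, (height, 1)),
            np.tile(reporter, (height, 1)),
        ]
    ).astype(np.float32)
    tifffile.imwrite(path, img)


# -- configuration ----------------------------------------------------------


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a YAML mapping")
    return cfg


def zones_from_config(cfg: dict) -> list[ZoneDefinition]:
    """Parse ``zones: {name: {x: [lo, hi], y: [lo, hi]}, ...}``."""
    zones = []
    for name, spec in (cfg.get("zones") or {}).items():
        try:
            zones.append(
                ZoneDefinition(
                    name=str(name),
                    x_range=(float(spec["x"][0]), float(spec["x"][1])),
                    y_range=(float(spec["y"][0]), float(spec["y"][1])),
                )
            )
        except (KeyError, TypeError, IndexError) as err:
            raise ParseError(f"zone {name!r}: expected x/y [lo, hi] pairs") from err
    return zones
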