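"""Calibrated kinematics from digitized pixel trajectories.

This is the measurement layer between video digitization and the
energy-conservation inversion: pixel tracks in, velocities / rotation
rates / direction angles out.  Speeds use a forward difference over the
first inter-frame interval after impact (frame indices 0 and 1 of the
post-impact track), matching how post-impact velocities are read off
high-speed footage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidDurationError, SchemaError, SnapmechError


@dataclass(frozen=True)
class Track:
    """One digitized trajectory: (frame, x_px, y_px) samples plus calibration.

    ``points`` are in image coordinates (y grows downward).  ``body_axis``
    is the termite body orientation at impact, also in image coordinates.
    """

    frame_rate: float
    scale: float  # metres per pixel
    points: tuple[tuple[int, float, float], ...]
    body_axis: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise SnapmechError(f"frame_rate must be positive, got {self.frame_rate!r}")
        if not self.scale > 0:
            raise SnapmechError(f"scale must be positive, got {self.scale!r}")
        if len(self.points) < 2:
            raise SnapmechError("a track needs at least 2 points")
        frames = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise SnapmechError("frame indices must be strictly increasing")


class DirectionAngle(NamedTuple):
    """Deviation from the body axis: magnitude in [0, 180] and signed value
    (positive = left of axis)."""

    angle_deg: float
    signed_deg: float


def calibrate_scale(reference_px: float, reference_mm: float) -> float:
    """Metres per pixel from a known reference length (e.g. dish diameter)."""
    if not reference_px > 0 or not reference_mm > 0:
        raise SnapmechError(
            f"reference lengths must be positive, got {reference_px!r} px, "
            f"{reference_mm!r} mm"
        )
    return (reference_mm * 1e-3) / reference_px


def first_interval_speed(track: Track) -> float:
    """Speed from the displacement between the first two samples (m/s).

    Forward difference: Euclidean pixel displacement × scale × frame rate,
    divided by the frame-index gap (so skipped frames don't inflate speed).
    """
    (f0, x0, y0), (f1, x1, y1) = track.points[0], track.points[1]
    gap = f1 - f0
    if gap == 0:
        raise InvalidDurationError("first two samples share a frame index")
    dist_px = math.hypot(x1 - x0, y1 - y0)
    return dist_px * track.scale * track.frame_rate / gap


def rotation_rate(rotations: float, duration: float) -> float:
    """Angular speed from a rotation count over a duration: 2π·n/T (rad/s)."""
    if not duration > 0:
        raise InvalidDurationError(f"duration must be positive, got {duration!r}")
    return 2.0 * math.pi * rotations / duration


def direction_angle(
    displacement: Sequence[float],
    body_axis: Sequence[float],
    y_down: bool = False,
) -> DirectionAngle:
    """Angle of a displacement relative to the body axis.

    Returns the unsigned deviation (arccos of the normalised dot product,
    in [0°, 180°]) and a signed version whose sign comes from the 2-D
    cross product — positive means left of the axis in the mathematical
    y-up convention.  Pass ``y_down=True`` for image coordinates (video
    convention); the y component is flipped before the sign test so that
    "left" keeps its anatomical meaning.
    """
    dx, dy = float(displacement[0]), float(displacement[1])
    ax, ay = float(body_axis[0]), float(body_axis[1])
    if dx == 0 and dy == 0:
        raise SnapmechError("displacement vector is zero")
    if ax == 0 and ay == 0:
        raise SnapmechError("body axis vector is zero")
    if y_down:
        dy, ay = -dy, -ay
    dot = dx * ax + dy * ay
    cross = ax * dy - ay * dx  # axis × displacement; >0 left of axis
    norm = math.hypot(dx, dy) * math.hypot(ax, ay)
    cosang = max(-1.0, min(1.0, dot / norm))
    angle = math.degrees(math.acos(cosang))
    signed = math.copysign(angle, cross) if cross != 0 else angle
    return DirectionAngle(angle_deg=angle, signed_deg=signed)


TRACK_COLUMNS = ["event_id", "subject", "frame", "x_px", "y_px"]


def read_tracks_csv(path, config_path) -> dict[tuple[object, str], Track]:
    """Read a track table plus its YAML side-car calibration.

    CSV columns: event_id, subject (ball|termite), frame, x_px, y_px.
    YAML keys: frame_rate; scale_m_per_px or (reference_px, reference_mm);
    optional body_axis: [dx, dy] in image coordinates.
    Returns a mapping (event_id, subject) -> Track.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing track column(s): {', '.join(missing)}")
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if "frame_rate" not in cfg:
        raise SchemaError(f"{config_path}: missing frame_rate")
    if "scale_m_per_px" in cfg:
        scale = float(cfg["scale_m_per_px"])
    elif "reference_px" in cfg and "reference_mm" in cfg:
        scale = calibrate_scale(float(cfg["reference_px"]), float(cfg["reference_mm"]))
    else:
        raise SchemaError(
            f"{config_path}: need scale_m_per_px or reference_px + reference_mm"
        )
    axis = tuple(cfg["body_axis"]) if "body_axis" in cfg else None
    tracks: dict[tuple[object, str], Track] = {}
    for (event_id, subject), grp in df.groupby(["event_id", "subject"], sort=False):
        grp = grp.sort_values("frame")
        pts = tuple(
            (int(f), float(x), float(y))
            for f, x, y in zip(grp["frame"], grp["x_px"], grp["y_px"])
        )
        tracks[(event_id, subject)] = Track(
            frame_rate=float(cfg["frame_rate"]), scale=scale, points=pts, body_axis=axis
        )
    return tracks


def track_displacement_px(track: Track) -> np.ndarray:
    """Pixel displacement vector over the first inter-frame interval."""
    (_, x0, y0), (_, x1, y1) = track.points[0], track.points[1]
    return np.array([x1 - x0, y1 - y0], dtype=float)
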