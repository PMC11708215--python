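"""Follicle-cell kinematics on a rotating egg chamber.

During stages ~1-8 the follicle epithelium rotates the egg chamber about its
anterior-posterior axis. With the chamber oriented so that rotation displaces
cells along the image y-axis, a tracked cell's angular position is recovered
from its projected offset from the chamber midline:

    theta = arctan((y - y_mid) / r) * 180 / pi      [degrees]

where r is the chamber radius measured as half the short-axis width in a
mid-focal plane. This projection is a small-angle approximation: near the
chamber edge (|y - y_mid| -> r) the projected displacement compresses true
arc length, so such samples are flagged. Angular velocity is the per-interval
difference quotient delta-theta / delta-t, averaged arithmetically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CellTrack", "angular_displacement", "angular_velocity", "mean_speed"]

#: samples with |y - y_mid| above this fraction of r are outside the regime
#: where the projection formula tracks true angle well.
EDGE_FLAG_FRACTION = 0.9


@dataclass
class CellTrack:
    """Manually tracked positions of one follicle cell.

    ``t_h`` are sample times in hours (strictly increasing); ``x_um``/``y_um``
    the in-plane coordinates in micrometres. ``y_mid_um`` is the chamber
    midline along the rotation-axis projection and ``r_um`` the chamber radius
    at the mid-focal plane.
    """

    cell_id: str
    t_h: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    y_mid_um: float
    r_um: float

    def __post_init__(self) -> None:
        self.t_h = np.asarray(self.t_h, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not (len(self.t_h) == len(self.x_um) == len(self.y_um)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t_h) > 1 and not np.all(np.diff(self.t_h) > 0):
            raise ValueError("sample times must be strictly increasing")
        if not self.r_um > 0:
            raise ValueError("chamber radius must be positive")

    @property
    def n_edge_flagged(self) -> int:
        """Samples with |y - y_mid| > 0.9 r, where the projection degrades."""
        off = np.abs(self.y_um - self.y_mid_um)
        return int(np.sum(off > EDGE_FLAG_FRACTION * self.r_um))


def angular_displacement(
    y: float | np.ndarray, y_mid: float, r: float
) -> float | np.ndarray:
    """Angular position in degrees: arctan((y - y_mid)/r) * 180/pi.

    Odd in (y - y_mid) and bounded in (-90, 90) degrees.
    """
    if not r > 0:
        raise ValueError("radius must be positive")
    out = np.degrees(np.arctan((np.asarray(y, dtype=float) - y_mid) / r))
    return float(out) if out.ndim == 0 else out


def angular_velocity(track: CellTrack) -> tuple[float, np.ndarray]:
    """Mean and per-interval angular velocity, degrees/hour.

    Each interval contributes delta-theta / delta-t; the track value is the
    arithmetic mean. Edge samples (beyond 0.9 r from the midline) trigger a
    warning because the projected angle underestimates true rotation there.
    """
    if len(track.t_h) < 2:
        raise ValueError("angular velocity needs at least 2 samples")
    if track.n_edge_flagged:
        warnings.warn(
            f"track {track.cell_id}: {track.n_edge_flagged} sample(s) beyond "
            f"{EDGE_FLAG_FRACTION:g}*r from the midline; angular estimates "
            "are unreliable near the chamber edge",
            stacklevel=2,
        )
    theta = angular_displacement(track.y_um, track.y_mid_um, track.r_um)
    per_interval = np.diff(theta) / np.diff(track.t_h)
    return float(per_interval.mean()), per_interval


def mean_speed(track: CellTrack) -> float:
    """Mean in-plane speed in um/minute.

    Mean over intervals of Euclidean step length divided by the interval
    duration; times are hours, so the result is divided by 60.
    """
    if len(track.t_h) < 2:
        raise ValueError("mean speed needs at least 2 samples")
    steps = np.hypot(np.diff(track.x_um), np.diff(track.y_um))
    speed_um_per_h = steps / np.diff(track.t_h)
    return float(speed_um_per_h.mean() / 60.0)
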