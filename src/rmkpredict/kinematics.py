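"""Planar reaching kinematics: lesion-frame transform and robot-measured metrics.

Movements are point-to-point reaches recorded by a planar end-effector robot
as timestamped positions (and optionally velocities) of the handle.  Each
movement starts at the central target (the origin) and runs toward one of
four peripheral targets labelled in a reference frame aligned with the lesion
side:

* ``A`` -- away from the body, +y;
* ``C`` -- toward the body, -y (the direction driven by elbow flexion and
  shoulder extension, hence most affected by the post-stroke flexor synergy);
* ``D`` -- lateral, +x;
* ``B`` -- medial, -x.

For a left-affected patient the recorded x axis is mirrored
(:func:`to_lesion_frame`) so that identical direction labels describe
identical shoulder/elbow synergies on either side.

Two metrics summarise each movement:

* **Movement Path Error (MPE)** -- the mean absolute deviation of the
  travelled path from the straight line joining the central and peripheral
  targets.  Because the peripheral targets lie on the coordinate axes, the
  deviation reduces to ``mean(|y|)`` for direction D and ``mean(|x|)`` for
  directions A and C; it is zero for a perfectly straight movement.
* **Mean Speed (MS)** -- the mean resultant planar velocity magnitude,
  ``mean(sqrt(vx**2 + vy**2))``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "DIRECTIONS",
    "MPE_DIRECTIONS",
    "Trajectory",
    "RMKFeatures",
    "to_lesion_frame",
    "differentiate",
    "resultant_speed",
    "compute_mpe",
    "compute_ms",
    "count_speed_peaks",
    "extract_features",
]

DIRECTIONS: tuple[str, ...] = ("A", "B", "C", "D")
#: Directions for which the path error is defined (targets on the axes;
#: direction B is used only for the speed metric).
MPE_DIRECTIONS: tuple[str, ...] = ("A", "C", "D")


@dataclass
class Trajectory:
    """One point-to-point planar movement.

    Positions are metres relative to the central target; timestamps are
    seconds and must be strictly increasing.  Velocities are optional -- when
    absent they can be derived from positions with :func:`differentiate`.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    direction: str
    side: str
    vx: np.ndarray | None = None
    vy: np.ndarray | None = None
    sample_rate: float | None = None
    frame: str = "robot"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.t.size
        if n < 2:
            raise ValueError("a trajectory needs at least two samples")
        if self.x.size != n or self.y.size != n:
            raise ValueError("t, x and y must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        for name in ("vx", "vy"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.size != n:
                    raise ValueError(f"{name} must match the sample count")
                setattr(self, name, v)
        if (self.vx is None) != (self.vy is None):
            raise ValueError("vx and vy must be given together")

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.t.size

    @property
    def has_velocities(self) -> bool:
        return self.vx is not None


def to_lesion_frame(traj: Trajectory) -> Trajectory:
    """Express a trajectory in the lesion-side reference frame.

    Right-affected recordings are already in the lesion frame and pass
    through unchanged.  Left-affected recordings have their x coordinates
    (and x velocities) sign-flipped, mirroring the workspace so the frame
    coincides with the lesion side.  The mirror map is an involution:
    applying it twice restores the original coordinates.
    """
    if not traj.side:
        raise ValueError("trajectory has no affected side set")
    new_frame = "lesion" if traj.frame == "robot" else "robot"
    if traj.side == "right":
        return replace(traj, frame=new_frame)
    return replace(
        traj,
        x=-traj.x,
        vx=None if traj.vx is None else -traj.vx,
        frame=new_frame,
    )


def differentiate(traj: Trajectory) -> Trajectory:
    """Derive velocities from positions by finite differences.

    Central differences on interior samples, one-sided at the endpoints,
    using the actual (possibly non-uniform) timestamps.  Exact for linear
    position signals; second-order accurate otherwise.
    """
    vx = np.gradient(traj.x, traj.t)
    vy = np.gradient(traj.y, traj.t)
    return replace(traj, vx=vx, vy=vy)


def resultant_speed(traj: Trajectory) -> np.ndarray:
    """Per-sample planar speed, deriving velocities if necessary."""
    if not traj.has_velocities:
        traj = differentiate(traj)
    return np.hypot(traj.vx, traj.vy)


def compute_mpe(traj: Trajectory) -> float:
    """Movement Path Error: mean distance from the ideal straight line.

    With the central target at the origin and the peripheral targets on the
    coordinate axes of the lesion frame, the point-to-line distance is
    ``|y|`` for direction D and ``|x|`` for directions A and C.  The metric
    is invariant under the left/right mirror transform, which only changes
    the sign of x.

    Raises for direction B, whose target does not define a path-error axis
    in this panel.
    """
    if traj.direction == "B":
        raise ValueError(
            "MPE is defined only for directions A, C and D; "
            "direction B contributes the mean-speed metric"
        )
    if traj.direction == "D":
        return float(np.mean(np.abs(traj.y)))
    return float(np.mean(np.abs(traj.x)))


def compute_ms(traj: Trajectory) -> float:
    """Mean Speed: average resultant velocity magnitude over the movement."""
    return float(np.mean(resultant_speed(traj)))


def count_speed_peaks(traj: Trajectory, min_prominence_frac: float = 0.05) -> int:
    """Count local maxima of the speed profile.

    A peak counts when its prominence is at least ``min_prominence_frac``
    times the maximum speed, which suppresses numerical ripple; a smooth
    single-submovement bell therefore yields exactly one peak.
    """
    if not 0 <= min_prominence_frac < 1:
        raise ValueError("min_prominence_frac must lie in [0, 1)")
    speed = resultant_speed(traj)
    top = float(np.max(speed))
    if top <= 0:
        return 0
    prominence = min_prominence_frac * top if min_prominence_frac > 0 else None
    peaks, _ = find_peaks(speed, prominence=prominence)
    return int(peaks.size)


@dataclass(frozen=True)
class RMKFeatures:
    """Per-patient robot-measured kinematic metrics.

    The four selected predictors are the path errors of directions A, C and D
    and the mean speed of direction B; the full per-direction panels (path
    error, mean speed, speed-peak count) are kept for exploratory use.
    Counts are averaged across repetitions, hence stored as floats.
    """

    mpe_a: float
    mpe_c: float
    mpe_d: float
    ms_b: float
    mpe: dict[str, float]
    ms: dict[str, float]
    speed_peaks: dict[str, float]

    def as_dict(self) -> dict[str, float]:
        """The four model predictors keyed by their column names."""
        return {
            "mpe_a": self.mpe_a,
            "mpe_c": self.mpe_c,
            "mpe_d": self.mpe_d,
            "ms_b": self.ms_b,
        }


def extract_features(
    trajectories: Mapping[str, Trajectory | Sequence[Trajectory]],
    min_prominence_frac: float = 0.05,
) -> RMKFeatures:
    """Extract the kinematic metric panel from one patient's movements.

    Parameters
    ----------
    trajectories:
        Mapping from direction label (``A``-``D``) to one trajectory or a
        sequence of repetitions.  All four directions are required.  Metrics
        are averaged across repetitions within a direction.
    """
    per_dir: dict[str, list[Trajectory]] = {}
    for direction, value in trajectories.items():
        reps = [value] if isinstance(value, Trajectory) else list(value)
        per_dir[direction] = reps
    missing = [d for d in DIRECTIONS if not per_dir.get(d)]
    if missing:
        raise ValueError(f"missing required direction(s): {', '.join(missing)}")

    mpe: dict[str, float] = {}
    ms: dict[str, float] = {}
    peaks: dict[str, float] = {}
    for direction in DIRECTIONS:
        reps = [to_lesion_frame(tr) for tr in per_dir[direction]]
        ms[direction] = float(np.mean([compute_ms(tr) for tr in reps]))
        peaks[direction] = float(
            np.mean([count_speed_peaks(tr, min_prominence_frac) for tr in reps])
        )
        if direction in MPE_DIRECTIONS:
            mpe[direction] = float(np.mean([compute_mpe(tr) for tr in reps]))

    return RMKFeatures(
        mpe_a=mpe["A"],
        mpe_c=mpe["C"],
        mpe_d=mpe["D"],
        ms_b=ms["B"],
        mpe=mpe,
        ms=ms,
        speed_peaks=peaks,
    )
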