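"""Activity-above-speed-threshold metric and immobility QC for centroid tracks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory",
    "LocomotionParams",
    "ActivityResult",
    "interval_speeds",
    "activity_above_threshold",
    "qc_immobility",
    "median_smooth",
]


@dataclass
class Trajectory:
    """A timestamped 2D centroid track (seconds, millimetres)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fly_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.x)) or not np.all(
            np.isfinite(self.y)
        ):
            raise ValueError("trajectory values must be finite")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class LocomotionParams:
    """Thresholds for the activity metric and immobility exclusion rule."""

    speed_threshold_mm_s: float = 2.7
    immobility_window_s: float = 60.0
    immobility_speed_eps_mm_s: float = 0.25
    assay_duration_s: float = 300.0

    def __post_init__(self) -> None:
        vals = (
            self.speed_threshold_mm_s,
            self.immobility_window_s,
            self.immobility_speed_eps_mm_s,
            self.assay_duration_s,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all locomotion parameters must be positive")
        if self.immobility_window_s > self.assay_duration_s:
            raise ValueError("immobility window cannot exceed assay duration")


@dataclass(frozen=True)
class ActivityResult:
    time_above_s: float
    fraction_above: float
    total_time_s: float
    excluded: bool = False
    exclusion_reason: str = ""


def interval_speeds(traj: Trajectory) -> np.ndarray:
    """Per-interval ``(dt, speed)`` pairs as an (n-1, 2) array.

    Speed is the Euclidean displacement between consecutive samples divided by
    the interval duration.
    """
    dt = np.diff(traj.t)
    dist = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return np.column_stack([dt, dist / dt])


def median_smooth(traj: Trajectory) -> Trajectory:
    """Centered 3-sample median filter on coordinates; endpoints untouched."""
    def f(v: np.ndarray) -> np.ndarray:
        out = v.copy()
        if len(v) >= 3:
            out[1:-1] = np.median(
                np.column_stack([v[:-2], v[1:-1], v[2:]]), axis=1
            )
        return out

    return Trajectory(t=traj.t, x=f(traj.x), y=f(traj.y), fly_id=traj.fly_id)


def qc_immobility(
    traj: Trajectory, params: LocomotionParams = LocomotionParams()
) -> tuple[bool, str]:
    """Exclusion check: any contiguous slow run longer than the window.

    A run of consecutive intervals each with speed below
    ``immobility_speed_eps_mm_s`` spanning strictly more than
    ``immobility_window_s`` seconds triggers exclusion.
    """
    iv = interval_speeds(traj)
    slow = iv[:, 1] < params.immobility_speed_eps_mm_s
    run = 0.0
    longest = 0.0
    for dt, is_slow in zip(iv[:, 0], slow):
        run = run + dt if is_slow else 0.0
        longest = max(longest, run)
    if longest > params.immobility_window_s:
        return True, (
            f"immobile for {longest:g}s (> {params.immobility_window_s:g}s)"
        )
    return False, ""


def activity_above_threshold(
    traj: Trajectory,
    params: LocomotionParams = LocomotionParams(),
    smooth: bool = False,
) -> ActivityResult:
    """Total time with speed strictly above the threshold, plus the QC verdict.

    Equality with the threshold contributes nothing ("above" is strict).
    """
    if smooth:
        traj = median_smooth(traj)
    iv = interval_speeds(traj)
    above = iv[:, 1] > params.speed_threshold_mm_s
    time_above = float(iv[above, 0].sum())
    total = float(traj.t[-1] - traj.t[0])
    excluded, reason = qc_immobility(traj, params)
    return ActivityResult(
        time_above_s=time_above,
        fraction_above=time_above / total,
        total_time_s=total,
        excluded=excluded,
        exclusion_reason=reason,
    )
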