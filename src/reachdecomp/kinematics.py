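"""Movement-time extraction from fingertip position traces.

The processing chain mirrors standard reach-kinematics practice: low-pass
filter the planar position at 5 Hz (second-order Butterworth, applied
forward-backward so threshold timings are not lagged), differentiate to
speed, then segment the movement between the instant speed first exceeds 5%
of its peak and the first instant at or after the peak where speed falls
below 5% of the peak *while the fingertip is inside the target disk*.
Movement time (MT) is the duration of that segment in ms.

Because right- and left-hemiparetic subjects show mirror-image target
difficulty, records from left-affected subjects are "flipped" left-to-right
(target k -> 6 - k, x mirrored about the sagittal axis) before pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .model import N_TARGETS

MT_TIMEOUT_MS = 5000.0  # trials had to finish within 5 s
ONSET_FRACTION = 0.05   # threshold as a fraction of peak speed


class MovementError(ValueError):
    """Raised when a trace contains no extractable movement."""


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled planar fingertip trace (seconds, cm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.size < 3:
            raise ValueError("trajectory needs at least 3 samples")
        dt = np.diff(t)
        if np.any(dt <= 0) or np.ptp(dt) > 1e-6:
            raise ValueError("time axis must be uniform and increasing")
        if not (len(self.x) == len(self.y) == t.size):
            raise ValueError("t, x, y must have equal length")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Trajectory":
        return cls(frame["t_s"].to_numpy(float),
                   frame["x_cm"].to_numpy(float),
                   frame["y_cm"].to_numpy(float))


@dataclass(frozen=True)
class TargetSpec:
    """Circular target on the table (cm)."""

    x: float
    y: float
    diameter: float = 3.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("target diameter must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class MovementSegment:
    onset_s: float
    offset_s: float
    mt_ms: float
    peak_speed_cm_s: float
    timeout: bool = False

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("offset must follow onset")


def lowpass_filter(traj: Trajectory, cutoff_hz: float = 5.0,
                   *, zero_phase: bool = True) -> Trajectory:
    """Second-order Butterworth low-pass on both coordinates.

    Zero-phase (forward-backward) by default, so onset/offset timings are
    not biased late; the effective magnitude response is then the square of
    the single-pass response (-6 dB at the cutoff).
    """
    nyquist = traj.sample_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist:g})")
    b, a = butter(2, cutoff_hz / nyquist)
    if zero_phase:
        x = filtfilt(b, a, traj.x)
        y = filtfilt(b, a, traj.y)
    else:
        from scipy.signal import lfilter
        x = lfilter(b, a, traj.x)
        y = lfilter(b, a, traj.y)
    return Trajectory(traj.t, x, y)


def compute_speed(traj: Trajectory, *, method: str = "central") -> np.ndarray:
    """Planar speed (cm/s) from componentwise numerical differentiation.

    Central differences in the interior, one-sided at the endpoints
    (``np.gradient``); ``method="forward"`` uses simple first differences.
    """
    if method == "central":
        vx = np.gradient(traj.x, traj.t)
        vy = np.gradient(traj.y, traj.t)
    elif method == "forward":
        dt = float(traj.t[1] - traj.t[0])
        vx = np.empty_like(traj.x)
        vy = np.empty_like(traj.y)
        vx[:-1] = np.diff(traj.x) / dt
        vy[:-1] = np.diff(traj.y) / dt
        vx[-1] = vx[-2]
        vy[-1] = vy[-2]
    else:
        raise ValueError(f"unknown differentiation method {method!r}")
    return np.hypot(vx, vy)


def extract_movement_time(traj: Trajectory, target: TargetSpec,
                          *, cutoff_hz: float = 5.0,
                          prefiltered: bool = False) -> MovementSegment:
    """Segment one reach and return its movement time.

    Onset: first sample with speed above 5% of the peak.  Offset: first
    sample at or after the peak with speed below 5% of the peak while the
    fingertip lies within the target disk (the search starts at the peak so
    sub-threshold jitter before movement onset cannot terminate the
    segment).  MT above 5000 ms is flagged as a timeout, not an error.
    """
    f = traj if prefiltered else lowpass_filter(traj, cutoff_hz)
    speed = compute_speed(f)
    peak = float(speed.max())
    if peak <= 0:
        raise MovementError("no movement: peak speed is zero")
    thr = ONSET_FRACTION * peak
    above = np.nonzero(speed > thr)[0]
    if above.size == 0:
        raise MovementError("no movement: speed never exceeds threshold")
    onset = int(above[0])
    i_peak = int(np.argmax(speed))
    inside = np.hypot(f.x - target.x, f.y - target.y) <= target.radius
    cand = np.nonzero((speed < thr) & inside)[0]
    cand = cand[cand >= i_peak]
    if cand.size == 0:
        raise MovementError("target never acquired: no in-target sub-threshold sample")
    offset = int(cand[0])
    mt_ms = (traj.t[offset] - traj.t[onset]) * 1000.0
    return MovementSegment(
        onset_s=float(traj.t[onset]),
        offset_s=float(traj.t[offset]),
        mt_ms=float(mt_ms),
        peak_speed_cm_s=peak,
        timeout=mt_ms > MT_TIMEOUT_MS,
    )


def flip_left_hemiparesis(records: pd.DataFrame, side: str) -> pd.DataFrame:
    """Mirror a left-affected subject's records left-to-right.

    Target index k is remapped to ``6 - k`` (an involution fixing the
    centre target); MT values are untouched.  Right-side records are
    returned unchanged (a copy).
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    out = records.copy()
    if side == "left":
        out["target"] = (N_TARGETS + 1) - out["target"]
    return out


def flip_trajectory(traj: Trajectory, home_x: float = 0.0) -> Trajectory:
    """Mirror a trace about the sagittal (x = home_x) axis."""
    return Trajectory(traj.t, 2.0 * home_x - traj.x, traj.y)
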