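"""Dynamic-frame timing, continuous curves and frame-sampled time-activity curves.

A dynamic PET acquisition is a contiguous sequence of time frames; each frame
records the time-average of the underlying activity concentration over its
duration. The clinical radiowater perfusion protocol modelled throughout this
package uses 24 frames (14 x 5 s, 3 x 10 s, 3 x 20 s, 4 x 30 s, 280 s total),
with the scan started at injection (t = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, Tuple

import numpy as np

__all__ = [
    "ScheduleError",
    "FrameSchedule",
    "ContinuousCurve",
    "SampledTAC",
    "build_frame_schedule",
    "default_frame_spec",
    "sample_frames",
]


class ScheduleError(ValueError):
    """Raised for inconsistent or unphysical frame schedules."""


#: Frame specification of the clinical 280 s dynamic perfusion protocol.
DEFAULT_FRAME_SPEC: Tuple[Tuple[int, float], ...] = ((14, 5.0), (3, 10.0), (3, 20.0), (4, 30.0))


def default_frame_spec() -> Tuple[Tuple[int, float], ...]:
    """The 24-frame clinical schedule as a (count, duration_s) specification."""
    return DEFAULT_FRAME_SPEC


@dataclass(frozen=True, eq=False)
class FrameSchedule:
    """Contiguous, non-overlapping dynamic frame grid (seconds from scan start)."""

    frame_starts: np.ndarray
    frame_durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.frame_starts, dtype=float)
        durs = np.asarray(self.frame_durations, dtype=float)
        object.__setattr__(self, "frame_starts", starts)
        object.__setattr__(self, "frame_durations", durs)
        if starts.ndim != 1 or durs.ndim != 1 or starts.size != durs.size:
            raise ScheduleError("frame_starts and frame_durations must be 1-D and equal length")
        if starts.size == 0:
            raise ScheduleError("schedule must contain at least one frame")
        if np.any(durs <= 0):
            raise ScheduleError("all frame durations must be positive")
        ends = starts + durs
        if not np.allclose(starts[1:], ends[:-1], rtol=0.0, atol=1e-9):
            raise ScheduleError("frames must be contiguous and non-overlapping")

    # numpy fields make the generated __eq__ unusable; compare values explicitly
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return bool(
            self.frame_starts.size == other.frame_starts.size
            and np.allclose(self.frame_starts, other.frame_starts, rtol=0.0, atol=1e-9)
            and np.allclose(self.frame_durations, other.frame_durations, rtol=0.0, atol=1e-9)
        )

    @property
    def n_frames(self) -> int:
        return int(self.frame_starts.size)

    @property
    def frame_ends(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations

    @property
    def mid_times(self) -> np.ndarray:
        return self.frame_starts + 0.5 * self.frame_durations

    @property
    def total_duration(self) -> float:
        return float(self.frame_ends[-1] - self.frame_starts[0])


def build_frame_schedule(spec: Iterable[Tuple[int, float]], start: float = 0.0) -> FrameSchedule:
    """Expand a ``[(count, duration_s), ...]`` specification into a FrameSchedule.

    Frames are laid out contiguously beginning at ``start`` (default 0, the
    injection time). ``[(14, 5), (3, 10), (3, 20), (4, 30)]`` yields the
    24-frame, 280 s clinical schedule.
    """
    spec = list(spec)
    if not spec:
        raise ScheduleError("empty frame specification")
    durations = []
    for count, duration in spec:
        if int(count) < 1:
            raise ScheduleError(f"frame count must be >= 1, got {count}")
        if duration <= 0:
            raise ScheduleError(f"frame duration must be positive, got {duration}")
        durations.extend([float(duration)] * int(count))
    durs = np.asarray(durations)
    starts = start + np.concatenate([[0.0], np.cumsum(durs)[:-1]])
    return FrameSchedule(starts, durs)


@dataclass(frozen=True, eq=False)
class ContinuousCurve:
    """Activity concentration (kBq/ml) on a strictly increasing time grid (s)."""

    time_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time_grid", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("time_grid and values must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("a curve needs at least two samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_grid must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("curve contains non-finite entries")

    def __call__(self, times: np.ndarray) -> np.ndarray:
        """Piecewise-linear interpolation, zero outside the support."""
        return np.interp(times, self.time_grid, self.values, left=0.0, right=0.0)


@dataclass(eq=False)
class SampledTAC:
    """Frame-sampled time-activity curve with decay-correction bookkeeping.

    ``decay_corrected`` records whether values have been referenced back to
    ``reference_time`` (default 0 s = injection); the correction operation in
    :mod:`flowphantom.kinetics` refuses to apply or remove the correction twice.
    """

    schedule: FrameSchedule
    values: np.ndarray
    decay_corrected: bool = False
    reference_time: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        self.values = v
        if v.ndim != 1 or v.size != self.schedule.n_frames:
            raise ValueError("need exactly one value per frame")
        if not np.all(np.isfinite(v)):
            raise ValueError("TAC contains non-finite values")

    def with_values(self, values: np.ndarray, **changes) -> "SampledTAC":
        return replace(self, values=np.asarray(values, dtype=float), **changes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampledTAC):
            return NotImplemented
        return bool(
            self.schedule == other.schedule
            and np.array_equal(self.values, other.values)
            and self.decay_corrected == other.decay_corrected
            and self.reference_time == other.reference_time
        )


def sample_frames(curve: ContinuousCurve, schedule: FrameSchedule) -> SampledTAC:
    """Average a continuous curve over each frame: the ideal acquisition.

    Each frame value is the time-average of the (piecewise-linear) curve over
    [start, start + duration); the sum of value x duration therefore equals the
    trapezoidal integral of the curve over the scan.
    """
    t, v = curve.time_grid, curve.values
    if schedule.frame_starts[0] < t[0] - 1e-9 or schedule.frame_ends[-1] > t[-1] + 1e-9:
        raise ValueError(
            f"schedule span [{schedule.frame_starts[0]}, {schedule.frame_ends[-1]}] s "
            f"extends past curve support [{t[0]}, {t[-1]}] s"
        )
    # cumulative trapezoid of the piecewise-linear curve, interpolated at frame edges
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))])

    def cum_at(times: np.ndarray) -> np.ndarray:
        times = np.clip(times, t[0], t[-1])
        idx = np.clip(np.searchsorted(t, times, side="right") - 1, 0, t.size - 2)
        t0, t1 = t[idx], t[idx + 1]
        v0 = v[idx]
        slope = (v[idx + 1] - v0) / (t1 - t0)
        dt = times - t0
        return cum[idx] + v0 * dt + 0.5 * slope * dt * dt

    integrals = cum_at(schedule.frame_ends) - cum_at(schedule.frame_starts)
    return SampledTAC(schedule, integrals / schedule.frame_durations)


def frame_average_matrix(
    t_fine: np.ndarray, schedule: FrameSchedule, lam: float = 0.0
) -> np.ndarray:
    """Dense matrix W with (W @ values) = trapezoidal frame averages on t_fine.

    ``t_fine`` must be uniform and cover the schedule; used by the fitter to
    turn a model curve on a fine grid into predicted frame values cheaply.

    With ``lam > 0`` each row becomes the exp(-lam t)-weighted frame average:
    this is how a decay-corrected frame value relates to the underlying
    decay-corrected curve (the scanner averages the *decaying* signal over the
    frame, and the correction divides by the mean decay factor), so a fitter
    comparing model curves against decay-corrected frame data should use the
    weighted form.
    """
    t_fine = np.asarray(t_fine, dtype=float)
    step = t_fine[1] - t_fine[0]
    n = t_fine.size
    W = np.zeros((schedule.n_frames, n))
    # trapezoid weights for [a, b]: step on interior points, step/2 on edges,
    # with fractional end segments handled by linear interpolation weights.
    for k, (a, b) in enumerate(zip(schedule.frame_starts, schedule.frame_ends)):
        ia = int(np.ceil((a - t_fine[0]) / step - 1e-9))
        ib = int(np.floor((b - t_fine[0]) / step + 1e-9))
        if ia > ib:
            raise ValueError("fine grid too coarse for frame")
        w = np.zeros(n)
        if ib > ia:
            w[ia:ib + 1] = step
            w[ia] = 0.5 * step
            w[ib] = 0.5 * step
        # fractional pieces outside [t_fine[ia], t_fine[ib]]
        for (edge, node, sign) in ((a, ia, -1), (b, ib, +1)):
            frac = sign * (edge - t_fine[node])
            if frac > 1e-12:
                j = node + sign
                # integral of linear interp over the fractional sliver
                w0 = frac * (1 - 0.5 * frac / step)
                w1 = 0.5 * frac * frac / step
                w[node] += w0
                w[j] += w1
        W[k] = w / (b - a)
    if lam != 0.0:
        decay = np.exp(-lam * t_fine)
        W = W * decay[None, :]
        W = W / (W.sum(axis=1, keepdims=True))
    return W
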