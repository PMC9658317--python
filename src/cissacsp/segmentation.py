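"""Sliding-window time segmentation of epoched trials.

Each trial is sliced into ``T`` equal-length, possibly overlapping windows.
Combining CSP features across windows injects temporal information that a
single whole-trial covariance averages away: the ERD/ERS response to a
motor-imagery cue is transient, so different windows carry different
discriminative content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trial_store import TrialSet

__all__ = ["WindowSpec", "SegmentedTrials", "plan_windows", "segment"]


@dataclass(frozen=True)
class WindowSpec:
    """Either a sliding window (length + stride, s) or explicit windows.

    Explicit windows are (start, end) pairs in seconds relative to trial
    start and take precedence when given.
    """

    window_length: float | None = None
    stride: float | None = None
    windows: tuple[tuple[float, float], ...] | None = None

    @classmethod
    def sliding(cls, window_length: float, stride: float) -> "WindowSpec":
        if window_length <= 0:
            raise ValueError(f"window_length must be positive, got {window_length}")
        if stride <= 0:
            raise ValueError(f"stride must be positive, got {stride}")
        return cls(window_length=window_length, stride=stride)

    @classmethod
    def explicit(cls, windows) -> "WindowSpec":
        wins = tuple((float(a), float(b)) for a, b in windows)
        if not wins:
            raise ValueError("explicit window list is empty")
        for a, b in wins:
            if not b > a:
                raise ValueError(f"window ({a}, {b}) has non-positive length")
        return cls(windows=wins)


@dataclass
class SegmentedTrials:
    """One :class:`TrialSet` per time window, sharing trial order and labels."""

    segments: list[TrialSet]
    windows: list[tuple[float, float]]
    spec: WindowSpec

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


def plan_windows(trial_length: float, spec: WindowSpec) -> list[tuple[float, float]]:
    """Return the ordered (start, end) windows for a trial of ``trial_length`` s.

    Sliding windows are ``[start, start + window_length)`` at starts
    0, stride, 2*stride, ... while the end stays within the trial, giving
    ``floor((trial_length - window_length)/stride) + 1`` windows; trailing
    samples that do not fill a whole window are dropped.
    """
    if spec.windows is not None:
        for a, b in spec.windows:
            if a < -1e-9 or b > trial_length + 1e-9:
                raise ValueError(
                    f"window ({a}, {b}) lies outside the trial [0, {trial_length}]"
                )
        return [tuple(w) for w in spec.windows]
    wl, stride = spec.window_length, spec.stride
    if wl is None or stride is None:
        raise ValueError("WindowSpec must define either explicit windows or length+stride")
    if wl > trial_length + 1e-9:
        raise ValueError(
            f"window length {wl} s exceeds trial length {trial_length} s"
        )
    count = int(np.floor((trial_length - wl) / stride + 1e-9)) + 1
    return [(i * stride, i * stride + wl) for i in range(count)]


def segment(ts: TrialSet, spec: WindowSpec) -> SegmentedTrials:
    """Slice every trial into the windows planned by :func:`plan_windows`.

    Window ``(start, end)`` maps to sample indices
    ``[round(start*fs), round(end*fs))`` — half-open, 0-based — so window
    lengths are reproducible even when ``t*fs`` is not an integer.
    """
    trial_length = ts.n_samples / ts.fs
    windows = plan_windows(trial_length, spec)
    segments = []
    for start, end in windows:
        i0 = int(round(start * ts.fs))
        i1 = int(round(end * ts.fs))
        segments.append(
            TrialSet(
                data=ts.data[:, :, i0:i1],
                labels=ts.labels,
                fs=ts.fs,
                channel_names=list(ts.channel_names),
                t0=ts.t0 + start,
            )
        )
    return SegmentedTrials(segments=segments, windows=windows, spec=spec)
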