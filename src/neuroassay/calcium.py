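"""Calcium-transient detection in fluorescence traces.

Traces are per-cell mean fluorescence intensities F (relative units, 0-255)
sampled at a few Hz.  Single Ca2+ transients are found with a
smoothing-derivative-threshold scheme: each trace is smoothed by averaging
neighboring points, a first difference is taken, and points where the
derivative exceeds ``accuracy_coeff * SD(derivative)`` mark pulse onsets
(positive crossing) and ends (negative crossing).  Because both the
derivative and its SD scale with any affine intensity rescaling, detection is
invariant to gain and offset changes of the imaging system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CalciumTraceSet:
    """Per-cell fluorescence traces, ``traces[cell, frame]`` on the 0-255 scale."""

    traces: np.ndarray
    frame_rate: float = 4.0
    cell_ids: list | None = None

    def __post_init__(self):
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim == 1:
            self.traces = self.traces[None, :]
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (cells x frames)")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if np.any(self.traces < 0) or np.any(self.traces > 255):
            raise ValueError("intensities must lie in [0, 255]")
        if self.cell_ids is None:
            self.cell_ids = list(range(self.traces.shape[0]))
        elif len(self.cell_ids) != self.traces.shape[0]:
            raise ValueError("cell_ids length does not match traces")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns cell_id, frame, F."""
        n_c, n_f = self.traces.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(self.cell_ids, n_f),
                "frame": np.tile(np.arange(n_f), n_c),
                "F": self.traces.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_rate: float = 4.0) -> "CalciumTraceSet":
        df = pd.read_csv(path)
        wide = df.pivot(index="cell_id", columns="frame", values="F").sort_index()
        return cls(wide.to_numpy(), frame_rate=frame_rate, cell_ids=wide.index.tolist())


@dataclass
class TransientDetectionParams:
    """Detection accuracy coefficient and preprocessing switches.

    ``accuracy_coeff`` multiplies the SD of the trace derivative to give the
    crossing threshold; ``smooth`` applies two-point neighbor averaging first;
    ``symmetric`` detects on ``|d|`` instead of signed crossings.

    ``noise_floor_coeff`` guards quiet traces: the threshold never drops
    below this multiple of the median-based (spike-insensitive) SD of the
    derivative.  On a trace carrying real transients the total SD dwarfs the
    noise SD and the floor is inactive; on a flat noisy trace the total SD
    *is* the noise SD, and without the floor an ``accuracy_coeff`` of 2 would
    amount to a 2-sigma test that flags noise in any sufficiently long
    recording.  Both terms scale with the intensity gain, so detection stays
    affine-invariant.
    """

    accuracy_coeff: float = 2.0
    smooth: bool = True
    symmetric: bool = False
    noise_floor_coeff: float = 5.0

    def __post_init__(self):
        if not self.accuracy_coeff > 0:
            raise ValueError("accuracy_coeff must be positive")
        if self.noise_floor_coeff < 0:
            raise ValueError("noise_floor_coeff must be non-negative")


@dataclass
class TransientSet:
    """Per-cell transient intervals ``{cell_id: [(start_s, end_s), ...]}``."""

    intervals: dict
    duration: float = None  # recording length, s

    def active_cells(self) -> list:
        return [cid for cid, iv in self.intervals.items() if len(iv) > 0]

    def n_transients(self, cell_id) -> int:
        return len(self.intervals[cell_id])

    def all_durations(self) -> np.ndarray:
        d = [e - s for iv in self.intervals.values() for s, e in iv]
        return np.asarray(d)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (cid, s, e) for cid, iv in self.intervals.items() for s, e in iv
        ]
        return pd.DataFrame(rows, columns=["cell_id", "start_s", "end_s"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def extract_roi_traces(stack, rois, frame_rate: float = 4.0) -> CalciumTraceSet:
    """Mean pixel intensity of each labeled ROI in each frame.

    ``stack`` is ``(frames, h, w)``, ``rois`` a label image of shape
    ``(h, w)`` where label 0 is background and label k > 0 marks cell k.
    """
    stack = np.asarray(stack)
    rois = np.asarray(rois)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D (frames, h, w)")
    if rois.shape != stack.shape[1:]:
        raise ValueError("ROI mask shape does not match frames")
    labels = np.unique(rois)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("no ROIs in mask")
    traces = np.empty((labels.size, stack.shape[0]))
    for i, lab in enumerate(labels):
        mask = rois == lab
        if not mask.any():
            raise ValueError(f"ROI {lab} is empty")
        traces[i] = stack[:, mask].mean(axis=1)
    return CalciumTraceSet(traces, frame_rate=frame_rate, cell_ids=labels.tolist())


def smooth_trace(trace) -> np.ndarray:
    """Two-point neighbor averaging: ``out[i] = (x[i] + x[i+1]) / 2``, length n-1."""
    x = np.asarray(trace, dtype=float)
    if x.size < 2:
        raise ValueError("smoothing needs at least 2 points")
    return 0.5 * (x[:-1] + x[1:])


def trace_derivative(trace) -> np.ndarray:
    """Simple first difference ``d[i] = x[i+1] - x[i]``, length n-1."""
    x = np.asarray(trace, dtype=float)
    if x.size < 2:
        raise ValueError("derivative needs at least 2 points")
    return np.diff(x)


def _detect_pulses_1d(trace, frame_rate, params):
    """Pulse intervals for one trace; returns list of (start_s, end_s)."""
    y = smooth_trace(trace) if params.smooth else np.asarray(trace, dtype=float)
    d = trace_derivative(y)
    sd = d.std()
    if sd == 0:
        return []
    # robust (transient-insensitive) noise SD of the derivative
    sd_noise = np.median(np.abs(d - np.median(d))) / 0.6745
    thr = max(params.accuracy_coeff * sd, params.noise_floor_coeff * sd_noise)
    n_frames = len(trace)
    # derivative sample i is assigned the time of frame i+1 (end of the
    # difference interval; with smoothing this is also its center frame)
    t = (np.arange(d.size) + 1) / frame_rate
    intervals = []
    open_t = None
    for i in range(d.size):
        if params.symmetric:
            # any suprathreshold |d| point alternately opens and closes
            opens = closes = abs(d[i]) > thr
        else:
            opens = d[i] > thr
            closes = d[i] < -thr
        if open_t is None:
            if opens:
                open_t = t[i]
        elif closes and t[i] > open_t:
            intervals.append((open_t, t[i]))
            open_t = None
    if open_t is not None:
        end = (n_frames - 1) / frame_rate
        if end > open_t:
            intervals.append((open_t, end))
    return intervals


def detect_transients(
    traces: CalciumTraceSet, params: TransientDetectionParams | None = None
) -> TransientSet:
    """Detect Ca2+ transients per cell via the derivative-threshold rule.

    Onsets are positive suprathreshold derivative points, ends the next
    negative suprathreshold point; an unmatched onset is closed at the trace
    end.  Cells with at least one pulse are flagged active.
    """
    if params is None:
        params = TransientDetectionParams()
    if traces.n_frames < 3:
        raise ValueError("need at least 3 frames")
    intervals = {
        cid: _detect_pulses_1d(traces.traces[i], traces.frame_rate, params)
        for i, cid in enumerate(traces.cell_ids)
    }
    return TransientSet(intervals, duration=traces.duration)


def calcium_metrics(transients: TransientSet, window: float = None) -> dict:
    """Activity metrics: active cells, oscillations/min, mean duration.

    Oscillation rate is reported both averaged over active cells only
    (``osc_per_min_active``) and over all cells (``osc_per_min_all``).
    """
    if window is None:
        window = transients.duration
    if window is None or not window > 0:
        raise ValueError("window must be positive")
    n_cells = len(transients.intervals)
    counts = np.array([len(iv) for iv in transients.intervals.values()])
    active = counts > 0
    out = {
        "window_s": float(window),
        "n_cells": int(n_cells),
        "n_active_cells": int(active.sum()),
        "active_fraction": float(active.mean()) if n_cells else 0.0,
        "osc_per_min_all": float(counts.mean() / (window / 60.0)) if n_cells else 0.0,
        "osc_per_min_active": (
            float(counts[active].mean() / (window / 60.0)) if active.any() else 0.0
        ),
    }
    d = transients.all_durations()
    if d.size:
        out["transient_duration_mean_s"] = float(d.mean())
        out["transient_duration_sem_s"] = (
            float(d.std(ddof=1) / np.sqrt(d.size)) if d.size > 1 else None
        )
    else:
        out["transient_duration_mean_s"] = None
        out["transient_duration_sem_s"] = None
    return out
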