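"""Network-burst ("small burst") detection from the total spiking rate.

A network burst is a short episode of synchronized high-rate firing across
many electrodes.  Detection works on the total spiking rate TSR(t): the
pooled spike count over all electrodes in consecutive 50 ms bins.  The burst
threshold is

    T_burst = c * SD(TSR),   c = 0.1 by default,

and bursts are maximal runs of bins whose count exceeds the threshold, after
merging runs separated by short sub-threshold gaps and dropping very short
runs.  The deliberately low coefficient keeps the whole rise and fall of a
burst above threshold while sparse basal activity (isolated single-bin
counts) is removed by the minimum-duration rule.

Bin edges only localize a burst to 50 ms; when the spike table is available
the burst boundaries are snapped to the first and last spike inside the
suprathreshold bin span, which recovers burst durations at sub-bin
resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spikes import SpikeEventTable, _run_edges


@dataclass
class TsrSeries:
    """Total spiking rate: pooled spike counts per time bin.

    ``counts[i]`` is the number of spikes from all electrodes in
    ``[t0 + i*bw, t0 + (i+1)*bw)`` with ``bw = bin_width`` (ms).
    """

    counts: np.ndarray
    bin_width: float = 50.0  # ms
    t0: float = 0.0  # s

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def times(self) -> np.ndarray:
        """Left edge of each bin, seconds."""
        return self.t0 + np.arange(self.n_bins) * self.bin_width * 1e-3

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width * 1e-3


@dataclass
class BurstDetectionParams:
    """Threshold coefficient and run-level clean-up rules.

    ``threshold_coeff`` multiplies the SD of the TSR to give the burst
    threshold.  Runs separated by at most ``merge_gap`` sub-threshold bins are
    merged; merged runs shorter than ``min_duration`` bins are dropped (this
    is what excludes isolated basal-activity bins at the low 0.1 coefficient).
    """

    threshold_coeff: float = 0.1
    min_duration: int = 2  # bins
    merge_gap: int = 1  # bins

    def __post_init__(self):
        if not self.threshold_coeff > 0:
            raise ValueError("threshold_coeff must be positive")
        if self.min_duration < 1 or self.merge_gap < 0:
            raise ValueError("min_duration >= 1 and merge_gap >= 0 required")


@dataclass
class BurstSet:
    """Detected bursts: start/end times (s), spike count, over a window."""

    start: np.ndarray
    end: np.ndarray
    n_spikes: np.ndarray
    window_duration: float = None

    def __post_init__(self):
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        self.n_spikes = np.asarray(self.n_spikes, dtype=np.int64)
        if not (self.start.shape == self.end.shape == self.n_spikes.shape):
            raise ValueError("start/end/n_spikes must have equal length")
        if np.any(self.end <= self.start):
            raise ValueError("bursts must have end > start")
        if self.start.size > 1 and np.any(self.start[1:] < self.end[:-1]):
            raise ValueError("bursts must be ordered and non-overlapping")

    def __len__(self) -> int:
        return self.start.size

    @property
    def durations(self) -> np.ndarray:
        return self.end - self.start

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"start_s": self.start, "end_s": self.end, "n_spikes": self.n_spikes}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, window_duration=None) -> "BurstSet":
        df = pd.read_csv(path)
        return cls(
            df["start_s"].to_numpy(),
            df["end_s"].to_numpy(),
            df["n_spikes"].to_numpy(),
            window_duration=window_duration,
        )


def compute_tsr(
    events: SpikeEventTable, bin_width: float = 50.0, window=None
) -> TsrSeries:
    """Bin pooled spike times of all channels into contiguous bins.

    ``window`` is a ``(t_start, t_end)`` pair in seconds; it defaults to
    ``(0, events.duration)`` (or the last spike time).  Spikes inside the
    window are conserved: the counts sum to the number of such spikes.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    if window is None:
        t1 = events.duration
        if t1 is None:
            t1 = float(events.time.max()) if len(events) else 0.0
        window = (0.0, t1)
    t0, t1 = float(window[0]), float(window[1])
    if not t1 > t0:
        raise ValueError("window must have positive length")
    bw = bin_width * 1e-3
    n_bins = int(np.ceil((t1 - t0) / bw - 1e-9))
    edges = t0 + np.arange(n_bins + 1) * bw
    counts, _ = np.histogram(events.time, bins=edges)
    return TsrSeries(counts.astype(np.int64), bin_width=bin_width, t0=t0)


def detect_bursts(
    tsr: TsrSeries,
    params: BurstDetectionParams | None = None,
    events: SpikeEventTable | None = None,
) -> BurstSet:
    """Segment network bursts by thresholding the TSR at ``c * SD(TSR)``.

    A zero-variance TSR yields no bursts (the threshold is undefined).
    Boundaries are the edges of the first and last suprathreshold bin; when
    ``events`` is given they are refined to the first/last spike inside that
    bin span, giving sub-bin duration resolution.
    """
    if params is None:
        params = BurstDetectionParams()
    if tsr.n_bins < 2:
        raise ValueError("TSR needs at least 2 bins")
    counts = tsr.counts.astype(float)
    sd = counts.std()
    window = tsr.duration
    if sd == 0:
        return BurstSet(np.empty(0), np.empty(0), np.empty(0, dtype=int), window)
    thr = params.threshold_coeff * sd
    starts, ends = _run_edges(counts > thr)
    if starts.size == 0:
        return BurstSet(np.empty(0), np.empty(0), np.empty(0, dtype=int), window)
    # merge runs separated by <= merge_gap sub-threshold bins
    m_starts, m_ends = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - m_ends[-1] <= params.merge_gap:
            m_ends[-1] = e
        else:
            m_starts.append(s)
            m_ends.append(e)
    bw = tsr.bin_width * 1e-3
    b_start, b_end, b_n = [], [], []
    for s, e in zip(m_starts, m_ends):
        if e - s < params.min_duration:
            continue
        t_lo = tsr.t0 + s * bw
        t_hi = tsr.t0 + e * bw
        n = int(tsr.counts[s:e].sum())
        if events is not None:
            in_span = (events.time >= t_lo) & (events.time < t_hi)
            if np.any(in_span):
                t = events.time[in_span]
                t_first, t_last = float(t.min()), float(t.max())
                if t_last > t_first:
                    t_lo, t_hi = t_first, t_last
        b_start.append(t_lo)
        b_end.append(t_hi)
        b_n.append(n)
    return BurstSet(
        np.asarray(b_start), np.asarray(b_end), np.asarray(b_n, dtype=int), window
    )


def burst_metrics(
    bursts: BurstSet, events: SpikeEventTable | None = None, window_duration=None
) -> dict:
    """Summary metrics: bursts/min, spikes/burst, population spikes/s, duration.

    Quantities that are undefined for an empty burst set (mean spikes per
    burst, duration statistics) are reported as ``None``.
    """
    window = window_duration
    if window is None:
        window = bursts.window_duration
    if window is None and events is not None:
        window = events.duration
    if window is None or not window > 0:
        raise ValueError("a positive window duration is required")
    n = len(bursts)
    out = {
        "window_s": float(window),
        "n_bursts": int(n),
        "bursts_per_min": n / (window / 60.0),
    }
    if n:
        out["spikes_per_burst_mean"] = float(bursts.n_spikes.mean())
        d = bursts.durations
        out["burst_duration_mean_s"] = float(d.mean())
        out["burst_duration_sem_s"] = (
            float(d.std(ddof=1) / np.sqrt(n)) if n > 1 else None
        )
    else:
        out["spikes_per_burst_mean"] = None
        out["burst_duration_mean_s"] = None
        out["burst_duration_sem_s"] = None
    if events is not None:
        out["population_spikes_per_s"] = len(events) / window
    return out


def save_metrics(metrics: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(metrics, f, indent=2)
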