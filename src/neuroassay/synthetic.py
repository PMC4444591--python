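"""Ground-truth simulators for MEA recordings, calcium imaging and viability.

Every generator draws from a single seeded ``numpy.random.Generator`` per
call and records the exact events it inserted, so detection modules can be
validated by parameter recovery rather than against inaccessible raw data.

The MEA simulator produces Gaussian electrode noise with embedded biphasic
extracellular spikes; spike trains are basal Poisson activity per channel
plus network bursts — intervals during which a random subset of channels
fires at an elevated rate.  The calcium simulator produces slow (~10 s)
fluorescence transients (fast rise, plateau, fast fall) on a 0-255 intensity
scale sampled at a few Hz, with a configurable fraction of silent dead
cells, and can render the traces into a small image stack with disk-shaped
ROIs.  Scenario presets set generator rates to the group means observed in
hippocampal cultures subjected to acute normobaric hypoxia, with and without
BDNF / k252a treatment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .calcium import CalciumTraceSet, extract_roi_traces
from .spikes import SignalRecording, SpikeEventTable
from .viability import ViabilityCounts

# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class MeaSimConfig:
    """Parameters of the MEA recording simulator.

    Rates are per channel (``basal_rate``, ``within_burst_rate`` in spikes/s)
    or per recording (``burst_rate`` in bursts/min).  ``burst_duration`` may
    be a scalar (ms) or a ``(lo, hi)`` pair for uniformly drawn durations.
    ``burst_min_gap`` keeps consecutive bursts separated so they remain
    distinct events at the 50 ms TSR bin scale; ``refractory_ms`` is the
    per-channel dead time the generator enforces between inserted spikes.
    """

    n_channels: int = 64
    sampling_rate: float = 20000.0  # Hz
    duration: float = 60.0  # s
    noise_sigma: float = 5.0  # uV
    spike_amplitude: float = 40.0  # uV, negative-leading biphasic peak
    spike_width: float = 1.0  # ms
    basal_rate: float = 1.0  # spikes/s/channel
    burst_rate: float = 6.0  # bursts/min
    burst_duration: object = 300.0  # ms, or (lo, hi) ms
    within_burst_rate: float = 50.0  # spikes/s/participating channel
    participating_fraction: float = 0.8
    burst_min_gap: float = 0.15  # s between burst end and next onset
    refractory_ms: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        for name in ("basal_rate", "burst_rate", "within_burst_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0 <= self.participating_fraction <= 1:
            raise ValueError("participating_fraction must be in [0, 1]")
        lo, hi = self._duration_range()
        if not 0 < lo <= hi:
            raise ValueError("burst_duration must be positive")

    def _duration_range(self):
        if np.isscalar(self.burst_duration):
            return float(self.burst_duration), float(self.burst_duration)
        lo, hi = self.burst_duration
        return float(lo), float(hi)


@dataclass
class CaSimConfig:
    """Parameters of the calcium-trace simulator.

    Intensities are on the 0-255 scale; transients rise over ``rise_time``,
    plateau, and fall over ``fall_time`` for a total of
    ``oscillation_duration`` seconds.  ``oscillation_rate`` is the target
    transients/min per active cell; ``dead_fraction`` of cells are silent
    (flat baseline plus noise).
    """

    n_cells: int = 20
    frame_rate: float = 4.0  # Hz
    duration: float = 600.0  # s
    oscillation_rate: float = 4.0  # /min per active cell
    oscillation_duration: float = 10.0  # s
    amplitude: float = 80.0
    baseline: float = 40.0
    noise_sigma: float = 2.0
    dead_fraction: float = 0.0
    rise_time: float = 0.5  # s
    fall_time: float = 0.5  # s
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not self.duration > 0 or not self.frame_rate > 0:
            raise ValueError("duration and frame_rate must be positive")
        if self.oscillation_rate < 0 or self.noise_sigma < 0:
            raise ValueError("rates and noise must be non-negative")
        if not self.oscillation_duration > 0:
            raise ValueError("oscillation_duration must be positive")
        if self.baseline + self.amplitude > 255 or self.baseline < 0:
            raise ValueError("baseline + amplitude must not exceed 255")
        if not 0 <= self.dead_fraction <= 1:
            raise ValueError("dead_fraction must be in [0, 1]")
        if self.rise_time + self.fall_time > self.oscillation_duration:
            raise ValueError("rise_time + fall_time exceeds oscillation_duration")
        if self.oscillation_rate > 0:
            cycle = 60.0 / self.oscillation_rate
            if cycle <= self.oscillation_duration:
                raise ValueError(
                    "oscillation_rate too high for non-overlapping transients "
                    f"of {self.oscillation_duration} s"
                )


@dataclass
class GroundTruth:
    """Generator-side event lists: the oracle against which detectors are scored."""

    spike_events: SpikeEventTable | None = None
    burst_intervals: list = field(default_factory=list)
    transient_intervals: dict = field(default_factory=dict)
    dead_cell_ids: list = field(default_factory=list)

    def to_json(self, path) -> None:
        obj = {
            "burst_intervals": [[float(a), float(b)] for a, b in self.burst_intervals],
            "transient_intervals": {
                str(k): [[float(a), float(b)] for a, b in v]
                for k, v in self.transient_intervals.items()
            },
            "dead_cell_ids": [int(i) for i in self.dead_cell_ids],
        }
        if self.spike_events is not None:
            obj["spike_events"] = {
                "channel": self.spike_events.channel.tolist(),
                "time": self.spike_events.time.tolist(),
            }
        with open(path, "w") as f:
            json.dump(obj, f)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as f:
            obj = json.load(f)
        ev = None
        if "spike_events" in obj:
            ev = SpikeEventTable(
                np.asarray(obj["spike_events"]["channel"]),
                np.asarray(obj["spike_events"]["time"]),
            )
        return cls(
            spike_events=ev,
            burst_intervals=[tuple(x) for x in obj.get("burst_intervals", [])],
            transient_intervals={
                int(k): [tuple(x) for x in v]
                for k, v in obj.get("transient_intervals", {}).items()
            },
            dead_cell_ids=obj.get("dead_cell_ids", []),
        )


# ---------------------------------------------------------------------------
# MEA simulation
# ---------------------------------------------------------------------------


def spike_template(sampling_rate: float, amplitude: float, width_ms: float = 1.0):
    """Biphasic extracellular spike template and its peak offset (samples).

    A negative half-sine lobe (60% of the width) followed by a smaller
    positive rebound (40% of the width at 40% amplitude) — the canonical
    shape of an extracellular action potential near the soma.
    """
    n = max(int(round(width_ms * 1e-3 * sampling_rate)), 4)
    n_neg = max(int(round(0.6 * n)), 2)
    n_pos = max(n - n_neg, 2)
    neg = -amplitude * np.sin(np.pi * (np.arange(n_neg) + 0.5) / n_neg)
    pos = 0.4 * amplitude * np.sin(np.pi * (np.arange(n_pos) + 0.5) / n_pos)
    tpl = np.concatenate([neg, pos])
    return tpl, int(np.argmin(tpl))


def _draw_burst_intervals(config: MeaSimConfig, rng) -> list:
    """Non-overlapping burst intervals from a Poisson onset process with dead time."""
    lam = config.burst_rate / 60.0
    if lam == 0:
        return []
    lo, hi = config._duration_range()
    intervals = []
    t = rng.exponential(1.0 / lam)
    prev_end = -np.inf
    while t < config.duration:
        if t >= prev_end + config.burst_min_gap:
            dur = (lo if lo == hi else rng.uniform(lo, hi)) * 1e-3
            end = min(t + dur, config.duration)
            if end > t:
                intervals.append((t, end))
                prev_end = end
        t += rng.exponential(1.0 / lam)
    return intervals


def generate_mea_events(config: MeaSimConfig, rng=None):
    """Draw the spike raster (basal + burst spikes) without rendering voltage.

    Returns ``(SpikeEventTable, GroundTruth)``.  Useful for long simulations
    where only spike-train statistics matter; :func:`generate_mea_recording`
    renders the same raster into voltage traces.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    bursts = _draw_burst_intervals(config, rng)
    n_part = int(round(config.participating_fraction * config.n_channels))
    per_channel = [[] for _ in range(config.n_channels)]
    for ch in range(config.n_channels):
        n_basal = rng.poisson(config.basal_rate * config.duration)
        if n_basal:
            per_channel[ch].append(rng.uniform(0.0, config.duration, n_basal))
    for (t0, t1) in bursts:
        chans = rng.choice(config.n_channels, size=n_part, replace=False)
        for ch in chans:
            n_sp = rng.poisson(config.within_burst_rate * (t1 - t0))
            if n_sp:
                per_channel[ch].append(rng.uniform(t0, t1, n_sp))
    dead = config.refractory_ms * 1e-3
    chan_out, time_out = [], []
    for ch in range(config.n_channels):
        if not per_channel[ch]:
            continue
        t = np.sort(np.concatenate(per_channel[ch]))
        if dead > 0 and t.size > 1:
            kept = [t[0]]
            for ti in t[1:]:
                if ti - kept[-1] >= dead:
                    kept.append(ti)
            t = np.asarray(kept)
        chan_out.append(np.full(t.size, ch, dtype=np.int64))
        time_out.append(t)
    if chan_out:
        channel = np.concatenate(chan_out)
        time = np.concatenate(time_out)
    else:
        channel = np.empty(0, dtype=np.int64)
        time = np.empty(0)
    amp = np.full(time.shape, -config.spike_amplitude)
    events = SpikeEventTable(
        channel,
        time,
        amp,
        duration=config.duration,
        channel_ids=list(range(config.n_channels)),
    )
    gt = GroundTruth(spike_events=events, burst_intervals=bursts)
    return events, gt


def generate_mea_recording(config: MeaSimConfig):
    """Render a full voltage recording: Gaussian noise plus inserted spikes.

    Returns ``(SignalRecording, GroundTruth)``; the ground truth lists every
    inserted spike (after the generator's per-channel refractory dead time)
    and every burst interval.  With all rates zero the output is pure noise
    and the ground truth is empty.  Identical configs (same seed) produce
    bit-identical arrays.
    """
    rng = np.random.default_rng(config.seed)
    events, gt = generate_mea_events(config, rng)
    n_samples = int(round(config.duration * config.sampling_rate))
    sig = rng.normal(0.0, config.noise_sigma, (config.n_channels, n_samples)).astype(
        np.float32
    )
    if len(events):
        tpl, peak_off = spike_template(
            config.sampling_rate, config.spike_amplitude, config.spike_width
        )
        tpl = tpl.astype(np.float32)
        w = tpl.size
        idx = np.round(events.time * config.sampling_rate).astype(np.int64) - peak_off
        for ch, i0 in zip(events.channel, idx):
            a = max(i0, 0)
            b = min(i0 + w, n_samples)
            if b > a:
                sig[ch, a:b] += tpl[a - i0 : b - i0]
    rec = SignalRecording(
        sig,
        config.sampling_rate,
        channel_ids=list(range(config.n_channels)),
        filtered=False,
    )
    return rec, gt


# ---------------------------------------------------------------------------
# calcium simulation
# ---------------------------------------------------------------------------


def _transient_shape(t, onset, dur, rise, fall, amplitude):
    """Trapezoidal transient value at times t (vectorized)."""
    x = t - onset
    up = np.clip(x / rise, 0.0, 1.0) if rise > 0 else (x >= 0).astype(float)
    down = np.clip((dur - x) / fall, 0.0, 1.0) if fall > 0 else (x <= dur).astype(float)
    return amplitude * np.clip(np.minimum(up, down), 0.0, 1.0) * ((x >= 0) & (x <= dur))


def _draw_transient_onsets(config: CaSimConfig, rng) -> list:
    """Renewal process: exponential gaps between non-overlapping transients.

    The gap mean is chosen so the realized rate matches ``oscillation_rate``:
    mean cycle length = gap + duration = 60 / rate.
    """
    if config.oscillation_rate == 0:
        return []
    gap_mean = 60.0 / config.oscillation_rate - config.oscillation_duration
    intervals = []
    t = rng.exponential(gap_mean)
    while t < config.duration:
        end = min(t + config.oscillation_duration, config.duration)
        if end > t:
            intervals.append((t, end))
        t = t + config.oscillation_duration + rng.exponential(gap_mean)
    return intervals


@dataclass
class CalciumData:
    """Simulator output: traces, optional rendered stack + ROI labels, truth."""

    traces: CalciumTraceSet
    ground_truth: GroundTruth
    stack: np.ndarray | None = None  # (frames, h, w) uint8
    rois: np.ndarray | None = None  # (h, w) int labels


def _place_disks(n, size, radius, margin, rng, max_tries=20000):
    """Non-overlapping disk centers on a size x size grid; error if impossible."""
    centers = []
    min_d2 = (2 * radius + 2) ** 2
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} non-overlapping nuclei in a {size}x{size} image"
            )
        tries += 1
        c = rng.uniform(margin, size - margin, 2)
        if all((c[0] - a) ** 2 + (c[1] - b) ** 2 >= min_d2 for a, b in centers):
            centers.append((c[0], c[1]))
    return centers


def generate_calcium_data(
    config: CaSimConfig,
    render_stack: bool = False,
    image_size: int = 64,
    roi_radius: int = 3,
) -> CalciumData:
    """Simulate per-cell fluorescence traces, optionally as an image stack.

    Active cells show trapezoidal transients at renewal-process onsets; dead
    cells (a ``dead_fraction`` random subset) stay at flat baseline.  Without
    rendering, traces are the clean signal plus Gaussian intensity noise,
    clipped to [0, 255].  With rendering, each cell is a disk in a
    ``image_size``-pixel square stack, pixels get independent noise, and the
    stored traces are the ROI means of the rendered stack so that trace-level
    and image-level analyses see exactly the same data.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration * config.frame_rate))
    t = np.arange(n_frames) / config.frame_rate
    n_dead = int(round(config.dead_fraction * config.n_cells))
    dead_ids = sorted(rng.choice(config.n_cells, size=n_dead, replace=False).tolist())
    dead_set = set(dead_ids)
    clean = np.full((config.n_cells, n_frames), float(config.baseline))
    transient_intervals = {}
    for c in range(config.n_cells):
        if c in dead_set:
            transient_intervals[c] = []
            continue
        ivs = _draw_transient_onsets(config, rng)
        transient_intervals[c] = ivs
        for (s, e) in ivs:
            clean[c] += _transient_shape(
                t, s, config.oscillation_duration, config.rise_time,
                config.fall_time, config.amplitude,
            )
    clean = np.clip(clean, 0.0, 255.0)
    gt = GroundTruth(
        transient_intervals=transient_intervals, dead_cell_ids=dead_ids
    )
    if not render_stack:
        noisy = clean + rng.normal(0.0, config.noise_sigma, clean.shape)
        traces = CalciumTraceSet(
            np.clip(noisy, 0.0, 255.0), frame_rate=config.frame_rate
        )
        return CalciumData(traces=traces, ground_truth=gt)
    # render cells as disks; background at a dim level distinct from cells
    centers = _place_disks(
        config.n_cells, image_size, roi_radius, roi_radius + 1, rng
    )
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    rois = np.zeros((image_size, image_size), dtype=np.int32)
    for c, (cy, cx) in enumerate(centers):
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= roi_radius**2
        rois[mask] = c + 1  # labels are 1-based; cell c has label c+1
    background = 10.0
    stack = np.empty((n_frames, image_size, image_size), dtype=np.uint8)
    base_img = np.full((image_size, image_size), background)
    cell_masks = [rois == c + 1 for c in range(config.n_cells)]
    for f in range(n_frames):
        frame = base_img.copy()
        for c, mask in enumerate(cell_masks):
            frame[mask] = clean[c, f]
        frame += rng.normal(0.0, config.noise_sigma, frame.shape)
        stack[f] = np.clip(np.round(frame), 0, 255).astype(np.uint8)
    traces = extract_roi_traces(stack, rois, frame_rate=config.frame_rate)
    traces.cell_ids = [c - 1 for c in traces.cell_ids]  # back to 0-based cell ids
    return CalciumData(traces=traces, ground_truth=gt, stack=stack, rois=rois)


# ---------------------------------------------------------------------------
# viability simulation
# ---------------------------------------------------------------------------


def generate_viability_image(
    n_total: int,
    n_dead: int,
    size: int = 256,
    seed: int = 0,
    radius: int = 4,
    intensity: float = 200.0,
    background: float = 10.0,
    noise_sigma: float = 3.0,
):
    """Two-channel stained-nuclei image with known dead fraction.

    Channel 0 carries all ``n_total`` nuclei (bisBenzimide, total stain);
    channel 1 carries the ``n_dead`` subset (propidium iodide, dead stain).
    Nuclei are non-overlapping disks; placement failure raises.  Returns
    ``(image (2, size, size) uint8, GroundTruth)``.
    """
    if n_dead > n_total:
        raise ValueError("n_dead cannot exceed n_total")
    if n_total < 0 or n_dead < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    centers = _place_disks(n_total, size, radius, radius + 1, rng)
    dead_ids = sorted(rng.choice(n_total, size=n_dead, replace=False).tolist())
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.full((2, size, size), background)
    for i, (cy, cx) in enumerate(centers):
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        img[0][mask] = intensity
        if i in dead_ids:
            img[1][mask] = intensity
    img += rng.normal(0.0, noise_sigma, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    gt = GroundTruth(dead_cell_ids=dead_ids)
    return img, gt


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

#: Group means of the in vitro hypoxia assay used as simulation targets:
#: network-burst rate (/min), pooled spike rate (spikes/s over 64 electrodes),
#: mean spikes per burst (None = derived from the two rates), calcium
#: oscillation rate (/min per active cell), fraction of cells with calcium
#: activity, and dead cells per 100 (dual-stain counts).
_SCENARIOS = {
    "sham": dict(
        burst_rate=3.54, pop_rate=62.21, spikes_per_burst=None,
        ca_rate=4.41, ca_active=0.954, dead_per_100=2,
    ),
    "hypoxia": dict(
        burst_rate=0.21, pop_rate=3.04, spikes_per_burst=None,
        ca_rate=0.19, ca_active=0.056, dead_per_100=23,
    ),
    "hypoxia_bdnf": dict(
        burst_rate=2.78, pop_rate=50.05, spikes_per_burst=None,
        ca_rate=1.79, ca_active=0.339, dead_per_100=8,
    ),
    "hypoxia_bdnf_k252a": dict(
        burst_rate=0.231, pop_rate=None, spikes_per_burst=214.32,
        ca_rate=0.19, ca_active=0.056, dead_per_100=27,
    ),
}

#: Fraction of the pooled spike rate carried by basal (non-burst) activity.
#: Bursts dominate the spike count in these cultures (hundreds to thousands
#: of spikes per burst); a small basal share also keeps the low TSR burst
#: threshold (0.1 x SD) above chance coincidences of basal spikes.
_BASAL_FRACTION = 0.01
_PRESET_BURST_DURATION_MS = 300.0
_PRESET_PARTICIPATION = 0.8


@dataclass
class ScenarioPreset:
    """Generator configs and viability counts for one experimental group."""

    name: str
    mea: MeaSimConfig
    calcium: CaSimConfig
    viability: ViabilityCounts


def scenario_names() -> list:
    return list(_SCENARIOS)


def scenario_preset(name: str, seed: int = 0) -> ScenarioPreset:
    """Simulation preset emulating one experimental group.

    The generator rates are set so that the simulated recordings reproduce
    the group means: network-burst rate, pooled spike rate, calcium
    oscillation rate, fraction of calcium-active cells, and dead-cell count
    per 100 cells.  Within-burst firing is calibrated from the spikes/burst
    implied by the burst and pooled spike rates (basal activity is assigned
    a small fixed share of the pooled rate so the TSR threshold separates
    bursts from basal spiking, as in the recorded cultures where bursts
    dominate the spike count).
    """
    if name not in _SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; known: {', '.join(_SCENARIOS)}"
        )
    s = _SCENARIOS[name]
    n_channels = 64
    burst_per_s = s["burst_rate"] / 60.0
    if s["pop_rate"] is not None:
        pop_rate = s["pop_rate"]
        spb = s["spikes_per_burst"]
        if spb is None:
            spb = pop_rate * (1.0 - _BASAL_FRACTION) / burst_per_s
    else:
        spb = s["spikes_per_burst"]
        pop_rate = burst_per_s * spb / (1.0 - _BASAL_FRACTION)
    n_part = int(round(_PRESET_PARTICIPATION * n_channels))
    dur_s = _PRESET_BURST_DURATION_MS * 1e-3
    mea = MeaSimConfig(
        n_channels=n_channels,
        duration=600.0,
        basal_rate=_BASAL_FRACTION * pop_rate / n_channels,
        burst_rate=s["burst_rate"],
        burst_duration=_PRESET_BURST_DURATION_MS,
        within_burst_rate=spb / (n_part * dur_s),
        participating_fraction=_PRESET_PARTICIPATION,
        seed=seed,
    )
    calcium = CaSimConfig(
        n_cells=100,
        duration=600.0,
        oscillation_rate=s["ca_rate"],
        dead_fraction=1.0 - s["ca_active"],
        seed=seed,
    )
    viability = ViabilityCounts(n_dead=s["dead_per_100"], n_total=100)
    return ScenarioPreset(name=name, mea=mea, calcium=calcium, viability=viability)
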