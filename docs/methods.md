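# Methods

This note documents the models implemented in `neuroassay`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that matter when comparing results.

## Spike detection (`neuroassay.spikes`)

**Model.** Extracellular spikes are brief (~1 ms) voltage deflections riding
on electrode noise. Detection is per channel:

1. Zero-phase band-pass filter, 4th-order Butterworth applied
   forward–backward (`sosfiltfilt`), corners 300–8000 Hz. Zero-phase
   filtering is required so spike timestamps are not systematically
   shifted; 4th order is a conventional compromise between roll-off and
   ringing.
2. Noise estimate σ = median(|x|)/0.6745. The constant is the 75th
   percentile of the standard normal (median(|Z|) = Φ⁻¹(0.75) ≈ 0.6745),
   so on Gaussian noise the estimator converges to the true SD while being
   nearly immune to contamination by the spikes themselves — unlike the
   sample SD, which grows with firing rate.
3. Threshold T = N_S·σ with N_S = 4. On a 5 µV-SD channel this puts T at
   20 µV, the regime where spikes above 20 µV are reliably caught.
4. Each maximal suprathreshold excursion of |x| (or −x with
   `polarity="negative"`) contributes one event, timestamped at its
   extremum. The excursion must stay above threshold for at least
   `min_width` = 0.15 ms: a real spike crosses a 4σ threshold for a
   sizable fraction of its width, whereas threshold crossings of Gaussian
   noise are mostly single samples. Without this guard, a stationary
   Gaussian process with ~5 kHz bandwidth crosses 4σ about once per
   second per channel, which would contaminate rasters and the TSR at
   exactly the rate scale of basal activity.
5. Refractory rule: events closer than 1 ms to the previously *accepted*
   event on the same channel are discarded (greedy, earliest kept). An
   interval of exactly 1 ms is allowed — "minimal interspike interval"
   is read as inclusive.

σ and T are computed per channel, since electrode noise varies across an
array. Both-polarity detection is the default because the simulator's
biphasic template has a significant positive rebound and polarity is not
otherwise constrained; negative-only detection is available.

## Network-burst detection (`neuroassay.bursts`)

**Model.** A network burst is a short episode of synchronized firing across
electrodes. The total spiking rate TSR(t) is the pooled spike count of all
channels in consecutive 50 ms bins. The burst threshold is
T_burst = c·SD(TSR) with c = 0.1 (SD about the mean, ddof = 0); bursts are
maximal runs of bins with counts strictly above T_burst, after merging runs
separated by ≤ `merge_gap` = 1 sub-threshold bin and dropping merged runs
spanning < `min_duration` = 2 bins. The deliberately low coefficient keeps
the full rise and fall of a burst above threshold; the minimum-duration rule
is what removes isolated basal-activity bins. A zero-variance TSR yields no
bursts (the threshold is undefined); this is documented behavior.

**Boundary refinement.** Bins localize spikes only to 50 ms. When the spike
table is passed to `detect_bursts`, each burst's boundaries are snapped to
the first and last spike inside its suprathreshold bin span. This matters
quantitatively: at 50 ms resolution the bin span overestimates a burst's
duration by ~+1 bin on average, which for 150–400 ms bursts is a
15–30% relative error; with spike-snapped boundaries the mean relative
duration error on simulated rasters with bursts at occurrence rates up to
5 Hz is ~3%, within the 10% accuracy bound this detector family is
validated to. `scripts/acceptance.py` recomputes this figure.

**Caveats.** With basal activity heavy enough that 0.1·SD(TSR) falls below
one spike per bin, chance coincidences of basal spikes in neighboring bins
are reported as bursts; the coefficient was designed for recordings in
which bursts dominate the spike count. Raising the threshold coefficient
does not *strictly* monotonically reduce the burst count in pathological
cases — a higher threshold can split one run into two — but it is monotone
when each burst is unimodal in the TSR, which is the generic case.

## Calcium-transient detection (`neuroassay.calcium`)

**Model.** Per-cell fluorescence F (relative units 0–255, ~4 Hz frame
rate) is extracted as the mean pixel intensity of each ROI per frame.
Detection per trace:

1. Two-point smoothing: out[i] = (x[i]+x[i+1])/2 (applied once).
2. Simple derivative: d[i] = y[i+1] − y[i]. Derivative sample i is
   assigned the time of frame i+1 (with smoothing this is the center of
   the three frames the difference spans).
3. Threshold θ = a·SD(d) with accuracy coefficient a = 2.0 (a
   required-documented parameter; detection counts are sensitive to it).
   A pulse opens at the first point with d > θ and closes at the next
   point with d < −θ; unmatched onsets are closed at the trace end.
   `symmetric=True` switches to the |d| > θ alternation variant.
4. Noise floor: θ never drops below 5× the median-based (robust) SD of
   the derivative. On a trace with real transients the total SD is
   dominated by the transient edges and the floor is inactive; on a flat
   noisy trace SD(d) *is* the noise SD, and a bare 2·SD rule is a 2σ test
   that would flag noise in any sufficiently long recording regardless of
   the noise amplitude. Both terms scale with intensity gain, so detection
   remains invariant under affine rescaling of F.

Oscillations/min is reported both averaged over active cells (≥ 1 pulse)
and over all cells; conditioning on detected-active cells upward-biases
the rate in sparse groups (cells with zero events drop out of the
denominator), so recovery benchmarks use the all-cells figure on fully
active populations.

## Viability (`neuroassay.viability`)

Dead-cell percentage = 100·n_dead/n_total from propidium-iodide (dead) and
bisBenzimide (all nuclei) channel counts. Counting is deliberately simple
and auditable: global threshold (Otsu or fixed) + 8-connected components
with area ≥ 5 px. For two-channel images the Otsu threshold is learned on
the total-stain channel and reused for the dead-stain channel: the dead
channel may contain no nuclei at all, and Otsu on a unimodal background
image splits noise into spurious objects. Touching nuclei merged by the
threshold count as one component (no watershed splitting); counts can also
be supplied directly as numbers.

## Synthetic data (`neuroassay.synthetic`)

All generators draw from a single `numpy.random.Generator` seeded per
call; identical configs give bit-identical output, and every inserted
event is recorded as ground truth.

**MEA.** Gaussian noise (SD 5 µV default) per channel; spikes are a
biphasic template — negative half-sine (60% of a 1 ms width) followed by a
40%-amplitude positive rebound — inserted at the drawn times, default peak
40 µV. Spike trains: a basal Poisson process per channel, plus network
bursts. Burst onsets follow a Poisson process with a dead time (no overlap;
≥ 150 ms between bursts so consecutive bursts remain distinct at the 50 ms
bin scale); during a burst a freshly drawn subset of channels
(`participating_fraction`, default 0.8) fires as a Poisson process at
`within_burst_rate`. A 1 ms dead time per channel is enforced on the
generated trains so ground truth itself satisfies the refractory
invariant. Burst durations are fixed or drawn uniformly from a range.
`generate_mea_events` returns the raster without rendering voltage — used
for long simulations where only spike-train statistics matter;
`generate_mea_recording` renders the same raster.

**Calcium.** Transients are trapezoids: 0.5 s linear rise, plateau, 0.5 s
linear fall, total `oscillation_duration` = 10 s, amplitude 80 above a
baseline of 40 on the 0–255 scale, Gaussian intensity noise (SD 2).
Onsets per active cell follow a renewal process — exponential gap plus the
fixed transient duration — with the gap mean set so the realized rate
equals `oscillation_rate`; rates requiring overlapping transients are
rejected. A `dead_fraction` subset of cells is silent (flat baseline).
With `render_stack=True` the cells become non-overlapping disks in a small
uint8 image stack with per-pixel noise, and the stored traces are the ROI
means of the rendered stack, so trace-level and image-level analyses see
identical data.

**Viability images.** Non-overlapping disks (rejection-sampled placement,
error if impossible) at intensity 200 over background 10; channel 0 holds
all nuclei, channel 1 the dead subset.

**What the generators do not emulate:** real spike-waveform diversity and
amplitude variation, electrode drift and artifacts, non-Gaussian /
correlated noise, burst-internal rate structure (rectangular rate
elevation only), calcium indicator photobleaching, ΔF/F baseline drift,
overlapping cells. Passing recovery tests therefore demonstrates
correctness of the detectors under their stated assumptions, not
performance on arbitrary real recordings.

## Scenario presets

`scenario_preset(name)` returns generator configs whose target rates equal
the group means of the emulated hypoxia assay:

| group               | bursts/min | pooled spikes/s | Ca osc/min | Ca-active | dead/100 |
|---------------------|-----------:|----------------:|-----------:|----------:|---------:|
| sham                | 3.54       | 62.21           | 4.41       | 95.4%     | 2        |
| hypoxia             | 0.21       | 3.04            | 0.19       | 5.6%      | 23       |
| hypoxia_bdnf        | 2.78       | 50.05           | 1.79       | 33.9%     | 8        |
| hypoxia_bdnf_k252a  | 0.231      | derived (0.87)  | 0.19       | 5.6%      | 27       |

Within-burst firing is calibrated from the spikes/burst implied by the
burst and pooled spike rates (burst duration 300 ms, 80% of 64 channels
participating); basal activity is assigned a fixed 1% share of the pooled
rate — in these cultures bursts dominate the spike count (hundreds to
thousands of spikes per burst), and a small basal share is also what keeps
the 0.1·SD(TSR) threshold above chance basal coincidences in the sparse
hypoxia group. Group SEMs are not modeled, only means. For the k252a
group only burst counts and spikes/burst are available; its pooled rate is
derived from those, and its calcium and viability values are filled with
the hypoxia-like levels that group exhibits. The `hypoxia_bdnf` dead-cell
count (8/100) is an intermediate value; only the direction (a reduction
versus hypoxia) is constrained by the assay.

## Statistics (`neuroassay.stats`)

Mean ± SEM (SEM = sample SD/√n, absent for n = 1). One-way fixed-effects
ANOVA (scipy); with two groups F equals the square of the equal-variance
two-sample t statistic, which the tests verify, and the type-I error rate
under a simulated null is calibrated at α = 0.05. Two-factor designs
(treatment × day) use an OLS fit with type-II decomposition (statsmodels).
The comparison report flags each group against the sham and hypoxia
references using two-group ANOVA with Holm correction across the
comparisons of each metric; a Student–Newman–Keuls post-hoc is *not*
implemented — Holm-corrected pairwise comparisons are the package's
documented substitute for a post-hoc procedure.

## Pipeline (`neuroassay.pipeline`, CLI)

`run_pipeline(RunConfig)` executes simulate → detect → metrics → report
per scenario and seed, with per-(seed, scenario) child seeds derived via
`numpy.random.SeedSequence` and all stage outputs written as CSV/JSON (no
hidden state; the manifest records version, configuration and its hash;
no timestamps, so reruns are byte-identical). `render_signals=True` runs
the full voltage chain (noise rendering, filtering, spike detection);
the default raster-level mode skips voltage synthesis, which changes the
cost from minutes to seconds for multi-replicate runs while exercising
identical burst/calcium/statistics code. Viability counts per replicate
are drawn binomially around the preset fraction so the report's ANOVA has
within-group variance.

**Problem sizes.** The validation script uses 20 recordings × 60 s × 64
channels at the raster level (~1400 bursts); the test suite recovers
preset rates from 10–20 raster-level replicates of 10–30 minutes and runs
the voltage chain on smaller recordings (≤ 10 s, ≤ 16 channels), which
already contain thousands of spikes — ample for the per-spike and
per-burst properties being checked.

## Known limitations

- The burst detector's 0.1 coefficient presumes burst-dominated activity;
  under basal-dominated activity it reports spurious bursts (see above).
- The transient detector's accuracy coefficient is a free parameter;
  values far from 2 trade misses against false pulses, and only the
  noise floor keeps silent cells quiet.
- Nucleus counting has no clump splitting; dense fields undercount.
- Two-way ANOVA assumes a complete crossed design with per-cell
  replicates; unbalanced but complete designs use type-II sums of squares.
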