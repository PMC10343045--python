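# Methods

This note records the models behind `multisync`, the defaults and why they
were chosen, the numerical conventions, and what the simulation-based tests
do and do not establish about real recordings.

## The acquisition model

Two devices record the same physiology on independent clocks. The clock
transform is affine: `device_time = offset + (1 + drift) · true_time`, with
`drift = 0` by default (no drift figure is available for the hardware class
modelled; the parameter exists so users can inject one). When a trigger
fires at true time *t*, each device annotates it at

```
mark = clock(t) + λ,   λ ~ N(μ, σ²) truncated below at λ_floor ≥ 0
```

Defaults for the marking latency λ: research path μ = 0.5 ms, σ = 0 (GPIO
trigger lines are near-deterministic); monitor path μ = 105 ms, σ = 19 ms,
floor 0 (the empirically observed bench values for a networked annotation
path). Truncation prevents unphysical negative delays; for these defaults
the truncated region carries ≈ 10⁻⁸ of the mass, so the truncated moments
are indistinguishable from (μ, σ). Messages themselves are modelled at the
transport-abstraction level: a versioned JSON envelope `{label, seq,
timestamp}` around a user-defined payload string, identical over the
UDP-like and TCP-like transports. The payload↔marker mapping must be
injective; decoding an ambiguous mapping is an error rather than a guess.

## The session simulator

`simulate_session` derives every channel from shared sources so that
cross-device analyses have a physical ground truth:

* **ECG** — sums of Gaussian bumps per beat (dominant R, σ = 10 ms; smaller
  P and T placed at fractions of the local RR interval). Beat times follow a
  bpm profile with multiplicative RR jitter (default 3 %). Morphology is
  schematic on purpose: every algorithm here depends on timing, none on
  clinical waveform shape.
* **Monitor channels** — the 2000 Hz research ECG is polyphase-resampled to
  250 Hz and passed through a 0.5–40 Hz zero-phase Butterworth as an
  approximation of the monitor's inbuilt, non-defeatable "monitor-mode"
  filter (the true response is proprietary; this is a documented stand-in).
  Monitor series start on the shifted clock.
* **Impedance pneumograph** — one raised-cosine excursion of width 1.2 s per
  breath (smooth and band-limited, which is exactly what an amplitude
  threshold detector needs), plus optional cardiac-frequency bumps at the R
  peaks (default gain 0.15 of breath amplitude) and white noise (sd 0.02).
  Breathing defaults: period 1.5 s (40 breaths/min, an infant-like rate)
  with 5 % jitter. `ip_breath_amplitude = 0` emulates the bench
  configuration in which electrodes are pasted together on a table — the
  condition under which marking precision is measured.
* **Push-button artifact** — a negative half-sine starting exactly at the
  press time, depth 5 signal units, width 0.5 s; its onset sample is
  `floor((press − start) · rate)`.
* **EEG** — white background noise plus a template inserted at each
  stimulus time (+ optional per-trial jitter, realised on the sample grid so
  alignment recovery has an exact answer).
* **Numerics** — instantaneous heart rate interpolated to 1 Hz; SpO₂ as
  97 % plus small noise.

All generators draw from independent child streams of one seed
(`numpy.random.SeedSequence.spawn`), so sessions are bit-reproducible and
adding a channel does not perturb the others.

**What the generator does not emulate:** clinical ECG/EEG morphology,
movement and electrode-pop artifacts, non-stationary breathing amplitude
beyond step changes, monitor firmware buffering beyond a single latency
distribution, or clock drift during a session (unless configured). Passing
recovery tests therefore demonstrates the *estimators* are correct under
known conditions, not that real recordings meet those conditions.

## Marking precision (artifact-onset timing)

The IP is epoched ±1 s around each mark, baseline corrected to the pre-mark
mean, and the onset is the earliest sample in the epoch strictly below
`0.03 × min(signal in (0, +1] s after the mark)`. The full epoch is scanned
because the physical artifact precedes the delayed mark; only the
threshold-defining window is post-mark. If the post-mark minimum is
non-negative there is no artifact to time and the event errors out rather
than returning a fabricated latency. Latency is reported as
`mark − onset` (positive when the mark is late). A per-event onset-override
table substitutes manual onset times where the automatic rule misfits.

Because the rule times the first *sample* past threshold, the detected
latency reads low by up to one IP sample (16 ms at 62.5 Hz) plus the
artifact's own threshold-crossing time (≈ 4 ms for the default half-sine),
and cardiac bumps riding on the artifact can add a few ms more. Validation
therefore scores the recovered mean against the configured mean with a
2-sample band and the sd within 3 standard errors; press schedules are
chosen off the sample grid, since a manual press has uniform phase relative
to the 62.5 Hz grid and grid-aligned presses would force the worst-case
quantisation on every event.

## Inter-device lag (ECG cross-correlation)

Monitor ECG: zero-phase 12–40 Hz band-pass (4th-order Butterworth,
forward-backward). Research ECG: the same band, a 50 Hz zero-phase IIR
notch (Q = 30), then polyphase resampling to 250 Hz. Epochs of ±5 s around
the event are mean-removed (no amplitude normalisation — the argmax is
scale-invariant) and cross-correlated over all integer shifts; the search
is restricted to ±2.5 s (well above plausible offsets, below the epoch
half-length, limiting heartbeat-period aliasing) and ties are broken toward
the smallest |lag| with a 10⁻⁹ relative tolerance. Sub-sample misalignment
of the two epoch grids is folded into the reported lag, so recovery error
is bounded by half a sample plus the research-path marking latency.

Two referencings are supported and deliberately distinct:

* a **single reference time** applied to both series on their own clocks
  (`estimate_event_lag`, default in `session_lag_analysis`) measures the
  inter-device *clock offset*;
* **per-device marks** (`use_device_marks=True`) reproduce the clinical
  procedure — epoching each recording around its own annotation — in which
  the clock offset cancels and the measured lag is the *marking-latency
  difference* between the paths. With realistic defaults this is ≈ the
  monitor latency, i.e. on the order of 100 ms.

## Evoked responses

EEG filtering is zero-phase 0.5–30 Hz plus the 50 Hz notch. Epochs run from
0.5 s before to 1 s after the stimulus and include both endpoints
(`round((pre+post)·rate) + 1` samples); baseline intervals are half-open
`[−pre, 0)`, so the stimulus sample itself is never part of the baseline.
Events too near a record edge are skipped with a warning (or raise in
strict mode). Averaging commutes with baseline correction; both paths are
tested.

Woody alignment is a single pass against a fixed template: normalised
cross-correlation over integer shifts within ±100 ms, ties toward zero
shift, true shifts beyond the bound clamping to the bound. The magnitude is
the unconstrained scalar least-squares coefficient over the template
support (nothing here requires non-negativity, so none is imposed). The
packaged template is a synthetic damped biphasic waveform on a 0–0.8 s
support — a stand-in, clearly labelled, because the canonical
noxious-evoked coefficients are not redistributable; its support leaves
head-room for the full ±100 ms range inside the standard epoch, and any
user-supplied waveform is accepted in its place.

Vital-sign epochs: −15…+45 s raw around a single lance (61 samples at
1 Hz); −5…+10 s baseline-corrected around train stimuli.

## Respiration

Cardiac interference is removed by a 6th-order zero-phase Butterworth
low-pass whose cutoff is 0.6 × the cardiac frequency estimated from ECG R
peaks (median inter-beat interval), clipped to [0.8 Hz, 0.9 × Nyquist]; at
the cardiac fundamental this provides > 20 dB attenuation while leaving the
respiratory band essentially untouched. With no detectable R peaks the
filter falls back to a fixed 1.5 Hz cutoff with a warning.

The breath detector is an adaptive amplitude-threshold scan: the threshold
is 0.4 × the running median of the last 5 excursion peak amplitudes (seeded
from the 98th percentile of the first 15 s), each breath is timed at the
rising threshold crossing (linearly interpolated between samples), and a
0.3 s refractory period suppresses double counts. The 0.4 fraction is low
enough that a sudden halving of breath amplitude is still detected before
the running median adapts. All constants are exposed in
`BreathDetectorParams`. Detected breath times sit at a constant phase
offset from excursion onsets (the crossing, not the onset, is the defined
breath time); recovery tests compare inter-breath intervals and
offset-compensated times.

Windowed respiratory rate: 20 s windows stepped by 1 s; per window,
RR = 60 / mean(IBIs of breaths inside it), where an edge gap (window edge to
nearest breath) greater than 1.5 s is included as an additional interval.
Windows with no usable interval are flagged undefined (NaN) rather than
reported as zero — apnoeic windows must not masquerade as a rate. Note a
consequence of the published rule taken literally: for true breathing
periods above 1.5 s, ordinary edge spacings also get padded, biasing the
windowed rate slightly upward; the stationarity invariant RR = 60/T
therefore holds exactly only for T ≤ 1.5 s, and the two hand-worked window
cases (33.0 and 3.243 breaths/min) pin the literal rule.

## File formats

CSV channels are `time_s,value` with ≥ 6 fractional digits on times (exact
millisecond round trips) and `%.12g` on values (round trip < 10⁻⁹).
Timestamps deviating from a uniform grid by more than 0.1 % are rejected.
EDF is read through MNE, channel-by-channel so mixed-rate files keep native
rates; writing uses a minimal EDF+ writer built into the package. EDF is
16-bit quantised, so a round trip is exact only to
`(phys_max − phys_min)/65535`, and the format stores a single file start
time (per-channel start offsets live in the CSV/JSON representations, not
in EDF).

## Validation problem sizes

The packaged validation runs use 7 simulated bench sessions × 5 presses
(35 events) for marking-precision recovery; clock offsets
{0, 50, 100, 200, 334} ms × 3 stimuli for lag recovery; all 401 integer
shifts in ±100 ms at 2000 Hz for Woody recovery; 10⁴ Monte-Carlo draws for
the latency model's moments; and 60–120 s records for breath-detection
sweeps. These sizes give standard errors comfortably inside every asserted
band while keeping a full run to seconds.

## Known limitations

* The monitor's inbuilt filter and the clinical breath-detection reference
  algorithm are both approximated by documented stand-ins; absolute numbers
  from real monitors will differ in detail.
* The onset rule's one-sample quantisation means bench latencies read
  systematically low by roughly half to one IP sample; the rule is kept
  sample-based deliberately (it is the published definition of the
  measurement).
* No artifact rejection is performed anywhere; heavily contaminated epochs
  will bias averages and lag estimates, and the cross-correlation values
  should be visually checked on real data.
* Drift estimation over long recordings is out of scope; the affine drift
  parameter is an input, not an estimate.
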