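# multisync

Time-locking and synchronisation analysis for dual-device physiological
recordings — a research-grade electrophysiology amplifier (EEG/ECG at
2000 Hz) running alongside a hospital vital-signs monitor (ECG 250 Hz,
impedance pneumograph 62.5 Hz, PPG 125 Hz, heart-rate and SpO₂ numerics at
1 Hz) — together with a ground-truthed simulator of such sessions.

When stimuli (heel lance, visual, tactile, auditory, experimental noxious,
push button) are marked onto two independent recorders, the marks land with
device-specific delays: sub-millisecond on the research path, on the order
of 100 ms on the networked monitor path. Interpreting multimodal responses
— evoked potentials, heart-rate changes, breathing pauses — requires knowing
those delays. This package is for physiologists and neonatal researchers who
need to (a) quantify event-marking precision and inter-device alignment, and
(b) run the standard stimulus-locked analyses on both recordings.

## What it computes

* **Marking precision.** A push button pressed onto the ECG electrodes
  leaves a sharp negative artifact on the impedance pneumograph (IP) and
  simultaneously generates an event mark. The signal is epoched ±1 s around
  the mark, baseline corrected to the pre-mark mean, and the artifact onset
  is the earliest sample below a threshold of 3 % of the post-mark minimum.
  Latency per event is *t*(mark) − *t*(onset); summaries are mean, sd
  (n−1), range, and per-session means.
* **Inter-device lag.** Both devices record the same ECG. Each signal is
  band-passed 12–40 Hz (the research signal additionally 50 Hz-notched and
  resampled to 250 Hz), epoched ±5 s around an event, and the lag is the
  argmax of the cross-correlation over shifts in ±`max_lag`, ties toward
  zero. Positive lag means the second series lags the first.
* **Evoked responses.** EEG is filtered 0.5–30 Hz (50 Hz notch), epoched
  −0.5…+1 s, baseline corrected to the pre-stimulus mean, and averaged.
  Single-trial noxious responses are Woody-filtered: a template *w* is slid
  over shifts τ ∈ [−100, +100] ms, τ* = argmax corr(x(t+τ), w(t)), and the
  response magnitude is the scalar least-squares fit
  β = ⟨x, w_τ*⟩ / ⟨w, w⟩. Vital-sign numerics are epoched −15…+45 s around
  a single lance (raw) or −5…+10 s around train stimuli (baseline
  corrected).
* **Respiratory rate.** The IP is low-passed below the cardiac band (cutoff
  steered by ECG R peaks), breaths are detected by an adaptive amplitude
  threshold (a fraction of the running median of recent excursion
  amplitudes, timed at the rising crossing), and the rate in 20 s windows
  stepped by 1 s is RR = 60 / mean(IBI), where any edge gap > 1.5 s is
  included as an extra inter-breath interval so breathing pauses straddling
  the window edge lower the rate.
* **Simulation.** `simulate_session` builds both device recordings from one
  physiological source with configurable clock offset, affine drift, and
  truncated-normal marking latency (defaults: mean 105 ms, sd 19 ms on the
  monitor path; 0.5 ms on the research path), and returns every hidden
  quantity as ground truth.

## Worked example

```python
import numpy as np
import multisync as ms
from multisync.sync import session_precision, session_lag_analysis

cfg = ms.SessionConfig(
    duration=45.0,
    stimulus_times=(10.0, 20.0, 30.0),
    press_times=(14.5, 24.5, 34.5),
    inter_device_offset=0.12,      # monitor clock runs 120 ms ahead
    ip_breath_amplitude=0.0,       # bench recording: no infant attached
)
session = ms.simulate_session(cfg, rng_seed=1)

marks = [m for m in session.monitor_events if m.marker.name == "push_button"]
prec = session_precision(session.monitor["IP"], marks)
print("marking latency per press (ms):", np.round(prec.per_event_latency * 1000, 1))

lag = session_lag_analysis(session)
print("inter-device lag per event (ms):", np.round(lag.per_event_lag * 1000, 1))
```

prints

```
marking latency per press (ms): [ 97.7  87.6 104.8]
inter-device lag per event (ms): [120. 120. 120. 120. 120. 120.]
```

The three presses were annotated 110/100/117 ms late (truncated-normal
draws around the 105 ms default); the artifact-onset rule recovers each
within its one-sample resolution at 62.5 Hz, reading slightly low because
it times the first *sample* past threshold. The ECG cross-correlation
recovers the configured 120 ms clock offset exactly at 250 Hz resolution
for every one of the six events.

The same analyses run from the shell:

```bash
multisync simulate --seed 1 --bench --out session/
multisync precision --signals session/monitor/IP.csv \
                    --events session/events_monitor.json --marker push_button
multisync sync --a session/research/ECG.csv --b session/monitor/ECG.csv \
               --events session/events_research.json
multisync resp --ip session/monitor/IP.csv --ecg session/monitor/ECG.csv
multisync report --config run.yaml --out results/
```

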