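# gripsense

Surface-EMG grip-event detection, adaptive rehabilitation-game simulation,
and muscle-fatigue analysis.

## The problem

Hand-grip rehabilitation systems built on wearable surface electromyography
(sEMG) let a patient control a game by squeezing a resistive ball: a forearm
band records the electrical activity of the finger-flexor muscles
(flexor digitorum superficialis/profundus), an acquisition module turns
threshold crossings into in-game jump commands, and the recorded signal
doubles as clinical data about muscle function and fatigue.  `gripsense`
re-creates that whole stack as testable, deterministic software for people
who build or evaluate such systems: a synthetic 500 Hz sEMG generator with
known grip-event ground truth, the device's calibration and trigger logic, a
headless adaptive game, the offline fatigue pipeline, and the evaluation
layer that scores detection reliability.

## The core methods

**Trigger detection.**  The on-device amplitude is the absolute first
difference of the raw stream, `a_i = |x_i − x_{i−1}|`, smoothed by a
300-sample rolling mean (0.6 s at 500 Hz).  A four-state calibration
(5 s standby → 5 s relax → 3 s maximal squeeze → calibrated) measures the
smoothed amplitude at rest (`A_rest`) and at maximal contraction (`A_max`)
and sets the trigger threshold at the 60% point,

    θ = A_rest + 0.60 · (A_max − A_rest).

Triggers fire on rising crossings of the smoothed amplitude above θ, with a
0.3 s refractory period.  Because the amplitude is a difference, the chain
is invariant to DC offset and linear in analog gain.

**Detection reliability.**  Detected triggers are matched one-to-one to
ground-truth squeeze onsets within ±0.2 s (after correcting the detector's
nominal latency, 0.60 · 0.6 s = 0.36 s); matched pairs are TP, unmatched
truth FN, unmatched detections FP, and

    F1 = 2·TP / (2·TP + FP + FN).

**Fatigue.**  The offline pipeline bandpasses to 20–250 Hz, normalizes to
[−1, 1], rectifies, and picks grip-exertion peaks.  Per game segment it
reports the mean peak amplitude (MPA) and the median frequency (MDF) — the
frequency splitting the Welch power spectrum into equal-power halves, which
declines with fatigue.  The session's fatigue statistic is
`100 · (MDF₃ − MDF₁)/MDF₁` between the last and first game.

**Adaptive game.**  A headless jump-and-run: three difficulty levels
(speed, obstacle size, coins), a ~15 s success-rate window that raises the
level after a very good window and lowers it after a poor one, three lives
(green → yellow → red), and a 5 s pause plus reset to level 1 after the
third collision.

## Worked example

Run the full study protocol — calibration, then three 5 min games with
3 min rests — on a simulated participant (burst gain 6, ~one squeeze every
12 s):

```python
from dataclasses import replace
from gripsense import SessionConfig, run_protocol

cfg = SessionConfig(seed=1)
cfg = replace(cfg, simulator=replace(cfg.simulator, burst_gain=6.0,
                                     mean_inter_event_s=12.0))
res = run_protocol(cfg, out_dir="demo")
print(f"TP={res.match.tp} FP={res.match.fp} FN={res.match.fn} F1={res.f1:.4f}")
for m in res.metrics:
    print(f"{m.segment_id}: MPA={m.mpa:.3f} MDF={m.mdf_hz:.1f} Hz")
print(f"pct_change_mdf={res.fatigue.pct_change_mdf:.2f}%")
```

prints

```
TP=72 FP=2 FN=0 F1=0.9863
Game 1: MPA=0.202 MDF=99.8 Hz
Game 2: MPA=0.190 MDF=99.3 Hz
Game 3: MPA=0.196 MDF=100.0 Hz
pct_change_mdf=0.22%
```

All 72 simulated squeezes were detected within ±0.2 s of onset (two
spurious triggers), giving F1 = 0.986.  With no configured median-frequency
drift, the per-game MDF stays at the 100 Hz target and the fatigue percent
change is ~0; configure `mdf_drift_pct_per_min=-2.0` on the simulator to see
the MDF decline and a negative percent change.  `demo/` receives every
intermediate CSV (raw stream, ground truth, triggers, per-game click /
difficulty / outcome logs, per-segment metrics, per-minute MDF, report).

The same stages are available on the command line:

```sh
gripsense simulate --seed 5 --duration 60 --out run/
gripsense calibrate --emg cal.csv --out profile.yaml
gripsense detect --emg run/emg.csv --profile profile.yaml --out run/
gripsense play --triggers run/triggers.csv --out run/
gripsense analyze --emg run/emg.csv --segments segments.csv --out run/
gripsense evaluate --truth run/ground_truth.csv --detected run/triggers.csv --latency 0.36
gripsense protocol --seed 1 --out run/
```

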