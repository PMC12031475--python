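# Methods

This note documents the models, defaults and design choices behind
`gripsense`, and what the simulator-based tests do and do not show about
real recordings.

## Synthetic sEMG model (`gripsense.sim`)

A session is band-limited Gaussian noise, amplitude-modulated by a
rest/burst envelope:

- **Spectral template.**  Per 1 s block, white Gaussian noise is shaped in
  the frequency domain to a flat band placed *symmetrically* about the
  target median frequency, with half-width
  `min(60 Hz, target − band_low, band_high − target)`.  Symmetry makes the
  spectral median exactly the target, which is the point: the free
  parameter of the generator must be the median frequency itself, not a
  physiological shape parameter.  A unimodal physiological template
  (e.g. the classic interference-EMG spectrum) would require solving for
  its median numerically and would add nothing the tests can use.
- **Fatigue drift.**  `mdf_drift_pct_per_min` moves the target linearly in
  time, realized piecewise-constant per 1 s block (evaluated at the block
  midpoint).  Blocks are synthesized independently; the joins are
  discontinuous in value but spectrally negligible at these block lengths.
- **Envelope.**  Rest RMS `rest_rms` (default 1, arbitrary units) and burst
  RMS `burst_gain × rest_rms`, with 50 ms trapezoidal rise/fall ramps so
  onset times are well defined and no broadband step artifacts appear.
  Each block's carrier is normalized to unit RMS before modulation, so
  segment RMS tracks the envelope closely.
- **Scheduling.**  Either an explicit onset list (validated non-overlapping
  and inside the session) or random scheduling with a mean inter-event
  interval: a guaranteed clearance gap plus an exponential jitter, so
  bursts never overlap by construction.
- **Units.**  Zero-mean arbitrary units.  The detector operates on
  sample differences and is offset invariant, so an ADC offset would be
  purely cosmetic.
- **Defaults.**  500 Hz sampling, 20–250 Hz band, target MDF 100 Hz
  (mid-band, representative of forearm sEMG), burst gain 5 (a clear but not
  extreme contraction), 1 s bursts, ~one event per 10 s — a plausible
  squeeze cadence for a jump-on-grip game.

What the simulator does **not** emulate: motor-unit structure, tremor,
movement artifacts, electrode lift-off, mains hum, amplitude
non-stationarity at rest.  Passing tests therefore demonstrate that the
pipeline is correct and well calibrated for its signal model, not that the
detection F1 or fatigue estimates would reach the same values on human
data.

## Acquisition-module logic (`gripsense.dam`)

- Amplitude `|x_i − x_{i−1}|`, 300-sample rolling mean; warm-up uses the
  mean of the available prefix (no zero-padding, so the stream start is not
  biased low).  Trigger emission is additionally suppressed until the
  window has filled once: a prefix mean over a handful of samples is too
  noisy to compare against a threshold calibrated on the full window.
- Calibration windows: 0–5 s discarded (standby), 5–10 s rest anchor,
  10–13 s maximal anchor; the threshold is
  `rest + fraction · (max − rest)` with fraction 0.60.  "60% between full
  relaxation and maximal contraction" is read as linear interpolation
  between the two calibration anchors — the only reading bounded by both.
- A valid calibration requires `max ≥ 1.5 × rest` (configurable), the
  concrete stand-in for "reliably detecting muscle activity"; failure
  signals the caller to raise the analog gain and retry.
- Detection fires on rising crossings of the *same* rolling amplitude the
  threshold was calibrated on (calibration and detection must share
  units), with a 0.3 s refractory period — below any plausible
  inter-squeeze interval, above the dwell of threshold-hovering noise.
- **Latency.**  For a step from rest to the calibrated maximal amplitude,
  the rolling mean crosses the threshold once a fraction
  `threshold_fraction` of the window lies inside the burst, i.e. after
  `0.60 × 0.6 s = 0.36 s`.  `detection_latency_s` exposes this closed form;
  end-to-end evaluation shifts ground-truth onsets by it before ±0.2 s
  matching, so the F1 measures detection reliability, not fixed delay.
- Triggers are emitted as edges; the level trace (the device's activity
  indicator) is returned alongside.  Evaluation uses edges.

## Game engine (`gripsense.game`)

Deterministic fixed-step simulation (20 ms ticks, simulated clock).
Structure fixed by the game's design: three levels with strictly increasing
speed; level 1 spawns only small obstacles, level 3 only large; coins only
at levels ≥ 2.  Numeric defaults (speeds 1.0/1.3/1.6 world-units/s, spawn
every 2 s ± 0.3 s, 0.7 s jumps, level-2 large-obstacle probability 0.5)
are engine choices.  The success-rate window is 15 s with thresholds
≥ 0.8 up / ≤ 0.4 down — a symmetric dead band around "moderately well";
transitions move one level at a time, clamped to [1, 3].  An alternative
~1 min evaluation window is a config change (`window_s`).

Obstacle mechanics: an obstacle arrives `spawn_distance / speed` after
spawning; it is cleared when the jump midpoint falls within a
size-dependent margin of the arrival (0.35 s small, 0.20 s large — larger
obstacles punish mistiming), otherwise it costs a life.  Coins never cost
lives and missed coins are not attempts; they add decision load, not
penalty.  The third collision pauses the game for exactly 5 s of game
clock, resets to level 1 and restores three lives; nothing spawns and no
outcomes resolve while paused.  Clicks are logged at exact trigger times,
so replaying a trigger list reproduces the click log identically.

## Signal analysis (`gripsense.analysis`)

- **Filter.**  4th-order Butterworth bandpass applied forward–backward
  (zero phase, so peak timing is preserved).  The upper edge is clamped to
  `0.99 × fs/2`: a 250 Hz edge is unrealizable at 500 Hz sampling.
- **Normalization scope.**  Per full recording, so MPA differences across
  games survive; per-segment normalization would force the segment maxima
  to 1 and flatten MPA.  MDF is computed on the bandpassed,
  pre-normalization signal — rectification distorts the spectrum, and MDF
  is scale invariant anyway.
- **MDF estimator.**  Welch spectrum, 1 s Hann windows, 50% overlap;
  the median is found by linear interpolation of the cumulative power
  between bins.  For spectra with two separated equal-power lobes, where
  the cumulative curve plateaus at exactly one half, the crossing is
  evaluated at 0.5 ± 10⁻³ and the two frequencies averaged — the midpoint
  of the cumulative step (two equal tones at 60 and 120 Hz give ≈ 90 Hz
  rather than an arbitrary lobe edge).  Segments must cover ≥ 1 s.
- **Peaks.**  `scipy.signal.find_peaks` with minimum height 0.1 (normalized
  units) and 0.5 s separation by default; both configurable, since
  appropriate values depend on burst contrast (tests recovering one peak
  per simulated burst use height 0.3 and the burst cadence as separation).
- **Known bias.**  With a drifting MDF the band's lower half approaches the
  20 Hz filter edge, whose rolloff clips low-frequency power and biases
  segment MDF slightly upward.  At −2%/min over 15 min the recovered
  percent change is ≈ −18 to −20% against the −21.1% predicted from the
  segment midpoints; the drift-recovery tests use a pre-measured ±4
  percentage-point window around the prediction.

## Evaluation (`gripsense.evaluation`)

- **Matching.**  One-to-one, tolerance ±0.2 s read as a closed interval.
  Greedy over truth events in increasing time, each matched to the
  *earliest* unused detection in its window.  For equal-width windows this
  greedy is maximum-cardinality (exchange argument: any optimal matching
  can be rewritten pair-by-pair to use the earliest eligible detection
  without losing a pair), which the tests confirm against brute-force
  bipartite matching on 1000 random instances.  A nearest-detection
  greedy was considered and rejected: it can strand a detection that a
  later truth event needed (truth {0, 0.1}, detections {−0.15, 0.05},
  tolerance 0.2 → nearest-greedy finds one pair, optimal finds two).
- **F1.**  `2TP/(2TP+FP+FN)`; all-zero counts return 0 with a warning
  rather than crashing on empty sessions.
- **Group tests.**  Welch (unequal-variance) two-sample t-test by default,
  pooled variance and paired variants by flag; two-sided p-values;
  significance at the exploratory alpha = 0.25.  The type-I error of the
  default test under a simulated null is checked against the nominal rate.
- **Questionnaire.**  Per-question mean ± sample SD over respondents
  (scores validated in 1–5); the grand mean is the mean of the six
  question means.  No SD is attached to the grand mean: a single
  defensible derivation does not exist at the aggregated level, so only
  the mean is reported.
- **Demographics.**  Sample SD (n−1) throughout.

## Protocol and I/O

`run_protocol` chains simulate → calibrate → detect → play (three games)
→ analyze → evaluate, all seeded from one master seed via independent
`SeedSequence` children (no stage reads global entropy).  The simulated
participant squeezes only inside the three 5 min game windows; the 13 s
calibration stream carries a maximal burst in its squeeze window.  All
artifacts are UTF-8, dot-decimal, header-row CSV with times in seconds
from session start; readers validate schema strictly and reject
locale-style decimal commas instead of misparsing them.

Problem sizes in the test suite are chosen for sharp, fast checks: 60 s
rest sessions for spectral recovery (repeated-seed spread ≈ ±1.5 Hz at
60 s), 125 s / 24-event sessions for end-to-end detection, a 15 min
continuous session for drift recovery, and a scaled-down 3 × 60 s protocol
for pipeline determinism tests, with one full-length protocol test kept.

## Limitations

- The simulator's flat spectral band is a control device, not a
  physiological spectrum; absolute MPA values depend on its burst contrast.
- Detection latency is corrected by a closed form that assumes burst
  plateaus near the calibrated maximum; much weaker squeezes cross later,
  and drifting spectra lower difference-amplitudes (the difference
  operator is a high-pass), which degrades detection margin — visible as
  reduced F1 when drift and detection are combined.
- The game's numeric constants (speeds, margins, spawn cadence) shape the
  difficulty trajectory; only the transition *rules* are fixed.
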