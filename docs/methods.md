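# Methods

This note documents the models behind `lickometry`, the defaults and why
they were chosen, and what the synthetic data can and cannot establish.

## Lick-train generator

Mouse licking is modelled as an alternating-renewal process: *bouts* of
rhythmic licking separated by pauses.

- **Within-bout interlick intervals (ILIs)** are gamma-distributed
  (shape 10) truncated below at a refractory floor, default 60 ms. The
  gamma family gives the unimodal, positively skewed, fairly regular ILI
  distributions observed in rodents; shape 10 corresponds to a
  coefficient of variation near 0.32. The gamma scale is calibrated
  numerically (closed-form truncated-gamma mean, Brent root-finding) so
  that the *truncated* distribution's mean is exactly
  `1000 / mean_within_bout_rate` ms — with the default 8.5 licks/s,
  117.6 ms — so the empirical within-bout rate recovers the target
  without truncation bias.
- **Refractory floor 60 ms**: just above the 50 ms verification period of
  the polled prototype, so that detector can in principle resolve every
  lick; also below any physiologically plausible ILI at ≤ 16.7 licks/s.
- **Bout lengths** are geometric (mean 20 licks) and **inter-bout pauses**
  exponential (mean 30 s). Both are free parameters; the defaults give a
  moderately drinking mouse (~400 licks in 10 min).
- **Contact durations** are lognormal, mean 40 ms, sd 10 ms, clipped to
  end at least 1 ms before the next lick. 40 ms is chosen so that a 50 ms
  polling detector lands in the ~0.9 recall regime that capacitive
  lickometers reach in practice; it is explicitly an assumption, not a
  measurement.

Time is real-valued milliseconds from session start; a configured session
start timestamp anchors conversion to wall clock (file dialects carry
ISO-8601 with millisecond precision).

## Emulated pulse protocols

The in-silico validation replicates a three-phase bench design: phase 1
pulses bottle A of each active cage, phase 2 bottle B, phase 3 both.
Pulses are exact square waves — 12,000 onsets per pulsed output at exactly
200 ms (5 Hz) or 100 ms (10 Hz) period, 50 % duty. "Alternating" in
phase 3 is implemented as a half-period offset of B relative to A within
each cage; the offset is a design choice (the alternation scheme is
otherwise under-determined) and is asserted in tests as exactly half a
period. The number of simultaneously active cages sweeps 1–8.

## Sensor model

Sensor units are abstract ("a.u."): real capacitance counts are
hardware-specific. Defaults — baseline 100, Gaussian noise sd 2, touch
amplitude 50 — give an SNR of 25, making clean-touch detection essentially
deterministic unless degraded on purpose. Samples are instantaneous point
reads; integration over the read window is not modelled (simpler, and
sufficient for the event-counting logic this package validates).
Confuser events (elevations without a lick) are a Poisson process with
exponential dwell, default mean 150 ms; they exist to reproduce the
precision gap between capacitive and beam-break sensing and default to
off for capacitive simulations.

## Detection

- **Threshold**: baseline mean + k·sd with k = 5 by default. The
  post-hoc "establish a threshold" step is under-determined in practice;
  k = 5 separates default noise (sd 2) from the touch amplitude (50) by
  over 20 noise standard deviations. The file-based `detect` command uses
  a robust variant (median + k·MAD) so the statistics are not biased by
  the licks present in the trace.
- **Prototype detector**: polls every 50 ms, counts rising threshold
  crossings (a poll above threshold following a poll at or below it), and
  skips polls within a 5 ms post-count delay. Event-level rising-edge
  semantics plus the short refractory reproduce "do not count
  duplicates" behaviour; timestamps are the counting poll instants — what
  the hardware can actually know, not the true onset.
- **Multiplexer**: 16 channels in fixed order (1A, 1B, …, 8B), one frame
  per 60 ms, channel *c* read at `c · 60/16` ms into the frame
  (sequential scan; the scan schedule is a design choice). Per-channel
  rate is therefore 16.67 samples/s.
- **Wireless counting** is either `edge` (rising crossings of sampled
  values — exact for 5 Hz/50 % duty pulses, whose 100 ms high phase always
  spans a read) or `latched` (default for the protocol grid): the
  front-end accumulates pulse onsets between reads and each read drains
  the counter. The latch is a *counter*, not a flip-flop, so it conserves
  events even when more than one falls between reads; multiple events
  drained at one read are stamped at that read instant with 1 µs spacers
  to keep timestamps strictly increasing. A 16.67 Hz instantaneous read
  of a 10 Hz/50 % duty wave would otherwise alias away a large fraction
  of pulses, which is incompatible with the sub-0.1 % reading errors such
  systems achieve; the residual reading error is injected as a per-event
  miss probability, default 5 × 10⁻⁴.

## Transport

The radio link drops whole frame-packets (all 16 channel values travel
together); event losses per drop therefore depend on how many active
channels the frame carried, which is what makes transmission-error
distributions vary across phases and cage counts even though the
per-packet loss rate is constant. Loss is Bernoulli per packet
(default p = 0.008, i.e. mean transmission error ≈ −0.8 %, the sub-percent
regime of a busy shared network — explicitly a tuning, not a measurement)
or a two-state Gilbert–Elliott burst channel (defaults: good→bad 0.01,
bad→good 0.2, bad-state loss 0.5). Duplicate delivery is supported and
defaults to 0. The sign convention: negative transmission error = net
loss, positive = net duplication.

## Validation protocol and scoring

`run_insilico_protocol` runs every (phase × frequency × active-cage ×
replicate) cell: generate pulses, acquire (latched, with the miss
probability), assign each detected event to the frame that drains it,
drop frames by one shared per-cell loss draw, and tabulate per output:
emitted, centrally detected, received, reading error, transmission error.
Per-cell seeds derive from `(base_seed, phase, frequency, cages,
replicate)` so any single cell is reproducible in isolation. Replicates
default to 10 per cell; the replicate count behind the published-style
error boxes is configurable, not inferred. The grid computation uses
exact event-level arithmetic instead of materialising dense 16-channel
traces; tests assert its equivalence with the dense
multiplex-then-detect route at small scale. Statistical comparison of
error distributions across phases (rank tests, post-hoc corrections) is
deliberately out of scope — the long-form report exposes per-cell values
so any test can be applied externally.

Event matching is one-to-one: a detection at time *d* can match a truth
onset *o* with contact *c* when `o ≤ d ≤ o + c + tolerance`, tolerance
defaulting to one 60 ms frame — a detection within the same contact or
the immediately following frame is the same lick, and detections never
legitimately precede onsets because they are stamped at read instants.
Detections are processed in time order and each takes the compatible
unmatched truth whose window expires first (ties toward the earlier
onset); for point-in-interval matching this earliest-deadline rule
attains the maximum matching, and tests verify equality with a
brute-force optimal-assignment oracle on random instances.

## Microstructure

- **Bout break 1000 ms**: the conventional rodent-lickometry criterion; a
  new bout starts at any lick whose preceding ILI exceeds it. It is a
  prominent, documented parameter of every bout-level statistic.
- **Within-bout frequency** is `1000 / mean(within-bout ILI)`.
- **Light/dark tagging** uses a 12/12 h cycle with lights on at 07:00 by
  default; bins are tagged by their start instant.
- **Intake correlation**: Spearman rank correlation of per-bottle-session
  fluid intake (bottle weight before − after, grams) against total licks,
  with a descriptive least-squares R². p-values use pairing permutations
  for n ≤ 20 and the asymptotic approximation otherwise.
- **Synthetic intake sessions** stand in for an in vivo dataset (no animal
  data ship with the package): per animal × session × bottle a lick train
  is generated (bottle A water, B 10 % v/v ethanol, density 0.984 g/mL),
  and grams consumed are `licks × µL-per-lick / 1000 × density` plus
  Gaussian weighing noise (sd 0.05 g). Per-lick volume defaults to 1.5 µL
  with per-animal lognormal variation (log-sd 0.1), and between-animal
  appetite differences are emulated by drawing each animal's inter-bout
  pause mean uniformly from 20–60 s. These two variation sources are
  design choices that give the synthetic dataset the between-subject
  spread real cohorts show; the default 24 animals × 2 sessions ×
  2 bottles = 96 points yield a strong (ρ > 0.8) lick–intake correlation.
  The device itself measures no volume — the µL-per-lick conversion is an
  assumption of the simulator, not a property of the hardware.

## Problem sizes used

The acceptance script recovers the within-bout rate from one 1800 s
session (~1100 within-bout ILIs) and runs the full default grid —
640 output-cells, 34.56 million emulated pulses — which completes in
seconds because the grid path is event-arithmetic, not dense sampling.
Property suites in the tests use 100–300 randomised small instances per
oracle comparison.

## What passing tests do and do not show

The synthetic generator reproduces the *structure* of mouse drinking
(bouts, ILI scale, circadian windowing) but not: volume dynamics within a
bout, sensor drift, grooming/approach artefacts beyond the Poisson
confuser model, inter-individual ILI shape differences, or real network
weather. Consequently, in vivo figures of merit (precision/recall against
video annotation, the observed lick–intake correlation of real cohorts)
are *not* reproduced here; what the suite establishes instead is that
every stage is exact or statistically calibrated under its stated model:
detectors match brute-force oracles, the latch conserves events, losses
match their binomial/burst expectations, matching attains the optimal
assignment, and the synthetic intake analogue behaves qualitatively like
the in vivo finding.

## Known limitations

- No electrical modelling of light-dependent-resistor or photoelectric
  hardware; confuser events abstract their false-positive mode.
- Point-read sampling understates what integrating capacitive front-ends
  see; real traces may have slower rise/decay.
- The burst-loss defaults are illustrative; fit them to your network
  before drawing quantitative conclusions from burst-mode runs.
- Timestamps of detected events are read instants; onset-latency
  correction is intentionally not applied.
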