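# lickometry

Simulation and analysis toolkit for multi-cage, two-bottle **lickometers** —
devices that timestamp every tongue contact a rodent makes with a drinking
sipper. It models the complete computational chain of a wireless capacitive
lickometer for eight cages with two bottles each, end to end:

1. **Ground truth** — synthetic mouse lick trains with bout structure
   (within-bout rate centred on the C57Bl/6 typical 8.5 licks/s), and
   deterministic emulated pulse protocols at 5/10 Hz for bench-style
   validation;
2. **Sensor model** — capacitive-style traces: baseline + touch elevations +
   Gaussian noise, with optional "confuser" events (approach without
   licking, the failure mode of beam-break sensors);
3. **Detection** — a polled single-channel prototype (50 ms verification,
   5 ms anti-duplicate delay) and a 16-channel multiplexed wireless scheme
   (60 ms frames ⇒ 16.67 samples/s per channel), with thresholds set as
   baseline mean + k·sd;
4. **Transport** — UDP-style lossy packet delivery (Bernoulli or
   Gilbert–Elliott burst loss) and the two chain metrics:
   *reading error* = (emitted − detected)/emitted × 100 and
   *transmission error* = (received − sent)/sent × 100 (negative = net loss);
5. **Validation** — precision/recall scoring of detections against ground
   truth via tolerance-window matching, and the full three-phase in-silico
   protocol grid (bottle A only / B only / alternating × 5 and 10 Hz ×
   1–8 simultaneously active cages × replicates, 12,000 pulses per output);
6. **Microstructure** — interlick intervals, bout segmentation (1 s break
   criterion), within-bout frequency, two-bottle preference, circadian
   time-binned counts, and the lick-count-versus-fluid-intake Spearman
   correlation used to validate lickometers in vivo.

Who it is for: behavioural-neuroscience labs building or validating
lick-detection hardware, and anyone needing a tested reference
implementation of drinking-microstructure analytics over lick timestamps.

## Worked example

Simulate a one-cage session, detect licks in the raw trace, and summarise
the microstructure:

```bash
$ lickometry simulate --seed 1 --cages 1 --duration 300 --out-dir demo
wrote demo/raw_trace.tsv and demo/ground_truth.csv (393 ground-truth licks)

$ lickometry detect --input demo/raw_trace.tsv --out demo/events.csv
wrote demo/events.csv: 215 licks across 2 channels

$ lickometry analyze --events demo/events.csv --out demo/summary.csv
wrote demo/summary.csv: 2 channels
```

`demo/summary.csv` then holds, per channel, the totals and bout statistics:

```
cage_id,bottle_id,total_licks,n_bouts,mean_licks_per_bout,mean_within_bout_ili_ms,within_bout_frequency_hz,cage_preference_a
1,A,120,10,12.0,211.09,4.74,0.558
1,B,95,8,11.875,205.52,4.87,0.558
```

Note what the numbers show: point-sampling a ~40 ms tongue contact on a
60 ms frame grid misses roughly every other lick (215 detected of 393
emitted), which halves the apparent within-bout frequency — exactly the
aliasing problem that the *latched* acquisition mode solves by retaining
events between frame reads. The in-silico grid quantifies that chain:

```bash
$ lickometry validate --replicates 2 --seed 7 --out report.csv
wrote report.csv: 128 cells; mean reading error 0.0493%, mean |transmission error| 0.7836%
```

Reading errors of a few hundredths of a percent and sub-percent
transmission losses are the operating regime of a healthy wireless
lickometer; the per-cell report lets you localise anything worse to a
phase, frequency, or cage count.

## Library surface

```python
import lickometry as lk

train  = lk.generate_lick_train(lk.LickGenParams(seed=1))
signal = lk.render_continuous(train, lk.SensorParams())
base   = lk.capture_baseline(lk.SensorParams())
thr    = lk.estimate_threshold(base, k=5)
events = lk.detect_prototype(signal, lk.DetectorConfig(mode="prototype", threshold=thr))
score  = lk.match_events(events, train, tolerance=60)
print(lk.precision(score), lk.recall(score))
```

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
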