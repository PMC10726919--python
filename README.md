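# somnivid

Noninvasive sleep monitoring for mice from cage video.

EEG/EMG polysomnography is the gold standard for scoring rodent sleep, but it
is invasive: electrode implantation surgery can itself perturb sleep, rules
out fragile disease models, and makes lifetime or large-cohort monitoring
impractical. Video actigraphy exploits a robust behavioral fact: a mouse that
stays motionless for at least 40 s is almost always asleep. `somnivid`
implements that pipeline end to end:

1. **Motion detection** — frames from an overhead infrared camera are
   segmented by ViBe, a sample-based background subtractor: each pixel keeps
   N = 20 past intensity samples and is foreground when fewer than 2 samples
   lie within a radius R = 20 of its current value; background pixels refresh
   their own model and a random 8-neighbor's model with probability 1/16 per
   frame. The per-frame count of foreground ("moved") pixels, binned per
   second, is the actigraphy signal.
2. **Sleep scoring** — a bin is *active* when its count exceeds a threshold
   θ, expressed as a percentage of a reference count (99th percentile of
   positive counts by default, so the threshold is camera-resolution free).
   Every maximal inactive run of duration ≥ T is scored Sleep from its onset;
   T = 40 s by default, with 35 s and 45 s as standard sweep alternatives.
   θ is calibrated by scanning a 5% grid from 0% to 100% against a concurrent
   EEG/EMG reference. Sub-threshold micro-motion (abdominal breathing, ear
   flicks) never wakes the scorer.
3. **Agreement** — the video hypnogram is compared with a reference hypnogram
   (Wake/NREM/REM in 10 s epochs; total sleep = NREM + REM) by splitting both
   into 24 × 1 h segments and running Bland–Altman on the paired per-hour
   sleep totals: bias = mean(video − reference), 95% limits of agreement =
   bias ± 1.96 × SD. A percent consistency coefficient
   C = 100 · (1 − Σ|dᵢ| / Σ refᵢ) summarizes agreement (alternative formulas
   selectable; reports always name the formula used).
4. **Synthetic data** — a generator produces ground-truthed hypnograms
   (lognormal sleep/wake bouts modulated by a 12/12 light-dark cycle, lights
   on 08:00, brief arousals shorter than the immobility rule), motion traces
   (locomotion vs. breathing-band micro-motion counts), rendered cage video
   (a random-walking ellipse blob with breathing pulsation during sleep), and
   imperfect epoch-scored references with configurable sensitivity and
   specificity — so every stage is testable without animal data.

## Worked example

Simulate a day of mouse behavior, score it, and compare against the
(imperfect, sensitivity = specificity = 0.95) reference scorer:

```sh
somnivid --seed 1 --out-dir demo simulate --duration 86400 \
    --sensitivity 0.95 --specificity 0.95
somnivid --out-dir demo score --trace demo/trace.csv --threshold-pct 10
somnivid --out-dir demo compare --video-hyp demo/hypnogram.csv \
    --reference demo/reference.csv
```

which prints

```
simulated 86400 s -> demo
total sleep 43387 s -> demo/hypnogram.csv
bias -13.8 s, LoA [-178.9, 151.4] s, consistency 96.1% (sum-abs)
```

The mouse slept 43,387 s of the 24 h day (about 50%, light-phase dominant, as
expected for a nocturnal animal). Against the noisy reference the video
system underestimates hourly sleep by 13.8 s on average, 95% of hourly
differences fall between −178.9 and +151.4 s, and the consistency coefficient
is 96.1%. The immobility-rule sweep

```sh
somnivid --out-dir demo sweep --trace demo/trace.csv \
    --reference demo/reference.csv --threshold-pct 10
```

```
 immobility_min_s  video_sleep_s  reference_sleep_s   loa_low_s  loa_high_s  consistency_pct
             35.0        43387.0            43660.0 -178.934137  151.434137        96.129180
             40.0        43387.0            43660.0 -178.934137  151.434137        96.129180
             45.0        43302.0            43660.0 -174.783962  140.617296        96.312414
```

shows the defining monotonicity of the rule: video sleep totals never
increase as T grows, because the qualifying immobility runs at a longer T are
a subset of those at a shorter T.

To extract a trace from actual video instead, use
`somnivid extract --video cage.avi --bin-s 1 --seed 0`; `simulate --render`
writes a synthetic AVI you can feed straight back through `extract`.

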