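# Methods

## Behavioral premise

The pipeline rests on the immobility rule for mice: a continuous motionless
period of at least T = 40 s is scored as sleep. The rule's lineage in video
somnography labels the whole immobility episode as sleep from its onset, not
from second T onward; `somnivid` follows that convention. Runs of exactly
T seconds qualify (inclusive boundary), as do runs truncated by the recording
edges whose observed duration qualifies. The rule cannot see sleep stages:
NREM/REM discrimination and any sleep-depth measure are out of scope by
construction, and interventions that dissociate immobility from sleep
(e.g. quiet wakefulness) are a known failure mode of the whole approach.

## Motion detection

ViBe keeps, per pixel, a buffer of `n_samples = 20` past intensities. A pixel
is background when at least `min_matches = 2` samples lie within
`match_radius = 20` gray levels of its current intensity; the comparison is
inclusive (|v − s| ≤ R), which fixes the classification at the boundary.
Background pixels refresh one of their own samples and one sample of a random
8-neighbor (with the observed value v(x)) each with probability
1/`subsample_factor` = 1/16 per frame; foreground pixels never update their
own model. These four constants are the canonical defaults of the original
sample-based classifier and are all exposed in `ViBeParams`.

Initialization draws each pixel's samples, with replacement and seeded, from
its 8-neighborhood in the first frame (border neighborhoods are coordinate-
clamped). A burn-in of 2 s of frames lets the model stabilize; burn-in counts
are reported as zero and the trace stays aligned to the recording start
(dropping the bins instead would shift every downstream comparison against
the reference clock).

**Stationary-object timeout.** A strictly conservative update deadlocks on an
object that stops moving: a mouse that falls asleep at a new spot would read
as foreground indefinitely, because its pixels never update and neighbor
diffusion only injects background-colored samples. `somnivid` therefore
carries the standard anti-deadlock extension from the ViBe+ lineage: a pixel
classified foreground for `stationary_timeout = 16` consecutive frames
(= `subsample_factor`; 3.2 s at 5 fps) has `min_matches` samples refreshed
with its current value and immediately reads background while the scene stays
still. This gives the classifier a bounded sleep-onset absorption delay and
makes ghosts (the stale imprint left when a long-stationary animal moves
away) dissolve within about one timeout instead of lingering. Setting
`stationary_timeout = 0` restores the strictly conservative classifier.

The per-frame step is two-phase — classify every pixel against the
frame-start model, then apply updates (own-sample, neighbor, timeout, in that
fixed order, row-major, last write wins) — so results do not depend on pixel
visit order. All randomness comes from one seeded generator, and the random
fields are drawn unconditionally per frame, so a replay is byte-identical. A
numba-compiled kernel and a pure-numpy kernel implement the same semantics;
the test suite asserts they agree bitwise, and the numpy kernel is the
fallback when no compiler is available.

Per-bin aggregation of per-frame counts uses the maximum (default): one
vigorous movement inside a second marks that second active. Mean aggregation
is available. Grayscale conversion is Rec.601 luma; infrared night-vision
footage is effectively single-channel already.

## Sleep scoring and calibration

A bin is active iff `count > threshold_pct/100 × reference_count` — strictly,
so that counts sitting exactly at the threshold (breathing, ear movements)
remain inactive. The activity percentage needs a definition of 100%:
`reference_count` defaults to the 99th percentile of the trace's positive
counts, a proxy for full-body motion that makes thresholds comparable across
camera resolutions; it is overridable everywhere.

Calibration replicates how such systems are tuned in practice: scan
thresholds on a 5% grid from 0% to 100%, score sleep at each, and keep the
threshold maximizing bin-level accuracy against a concurrent EEG/EMG-derived
reference, breaking ties toward the lowest threshold (favoring wake
sensitivity, so breathing-scale motion is not scored as arousal). Two
accuracy objectives are available:

* `objective="hypnogram"` (default) — accuracy of the scored hypnogram, i.e.
  calibration *through* the immobility rule. Because the rule forgives
  isolated bin errors, this objective is piecewise-flat and genuinely jagged
  in the threshold: wide near-optimal plateaus punctuated by 0.1–0.2%
  accuracy notches wherever a run's topology flips. Its argmax is therefore
  not sharply identifiable — refining the grid moves the maximizer by more
  than a grid step on a few percent of traces while changing accuracy by
  almost nothing. The guarantee that matters, and that the tests check, is in
  accuracy terms: the 5% grid pick scores within 0.5% bin accuracy of a 0.1%
  brute-force scan.
* `objective="activity"` — accuracy of the raw binarization against the
  reference's wake/sleep bins. This is the plain two-class decision problem;
  its optimum is the Bayes cutoff of the wake and sleep count distributions
  and its argmax is stable under grid refinement (the 5% grid lands within
  one step of a 0.1% scan). Use it when the threshold value itself is the
  quantity of interest.

Scoring, totals, hourly segmentation, and run-length encoding are exact
set operations on the activity series; `hourly_sleep` refuses hypnograms that
do not cover exactly 24 segments (no silent padding). Hour segments are
anchored at the recording start; recordings conventionally begin at lights-on
(08:00). The segment length `hour_s` defaults to a true hour and scales for
condensed-day protocols (below).

## Agreement

References are Wake/NREM/REM labels in 10 s epochs; total sleep is the union
of NREM and REM. The video hypnogram is majority-resampled onto the epoch
grid; exact ties go to Wake — the conservative choice against over-scoring
sleep. Comparison granularity is the per-hour paired sleep total (24 segments
per subject), not epoch-by-epoch: Bland–Altman bias, sample SD (n − 1), and
95% limits bias ± 1.96 SD are computed on the pooled subject-hours. Pooling
is simple (no random effect for subject) and the report says so.

The percent consistency coefficient has no single published formula in this
literature; the default is C = 100 · (1 − Σ|dᵢ|/Σ refᵢ) over subject-hours,
with a totals-ratio variant and the concordance correlation coefficient
selectable, and every report names the formula that produced its number.
C = 100 exactly when all paired values are equal; it is invariant under
rescaling both series; swapping the two systems negates the bias and mirrors
the limits.

## Synthetic data

The generator emulates the statistical structure the system assumes, not
mouse physiology; its outputs are declared test fixtures.

* **Hypnograms.** Alternating sleep/wake bouts with lognormal durations
  (σ_log = 0.6), phase-specific medians (defaults: sleep 480 s light / 240 s
  dark), and phase sleep-fraction targets (2/3 light, 1/3 dark — the
  nocturnal pattern) from which wake medians are derived; phase is decided at
  bout onset against a 12/12 cycle anchored at lights-on 08:00. Bouts are
  floored at `min_bout_s` (20 s) and rounded onto a `quantize_s` grid (1 s).
  A final bout truncated below the floor by the recording end is absorbed
  into its predecessor so the floor invariant holds for every emitted bout.
  Brief arousals (2/h of sleep, 4–20 s — always below the immobility rule)
  flip truth bins to Wake and are logged as events. Interventions (caffeine,
  diazepam, predator odor, LPS, social-defeat stress) act purely as named
  multipliers on the bout medians.
* **Traces.** Wake bins draw gamma counts with mean ≈ the blob area (300 px,
  shape 8); sleep bins draw a small gamma (mean 6 px) plus a breathing-band
  periodic term (8 px at 2.5 Hz) — a ≥5× separation by default, with overlap
  knobs (`sleep_base`, `sleep_shape`, `wake_mean`) for stress-testing
  calibration, and a dropout probability emulating frame loss.
* **Video.** An ellipse blob (12 × 8 px semi-axes ≈ 302 px area, contrast 140
  gray levels over background) random-walks during wake (σ = 8 px/frame,
  reflected so it never exits the frame) and holds position during sleep with
  ±3% area pulsation at 2.5 Hz plus occasional 1–2 px edge flickers; optional
  Gaussian pixel noise. Note 2.5 Hz sampled at the 5 fps test default aliases
  the pulsation to zero — sleep micro-motion in rendered tests then comes
  from the flickers, which is still sub-threshold by design. Frames are
  generated lazily from per-frame counter-keyed generators, so streams are
  byte-reproducible and never held in memory.
* **References.** The truth is majority-resampled to 10 s epochs; each sleep
  epoch is kept with probability `sensitivity`, each wake epoch with
  probability `specificity`; scored-sleep epochs are labeled REM with
  probability `rem_fraction` (0.1), else NREM.

What the generator does **not** emulate — posture changes without
translation, grooming, multi-animal occlusion, lighting drift, camera noise
correlated in space — bounds what passing tests show about real recordings:
they validate the algorithmic chain, not the biological classifier accuracy.

## The condensed-day regime

End-to-end identity checks run a full circadian day condensed 12-fold into a
2 h recording (`condensed_day_spec()`): 7200 s day, bout medians 90/70 s (the
1/12-condensed counterparts of realistic ~18/14 min mouse sleep episodes),
phase sleep fractions 0.75/0.45 (≈52% daily sleep, matching typical
C57BL/6J physiology), bouts floored at 60 s, boundaries quantized to the
10 s epoch grid, arousals off, and hour segments of 300 s. The quantization
makes the problem well-posed: an epoch-quantized reference can represent the
truth exactly, and majority resampling absorbs the classifier's ≤3.2 s
sleep-onset absorption delay, so the pipeline recovers bias = 0 and
consistency = 100% exactly from rendered video. With degraded references
(sensitivity = specificity = 0.9, six scorings pooled, emulating a 6-animal
group) consistency drops to about 90–91%: at condensed scale the 300 s
segments leave little cancellation between missed-sleep and false-sleep
epoch flips, so this figure sits near 90% by construction and fluctuates
±1% across seeds; the same degradation at full 24 h scale yields ≈96–97%.

## Problem sizes and numerics

The validation suite uses: 1,000 random activity sequences of length 10⁴
(× T ∈ {35, 40, 45}) for oracle equivalence; 200 simulated 24 h traces for
monotonicity; 500 replicates of 144 Normal(100, 150) differences plus one
n = 10⁴ draw for Bland–Altman recovery and coverage; 320 × 240 @ 5 fps
renders (36,000 frames for the condensed day) for detector fidelity and the
end-to-end identity; and 100 two-hour traces for calibration recovery.
Tie-breaks: lowest threshold in calibration, Wake on resampling ties, first
(lowest) index on accuracy-curve ties. Degenerate inputs: empty traces,
spans that do not divide into segments, references with unknown labels, and
sub-bin immobility windows all raise explicit errors rather than guessing.
Seeding is mandatory everywhere; no wall-clock entropy is used anywhere in
the package.

## Known limitations

* Immobility is a proxy: quiet wakefulness inflates, and sleep with gross
  twitching deflates, the sleep estimate; nothing in video can separate NREM
  from REM.
* The classifier's stationary timeout trades a bounded sleep-onset delay for
  absorption; with the timeout disabled the classifier is faithful to the
  strictly conservative original but cannot score a sleeping animal.
* The consistency coefficient is formula-dependent; cross-study comparisons
  require the formula, which is why reports embed it.
* Uncompressed AVI and TIFF stacks are the only containers decoded without
  an external codec backend; compressed recordings must be re-encoded first.
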