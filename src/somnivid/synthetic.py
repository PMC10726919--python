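"""Ground-truthed synthetic inputs: hypnograms, motion traces, rendered video,
and imperfect reference scorings.

The generator emulates the statistical structure the monitoring system
assumes, not mouse physiology: alternating sleep/wake bouts with lognormal
durations whose phase-specific medians encode the nocturnal pattern (mice
sleep predominantly in the light phase of a 12/12 cycle, lights on 08:00);
brief arousals inside sleep bouts that stay shorter than the immobility rule;
wake locomotion versus sleep micro-motion (breathing-band periodic term plus
small noise) in the pixel counts; and an epoch-quantized reference scorer
with configurable sensitivity/specificity. Interventions (caffeine, diazepam,
predator odor, LPS, social-defeat stress) are emulated purely as multipliers
on the bout-duration medians.

Every artifact is reproducible bit-for-bit from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    REF_NREM,
    REF_REM,
    REF_WAKE,
    SLEEP,
    WAKE,
    Hypnogram,
    MotionTrace,
    ReferenceHypnogram,
)
from .videoio import FrameStream

__all__ = [
    "SimSpec",
    "TraceNoiseSpec",
    "VideoSpec",
    "GroundTruth",
    "INTERVENTIONS",
    "simulate_hypnogram",
    "simulate_trace",
    "render_video",
    "degrade_reference",
]

#: Named bout-median multipliers (sleep, wake) emulating interventions.
#: Wake-promoting agents shrink sleep bouts and stretch wake bouts; the
#: hypnotic does the opposite. These are declared test fixtures, not
#: pharmacology.
INTERVENTIONS: Mapping[str, Mapping[str, float]] = {
    "caffeine": {"sleep": 0.4, "wake": 2.5},
    "diazepam": {"sleep": 2.0, "wake": 0.5},
    "cat_litter": {"sleep": 0.5, "wake": 2.0},
    "lps": {"sleep": 1.6, "wake": 0.7},
    "csds": {"sleep": 0.6, "wake": 1.6},
}


@dataclass(frozen=True)
class SimSpec:
    """Behavioral simulation parameters.

    duration_s
        Recording length (default a full day, 86,400 s).
    day_length_s
        Length of one light-dark cycle; the light phase is its first half,
        anchored at ``lights_on_clock``. Condensed-day protocols shrink this
        together with duration_s.
    sleep_median_light_s / sleep_median_dark_s
        Medians of the lognormal sleep-bout distribution per phase.
    light_sleep_fraction / dark_sleep_fraction
        Target long-run sleep fraction per phase; wake-bout medians are
        derived as sleep_median * (1 - f) / f so the realized fraction
        converges on the target.
    bout_sigma
        Log-scale SD of the bout-duration lognormals.
    min_bout_s
        Floor on sampled bout durations.
    quantize_s
        Bout boundaries are rounded onto this grid (1 s by default; set to the
        reference epoch width when an epoch-quantized scorer must be able to
        represent the truth exactly).
    brief_arousal_per_h
        Expected brief arousals per hour of sleep; each is an activity burst
        shorter than the immobility rule (durations drawn uniformly from
        ``arousal_duration_range``, which must stay below 40 s).
    intervention
        Optional key into :data:`INTERVENTIONS`.
    """

    duration_s: int = 86_400
    day_length_s: int = 86_400
    lights_on_clock: str = "08:00"
    start_clock: str = "08:00"
    sleep_median_light_s: float = 480.0
    sleep_median_dark_s: float = 240.0
    light_sleep_fraction: float = 2.0 / 3.0
    dark_sleep_fraction: float = 1.0 / 3.0
    bout_sigma: float = 0.6
    min_bout_s: float = 20.0
    quantize_s: float = 1.0
    brief_arousal_per_h: float = 2.0
    arousal_duration_range: tuple[float, float] = (4.0, 20.0)
    intervention: str | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.day_length_s <= 0:
            raise ValueError("duration_s and day_length_s must be > 0")
        if not (0 < self.light_sleep_fraction < 1 and 0 < self.dark_sleep_fraction < 1):
            raise ValueError("phase sleep fractions must lie strictly in (0, 1)")
        if self.min_bout_s <= 0 or self.quantize_s <= 0:
            raise ValueError("min_bout_s and quantize_s must be > 0")
        if self.brief_arousal_per_h < 0:
            raise ValueError("brief_arousal_per_h must be >= 0")
        lo, hi = self.arousal_duration_range
        if not (0 < lo <= hi < 40):
            raise ValueError("arousal durations must lie in (0, 40) s (below the immobility rule)")
        if self.intervention is not None and self.intervention not in INTERVENTIONS:
            raise ValueError(
                f"unknown intervention {self.intervention!r}; known: {sorted(INTERVENTIONS)}"
            )

    def medians(self, phase_light: bool) -> tuple[float, float]:
        """(sleep_median, wake_median) for the phase, intervention applied."""
        if phase_light:
            s, f = self.sleep_median_light_s, self.light_sleep_fraction
        else:
            s, f = self.sleep_median_dark_s, self.dark_sleep_fraction
        w = s * (1.0 - f) / f
        if self.intervention is not None:
            mult = INTERVENTIONS[self.intervention]
            s *= mult["sleep"]
            w *= mult["wake"]
        return s, w


@dataclass(frozen=True)
class TraceNoiseSpec:
    """Count-emission model for :func:`simulate_trace`.

    Wake counts are gamma with mean ``wake_mean`` (about the blob area in
    pixels). Sleep counts are a small breathing-band periodic term plus gamma
    noise, strictly separated from wake counts by default (>= 5x); raise
    ``sleep_base``/lower ``wake_mean`` to create overlap for stress-testing
    calibration. ``dropout_p`` zeroes a bin (frame loss).
    """

    wake_mean: float = 300.0
    wake_shape: float = 8.0
    sleep_base: float = 6.0
    sleep_shape: float = 3.0
    breathing_amp: float = 8.0
    breathing_hz: float = 2.5
    dropout_p: float = 0.0
    frame_area: int = 320 * 240

    def __post_init__(self) -> None:
        if self.wake_mean <= 0 or self.wake_shape <= 0 or self.sleep_shape <= 0:
            raise ValueError("wake_mean, wake_shape, sleep_shape must be > 0")
        if self.sleep_base < 0 or self.breathing_amp < 0:
            raise ValueError("sleep_base and breathing_amp must be >= 0")
        if not 0 <= self.dropout_p <= 1:
            raise ValueError("dropout_p must be in [0, 1]")


@dataclass(frozen=True)
class VideoSpec:
    """Rendering parameters for the synthetic cage view.

    The mouse is an ellipse blob that random-walks during wake and holds
    position during sleep with breathing-band area pulsation (default 2.5 Hz,
    +/-3% area) and occasional 1-2 px edge flickers (ear movements). Test
    default 320x240; the reference hardware records 1920x1080.
    """

    width: int = 320
    height: int = 240
    fps: float = 5.0
    blob_rx: float = 12.0
    blob_ry: float = 8.0
    background: int = 40
    blob_intensity: int = 180
    noise_sd: float = 0.0
    walk_step_px: float = 8.0
    breathing_amp: float = 0.03
    breathing_hz: float = 2.5
    flicker_p: float = 0.2
    flicker_px: int = 2

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.blob_rx <= 0 or self.blob_ry <= 0:
            raise ValueError("blob axes must be > 0")
        if 2 * self.blob_rx + 4 >= self.width or 2 * self.blob_ry + 4 >= self.height:
            raise ValueError("blob must fit inside the frame with a margin")
        if not 0 <= self.background <= 255 or not 0 <= self.blob_intensity <= 255:
            raise ValueError("intensities must be in [0, 255]")

    @property
    def blob_area_px(self) -> float:
        return float(np.pi * self.blob_rx * self.blob_ry)


@dataclass
class GroundTruth:
    """Simulated truth: 1 s-bin hypnogram, bout table, and event log."""

    hypnogram: Hypnogram
    bouts: pd.DataFrame  # state, onset_s, duration_s (pre-arousal architecture)
    events: pd.DataFrame  # kind, onset_s, duration_s
    spec: SimSpec
    seed: int


def condensed_day_spec(duration_s: int = 7200) -> SimSpec:
    """A full circadian day condensed 12-fold into a 2 h recording.

    Bout-duration medians are the 1/12-condensed counterparts of realistic
    mouse sleep-episode durations (~18 min light phase, ~14 min dark phase),
    floored at 60 s so every sleep bout comfortably exceeds the 40 s
    immobility rule, and quantized to the 10 s reference-epoch grid so an
    epoch-based scorer can represent the truth exactly. The phase sleep
    fractions (0.75 light / 0.45 dark) give a daily sleep fraction near the
    ~52% typical of C57BL/6J mice under a 12/12 light-dark cycle. Brief
    arousals are off: this spec defines the well-posed regime used for
    end-to-end identity checks.
    """
    return SimSpec(
        duration_s=duration_s,
        day_length_s=duration_s,
        quantize_s=10.0,
        min_bout_s=60.0,
        sleep_median_light_s=90.0,
        sleep_median_dark_s=70.0,
        light_sleep_fraction=0.75,
        dark_sleep_fraction=0.45,
        brief_arousal_per_h=0.0,
    )


def _phase_is_light(t: np.ndarray | float, spec: SimSpec) -> np.ndarray | bool:
    """Light phase = first half of the day cycle, recording anchored at lights-on."""
    from .containers import clock_to_seconds

    offset = clock_to_seconds(spec.start_clock) - clock_to_seconds(spec.lights_on_clock)
    scale = spec.day_length_s / 86_400.0
    tt = (np.asarray(t, dtype=float) + offset * scale) % spec.day_length_s
    return tt < spec.day_length_s / 2


def simulate_hypnogram(spec: SimSpec, seed: int = 0) -> GroundTruth:
    """Sample alternating sleep/wake bouts until ``duration_s`` is covered.

    Bout durations are lognormal with phase-appropriate medians (phase decided
    at bout onset), floored at ``min_bout_s`` and rounded onto the
    ``quantize_s`` grid. Brief arousals are then inserted into sleep bouts:
    they flip truth bins to Wake (motion is motion) and are logged as events,
    but being shorter than the immobility rule they are recoverable by the
    scorer. Deterministic per (spec, seed).
    """
    rng = np.random.default_rng(seed)
    states = np.zeros(int(spec.duration_s), dtype=np.uint8)
    rows = []
    t = 0.0
    light0 = bool(_phase_is_light(0.0, spec))
    f0 = spec.light_sleep_fraction if light0 else spec.dark_sleep_fraction
    state = SLEEP if rng.random() < f0 else WAKE
    q = spec.quantize_s
    while t < spec.duration_s:
        light = bool(_phase_is_light(t, spec))
        s_med, w_med = spec.medians(light)
        median = s_med if state == SLEEP else w_med
        if not np.isfinite(median):
            dur = spec.duration_s - t
        else:
            dur = float(rng.lognormal(mean=np.log(median), sigma=spec.bout_sigma))
            dur = max(dur, spec.min_bout_s)
            dur = max(q, round(dur / q) * q)
        dur = min(dur, spec.duration_s - t)
        rows.append({"state": "sleep" if state == SLEEP else "wake", "onset_s": t, "duration_s": dur})
        states[int(round(t)) : int(round(t + dur))] = state
        t += dur
        state = WAKE if state == SLEEP else SLEEP
    # The recording end can truncate the final bout below the documented
    # min_bout_s floor; absorb such a remnant into the preceding bout so the
    # floor invariant holds for every emitted bout.
    if len(rows) > 1 and rows[-1]["duration_s"] < spec.min_bout_s:
        remnant = rows.pop()
        rows[-1]["duration_s"] += remnant["duration_s"]
        prev_state = SLEEP if rows[-1]["state"] == "sleep" else WAKE
        states[int(round(remnant["onset_s"])) :] = prev_state
    bouts = pd.DataFrame(rows)

    events = []
    if spec.brief_arousal_per_h > 0:
        lo, hi = spec.arousal_duration_range
        for row in rows:
            if row["state"] != "sleep":
                continue
            n_ev = rng.poisson(spec.brief_arousal_per_h * row["duration_s"] / 3600.0)
            for _ in range(n_ev):
                dur = float(rng.uniform(lo, hi))
                dur = max(q, round(dur / q) * q)
                dur = min(dur, 39.0, row["duration_s"])
                latest = row["onset_s"] + row["duration_s"] - dur
                onset = float(rng.uniform(row["onset_s"], latest))
                onset = round(onset / q) * q
                onset = min(max(onset, row["onset_s"]), latest)
                a = int(round(onset))
                b = int(round(onset + dur))
                states[a:b] = WAKE
                events.append({"kind": "arousal", "onset_s": float(onset), "duration_s": dur})
    for k in range(int(np.ceil(spec.duration_s / (spec.day_length_s / 2)))):
        edge = k * spec.day_length_s / 2
        if 0 < edge < spec.duration_s:
            events.append({"kind": "phase_boundary", "onset_s": float(edge), "duration_s": 0.0})
    events_df = pd.DataFrame(events, columns=["kind", "onset_s", "duration_s"])

    hyp = Hypnogram(states=states, bin_s=1.0, start_clock=spec.start_clock)
    return GroundTruth(hypnogram=hyp, bouts=bouts, events=events_df, spec=spec, seed=seed)


def simulate_trace(
    gt: GroundTruth, noise: TraceNoiseSpec | None = None, seed: int = 0
) -> MotionTrace:
    """Draw per-bin pixel counts from the state-appropriate distribution.

    Wake bins (including arousal bins, which the truth hypnogram already
    labels Wake) draw from the locomotion gamma; sleep bins draw the breathing
    micro-motion term.
    """
    if noise is None:
        noise = TraceNoiseSpec()
    rng = np.random.default_rng(seed)
    states = gt.hypnogram.states
    n = states.size
    t = np.arange(n, dtype=float) * gt.hypnogram.bin_s

    wake_scale = noise.wake_mean / noise.wake_shape
    wake_counts = rng.gamma(noise.wake_shape, wake_scale, size=n)
    sleep_scale = max(noise.sleep_base, 1e-9) / noise.sleep_shape
    micro = noise.breathing_amp * np.abs(np.sin(np.pi * noise.breathing_hz * t))
    sleep_counts = rng.gamma(noise.sleep_shape, sleep_scale, size=n) + micro

    counts = np.where(states == WAKE, wake_counts, sleep_counts)
    if noise.dropout_p > 0:
        counts[rng.random(n) < noise.dropout_p] = 0
    counts = np.clip(np.round(counts), 0, noise.frame_area).astype(np.int64)
    return MotionTrace(
        counts=counts,
        bin_s=gt.hypnogram.bin_s,
        start_clock=gt.hypnogram.start_clock,
        frame_area=noise.frame_area,
    )


def _ellipse_mask(
    h: int, w: int, cy: float, cx: float, ry: float, rx: float
) -> np.ndarray:
    yy = (np.arange(h)[:, None] - cy) / ry
    xx = (np.arange(w)[None, :] - cx) / rx
    return yy * yy + xx * xx <= 1.0


def render_video(
    gt: GroundTruth, vspec: VideoSpec | None = None, seed: int = 0
) -> FrameStream:
    """Render the truth as a lazy, byte-reproducible grayscale frame stream.

    The blob random-walks during Wake frames (reflected at the walls so it
    never leaves the frame) and holds position during Sleep with area
    pulsation and sporadic edge flickers; Gaussian pixel noise is added when
    ``noise_sd > 0``. Use :func:`somnivid.videoio.write_avi` to persist.
    """
    if vspec is None:
        vspec = VideoSpec()
    n_seconds = gt.hypnogram.states.size
    fps = vspec.fps
    n_frames = int(round(n_seconds * fps))
    if n_frames < 1:
        raise ValueError("ground truth too short to render a single frame")

    frame_state = gt.hypnogram.states[
        np.minimum((np.arange(n_frames) / fps).astype(np.int64), n_seconds - 1)
    ]

    # Pre-walk the blob trajectory once (deterministic per seed).
    walk_rng = np.random.default_rng([seed, 0])
    h, w = vspec.height, vspec.width
    lo_x, hi_x = vspec.blob_rx + 2, w - vspec.blob_rx - 3
    lo_y, hi_y = vspec.blob_ry + 2, h - vspec.blob_ry - 3
    pos = np.empty((n_frames, 2), dtype=np.float64)
    x, y = w / 2.0, h / 2.0
    steps = walk_rng.normal(0.0, vspec.walk_step_px, size=(n_frames, 2))
    for i in range(n_frames):
        if frame_state[i] == WAKE:
            x += steps[i, 0]
            y += steps[i, 1]
            # reflect into the admissible box
            x = lo_x + abs((x - lo_x) % (2 * (hi_x - lo_x)) - (hi_x - lo_x))
            y = lo_y + abs((y - lo_y) % (2 * (hi_y - lo_y)) - (hi_y - lo_y))
        pos[i] = (y, x)

    def gen():
        for i in range(n_frames):
            rng = np.random.default_rng([seed, 1, i])
            frame = np.full((h, w), vspec.background, dtype=np.float64)
            cy, cx = pos[i]
            if frame_state[i] == SLEEP:
                s = 1.0 + vspec.breathing_amp * np.sin(
                    2 * np.pi * vspec.breathing_hz * i / fps
                )
            else:
                s = 1.0
            mask = _ellipse_mask(h, w, cy, cx, vspec.blob_ry * np.sqrt(s), vspec.blob_rx * np.sqrt(s))
            frame[mask] = vspec.blob_intensity
            if frame_state[i] == SLEEP and vspec.flicker_px > 0 and rng.random() < vspec.flicker_p:
                ring = _ellipse_mask(
                    h, w, cy, cx, vspec.blob_ry * np.sqrt(s) + 1.5, vspec.blob_rx * np.sqrt(s) + 1.5
                ) & ~mask
                ri, rj = np.nonzero(ring)
                if ri.size:
                    pick = rng.integers(0, ri.size, size=min(vspec.flicker_px, ri.size))
                    frame[ri[pick], rj[pick]] = vspec.blob_intensity
            if vspec.noise_sd > 0:
                frame = frame + rng.normal(0.0, vspec.noise_sd, size=frame.shape)
            yield np.clip(np.round(frame), 0, 255).astype(np.uint8)

    return FrameStream(
        frames=gen,
        fps=fps,
        width=w,
        height=h,
        n_frames=n_frames,
        start_clock=gt.hypnogram.start_clock,
    )


def degrade_reference(
    gt: GroundTruth,
    sensitivity: float = 1.0,
    specificity: float = 1.0,
    rem_fraction: float = 0.1,
    epoch_s: float = 10.0,
    seed: int = 0,
) -> ReferenceHypnogram:
    """Emulate manual epoch scoring of the truth with miss/false-alarm rates.

    The truth is majority-resampled to ``epoch_s`` epochs; each sleep epoch is
    kept Sleep with probability ``sensitivity`` and each wake epoch kept Wake
    with probability ``specificity``; epochs scored Sleep are assigned REM
    with probability ``rem_fraction``, else NREM.
    """
    from .agreement import resample_to_epochs

    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1 and 0 <= rem_fraction <= 1):
        raise ValueError("sensitivity, specificity, rem_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = resample_to_epochs(gt.hypnogram, epoch_s)
    n = truth.states.size
    u = rng.random(n)
    scored_sleep = np.where(
        truth.states == SLEEP, u < sensitivity, u >= specificity
    )
    labels = np.full(n, REF_WAKE, dtype=np.uint8)
    is_rem = rng.random(n) < rem_fraction
    labels[scored_sleep & is_rem] = REF_REM
    labels[scored_sleep & ~is_rem] = REF_NREM
    return ReferenceHypnogram(
        epoch_labels=labels, epoch_s=epoch_s, start_clock=gt.hypnogram.start_clock
    )
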