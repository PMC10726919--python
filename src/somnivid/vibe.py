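"""Sample-based background subtraction (ViBe) and motion-trace extraction.

Each pixel keeps a buffer of ``n_samples`` past intensities. A pixel is
background when at least ``min_matches`` stored samples lie within
``match_radius`` of its current intensity (inclusive comparison). Background
pixels stochastically refresh one of their own samples and one sample of a
random 8-neighbor (each with probability ``1/subsample_factor``), which lets
ghosts left by departed objects dissolve through spatial diffusion. Foreground
pixels never update their own model — the conservative policy that keeps a
moving mouse crisp — so the classifier additionally carries a stationary-
object timeout: a pixel classified foreground for ``stationary_timeout``
consecutive frames refreshes ``min_matches`` samples with its current value.
Without that escape valve an animal that stops moving (i.e. falls asleep at a
new spot) would read as foreground indefinitely; with it, immobility is
absorbed into the background within a few seconds and the per-frame foreground
count drops to the micro-motion floor that the sleep scorer thresholds.

The per-frame step has two phases so results are independent of pixel visit
order: classification against the frame-start model, then updates (own-sample,
neighbor, timeout — in that fixed order, row-major, last write wins). All
randomness comes from a seeded generator; identical (model, frame, seed state)
gives byte-identical output. A compiled kernel (numba) and a pure-numpy kernel
implement the same semantics; the numpy path is both the fallback and an
independent cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import MotionTrace
from .videoio import FrameStream

logger = logging.getLogger(__name__)

__all__ = ["ViBeParams", "ViBeModel", "init_vibe", "vibe_step", "motion_trace"]

# 8-neighborhood offsets, row-major order.
_NEIGHBOR_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


@dataclass(frozen=True)
class ViBeParams:
    """Classifier parameters (canonical defaults of the original algorithm).

    Parameters
    ----------
    n_samples
        Background samples kept per pixel (N = 20).
    match_radius
        Intensity distance for a sample match, inclusive (R = 20).
    min_matches
        Matches required to call a pixel background (#min = 2).
    subsample_factor
        Expected update interval in frames (phi = 16); each background pixel
        updates its own model and one neighbor's model with probability
        1/phi per frame.
    burn_in_s
        Seconds of video discarded while the model stabilizes (default 2 s;
        burn-in frames = round(burn_in_s * fps)). Counts during burn-in are
        reported as zero.
    stationary_timeout
        Consecutive foreground classifications after which a pixel is
        force-absorbed into the background (default = subsample_factor;
        0 disables the timeout and restores strictly conservative updating).
    """

    n_samples: int = 20
    match_radius: int = 20
    min_matches: int = 2
    subsample_factor: int = 16
    burn_in_s: float = 2.0
    stationary_timeout: int = 16

    def __post_init__(self) -> None:
        if min(self.n_samples, self.match_radius, self.min_matches, self.subsample_factor) <= 0:
            raise ValueError("n_samples, match_radius, min_matches, subsample_factor must be > 0")
        if self.min_matches > self.n_samples:
            raise ValueError(
                f"min_matches ({self.min_matches}) cannot exceed n_samples ({self.n_samples})"
            )
        if self.burn_in_s < 0:
            raise ValueError("burn_in_s must be >= 0")
        if self.stationary_timeout < 0:
            raise ValueError("stationary_timeout must be >= 0 (0 disables)")

    def burn_in_frames(self, fps: float) -> int:
        return int(round(self.burn_in_s * fps))


@dataclass
class ViBeModel:
    """Mutable per-pixel state: sample buffer, RNG, foreground streak counts."""

    samples: np.ndarray  # (H, W, N) uint8
    params: ViBeParams
    rng_seed: int
    rng: np.random.Generator = field(repr=False, default=None)  # type: ignore[assignment]
    fg_streak: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples.ndim != 3 or self.samples.shape[2] != self.params.n_samples:
            raise ValueError(
                f"samples must have shape (H, W, {self.params.n_samples}), got {self.samples.shape}"
            )
        if self.rng is None:
            self.rng = np.random.default_rng(self.rng_seed)
        if self.fg_streak is None:
            self.fg_streak = np.zeros(self.samples.shape[:2], dtype=np.int32)

    @property
    def shape(self) -> tuple[int, int]:
        return self.samples.shape[:2]


def init_vibe(first_frame: np.ndarray, params: ViBeParams, seed: int) -> ViBeModel:
    """Initialize the background model from a single frame.

    Each pixel's ``n_samples`` are drawn with replacement (seeded) from the
    intensities of its 8-neighborhood in the first frame; border pixels use
    coordinate-clamped neighborhoods.
    """
    frame = np.asarray(first_frame, dtype=np.uint8)
    if frame.ndim != 2 or frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError(f"first frame must be a nonempty 2-D grid, got shape {frame.shape}")
    h, w = frame.shape
    rng = np.random.default_rng(seed)
    choice = rng.integers(0, 8, size=(h, w, params.n_samples))
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    ni = np.clip(ii[:, :, None] + _NEIGHBOR_OFFSETS[choice, 0], 0, h - 1)
    nj = np.clip(jj[:, :, None] + _NEIGHBOR_OFFSETS[choice, 1], 0, w - 1)
    samples = frame[ni, nj]
    return ViBeModel(samples=samples, params=params, rng_seed=seed, rng=rng)


def _draw_step_randoms(model: ViBeModel) -> tuple[np.ndarray, ...]:
    """Per-frame random fields, drawn unconditionally so the RNG stream does
    not depend on frame content (keeps replays bit-stable)."""
    h, w = model.shape
    n = model.params.n_samples
    rng = model.rng
    r_self = rng.random((h, w))
    r_self_idx = rng.integers(0, n, size=(h, w))
    r_nb = rng.random((h, w))
    r_nb_choice = rng.integers(0, 8, size=(h, w))
    r_nb_idx = rng.integers(0, n, size=(h, w))
    return r_self, r_self_idx, r_nb, r_nb_choice, r_nb_idx


def _step_numpy(
    samples: np.ndarray,
    fg_streak: np.ndarray,
    frame: np.ndarray,
    match_radius: int,
    min_matches: int,
    subsample_factor: int,
    stationary_timeout: int,
    r_self: np.ndarray,
    r_self_idx: np.ndarray,
    r_nb: np.ndarray,
    r_nb_choice: np.ndarray,
    r_nb_idx: np.ndarray,
) -> np.ndarray:
    """Reference (pure-numpy) step kernel; mutates samples/fg_streak in place."""
    h, w, n = samples.shape
    f16 = frame.astype(np.int16)
    matches = np.zeros((h, w), dtype=np.int32)
    for k in range(n):
        matches += np.abs(samples[:, :, k].astype(np.int16) - f16) <= match_radius
    bg = matches >= min_matches
    p = 1.0 / subsample_factor

    # Phase 2a: own-sample refresh for background pixels.
    upd = bg & (r_self < p)
    ri, rj = np.nonzero(upd)
    samples[ri, rj, r_self_idx[ri, rj]] = frame[ri, rj]

    # Phase 2b: neighbor diffusion — insert v(x) into a random neighbor's buffer.
    upd = bg & (r_nb < p)
    ri, rj = np.nonzero(upd)
    off = _NEIGHBOR_OFFSETS[r_nb_choice[ri, rj]]
    ni = np.clip(ri + off[:, 0], 0, h - 1)
    nj = np.clip(rj + off[:, 1], 0, w - 1)
    samples[ni, nj, r_nb_idx[ri, rj]] = frame[ri, rj]

    # Phase 2c: stationary-object timeout.
    fg_streak[bg] = 0
    fg_streak[~bg] += 1
    if stationary_timeout > 0:
        hit = fg_streak >= stationary_timeout
        if hit.any():
            ri, rj = np.nonzero(hit)
            for t in range(min_matches):
                samples[ri, rj, (r_self_idx[ri, rj] + t) % n] = frame[ri, rj]
            fg_streak[hit] = 0
    return ~bg


def _build_numba_kernel():
    from numba import njit

    @njit(cache=True)
    def kernel(
        samples,
        fg_streak,
        frame,
        match_radius,
        min_matches,
        subsample_factor,
        stationary_timeout,
        r_self,
        r_self_idx,
        r_nb,
        r_nb_choice,
        r_nb_idx,
        offsets,
        mask_out,
    ):
        h, w, n = samples.shape
        p = 1.0 / subsample_factor
        # Phase 1: classify against the frame-start model.
        for i in range(h):
            for j in range(w):
                v = np.int16(frame[i, j])
                m = 0
                for k in range(n):
                    d = np.int16(samples[i, j, k]) - v
                    if -match_radius <= d <= match_radius:
                        m += 1
                        if m >= min_matches:
                            break
                mask_out[i, j] = 0 if m >= min_matches else 1
        # Phase 2a: own-sample refresh (background pixels).
        for i in range(h):
            for j in range(w):
                if mask_out[i, j] == 0 and r_self[i, j] < p:
                    samples[i, j, r_self_idx[i, j]] = frame[i, j]
        # Phase 2b: neighbor diffusion with v(x).
        for i in range(h):
            for j in range(w):
                if mask_out[i, j] == 0 and r_nb[i, j] < p:
                    c = r_nb_choice[i, j]
                    ni = i + offsets[c, 0]
                    nj = j + offsets[c, 1]
                    if ni < 0:
                        ni = 0
                    elif ni > h - 1:
                        ni = h - 1
                    if nj < 0:
                        nj = 0
                    elif nj > w - 1:
                        nj = w - 1
                    samples[ni, nj, r_nb_idx[i, j]] = frame[i, j]
        # Phase 2c: streaks and stationary-object timeout.
        for i in range(h):
            for j in range(w):
                if mask_out[i, j] == 0:
                    fg_streak[i, j] = 0
                else:
                    fg_streak[i, j] += 1
                    if stationary_timeout > 0 and fg_streak[i, j] >= stationary_timeout:
                        for t in range(min_matches):
                            samples[i, j, (r_self_idx[i, j] + t) % n] = frame[i, j]
                        fg_streak[i, j] = 0

    return kernel


try:  # compiled kernel when numba is importable; numpy otherwise
    _NUMBA_KERNEL = _build_numba_kernel()
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    _NUMBA_KERNEL = None
    HAVE_NUMBA = False


def vibe_step(
    model: ViBeModel, frame: np.ndarray, *, use_numba: bool | None = None
) -> tuple[np.ndarray, ViBeModel]:
    """Classify one frame and update the model in place.

    Returns ``(foreground_mask, model)`` where the mask is a boolean (H, W)
    grid (True = foreground) and ``model`` is the same object, advanced by one
    step. Classification uses the model state at frame start.
    """
    frame = np.asarray(frame, dtype=np.uint8)
    if frame.shape != model.shape:
        raise ValueError(f"frame shape {frame.shape} does not match model {model.shape}")
    p = model.params
    randoms = _draw_step_randoms(model)
    if use_numba is None:
        use_numba = HAVE_NUMBA
    if use_numba and _NUMBA_KERNEL is not None:
        mask = np.empty(model.shape, dtype=np.uint8)
        _NUMBA_KERNEL(
            model.samples,
            model.fg_streak,
            frame,
            p.match_radius,
            p.min_matches,
            p.subsample_factor,
            p.stationary_timeout,
            randoms[0],
            randoms[1],
            randoms[2],
            randoms[3],
            randoms[4],
            _NEIGHBOR_OFFSETS,
            mask,
        )
        return mask.astype(bool), model
    mask = _step_numpy(
        model.samples,
        model.fg_streak,
        frame,
        p.match_radius,
        p.min_matches,
        p.subsample_factor,
        p.stationary_timeout,
        *randoms,
    )
    return mask, model


def motion_trace(
    stream: FrameStream,
    params: ViBeParams | None = None,
    bin_s: float = 1.0,
    seed: int = 0,
    *,
    aggregation: str = "max",
) -> MotionTrace:
    """Run the classifier over a frame stream and bin foreground counts.

    The model is initialized from the first frame and updated on every frame.
    Counts during the burn-in window are reported as zero (the model is still
    stabilizing) and the trace stays aligned to the recording start. Within
    each bin counts are aggregated by ``max`` (default: one vigorous movement
    marks the whole bin active) or ``mean``.
    """
    if params is None:
        params = ViBeParams()
    if aggregation not in ("max", "mean"):
        raise ValueError(f"aggregation must be 'max' or 'mean', got {aggregation!r}")
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    burn_in = params.burn_in_frames(stream.fps)
    if stream.n_frames <= burn_in:
        raise ValueError(
            f"stream has {stream.n_frames} frames but burn-in requires more than "
            f"{burn_in} frames ({params.burn_in_s} s at {stream.fps} fps)"
        )
    frames_per_bin = stream.fps * bin_s
    n_bins = int(np.floor(stream.n_frames / frames_per_bin))
    if n_bins < 1:
        raise ValueError("stream shorter than one bin")

    counts = np.zeros(stream.n_frames, dtype=np.int64)
    model: ViBeModel | None = None
    for idx, frame in enumerate(stream.iter_frames()):
        if model is None:
            model = init_vibe(frame, params, seed)
        mask, model = vibe_step(model, frame)
        counts[idx] = int(mask.sum())
    if burn_in > 0:
        logger.info("burn-in: reporting the first %d frame counts as zero", burn_in)
        counts[:burn_in] = 0

    edges = (np.arange(n_bins + 1) * frames_per_bin).round().astype(np.int64)
    if aggregation == "max":
        binned = np.array([counts[a:b].max() for a, b in zip(edges[:-1], edges[1:])])
    else:
        binned = np.array(
            [int(round(counts[a:b].mean())) for a, b in zip(edges[:-1], edges[1:])]
        )
    return MotionTrace(
        counts=binned,
        bin_s=bin_s,
        start_clock=stream.start_clock,
        frame_area=stream.width * stream.height,
    )
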