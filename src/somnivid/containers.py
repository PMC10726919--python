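"""Core data containers shared across the pipeline.

Conventions
-----------
* Sleep/wake hypnograms use integer codes ``WAKE = 0``, ``SLEEP = 1``.
* Reference (EEG/EMG-style) hypnograms use ``REF_WAKE = 0``, ``REF_NREM = 1``,
  ``REF_REM = 2`` in fixed-width epochs (10 s by default).
* Wall-clock anchors are "HH:MM" strings; recordings conventionally start at
  lights-on (08:00) under a 12/12 light-dark cycle.
* All CSV round-trips go through pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

WAKE = 0
SLEEP = 1
STATE_NAMES = {WAKE: "wake", SLEEP: "sleep"}
STATE_CODES = {v: k for k, v in STATE_NAMES.items()}

REF_WAKE = 0
REF_NREM = 1
REF_REM = 2
REF_NAMES = {REF_WAKE: "wake", REF_NREM: "nrem", REF_REM: "rem"}
REF_CODES = {v: k for k, v in REF_NAMES.items()}


def clock_to_seconds(clock: str) -> int:
    """Convert an "HH:MM" wall-clock string to seconds after midnight."""
    try:
        hh, mm = clock.split(":")
        h, m = int(hh), int(mm)
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"clock must be 'HH:MM', got {clock!r}") from exc
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ValueError(f"clock out of range: {clock!r}")
    return 3600 * h + 60 * m


@dataclass
class MotionTrace:
    """Per-bin count of foreground ("moved") pixels — the actigraphy signal.

    Parameters
    ----------
    counts
        Non-negative integer pixel counts, one per time bin.
    bin_s
        Seconds per bin (default 1).
    start_clock
        Wall-clock time of bin 0.
    frame_area
        width x height of the source frames; the ceiling of any count.
    """

    counts: np.ndarray
    bin_s: float = 1.0
    start_clock: str = "08:00"
    frame_area: int = 1920 * 1080

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D array")
        if self.bin_s <= 0:
            raise ValueError(f"bin_s must be > 0, got {self.bin_s}")
        if self.frame_area <= 0:
            raise ValueError(f"frame_area must be > 0, got {self.frame_area}")
        if self.counts.size and (self.counts.min() < 0 or self.counts.max() > self.frame_area):
            raise ValueError(
                "counts must lie in [0, frame_area]="
                f"[0, {self.frame_area}]; observed range "
                f"[{self.counts.min()}, {self.counts.max()}]"
            )
        clock_to_seconds(self.start_clock)

    @property
    def duration_s(self) -> float:
        return float(self.counts.size * self.bin_s)

    @property
    def times_s(self) -> np.ndarray:
        """Bin start offsets from recording start, in seconds."""
        return np.arange(self.counts.size) * self.bin_s

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times_s, "count": self.counts}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        start_clock: str = "08:00",
        frame_area: int | None = None,
    ) -> "MotionTrace":
        df = pd.read_csv(path)
        for col in ("time_s", "count"):
            if col not in df.columns:
                raise ValueError(f"trace CSV {path} missing required column {col!r}")
        if len(df) < 2:
            bin_s = 1.0
        else:
            steps = np.diff(df["time_s"].to_numpy(dtype=float))
            bin_s = float(steps[0])
            if not np.allclose(steps, bin_s):
                raise ValueError(f"trace CSV {path} has irregular time steps")
        counts = df["count"].to_numpy(dtype=np.int64)
        if frame_area is None:
            frame_area = int(max(counts.max(initial=0), 1))
        return cls(counts, bin_s=bin_s, start_clock=start_clock, frame_area=frame_area)


@dataclass
class Hypnogram:
    """Per-bin Sleep/Wake labels (codes WAKE=0, SLEEP=1)."""

    states: np.ndarray
    bin_s: float = 1.0
    start_clock: str = "08:00"

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.ndim != 1:
            raise ValueError("states must be a 1-D array")
        if self.bin_s <= 0:
            raise ValueError(f"bin_s must be > 0, got {self.bin_s}")
        bad = set(np.unique(self.states)) - {WAKE, SLEEP}
        if bad:
            raise ValueError(f"unknown state codes {sorted(bad)}; allowed: 0=wake, 1=sleep")
        clock_to_seconds(self.start_clock)

    @property
    def duration_s(self) -> float:
        return float(self.states.size * self.bin_s)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.states.size) * self.bin_s

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.times_s,
                "state": [STATE_NAMES[s] for s in self.states],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, start_clock: str = "08:00") -> "Hypnogram":
        df = pd.read_csv(path)
        for col in ("time_s", "state"):
            if col not in df.columns:
                raise ValueError(f"hypnogram CSV {path} missing required column {col!r}")
        labels = df["state"].astype(str).str.strip().str.lower()
        unknown = sorted(set(labels) - set(STATE_CODES))
        if unknown:
            raise ValueError(f"unknown state label(s) {unknown} in {path}; expected sleep/wake")
        states = labels.map(STATE_CODES).to_numpy(dtype=np.uint8)
        if len(df) < 2:
            bin_s = 1.0
        else:
            steps = np.diff(df["time_s"].to_numpy(dtype=float))
            bin_s = float(steps[0])
            if not np.allclose(steps, bin_s):
                raise ValueError(f"hypnogram CSV {path} has irregular time steps")
        return cls(states, bin_s=bin_s, start_clock=start_clock)


@dataclass
class ReferenceHypnogram:
    """Wake/NREM/REM labels in fixed-width epochs, standing in for manual
    EEG/EMG scoring (10 s epochs by convention)."""

    epoch_labels: np.ndarray
    epoch_s: float = 10.0
    start_clock: str = "08:00"

    def __post_init__(self) -> None:
        self.epoch_labels = np.asarray(self.epoch_labels, dtype=np.uint8)
        if self.epoch_labels.ndim != 1:
            raise ValueError("epoch_labels must be a 1-D array")
        if self.epoch_s <= 0:
            raise ValueError(f"epoch_s must be > 0, got {self.epoch_s}")
        bad = set(np.unique(self.epoch_labels)) - {REF_WAKE, REF_NREM, REF_REM}
        if bad:
            raise ValueError(
                f"unknown reference codes {sorted(bad)}; allowed: 0=wake, 1=nrem, 2=rem"
            )
        clock_to_seconds(self.start_clock)

    @property
    def duration_s(self) -> float:
        return float(self.epoch_labels.size * self.epoch_s)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "epoch_index": np.arange(self.epoch_labels.size),
                "label": [REF_NAMES[s] for s in self.epoch_labels],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, epoch_s: float = 10.0, start_clock: str = "08:00"
    ) -> "ReferenceHypnogram":
        df = pd.read_csv(path)
        for col in ("epoch_index", "label"):
            if col not in df.columns:
                raise ValueError(f"reference CSV {path} missing required column {col!r}")
        labels = df["label"].astype(str).str.strip().str.lower()
        unknown = sorted(set(labels) - set(REF_CODES))
        if unknown:
            raise ValueError(
                f"unknown reference label(s) {unknown} in {path}; expected wake/nrem/rem"
            )
        codes = labels.map(REF_CODES).to_numpy(dtype=np.uint8)
        return cls(codes, epoch_s=epoch_s, start_clock=start_clock)
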