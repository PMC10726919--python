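"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from somnivid import ActivitySeries, Hypnogram
from somnivid.containers import SLEEP, WAKE


def oracle_score_sleep(active: np.ndarray, bin_s: float, immobility_min_s: float) -> np.ndarray:
    """Brute-force maximal-run scan: walk the sequence element by element,
    collect each maximal inactive run, and mark it Sleep when its duration
    qualifies. Independent of the vectorized implementation."""
    n = len(active)
    states = [WAKE] * n
    i = 0
    while i < n:
        if active[i]:
            i += 1
            continue
        j = i
        while j < n and not active[j]:
            j += 1
        if (j - i) * bin_s >= immobility_min_s:
            for k in range(i, j):
                states[k] = SLEEP
        i = j
    return np.array(states, dtype=np.uint8)


def oracle_bouts(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Naive scan into (state, onset, length) runs."""
    out = []
    i = 0
    n = len(states)
    while i < n:
        j = i
        while j < n and states[j] == states[i]:
            j += 1
        out.append((int(states[i]), i, j - i))
        i = j
    return out


def random_activity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Activity sequence with mixed bout scales (short flickers to long runs)."""
    out = np.empty(n, dtype=bool)
    i = 0
    state = bool(rng.integers(0, 2))
    while i < n:
        scale = rng.choice([3, 15, 60, 300])
        ln = 1 + rng.geometric(1.0 / scale)
        out[i : i + ln] = state
        i += ln
        state = not state
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_activity():
    def _make(active, bin_s=1.0):
        return ActivitySeries(active=np.asarray(active, dtype=bool), bin_s=bin_s)

    return _make


@pytest.fixture
def make_hypnogram():
    def _make(states, bin_s=1.0):
        return Hypnogram(states=np.asarray(states, dtype=np.uint8), bin_s=bin_s)

    return _make
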