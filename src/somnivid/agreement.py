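"""Agreement between video-derived and EEG/EMG-derived hypnograms.

Comparison granularity is the per-hour paired sleep total (24 segments per
subject), matching how video somnography is validated against manual EEG/EMG
scoring: each recording is split into 24 x 1 h segments, the sleep seconds per
segment from the two systems form paired measurements, and Bland-Altman bias
and 95% limits of agreement (bias +/- 1.96 x sample SD of the differences)
summarize agreement. Reference total sleep is the union of NREM and REM
epochs.

The percent "consistency" coefficient quoted for such systems has no single
published formula; the default here is

    C = 100 * (1 - sum_i |d_i| / sum_i ref_i)

over all subject-hours (d_i = video_i - ref_i), with a totals-ratio variant
and the concordance correlation coefficient selectable. Reports always record
which formula produced the number. Pooling across subjects is simple pooling
(no random effect for subject), and the report says so.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    REF_NREM,
    REF_REM,
    REF_WAKE,
    SLEEP,
    WAKE,
    Hypnogram,
    ReferenceHypnogram,
)
from .scoring import hourly_sleep

__all__ = [
    "AgreementReport",
    "collapse_reference",
    "resample_to_epochs",
    "paired_hourly",
    "bland_altman",
    "consistency_pct",
    "compare",
    "compare_many",
    "CONSISTENCY_FORMULAS",
]

CONSISTENCY_FORMULAS = ("sum-abs", "total-ratio", "ccc")


@dataclass
class AgreementReport:
    """Bland-Altman summary plus the consistency coefficient.

    ``loa_low_s``/``loa_high_s`` are bias -/+ 1.96 x sd_diff_s. ``pairs`` is
    the per-(subject, hour) table with columns subject, hour, video_sleep_s,
    reference_sleep_s, diff_s.
    """

    bias_s: float
    sd_diff_s: float
    loa_low_s: float
    loa_high_s: float
    n_pairs: int
    consistency_pct: float | None = None
    formula: str | None = None
    pairs: pd.DataFrame | None = field(default=None, repr=False)
    pooling: str = "simple pooling across subjects (no subject random effect)"

    def to_dict(self) -> dict:
        out = {
            "bias_s": self.bias_s,
            "sd_diff_s": self.sd_diff_s,
            "loa": [self.loa_low_s, self.loa_high_s],
            "consistency_pct": self.consistency_pct,
            "formula": self.formula,
            "n_pairs": self.n_pairs,
            "pooling": self.pooling,
        }
        if self.pairs is not None:
            out["per_hour"] = self.pairs.to_dict(orient="records")
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def collapse_reference(ref: ReferenceHypnogram) -> Hypnogram:
    """Collapse Wake/NREM/REM epochs to Sleep/Wake (sleep = NREM + REM)."""
    states = np.where(
        np.isin(ref.epoch_labels, (REF_NREM, REF_REM)), SLEEP, WAKE
    ).astype(np.uint8)
    return Hypnogram(states=states, bin_s=ref.epoch_s, start_clock=ref.start_clock)


def resample_to_epochs(h: Hypnogram, epoch_s: float) -> Hypnogram:
    """Majority-vote resample onto a coarser epoch grid; exact ties -> Wake.

    The tie rule is conservative against over-scoring sleep. Constant
    hypnograms are unchanged at any epoch width.
    """
    factor = epoch_s / h.bin_s
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"epoch_s ({epoch_s}) must be an integer multiple of bin_s ({h.bin_s})")
    factor = int(round(factor))
    if factor == 1:
        return Hypnogram(h.states.copy(), bin_s=epoch_s, start_clock=h.start_clock)
    if h.states.size % factor != 0:
        raise ValueError(
            f"hypnogram length {h.states.size} bins is not a whole number of "
            f"{epoch_s} s epochs"
        )
    sleep_per_epoch = (h.states == SLEEP).reshape(-1, factor).sum(axis=1)
    states = (2 * sleep_per_epoch > factor).astype(np.uint8)  # strict majority
    return Hypnogram(states=states, bin_s=epoch_s, start_clock=h.start_clock)


def paired_hourly(
    video: Hypnogram,
    ref: Hypnogram,
    subject: str = "subject-0",
    hour_s: float = 3600.0,
) -> pd.DataFrame:
    """Per-hour sleep seconds from each source, paired per segment."""
    if not np.isclose(video.duration_s, ref.duration_s):
        raise ValueError(
            f"span mismatch: video covers {video.duration_s:.0f} s, "
            f"reference covers {ref.duration_s:.0f} s"
        )
    v = hourly_sleep(video, hour_s=hour_s)
    r = hourly_sleep(ref, hour_s=hour_s)
    return pd.DataFrame(
        {
            "subject": subject,
            "hour": np.arange(24),
            "video_sleep_s": v,
            "reference_sleep_s": r,
            "diff_s": v - r,
        }
    )


def bland_altman(pairs: pd.DataFrame) -> AgreementReport:
    """Bias, sample SD (n-1), and 95% limits of agreement of video - reference."""
    d = pairs["diff_s"].to_numpy(dtype=float)
    if d.size < 2:
        raise ValueError(f"Bland-Altman needs >= 2 pairs (SD undefined), got {d.size}")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementReport(
        bias_s=bias,
        sd_diff_s=sd,
        loa_low_s=bias - 1.96 * sd,
        loa_high_s=bias + 1.96 * sd,
        n_pairs=int(d.size),
        pairs=pairs,
    )


def consistency_pct(pairs: pd.DataFrame, formula: str = "sum-abs") -> float:
    """Percent agreement between paired sleep totals.

    sum-abs (default): 100 * (1 - sum|d_i| / sum ref_i)
    total-ratio:       100 * (1 - |sum v_i - sum ref_i| / sum ref_i)
    ccc:               100 * concordance correlation coefficient
    """
    v = pairs["video_sleep_s"].to_numpy(dtype=float)
    r = pairs["reference_sleep_s"].to_numpy(dtype=float)
    ref_total = r.sum()
    if ref_total <= 0:
        raise ValueError("reference sleep total is zero; consistency undefined")
    if formula == "sum-abs":
        return float(100.0 * (1.0 - np.abs(v - r).sum() / ref_total))
    if formula == "total-ratio":
        return float(100.0 * (1.0 - abs(v.sum() - ref_total) / ref_total))
    if formula == "ccc":
        vm, rm = v.mean(), r.mean()
        sv, sr = v.var(), r.var()
        cov = np.mean((v - vm) * (r - rm))
        denom = sv + sr + (vm - rm) ** 2
        if denom == 0:
            return 100.0
        return float(100.0 * 2 * cov / denom)
    raise ValueError(f"unknown consistency formula {formula!r}; choose from {CONSISTENCY_FORMULAS}")


def compare_many(
    pairs,
    epoch_s: float | None = None,
    hour_s: float = 3600.0,
    formula: str = "sum-abs",
    subjects=None,
) -> AgreementReport:
    """Compare (video Hypnogram, ReferenceHypnogram) pairs, pooled.

    Each video hypnogram is majority-resampled to the reference epoch width,
    the reference is collapsed to Sleep/Wake, per-hour sleep totals are paired
    per subject, and the pooled pairs feed Bland-Altman and the consistency
    coefficient.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("compare_many needs at least one (video, reference) pair")
    if subjects is None:
        subjects = [f"subject-{i}" for i in range(len(pairs))]
    tables = []
    for subject, (video, ref) in zip(subjects, pairs):
        if isinstance(ref, ReferenceHypnogram):
            ref_h = collapse_reference(ref)
        else:
            ref_h = ref
        eps = epoch_s if epoch_s is not None else ref_h.bin_s
        v = video if video.bin_s == eps else resample_to_epochs(video, eps)
        r = ref_h if ref_h.bin_s == eps else resample_to_epochs(ref_h, eps)
        tables.append(paired_hourly(v, r, subject=subject, hour_s=hour_s))
    pooled = pd.concat(tables, ignore_index=True)
    report = bland_altman(pooled)
    report.consistency_pct = consistency_pct(pooled, formula=formula)
    report.formula = formula
    return report


def compare(
    video: Hypnogram,
    reference: ReferenceHypnogram | Hypnogram,
    epoch_s: float | None = None,
    hour_s: float = 3600.0,
    formula: str = "sum-abs",
    subject: str = "subject-0",
) -> AgreementReport:
    """Single-subject convenience wrapper around :func:`compare_many`."""
    return compare_many(
        [(video, reference)], epoch_s=epoch_s, hour_s=hour_s, formula=formula,
        subjects=[subject],
    )


def plot_bland_altman(report: AgreementReport, path: str | Path | None = None):
    """Scatter of per-pair differences against means with bias and limits.

    Requires matplotlib; imported lazily so headless pipelines stay light.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.pairs is None:
        raise ValueError("report carries no per-pair table to plot")
    v = report.pairs["video_sleep_s"]
    r = report.pairs["reference_sleep_s"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((v + r) / 2, v - r, s=12, alpha=0.6)
    for y, style in ((report.bias_s, "-"), (report.loa_low_s, "--"), (report.loa_high_s, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of paired hourly sleep (s)")
    ax.set_ylabel("video - reference (s)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
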