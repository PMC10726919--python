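"""Generator properties: reproducibility, conservation, recoverability."""

import numpy as np
import pytest

from somnivid import (
    ScoringParams,
    SimSpec,
    TraceNoiseSpec,
    VideoSpec,
    binarize,
    collapse_reference,
    degrade_reference,
    motion_trace,
    render_video,
    resample_to_epochs,
    score_sleep,
    simulate_hypnogram,
    simulate_trace,
    total_sleep,
)
from somnivid.containers import SLEEP, WAKE
from somnivid.synthetic import condensed_day_spec
from somnivid.vibe import ViBeParams


def _all_state_truth(state, duration_s):
    """Hand-built single-bout ground truth (degenerate architectures)."""
    import pandas as pd

    from somnivid import GroundTruth, Hypnogram

    name = "sleep" if state == SLEEP else "wake"
    return GroundTruth(
        hypnogram=Hypnogram(np.full(duration_s, state, dtype=np.uint8), bin_s=1.0),
        bouts=pd.DataFrame({"state": [name], "onset_s": [0.0], "duration_s": [float(duration_s)]}),
        events=pd.DataFrame(columns=["kind", "onset_s", "duration_s"]),
        spec=SimSpec(duration_s=duration_s),
        seed=0,
    )


class TestSimulateHypnogram:
    def test_deterministic_per_seed(self):
        spec = SimSpec(duration_s=7200)
        a = simulate_hypnogram(spec, seed=5)
        b = simulate_hypnogram(spec, seed=5)
        np.testing.assert_array_equal(a.hypnogram.states, b.hypnogram.states)
        assert a.bouts.equals(b.bouts)

    def test_bout_durations_sum_to_duration(self):
        gt = simulate_hypnogram(SimSpec(duration_s=86400), seed=1)
        assert gt.bouts["duration_s"].sum() == 86400
        # contiguous, non-overlapping, alternating
        onsets = gt.bouts["onset_s"].to_numpy()
        durs = gt.bouts["duration_s"].to_numpy()
        np.testing.assert_allclose(onsets[1:], (onsets + durs)[:-1])
        states = gt.bouts["state"].to_numpy()
        assert all(states[i] != states[i + 1] for i in range(len(states) - 1))

    def test_degenerate_wake_dominant_spec_is_all_wake(self):
        spec = SimSpec(
            duration_s=3600,
            light_sleep_fraction=1e-9,
            dark_sleep_fraction=1e-9,
        )
        gt = simulate_hypnogram(spec, seed=2)
        assert np.all(gt.hypnogram.states == WAKE)

    def test_light_phase_sleep_fraction_near_target(self):
        """Monte-Carlo: realized light-phase sleep fraction tracks the target."""
        spec = SimSpec(duration_s=86400, brief_arousal_per_h=0.0)
        fracs = []
        for seed in range(30):
            gt = simulate_hypnogram(spec, seed=seed)
            light = gt.hypnogram.states[: 43200]
            fracs.append(np.mean(light == SLEEP))
        assert abs(np.mean(fracs) - spec.light_sleep_fraction) <= 0.03

    def test_arousals_logged_and_short(self):
        spec = SimSpec(duration_s=86400, brief_arousal_per_h=3.0)
        gt = simulate_hypnogram(spec, seed=3)
        arousals = gt.events[gt.events["kind"] == "arousal"]
        assert len(arousals) > 0
        assert (arousals["duration_s"] < 40).all()

    def test_intervention_multipliers_shift_sleep(self):
        base = SimSpec(duration_s=86400, brief_arousal_per_h=0.0)
        caffeine = SimSpec(duration_s=86400, brief_arousal_per_h=0.0, intervention="caffeine")
        diazepam = SimSpec(duration_s=86400, brief_arousal_per_h=0.0, intervention="diazepam")
        t_base = np.mean(
            [total_sleep(simulate_hypnogram(base, seed=s).hypnogram) for s in range(5)]
        )
        t_caf = np.mean(
            [total_sleep(simulate_hypnogram(caffeine, seed=s).hypnogram) for s in range(5)]
        )
        t_dzp = np.mean(
            [total_sleep(simulate_hypnogram(diazepam, seed=s).hypnogram) for s in range(5)]
        )
        assert t_caf < t_base < t_dzp

    def test_unknown_intervention_rejected(self):
        with pytest.raises(ValueError, match="unknown intervention"):
            SimSpec(intervention="espresso")


class TestSimulateTrace:
    def test_separated_counts_recover_truth_exactly(self):
        """With strictly separated count distributions, binarization recovers
        the true activity pattern bin-for-bin, so scoring the trace equals
        scoring the truth itself (identical up to runs truncated below the
        immobility rule at the recording boundary)."""
        from conftest import oracle_score_sleep

        spec = SimSpec(duration_s=7200, min_bout_s=60, brief_arousal_per_h=0.0)
        gt = simulate_hypnogram(spec, seed=4)
        trace = simulate_trace(gt, TraceNoiseSpec(), seed=5)
        params = ScoringParams(threshold_pct=10, reference_count=600, immobility_min_s=40)
        act = binarize(trace, params)
        np.testing.assert_array_equal(act.active, gt.hypnogram.states == WAKE)
        hyp = score_sleep(act, 40)
        np.testing.assert_array_equal(
            hyp.states, oracle_score_sleep(gt.hypnogram.states == WAKE, 1.0, 40)
        )

    def test_all_sleep_breathing_below_threshold(self):
        gt = _all_state_truth(SLEEP, 3600)
        trace = simulate_trace(gt, TraceNoiseSpec(), seed=2)
        params = ScoringParams(threshold_pct=10, reference_count=600, immobility_min_s=40)
        hyp = score_sleep(binarize(trace, params), 40)
        assert total_sleep(hyp) == 3600

    def test_accuracy_degrades_monotonically_with_overlap(self):
        spec = SimSpec(duration_s=7200, brief_arousal_per_h=0.0)
        gt = simulate_hypnogram(spec, seed=6)
        accs = []
        for sleep_base in (6.0, 60.0, 120.0):
            noise = TraceNoiseSpec(sleep_base=sleep_base, sleep_shape=2.0)
            trace = simulate_trace(gt, noise, seed=7)
            params = ScoringParams(threshold_pct=30, reference_count=600, immobility_min_s=40)
            hyp = score_sleep(binarize(trace, params), 40)
            accs.append(np.mean(hyp.states == gt.hypnogram.states))
        assert accs[0] > accs[1] > accs[2]

    def test_dropout_zeroes_bins(self):
        spec = SimSpec(duration_s=3600, light_sleep_fraction=1e-9, dark_sleep_fraction=1e-9)
        gt = simulate_hypnogram(spec, seed=1)
        trace = simulate_trace(gt, TraceNoiseSpec(dropout_p=0.3), seed=2)
        assert np.mean(trace.counts == 0) > 0.2


class TestRenderVideo:
    def test_fixed_seed_byte_identical(self):
        gt = simulate_hypnogram(SimSpec(duration_s=60, quantize_s=10, min_bout_s=60), seed=1)
        vs = VideoSpec(noise_sd=2.0)
        a = render_video(gt, vs, seed=9).load()
        b = render_video(gt, vs, seed=9).load()
        np.testing.assert_array_equal(a, b)

    def test_all_sleep_counts_below_5pct_of_area(self):
        gt = _all_state_truth(SLEEP, 120)
        vs = VideoSpec()
        trace = motion_trace(render_video(gt, vs, seed=3), ViBeParams(), bin_s=1.0, seed=4)
        assert trace.counts.max() <= 0.05 * vs.blob_area_px

    def test_all_wake_counts_near_blob_area(self):
        gt = _all_state_truth(WAKE, 120)
        vs = VideoSpec(walk_step_px=30.0)  # step > blob diameter
        trace = motion_trace(render_video(gt, vs, seed=3), ViBeParams(), bin_s=1.0, seed=4)
        # skip burn-in plus the few seconds it takes the ghost of the blob's
        # initial position (part of the first-frame background model) to clear
        post = trace.counts[4:]
        assert np.all(post >= 0.9 * vs.blob_area_px)
        assert np.all(post <= 1.1 * vs.blob_area_px)

    def test_blob_never_leaves_frame(self):
        gt = simulate_hypnogram(SimSpec(duration_s=300, light_sleep_fraction=1e-9, dark_sleep_fraction=1e-9), seed=5)
        vs = VideoSpec(walk_step_px=40.0)
        for i, frame in enumerate(render_video(gt, vs, seed=6).iter_frames()):
            if i % 100:
                continue
            fg = frame > vs.background + 50
            assert fg.sum() > 0
            assert not fg[0, :].any() and not fg[-1, :].any()
            assert not fg[:, 0].any() and not fg[:, -1].any()


class TestDegradeReference:
    def test_perfect_scorer_matches_truth(self):
        gt = simulate_hypnogram(SimSpec(duration_s=7200, quantize_s=10), seed=1)
        ref = degrade_reference(gt, 1.0, 1.0, epoch_s=10, seed=2)
        truth = resample_to_epochs(gt.hypnogram, 10.0)
        np.testing.assert_array_equal(collapse_reference(ref).states, truth.states)

    def test_zero_sensitivity_never_scores_true_sleep(self):
        gt = simulate_hypnogram(SimSpec(duration_s=7200, quantize_s=10), seed=1)
        ref = degrade_reference(gt, 0.0, 1.0, epoch_s=10, seed=2)
        truth = resample_to_epochs(gt.hypnogram, 10.0)
        sleep_epochs = truth.states == SLEEP
        assert np.all(collapse_reference(ref).states[sleep_epochs] == WAKE)

    def test_miss_rate_matches_binomial(self):
        """sens = spec = 0.9 over 8,640 epochs: empirical agreement 0.9 +/- 0.01."""
        gt = simulate_hypnogram(SimSpec(duration_s=86400, quantize_s=10), seed=3)
        ref = degrade_reference(gt, 0.9, 0.9, epoch_s=10, seed=4)
        truth = resample_to_epochs(gt.hypnogram, 10.0)
        agreement = np.mean(collapse_reference(ref).states == truth.states)
        assert abs(agreement - 0.9) <= 0.01

    def test_rem_fraction_among_scored_sleep(self):
        from somnivid.containers import REF_NREM, REF_REM

        gt = simulate_hypnogram(SimSpec(duration_s=86400, quantize_s=10), seed=3)
        ref = degrade_reference(gt, 1.0, 1.0, rem_fraction=0.25, epoch_s=10, seed=4)
        n_rem = np.count_nonzero(ref.epoch_labels == REF_REM)
        n_sleep = n_rem + np.count_nonzero(ref.epoch_labels == REF_NREM)
        assert n_sleep > 0
        assert abs(n_rem / n_sleep - 0.25) < 0.03


class TestContracts:
    def test_generator_outputs_satisfy_downstream_preconditions(self):
        """Everything the generator emits feeds the scorer and the agreement
        module without adaptation."""
        from somnivid import compare

        spec = condensed_day_spec()
        gt = simulate_hypnogram(spec, seed=0)
        trace = simulate_trace(gt, TraceNoiseSpec(), seed=1)
        ref = degrade_reference(gt, 0.95, 0.95, epoch_s=10, seed=2)
        params = ScoringParams(threshold_pct=10, reference_count=600, immobility_min_s=40)
        hyp = score_sleep(binarize(trace, params), 40)
        rep = compare(hyp, ref, epoch_s=10.0, hour_s=spec.duration_s / 24)
        assert rep.n_pairs == 24
        assert 0 <= rep.consistency_pct <= 100
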