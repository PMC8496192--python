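"""Gait-phase reconstruction, cycle segmentation, regularity splitting."""

import numpy as np
import pytest

from gaitmod import (GaitCycleTable, circular_rms_error, cycle_variability,
                     phase_from_accel, phase_from_force, preprocess_recording,
                     split_regularity, wrap_phase)


class TestPhaseFromForce:
    def test_pure_sinusoid_anchors_and_interpolation(self):
        """force = sin(2*pi*t/2): strikes at even seconds, lifts at odd;
        quarter-cycle points interpolate to +-pi/2."""
        fs = 100.0
        t = np.arange(int(8 * fs)) / fs
        ph, table = phase_from_force(np.sin(2 * np.pi * t / 2), fs)
        # cycles open at lifts (t = 1, 3, 5)
        np.testing.assert_allclose(table.lift_sample, [100, 300, 500])
        np.testing.assert_allclose(table.strike_sample, [200, 400, 600])
        np.testing.assert_allclose(table.duration_s, 2.0, atol=0.02)
        # strike -> phase 0, midpoints -> +-pi/2
        assert abs(ph.phase[200]) < 0.05
        assert abs(ph.phase[250] - np.pi / 2) < 0.05
        assert abs(ph.phase[150] - (-np.pi / 2)) < 0.05

    def test_recovers_generator_truth_with_jitter(self, beta_session,
                                                  beta_session_pre):
        ph, _ = phase_from_force(beta_session_pre.get("force_left"),
                                 beta_session_pre.fs)
        truth = beta_session.truth_phase
        both = ph.valid & truth.valid
        assert both.mean() > 0.9
        assert circular_rms_error(ph.phase[both], truth.phase[both]) < 0.1

    def test_zero_jitter_cycle_boundaries_within_one_sample(
            self, zero_jitter_session):
        rec = preprocess_recording(zero_jitter_session.recording)
        _, table = phase_from_force(rec.get("force_left"), rec.fs)
        truth = zero_jitter_session.truth_cycles
        # align on overlapping cycles by nearest lift
        for lift in table.lift_sample:
            assert np.min(np.abs(truth.lift_sample - lift)) <= 1.0

    def test_constant_force_raises(self):
        with pytest.raises(ValueError, match="no gait cycles"):
            phase_from_force(np.ones(1000), 100.0)

    def test_phase_histogram_is_near_uniform(self, beta_session_pre):
        ph, _ = phase_from_force(beta_session_pre.get("force_left"),
                                 beta_session_pre.fs)
        counts, _ = np.histogram(ph.phase[ph.valid],
                                 bins=np.linspace(-np.pi, np.pi, 19))
        assert counts.max() < 2 * counts.min()


class TestPhaseFromAccel:
    def test_planted_minima_found(self, zero_jitter_session):
        rec = preprocess_recording(zero_jitter_session.recording)
        ph, table = phase_from_accel(rec.get("accel_x"), rec.get("accel_y"),
                                     rec.fs)
        truth = zero_jitter_session.truth_cycles
        assert abs(table.n_cycles - truth.n_cycles) <= 1
        assert not ph.strike_anchored
        # anchors (x minima) sit at the truth lifts (phase +-pi)
        for lift in table.lift_sample[1:-1]:
            near = np.min(np.abs(truth.lift_sample - lift))
            assert near <= 0.05 * rec.fs

    def test_midpoint_between_anchors_is_phase_zero(self):
        fs = 100.0
        t = np.arange(int(10 * fs)) / fs
        acc_x = np.cos(2 * np.pi * t / 2)
        acc_y = -np.sin(2 * np.pi * t / 2)
        ph, table = phase_from_accel(acc_x, acc_y, fs)
        mid = int((table.lift_sample[0] + table.next_lift_sample[0]) / 2)
        assert abs(ph.phase[mid]) < 0.05

    def test_too_few_anchors_raise(self):
        with pytest.raises(ValueError, match="anchors"):
            phase_from_accel(np.zeros(500), np.zeros(500), 100.0)


class TestCycleVariability:
    def test_identical_cycles_zero(self):
        table = GaitCycleTable(
            lift_sample=[0, 200], strike_sample=[100, 300],
            next_lift_sample=[200, 400], duration_s=[2.0, 2.0],
            lift_duration_s=[1.0, 1.0], fs=100.0)
        assert cycle_variability(table) == 0.0

    def test_hand_computed_sample_sd(self):
        """Lift durations {0.9, 1.1} s -> sample SD (n-1) = 0.1414... s."""
        table = GaitCycleTable(
            lift_sample=[0, 200], strike_sample=[90, 310],
            next_lift_sample=[200, 400], duration_s=[2.0, 2.0],
            lift_duration_s=[0.9, 1.1], fs=100.0)
        assert cycle_variability(table) == pytest.approx(np.sqrt(0.02),
                                                         abs=1e-12)

    def test_zero_jitter_session_variability_tiny(self, zero_jitter_session):
        rec = preprocess_recording(zero_jitter_session.recording)
        _, table = phase_from_force(rec.get("force_left"), rec.fs)
        assert cycle_variability(table) < 2.0 / rec.fs

    def test_single_cycle_rejected(self):
        table = GaitCycleTable([0], [100], [200], [2.0], [1.0], fs=100.0)
        with pytest.raises(ValueError, match="2 cycles"):
            cycle_variability(table)


def _table(durations):
    durations = np.asarray(durations, float)
    starts = np.concatenate([[0], np.cumsum(durations)]) * 100
    return GaitCycleTable(
        lift_sample=starts[:-1],
        strike_sample=starts[:-1] + durations * 50,
        next_lift_sample=starts[1:],
        duration_s=durations,
        lift_duration_s=durations / 2,
        fs=100.0,
    )


class TestSplitRegularity:
    def test_forced_ordering(self):
        split = split_regularity(_table([2.0, 2.0, 1.5, 2.0, 2.0, 2.5, 2.0,
                                         2.0]))
        assert sorted(split.less_regular_idx) == [2, 5]
        assert all(split.label[i] == "regular" for i in split.regular_idx)
        assert len(split.regular_idx) == 2

    def test_tie_break_deterministic_and_sized(self):
        a = split_regularity(_table([2.0] * 8))
        b = split_regularity(_table([2.0] * 8))
        assert np.array_equal(a.regular_idx, b.regular_idx)
        assert len(a.regular_idx) == len(a.less_regular_idx) == 2
        assert not set(a.regular_idx) & set(a.less_regular_idx)

    def test_order_statistics_on_jittered_session(self, beta_session_pre):
        _, table = phase_from_force(beta_session_pre.get("force_left"),
                                    beta_session_pre.fs)
        split = split_regularity(table)
        assert (split.deviation_s[split.regular_idx].mean()
                < split.deviation_s[split.less_regular_idx].mean())

    def test_invariant_to_cycle_ordering(self, rng):
        durations = 2.0 + 0.2 * rng.standard_normal(16)
        perm = rng.permutation(16)
        a = split_regularity(_table(durations))
        b = split_regularity(_table(durations[perm]))
        assert set(perm[b.regular_idx]) == set(a.regular_idx)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            split_regularity(_table([2.0] * 8), fraction=0.8)


def test_wrap_phase_range():
    x = np.linspace(-10, 10, 1001)
    w = wrap_phase(x)
    assert np.all((w >= -np.pi) & (w < np.pi))
    np.testing.assert_allclose(np.cos(w), np.cos(x), atol=1e-12)
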