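import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from burstlab.evaluate import (burst_count_recovery, burst_summary,
                               hamming_distance_fraction, roc_sweep,
                               run_property_benchmark,
                               sensitivity_specificity,
                               spikes_in_bursts_fraction, summarize_benchmark,
                               tp_fp_spike_fractions)
from burstlab.simulate import sim_poisson_bursting, BurstingModelParams
from burstlab.types import Burst, BurstSet, LabeledTrain, SpikeTrain
from burstlab import detectors


def make_train(times, duration=None):
    times = np.asarray(times, dtype=float)
    if duration is None:
        duration = float(times[-1]) + 1.0
    return SpikeTrain(times=times, duration=duration)


def burst_from_indices(train, i, j):
    return Burst(i, j, float(train.times[i]), float(train.times[j]))


class TestSpikeFractions:
    def test_no_bursts_zero(self):
        train = make_train(np.arange(10.0))
        assert spikes_in_bursts_fraction(train, BurstSet()) == 0.0

    def test_full_coverage_one(self):
        train = make_train(np.arange(10.0))
        bs = BurstSet(bursts=[burst_from_indices(train, 0, 9)])
        assert spikes_in_bursts_fraction(train, bs) == 1.0

    def test_partial_coverage(self):
        train = make_train(np.arange(10.0))
        bs = BurstSet(bursts=[burst_from_indices(train, 0, 7)])
        assert spikes_in_bursts_fraction(train, bs) == pytest.approx(0.8)


class TestTpFp:
    def _labeled(self):
        # 10 burst spikes (dense) then 10 noise spikes (sparse)
        burst = np.arange(10) * 0.01
        noise = 10.0 + np.arange(10) * 2.0
        times = np.concatenate([burst, noise])
        train = SpikeTrain(times=times, duration=40.0)
        truth = BurstSet(bursts=[Burst(0, 9, 0.0, 0.09)])
        membership = np.concatenate([np.ones(10, bool), np.zeros(10, bool)])
        return LabeledTrain(train=train, truth=truth, membership=membership)

    def test_perfect_detection(self):
        lt = self._labeled()
        r = tp_fp_spike_fractions(lt.truth, lt)
        assert (r.tp_fraction, r.fp_fraction) == (1.0, 0.0)

    def test_empty_detection(self):
        lt = self._labeled()
        r = tp_fp_spike_fractions(BurstSet(), lt)
        assert (r.tp_fraction, r.fp_fraction) == (0.0, 0.0)

    def test_partial_detection_counts(self):
        lt = self._labeled()
        detected = BurstSet(bursts=[
            Burst(0, 4, 0.0, 0.04),          # 5 of 10 burst spikes
            Burst(10, 11, 10.0, 12.0),        # 2 of 10 noise spikes
        ])
        r = tp_fp_spike_fractions(detected, lt)
        assert r.tp_fraction == pytest.approx(0.5)
        assert r.fp_fraction == pytest.approx(0.2)

    def test_undefined_denominator_is_nan(self):
        lt = sim_poisson_bursting(BurstingModelParams(0.2, 5.0, 0.3, 300.0), 0)
        r = tp_fp_spike_fractions(lt.truth, lt)  # no noise spikes at all
        assert math.isnan(r.fp_fraction)


class TestSensitivitySpecificity:
    def test_agreement_and_saturation(self):
        train = make_train(np.arange(12.0), duration=12.0)
        ann = BurstSet(bursts=[Burst(2, 5, 2.0, 5.0)])
        r = sensitivity_specificity(ann, ann, train)
        assert (r.sensitivity, r.false_positive_rate) == (1.0, 0.0)
        everything = BurstSet(bursts=[Burst(0, 11, 0.0, 11.0)])
        r = sensitivity_specificity(everything, ann, train)
        assert (r.sensitivity, r.false_positive_rate) == (1.0, 1.0)

    def test_half_overlap_hand_count(self):
        # 12 spikes at integers; annotation covers spikes 2..5,
        # detection covers 4..7: 2 of 4 annotated detected;
        # 2 of 8 outside spikes flagged
        train = make_train(np.arange(12.0), duration=12.0)
        ann = BurstSet(bursts=[Burst(2, 5, 2.0, 5.0)])
        det = BurstSet(bursts=[Burst(4, 7, 4.0, 7.0)])
        r = sensitivity_specificity(det, ann, train)
        assert r.sensitivity == pytest.approx(2 / 4)
        assert r.false_positive_rate == pytest.approx(2 / 8)


class TestHamming:
    def test_basic_values(self):
        a = np.zeros(6000, dtype=int)
        b = a.copy()
        assert hamming_distance_fraction(a, b) == 0.0
        assert hamming_distance_fraction(a, 1 - a) == 1.0
        c = a.copy()
        c[:300] = 1
        assert hamming_distance_fraction(a, c) == pytest.approx(0.05)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hamming_distance_fraction(np.zeros(5), np.zeros(6))

    @given(st.integers(1, 200), st.integers(0, 2**30))
    @settings(deadline=None, max_examples=40)
    def test_metric_axioms(self, n, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (rng.integers(0, 2, n) for _ in range(3))
        dab = hamming_distance_fraction(a, b)
        assert dab == hamming_distance_fraction(b, a)          # symmetry
        assert hamming_distance_fraction(a, a) == 0.0          # identity
        assert (dab == 0.0) == bool(np.array_equal(a, b))
        dac = hamming_distance_fraction(a, c)
        dcb = hamming_distance_fraction(c, b)
        assert dab <= dac + dcb + 1e-12                        # triangle


class TestBurstSummary:
    def test_periodic_bursts_cv_zero(self):
        train = make_train(np.arange(0, 40, 0.5), duration=40.0)
        bursts = [Burst(8 * k, 8 * k + 2, 4.0 * k, 4.0 * k + 1.0)
                  for k in range(10)]
        s = burst_summary(train, BurstSet(bursts=bursts))
        assert s.cv_of_ibi == pytest.approx(0.0)
        assert s.mean_burst_duration == pytest.approx(1.0)

    def test_few_bursts_undefined_cv(self):
        train = make_train(np.arange(10.0))
        bs = BurstSet(bursts=[Burst(0, 2, 0.0, 2.0), Burst(5, 7, 5.0, 7.0)])
        assert math.isnan(burst_summary(train, bs).cv_of_ibi)

    def test_mean_duration(self):
        train = make_train(np.arange(0, 40, 0.5), duration=40.0)
        durations = [0.1, 0.2, 0.3, 0.4]
        bursts = [Burst(10 * k, 10 * k + 1, 5.0 * k, 5.0 * k + d)
                  for k, d in enumerate(durations)]
        s = burst_summary(train, BurstSet(bursts=bursts))
        assert s.mean_burst_duration == pytest.approx(0.25)
        assert s.burst_count == 4


class TestBurstCountRecovery:
    def test_intersection_matching(self):
        truth = BurstSet(bursts=[Burst(0, 2, 0.0, 1.0), Burst(5, 7, 5.0, 6.0)])
        det = BurstSet(bursts=[Burst(1, 3, 0.5, 1.5)])
        assert burst_count_recovery(det, truth) == pytest.approx(0.5)


class TestRocSweep:
    def _annotated_setup(self):
        lt = sim_poisson_bursting(BurstingModelParams(0.2, 5.0, 0.3, 300.0), 5)
        return [lt.train], {lt.train.id: lt.truth}

    def test_cma_has_single_point(self):
        trains, ann = self._annotated_setup()
        out = roc_sweep("cma", ann, trains)
        assert len(out) == 1

    def test_self_annotation_reaches_perfect_corner(self):
        trains, ann = self._annotated_setup()
        det = detectors.detect_all(trains, "mi")
        ann_self = {trains[0].id: det[0]}
        out = roc_sweep("mi", ann_self, trains,
                        grid=[("max_begin_isi", 0.17)])
        # sweeping over the same operating point that produced the
        # annotation must classify perfectly (grid point reproduces the
        # default begin/end ISI pair exactly)
        row = out.iloc[0]
        assert row.distance_to_perfect == pytest.approx(0.0, abs=1e-12)

    def test_per_train_mean_equals_average(self):
        lt1 = sim_poisson_bursting(BurstingModelParams(0.2, 5.0, 0.3, 300.0), 6)
        lt2 = sim_poisson_bursting(BurstingModelParams(0.2, 5.0, 0.3, 300.0), 7)
        trains = [lt1.train, lt2.train]
        ann = {lt1.train.id: lt1.truth, lt2.train.id: lt2.truth}
        out = roc_sweep("mi", ann, trains, grid=[("max_begin_isi", 0.17)])
        per_train = [
            sensitivity_specificity(bs, ann[tr.id], tr).sensitivity
            for tr, bs in zip(trains, detectors.detect_all(trains, "mi"))
        ]
        assert out.iloc[0].sensitivity == pytest.approx(np.mean(per_train))


class TestPropertyBenchmark:
    def test_unknown_property_rejected(self):
        with pytest.raises(ValueError):
            run_property_benchmark("D1", ["mi"], n_trains=1)

    def test_deterministic_under_seed(self):
        a = run_property_benchmark("D7", ["mi", "cma"], n_trains=3, seed=9)
        b = run_property_benchmark("D7", ["mi", "cma"], n_trains=3, seed=9)
        assert a.equals(b)

    def test_nonbursting_ground_truth_empty(self):
        t = run_property_benchmark("D5", ["mi"], n_trains=4, seed=2)
        # nonbursting trains have no truth rows, only detected fractions
        assert set(t.metric) == {"fraction_spikes_in_bursts"}

    def test_summary_shape(self):
        t = run_property_benchmark("D7", ["mi"], n_trains=5, seed=3)
        s = summarize_benchmark(t)
        assert {"median", "iqr", "n"} <= set(s.columns)
        row = s[(s.method == "mi") & (s.metric == "tp_fraction")]
        assert float(row["median"].iloc[0]) > 0.9
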