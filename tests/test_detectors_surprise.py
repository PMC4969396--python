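"""Tests for the surprise-based detectors (PS, RS, RGS)."""
import itertools
import math

import numpy as np
import pytest
from scipy import stats

from burstlab.detectors import (detect_poisson_surprise, detect_rank_surprise,
                                detect_rgs, poisson_surprise,
                                rank_surprise_pvalue, rgs_central_distribution)
from burstlab.params import SURPRISE_MIN, RgsParams
from burstlab.types import SpikeTrain


def make_train(times, duration=None):
    times = np.asarray(times, dtype=float)
    if duration is None:
        duration = float(times[-1]) + 1.0
    return SpikeTrain(times=times, duration=duration)


class TestPoissonSurprise:
    def test_zero_count_is_certain(self):
        assert poisson_surprise(0, 1.0, 1.0) == 0.0

    def test_closed_form_small_case(self):
        # P(N >= 5) for Poisson(1) = 1 - e^-1 * sum_{k<5} 1/k!
        p = 1 - math.exp(-1) * sum(1 / math.factorial(k) for k in range(5))
        assert poisson_surprise(5, 1.0, 1.0) == pytest.approx(-math.log(p), rel=1e-12)

    def test_monotone_in_count(self):
        s = [poisson_surprise(n, 2.0, 1.5) for n in range(1, 30)]
        assert all(b >= a for a, b in zip(s, s[1:]))

    def test_matches_scipy_log_tail(self):
        for n, mu in [(3, 1.0), (10, 2.5), (50, 5.0), (200, 20.0), (5, 30.0)]:
            expected = -stats.poisson.logsf(n - 1, mu)
            got = poisson_surprise(n, 1.0, mu)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_no_underflow_for_extreme_surprise(self):
        s = poisson_surprise(500, 1.0, 0.5)
        assert 600 < s < 3000 and math.isfinite(s)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            poisson_surprise(3, 1.0, 0.0)
        with pytest.raises(ValueError):
            poisson_surprise(-1, 1.0, 1.0)


class TestDetectPoissonSurprise:
    def test_periodic_train_has_no_bursts(self):
        train = make_train(np.arange(0, 300, 1.0), duration=300.0)
        assert len(detect_poisson_surprise(train)) == 0

    def test_planted_cluster_detected(self, sparse_train_with_cluster):
        train, cluster = sparse_train_with_cluster
        bs = detect_poisson_surprise(train)
        assert len(bs) >= 1
        best = max(bs, key=lambda b: b.surprise)
        assert best.surprise >= SURPRISE_MIN
        # the dense cluster is inside the detected burst
        assert best.begin_time <= cluster[0] and best.end_time >= cluster[-1]

    def test_all_surprises_clear_threshold(self, d11_trains):
        bs = detect_poisson_surprise(d11_trains[0].train)
        assert len(bs) > 0
        assert all(b.surprise >= SURPRISE_MIN for b in bs)


class TestRankSurprisePvalue:
    def test_single_draw(self):
        assert rank_surprise_pvalue(1, 1, 10) == pytest.approx(0.1)

    def test_two_draws_enumerated(self):
        # outcomes (1,1), (1,2), (2,1) of 100 equally likely pairs
        assert rank_surprise_pvalue(3, 2, 10) == pytest.approx(0.03)

    @pytest.mark.parametrize("q,n", [(1, 5), (2, 7), (3, 12), (3, 5)])
    def test_matches_exhaustive_enumeration(self, q, n):
        for s in range(q, q * n + 1, max(1, (q * n - q) // 7)):
            exact = sum(1 for combo in itertools.product(range(1, n + 1), repeat=q)
                        if sum(combo) <= s) / n**q
            assert rank_surprise_pvalue(s, q, n) == pytest.approx(exact, abs=1e-12)

    def test_gaussian_branch_close_to_exact(self):
        q, n = 30, 100
        for s in [int(q * (n + 1) / 2), int(q * (n + 1) / 2) - 300]:
            exact = rank_surprise_pvalue(s, q, n, exact_limit=60)
            approx = rank_surprise_pvalue(s, q, n, exact_limit=10)
            assert approx == pytest.approx(exact, abs=5e-3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rank_surprise_pvalue(0, 1, 10)
        with pytest.raises(ValueError):
            rank_surprise_pvalue(21, 2, 10)


class TestDetectRankSurprise:
    def test_uniform_isis_give_no_bursts(self):
        train = make_train(np.arange(0, 50, 0.5), duration=50.0)
        assert len(detect_rank_surprise(train)) == 0

    def test_planted_low_isi_run_detected(self):
        rng = np.random.default_rng(3)
        sparse = np.sort(rng.uniform(0, 100, 40))
        run = 50.0 + np.arange(8) * 0.005
        times = np.unique(np.concatenate([sparse, run]))
        train = SpikeTrain(times=times, duration=100.0)
        bs = detect_rank_surprise(train)
        assert len(bs) >= 1
        best = max(bs, key=lambda b: b.surprise)
        assert best.surprise >= SURPRISE_MIN
        assert best.begin_time <= run[0] and best.end_time >= run[-1]

    def test_bursts_only_contain_small_isis(self, d7_trains):
        train = d7_trains[0].train
        limit = np.percentile(np.diff(train.times), 75)
        for b in detect_rank_surprise(train):
            inner = np.diff(train.times[b.first_index : b.last_index + 1])
            assert np.all(inner <= limit)


class TestRgs:
    def test_central_distribution_recovers_gaussian(self):
        rng = np.random.default_rng(0)
        x = rng.normal(-1.5, 0.6, 20000)
        center, spread = rgs_central_distribution(x)
        assert center == pytest.approx(-1.5, abs=0.02)
        assert spread == pytest.approx(0.6, abs=0.02)

    def test_constant_input_degenerate(self):
        center, spread = rgs_central_distribution(np.full(100, 2.0))
        assert spread == 0.0

    def test_contamination_robustness(self):
        rng = np.random.default_rng(1)
        clean = rng.normal(0.0, 1.0, 9000)
        x = np.concatenate([clean, np.full(1000, -8.0)])  # 10% low outliers
        center, _ = rgs_central_distribution(x)
        # the median moves at most to the clean 5/9 quantile (~0.14 sigma);
        # the mean would move a full 0.8 sigma
        assert abs(center - np.median(clean)) < 0.2
        assert abs(center - np.median(clean)) < abs(np.mean(x) - np.mean(clean))

    def test_pooling_invariance_under_duplication(self):
        rng = np.random.default_rng(2)
        times = np.cumsum(rng.lognormal(0.0, 1.0, 300))
        tr = SpikeTrain(times=times, duration=float(times[-1]) + 1)
        single = detect_rgs([tr])
        double = detect_rgs([tr, tr])
        assert len(double) == 2
        for bs in double:
            assert [(b.first_index, b.last_index) for b in bs] == [
                (b.first_index, b.last_index) for b in single[0]]

    def test_gaussian_log_isis_give_few_bursts(self):
        rng = np.random.default_rng(3)
        isis = np.exp(rng.normal(0.0, 0.3, 500))
        times = np.cumsum(isis)
        tr = SpikeTrain(times=times, duration=float(times[-1]) + 1)
        bs = detect_rgs([tr])[0]
        # at a 2.58-sigma tail essentially no seed runs clear the
        # surprise threshold on a homogeneous lognormal train
        assert len(bs) <= 2

    def test_planted_deep_cluster_detected(self):
        rng = np.random.default_rng(4)
        isis = list(np.exp(rng.normal(0.0, 0.3, 200)))
        # insert a run of ISIs ~ exp(-5 * 0.3 * 2.58) below centre
        deep = [math.exp(-5 * 0.3 * 2.58)] * 6
        isis[100:100] = deep
        times = np.cumsum(isis)
        tr = SpikeTrain(times=times, duration=float(times[-1]) + 1)
        bs = detect_rgs([tr], RgsParams())[0]
        assert len(bs) >= 1
        assert max(b.surprise for b in bs) >= SURPRISE_MIN

    def test_empty_inputs(self):
        with pytest.raises(ValueError):
            detect_rgs([])
        tr = SpikeTrain(times=np.array([1.0]), duration=2.0)
        assert len(detect_rgs([tr])[0]) == 0
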