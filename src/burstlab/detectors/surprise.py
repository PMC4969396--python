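"""Poisson surprise (PS) burst detector.

The baseline is a homogeneous Poisson process whose rate equals the mean
firing rate of the whole train.  For an interval of length ``T`` holding
``N`` spikes the surprise statistic is ``S = -log p`` with ``p`` the upper
tail of a Poisson(rate*T) count at ``N``.  Bursts are grown from dense seed
runs by a surprise-maximization search and kept when their final surprise
clears the significance threshold (``-log(0.01)`` by default).
"""
from __future__ import annotations

import math

import numpy as np
from scipy.special import logsumexp

from ..params import PoissonSurpriseParams
from ..types import BurstSet, SpikeTrain, bursts_from_runs

__all__ = ["poisson_surprise", "detect_poisson_surprise"]


def _log_poisson_tail(n: int, mu: float) -> float:
    """log P(X >= n) for X ~ Poisson(mu), by log-space term summation.

    Summing log-domain terms keeps the result finite for surprise values
    far beyond where the linear-domain tail would underflow (S up to
    several hundred).
    """
    if n <= 0:
        return 0.0
    log_mu = math.log(mu)
    log_term = n * log_mu - mu - math.lgamma(n + 1)
    terms = [log_term]
    peak = log_term
    k = n
    # Poisson pmf decays geometrically once k > mu; stop when the current
    # term is negligible relative to the running peak
    while True:
        k += 1
        log_term += log_mu - math.log(k)
        terms.append(log_term)
        peak = max(peak, log_term)
        if k > mu + 1 and log_term < peak - 40.0:
            break
        if k > n + 10_000_000:  # unreachable safety valve
            break
    return min(float(logsumexp(terms)), 0.0)


def poisson_surprise(count: int, interval: float, rate: float) -> float:
    """Surprise ``S = -log P(N >= count)`` for a Poisson(rate*interval) count.

    Parameters are the spike count ``N`` in the interval, the interval
    length ``T`` in seconds, and the baseline rate in Hz.
    """
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    if interval <= 0:
        raise ValueError(f"interval must be positive, got {interval}")
    if count < 0:
        raise ValueError(f"count must be nonnegative, got {count}")
    return -_log_poisson_tail(count, rate * interval)


def detect_poisson_surprise(train: SpikeTrain,
                            params: PoissonSurpriseParams | None = None) -> BurstSet:
    """Detect bursts by Poisson surprise maximization.

    Seeds are runs of at least two consecutive ISIs shorter than half the
    mean ISI.  Each seed is extended forward up to ``params.lookahead``
    spikes at a time while the surprise grows, leading spikes are trimmed
    while that helps, and a final single-step polish guarantees no
    one-spike extension or trim at either end can improve the surprise.
    """
    if params is None:
        params = PoissonSurpriseParams()
    name = "ps"
    t = train.times
    n = t.size
    if n < 3 or train.duration <= 0:
        return bursts_from_runs(train, [], name, vars(params))
    rate = n / train.duration
    if rate <= 0:
        return bursts_from_runs(train, [], name, vars(params))
    mean_isi = 1.0 / rate
    isis = np.diff(t)

    def surprise(i: int, j: int) -> float:
        T = t[j] - t[i]
        if T <= 0:
            return 0.0
        return poisson_surprise(j - i + 1, T, rate)

    # seed runs: >= 2 consecutive ISIs < mean_isi / 2 (>= 3 spikes)
    dense = isis < mean_isi / 2
    seeds: list[tuple[int, int]] = []
    k = 0
    while k < dense.size:
        if dense[k]:
            m = k
            while m + 1 < dense.size and dense[m + 1]:
                m += 1
            if m > k:  # at least two dense ISIs
                seeds.append((k, m + 1))
            k = m + 1
        else:
            k += 1

    accepted: list[tuple[int, int]] = []
    surprises: list[float] = []
    floor_idx = 0  # first spike index available (no overlap with previous burst)
    for i0, j0 in seeds:
        if i0 < floor_idx:
            i0 = floor_idx
            if j0 - i0 + 1 < 3:
                continue
        i, j = i0, j0
        s = surprise(i, j)
        # forward extension, up to `lookahead` spikes per step
        improved = True
        while improved:
            improved = False
            best_m, best_s = 0, s
            for m in range(1, params.lookahead + 1):
                if j + m > n - 1:
                    break
                cand = surprise(i, j + m)
                if cand > best_s:
                    best_m, best_s = m, cand
            if best_m:
                j += best_m
                s = best_s
                improved = True
        # trim leading spikes
        while j - i + 1 > 3:
            cand = surprise(i + 1, j)
            if cand > s:
                i += 1
                s = cand
            else:
                break
        # single-step polish at both ends (local maximality post-condition)
        while True:
            moves = []
            if i - 1 >= floor_idx:
                moves.append((i - 1, j))
            if j + 1 <= n - 1:
                moves.append((i, j + 1))
            if j - i + 1 > 3:
                moves.append((i + 1, j))
                moves.append((i, j - 1))
            best = max(((surprise(a, b), a, b) for a, b in moves), default=None)
            if best is None or best[0] <= s:
                break
            s, i, j = best
        if s >= params.min_surprise and j - i + 1 >= 3:
            accepted.append((i, j))
            surprises.append(s)
            floor_idx = j + 1
    return bursts_from_runs(train, accepted, name, vars(params), surprises)
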