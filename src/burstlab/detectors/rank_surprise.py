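"""Rank surprise (RS) burst detector.

ISIs are ranked over the whole train (smallest = rank 1, ties by
mid-ranks).  For a candidate window of ``q`` consecutive ISIs the rank sum
is compared with the distribution of a sum of ``q`` i.i.d. uniform draws on
``{1..N}`` (``N`` = total number of ISIs): the lower-tail probability gives
the rank surprise ``RS = -log p``.  Candidate windows are restricted to
ISIs at or below the 75th percentile; accepted bursts maximize RS greedily
without overlap.
"""
from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.stats import norm, rankdata

from ..params import RankSurpriseParams
from ..types import BurstSet, SpikeTrain, bursts_from_runs

__all__ = ["rank_surprise_pvalue", "detect_rank_surprise"]


@lru_cache(maxsize=256)
def _uniform_sum_cdf(q: int, n: int) -> np.ndarray:
    """CDF of a sum of q i.i.d. uniforms on {1..n}; index = sum value.

    Built by iterated convolution with the uniform pmf (a length-n sliding
    window, evaluated via cumulative sums).
    """
    pmf = np.zeros(q * n + 1)
    pmf[1 : n + 1] = 1.0 / n
    for _ in range(q - 1):
        c = np.concatenate([[0.0], np.cumsum(pmf)])
        # new_pmf[s] = sum_{u=1..n} pmf[s-u] / n
        new = np.zeros_like(pmf)
        hi = np.minimum(np.arange(pmf.size), pmf.size)
        lo = np.maximum(np.arange(pmf.size) - n, 0)
        new = (c[hi] - c[lo]) / n
        pmf = new
    return np.cumsum(pmf)


def rank_surprise_pvalue(rank_sum: float, q: int, n_isis: int,
                         exact_limit: int = 60) -> float:
    """P(U1 + ... + Uq <= rank_sum) for i.i.d. uniforms on {1..n_isis}.

    Exact by convolution for ``q <= exact_limit``; a continuity-corrected
    Gaussian approximation is used for larger windows.  Mid-rank (half
    integer) sums are floored for the exact computation.
    """
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    if n_isis < 1:
        raise ValueError(f"n_isis must be >= 1, got {n_isis}")
    if rank_sum < q - 1e-9 or rank_sum > q * n_isis + 1e-9:
        raise ValueError(
            f"rank_sum {rank_sum} outside [{q}, {q * n_isis}] for q={q}, N={n_isis}"
        )
    if q <= exact_limit:
        cdf = _uniform_sum_cdf(q, n_isis)
        s = min(int(math.floor(rank_sum + 1e-9)), q * n_isis)
        return float(cdf[s])
    mean = q * (n_isis + 1) / 2.0
    var = q * (n_isis**2 - 1) / 12.0
    return float(norm.cdf((rank_sum + 0.5 - mean) / math.sqrt(var)))


def _log_rank_surprise(rank_sum: float, q: int, n_isis: int,
                       exact_limit: int) -> float:
    """RS = -log p, in log space for the Gaussian branch."""
    if q <= exact_limit:
        p = rank_surprise_pvalue(rank_sum, q, n_isis, exact_limit)
        return float("inf") if p == 0.0 else -math.log(p)
    mean = q * (n_isis + 1) / 2.0
    var = q * (n_isis**2 - 1) / 12.0
    return -float(norm.logcdf((rank_sum + 0.5 - mean) / math.sqrt(var)))


def detect_rank_surprise(train: SpikeTrain,
                         params: RankSurpriseParams | None = None) -> BurstSet:
    """Detect bursts by exhaustive rank-surprise maximization.

    All windows of >= 2 consecutive ISIs at or below the percentile limit
    are scored; windows are then accepted greedily by descending RS (ties
    to the earlier start) with overlap exclusion.
    """
    if params is None:
        params = RankSurpriseParams()
    name = "rs"
    t = train.times
    n = t.size
    if n < 3:
        return bursts_from_runs(train, [], name, vars(params))
    isis = np.diff(t)
    n_isis = isis.size
    ranks = rankdata(isis)  # mid-ranks for ties
    limit = float(np.percentile(isis, params.isi_limit_percentile))
    ok = isis <= limit

    # maximal runs of admissible ISIs, >= 2 ISIs (>= 3 spikes)
    candidates: list[tuple[float, int, int]] = []  # (RS, u, v) over ISI indices
    rank_prefix = np.concatenate([[0.0], np.cumsum(ranks)])
    i = 0
    while i < n_isis:
        if ok[i]:
            j = i
            while j + 1 < n_isis and ok[j + 1]:
                j += 1
            for u in range(i, j):
                for v in range(u + 1, j + 1):
                    q = v - u + 1
                    rs = _log_rank_surprise(
                        rank_prefix[v + 1] - rank_prefix[u], q, n_isis,
                        params.exact_limit)
                    if rs >= params.min_surprise:
                        candidates.append((rs, u, v))
            i = j + 1
        else:
            i += 1

    candidates.sort(key=lambda c: (-c[0], c[1]))
    taken = np.zeros(n_isis, dtype=bool)
    accepted: list[tuple[int, int]] = []
    surprises: list[float] = []
    for rs, u, v in candidates:
        # a 1-ISI halo keeps accepted bursts from sharing a boundary spike
        if taken[max(u - 1, 0) : min(v + 2, n_isis)].any():
            continue
        taken[u : v + 1] = True
        accepted.append((u, v + 1))  # spikes u .. v+1
        surprises.append(rs)
    order = np.argsort([a[0] for a in accepted])
    accepted = [accepted[k] for k in order]
    surprises = [surprises[k] for k in order]
    return bursts_from_runs(train, accepted, name, vars(params), surprises)
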