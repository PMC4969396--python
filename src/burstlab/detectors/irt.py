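"""ISI rank threshold (IRT) burst detector.

A heuristic sliding-window method.  Each ISI is assigned a normalized rank
``R`` in (0, 1] (smallest ISI first).  A spike-count cutoff ``theta_C`` is
the smallest count whose upper-tail frequency over disjoint 1-s windows is
at most ``count_tail_p``.  A burst begins at a spike whose forward 1-s
spike count exceeds ``theta_C`` and whose following ISI has rank below
``theta_R``; it runs until the forward count falls below ``theta_C / 2``.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from ..params import IrtParams
from ..types import BurstSet, SpikeTrain, bursts_from_runs

__all__ = ["spike_count_cutoff", "detect_irt"]


def spike_count_cutoff(train: SpikeTrain, tail_p: float = 0.05,
                       window: float = 1.0) -> int:
    """Smallest integer C with empirical P(window count >= C) <= tail_p.

    Counts are taken over disjoint windows of ``window`` seconds; a
    truncated final window contributes its raw count.
    """
    if not 0 < tail_p < 1:
        raise ValueError(f"tail_p must be in (0, 1), got {tail_p}")
    edges = np.arange(0.0, train.duration + window, window)
    counts = np.histogram(train.times, bins=edges)[0]
    if counts.size == 0:
        return 1
    counts = np.sort(counts)[::-1]
    for c in range(int(counts[0]) + 1, -1, -1):
        if np.mean(counts >= c) <= tail_p:
            cutoff = c
        else:
            break
    return cutoff


def detect_irt(train: SpikeTrain, params: IrtParams | None = None) -> BurstSet:
    """Detect bursts with the rank-threshold onset/offset rules."""
    if params is None:
        params = IrtParams()
    name = "irt"
    t = train.times
    n = t.size
    if n < 3:
        return bursts_from_runs(train, [], name, vars(params))
    theta_c = spike_count_cutoff(train, params.count_tail_p, params.window)
    isis = np.diff(t)
    # normalized ISI rank in (0, 1]; R[i] belongs to the ISI after spike i
    r = rankdata(isis) / isis.size
    # forward counts: spikes in (t_i, t_i + window]
    fwd = np.searchsorted(t, t + params.window, side="right") - np.arange(n) - 1

    accepted: list[tuple[int, int]] = []
    i = 0
    while i < n - 1:
        if fwd[i] > theta_c and r[i] < params.theta_r:
            j = i
            while j < n - 1 and fwd[j] >= theta_c / 2.0:
                j += 1
            # burst ends at the first spike whose forward count drops
            if j - i + 1 >= 3:
                accepted.append((i, j))
            i = j + 1
        else:
            i += 1
    return bursts_from_runs(train, accepted, name, vars(params))
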