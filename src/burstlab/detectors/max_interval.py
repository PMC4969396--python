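"""MaxInterval burst detector.

A fixed-threshold method: a burst is seeded wherever consecutive spikes are
closer than a maximum *beginning* ISI, extended while ISIs stay below a
(laxer) maximum *end* ISI, adjacent bursts closer than a minimum interburst
interval are merged, and bursts failing a minimum duration or minimum spike
count are discarded.  Because all five thresholds are absolute, the same
parameters apply to every electrode of a recording.
"""
from __future__ import annotations

import numpy as np

from ..params import MaxIntervalParams
from ..types import BurstSet, SpikeTrain, bursts_from_runs

__all__ = ["detect_max_interval"]


def detect_max_interval(train: SpikeTrain,
                        params: MaxIntervalParams | None = None) -> BurstSet:
    """Detect bursts with the five-threshold MaxInterval rules."""
    if params is None:
        params = MaxIntervalParams()
    name = "mi"
    t = train.times
    n = t.size
    if n < 2:
        return bursts_from_runs(train, [], name, vars(params))
    isis = np.diff(t)

    # seed + extend: a burst starts at an ISI <= max_begin_isi and runs
    # while ISIs stay <= max_end_isi
    runs: list[list[int]] = []
    i = 0
    while i < n - 1:
        if isis[i] <= params.max_begin_isi:
            j = i + 1
            while j < n - 1 and isis[j] <= params.max_end_isi:
                j += 1
            runs.append([i, j])  # spikes i..j inclusive
            i = j + 1
        else:
            i += 1

    # merge bursts separated by less than min_ibi, iterated to fixpoint
    merged: list[list[int]] = []
    for run in runs:
        if merged and t[run[0]] - t[merged[-1][1]] < params.min_ibi:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    kept = [
        (i, j)
        for i, j in merged
        if (j - i + 1) >= params.min_spikes and (t[j] - t[i]) >= params.min_duration
    ]
    return bursts_from_runs(train, kept, name, vars(params))
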