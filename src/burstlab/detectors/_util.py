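"""Shared helpers for ISI-threshold detectors."""
from __future__ import annotations

import numpy as np

__all__ = ["isi_runs_below"]


def isi_runs_below(isis: np.ndarray, cutoff: float, min_spikes: int = 3,
                   strict: bool = True) -> list[tuple[int, int]]:
    """Maximal runs of consecutive ISIs below ``cutoff``.

    Returns inclusive spike-index pairs ``(first, last)``; a run of *k*
    qualifying ISIs spans *k + 1* spikes.  Runs shorter than ``min_spikes``
    spikes are dropped.
    """
    if isis.size == 0:
        return []
    ok = isis < cutoff if strict else isis <= cutoff
    runs: list[tuple[int, int]] = []
    i = 0
    n = ok.size
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            if (j - i + 2) >= min_spikes:
                runs.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return runs
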