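"""logISI-histogram burst detector.

The histogram of log10(ISI) typically shows an intraburst peak (short
ISIs) separated from one or more interburst peaks.  The largest peak at or
below a 100-ms ISI is taken as the intraburst peak; for each histogram
minimum between it and a subsequent peak a *void parameter*

    v = 1 - h_min / sqrt(h_peak1 * h_peak2)

measures how well the peaks are separated.  The first minimum whose void
parameter exceeds 0.7 fixes the burst ISI cutoff ``maxISI``.  Bursts are
runs of at least three spikes with ISIs below the cutoff; when the chosen
cutoff exceeds the 100-ms cap, burst cores are found at the cap and then
their edges extended to absorb spikes within ``maxISI``.  Without an
intraburst peak no bursts are reported.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from ..params import LogIsiParams
from ..types import BurstSet, SpikeTrain, bursts_from_runs
from ._util import isi_runs_below

__all__ = ["void_parameter", "logisi_cutoff", "detect_logisi"]


def void_parameter(h_peak1: float, h_peak2: float, h_min: float) -> float:
    """Separation score of two histogram peaks flanking a minimum."""
    if h_peak1 <= 0 or h_peak2 <= 0:
        raise ValueError("peak heights must be positive")
    return 1.0 - h_min / float(np.sqrt(h_peak1 * h_peak2))


@dataclass(frozen=True)
class _CutoffResult:
    max_isi: float | None  # chosen cutoff, s; None when no void clears 0.7
    has_intraburst_peak: bool


def logisi_cutoff(isis: np.ndarray, params: LogIsiParams) -> _CutoffResult:
    """Locate the burst ISI cutoff from the smoothed log10-ISI histogram."""
    log_isis = np.log10(isis)
    lo = np.floor(log_isis.min() * params.bins_per_decade) / params.bins_per_decade
    hi = np.ceil(log_isis.max() * params.bins_per_decade) / params.bins_per_decade
    n_bins = max(int(round((hi - lo) * params.bins_per_decade)), 1)
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(log_isis, bins=edges)
    smooth = gaussian_filter1d(counts.astype(float), params.smooth_sigma_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0

    # zero-pad so maxima in the first/last bin count as peaks
    peaks, _props = find_peaks(np.concatenate([[0.0], smooth, [0.0]]))
    peaks = peaks - 1
    if peaks.size == 0:  # monotone histogram: use the global max as sole peak
        peaks = np.array([int(np.argmax(smooth))])
    peak_isis = 10.0 ** centers[peaks]
    candidates = peaks[peak_isis <= params.max_cutoff]
    if candidates.size == 0:
        return _CutoffResult(None, False)
    intra = int(candidates[np.argmax(smooth[candidates])])

    # minima between the intraburst peak and each subsequent peak, in ISI order
    for p2 in peaks[peaks > intra]:
        seg = smooth[intra : p2 + 1]
        m = intra + int(np.argmin(seg))
        v = void_parameter(smooth[intra], smooth[p2], smooth[m])
        if v >= params.void_threshold:
            return _CutoffResult(float(10.0 ** centers[m]), True)
    return _CutoffResult(None, True)


def _extend_runs(isis: np.ndarray, runs: list[tuple[int, int]],
                 max_isi: float) -> list[tuple[int, int]]:
    """Absorb spikes within ``max_isi`` of each burst edge; merge overlaps."""
    extended = []
    for i, j in runs:
        while i > 0 and isis[i - 1] < max_isi:
            i -= 1
        while j < isis.size and isis[j] < max_isi:
            j += 1
        extended.append([i, j])
    merged: list[list[int]] = []
    for run in extended:
        if merged and run[0] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], run[1])
        else:
            merged.append(run)
    return [(i, j) for i, j in merged]


def detect_logisi(train: SpikeTrain, params: LogIsiParams | None = None) -> BurstSet:
    """Detect bursts at the void-parameter-selected logISI cutoff."""
    if params is None:
        params = LogIsiParams()
    name = "logisi"
    t = train.times
    if t.size < 3:
        return bursts_from_runs(train, [], name, vars(params))
    isis = np.diff(t)
    res = logisi_cutoff(isis, params)
    if not res.has_intraburst_peak:
        return bursts_from_runs(train, [], name, vars(params))
    if res.max_isi is not None and res.max_isi <= params.max_cutoff:
        runs = isi_runs_below(isis, res.max_isi, params.min_spikes, strict=True)
        used = res.max_isi
    else:
        # fallback: cores at the cap, edge extension when a cutoff exists
        runs = isi_runs_below(isis, params.max_cutoff, params.min_spikes,
                              strict=True)
        if res.max_isi is not None:
            runs = _extend_runs(isis, runs, res.max_isi)
        used = params.max_cutoff
    return bursts_from_runs(train, runs, name, {**vars(params), "max_isi": used})
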