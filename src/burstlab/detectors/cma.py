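"""Cumulative moving average (CMA) burst detector.

The ISI histogram (1-ms bins by default) is turned into its cumulative
moving average curve; the skewness of that curve selects a coefficient
``alpha_1``, and the ISI of the bin where the CMA comes closest to
``alpha_1 * CMA_MAX`` becomes the burst cutoff ``maxISI``.  Bursts are runs
of more than two spikes whose ISIs fall below the cutoff.  Only burst
cores are reported: the original method's optional "burst-related spike"
extension (driven by ``alpha_2``) is deliberately not applied.
"""
from __future__ import annotations

import numpy as np

from ..params import CmaParams
from ..types import BurstSet, SpikeTrain, bursts_from_runs
from ._util import isi_runs_below

__all__ = ["alpha_from_skew", "cma_curve", "detect_cma"]


def alpha_from_skew(skew: float) -> tuple[float, float]:
    """Skewness-dependent (alpha_1, alpha_2) coefficients."""
    if skew < 1:
        return 1.0, 0.5
    if skew < 4:
        return 0.7, 0.5
    if skew < 9:
        return 0.5, 0.9
    return 0.3, 0.1


def cma_curve(isis: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """ISI-histogram CMA curve: (bin centers, CMA values).

    ``CMA[i]`` is the mean of the histogram counts of bins ``0..i``.
    """
    if isis.size == 0:
        raise ValueError("need at least one ISI")
    n_bins = max(int(np.ceil(isis.max() / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(isis, bins=edges)
    cma = np.cumsum(counts) / np.arange(1, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, cma


def _curve_skewness(cma: np.ndarray) -> float:
    """Sample skewness of the CMA values.

    The CMA curve rises to its peak over the short-ISI bins and decays
    roughly hyperbolically over the tail, so trains with a long ISI tail
    yield strongly right-skewed CMA value distributions and hence a
    smaller alpha_1 (a cutoff deeper into the tail).
    """
    if cma.size < 3:
        return 0.0
    sd = float(np.std(cma))
    if sd == 0:
        return 0.0
    return float(np.mean((cma - np.mean(cma)) ** 3) / sd**3)


def detect_cma(train: SpikeTrain, params: CmaParams | None = None) -> BurstSet:
    """Detect burst cores at the skewness-adapted CMA cutoff."""
    if params is None:
        params = CmaParams()
    name = "cma"
    t = train.times
    if t.size < 3:
        return bursts_from_runs(train, [], name, vars(params))
    isis = np.diff(t)
    centers, cma = cma_curve(isis, params.bin_width)
    alpha1, _alpha2 = alpha_from_skew(_curve_skewness(cma))
    peak = int(np.argmax(cma))
    cma_max = float(cma[peak])
    # the cutoff lies on the decaying flank beyond the CMA peak
    cutoff_bin = peak + int(np.argmin(np.abs(cma[peak:] - alpha1 * cma_max)))
    max_isi = float(centers[cutoff_bin])
    runs = isi_runs_below(isis, max_isi, params.min_spikes, strict=True)
    return bursts_from_runs(train, runs, name,
                            {**vars(params), "max_isi": max_isi, "alpha1": alpha1})
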