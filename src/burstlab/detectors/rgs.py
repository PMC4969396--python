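"""Robust Gaussian surprise (RGS) burst detector.

Bursts are treated as low outliers from a "central distribution" of
log-ISIs.  The center is the median of the pooled log-ISIs and the spread a
Gaussian-consistent scaled MAD (median absolute deviation times 1.4826).
ISIs whose normalized log value lies below ``-2.58`` spreads seed candidate
bursts; each seed is extended while the Gaussian burst surprise

    GS_B = -log P( sum of k N(0, sigma^2) variables <= observed sum )

keeps growing, and bursts below the surprise threshold are discarded.  When
several trains (channels of one recording) are supplied their ISIs are
pooled to build one shared central distribution.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm

from ..params import RgsParams
from ..types import BurstSet, SpikeTrain, bursts_from_runs

__all__ = ["rgs_central_distribution", "detect_rgs", "detect_rgs_single"]


def rgs_central_distribution(log_isis: np.ndarray,
                             gaussian_consistent: bool = True) -> tuple[float, float]:
    """Robust (center, spread) of the pooled log-ISI distribution.

    Center is the median; spread is the MAD, scaled by 1.4826 when
    ``gaussian_consistent`` so it estimates a Gaussian sigma.  A zero
    spread marks a degenerate (e.g. constant) input.
    """
    x = np.asarray(log_isis, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one ISI")
    center = float(np.median(x))
    mad = float(np.median(np.abs(x - center)))
    spread = mad * 1.4826 if gaussian_consistent else mad
    return center, spread


def _detect_one(train: SpikeTrain, center: float, spread: float,
                params: RgsParams) -> BurstSet:
    name = "rgs"
    t = train.times
    n = t.size
    if n < 3 or spread <= 0:
        return bursts_from_runs(train, [], name, vars(params))
    x = np.log(np.diff(t)) - center  # normalized log-ISIs
    thr = -params.mad_multiplier * spread

    def gs(i: int, j: int) -> float:
        """Surprise of ISI window i..j (spikes i..j+1), lower Gaussian tail."""
        k = j - i + 1
        z = x[i : j + 1].sum() / (spread * math.sqrt(k))
        return -float(norm.logcdf(z))

    below = x < thr
    accepted: list[tuple[int, int]] = []
    surprises: list[float] = []
    floor = 0  # first ISI index free of earlier bursts
    m = x.size
    k = 0
    while k < m:
        if below[k] and k >= floor:
            j = k
            while j + 1 < m and below[j + 1]:
                j += 1
            i0, j0 = k, j
            s = gs(i0, j0)
            # extend at both ends while the surprise grows
            while True:
                moves = []
                if i0 - 1 >= floor:
                    moves.append((i0 - 1, j0))
                if j0 + 1 < m:
                    moves.append((i0, j0 + 1))
                if j0 > i0:
                    moves.append((i0 + 1, j0))
                    moves.append((i0, j0 - 1))
                best = max(((gs(a, b), a, b) for a, b in moves), default=None)
                if best is None or best[0] <= s:
                    break
                s, i0, j0 = best
            if s >= params.min_surprise and (j0 - i0 + 2) >= 3:
                accepted.append((i0, j0 + 1))  # spikes i0 .. j0+1
                surprises.append(s)
                floor = j0 + 2  # 1-ISI halo: no shared boundary spike
            k = max(j, j0) + 1
        else:
            k += 1
    return bursts_from_runs(train, accepted, name, vars(params), surprises)


def detect_rgs(trains: list[SpikeTrain] | SpikeTrain,
               params: RgsParams | None = None) -> list[BurstSet]:
    """Detect bursts on one or more trains sharing a pooled central distribution."""
    if params is None:
        params = RgsParams()
    if isinstance(trains, SpikeTrain):
        trains = [trains]
    if not trains:
        raise ValueError("need at least one spike train")
    pooled = np.concatenate(
        [np.diff(tr.times) for tr in trains if tr.n_spikes >= 2] or [np.empty(0)]
    )
    if pooled.size == 0:
        return [bursts_from_runs(tr, [], "rgs", vars(params)) for tr in trains]
    center, spread = rgs_central_distribution(
        np.log(pooled), params.gaussian_consistent_mad)
    return [_detect_one(tr, center, spread, params) for tr in trains]


def detect_rgs_single(train: SpikeTrain, params: RgsParams | None = None) -> BurstSet:
    """Single-train convenience wrapper around :func:`detect_rgs`."""
    return detect_rgs([train], params)[0]
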