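"""Synthetic spike-train generators with ground-truth burst labels.

The generators implement the point-process models used for detector
benchmarking:

* homogeneous Poisson and gamma-renewal trains (nonbursting controls, with
  the smallest 10th percentile of ISIs removed to eliminate chance
  burst-like runs);
* an inhomogeneous Poisson train with linearly ramping rate (nonstationary
  nonbursting control);
* the Poisson bursting model — burst centers form a Poisson process of rate
  ``burst_rate``; each burst carries a Poisson-distributed number of spikes
  placed uniformly in a window of width ``spread`` centered on the burst
  center; overlapping bursts are resolved by keeping the earlier one;
* a nonstationary variant drawing per-burst size and spread from uniform
  ranges, retaining only bursts whose within-burst rate exceeds 5 Hz;
* a noisy variant superposing trimmed gamma-ISI noise spikes, excluding any
  noise spike within a 0.5-s margin of a burst.

Every generator is deterministic given a seed (or an explicit
``numpy.random.Generator``).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .types import Burst, BurstSet, LabeledTrain, SpikeTrain

__all__ = [
    "BurstingModelParams",
    "trim_smallest_isis",
    "sim_poisson_train",
    "sim_gamma_train",
    "sim_inhomogeneous_poisson",
    "sim_poisson_bursting",
    "sim_nonstationary_bursting",
    "sim_noisy_bursting",
    "simulate_property",
    "PROPERTY_IDS",
]

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence, None]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class BurstingModelParams:
    """Parameters of the Poisson bursting model.

    burst_rate:
        Rate (Hz) of the Poisson process of burst centers.
    mean_count:
        Mean of the Poisson distribution of spikes per burst.
    spread:
        Width (s) of the zero-mean uniform distribution of spike positions
        around the burst center.
    duration:
        Train length, seconds.
    """

    burst_rate: float
    mean_count: float
    spread: float
    duration: float = 300.0

    def __post_init__(self) -> None:
        if min(self.burst_rate, self.mean_count, self.spread, self.duration) <= 0:
            if self.burst_rate == 0:  # degenerate but valid: no bursts
                return
            raise ValueError("bursting model parameters must be positive")


def trim_smallest_isis(train: SpikeTrain, fraction: float) -> SpikeTrain:
    """Remove the smallest ``fraction`` of ISIs by deleting spikes.

    For each of the ``floor(fraction * (n - 1))`` smallest ISIs (of the
    original train) the later of its two bounding spikes is deleted.  Used
    to strip chance burst-like runs from simulated nonbursting trains.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    n = train.n_spikes
    if n <= 1 or fraction == 0:
        return train
    isis = np.diff(train.times)
    k = int(np.floor(fraction * (n - 1)))
    if k == 0:
        return train
    order = np.argsort(isis, kind="stable")[:k]
    keep = np.ones(n, dtype=bool)
    keep[order + 1] = False  # later bounding spike of each selected ISI
    return SpikeTrain(times=train.times[keep], duration=train.duration, id=train.id)


def sim_poisson_train(rate: float, duration: float, seed: SeedLike = None,
                      id: str = "") -> SpikeTrain:
    """Homogeneous Poisson spike train (exponential ISIs) on [0, duration]."""
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    rng = _rng(seed)
    times = []
    if rate > 0:
        t = 0.0
        # draw in blocks for speed; expected count = rate * duration
        block = max(16, int(rate * duration * 1.2) + 16)
        while True:
            gaps = rng.exponential(1.0 / rate, size=block)
            cum = t + np.cumsum(gaps)
            inside = cum[cum <= duration]
            times.append(inside)
            if inside.size < block:
                break
            t = cum[-1]
        times = np.concatenate(times) if times else np.empty(0)
    else:
        times = np.empty(0)
    return SpikeTrain(times=np.asarray(times, dtype=float), duration=duration, id=id)


def sim_gamma_train(shape: float, rate: float, duration: float,
                    seed: SeedLike = None, id: str = "") -> SpikeTrain:
    """Renewal train with i.i.d. Gamma(shape, rate) ISIs (mean shape/rate)."""
    if shape <= 0 or rate <= 0:
        raise ValueError("gamma shape and rate must be positive")
    rng = _rng(seed)
    mean_isi = shape / rate
    out = []
    t = 0.0
    block = max(16, int(duration / mean_isi * 1.2) + 16)
    while True:
        gaps = rng.gamma(shape, scale=1.0 / rate, size=block)
        cum = t + np.cumsum(gaps)
        inside = cum[cum <= duration]
        out.append(inside)
        if inside.size < block:
            break
        t = cum[-1]
    times = np.concatenate(out) if out else np.empty(0)
    return SpikeTrain(times=times, duration=duration, id=id)


def sim_inhomogeneous_poisson(base: float, slope: float, duration: float,
                              seed: SeedLike = None, id: str = "") -> SpikeTrain:
    """Inhomogeneous Poisson train with rate ``base + slope * t``, by thinning."""
    lam0, lam1 = base, base + slope * duration
    if min(lam0, lam1) < 0:
        raise ValueError("rate must be nonnegative over [0, duration]")
    lam_max = max(lam0, lam1)
    if lam_max == 0:
        return SpikeTrain(times=np.empty(0), duration=duration, id=id)
    rng = _rng(seed)
    candidate = sim_poisson_train(lam_max, duration, rng)
    t = candidate.times
    accept = rng.random(t.size) < (base + slope * t) / lam_max
    return SpikeTrain(times=t[accept], duration=duration, id=id)


def _draw_burst_size(rng: np.random.Generator, mean_count: float,
                     min_spikes: int) -> int:
    """Poisson burst size, resampled until >= min_spikes.

    Sizes below the global three-spike floor would be undetectable by
    construction and poison true-positive accounting, so they are redrawn.
    """
    for _ in range(10_000):
        k = int(rng.poisson(mean_count))
        if k >= min_spikes:
            return k
    raise RuntimeError("burst size resampling failed to reach the minimum")


def _draw_burst_spikes(rng: np.random.Generator, center: float, size: int,
                       spread: float) -> np.ndarray:
    """Uniform spike positions in [center - spread/2, center + spread/2]."""
    while True:
        pos = np.sort(center + rng.uniform(-spread / 2, spread / 2, size=size))
        if size < 2 or np.all(np.diff(pos) > 0):  # resample exact ties
            return pos


def _assemble_labeled(bursts: list[np.ndarray], noise: np.ndarray,
                      duration: float, id: str, method: str) -> LabeledTrain:
    """Merge burst-spike arrays and noise spikes into a LabeledTrain."""
    burst_times = np.concatenate(bursts) if bursts else np.empty(0)
    all_times = np.concatenate([burst_times, noise])
    order = np.argsort(all_times, kind="stable")
    times = all_times[order]
    membership = np.concatenate(
        [np.ones(burst_times.size, dtype=bool), np.zeros(noise.size, dtype=bool)]
    )[order]
    train = SpikeTrain(times=times, duration=duration, id=id)
    truth_bursts = []
    for spikes in bursts:
        i0 = int(np.searchsorted(times, spikes[0]))
        i1 = int(np.searchsorted(times, spikes[-1]))
        truth_bursts.append(Burst(i0, i1, float(spikes[0]), float(spikes[-1])))
    truth = BurstSet(bursts=truth_bursts, method=method)
    return LabeledTrain(train=train, truth=truth, membership=membership)


def _sim_burst_arrays(
    rng: np.random.Generator,
    duration: float,
    burst_rate: float,
    mean_count,
    spread,
    min_within_rate: float = 0.0,
    min_spikes: int = 3,
) -> list[tuple[float, np.ndarray]]:
    """Kept (center, spike-times) pairs of the Poisson bursting model.

    ``mean_count`` and ``spread`` may be scalars (stationary model) or
    ``(lo, hi)`` ranges sampled per burst (nonstationary model).  Bursts
    are processed in center order; a burst whose occupied interval
    [min spike, max spike] intersects an earlier kept burst's interval is
    dropped whole, as is any burst with spikes outside [0, duration].
    """
    if burst_rate <= 0:
        return []
    # Poisson process of burst centers
    n_centers = rng.poisson(burst_rate * duration)
    centers = np.sort(rng.uniform(0.0, duration, size=n_centers))
    kept: list[tuple[float, np.ndarray]] = []
    for c in centers:
        n_mean = (rng.uniform(*mean_count) if isinstance(mean_count, tuple)
                  else mean_count)
        r = rng.uniform(*spread) if isinstance(spread, tuple) else spread
        size = _draw_burst_size(rng, n_mean, min_spikes)
        spikes = _draw_burst_spikes(rng, c, size, r)
        if spikes[0] < 0 or spikes[-1] > duration:
            continue
        occupied = spikes[-1] - spikes[0]
        if min_within_rate > 0 and occupied > 0 and size / occupied <= min_within_rate:
            continue
        if any(spikes[0] <= k[-1] and spikes[-1] >= k[0] for _, k in kept):
            continue  # earlier burst wins; later overlapping burst dropped
        kept.append((c, spikes))
    kept.sort(key=lambda s: s[1][0])
    return kept


def sim_poisson_bursting(params: BurstingModelParams, seed: SeedLike = None,
                         id: str = "") -> LabeledTrain:
    """Stationary Poisson bursting train; every spike is a burst spike."""
    rng = _rng(seed)
    kept = _sim_burst_arrays(rng, params.duration, params.burst_rate,
                             params.mean_count, params.spread)
    return _assemble_labeled([sp for _, sp in kept], np.empty(0),
                             params.duration, id, "sim_poisson_bursting")


def sim_nonstationary_bursting(
    duration: float = 300.0,
    burst_rate: float = 0.3,
    count_range: tuple[float, float] = (5.0, 18.0),
    spread_range: tuple[float, float] = (0.3, 3.0),
    min_within_rate: float = 5.0,
    seed: SeedLike = None,
    id: str = "",
) -> LabeledTrain:
    """Bursting train with per-burst uniform size and spread draws.

    Only bursts whose within-burst firing rate (spike count over occupied
    duration) exceeds ``min_within_rate`` Hz are retained.
    """
    rng = _rng(seed)
    kept = _sim_burst_arrays(rng, duration, burst_rate, count_range,
                             spread_range, min_within_rate=min_within_rate)
    return _assemble_labeled([sp for _, sp in kept], np.empty(0), duration, id,
                             "sim_nonstationary_bursting")


def sim_noisy_bursting(
    params: Optional[BurstingModelParams] = None,
    noise_shape: float = 1.0,
    noise_rate: float = 0.5,
    noise_trim_fraction: float = 0.1,
    margin: float = 0.5,
    seed: SeedLike = None,
    id: str = "",
) -> LabeledTrain:
    """Poisson bursting train superposed with trimmed gamma-ISI noise.

    Noise spikes are drawn as an independent gamma-renewal train and the
    smallest ``noise_trim_fraction`` of noise ISIs are removed.  Any noise
    spike within ``margin`` seconds of a kept burst's *center* (a zone
    that, at the default spread of 0.8 s, covers the whole burst window
    plus a protective strip) or inside the burst span itself is deleted,
    so burst and noise spikes never overlap.
    """
    if params is None:
        params = BurstingModelParams(burst_rate=0.5, mean_count=8.0, spread=0.8)
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    rng = _rng(seed)
    kept = _sim_burst_arrays(rng, params.duration, params.burst_rate,
                             params.mean_count, params.spread)
    noise_train = sim_gamma_train(noise_shape, noise_rate, params.duration, rng)
    noise_train = trim_smallest_isis(noise_train, noise_trim_fraction)
    noise = noise_train.times
    if kept:
        keepmask = np.ones(noise.size, dtype=bool)
        for c, spikes in kept:
            keepmask &= np.abs(noise - c) > margin
            keepmask &= (noise < spikes[0]) | (noise > spikes[-1])
        noise = noise[keepmask]
    return _assemble_labeled([sp for _, sp in kept], noise, params.duration,
                             id, "sim_noisy_bursting")


# ---------------------------------------------------------------------------
# Benchmark model registry (properties D4-D11)
# ---------------------------------------------------------------------------

PROPERTY_IDS = ("D4", "D5", "D6", "D7", "D8", "D9", "D10", "D11")

#: nonbursting controls trim the smallest 10th percentile of ISIs
_TRIM = 0.1


def simulate_property(prop: str, index: int, seed: int,
                      duration: float = 300.0) -> LabeledTrain:
    """Simulate train ``index`` of benchmark property ``prop``.

    Seeding is hierarchical: (seed, property number, train index) define an
    independent substream, so any single train is reproducible in
    isolation.  Nonbursting properties return an empty ground-truth set;
    for D5 the first half of the trains are Poisson (0.5 Hz) and the second
    half gamma-renewal (shape 1, rate 0.5), mirroring the 50/50 design.
    """
    prop = prop.upper()
    if prop not in PROPERTY_IDS:
        raise ValueError(f"unknown property {prop!r}; choose from {PROPERTY_IDS}")
    pnum = int(prop[1:])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), pnum, int(index)]))
    tid = f"{prop}-{index}"

    def nonbursting(train: SpikeTrain) -> LabeledTrain:
        train = trim_smallest_isis(train, _TRIM)
        return LabeledTrain(train=train, truth=BurstSet(method=prop),
                            membership=np.zeros(train.n_spikes, dtype=bool))

    if prop == "D4":
        return nonbursting(sim_poisson_train(1.0, duration, rng, id=tid))
    if prop == "D5":
        if index % 2 == 0:
            return nonbursting(sim_poisson_train(0.5, duration, rng, id=tid))
        return nonbursting(sim_gamma_train(1.0, 0.5, duration, rng, id=tid))
    if prop == "D6":
        return nonbursting(
            sim_inhomogeneous_poisson(1.0, 1.0 / duration, duration, rng, id=tid))
    if prop == "D7":
        p = BurstingModelParams(0.2, 5.0, 0.3, duration)
        return sim_poisson_bursting(p, rng, id=tid)
    if prop == "D8":
        return sim_nonstationary_bursting(duration, seed=rng, id=tid)
    if prop == "D9":
        p = BurstingModelParams(0.1, 18.0, 3.0, duration)
        return sim_poisson_bursting(p, rng, id=tid)
    if prop == "D10":
        p = BurstingModelParams(1.0, 10.0, 0.5, duration)
        return sim_poisson_bursting(p, rng, id=tid)
    # D11
    p = BurstingModelParams(0.5, 8.0, 0.8, duration)
    return sim_noisy_bursting(p, seed=rng, id=tid)
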