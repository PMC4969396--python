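"""Core domain types: spike trains, bursts, and labeled (ground-truth) trains.

All times are in seconds throughout the package.  Spike indices are 0-based
and burst index ranges are inclusive at both ends; burst time intervals are
closed ``[begin_time, end_time]``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "SpikeTrain",
    "Burst",
    "BurstSet",
    "LabeledTrain",
    "compute_isis",
    "burst_mask",
    "spike_membership",
    "bursts_from_runs",
]


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered sequence of spike times on a single electrode/unit.

    Parameters
    ----------
    times:
        Strictly increasing spike times, in seconds, all within
        ``[0, duration]``.
    duration:
        Length of the recording in seconds (> 0).
    id:
        Opaque label (electrode, well, age tag, ...).
    """

    times: np.ndarray
    duration: float
    id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if t[0] < 0 or t[-1] > self.duration:
                raise ValueError(
                    "spike times must lie within [0, duration]; got range "
                    f"[{t[0]}, {t[-1]}] with duration {self.duration}"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def firing_rate(self) -> float:
        """Mean firing rate over the whole recording, in Hz."""
        return self.n_spikes / self.duration

    def __len__(self) -> int:
        return self.n_spikes


def compute_isis(train: SpikeTrain) -> np.ndarray:
    """Interspike intervals (seconds); length ``max(n - 1, 0)``."""
    return np.diff(train.times)


@dataclass(frozen=True)
class Burst:
    """A contiguous run of spikes classified as a burst.

    ``first_index``/``last_index`` are 0-based inclusive indices into the
    parent train; ``begin_time``/``end_time`` are the corresponding spike
    times.  ``surprise`` carries the detector's score where one exists
    (PS, RS and RGS values).
    """

    first_index: int
    last_index: int
    begin_time: float
    end_time: float
    surprise: Optional[float] = None

    def __post_init__(self) -> None:
        if self.last_index < self.first_index:
            raise ValueError("last_index must be >= first_index")
        if self.end_time < self.begin_time:
            raise ValueError("end_time must be >= begin_time")

    @property
    def n_spikes(self) -> int:
        return self.last_index - self.first_index + 1

    @property
    def duration(self) -> float:
        return self.end_time - self.begin_time


@dataclass
class BurstSet:
    """Ordered, non-overlapping bursts produced by one detector run."""

    bursts: list[Burst] = field(default_factory=list)
    method: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        b = sorted(self.bursts, key=lambda x: x.begin_time)
        for prev, nxt in zip(b, b[1:]):
            if nxt.first_index <= prev.last_index:
                raise ValueError("bursts overlap in spike indices")
        self.bursts = b

    def __len__(self) -> int:
        return len(self.bursts)

    def __iter__(self) -> Iterator[Burst]:
        return iter(self.bursts)

    def __getitem__(self, i: int) -> Burst:
        return self.bursts[i]

    @property
    def intervals(self) -> np.ndarray:
        """(n, 2) array of [begin_time, end_time] rows."""
        if not self.bursts:
            return np.empty((0, 2))
        return np.array([[b.begin_time, b.end_time] for b in self.bursts])


@dataclass
class LabeledTrain:
    """A spike train with known (simulated) ground-truth bursts.

    ``membership[i]`` is True when spike *i* is a burst spike, False when it
    is a noise spike.  Consistency with ``truth`` intervals is enforced.
    """

    train: SpikeTrain
    truth: BurstSet
    membership: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.membership, dtype=bool)
        object.__setattr__(self, "membership", m)
        if m.size != self.train.n_spikes:
            raise ValueError("membership length must equal spike count")
        expected = spike_membership(self.train, self.truth)
        if not np.array_equal(m, expected):
            raise ValueError("membership inconsistent with truth intervals")
        for b in self.truth:
            if b.n_spikes < 1:
                raise ValueError("every ground-truth burst needs >= 1 spike")


def spike_membership(train: SpikeTrain, bursts: BurstSet) -> np.ndarray:
    """Boolean vector: spike i is inside some burst's index range."""
    mask = np.zeros(train.n_spikes, dtype=bool)
    for b in bursts:
        mask[b.first_index : b.last_index + 1] = True
    return mask


def burst_mask(train: SpikeTrain, bursts: BurstSet, bin_width: float) -> np.ndarray:
    """Binarize bursting state over time bins of width ``bin_width`` seconds.

    The vector has ``ceil(duration / bin_width)`` entries; bin *b* is 1 iff
    the half-open bin ``[b*w, (b+1)*w)`` intersects any burst's closed time
    interval.  A 300-s train at 50-ms bins gives a length-6000 vector.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    n_bins = int(np.ceil(train.duration / bin_width))
    mask = np.zeros(n_bins, dtype=np.int8)
    for b in bursts:
        lo = int(np.floor(b.begin_time / bin_width))
        hi = int(np.floor(b.end_time / bin_width))
        mask[max(lo, 0) : min(hi, n_bins - 1) + 1] = 1
    return mask


def bursts_from_runs(
    train: SpikeTrain,
    runs: Sequence[tuple[int, int]],
    method: str = "",
    params: dict | None = None,
    surprises: Sequence[Optional[float]] | None = None,
) -> BurstSet:
    """Assemble a :class:`BurstSet` from inclusive spike-index runs."""
    t = train.times
    bursts = []
    for k, (i, j) in enumerate(runs):
        s = surprises[k] if surprises is not None else None
        bursts.append(Burst(i, j, float(t[i]), float(t[j]), surprise=s))
    return BurstSet(bursts=bursts, method=method, params=dict(params or {}))
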