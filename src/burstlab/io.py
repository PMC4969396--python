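"""Readers and writers for spike-time and burst-interval files.

Two plain-text input layouts are supported:

* ``timestamps`` — one decimal spike time (seconds) per line; one train per
  file.
* ``multitrain_csv`` — CSV with header ``train_id,time_s``; one train per
  distinct ``train_id``.

Burst intervals round-trip through a CSV with header
``train_id,begin_s,end_s,n_spikes,method``.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import Burst, BurstSet, SpikeTrain

__all__ = ["read_spike_trains", "write_bursts", "read_bursts"]

#: decimal places used when writing times (0.1 ms resolution)
_TIME_DECIMALS = 4


def _default_duration(last_time: float) -> float:
    """Round the last spike time up to the next whole second (>= 1 s)."""
    return max(float(math.ceil(last_time)), 1.0)


def _make_train(times: np.ndarray, duration: Optional[float], train_id: str,
                context: str) -> SpikeTrain:
    if np.any(times < 0):
        bad = int(np.argmax(times < 0))
        raise ValueError(f"{context}: negative spike time at entry {bad + 1}")
    if times.size and np.any(np.diff(times) <= 0):
        bad = int(np.argmax(np.diff(times) <= 0))
        raise ValueError(
            f"{context}: times not strictly increasing at entry {bad + 2} "
            "(unsorted or duplicate spike time)"
        )
    if duration is None:
        duration = _default_duration(float(times[-1])) if times.size else 1.0
    return SpikeTrain(times=times, duration=duration, id=train_id)


def read_spike_trains(
    path: str | Path,
    format: str = "timestamps",
    duration: Optional[float] = None,
) -> list[SpikeTrain]:
    """Read spike trains from a plain-text file.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"timestamps"`` or ``"multitrain_csv"`` (see module docstring).
    duration:
        Recording duration in seconds applied to every train.  When omitted
        the last spike time, rounded up to the next integer second, is used.
    """
    path = Path(path)
    if format == "timestamps":
        times = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                try:
                    times.append(float(line))
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: cannot parse spike time {line!r}"
                    ) from None
        arr = np.asarray(times, dtype=float)
        return [_make_train(arr, duration, path.stem, str(path))]
    if format == "multitrain_csv":
        df = pd.read_csv(path)
        required = {"train_id", "time_s"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"{path}: multitrain CSV needs columns {sorted(required)}, "
                f"found {list(df.columns)}"
            )
        if not np.isfinite(df["time_s"].to_numpy(dtype=float)).all():
            raise ValueError(f"{path}: non-finite spike time")
        trains = []
        for tid, grp in df.groupby("train_id", sort=True):
            arr = grp["time_s"].to_numpy(dtype=float)
            trains.append(_make_train(arr, duration, str(tid), f"{path} train {tid}"))
        return trains
    raise ValueError(f"unknown format {format!r}")


def write_spike_trains(trains: list[SpikeTrain], path: str | Path) -> None:
    """Write trains as a multi-train CSV (``train_id,time_s``)."""
    rows = [
        {"train_id": tr.id, "time_s": round(float(t), _TIME_DECIMALS)}
        for tr in trains
        for t in tr.times
    ]
    pd.DataFrame(rows, columns=["train_id", "time_s"]).to_csv(path, index=False)


def write_bursts(bursts: BurstSet | dict[str, BurstSet], path: str | Path) -> None:
    """Write burst intervals to CSV.

    Accepts a single :class:`BurstSet` (written under ``train_id=""`` unless
    a mapping is given) or a mapping ``train_id -> BurstSet``.
    """
    if isinstance(bursts, BurstSet):
        bursts = {"": bursts}
    rows = []
    for tid, bs in bursts.items():
        for b in bs:
            rows.append(
                {
                    "train_id": tid,
                    "begin_s": round(b.begin_time, _TIME_DECIMALS),
                    "end_s": round(b.end_time, _TIME_DECIMALS),
                    "n_spikes": b.n_spikes,
                    "method": bs.method,
                }
            )
    cols = ["train_id", "begin_s", "end_s", "n_spikes", "method"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_bursts(path: str | Path) -> dict[str, BurstSet]:
    """Read annotated burst intervals; inverse of :func:`write_bursts`.

    Index fields are reconstructed as a 0-based enumeration per train (the
    CSV stores time intervals, not parent-train indices); ``n_spikes`` is
    preserved through the index span so the round trip is exact.
    """
    df = pd.read_csv(path)
    required = {"train_id", "begin_s", "end_s"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: burst CSV needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    df["train_id"] = df["train_id"].fillna("").astype(str)
    out: dict[str, BurstSet] = {}
    for tid, grp in df.groupby("train_id", sort=True):
        grp = grp.sort_values("begin_s")
        bursts, cursor = [], 0
        method = str(grp["method"].iloc[0]) if "method" in grp else ""
        for _, row in grp.iterrows():
            begin, end = float(row["begin_s"]), float(row["end_s"])
            if end < begin:
                raise ValueError(
                    f"{path}: burst with end_s {end} < begin_s {begin} "
                    f"on train {tid!r}"
                )
            n = int(row["n_spikes"]) if "n_spikes" in row and pd.notna(row.get("n_spikes")) else 1
            bursts.append(Burst(cursor, cursor + n - 1, begin, end))
            cursor += n
        out[tid] = BurstSet(bursts=bursts, method=method)
    return out
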