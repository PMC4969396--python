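"""Scoring detector output against ground truth and benchmark drivers.

Implements the per-spike evaluation arithmetic (true/false-positive spike
fractions against simulated ground truth, sensitivity/specificity against
visual annotations), normalized Hamming distances between binarized burst
masks, burst summary statistics, ROC parameter sweeps, and the synthetic
benchmark over the D4-D11 train properties.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import detectors
from .params import default_params
from .simulate import PROPERTY_IDS, simulate_property
from .types import (BurstSet, LabeledTrain, SpikeTrain, burst_mask,
                    spike_membership)

__all__ = [
    "EvalResult",
    "BurstSummary",
    "spikes_in_bursts_fraction",
    "tp_fp_spike_fractions",
    "sensitivity_specificity",
    "hamming_distance_fraction",
    "burst_summary",
    "burst_count_recovery",
    "roc_sweep",
    "run_property_benchmark",
]


@dataclass(frozen=True)
class EvalResult:
    """Per-train detection scores; NaN marks an undefined denominator."""

    tp_fraction: float
    fp_fraction: float

    @property
    def sensitivity(self) -> float:
        return self.tp_fraction

    @property
    def false_positive_rate(self) -> float:
        return self.fp_fraction


@dataclass(frozen=True)
class BurstSummary:
    """Summary statistics of one train's detected bursts."""

    burst_count: int
    fraction_spikes_in_bursts: float
    mean_burst_duration: float  # s; NaN with no bursts
    cv_of_ibi: float  # NaN with < 3 bursts (< 2 interburst intervals)


def spikes_in_bursts_fraction(train: SpikeTrain, bursts: BurstSet) -> float:
    """Fraction of the train's spikes lying inside any detected burst."""
    if train.n_spikes == 0:
        return 0.0
    return float(spike_membership(train, bursts).mean())


def tp_fp_spike_fractions(detected: BurstSet, labeled: LabeledTrain) -> EvalResult:
    """True/false-positive spike fractions against simulated ground truth.

    ``tp`` is the proportion of within-burst spikes correctly flagged as
    bursting, ``fp`` the proportion of noise spikes erroneously flagged.
    An empty denominator (no burst spikes, or no noise spikes) yields NaN
    rather than a defined-by-fiat zero.
    """
    det = spike_membership(labeled.train, detected)
    truth = labeled.membership
    n_burst = int(truth.sum())
    n_noise = int((~truth).sum())
    tp = float(det[truth].sum() / n_burst) if n_burst else math.nan
    fp = float(det[~truth].sum() / n_noise) if n_noise else math.nan
    return EvalResult(tp, fp)


def sensitivity_specificity(detected: BurstSet, annotated: BurstSet,
                            train: SpikeTrain) -> EvalResult:
    """Per-spike sensitivity and false-positive rate against annotations.

    Membership is interval-based on both sides: a spike is annotated
    (resp. detected) as bursting when its time falls inside any annotated
    (resp. detected) closed burst interval.  For detector output this
    coincides with spike-index membership; for bursts read from interval
    files it is the only meaningful definition.  Sensitivity is the
    fraction of annotated-burst spikes detected; the false-positive rate
    is the fraction of the remaining spikes flagged as bursting.
    """
    t = train.times

    def in_intervals(bs: BurstSet) -> np.ndarray:
        m = np.zeros(t.size, dtype=bool)
        for b in bs:
            m |= (t >= b.begin_time) & (t <= b.end_time)
        return m

    ann = in_intervals(annotated)
    det = in_intervals(detected)
    n_in = int(ann.sum())
    n_out = int((~ann).sum())
    sens = float(det[ann].sum() / n_in) if n_in else math.nan
    fpr = float(det[~ann].sum() / n_out) if n_out else math.nan
    return EvalResult(sens, fpr)


def hamming_distance_fraction(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Fraction of time bins on which two burst masks disagree."""
    a = np.asarray(mask_a)
    b = np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if a.size == 0:
        return 0.0
    return float(np.mean((a != 0) != (b != 0)))


def burst_summary(train: SpikeTrain, bursts: BurstSet,
                  ibi_mode: str = "end_to_start") -> BurstSummary:
    """Burst count, spike fraction, mean duration, and CV of IBI.

    The interburst interval is the gap from one burst's end to the next
    burst's start (``"onset_to_onset"`` measures start-to-start instead).
    The CV needs at least two IBIs (three bursts) and is NaN otherwise.
    """
    n = len(bursts)
    frac = spikes_in_bursts_fraction(train, bursts)
    mean_dur = float(np.mean([b.duration for b in bursts])) if n else math.nan
    if n >= 3:
        iv = bursts.intervals
        if ibi_mode == "end_to_start":
            ibis = iv[1:, 0] - iv[:-1, 1]
        elif ibi_mode == "onset_to_onset":
            ibis = np.diff(iv[:, 0])
        else:
            raise ValueError(f"unknown ibi_mode {ibi_mode!r}")
        m = float(np.mean(ibis))
        cv = float(np.std(ibis, ddof=1) / m) if m > 0 else math.nan
    else:
        cv = math.nan
    return BurstSummary(n, frac, mean_dur, cv)


def burst_count_recovery(detected: BurstSet, truth: BurstSet) -> float:
    """Fraction of ground-truth bursts intersected by some detected burst."""
    if len(truth) == 0:
        return math.nan
    det = detected.intervals
    hits = 0
    for b in truth:
        if det.size and np.any((det[:, 0] <= b.end_time) & (det[:, 1] >= b.begin_time)):
            hits += 1
    return hits / len(truth)


# ---------------------------------------------------------------------------
# ROC sweep
# ---------------------------------------------------------------------------

def _surprise_grid(p_cutoffs: Sequence[float]):
    return [("min_surprise", -math.log(p)) for p in p_cutoffs]


def default_param_grid(method: str) -> list[tuple[str, object]]:
    """Per-method (field, value) grid for the ROC robustness sweep.

    Surprise-based methods vary the probability cutoff; IRT varies the
    count-cutoff tail level; logISI varies the maximum-cutoff cap; MI
    varies the beginning ISI with the end ISI held 0.130 s above it; CMA
    has no natural parameter and contributes a single point.
    """
    p_grid = np.geomspace(1e-6, 0.5, 12)
    if method in ("ps", "rs", "rgs"):
        return _surprise_grid(p_grid)
    if method == "irt":
        return [("count_tail_p", float(p)) for p in np.linspace(0.01, 0.5, 12)]
    if method == "logisi":
        return [("max_cutoff", float(c)) for c in np.linspace(0.02, 0.5, 12)]
    if method == "mi":
        return [("max_begin_isi", float(b)) for b in np.linspace(0.05, 1.0, 12)]
    if method == "cma":
        return [("bin_width", 0.001)]  # single operating point
    raise ValueError(f"no default grid for method {method!r}")


def roc_sweep(
    method: str,
    annotated: dict[str, BurstSet],
    trains: list[SpikeTrain],
    grid: Optional[list[tuple[str, object]]] = None,
    preset: str = "default",
    pooled: bool = False,
) -> pd.DataFrame:
    """Sweep one detector parameter and score against annotations.

    Returns a tidy frame with one row per grid point: the varied field and
    value, mean sensitivity and false-positive rate across trains
    (per-train averaging by default, spike-pooled when ``pooled``), and the
    Euclidean distance to the perfect-classification corner (0, 1).
    """
    if grid is None:
        grid = default_param_grid(method)
    rows = []
    for fieldname, value in grid:
        base = default_params(method, preset)
        if method == "mi" and fieldname == "max_begin_isi":
            # keep the end ISI a fixed 0.130 s above the beginning ISI
            p = replace(base, max_begin_isi=value, max_end_isi=value + 0.130)
        else:
            p = replace(base, **{fieldname: value})
        detected = detectors.detect_all(trains, method, p)
        if pooled:
            tp = fn = fp = tn = 0
            for tr, bs in zip(trains, detected):
                t = tr.times
                ann = np.zeros(t.size, dtype=bool)
                for b in annotated[tr.id]:
                    ann |= (t >= b.begin_time) & (t <= b.end_time)
                det = spike_membership(tr, bs)
                tp += int((det & ann).sum())
                fn += int((~det & ann).sum())
                fp += int((det & ~ann).sum())
                tn += int((~det & ~ann).sum())
            m_sens = tp / (tp + fn) if tp + fn else math.nan
            m_fpr = fp / (fp + tn) if fp + tn else math.nan
        else:
            results = [
                sensitivity_specificity(bs, annotated[tr.id], tr)
                for tr, bs in zip(trains, detected)
            ]

            def nanmean(vals):
                finite = [v for v in vals if not math.isnan(v)]
                return float(np.mean(finite)) if finite else math.nan

            m_sens = nanmean([r.sensitivity for r in results])
            m_fpr = nanmean([r.false_positive_rate for r in results])
        rows.append(
            {
                "method": method,
                "param": fieldname,
                "value": value,
                "sensitivity": m_sens,
                "false_positive_rate": m_fpr,
                "distance_to_perfect": math.hypot(m_fpr, 1.0 - m_sens),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic property benchmark
# ---------------------------------------------------------------------------

def run_property_benchmark(
    prop: str,
    methods: Sequence[str] = detectors.METHODS,
    n_trains: int = 100,
    duration: float = 300.0,
    seed: int = 0,
    preset: str = "default",
) -> pd.DataFrame:
    """Simulate ``n_trains`` trains of property ``prop`` and score each method.

    Returns a tidy frame, one row per (train, method, metric).  Metrics:

    * ``fraction_spikes_in_bursts`` — always;
    * ``tp_fraction`` / ``fp_fraction`` — whenever ground truth exists
      (``fp`` only when noise spikes exist, i.e. D11);
    * ``burst_count_ratio`` (detected / true count) and
      ``burst_recovery`` (fraction of true bursts intersected) — for
      bursting properties.

    Seeding is per (seed, property, train index), so any single row can be
    regenerated in isolation.
    """
    prop = prop.upper()
    if prop not in PROPERTY_IDS:
        raise ValueError(f"unknown property {prop!r}; choose from {PROPERTY_IDS}")
    labeled = [simulate_property(prop, i, seed, duration) for i in range(n_trains)]
    rows = []
    for method in methods:
        all_bursts = detectors.detect_all([lt.train for lt in labeled], method,
                                          preset=preset)
        for i, (lt, bs) in enumerate(zip(labeled, all_bursts)):
            rows.append((i, method, "fraction_spikes_in_bursts",
                         spikes_in_bursts_fraction(lt.train, bs)))
            if len(lt.truth) > 0:
                r = tp_fp_spike_fractions(bs, lt)
                rows.append((i, method, "tp_fraction", r.tp_fraction))
                if not math.isnan(r.fp_fraction):
                    rows.append((i, method, "fp_fraction", r.fp_fraction))
                rows.append((i, method, "burst_count_ratio",
                             len(bs) / len(lt.truth)))
                rows.append((i, method, "burst_recovery",
                             burst_count_recovery(bs, lt.truth)))
    return pd.DataFrame(rows, columns=["train", "method", "metric", "value"])


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of each (method, metric) over trains."""
    def iqr(x):
        q1, q3 = np.percentile(x, [25, 75])
        return q3 - q1

    out = (
        table.groupby(["method", "metric"])["value"]
        .agg(median="median", iqr=iqr, n="count")
        .reset_index()
    )
    return out
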