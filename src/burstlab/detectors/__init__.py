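"""Burst detectors and the method registry.

Seven detectors are built in, addressed by short names::

    mi      MaxInterval (five fixed ISI/duration thresholds)
    logisi  logISI-histogram void-parameter cutoff
    cma     cumulative moving average ISI-histogram cutoff
    ps      Poisson surprise maximization
    rs      rank surprise maximization
    rgs     robust Gaussian surprise (pooled central distribution)
    irt     ISI rank threshold

External detectors (for example a hidden semi-Markov model wrapper) can be
registered with :func:`register_detector` and are dispatched through the
same ``detect`` interface, returning the common ``BurstSet`` contract.
"""
from __future__ import annotations

from typing import Callable

from ..params import default_params
from ..types import BurstSet, SpikeTrain
from .cma import alpha_from_skew, cma_curve, detect_cma
from .irt import detect_irt, spike_count_cutoff
from .logisi import detect_logisi, logisi_cutoff, void_parameter
from .max_interval import detect_max_interval
from .rank_surprise import detect_rank_surprise, rank_surprise_pvalue
from .rgs import detect_rgs, detect_rgs_single, rgs_central_distribution
from .surprise import detect_poisson_surprise, poisson_surprise

__all__ = [
    "METHODS",
    "detect",
    "detect_all",
    "register_detector",
    "detect_max_interval",
    "detect_poisson_surprise",
    "detect_rank_surprise",
    "detect_rgs",
    "detect_rgs_single",
    "detect_irt",
    "detect_cma",
    "detect_logisi",
    "poisson_surprise",
    "rank_surprise_pvalue",
    "rgs_central_distribution",
    "spike_count_cutoff",
    "alpha_from_skew",
    "cma_curve",
    "void_parameter",
    "logisi_cutoff",
]

Detector = Callable[..., BurstSet]

_REGISTRY: dict[str, Detector] = {
    "mi": detect_max_interval,
    "logisi": detect_logisi,
    "cma": detect_cma,
    "ps": detect_poisson_surprise,
    "rs": detect_rank_surprise,
    "rgs": detect_rgs_single,
    "irt": detect_irt,
}

METHODS = tuple(_REGISTRY)


def register_detector(name: str, fn: Detector) -> None:
    """Register an external detector under ``name`` (plugin hook)."""
    if name in _REGISTRY:
        raise ValueError(f"detector {name!r} is already registered")
    _REGISTRY[name] = fn


def detect(train: SpikeTrain, method: str, params=None,
           preset: str = "default") -> BurstSet:
    """Run one detector on one train; preset defaults unless overridden."""
    try:
        fn = _REGISTRY[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(_REGISTRY)}")
    if params is None and method in METHODS:
        params = default_params(method, preset)
    return fn(train, params) if params is not None else fn(train)


def detect_all(trains: list[SpikeTrain], method: str, params=None,
               preset: str = "default") -> list[BurstSet]:
    """Run one detector across many trains.

    Per-train parameters (histogram cutoffs, surprise baselines) are
    derived independently for each train, except for the RGS method, which
    pools ISIs across all supplied trains into one central distribution.
    """
    if method == "rgs":
        if params is None:
            params = default_params("rgs", preset)
        return detect_rgs(trains, params)
    return [detect(tr, method, params, preset) for tr in trains]
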