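"""Detector parameter bundles and named presets.

Each detector has a small dataclass holding exactly its published tunables.
Two presets are shipped: ``"default"`` — the standard values used for the
synthetic benchmark — and ``"hipsc"`` — the alternate regime used for
human iPSC-derived network recordings (stricter surprise cutoff, wider
MaxInterval beginning ISI, 150-ms logISI cap).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

__all__ = [
    "SURPRISE_MIN",
    "PoissonSurpriseParams",
    "MaxIntervalParams",
    "CmaParams",
    "RankSurpriseParams",
    "IrtParams",
    "RgsParams",
    "LogIsiParams",
    "default_params",
    "PRESETS",
]

#: default minimum surprise value, -log(0.01) ~= 4.6, shared by the three
#: surprise-based detectors
SURPRISE_MIN = -math.log(0.01)


@dataclass(frozen=True)
class PoissonSurpriseParams:
    """Poisson surprise (PS) detector parameters."""

    min_surprise: float = SURPRISE_MIN
    #: forward-extension lookahead of the surprise-maximization search, spikes
    lookahead: int = 10


@dataclass(frozen=True)
class MaxIntervalParams:
    """MaxInterval (MI) detector thresholds, seconds unless noted."""

    max_begin_isi: float = 0.17
    max_end_isi: float = 0.3
    min_ibi: float = 0.2
    min_duration: float = 0.01
    min_spikes: int = 3

    def __post_init__(self) -> None:
        if self.max_end_isi < self.max_begin_isi:
            raise ValueError("max_end_isi must be >= max_begin_isi")


@dataclass(frozen=True)
class CmaParams:
    """Cumulative moving average (CMA) detector parameters.

    The burst cutoff coefficient alpha_1 (and the burst-related-spike
    coefficient alpha_2, unused for core detection) are chosen from the
    skewness of the CMA curve; see :func:`burstlab.detectors.cma.alpha_from_skew`.
    """

    bin_width: float = 0.001  # ISI histogram bin width, s
    min_spikes: int = 3


@dataclass(frozen=True)
class RankSurpriseParams:
    """Rank surprise (RS) detector parameters."""

    min_surprise: float = SURPRISE_MIN
    #: percentile of the ISI distribution bounding in-burst ISIs
    isi_limit_percentile: float = 75.0
    #: largest number of ISIs for which the exact uniform-sum convolution is
    #: used; larger windows fall back to the Gaussian approximation
    exact_limit: int = 60


@dataclass(frozen=True)
class IrtParams:
    """ISI rank threshold (IRT) detector parameters."""

    theta_r: float = 0.5
    #: tail level defining the spike-count cutoff theta_C over 1-s windows
    count_tail_p: float = 0.05
    window: float = 1.0  # s


@dataclass(frozen=True)
class RgsParams:
    """Robust Gaussian surprise (RGS) detector parameters."""

    min_surprise: float = SURPRISE_MIN
    #: multiplier on the (Gaussian-consistent) scaled MAD below which ISIs
    #: are candidate burst ISIs
    mad_multiplier: float = 2.58
    #: scale MAD by 1.4826 so the spread estimates a Gaussian sigma
    gaussian_consistent_mad: bool = True


@dataclass(frozen=True)
class LogIsiParams:
    """logISI-histogram detector parameters."""

    max_cutoff: float = 0.1  # largest admissible maxISI, s
    void_threshold: float = 0.7
    bins_per_decade: int = 10
    smooth_sigma_bins: float = 1.0  # Gaussian smoothing width, histogram bins
    min_spikes: int = 3


_DEFAULTS = {
    "ps": PoissonSurpriseParams(),
    "mi": MaxIntervalParams(),
    "cma": CmaParams(),
    "rs": RankSurpriseParams(),
    "irt": IrtParams(),
    "rgs": RgsParams(),
    "logisi": LogIsiParams(),
}

PRESETS: dict[str, dict[str, object]] = {
    "default": dict(_DEFAULTS),
    "hipsc": {
        **_DEFAULTS,
        "ps": PoissonSurpriseParams(min_surprise=-math.log(0.0025)),
        "mi": MaxIntervalParams(max_begin_isi=0.2),
        "logisi": LogIsiParams(max_cutoff=0.15),
    },
}


def default_params(method: str, preset: str = "default"):
    """Return the parameter bundle for ``method`` under ``preset``."""
    try:
        bundle = PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    try:
        return bundle[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(bundle)}")


def params_to_dict(p) -> dict:
    return asdict(p)


def params_with_overrides(p, **overrides):
    return replace(p, **overrides)
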