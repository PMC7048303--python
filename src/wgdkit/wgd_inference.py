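"""Paralog-age distributions and whole-genome-duplication inference.

A WGD leaves a coherent burst in the distribution of synonymous divergence
(dS) between surviving paralog pairs, superimposed on the continuous
background of small-scale duplications.  This module estimates that
distribution with a Gaussian kernel density, locates its mode inside a
search range that excludes the recent-duplication spike near dS = 0,
flags the pairs inside a dS window as WGD-derived, and converts dS to an
age with a synonymous substitution rate (T = dS / 2r by default: pairwise
divergence accumulates on both lineages).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .pair_catalog import GenePair

__all__ = [
    "DsDistribution",
    "WGDCall",
    "ds_distribution",
    "fourdtv_distribution",
    "classify_wgd_pairs",
    "date_event",
    "call_wgd",
]

#: default synonymous substitution rate, substitutions/site/year
DEFAULT_SYN_RATE = 2.81e-9
#: default dS window bounding the WGD-derived pairs (closed interval)
DEFAULT_WGD_WINDOW = (0.5, 0.9)
#: default KDE mode search range, excluding the small-scale-duplication spike
DEFAULT_SEARCH_RANGE = (0.2, 2.0)

_GRID_STEP = 0.005
_MIN_PAIRS = 10


@dataclass(frozen=True)
class DsDistribution:
    """Kernel density summary of a divergence-value sample."""

    values: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    mode: float
    search_range: tuple[float, float]


@dataclass(frozen=True)
class WGDCall:
    """One detected WGD: modal dS, pair window, and the implied age."""

    mode_ds: float
    window: tuple[float, float]
    n_pairs_in_window: int
    date_years: float
    rate_used: float


def _kde_summary(
    values: np.ndarray,
    clip: tuple[float, float],
    search_range: tuple[float, float],
) -> DsDistribution:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < _MIN_PAIRS:
        raise ValueError(
            f"need at least {_MIN_PAIRS} usable values, got {len(values)}"
        )
    values = np.clip(values, clip[0], clip[1])
    grid = np.arange(clip[0], clip[1] + _GRID_STEP / 2, _GRID_STEP)
    if np.ptp(values) == 0:
        # degenerate point mass: KDE bandwidth is undefined, mode is the value
        density = np.zeros_like(grid)
        density[np.argmin(np.abs(grid - values[0]))] = 1.0 / _GRID_STEP
        mode = float(values[0])
        return DsDistribution(values, grid, density, mode, search_range)
    kde = gaussian_kde(values, bw_method="silverman")
    density = kde(grid)
    lo, hi = search_range
    in_range = (grid >= lo) & (grid <= hi)
    if not in_range.any():
        raise ValueError("search range does not intersect the value grid")
    mode = float(grid[in_range][np.argmax(density[in_range])])
    return DsDistribution(values, grid, density, mode, search_range)


def ds_distribution(
    pairs: Sequence[GenePair],
    search_range: tuple[float, float] = DEFAULT_SEARCH_RANGE,
) -> DsDistribution:
    """Gaussian KDE (Silverman bandwidth) of finite, unsaturated pair dS.

    Values are clipped to [0, 3] and evaluated on a grid of step 0.005; the
    mode is the density argmax within ``search_range``.
    """
    values = np.array(
        [
            p.divergence.ds
            for p in pairs
            if p.divergence is not None
            and not p.divergence.saturated
            and math.isfinite(p.divergence.ds)
        ]
    )
    return _kde_summary(values, clip=(0.0, 3.0), search_range=search_range)


def fourdtv_distribution(
    pairs: Sequence[GenePair],
    search_range: tuple[float, float] = (0.02, 1.0),
) -> DsDistribution:
    """KDE summary of defined 4DTv rates, analogous to :func:`ds_distribution`."""
    values = np.array(
        [
            p.fourdtv.rate
            for p in pairs
            if p.fourdtv is not None and math.isfinite(p.fourdtv.rate)
        ]
    )
    return _kde_summary(values, clip=(0.0, 1.0), search_range=search_range)


def classify_wgd_pairs(
    pairs: Sequence[GenePair],
    window: tuple[float, float] = DEFAULT_WGD_WINDOW,
) -> int:
    """Set ``wgd_flag`` on pairs whose dS lies in the closed window.

    Returns the number of flagged pairs.  Pairs without a finite dS are
    never flagged.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    n = 0
    for p in pairs:
        flag = (
            p.divergence is not None
            and math.isfinite(p.divergence.ds)
            and lo <= p.divergence.ds <= hi
        )
        p.wgd_flag = flag
        n += flag
    return n


def date_event(
    ds: float, rate: float = DEFAULT_SYN_RATE, lineage_factor: float = 2.0
) -> float:
    """Convert a dS value to years: T = dS / (lineage_factor * rate).

    The default factor 2 treats dS as pairwise divergence accumulating on
    both lineages since the duplication.
    """
    if ds < 0:
        raise ValueError("ds must be non-negative")
    if rate <= 0:
        raise ValueError("rate must be positive")
    return ds / (lineage_factor * rate)


def call_wgd(
    pairs: Sequence[GenePair],
    window: tuple[float, float] = DEFAULT_WGD_WINDOW,
    rate: float = DEFAULT_SYN_RATE,
    search_range: tuple[float, float] = DEFAULT_SEARCH_RANGE,
    lineage_factor: float = 2.0,
) -> tuple[WGDCall, DsDistribution]:
    """Full WGD call: mode detection, window classification, dating."""
    dist = ds_distribution(pairs, search_range=search_range)
    n_in = classify_wgd_pairs(pairs, window=window)
    call = WGDCall(
        mode_ds=dist.mode,
        window=window,
        n_pairs_in_window=n_in,
        date_years=date_event(dist.mode, rate=rate, lineage_factor=lineage_factor),
        rate_used=rate,
    )
    return call, dist


def histogram_mode(
    values: Sequence[float],
    bin_width: float = 0.05,
    search_range: tuple[float, float] = DEFAULT_SEARCH_RANGE,
) -> float:
    """Histogram-based mode estimate (cross-check for the KDE mode)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    edges = np.arange(0.0, 3.0 + bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    in_range = (centers >= search_range[0]) & (centers <= search_range[1])
    return float(centers[in_range][np.argmax(counts[in_range])])
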