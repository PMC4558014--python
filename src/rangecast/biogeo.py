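"""Biogeographic summaries: range centroids, richness change, turnover.

Range centroids are attribute means (latitude, elevation, distance to
coast) weighted by each cell's share of the binary range; shifts between
periods are reported in km northward (1 degree latitude = 111.32 km), m
upslope, and km inland.  Community change per grid cell is summarised as
species gains and losses and as binary Bray-Curtis dissimilarity
(1 - Sorensen similarity) between the current and future species sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KM_PER_DEG_LAT = 111.32


@dataclass
class CentroidSummary:
    species_id: str
    season: str
    period: str
    latitude: float   # degrees N
    elevation: float  # m
    dist_coast: float  # km


@dataclass
class CommunityGrids:
    current_richness: np.ndarray
    future_richness: np.ndarray
    gain: np.ndarray
    loss: np.ndarray


def _grid(r):
    return np.asarray(r.grid if hasattr(r, "grid") else r).astype(bool)


def weighted_centroid(distribution, landscape, species_id="", season="",
                      period="base", weights=None) -> CentroidSummary:
    """Range centroid in attribute space (latitude, elevation, coast distance).

    Default weights give each range cell an equal share of the distribution
    (cell weight = 1 / range size).  Pass a suitability surface as
    ``weights`` for the continuous-weight variant.
    """
    grid = _grid(distribution)
    if weights is None:
        w = grid.astype(float)
    else:
        w = np.asarray(weights, dtype=float) * grid
    total = w.sum()
    if total == 0:
        raise ValueError("empty range: centroid undefined")
    w = w / total
    return CentroidSummary(
        species_id=species_id, season=season, period=period,
        latitude=float((w * landscape.latitude_grid).sum()),
        elevation=float((w * landscape.elevation).sum()),
        dist_coast=float((w * landscape.dist_coast).sum()))


def centroid_shift(current: CentroidSummary, future: CentroidSummary):
    """(northward km, upslope m, inland km) between two centroids."""
    if (current.species_id, current.season) != (future.species_id, future.season):
        raise ValueError("centroid shift requires matching species and season")
    return ((future.latitude - current.latitude) * KM_PER_DEG_LAT,
            future.elevation - current.elevation,
            future.dist_coast - current.dist_coast)


def richness_change(current_ranges, future_ranges) -> CommunityGrids:
    """Per-cell species gains and losses between two sets of range maps.

    ``current_ranges`` and ``future_ranges`` are parallel sequences (same
    species order).  Satisfies current - loss + gain = future richness.
    """
    cur = np.stack([_grid(r) for r in current_ranges])
    fut = np.stack([_grid(r) for r in future_ranges])
    if cur.shape != fut.shape:
        raise ValueError("current and future stacks differ in shape")
    return CommunityGrids(
        current_richness=cur.sum(axis=0),
        future_richness=fut.sum(axis=0),
        gain=(fut & ~cur).sum(axis=0),
        loss=(cur & ~fut).sum(axis=0))


def bray_curtis_cell(current_set, future_set) -> float:
    """Binary Bray-Curtis dissimilarity between two species sets.

    With a shared, b only-current, c only-future: ``1 - 2a / (2a + b + c)``;
    two empty sets are defined as identical (0).
    """
    cur, fut = set(current_set), set(future_set)
    a = len(cur & fut)
    b = len(cur - fut)
    c = len(fut - cur)
    if 2 * a + b + c == 0:
        return 0.0
    return 1.0 - 2.0 * a / (2.0 * a + b + c)


def dissimilarity_map(current_ranges, future_ranges):
    """Per-cell binary Bray-Curtis grid and its mean over occupied cells.

    Cells empty in both periods are 0 by convention and excluded from the
    mean.  Returns ``(grid, mean)``.
    """
    cur = np.stack([_grid(r) for r in current_ranges]).astype(np.int64)
    fut = np.stack([_grid(r) for r in future_ranges]).astype(np.int64)
    if cur.shape != fut.shape:
        raise ValueError("current and future stacks differ in shape")
    a = (cur & fut).sum(axis=0)
    b = (cur & ~fut).sum(axis=0)
    c = (fut & ~cur).sum(axis=0)
    denom = 2 * a + b + c
    occupied = denom > 0
    d = np.zeros(a.shape, dtype=float)
    d[occupied] = 1.0 - 2.0 * a[occupied] / denom[occupied]
    mean = float(d[occupied].mean()) if occupied.any() else 0.0
    return d, mean


def centroid_shift_table(shifts) -> pd.DataFrame:
    """Tidy table of per-species centroid shifts."""
    return pd.DataFrame(shifts, columns=["species_id", "season",
                                         "northward_km", "upslope_m", "inland_km"])
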