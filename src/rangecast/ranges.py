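"""Range delineation: Cohen's Kappa thresholding, consensus ensembles, sizes.

Continuous suitability surfaces are converted to binary range maps at the
threshold that maximises Cohen's Kappa against observed presence/absence.
Kappa measures the proportion of correctly predicted sites after chance
agreement is removed; maximising it gives a conservative range estimate,
particularly for rare species.  Projections from multiple circulation
models within a scenario x period are combined by cell-wise averaging of
suitability before thresholding (consensus forecasting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class KappaCurve:
    """Confusion counts and kappa at every candidate threshold."""

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    kappa: np.ndarray

    def to_frame(self):
        return pd.DataFrame({"threshold": self.thresholds, "tp": self.tp,
                             "fp": self.fp, "fn": self.fn, "tn": self.tn,
                             "kappa": self.kappa})


@dataclass
class RangeMap:
    """Binary range grid plus the threshold and provenance that produced it."""

    grid: np.ndarray
    threshold: float
    species_id: str = ""
    season: str = ""
    scenario: str = "none"
    period: str = "base"

    def __post_init__(self):
        self.grid = np.asarray(self.grid).astype(bool)

    @property
    def n_cells(self):
        return int(self.grid.sum())


def kappa(tp, fp, fn, tn):
    """Cohen's Kappa from confusion counts.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with observed agreement
    ``p_o = (TP+TN)/n`` and chance agreement
    ``p_e = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / n^2``.  The degenerate case
    ``p_e = 1`` (both margins single-class) is defined as 0.
    """
    tp, fp, fn, tn = (np.asarray(v, dtype=float) for v in (tp, fp, fn, tn))
    if np.any(tp < 0) or np.any(fp < 0) or np.any(fn < 0) or np.any(tn < 0):
        raise ValueError("confusion counts must be non-negative")
    n = tp + fp + fn + tn
    if np.any(n <= 0):
        raise ValueError("total count must be positive")
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(p_e >= 1.0, 0.0, (p_o - p_e) / (1.0 - p_e))
    if np.any(p_e >= 1.0):
        warnings.warn("kappa undefined (chance agreement = 1); returning 0")
    return float(k) if k.ndim == 0 else k


def max_kappa_threshold(observed, predicted):
    """Threshold maximising kappa, plus the full curve.

    Every unique predicted value is a candidate; ``prediction >= t`` is
    called presence.  Ties in kappa are broken toward the smallest
    threshold, which yields the larger (more conservative for rare species)
    range.
    """
    obs = np.asarray(observed).astype(bool).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    if obs.all() or not obs.any():
        raise ValueError("observations contain a single class; kappa threshold undefined")

    order = np.argsort(pred, kind="mergesort")
    pred_s, obs_s = pred[order], obs[order]
    n = len(obs)
    n_pos = int(obs.sum())
    # cumulative positives/negatives strictly below each sorted position
    cum_pos = np.concatenate([[0], np.cumsum(obs_s)])
    # first occurrence of each unique value in the sorted order
    first = np.flatnonzero(np.concatenate([[True], pred_s[1:] != pred_s[:-1]]))
    thresholds = pred_s[first]
    below_pos = cum_pos[first]          # positives with pred < t
    below_n = first                     # records with pred < t
    fn = below_pos
    tn = below_n - below_pos
    tp = n_pos - fn
    fp = (n - n_pos) - tn
    ks = kappa(tp, fp, fn, tn)
    best = int(np.flatnonzero(ks == ks.max())[0])  # smallest threshold on ties
    curve = KappaCurve(thresholds=thresholds, tp=tp, fp=fp, fn=fn, tn=tn, kappa=ks)
    return float(thresholds[best]), curve


def binarize(suitability, threshold, **labels) -> RangeMap:
    """Cells with suitability >= threshold form the range."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return RangeMap(grid=np.asarray(suitability) >= threshold,
                    threshold=threshold, **labels)


def ensemble(surfaces, labels=None):
    """Cell-wise mean of suitability surfaces from one scenario x period.

    ``surfaces`` may be plain arrays or (surface, labels) handled by the
    pipeline; label consistency is enforced when ``labels`` (a list of
    (scenario, period) tuples) is given.  The consensus surface is tagged
    gcm="consensus" by the caller.
    """
    if len(surfaces) == 0:
        raise ValueError("ensemble requires at least one surface")
    if labels is not None and len(set(labels)) > 1:
        raise ValueError(f"mixed scenario/period labels in ensemble: {sorted(set(labels))}")
    arrs = [np.asarray(s, dtype=float) for s in surfaces]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("ensemble members must share one grid")
    return np.mean(arrs, axis=0)


def range_size(rangemap, cell_area):
    """Range area in km^2 and cell count: ``(area, n_cells)``."""
    grid = rangemap.grid if isinstance(rangemap, RangeMap) else np.asarray(rangemap, dtype=bool)
    n = int(grid.sum())
    return n * cell_area, n
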