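"""Bioclimatic variables and the anomaly (delta) method for future climate.

Monthly minimum/maximum temperature and precipitation grids are summarised
into the 19 standard bioclimatic variables (annual means, extremes,
seasonality, and wettest/driest/warmest/coldest quarter summaries).  Future
fine-scale climate is built by adding coarse model anomalies
(future - reference) to a fine-scale baseline, the conventional delta
method.  Extraction of grid values at survey points is nearest-cell.

Conventions
-----------
* A "quarter" is any of the 12 consecutive 3-month windows, wrapping
  December -> January.  Ties in wettest/driest/warmest/coldest are broken
  by the earliest starting month.
* Monthly mean temperature is ``(tmin + tmax) / 2``.
* BIO4 is the sample standard deviation (ddof=1) of monthly mean
  temperature x 100; BIO15 is sample SD of monthly precipitation over
  (mean + 1) x 100, the convention of the dominant SDM toolchain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BIO_NAMES = tuple(f"bio{i:02d}" for i in range(1, 20))

SCENARIOS = ("A2", "A1B", "B2")
PERIODS = ("2020", "2050", "2080")


@dataclass
class MonthlyClimate:
    """A 12-month stack of tmin/tmax (degC) and precipitation (mm) grids.

    ``period`` is one of ``base, 2020, 2050, 2080``; ``scenario`` one of
    ``A2, A1B, B2, none``; ``gcm`` a free-form model label.
    """

    tmin: np.ndarray  # (12, ny, nx)
    tmax: np.ndarray
    prec: np.ndarray
    period: str = "base"
    scenario: str = "none"
    gcm: str = "none"

    def __post_init__(self):
        self.tmin = np.asarray(self.tmin, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        self.prec = np.asarray(self.prec, dtype=float)
        for name, arr in (("tmin", self.tmin), ("tmax", self.tmax), ("prec", self.prec)):
            if arr.ndim != 3 or arr.shape[0] != 12:
                raise ValueError(f"{name} must have shape (12, ny, nx), got {arr.shape}")
        if not (self.tmin.shape == self.tmax.shape == self.prec.shape):
            raise ValueError("tmin/tmax/prec shapes differ")
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax < tmin at some cell/month")
        if np.any(self.prec < 0):
            raise ValueError("negative precipitation")

    @property
    def shape(self):
        return self.tmin.shape[1:]

    @property
    def tmean(self):
        return (self.tmin + self.tmax) / 2.0


@dataclass
class BioclimGrid:
    """Stack of the 19 bioclimatic layers plus provenance labels."""

    layers: dict = field(default_factory=dict)  # name -> (ny, nx) array
    period: str = "base"
    scenario: str = "none"
    gcm: str = "none"

    def __getitem__(self, name):
        return self.layers[name]

    @property
    def shape(self):
        return next(iter(self.layers.values())).shape

    def stack(self, names):
        """Column-stack the named layers into an (n_cells, n_layers) matrix."""
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"bioclim layers missing from grid: {missing}")
        return np.column_stack([self.layers[n].ravel() for n in names])


def compute_bioclim(monthly: MonthlyClimate) -> BioclimGrid:
    """Derive BIO1-BIO19 from a :class:`MonthlyClimate`."""
    tmin, tmax, prec = monthly.tmin, monthly.tmax, monthly.prec
    tavg = monthly.tmean

    b = {}
    b["bio01"] = tavg.mean(axis=0)
    b["bio02"] = (tmax - tmin).mean(axis=0)
    b["bio04"] = tavg.std(axis=0, ddof=1) * 100.0
    b["bio05"] = tmax.max(axis=0)
    b["bio06"] = tmin.min(axis=0)
    b["bio07"] = b["bio05"] - b["bio06"]
    with np.errstate(divide="ignore", invalid="ignore"):
        b["bio03"] = np.where(b["bio07"] > 0, b["bio02"] / b["bio07"] * 100.0, 0.0)
    b["bio12"] = prec.sum(axis=0)
    b["bio13"] = prec.max(axis=0)
    b["bio14"] = prec.min(axis=0)
    b["bio15"] = prec.std(axis=0, ddof=1) / (prec.mean(axis=0) + 1.0) * 100.0

    # all 12 wrapped consecutive-3-month windows
    qt = np.stack([tavg[[q, (q + 1) % 12, (q + 2) % 12]].mean(axis=0) for q in range(12)])
    qp = np.stack([prec[[q, (q + 1) % 12, (q + 2) % 12]].sum(axis=0) for q in range(12)])

    wettest = qp.argmax(axis=0)
    driest = qp.argmin(axis=0)
    warmest = qt.argmax(axis=0)
    coldest = qt.argmin(axis=0)

    def _pick(stack, idx):
        return np.take_along_axis(stack, idx[None], axis=0)[0]

    b["bio08"] = _pick(qt, wettest)
    b["bio09"] = _pick(qt, driest)
    b["bio10"] = qt.max(axis=0)
    b["bio11"] = qt.min(axis=0)
    b["bio16"] = qp.max(axis=0)
    b["bio17"] = qp.min(axis=0)
    b["bio18"] = _pick(qp, warmest)
    b["bio19"] = _pick(qp, coldest)

    return BioclimGrid(layers={k: b[k] for k in BIO_NAMES},
                       period=monthly.period, scenario=monthly.scenario, gcm=monthly.gcm)


def _nearest_index_map(n_fine: int, n_coarse: int) -> np.ndarray:
    """Map fine-grid indices to the coarse cell containing each fine-cell center."""
    centers = (np.arange(n_fine) + 0.5) / n_fine  # in [0, 1)
    idx = np.floor(centers * n_coarse).astype(int)
    return np.clip(idx, 0, n_coarse - 1)


def resample_nearest(coarse: np.ndarray, fine_shape) -> np.ndarray:
    """Nearest-cell resampling of a (..., nyc, nxc) stack onto a fine grid.

    Assumes the two grids cover the same spatial extent.
    """
    nyf, nxf = fine_shape
    iy = _nearest_index_map(nyf, coarse.shape[-2])
    ix = _nearest_index_map(nxf, coarse.shape[-1])
    return coarse[..., iy[:, None], ix[None, :]]


def delta_downscale(baseline_fine: MonthlyClimate,
                    future_coarse: MonthlyClimate,
                    reference_coarse: MonthlyClimate) -> MonthlyClimate:
    """Build fine-scale future climate by the additive anomaly (delta) method.

    The coarse future-minus-reference difference is computed per month and
    variable, resampled to the fine grid by nearest cell, and added to the
    fine baseline.  Precipitation is floored at 0.  Output labels (period,
    scenario, gcm) are inherited from ``future_coarse``.
    """
    if future_coarse.shape != reference_coarse.shape:
        raise ValueError(
            f"future and reference coarse grids differ in shape: "
            f"{future_coarse.shape} vs {reference_coarse.shape}")
    fine = baseline_fine.shape

    def _anom(fut, ref):
        return resample_nearest(fut - ref, fine)

    tmin = baseline_fine.tmin + _anom(future_coarse.tmin, reference_coarse.tmin)
    tmax = baseline_fine.tmax + _anom(future_coarse.tmax, reference_coarse.tmax)
    prec = np.maximum(baseline_fine.prec + _anom(future_coarse.prec, reference_coarse.prec), 0.0)
    # differing tmin/tmax anomalies can invert the diurnal ordering; clip up
    tmax = np.maximum(tmax, tmin)
    return MonthlyClimate(tmin=tmin, tmax=tmax, prec=prec,
                          period=future_coarse.period,
                          scenario=future_coarse.scenario,
                          gcm=future_coarse.gcm)


def extract_at_points(grid: np.ndarray, points, cell_size: float) -> np.ndarray:
    """Nearest-cell values of ``grid`` at point coordinates (no interpolation).

    ``points`` is an (m, 2) array-like of (x, y) in km with the grid origin
    at (0, 0); any point inside cell (i, j) maps to that cell.  Out-of-bounds
    points raise a ValueError naming the offending point.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ny, nx = grid.shape
    col = np.floor(pts[:, 0] / cell_size).astype(int)
    row = np.floor(pts[:, 1] / cell_size).astype(int)
    # a point exactly on the far edge belongs to the last cell
    col = np.where((pts[:, 0] == nx * cell_size), nx - 1, col)
    row = np.where((pts[:, 1] == ny * cell_size), ny - 1, row)
    bad = (col < 0) | (col >= nx) | (row < 0) | (row >= ny)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"point {i} at ({pts[i, 0]}, {pts[i, 1]}) lies outside the "
            f"{nx}x{ny} grid (cell_size={cell_size})")
    return grid[row, col]
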