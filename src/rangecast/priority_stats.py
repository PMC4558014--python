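"""Conservation-rank correlations and variance-components attribution.

Climate sensitivity categories are converted to ordinal ranks (highest
threat = lowest rank) and compared with existing priority schemes — IUCN
Red List, US federal listing / Birds of Conservation Concern, Partners in
Flight threat scores — by Kendall rank correlation.  Variation in range
outcomes (current range size, relative change in range size) is attributed
to categorical covariates treated as random effects, via REML estimation of
a random-intercepts variance-components model.

Because all rank schemes here are heavily tied 3-level ordinals, the
tie-corrected tau-b is the primary statistic; tau-a is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

log = logging.getLogger(__name__)

#: highest threat -> lowest rank; the climate-stable group ranks highest
AUDUBON_RANKS = {"endangered": 1, "threatened": 2, "stable": 3}
FED_BCC_RANKS = {"federal": 1, "bcc": 2, "none": 3}
IUCN_RANKS = {"endangered": 1, "threatened": 2, "least_concern": 3}


@dataclass
class VarianceComponents:
    """REML variance estimates and proportions per random factor."""

    variances: dict       # factor -> sigma^2 >= 0
    residual: float
    dropped: list = field(default_factory=list)

    @property
    def total(self):
        return sum(self.variances.values()) + self.residual

    @property
    def proportions(self):
        t = self.total
        if t == 0:
            out = {k: 0.0 for k in self.variances}
            out["residual"] = 1.0
            return out
        out = {k: v / t for k, v in self.variances.items()}
        out["residual"] = self.residual / t
        return out

    def to_frame(self):
        props = self.proportions
        rows = [(k, self.variances[k], props[k]) for k in self.variances]
        rows.append(("residual", self.residual, props["residual"]))
        return pd.DataFrame(rows, columns=["factor", "variance", "proportion"])


def _rank_one(value, mapping, scheme, species):
    try:
        return mapping[value]
    except KeyError:
        raise ValueError(f"unknown {scheme} status {value!r} for species "
                         f"{species}") from None


def assign_ranks(statuses: pd.DataFrame) -> pd.DataFrame:
    """Ordinal ranks per priority scheme for each species.

    Expects columns ``species_id``, ``audubon_category`` and any of
    ``iucn_status``, ``fed_bcc_status``, ``pif_score``.  Species in the
    "other" category (introduced/marginal) are excluded.  PIF scores are
    kept as published and additionally expressed as ``pif_rank`` under the
    same polarity as the other schemes (highest threat score -> lowest
    rank); missing PIF values stay missing.
    """
    df = statuses[statuses["audubon_category"] != "other"].copy()
    df["audubon_rank"] = [
        _rank_one(v, AUDUBON_RANKS, "audubon", s)
        for v, s in zip(df["audubon_category"], df["species_id"])]
    if "fed_bcc_status" in df:
        df["fed_bcc_rank"] = [
            _rank_one(v, FED_BCC_RANKS, "fed_bcc", s)
            for v, s in zip(df["fed_bcc_status"], df["species_id"])]
    if "iucn_status" in df:
        df["iucn_rank"] = [
            _rank_one(v, IUCN_RANKS, "iucn", s)
            for v, s in zip(df["iucn_status"], df["species_id"])]
    if "pif_score" in df:
        pif = pd.to_numeric(df["pif_score"], errors="coerce")
        df["pif_score"] = pif
        df["pif_rank"] = (-pif).rank(method="dense")
    return df


def kendall_tau(x, y):
    """Tie-corrected Kendall tau-b with a two-sided asymptotic p-value.

    Pairwise-complete cases only; raises if fewer than 3 remain or either
    vector is constant (tau undefined under total ties).
    """
    x = pd.to_numeric(pd.Series(list(x)), errors="coerce")
    y = pd.to_numeric(pd.Series(list(y)), errors="coerce")
    ok = x.notna() & y.notna()
    x, y = x[ok].to_numpy(), y[ok].to_numpy()
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, have {len(x)}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau undefined: one vector is entirely tied")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def kendall_tau_a(x, y):
    """Uncorrected tau-a = (concordant - discordant) / C(n, 2)."""
    x = pd.to_numeric(pd.Series(list(x)), errors="coerce")
    y = pd.to_numeric(pd.Series(list(y)), errors="coerce")
    ok = x.notna() & y.notna()
    x, y = x[ok].to_numpy(), y[ok].to_numpy()
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, have {n}")
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    s = (dx * dy)[np.triu_indices(n, 1)].sum()
    return float(s / (n * (n - 1) / 2))


def relative_change(current_size, future_size):
    """(future - current) / current; current must be positive."""
    current_size = np.asarray(current_size, dtype=float)
    future_size = np.asarray(future_size, dtype=float)
    if np.any(current_size <= 0):
        raise ValueError("relative change undefined for zero current range size")
    out = (future_size - current_size) / current_size
    return float(out) if out.ndim == 0 else out


# --- REML variance components -------------------------------------------

# sigma_e^2 is floored at this fraction of var(y): with exactly zero
# residual noise the REML likelihood diverges on the boundary, and the
# floor regularises it while leaving the factor variances identified.
_RESID_FLOOR = 1e-6


def variance_components(response, factors, floor=_RESID_FLOOR) -> VarianceComponents:
    """REML variance components for crossed random-intercept factors.

    ``factors`` is a DataFrame (or dict of sequences) of categorical
    columns.  Factors with fewer than two observed levels are dropped with
    a log entry.  Negative estimates cannot occur (variances are optimised
    in log space); estimates at the lower bound are reported as 0.

    The REML criterion is evaluated in the q-dimensional level space via
    the Woodbury identity, so cost scales with the total number of factor
    levels rather than the number of observations.
    """
    y = np.asarray(response, dtype=float)
    fdf = pd.DataFrame(factors)
    kept, codes, dropped = [], [], []
    for name in fdf.columns:
        c, levels = pd.factorize(fdf[name], sort=True)
        if len(levels) < 2:
            dropped.append(name)
            log.info("variance_components: dropping factor %r (<2 levels)", name)
            continue
        kept.append(name)
        codes.append(c)
    if not kept:
        raise ValueError("no factor has 2 or more levels")

    vy = float(np.var(y))
    if vy == 0:
        # constant response: nothing to attribute, all proportions 0 with
        # residual 1 (see VarianceComponents.proportions for total == 0)
        return VarianceComponents(variances={k: 0.0 for k in kept},
                                  residual=0.0, dropped=dropped)

    s2, se2 = _reml_fit(y, codes, floor)
    variances = {k: (0.0 if v < 10 * floor * vy else float(v))
                 for k, v in zip(kept, s2)}
    return VarianceComponents(variances=variances, residual=float(se2),
                              dropped=dropped)


def _reml_fit(y, factor_codes, floor):
    n = len(y)
    sd = y.std()
    ys = (y - y.mean()) / sd
    Zs = []
    for c in factor_codes:
        q = int(c.max()) + 1
        Z = np.zeros((n, q))
        Z[np.arange(n), c] = 1.0
        Zs.append(Z)
    Z = np.hstack(Zs)
    qs = [z.shape[1] for z in Zs]
    ZtZ = Z.T @ Z
    Zty = Z.T @ ys
    Zt1 = Z.sum(axis=0)
    one = np.ones(n)

    def neg2reml(logs):
        s2 = np.exp(logs[:-1])
        se2 = np.exp(logs[-1])
        rd = np.sqrt(np.concatenate([np.full(q, s) for q, s in zip(qs, s2)]) / se2)
        M = np.eye(len(rd)) + rd[:, None] * ZtZ * rd[None, :]
        try:
            cho = linalg.cho_factor(M, lower=True, check_finite=False)
        except (np.linalg.LinAlgError, ValueError):
            return 1e12
        logdet_m = 2.0 * np.log(np.diag(cho[0])).sum()

        def vinv(ztv, v):
            return (v - Z @ (rd * linalg.cho_solve(cho, rd * ztv))) / se2

        viy = vinv(Zty, ys)
        vi1 = vinv(Zt1, one)
        xtvix = float(one @ vi1)
        if xtvix <= 0 or not np.isfinite(xtvix):
            return 1e12
        beta = float(one @ viy) / xtvix
        quad = float(ys @ viy) - beta * beta * xtvix
        val = n * np.log(se2) + logdet_m + np.log(xtvix) + quad
        return val if np.isfinite(val) else 1e12

    k = len(qs)
    x0 = np.log(np.full(k + 1, 1.0 / (k + 1)))
    bounds = [(np.log(1e-10), 10.0)] * k + [(np.log(floor), 10.0)]
    res = optimize.minimize(neg2reml, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
    polish = optimize.minimize(neg2reml, res.x, method="Nelder-Mead", bounds=bounds,
                               options={"xatol": 1e-12, "fatol": 1e-14,
                                        "maxiter": 20000, "maxfev": 20000})
    best = polish if polish.fun <= res.fun else res
    x = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
    out = np.exp(x) * sd * sd
    return out[:-1], out[-1]
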