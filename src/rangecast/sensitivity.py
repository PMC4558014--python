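"""Climate sensitivity: range stability, expansion, and category assignment.

For each species the projected change in its binary range decomposes into
*stability* (the fraction of the current range still suitable at a future
time; loss = 1 - stability) and *potential expansion* (newly suitable area
outside the current range, as a proportion of current range size; never
truncated here — truncation at 1 is a plotting convention only).

Categories, evaluated across emissions scenarios:

* **climate endangered** — loss of more than 50% of current range by 2050
  in *all* scenarios, with no net gain (expansion < loss at 2050, per
  scenario);
* **climate threatened** — not endangered, and loss of more than 50% by
  2080 in all scenarios (net gain from expansion possible);
* **climate stable** — everything else (loss of less than half in at least
  one scenario/horizon);
* **other** — introduced species or species only marginally inside the
  study area, regardless of projections.

Loss comparisons are strict (>50%); a species at exactly 50% loss is
stable.  Severity is monotone in loss: increasing any loss value can never
move a species to a less severe category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("endangered", "threatened", "stable", "other")
SEVERITY = {"endangered": 0, "threatened": 1, "stable": 2, "other": 3}
DEFAULT_SCENARIOS = ("A2", "A1B", "B2")


@dataclass
class SensitivityRecord:
    """Per-species loss/expansion by (scenario, period), flags, and category."""

    species_id: str
    season: str
    loss: dict = field(default_factory=dict)       # (scenario, period) -> L in [0, 1]
    expansion: dict = field(default_factory=dict)  # (scenario, period) -> E >= 0
    introduced: bool = False
    marginal: bool = False
    category: str = ""

    @property
    def flagged(self):
        return self.introduced or self.marginal

    def stability_of(self, scenario, period):
        return 1.0 - self.loss[(scenario, str(period))]


def _as_bool_grid(r):
    grid = r.grid if hasattr(r, "grid") else r
    return np.asarray(grid).astype(bool)


def stability(current, future) -> float:
    """Fraction of the current range retained in the future range."""
    cur, fut = _as_bool_grid(current), _as_bool_grid(future)
    if cur.shape != fut.shape:
        raise ValueError("current and future ranges are on different grids")
    n_cur = cur.sum()
    if n_cur == 0:
        raise ValueError("current range is empty; species is unmodelable")
    return float((cur & fut).sum() / n_cur)


def expansion(current, future) -> float:
    """Newly suitable cells outside the current range, / current range size."""
    cur, fut = _as_bool_grid(current), _as_bool_grid(future)
    if cur.shape != fut.shape:
        raise ValueError("current and future ranges are on different grids")
    n_cur = cur.sum()
    if n_cur == 0:
        raise ValueError("current range is empty; species is unmodelable")
    return float((fut & ~cur).sum() / n_cur)


def classify(record: SensitivityRecord, scenarios=DEFAULT_SCENARIOS) -> str:
    """Assign the climate sensitivity category for a record.

    ``scenarios`` restricts the evaluation (a single-scenario tuple gives
    the per-scenario classification used in the seasonal count tables).
    """
    if record.flagged:
        return "other"
    for scen in scenarios:
        for per in ("2050", "2080"):
            if (scen, per) not in record.loss:
                raise KeyError(f"{record.species_id}: loss missing for "
                               f"scenario {scen}, period {per}")
            if (scen, per) not in record.expansion:
                raise KeyError(f"{record.species_id}: expansion missing for "
                               f"scenario {scen}, period {per}")
    endangered = all(
        record.loss[(s, "2050")] > 0.5
        and record.expansion[(s, "2050")] < record.loss[(s, "2050")]
        for s in scenarios)
    if endangered:
        return "endangered"
    if all(record.loss[(s, "2080")] > 0.5 for s in scenarios):
        return "threatened"
    return "stable"


def combine_seasons(breeding_cat, nonbreeding_cat):
    """Overall category across seasons: the more severe one wins.

    Returns ``(overall, detail)`` where detail is ``"one-season"`` or
    ``"both-seasons"`` depending on whether both seasons share the overall
    category (single-season species are one-season by definition).
    """
    cats = [c for c in (breeding_cat, nonbreeding_cat) if c]
    if not cats:
        raise ValueError("at least one season must be present")
    non_other = [c for c in cats if c != "other"]
    if not non_other:
        return "other", "both-seasons" if len(cats) == 2 else "one-season"
    overall = min(non_other, key=lambda c: SEVERITY[c])
    detail = "both-seasons" if cats.count(overall) == 2 else "one-season"
    return overall, detail


def tabulate_categories(records, scenarios=DEFAULT_SCENARIOS) -> pd.DataFrame:
    """Season x scenario category counts (one row per season and scenario,
    plus an all-scenarios row per season and a combined either-season row).

    Rows are indexed by (season, scenario_label); columns are the four
    categories.  Within each row the counts partition the season's species.
    """
    recs = list(records)
    by_season = {}
    for r in recs:
        by_season.setdefault(r.season, []).append(r)

    rows = {}
    for season, rs in sorted(by_season.items()):
        for scen in scenarios:
            rows[(season, scen)] = _count([classify(r, (scen,)) for r in rs])
        rows[(season, "all")] = _count([classify(r, scenarios) for r in rs])

    # combined either-season row under the all-scenarios rule
    per_species = {}
    for r in recs:
        per_species.setdefault(r.species_id, {})[r.season] = classify(r, scenarios)
    combined = [combine_seasons(d.get("breeding"), d.get("nonbreeding"))[0]
                for d in per_species.values()]
    rows[("either", "all")] = _count(combined)

    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(CATEGORIES))
    df.index = pd.MultiIndex.from_tuples(df.index, names=["season", "scenario"])
    return df


def _count(cats):
    return [sum(c == k for c in cats) for k in CATEGORIES]
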