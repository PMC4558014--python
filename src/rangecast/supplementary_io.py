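"""Parsing published per-species summary tables from CSV exports.

The journal's supplementary appendices ship as spreadsheets; this module
consumes CSV exports of them, with a user-editable *schema map* translating
whatever column names the export carries into the canonical field names the
pipeline uses.  Loss/expansion fields given as percentages ("62%" or 62)
are normalised to proportions.

Canonical species-summary fields:

* ``species_id``, ``season`` (breeding | nonbreeding)
* ``loss_<scenario>_<period>`` — proportional loss of current range
* ``expansion_<scenario>_<period>`` — potential expansion / current range,
  or alternatively ``change_<scenario>_<period>`` (relative change in range
  size), from which expansion is recovered as ``change + loss``
* ``introduced``, ``marginal`` — flags
* ``category`` — the published category, if the export carries one
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bioclim import PERIODS, SCENARIOS
from .priority_stats import FED_BCC_RANKS, IUCN_RANKS
from .sensitivity import CATEGORIES, SensitivityRecord

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", "", "nan"}


def _to_bool(series):
    def conv(v):
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return True
        if s in _FALSY:
            return False
        raise ValueError(f"cannot interpret {v!r} as a boolean flag")
    return series.map(conv)


def _to_proportion(series, column):
    """Numeric loss/expansion column, percent-vs-proportion auto-detected."""
    s = series.astype(str).str.strip()
    pct = s.str.endswith("%")
    vals = pd.to_numeric(s.str.rstrip("%"), errors="coerce").astype(float)
    if pct.any():
        vals[pct] = vals[pct] / 100.0
    finite = vals.dropna()
    # a loss/expansion column whose magnitudes run past 1.5 is in percent
    if len(finite) and finite.abs().max() > 1.5:
        vals = vals / 100.0
    return vals


def _apply_schema(df, schema_map):
    if not schema_map:
        return df.copy()
    missing = {}
    renames = {}
    for canonical, column in schema_map.items():
        if column not in df.columns:
            missing[canonical] = column
        else:
            renames[column] = canonical
    if missing:
        raise ValueError(
            f"columns not found for schema entries {missing}; "
            f"available columns: {list(df.columns)}")
    return df.rename(columns=renames)


def read_species_summaries(path, schema_map=None) -> pd.DataFrame:
    """Read an S1-style per-species range-change summary into canonical form.

    Returns one row per species x season with proportional losses, expansion
    (derived from range-size change when not given directly), flags, and
    the published category when present.
    """
    raw = pd.read_csv(path)
    df = _apply_schema(raw, schema_map)
    if "species_id" not in df or "season" not in df:
        raise ValueError(
            f"species_id and season columns are required; found {list(df.columns)}")
    out = pd.DataFrame({"species_id": df["species_id"].astype(str),
                        "season": df["season"].astype(str)})
    for scen in SCENARIOS:
        for per in PERIODS:
            lcol, ecol, ccol = (f"loss_{scen}_{per}", f"expansion_{scen}_{per}",
                                f"change_{scen}_{per}")
            if lcol in df:
                out[lcol] = _to_proportion(df[lcol], lcol)
            if ecol in df:
                out[ecol] = _to_proportion(df[ecol], ecol)
            elif ccol in df and lcol in out:
                out[ecol] = _to_proportion(df[ccol], ccol) + out[lcol]
    for flag in ("introduced", "marginal"):
        out[flag] = _to_bool(df[flag]) if flag in df else False
    if "category" in df:
        cat = df["category"].astype(str).str.strip().str.lower()
        bad = ~cat.isin(CATEGORIES)
        if bad.any():
            raise ValueError(f"unknown categories in export: "
                             f"{sorted(cat[bad].unique())}")
        out["category"] = cat
    loss_cols = [c for c in out.columns if c.startswith("loss_")]
    bad = out[loss_cols].stack().pipe(lambda s: s[(s < 0) | (s > 1)])
    if len(bad):
        raise ValueError(f"loss values outside [0, 1] after normalisation: "
                         f"{bad.head().to_dict()}")
    return out


def to_sensitivity_records(summaries: pd.DataFrame):
    """Convert canonical summary rows into SensitivityRecord objects."""
    records = []
    for _, row in summaries.iterrows():
        loss, expn = {}, {}
        for scen in SCENARIOS:
            for per in PERIODS:
                lcol, ecol = f"loss_{scen}_{per}", f"expansion_{scen}_{per}"
                if lcol in row and pd.notna(row[lcol]):
                    loss[(scen, per)] = float(row[lcol])
                if ecol in row and pd.notna(row[ecol]):
                    expn[(scen, per)] = float(row[ecol])
        records.append(SensitivityRecord(
            species_id=row["species_id"], season=row["season"],
            loss=loss, expansion=expn,
            introduced=bool(row["introduced"]), marginal=bool(row["marginal"])))
    return records


def read_status_table(path, schema_map=None) -> pd.DataFrame:
    """Read an S7-style conservation-status table.

    Canonical columns: ``species_id`` plus any of ``audubon_category``,
    ``iucn_status``, ``fed_bcc_status``, ``pif_score``.  Status strings are
    validated against the controlled vocabularies; missing values are
    preserved as missing.
    """
    raw = pd.read_csv(path)
    df = _apply_schema(raw, schema_map)
    if "species_id" not in df:
        raise ValueError(f"species_id column required; found {list(df.columns)}")
    keep = [c for c in ("species_id", "audubon_category", "iucn_status",
                        "fed_bcc_status", "pif_score") if c in df.columns]
    out = df[keep].copy()
    vocab = {"audubon_category": set(CATEGORIES),
             "iucn_status": set(IUCN_RANKS),
             "fed_bcc_status": set(FED_BCC_RANKS)}
    for col, allowed in vocab.items():
        if col not in out:
            continue
        norm = (out[col].astype(str).str.strip().str.lower()
                .str.replace(r"[ /-]+", "_", regex=True))
        norm[out[col].isna()] = np.nan
        bad = norm.dropna()[~norm.dropna().isin(allowed)]
        if len(bad):
            raise ValueError(f"unknown {col} value(s) {sorted(bad.unique())}; "
                             f"allowed: {sorted(allowed)}")
        out[col] = norm
    if "pif_score" in out:
        out["pif_score"] = pd.to_numeric(out["pif_score"], errors="coerce")
    return out
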