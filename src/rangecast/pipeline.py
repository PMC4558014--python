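"""End-to-end orchestration: simulate -> bioclim -> fit -> project -> classify
-> summarise -> stats, from a single seeded configuration.

A run generates a synthetic landscape and baseline climate, draws a species
cohort with known truth, samples survey records, fits one boosted-tree
occurrence model per species, projects it onto consensus future climates
built by the delta method, delineates max-Kappa ranges, classifies each
species' climate sensitivity, and produces the downstream biogeographic and
statistical summaries.  Everything is reproducible from (config, seed), and
every output table carries the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biogeo, gridio, priority_stats, ranges, sdm, sensitivity
from .bioclim import (BIO_NAMES, MonthlyClimate, PERIODS, SCENARIOS,
                      compute_bioclim, delta_downscale)
from . import synthetic_data as synth

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full synthetic run."""

    # landscape
    nx: int = 100
    ny: int = 100
    cell_size: float = 10.0  # km
    # species cohort
    n_species: int = 30
    archetype_mix: dict = field(default_factory=lambda: {
        "shrinker": 1 / 3, "shifter": 1 / 3, "stable": 1 / 3})
    n_flagged: int = 0
    # survey
    n_sites: int = 500
    train_years: tuple = (2000, 2009)   # inclusive ranges
    test_years: tuple = (1980, 1999)
    test_only_site_fraction: float = 0.1
    detect_beta: float = 0.3
    # climate futures: per-scenario GCM counts (13 combinations by default)
    gcms_per_scenario: dict = field(default_factory=lambda: {
        "A2": 5, "A1B": 4, "B2": 4})
    gcm_jitter_sd: float = 0.3
    coarse_factor: int = 4  # anomaly grids are this much coarser than baseline
    # modelling
    bioclim_subset: tuple = BIO_NAMES
    model: sdm.ModelSettings = field(default_factory=sdm.ModelSettings)
    # statistics
    status_alignment: float = 0.5
    # bookkeeping
    seed: int = 0
    outdir: str = ""

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "model" in raw:
            raw["model"] = sdm.ModelSettings(**raw["model"])
        return cls(**raw)

    def hash(self):
        d = asdict(self)
        d["model"] = vars(self.model) if not isinstance(self.model, dict) else self.model
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    config: RunConfig
    landscape: object = None
    species: list = field(default_factory=list)
    truth: object = None
    models: dict = field(default_factory=dict)        # species_id -> SDMModel
    skipped: dict = field(default_factory=dict)       # species_id -> reason
    metrics: pd.DataFrame = None
    metrics_spatial: pd.DataFrame = None
    current_ranges: dict = field(default_factory=dict)
    future_ranges: dict = field(default_factory=dict)  # (sp, scen, per) -> RangeMap
    records: list = field(default_factory=list)        # SensitivityRecord
    categories: dict = field(default_factory=dict)
    combined: pd.DataFrame = None
    category_table: pd.DataFrame = None
    species_summaries: pd.DataFrame = None
    recovery: pd.DataFrame = None
    centroid_shifts: pd.DataFrame = None
    community: dict = field(default_factory=dict)      # season -> (grids, dissim, mean)
    correlations: pd.DataFrame = None
    var_components: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    @property
    def recovery_rate(self):
        return float(self.recovery["recovered"].mean()) if len(self.recovery) else np.nan


def _seed(base, *keys):
    """Stable 31-bit sub-seed from the run seed and a stage/key path."""
    parts = [int(base)] + [zlib.crc32(str(k).encode()) for k in keys]
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2 ** 31))


def _coarsen(mc: MonthlyClimate, factor: int) -> MonthlyClimate:
    """Block-mean a monthly climate onto a grid coarser by ``factor``."""
    def block(a):
        m, ny, nx = a.shape
        ny2, nx2 = ny // factor * factor, nx // factor * factor
        a = a[:, :ny2, :nx2]
        return a.reshape(m, ny2 // factor, factor, nx2 // factor, factor).mean(axis=(2, 4))
    tmin, tmax, prec = block(mc.tmin), block(mc.tmax), block(mc.prec)
    return MonthlyClimate(tmin=tmin, tmax=tmax, prec=prec, period=mc.period,
                          scenario=mc.scenario, gcm=mc.gcm)


def _years(span):
    return list(range(span[0], span[1] + 1))


def run_end_to_end(config: RunConfig) -> RunResult:
    """Execute the full pipeline; returns all artifacts, writing them to
    ``config.outdir`` when set."""
    t_start = time.time()
    cfg = config
    res = RunResult(config=cfg)
    timings = res.timings

    # --- landscape, baseline climate, truth ------------------------------
    t0 = time.time()
    ls = synth.make_landscape(cfg.nx, cfg.ny, cfg.cell_size, seed=_seed(cfg.seed, "landscape"))
    base_mc = synth.make_baseline_climate(ls, seed=_seed(cfg.seed, "climate"))
    base_bio = compute_bioclim(base_mc)
    res.landscape = ls

    species = synth.make_species(cfg.n_species, cfg.archetype_mix, base_bio,
                                 seed=_seed(cfg.seed, "species"),
                                 n_flagged=cfg.n_flagged)
    res.species = species

    truth_bios = {}
    for scen in cfg.gcms_per_scenario:
        for per in PERIODS:
            mc = synth.make_future_climate(base_mc, scen, per, gcm_jitter_sd=0.0,
                                           gcm="truth")
            truth_bios[(scen, per)] = compute_bioclim(mc)
    res.truth = synth.build_truth(species, base_bio, truth_bios)
    timings["simulate"] = time.time() - t0

    # --- survey and occurrence sampling ----------------------------------
    t0 = time.time()
    all_years = sorted(set(_years(cfg.train_years)) | set(_years(cfg.test_years)))
    survey = synth.make_survey_design(ls, n_sites=cfg.n_sites, years=all_years,
                                      seed=_seed(cfg.seed, "survey"))
    # extra sites surveyed only in the test decades, for the spatially
    # independent re-evaluation
    n_extra = int(round(cfg.test_only_site_fraction * cfg.n_sites))
    if n_extra:
        extra = synth.make_survey_design(ls, n_sites=n_extra,
                                         years=_years(cfg.test_years),
                                         seed=_seed(cfg.seed, "survey-extra"))
        sy = extra.site_years.copy()
        sy["site_id"] = sy["site_id"].str.replace("site", "xsite", regex=False)
        survey = synth.SurveyDesign(
            site_years=pd.concat([survey.site_years, sy], ignore_index=True),
            cell_size=survey.cell_size, extent=survey.extent)

    site_covs = sdm.attach_bioclim_covariates(
        survey.site_years, base_bio, ls.cell_size, cfg.bioclim_subset)
    timings["survey"] = time.time() - t0

    # --- per-species model fitting and evaluation -------------------------
    t0 = time.time()
    metrics_rows, spatial_rows = [], []
    thresholds, constants = {}, {}
    for sp in species:
        suit = synth.true_suitability(sp, base_bio)
        occ = synth.sample_occurrences(suit, survey, detect_beta=cfg.detect_beta,
                                       seed=_seed(cfg.seed, "occ", sp.species_id),
                                       species_id=sp.species_id, season=sp.season)
        occ[list(cfg.bioclim_subset)] = site_covs[list(cfg.bioclim_subset)].to_numpy()
        # the survey covariate the emitted table blanks for the other season
        scov = sdm.survey_covariate(sp.season)
        occ[scov] = survey.site_years[scov].to_numpy()
        train, test = sdm.split_train_test(occ, _years(cfg.train_years),
                                           _years(cfg.test_years))
        covars = list(cfg.bioclim_subset) + [scov]
        try:
            model = sdm.fit_brt(train, covars, settings=cfg.model,
                                seed=_seed(cfg.seed, "fit", sp.species_id),
                                species_id=sp.species_id, season=sp.season)
        except sdm.InsufficientDataError as exc:
            log.warning("skipping %s: %s", sp.species_id, exc)
            res.skipped[sp.species_id] = str(exc)
            continue
        res.models[sp.species_id] = model
        m = sdm.evaluate(model, test)
        metrics_rows.append(vars(m))
        indep = sdm.spatially_independent_subset(test, train)
        if len(indep) and indep["presence"].nunique() == 2:
            spatial_rows.append(vars(sdm.evaluate(model, indep)))
        # threshold fitted once per species on training-period data
        thr, _curve = ranges.max_kappa_threshold(
            train["presence"].to_numpy(), model.predict(train))
        thresholds[sp.species_id] = thr
        constants[sp.species_id] = {scov: float(train[scov].median())}
    res.metrics = pd.DataFrame(metrics_rows)
    res.metrics_spatial = pd.DataFrame(spatial_rows)
    if len(res.metrics) >= 3:
        res.metrics = sdm.model_qc_filter(res.metrics)
    else:
        res.metrics["keep"] = True
    timings["fit"] = time.time() - t0

    kept = [sp for sp in species if sp.species_id in res.models
            and bool(res.metrics.set_index("species_id")["keep"].get(sp.species_id, True))]

    # --- current ranges ----------------------------------------------------
    t0 = time.time()
    modeled = []
    for sp in kept:
        model = res.models[sp.species_id]
        surf = sdm.predict_suitability(model, base_bio, constants[sp.species_id])
        rmap = ranges.binarize(surf, thresholds[sp.species_id],
                               species_id=sp.species_id, season=sp.season,
                               scenario="none", period="base")
        if rmap.n_cells == 0:
            log.warning("%s: empty current range; species unmodelable", sp.species_id)
            res.skipped[sp.species_id] = "empty current range"
            continue
        res.current_ranges[sp.species_id] = rmap
        modeled.append(sp)

    # --- future projections: per-GCM grids, consensus, ranges -------------
    ref_coarse = _coarsen(base_mc, cfg.coarse_factor)
    ens_suit = {}  # (species_id, scen, per) -> consensus surface
    for scen, n_gcm in cfg.gcms_per_scenario.items():
        for per in PERIODS:
            fut_bios = []
            for g in range(n_gcm):
                mc = synth.make_future_climate(
                    base_mc, scen, per, gcm_jitter_sd=cfg.gcm_jitter_sd,
                    seed=_seed(cfg.seed, "gcm", scen, g), gcm=f"gcm{g + 1}")
                fine = delta_downscale(base_mc, _coarsen(mc, cfg.coarse_factor),
                                       ref_coarse)
                fut_bios.append(compute_bioclim(fine))
            for sp in modeled:
                model = res.models[sp.species_id]
                surfaces = [sdm.predict_suitability(model, fb, constants[sp.species_id])
                            for fb in fut_bios]
                ens = ranges.ensemble(surfaces,
                                      labels=[(fb.scenario, fb.period) for fb in fut_bios])
                ens_suit[(sp.species_id, scen, per)] = ens
                res.future_ranges[(sp.species_id, scen, per)] = ranges.binarize(
                    ens, thresholds[sp.species_id], species_id=sp.species_id,
                    season=sp.season, scenario=scen, period=per)
    timings["project"] = time.time() - t0

    # --- sensitivity classification ---------------------------------------
    t0 = time.time()
    scen_list = tuple(cfg.gcms_per_scenario)
    for sp in modeled:
        cur = res.current_ranges[sp.species_id]
        loss, expn = {}, {}
        for scen in scen_list:
            for per in PERIODS:
                fut = res.future_ranges[(sp.species_id, scen, per)]
                loss[(scen, per)] = 1.0 - sensitivity.stability(cur, fut)
                expn[(scen, per)] = sensitivity.expansion(cur, fut)
        rec = sensitivity.SensitivityRecord(
            species_id=sp.species_id, season=sp.season, loss=loss, expansion=expn,
            introduced=sp.introduced, marginal=sp.marginal)
        rec.category = sensitivity.classify(rec, scen_list)
        res.records.append(rec)
        res.categories[sp.species_id] = rec.category
    res.category_table = sensitivity.tabulate_categories(res.records, scen_list)

    by_sp = {}
    for rec in res.records:
        by_sp.setdefault(rec.species_id, {})[rec.season] = rec.category
    res.combined = pd.DataFrame(
        [(spid, *sensitivity.combine_seasons(d.get("breeding"), d.get("nonbreeding")))
         for spid, d in by_sp.items()],
        columns=["species_id", "category", "seasons"])

    res.recovery = pd.DataFrame(
        [(sp.species_id, sp.archetype, res.truth.expected[sp.species_id],
          res.categories[sp.species_id],
          res.categories[sp.species_id] == res.truth.expected[sp.species_id])
         for sp in modeled],
        columns=["species_id", "archetype", "expected", "assigned", "recovered"])
    res.species_summaries = _species_summary_table(res, scen_list)
    timings["classify"] = time.time() - t0

    # --- biogeographic summaries (highest-emissions end-of-century) -------
    t0 = time.time()
    shift_rows = []
    for sp in modeled:
        cur = res.current_ranges[sp.species_id]
        fut = res.future_ranges[(sp.species_id, "A2", "2080")]
        if fut.n_cells == 0:
            continue
        c0 = biogeo.weighted_centroid(cur, ls, sp.species_id, sp.season, "base")
        c1 = biogeo.weighted_centroid(fut, ls, sp.species_id, sp.season, "2080")
        north, up, inland = biogeo.centroid_shift(c0, c1)
        shift_rows.append((sp.species_id, sp.season, north, up, inland))
    res.centroid_shifts = biogeo.centroid_shift_table(shift_rows)

    for season in ("breeding", "nonbreeding"):
        sps = [sp for sp in modeled if sp.season == season]
        if not sps:
            continue
        cur = [res.current_ranges[sp.species_id] for sp in sps]
        fut = [res.future_ranges[(sp.species_id, "A2", "2080")] for sp in sps]
        grids = biogeo.richness_change(cur, fut)
        dmap, dmean = biogeo.dissimilarity_map(cur, fut)
        res.community[season] = {"grids": grids, "dissimilarity": dmap,
                                 "mean_dissimilarity": dmean}
    timings["summarize"] = time.time() - t0

    # --- rank correlations and variance components ------------------------
    t0 = time.time()
    statuses = synth.make_conservation_statuses(
        modeled, res.categories, seed=_seed(cfg.seed, "statuses"),
        alignment=cfg.status_alignment)
    statuses["audubon_category"] = statuses["species_id"].map(res.categories)
    ranked = priority_stats.assign_ranks(statuses)
    corr_rows = []
    for scheme, col in (("iucn", "iucn_rank"), ("fed_bcc", "fed_bcc_rank"),
                        ("pif", "pif_rank")):
        sub = ranked[["audubon_rank", col]].dropna()
        try:
            tau_b, p = priority_stats.kendall_tau(sub["audubon_rank"], sub[col])
            tau_a = priority_stats.kendall_tau_a(sub["audubon_rank"], sub[col])
        except ValueError as exc:
            log.warning("correlation %s skipped: %s", scheme, exc)
            continue
        corr_rows.append((scheme, tau_b, tau_a, p, len(sub)))
    res.correlations = pd.DataFrame(
        corr_rows, columns=["scheme", "tau_b", "tau_a", "p_value", "n"])

    vc_rows = []
    for sp in modeled:
        cur_area, _ = ranges.range_size(res.current_ranges[sp.species_id], ls.cell_area)
        for scen in scen_list:
            fut_area, _ = ranges.range_size(
                res.future_ranges[(sp.species_id, scen, "2080")], ls.cell_area)
            rec = next(r for r in res.records if r.species_id == sp.species_id)
            vc_rows.append((sp.species_id, sp.season, sp.archetype, scen,
                            priority_stats.relative_change(cur_area, fut_area),
                            rec.stability_of(scen, "2080")))
    vc = pd.DataFrame(vc_rows, columns=["species_id", "season", "archetype",
                                        "scenario", "relative_change", "stability"])
    for response in ("relative_change", "stability"):
        res.var_components[response] = priority_stats.variance_components(
            vc[response], vc[["species_id", "archetype", "scenario"]])
    res.var_components["observations"] = vc
    timings["stats"] = time.time() - t0
    timings["total"] = time.time() - t_start

    if cfg.outdir:
        write_outputs(res, Path(cfg.outdir))
    return res


def _species_summary_table(res: RunResult, scenarios) -> pd.DataFrame:
    """Per-species loss/expansion table mirroring the published appendix layout."""
    rows = []
    for rec in res.records:
        row = {"species_id": rec.species_id, "season": rec.season,
               "introduced": rec.introduced, "marginal": rec.marginal,
               "category": rec.category}
        for (scen, per), v in sorted(rec.loss.items()):
            row[f"loss_{scen}_{per}"] = v
            row[f"expansion_{scen}_{per}"] = rec.expansion[(scen, per)]
            row[f"change_{scen}_{per}"] = rec.expansion[(scen, per)] - v
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(res: RunResult, outdir: Path):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = res.config
    stamp = {"config_hash": cfg.hash(), "seed": cfg.seed}

    def save(df, name):
        df = df.copy()
        for k, v in stamp.items():
            df[k] = v
        df.to_csv(outdir / name, index=isinstance(df.index, pd.MultiIndex))

    save(res.species_summaries, "species_summaries.csv")
    save(res.category_table.reset_index(), "category_counts.csv")
    save(res.combined, "combined_categories.csv")
    save(res.recovery, "truth_recovery.csv")
    save(res.metrics, "model_metrics.csv")
    if res.metrics_spatial is not None and len(res.metrics_spatial):
        save(res.metrics_spatial, "model_metrics_spatially_independent.csv")
    save(res.centroid_shifts, "centroid_shifts.csv")
    if res.correlations is not None:
        save(res.correlations, "rank_correlations.csv")
    for response in ("relative_change", "stability"):
        if response in res.var_components:
            save(res.var_components[response].to_frame(),
                 f"variance_components_{response}.csv")
    for season, comm in res.community.items():
        for layer in ("gain", "loss"):
            gridio.write_ascii_grid(outdir / f"{layer}_{season}_A2_2080.asc",
                                    getattr(comm["grids"], layer), cfg.cell_size)
        gridio.write_ascii_grid(outdir / f"dissimilarity_{season}_A2_2080.asc",
                                comm["dissimilarity"], cfg.cell_size)
    runlog = {"config_hash": cfg.hash(), "seed": cfg.seed,
              "timings_s": {k: round(v, 2) for k, v in res.timings.items()},
              "n_species": len(res.species), "n_modeled": len(res.models),
              "skipped": res.skipped,
              "recovery_rate": res.recovery_rate,
              "versions": _versions()}
    (outdir / "run_log.json").write_text(json.dumps(runlog, indent=2))


def _versions():
    import sklearn
    import xgboost
    import scipy
    return {"numpy": np.__version__, "pandas": pd.__version__,
            "scipy": scipy.__version__, "scikit-learn": sklearn.__version__,
            "xgboost": xgboost.__version__}


def reproduce_published(s1_csv=None, s7_csv=None, s1_schema=None, s7_schema=None,
                        references=None):
    """Re-derive headline counts and rank correlations from supplementary
    CSV exports.

    ``s1_csv`` (per-species loss/expansion summaries) yields classification
    counts per season and combined; ``s7_csv`` (conservation statuses)
    yields Kendall correlations (tau-b and tau-a).  ``references`` is an
    optional mapping of quantity name -> published value, echoed alongside
    computed values.  Missing files are skipped with a warning.
    """
    from . import supplementary_io as sio

    report = {}
    refs = dict(references or {})

    if s1_csv and Path(s1_csv).exists():
        summaries = sio.read_species_summaries(s1_csv, s1_schema)
        records = sio.to_sensitivity_records(summaries)
        for rec in records:
            rec.category = sensitivity.classify(rec)
        table = sensitivity.tabulate_categories(records)
        either = table.loc[("either", "all")]
        counts = {
            "endangered": int(either["endangered"]),
            "threatened": int(either["threatened"]),
            "endangered_or_threatened": int(either["endangered"] + either["threatened"]),
            "stable": int(either["stable"]),
            "other": int(either["other"]),
        }
        rows = [(k, v, refs.get(k)) for k, v in counts.items()]
        report["counts"] = pd.DataFrame(rows, columns=["quantity", "computed", "published"])
        report["category_table"] = table
    elif s1_csv:
        log.warning("species-summary export %s not found; skipping counts", s1_csv)

    if s7_csv and Path(s7_csv).exists():
        statuses = sio.read_status_table(s7_csv, s7_schema)
        ranked = priority_stats.assign_ranks(statuses)
        rows = []
        for scheme, col in (("iucn", "iucn_rank"), ("fed_bcc", "fed_bcc_rank"),
                            ("pif", "pif_rank")):
            if col not in ranked:
                continue
            sub = ranked[["audubon_rank", col]].dropna()
            tau_b, p = priority_stats.kendall_tau(sub["audubon_rank"], sub[col])
            tau_a = priority_stats.kendall_tau_a(sub["audubon_rank"], sub[col])
            rows.append((scheme, tau_b, tau_a, p, len(sub), refs.get(f"tau_{scheme}")))
        report["correlations"] = pd.DataFrame(
            rows, columns=["scheme", "tau_b", "tau_a", "p_value", "n", "published"])
    elif s7_csv:
        log.warning("status export %s not found; skipping correlations", s7_csv)

    return report
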