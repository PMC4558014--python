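"""Synthetic landscapes, climates, virtual species, and survey data.

Everything downstream of this module (bioclim derivation, SDM fitting,
range delineation, sensitivity classification, biogeographic summaries) can
be exercised against data generated here, for which exact ground truth is
known.

The generator emulates the structure of continental survey data:

* a gridded landscape with elevation, distance to a western coastline, and
  a south-to-north latitude gradient;
* monthly baseline climate (latitudinal + lapse-rate temperature structure,
  seasonal cycle, coastal precipitation gradient);
* future climates under three emissions scenarios x three periods, with
  per-GCM spatially smooth jitter standing in for the spread of circulation
  models;
* virtual species whose occurrence probability is a product of independent
  Gaussian responses to bioclimatic variables, in three archetypes:
  *shrinkers* (optima in cold climate states that disappear under warming),
  *shifters* (optima that translate spatially), and *stable* species (broad
  tolerances);
* presence/absence records at survey sites, with detection saturating in
  survey effort: ``P(detect) = suitability * (1 - exp(-beta * hours))``.

Occupancy and detection are deliberately conflated into a single Bernoulli
probability; effort enters the fitted models as a covariate rather than as
a separate detection layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .bioclim import BioclimGrid, MonthlyClimate, PERIODS, SCENARIOS, extract_at_points
from . import ranges as _ranges
from . import sensitivity as _sensitivity

ARCHETYPES = ("shrinker", "shifter", "stable")

#: archetype -> (quantile of baseline bio01 at the niche optimum, niche breadth degC)
ARCHETYPE_NICHE = {
    "shrinker": (0.02, 0.6),
    "shifter": (0.40, 1.6),
    "stable": (0.50, 5.0),
}

#: category each archetype is engineered to receive (unflagged species)
ARCHETYPE_CATEGORY = {
    "shrinker": "endangered",
    "shifter": "threatened",
    "stable": "stable",
}

#: additive warming (degC) per scenario and period, ordered B2 < A1B < A2
#: and 2020 < 2050 < 2080, mimicking SRES trajectories
WARMING_C = {
    "A2": {"2020": 1.1, "2050": 2.2, "2080": 4.0},
    "A1B": {"2020": 1.0, "2050": 1.9, "2080": 3.2},
    "B2": {"2020": 0.8, "2050": 1.3, "2080": 2.8},
}

#: multiplicative precipitation change per scenario and period (mild drying)
PREC_MULT = {
    "A2": {"2020": 0.97, "2050": 0.93, "2080": 0.88},
    "A1B": {"2020": 0.98, "2050": 0.95, "2080": 0.91},
    "B2": {"2020": 0.98, "2050": 0.96, "2080": 0.93},
}

#: truth ranges are cells with suitability >= TRUTH_LEVEL * p_max
TRUTH_LEVEL = 0.5


@dataclass
class Landscape:
    """Gridded study area: elevation (m), distance to coast (km), latitude (degN).

    Arrays are (ny, nx) with row index increasing northward.  ``latitude``
    is one value per row and strictly monotone.
    """

    nx: int
    ny: int
    cell_size: float  # km
    elevation: np.ndarray
    dist_coast: np.ndarray
    latitude: np.ndarray  # (ny,)

    def __post_init__(self):
        if not np.all(np.isfinite(self.elevation)):
            raise ValueError("elevation contains non-finite values")
        if np.any(self.dist_coast < 0):
            raise ValueError("dist_coast must be >= 0")
        dlat = np.diff(self.latitude)
        if not (np.all(dlat > 0) or np.all(dlat < 0)):
            raise ValueError("latitude must be strictly monotone across rows")

    @property
    def latitude_grid(self):
        return np.broadcast_to(self.latitude[:, None], (self.ny, self.nx))

    @property
    def cell_area(self):
        return self.cell_size ** 2


@dataclass
class NicheSpec:
    """Gaussian niche of a virtual species over selected bioclim variables."""

    species_id: str
    season: str  # breeding | nonbreeding
    response: dict  # variable name -> (optimum mu, breadth sigma)
    p_max: float
    archetype: str
    introduced: bool = False
    marginal: bool = False

    def __post_init__(self):
        if not (0.0 < self.p_max <= 1.0):
            raise ValueError(f"p_max must be in (0, 1], got {self.p_max}")
        for var, (mu, sigma) in self.response.items():
            if sigma <= 0:
                raise ValueError(f"sigma for {var} must be > 0, got {sigma}")

    @property
    def flagged(self):
        return self.introduced or self.marginal


@dataclass
class SurveyDesign:
    """Survey sites and per site-year covariates.

    ``site_years`` has one row per site x year with columns site_id, x, y,
    year, effort_hours (the non-breeding analog of count-circle
    party-hours), and ordinal_date (the breeding analog of route survey
    day-of-year).
    """

    site_years: pd.DataFrame
    cell_size: float
    extent: tuple  # (x_max, y_max) in km

    def __post_init__(self):
        sy = self.site_years
        if (sy["effort_hours"] <= 0).any():
            raise ValueError("effort_hours must be > 0")
        if ((sy["ordinal_date"] < 1) | (sy["ordinal_date"] > 366)).any():
            raise ValueError("ordinal_date must be in [1, 366]")
        xmax, ymax = self.extent
        if ((sy["x"] < 0) | (sy["x"] > xmax) | (sy["y"] < 0) | (sy["y"] > ymax)).any():
            raise ValueError("site coordinates outside landscape")

    @property
    def sites(self):
        return self.site_years.drop_duplicates("site_id")[["site_id", "x", "y"]]

    @property
    def years(self):
        return sorted(self.site_years["year"].unique())


def _smooth_field(rng, shape, sigma_cells):
    """Spatially autocorrelated field with zero mean and unit variance."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=sigma_cells, mode="reflect")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def make_landscape(nx, ny, cell_size=10.0, seed=0, lat_range=(30.0, 60.0),
                   elev_base=500.0, elev_relief=150.0):
    """Generate a landscape with a western coastline and northward latitude.

    Elevation is a smooth (spatially autocorrelated) field, floored at sea
    level; the coast is the westernmost column of cells, and distance to
    coast is the Euclidean distance transform in km.
    """
    if nx < 10 or ny < 10:
        raise ValueError(f"grid must be at least 10x10, got {nx}x{ny}")
    rng = np.random.default_rng(seed)
    elevation = np.maximum(0.0, elev_base + elev_relief * _smooth_field(rng, (ny, nx), max(nx, ny) / 12))
    coast = np.ones((ny, nx), dtype=bool)
    coast[:, 0] = False  # coastline cells
    dist_coast = ndimage.distance_transform_edt(coast) * cell_size
    latitude = np.linspace(lat_range[0], lat_range[1], ny)
    return Landscape(nx=nx, ny=ny, cell_size=cell_size, elevation=elevation,
                     dist_coast=dist_coast, latitude=latitude)


def make_baseline_climate(landscape, lapse_rate=-0.0065, seasonal_amplitude=10.0,
                          seed=0, t_south=14.0, lat_gradient=-0.6,
                          diurnal_range=8.0, noise_sd=0.5,
                          prec_coast=100.0, prec_inland=40.0, prec_decay_km=250.0,
                          prec_seasonal=0.3, prec_noise_sd=5.0):
    """Baseline monthly climate for the reference period.

    Annual-mean minimum temperature is a latitudinal gradient plus a
    lapse-rate elevation term plus a small smooth noise field; months add a
    sinusoidal seasonal cycle (mean-zero over the year) peaking in July.
    ``tmax = tmin + diurnal_range``.  Monthly precipitation decays from the
    coast inland with its own seasonal cycle, floored at 0.
    """
    if lapse_rate > 0:
        raise ValueError("lapse_rate must be <= 0 degC/m")
    rng = np.random.default_rng(seed)
    ls = landscape
    t_annual = (t_south + lat_gradient * (ls.latitude_grid - ls.latitude.min())
                + lapse_rate * ls.elevation
                + noise_sd * _smooth_field(rng, (ls.ny, ls.nx), max(ls.nx, ls.ny) / 15))
    months = np.arange(12)
    seasonal = seasonal_amplitude * np.cos(2 * np.pi * (months - 6) / 12.0)
    tmin = t_annual[None, :, :] + seasonal[:, None, None]
    tmax = tmin + diurnal_range

    p_annual = (prec_inland + (prec_coast - prec_inland) * np.exp(-ls.dist_coast / prec_decay_km)
                + prec_noise_sd * _smooth_field(rng, (ls.ny, ls.nx), max(ls.nx, ls.ny) / 15))
    p_seasonal = 1.0 + prec_seasonal * np.cos(2 * np.pi * months / 12.0)
    prec = np.maximum(p_annual[None, :, :] * p_seasonal[:, None, None], 0.0)
    return MonthlyClimate(tmin=tmin, tmax=tmax, prec=prec, period="base")


def make_future_climate(baseline, scenario, period, gcm_jitter_sd=0.3, seed=0,
                        gcm=None):
    """Future monthly climate: additive warming plus smooth per-GCM jitter.

    Warming and precipitation multipliers come from :data:`WARMING_C` and
    :data:`PREC_MULT`; within a scenario the warming is ordered
    2020 <= 2050 <= 2080.  The jitter field (one per GCM seed) is shared by
    tmin and tmax so the diurnal range is preserved.
    """
    period = str(period)
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}; expected one of {PERIODS}")
    rng = np.random.default_rng(seed)
    shape = baseline.shape
    jitter = 0.0
    if gcm_jitter_sd > 0:
        jitter = gcm_jitter_sd * _smooth_field(rng, shape, max(shape) / 12)
    delta = WARMING_C[scenario][period] + jitter
    return MonthlyClimate(
        tmin=baseline.tmin + delta,
        tmax=baseline.tmax + delta,
        prec=np.maximum(baseline.prec * PREC_MULT[scenario][period], 0.0),
        period=period, scenario=scenario,
        gcm=gcm if gcm is not None else f"gcm{seed}")


def make_species(n_species, archetype_mix, baseline, seed=0, n_flagged=0,
                 niche_var="bio01", seasons=("breeding", "nonbreeding")):
    """Draw a cohort of virtual species with archetype-calibrated niches.

    Optima are placed at archetype-specific quantiles of the baseline
    ``niche_var`` distribution over cells (see :data:`ARCHETYPE_NICHE`),
    with small per-species jitter, so that truth ranges of shrinkers lose
    most cells by 2050 with nowhere to go, shifters translate (loss > 50%
    only by 2080), and stable species retain most of their range.  Species
    alternate between breeding and non-breeding seasons; ``n_flagged``
    species are marked introduced/marginal (alternating).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    props = np.array([archetype_mix.get(a, 0.0) for a in ARCHETYPES], dtype=float)
    if abs(props.sum() - 1.0) > 1e-6:
        raise ValueError(f"archetype proportions must sum to 1, got {props.sum()}")
    counts = np.floor(props * n_species).astype(int)
    # largest-remainder apportionment of the leftover species
    frac = props * n_species - counts
    for i in np.argsort(-frac)[: n_species - counts.sum()]:
        counts[i] += 1

    rng = np.random.default_rng(seed)
    x = baseline[niche_var].ravel()
    species = []
    k = 0
    for arch, cnt in zip(ARCHETYPES, counts):
        q, sigma0 = ARCHETYPE_NICHE[arch]
        mu0 = float(np.quantile(x, q))
        for _ in range(cnt):
            sigma = sigma0 * rng.uniform(0.9, 1.1)
            mu = mu0 + rng.uniform(-0.3, 0.3)
            species.append(NicheSpec(
                species_id=f"sp{k + 1:03d}",
                season=seasons[k % len(seasons)],
                response={niche_var: (mu, sigma)},
                p_max=float(rng.uniform(0.85, 0.95)),
                archetype=arch))
            k += 1
    if n_flagged:
        idx = rng.choice(n_species, size=min(n_flagged, n_species), replace=False)
        for j, i in enumerate(sorted(idx)):
            if j % 2 == 0:
                species[i].introduced = True
            else:
                species[i].marginal = True
    return species


def true_suitability(niche: NicheSpec, bioclim_grid: BioclimGrid) -> np.ndarray:
    """Exact occupancy-probability surface of a virtual species.

    ``p_max * prod_v exp(-(x_v - mu_v)^2 / (2 sigma_v^2))`` over the niche's
    variables; raises KeyError naming any variable absent from the grid.
    """
    surf = np.full(bioclim_grid.shape, niche.p_max)
    for var, (mu, sigma) in niche.response.items():
        if var not in bioclim_grid.layers:
            raise KeyError(f"variable {var!r} required by {niche.species_id} "
                           f"is missing from the bioclim grid")
        xv = bioclim_grid[var]
        surf = surf * np.exp(-((xv - mu) ** 2) / (2.0 * sigma ** 2))
    return surf


def make_survey_design(landscape, n_sites=500, years=range(1980, 2010), seed=0,
                       effort_log_mean=np.log(8.0), effort_log_sd=0.4,
                       date_range=(152, 196)):
    """Random survey sites with lognormal effort and early-summer dates."""
    rng = np.random.default_rng(seed)
    ls = landscape
    xs = rng.uniform(0, ls.nx * ls.cell_size, n_sites)
    ys = rng.uniform(0, ls.ny * ls.cell_size, n_sites)
    years = list(years)
    rows = []
    for s in range(n_sites):
        for yr in years:
            rows.append((f"site{s + 1:04d}", xs[s], ys[s], yr))
    df = pd.DataFrame(rows, columns=["site_id", "x", "y", "year"])
    df["effort_hours"] = rng.lognormal(effort_log_mean, effort_log_sd, len(df))
    df["ordinal_date"] = rng.integers(date_range[0], date_range[1] + 1, len(df))
    return SurveyDesign(site_years=df, cell_size=ls.cell_size,
                        extent=(ls.nx * ls.cell_size, ls.ny * ls.cell_size))


def sample_occurrences(suitability, survey_design, detect_beta=0.3, seed=0,
                       species_id="sp001", season="nonbreeding"):
    """Bernoulli presence/absence records at survey sites.

    ``P(presence) = suitability(site) * (1 - exp(-detect_beta * effort))``.
    Breeding-season records carry ordinal_date and a blank effort column;
    non-breeding records the reverse, mirroring the two survey programs'
    covariates.
    """
    if detect_beta < 0:
        raise ValueError("detect_beta must be >= 0")
    rng = np.random.default_rng(seed)
    sy = survey_design.site_years
    suit = extract_at_points(suitability, sy[["x", "y"]].to_numpy(),
                             survey_design.cell_size)
    p = suit * (1.0 - np.exp(-detect_beta * sy["effort_hours"].to_numpy()))
    occ = sy[["site_id", "x", "y", "year", "effort_hours", "ordinal_date"]].copy()
    occ.insert(4, "season", season)
    occ.insert(5, "species_id", species_id)
    occ["presence"] = (rng.random(len(occ)) < p).astype(int)
    if season == "breeding":
        occ["effort_hours"] = np.nan
    else:
        occ["ordinal_date"] = np.nan
    return occ.reset_index(drop=True)


@dataclass
class TruthTable:
    """Exact per-species ranges, loss/expansion, and categories.

    Derived from the niches alone (no sampling): the truth range on a
    climate surface is the set of cells where true suitability is at least
    ``TRUTH_LEVEL * p_max``; loss/expansion and categories follow by the
    same rules the sensitivity module applies to fitted ranges.
    """

    current: dict = field(default_factory=dict)   # species_id -> bool grid
    future: dict = field(default_factory=dict)    # (species_id, scenario, period) -> bool grid
    records: dict = field(default_factory=dict)   # species_id -> SensitivityRecord
    category: dict = field(default_factory=dict)  # species_id -> category
    expected: dict = field(default_factory=dict)  # species_id -> archetype-implied category


def truth_range(niche: NicheSpec, bioclim_grid: BioclimGrid) -> np.ndarray:
    return true_suitability(niche, bioclim_grid) >= TRUTH_LEVEL * niche.p_max


def build_truth(species, baseline_bioclim, future_bioclims) -> TruthTable:
    """Evaluate every species' exact ranges and category.

    ``future_bioclims`` maps (scenario, period) to a (jitter-free)
    BioclimGrid; categories are produced by the sensitivity classifier
    applied to the exact loss/expansion values, so truth is self-consistent
    with the classification rules by construction.
    """
    tt = TruthTable()
    for sp in species:
        cur = truth_range(sp, baseline_bioclim)
        tt.current[sp.species_id] = cur
        loss, expansion = {}, {}
        for (scen, per), grid in future_bioclims.items():
            fut = truth_range(sp, grid)
            tt.future[(sp.species_id, scen, per)] = fut
            loss[(scen, per)] = 1.0 - _sensitivity.stability(cur, fut)
            expansion[(scen, per)] = _sensitivity.expansion(cur, fut)
        rec = _sensitivity.SensitivityRecord(
            species_id=sp.species_id, season=sp.season, loss=loss,
            expansion=expansion, introduced=sp.introduced, marginal=sp.marginal)
        rec.category = _sensitivity.classify(rec)
        tt.records[sp.species_id] = rec
        tt.category[sp.species_id] = rec.category
        tt.expected[sp.species_id] = ("other" if sp.flagged
                                      else ARCHETYPE_CATEGORY[sp.archetype])
    return tt


def make_conservation_statuses(species, categories, seed=0, alignment=0.5,
                               pif_missing_rate=0.3):
    """Synthetic IUCN / federal-BCC / PIF statuses for a species cohort.

    With probability ``alignment`` a species' status matches its climate
    sensitivity category (the aligned fraction controls how strongly the
    resulting rank correlations depart from zero); otherwise the status is
    drawn uniformly.  A fraction of species lack a PIF score, as unranked
    species do in the published assessments.
    """
    rng = np.random.default_rng(seed)
    iucn_by_cat = {"endangered": "endangered", "threatened": "threatened",
                   "stable": "least_concern"}
    fed_by_cat = {"endangered": "federal", "threatened": "bcc", "stable": "none"}
    pif_by_cat = {"endangered": (15, 20), "threatened": (10, 14), "stable": (4, 9)}
    rows = []
    for sp in species:
        cat = categories[sp.species_id]
        if cat == "other" or rng.random() > alignment:
            cat_draw = ["endangered", "threatened", "stable"][rng.integers(3)]
        else:
            cat_draw = cat
        lo, hi = pif_by_cat[cat_draw]
        pif = float(rng.integers(lo, hi + 1))
        if rng.random() < pif_missing_rate:
            pif = np.nan
        rows.append((sp.species_id, iucn_by_cat[cat_draw], fed_by_cat[cat_draw], pif))
    return pd.DataFrame(rows, columns=["species_id", "iucn_status",
                                       "fed_bcc_status", "pif_score"])
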