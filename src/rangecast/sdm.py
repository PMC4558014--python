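"""Species distribution models: boosted regression trees on occurrence data.

One model per species and season relates presence/absence to bioclimatic
covariates plus a survey covariate — party-hours of effort for non-breeding
(count-circle) data, ordinal survey date for breeding (route) data.  Models
are gradient-boosted classification trees with Bernoulli (logistic) loss,
learning rate 0.01 and interaction depth 5, with the tree count chosen by
k-fold cross-validated loss and floored at a suggested minimum of 1000
trees.  Training and test partitions are split by survey decade so that
evaluation happens outside the training period, optionally restricted to
sites never used in training (a spatially independent re-evaluation).

The booster backend is pluggable in principle — anything honouring the
probabilistic-classifier contract works — and is xgboost here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import roc_auc_score

from .bioclim import extract_at_points
from .ranges import max_kappa_threshold

log = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Raised when a species has too few presences or absences to model."""


@dataclass
class ModelSettings:
    """Booster configuration; defaults follow the study design."""

    learning_rate: float = 0.01
    tree_complexity: int = 5  # interaction depth -> booster max_depth
    n_folds: int = 10
    min_trees: int = 1000
    max_trees: int = 3000
    bag_fraction: float = 0.5
    early_stopping_rounds: int = 50
    min_presences: int = 20
    min_absences: int = 20
    n_threads: int = 1

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.tree_complexity < 1:
            raise ValueError("tree_complexity must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def booster_params(self, seed=0):
        return {
            "eta": self.learning_rate,
            "max_depth": self.tree_complexity,
            "objective": "binary:logistic",
            "subsample": self.bag_fraction,
            "tree_method": "hist",
            "nthread": self.n_threads,
            "seed": int(seed) % (2 ** 31),
        }


@dataclass
class SDMModel:
    species_id: str
    season: str
    booster: xgb.Booster
    n_trees: int
    covariates: list
    settings: ModelSettings
    n_train: int = 0
    train_years: tuple = ()
    cv_best_trees: int = 0
    min_trees_waived: bool = False

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Suitability in [0, 1] for each row of a covariate table."""
        missing = [c for c in self.covariates if c not in table.columns]
        if missing:
            raise KeyError(f"covariates missing from table: {missing}")
        X = table[self.covariates].to_numpy(dtype=float)
        return self.booster.predict(xgb.DMatrix(X, feature_names=self.covariates))

    def sidecar(self):
        """JSON-serialisable metadata to persist beside the booster file."""
        return {"species_id": self.species_id, "season": self.season,
                "n_trees": self.n_trees, "covariates": list(self.covariates),
                "n_train": int(self.n_train),
                "train_years": [int(y) for y in self.train_years],
                "cv_best_trees": int(self.cv_best_trees),
                "settings": vars(self.settings)}

    def save(self, path):
        """Persist as the booster's native JSON plus a metadata sidecar."""
        import json
        from pathlib import Path
        path = Path(path)
        self.booster.save_model(path)
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(self.sidecar(), indent=2))

    @classmethod
    def load(cls, path):
        import json
        from pathlib import Path
        path = Path(path)
        booster = xgb.Booster()
        booster.load_model(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        return cls(species_id=meta["species_id"], season=meta["season"],
                   booster=booster, n_trees=meta["n_trees"],
                   covariates=meta["covariates"],
                   settings=ModelSettings(**meta["settings"]),
                   n_train=meta["n_train"],
                   train_years=tuple(meta["train_years"]),
                   cv_best_trees=meta["cv_best_trees"])


@dataclass
class EvalMetrics:
    species_id: str
    season: str
    auc: float
    deviance_explained: float
    kappa_max: float
    tpr: float
    threshold: float
    n_test: int


def split_train_test(occurrences, train_years, test_years):
    """Partition records by year into training and test tables."""
    train_years, test_years = set(train_years), set(test_years)
    if train_years & test_years:
        raise ValueError(f"year ranges overlap: {sorted(train_years & test_years)}")
    train = occurrences[occurrences["year"].isin(train_years)]
    test = occurrences[occurrences["year"].isin(test_years)]
    if len(train) == 0:
        raise ValueError(f"no records in training years {sorted(train_years)}")
    if len(test) == 0:
        raise ValueError(f"no records in test years {sorted(test_years)}")
    log.info("train/test split: %d / %d records", len(train), len(test))
    return train.copy(), test.copy()


def spatially_independent_subset(test, train):
    """Test records at sites never surveyed in the training table."""
    return test[~test["site_id"].isin(set(train["site_id"]))].copy()


def attach_bioclim_covariates(occurrences, bioclim_grid, cell_size, names):
    """Join nearest-cell bioclim values onto an occurrence table."""
    occ = occurrences.copy()
    pts = occ[["x", "y"]].to_numpy()
    for name in names:
        occ[name] = extract_at_points(bioclim_grid[name], pts, cell_size)
    return occ


def survey_covariate(season):
    """The survey covariate paired with the bioclim layers for a season."""
    return "ordinal_date" if season == "breeding" else "effort_hours"


def fit_brt(train, covariates, settings=None, seed=0, species_id="", season=""):
    """Fit a boosted-tree occurrence model with CV-selected tree count.

    The cross-validated held-out log-loss curve picks the tree count (early
    stopping truncates the sweep once the curve stops improving); the count
    is floored at ``settings.min_trees`` and capped at ``settings.max_trees``,
    then the final booster is refit on all training rows.
    """
    settings = settings or ModelSettings()
    y = train["presence"].to_numpy(dtype=int)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos < settings.min_presences or n_neg < settings.min_absences:
        raise InsufficientDataError(
            f"{species_id or 'species'}: {n_pos} presences / {n_neg} absences; "
            f"need >= {settings.min_presences} / {settings.min_absences}")
    missing = [c for c in covariates if c not in train.columns]
    if missing:
        raise KeyError(f"covariates missing from training table: {missing}")
    X = train[list(covariates)].to_numpy(dtype=float)
    dtrain = xgb.DMatrix(X, label=y, feature_names=list(covariates))
    params = settings.booster_params(seed)
    cv = xgb.cv(params, dtrain, num_boost_round=settings.max_trees,
                nfold=settings.n_folds, metrics="logloss",
                early_stopping_rounds=settings.early_stopping_rounds,
                seed=int(seed) % (2 ** 31), shuffle=True)
    cv_best = int(cv["test-logloss-mean"].idxmin()) + 1
    n_trees = min(max(cv_best, settings.min_trees), settings.max_trees)
    booster = xgb.train(params, dtrain, num_boost_round=n_trees)
    years = tuple(sorted(train["year"].unique())) if "year" in train else ()
    return SDMModel(species_id=species_id, season=season, booster=booster,
                    n_trees=n_trees, covariates=list(covariates),
                    settings=settings, n_train=len(train), train_years=years,
                    cv_best_trees=cv_best)


def predict_suitability(model, bioclim_grid, constants):
    """Project a fitted model over a bioclim grid.

    Covariates absent from the grid (the survey covariates) must be supplied
    in ``constants`` as scalars — e.g. the median survey effort or median
    ordinal date — which become spatially uniform layers.
    """
    ny, nx = bioclim_grid.shape
    cols = []
    for name in model.covariates:
        if name in bioclim_grid.layers:
            cols.append(bioclim_grid[name].ravel())
        elif name in constants:
            cols.append(np.full(ny * nx, float(constants[name])))
        else:
            raise KeyError(f"covariate {name!r} is neither a bioclim layer "
                           f"nor a supplied constant")
    X = np.column_stack(cols)
    p = model.booster.predict(xgb.DMatrix(X, feature_names=model.covariates))
    return p.reshape(ny, nx)


def evaluate(model, test) -> EvalMetrics:
    """AUC, Bernoulli deviance explained, and max-kappa TPR on held-out data."""
    y = test["presence"].to_numpy(dtype=int)
    if y.all() or not y.any():
        raise ValueError("test set contains a single class; AUC undefined")
    p = np.clip(model.predict(test), 1e-9, 1 - 1e-9)
    auc = float(roc_auc_score(y, p))
    dev_resid = -2.0 * np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
    p_null = y.mean()
    dev_null = -2.0 * np.sum(y * np.log(p_null) + (1 - y) * np.log1p(-p_null))
    dev_expl = 1.0 - dev_resid / dev_null
    thr, curve = max_kappa_threshold(y, p)
    i = int(np.flatnonzero(curve.thresholds == thr)[0])
    tpr = float(curve.tp[i] / (curve.tp[i] + curve.fn[i]))
    return EvalMetrics(species_id=model.species_id, season=model.season,
                       auc=auc, deviance_explained=float(dev_expl),
                       kappa_max=float(curve.kappa[i]), tpr=tpr,
                       threshold=thr, n_test=len(y))


def model_qc_filter(metrics):
    """Flag species whose AUC or deviance explained falls far below the rest.

    A species is dropped when either metric is more than 2 sample standard
    deviations *below* the across-species mean (performing well can only be
    violated downward).  With fewer than 3 species the filter is undefined;
    with zero spread everything is kept.  Returns the input frame with
    ``keep`` and ``qc_reason`` columns.
    """
    df = metrics if isinstance(metrics, pd.DataFrame) else pd.DataFrame(
        [vars(m) for m in metrics])
    if len(df) < 3:
        raise ValueError("QC filter needs metrics for at least 3 species")
    out = df.copy()
    out["keep"] = True
    out["qc_reason"] = ""
    for col in ("auc", "deviance_explained"):
        mean, sd = out[col].mean(), out[col].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            continue
        low = out[col] < mean - 2.0 * sd
        out.loc[low, "keep"] = False
        out.loc[low, "qc_reason"] = out.loc[low, "qc_reason"].where(
            out.loc[low, "qc_reason"] == "",
            out.loc[low, "qc_reason"] + "; ")
        out.loc[low, "qc_reason"] += f"{col} > 2 SD below mean"
    for _, row in out[~out["keep"]].iterrows():
        log.info("QC drop %s/%s: %s", row.get("species_id"), row.get("season"),
                 row["qc_reason"])
    return out
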