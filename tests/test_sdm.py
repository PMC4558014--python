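"""Boosted-tree occurrence models: partitions, fitting, evaluation, QC."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from rangecast import sdm

FAST = sdm.ModelSettings(n_folds=3, min_trees=40, max_trees=150,
                         early_stopping_rounds=15, min_presences=10,
                         min_absences=10)


def toy_table(n, rng, signal=2.0, x=None):
    """Occurrence table with a monotone logistic response to one covariate."""
    x = rng.normal(size=n) if x is None else x
    p = 1 / (1 + np.exp(-signal * x))
    return pd.DataFrame({"x1": x, "presence": (rng.random(n) < p).astype(int),
                         "year": rng.integers(2000, 2010, n),
                         "site_id": [f"s{i % 50}" for i in range(n)]})


class TestSplit:
    def test_partition_is_exact(self, rng):
        occ = toy_table(400, rng)
        occ["year"] = rng.integers(1980, 2010, 400)
        train, test = sdm.split_train_test(occ, range(2000, 2010), range(1980, 2000))
        assert len(train) + len(test) == 400
        assert set(train.index).isdisjoint(test.index)
        assert (train["year"] >= 2000).all() and (test["year"] < 2000).all()
        n_train = (occ["year"] >= 2000).sum()
        assert len(train) == n_train

    def test_empty_partition_rejected(self, rng):
        occ = toy_table(50, rng)  # all years 2000-2009
        with pytest.raises(ValueError, match="no records in test years"):
            sdm.split_train_test(occ, range(2000, 2010), range(1980, 2000))

    def test_overlapping_ranges_rejected(self, rng):
        occ = toy_table(50, rng)
        with pytest.raises(ValueError, match="overlap"):
            sdm.split_train_test(occ, range(2000, 2010), range(2005, 2015))


class TestSpatialSubset:
    def test_shared_and_disjoint_sites(self, rng):
        occ = toy_table(100, rng)
        assert len(sdm.spatially_independent_subset(occ, occ)) == 0
        other = occ.copy()
        other["site_id"] = "elsewhere"
        assert len(sdm.spatially_independent_subset(occ, other)) == 100

    def test_mixed_case_matches_set_difference(self, rng):
        test = toy_table(200, rng)
        train = toy_table(200, rng)
        train["site_id"] = [f"s{i % 80}" for i in range(200)]
        got = sdm.spatially_independent_subset(test, train)
        keep = set(test["site_id"]) - set(train["site_id"])
        assert set(got["site_id"]) == keep
        assert len(got) == test["site_id"].isin(keep).sum()


class TestFitBrt:
    def test_monotone_response_is_recovered(self, rng):
        train = toy_table(800, rng, signal=2.5)
        model = sdm.fit_brt(train, ["x1"], settings=FAST, seed=0)
        probe = pd.DataFrame({"x1": np.linspace(-2.5, 2.5, 200)})
        pred = model.predict(probe)
        rho = spearmanr(pred, probe["x1"]).statistic
        assert rho > 0.9

    def test_permuted_labels_give_chance_auc(self, rng):
        """Held-out AUC under a permutation null stays near 0.5."""
        aucs = []
        for rep in range(10):
            df = toy_table(400, rng, signal=2.0)
            df["presence"] = rng.permutation(df["presence"].to_numpy())
            train, holdout = df.iloc[:280], df.iloc[280:]
            if holdout["presence"].nunique() < 2:
                continue
            model = sdm.fit_brt(train, ["x1"], settings=FAST, seed=rep)
            aucs.append(sdm.evaluate(model, holdout).auc)
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_separable_data_fits_training_auc(self, rng):
        x = np.concatenate([rng.uniform(-3, -1, 150), rng.uniform(1, 3, 150)])
        df = pd.DataFrame({"x1": x, "presence": (x > 0).astype(int),
                           "year": 2000, "site_id": "s"})
        model = sdm.fit_brt(df, ["x1"], settings=FAST, seed=1)
        assert sdm.evaluate(model, df).auc >= 0.99

    def test_insufficient_presences_raises(self, rng):
        df = toy_table(100, rng)
        df["presence"] = 0
        df.loc[:3, "presence"] = 1
        with pytest.raises(sdm.InsufficientDataError, match="presences"):
            sdm.fit_brt(df, ["x1"], settings=FAST)

    def test_cv_tree_count_reproducible(self, rng):
        train = toy_table(400, rng)
        m1 = sdm.fit_brt(train, ["x1"], settings=FAST, seed=42)
        m2 = sdm.fit_brt(train, ["x1"], settings=FAST, seed=42)
        assert m1.cv_best_trees == m2.cv_best_trees
        assert m1.n_trees == m2.n_trees

    def test_save_load_round_trip(self, rng, tmp_path):
        train = toy_table(300, rng)
        m = sdm.fit_brt(train, ["x1"], settings=FAST, seed=3,
                        species_id="spX", season="breeding")
        path = tmp_path / "spX.json"
        m.save(path)
        m2 = sdm.SDMModel.load(path)
        np.testing.assert_allclose(m.predict(train), m2.predict(train))
        assert (m2.species_id, m2.season, m2.covariates) == \
            ("spX", "breeding", ["x1"])

    def test_tree_count_floored_at_minimum(self, rng):
        train = toy_table(300, rng)
        settings = sdm.ModelSettings(n_folds=3, min_trees=120, max_trees=150,
                                     early_stopping_rounds=10,
                                     min_presences=10, min_absences=10)
        model = sdm.fit_brt(train, ["x1"], settings=settings, seed=0)
        assert model.n_trees >= 120


class TestPredictSuitability:
    def test_constants_fill_survey_covariates(self, bioclim_small, rng):
        df = toy_table(600, rng)
        df["bio01"] = rng.uniform(-5, 15, len(df))
        df["effort_hours"] = rng.uniform(1, 20, len(df))
        model = sdm.fit_brt(df, ["bio01", "effort_hours"], settings=FAST, seed=0)
        surf = sdm.predict_suitability(model, bioclim_small, {"effort_hours": 8.0})
        assert surf.shape == bioclim_small.shape
        assert np.all((surf >= 0) & (surf <= 1))
        with pytest.raises(KeyError, match="effort_hours"):
            sdm.predict_suitability(model, bioclim_small, {})

    def test_effort_learned_direction_is_monotone(self, bioclim_small, rng):
        """Detection rises with effort in the generator; predictions under a
        larger constant-effort layer must be higher on average."""
        n = 2000
        effort = rng.uniform(0.2, 20, n)
        p = 0.7 * (1 - np.exp(-0.3 * effort))
        df = pd.DataFrame({"bio01": rng.uniform(-5, 15, n),
                           "effort_hours": effort,
                           "presence": (rng.random(n) < p).astype(int),
                           "year": 2000, "site_id": "s"})
        model = sdm.fit_brt(df, ["bio01", "effort_hours"], settings=FAST, seed=0)
        low = sdm.predict_suitability(model, bioclim_small, {"effort_hours": 1.0})
        high = sdm.predict_suitability(model, bioclim_small, {"effort_hours": 15.0})
        assert high.mean() > low.mean()


class TestEvaluate:
    def test_perfect_separation_auc_one(self, rng):
        df = toy_table(300, rng)
        model = sdm.fit_brt(df, ["x1"], settings=FAST, seed=0)
        test = df.copy()
        test["presence"] = (model.predict(test) > np.median(model.predict(test))).astype(int)
        assert sdm.evaluate(model, test).auc == 1.0

    def test_auc_matches_pairwise_concordance_oracle(self, rng):
        df = toy_table(20, rng)
        model = sdm.fit_brt(toy_table(200, rng), ["x1"], settings=FAST, seed=0)
        y = df["presence"].to_numpy()
        if y.sum() in (0, len(y)):
            y[0] = 1 - y[0]
            df["presence"] = y
        p = model.predict(df)
        m = sdm.evaluate(model, df)
        conc = half = total = 0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                total += 1
                conc += p[i] > p[j]
                half += p[i] == p[j]
        assert m.auc == pytest.approx((conc + 0.5 * half) / total)

    def test_single_class_test_rejected(self, rng):
        model = sdm.fit_brt(toy_table(200, rng), ["x1"], settings=FAST, seed=0)
        bad = toy_table(30, rng)
        bad["presence"] = 1
        with pytest.raises(ValueError, match="single class"):
            sdm.evaluate(model, bad)

    def test_deviance_explained_positive_for_informative_model(self, rng):
        df = toy_table(1000, rng, signal=3.0)
        model = sdm.fit_brt(df.iloc[:700], ["x1"], settings=FAST, seed=0)
        m = sdm.evaluate(model, df.iloc[700:])
        assert 0 < m.deviance_explained <= 1
        assert 0 <= m.tpr <= 1 and m.kappa_max > 0


class TestQcFilter:
    def metrics(self, aucs, devs=None):
        devs = devs if devs is not None else [0.5] * len(aucs)
        return pd.DataFrame({"species_id": [f"s{i}" for i in range(len(aucs))],
                             "auc": aucs, "deviance_explained": devs})

    def test_identical_metrics_keep_all(self):
        out = sdm.model_qc_filter(self.metrics([0.8] * 5))
        assert out["keep"].all()

    def test_single_low_outlier_dropped(self):
        aucs = [0.80] * 9 + [0.50]
        vals = np.array(aucs)
        assert vals[-1] < vals.mean() - 2 * vals.std(ddof=1)
        out = sdm.model_qc_filter(self.metrics(aucs))
        assert not out.iloc[-1]["keep"]
        assert out.iloc[:-1]["keep"].all()

    def test_high_performers_never_dropped(self):
        # one-sided rule: an unusually *good* model is kept
        aucs = [0.6, 0.61, 0.59, 0.6, 0.99]
        out = sdm.model_qc_filter(self.metrics(aucs))
        assert out.iloc[-1]["keep"]

    def test_order_invariant(self, rng):
        aucs = list(rng.uniform(0.6, 0.9, 12))
        base = sdm.model_qc_filter(self.metrics(aucs)).set_index("species_id")["keep"]
        perm = rng.permutation(12)
        shuffled = self.metrics([aucs[i] for i in perm])
        shuffled["species_id"] = [f"s{i}" for i in perm]
        out = sdm.model_qc_filter(shuffled).set_index("species_id")["keep"]
        assert out.sort_index().equals(base.sort_index())

    def test_needs_three_species(self):
        with pytest.raises(ValueError, match="3 species"):
            sdm.model_qc_filter(self.metrics([0.8, 0.9]))
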