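"""Synthetic landscape/climate/species generation and occurrence sampling."""

import numpy as np
import pandas as pd
import pytest

from rangecast import sensitivity, synthetic_data as synth


class TestLandscape:
    def test_seeded_determinism(self):
        a = synth.make_landscape(50, 50, seed=1)
        b = synth.make_landscape(50, 50, seed=1)
        np.testing.assert_array_equal(a.elevation, b.elevation)
        np.testing.assert_array_equal(a.dist_coast, b.dist_coast)

    def test_coastal_cells_at_zero_distance(self, landscape_small):
        assert np.all(landscape_small.dist_coast[:, 0] == 0)

    def test_straight_coast_distance_is_column_times_cell(self, landscape_small):
        """Cell-center distance to a straight western coastline, checked
        against an exhaustive nearest-coast-cell search."""
        ls = landscape_small
        cols = np.arange(ls.nx) * ls.cell_size
        np.testing.assert_allclose(ls.dist_coast, np.tile(cols, (ls.ny, 1)))
        # brute force over coast cells for a few random cells
        rng = np.random.default_rng(0)
        for _ in range(20):
            i, j = rng.integers(0, ls.ny), rng.integers(0, ls.nx)
            d = min(np.hypot(i - ci, j) for ci in range(ls.ny)) * ls.cell_size
            assert ls.dist_coast[i, j] == pytest.approx(d)

    def test_latitude_strictly_monotone(self, landscape_small):
        assert np.all(np.diff(landscape_small.latitude) > 0)

    def test_rejects_tiny_grids(self):
        with pytest.raises(ValueError, match="at least 10x10"):
            synth.make_landscape(5, 50)


class TestBaselineClimate:
    def test_flat_noise_free_world_is_constant_along_rows(self):
        ls = synth.make_landscape(20, 20, seed=3, elev_relief=0.0, elev_base=0.0)
        mc = synth.make_baseline_climate(ls, lapse_rate=0.0, noise_sd=0.0,
                                         prec_noise_sd=0.0, seed=3)
        assert np.allclose(mc.tmin, mc.tmin[:, :, :1])

    def test_no_seasonality_means_identical_months(self, landscape_small):
        mc = synth.make_baseline_climate(landscape_small, seasonal_amplitude=0.0,
                                         noise_sd=0.0, prec_seasonal=0.0,
                                         prec_noise_sd=0.0, seed=3)
        assert np.allclose(mc.tmin, mc.tmin[:1])
        assert np.allclose(mc.prec, mc.prec[:1])

    def test_annual_mean_matches_generating_formula(self, landscape_small):
        ls = landscape_small
        lapse = -0.0065
        mc = synth.make_baseline_climate(ls, lapse_rate=lapse, noise_sd=0.0,
                                         t_south=14.0, lat_gradient=-0.6, seed=3)
        expected = (14.0 - 0.6 * (ls.latitude_grid - ls.latitude.min())
                    + lapse * ls.elevation)
        np.testing.assert_allclose(mc.tmin.mean(axis=0), expected, atol=1e-10)

    def test_positive_lapse_rate_rejected(self, landscape_small):
        with pytest.raises(ValueError, match="lapse_rate"):
            synth.make_baseline_climate(landscape_small, lapse_rate=0.001)


class TestFutureClimate:
    def test_no_jitter_is_uniform_warming(self, baseline_small):
        fut = synth.make_future_climate(baseline_small, "A2", "2080",
                                        gcm_jitter_sd=0.0)
        delta = synth.WARMING_C["A2"]["2080"]
        np.testing.assert_allclose(fut.tmin, baseline_small.tmin + delta)
        np.testing.assert_allclose(fut.tmax, baseline_small.tmax + delta)

    def test_warming_ordered_within_scenario(self, baseline_small):
        for scen, table in synth.WARMING_C.items():
            assert table["2020"] <= table["2050"] <= table["2080"]

    def test_unknown_labels_rejected(self, baseline_small):
        with pytest.raises(ValueError, match="scenario"):
            synth.make_future_climate(baseline_small, "RCP85", "2050")
        with pytest.raises(ValueError, match="period"):
            synth.make_future_climate(baseline_small, "A2", "2100")

    def test_gcm_jitter_averages_to_uniform_delta(self, baseline_small):
        """The mean over many GCM draws recovers the configured warming."""
        delta = synth.WARMING_C["B2"]["2050"]
        fields = [synth.make_future_climate(baseline_small, "B2", "2050",
                                            gcm_jitter_sd=0.5, seed=s).tmin[0]
                  - baseline_small.tmin[0]
                  for s in range(60)]
        mean_field = np.mean(fields, axis=0)
        mc_se = 0.5 / np.sqrt(60)
        assert np.abs(mean_field - delta).mean() < 4 * mc_se


class TestSpecies:
    def test_all_stable_mix_has_broad_niches(self, bioclim_small):
        sps = synth.make_species(5, {"stable": 1.0}, bioclim_small, seed=1)
        broad = synth.ARCHETYPE_NICHE["stable"][1]
        for sp in sps:
            (_, sigma), = sp.response.values()
            assert sigma >= broad * 0.9

    def test_seeded_reproducibility(self, bioclim_small):
        mix = {"shrinker": 0.5, "stable": 0.5}
        a = synth.make_species(7, mix, bioclim_small, seed=9)
        b = synth.make_species(7, mix, bioclim_small, seed=9)
        assert [(s.species_id, s.response, s.p_max) for s in a] == \
               [(s.species_id, s.response, s.p_max) for s in b]

    def test_mix_must_sum_to_one(self, bioclim_small):
        with pytest.raises(ValueError, match="sum to 1"):
            synth.make_species(5, {"stable": 0.5}, bioclim_small)

    def test_shrinker_truth_loses_majority_by_2050(self, bioclim_default,
                                                   future_bios_default):
        """On the study landscape, shrinker truth ranges lose more than half
        their cells at the configured 2050 warming in every scenario."""
        sps = synth.make_species(4, {"shrinker": 1.0}, bioclim_default, seed=2)
        for scen in ("A2", "A1B", "B2"):
            fut = future_bios_default[(scen, "2050")]
            for sp in sps:
                cur = synth.truth_range(sp, bioclim_default)
                future = synth.truth_range(sp, fut)
                assert 1 - sensitivity.stability(cur, future) > 0.5


class TestTrueSuitability:
    def test_peak_at_optimum(self, bioclim_small):
        sp = synth.NicheSpec("s", "breeding", {"bio01": (0.0, 1.0)}, 0.9, "stable")
        flat = synth.NicheSpec("s", "breeding",
                               {"bio01": (float(bioclim_small["bio01"][3, 3]), 1.0)},
                               0.9, "stable")
        surf = synth.true_suitability(flat, bioclim_small)
        assert surf[3, 3] == pytest.approx(0.9)
        assert np.all(surf <= 0.9 + 1e-12)
        # far-from-optimum suitability decays to 0
        far = synth.NicheSpec("s", "breeding", {"bio01": (500.0, 1.0)}, 0.9, "stable")
        assert synth.true_suitability(far, bioclim_small).max() < 1e-12

    def test_matches_scalar_gaussian_at_probe_cells(self, bioclim_small):
        sp = synth.NicheSpec("s", "breeding", {"bio01": (5.0, 2.0)}, 0.8, "stable")
        surf = synth.true_suitability(sp, bioclim_small)
        for (i, j) in [(0, 0), (10, 20), (29, 5)]:
            x = bioclim_small["bio01"][i, j]
            assert surf[i, j] == pytest.approx(
                0.8 * np.exp(-((x - 5.0) ** 2) / (2 * 4.0)))

    def test_missing_variable_named_in_error(self, bioclim_small):
        sp = synth.NicheSpec("spX", "breeding", {"bio99": (0, 1)}, 0.5, "stable")
        with pytest.raises(KeyError, match="bio99"):
            synth.true_suitability(sp, bioclim_small)


@pytest.fixture(scope="module")
def survey(landscape_small):
    return synth.make_survey_design(landscape_small, n_sites=40,
                                    years=range(2000, 2005), seed=4)


class TestOccurrences:

    def test_zero_suitability_gives_all_absences(self, survey, landscape_small):
        suit = np.zeros((landscape_small.ny, landscape_small.nx))
        occ = synth.sample_occurrences(suit, survey, detect_beta=0.4, seed=1)
        assert occ["presence"].sum() == 0

    def test_zero_effort_response_gives_all_absences(self, survey, landscape_small):
        suit = np.ones((landscape_small.ny, landscape_small.nx))
        occ = synth.sample_occurrences(suit, survey, detect_beta=0.0, seed=1)
        assert occ["presence"].sum() == 0

    def test_detection_frequency_matches_closed_form(self, landscape_small):
        """At suitability 1 and fixed effort, detection frequency over many
        draws approximates 1 - exp(-beta*h) within 3 binomial SEs."""
        design = synth.make_survey_design(landscape_small, n_sites=100,
                                          years=range(2000, 2100), seed=6)
        sy = design.site_years.copy()
        sy["effort_hours"] = 6.0
        design = synth.SurveyDesign(site_years=sy, cell_size=design.cell_size,
                                    extent=design.extent)
        suit = np.ones((landscape_small.ny, landscape_small.nx))
        occ = synth.sample_occurrences(suit, design, detect_beta=0.25, seed=8)
        p_true = 1 - np.exp(-0.25 * 6.0)
        n = len(occ)
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(occ["presence"].mean() - p_true) < 3 * se

    def test_detection_monotone_in_effort(self):
        beta = 0.3
        p = lambda h: 1 - np.exp(-beta * h)
        hours = np.linspace(0.1, 50, 100)
        assert np.all(np.diff(p(hours)) > 0)

    def test_breeding_records_blank_effort(self, survey, landscape_small):
        suit = np.full((landscape_small.ny, landscape_small.nx), 0.5)
        occ = synth.sample_occurrences(suit, survey, seed=1, season="breeding")
        assert occ["effort_hours"].isna().all()
        assert occ["ordinal_date"].notna().all()

    def test_sites_outside_grid_rejected(self, landscape_small):
        sy = pd.DataFrame({"site_id": ["a"], "x": [1e5], "y": [5.0],
                           "year": [2000], "effort_hours": [4.0],
                           "ordinal_date": [160]})
        with pytest.raises(ValueError, match="outside landscape"):
            synth.SurveyDesign(site_years=sy, cell_size=10.0, extent=(300, 300))


def test_truth_categories_match_classifier_exactly(truth_small):
    """Applying the sensitivity classifier to truth loss/expansion must
    reproduce the stored truth categories (self-consistency)."""
    for spid, rec in truth_small.records.items():
        assert sensitivity.classify(rec) == truth_small.category[spid]


def test_truth_categories_equal_archetype_expectation(bioclim_default,
                                                      future_bios_default):
    """At the default study scale (100x100 grid over 30-60 degN) each
    archetype's truth category equals the one it is engineered to receive.
    The calibration is specific to that landscape geometry, so this runs on
    a full-size (but fit-free, hence cheap) world."""
    mix = {"shrinker": 1 / 3, "shifter": 1 / 3, "stable": 1 / 3}
    sps = synth.make_species(30, mix, bioclim_default, seed=3)
    tt = synth.build_truth(sps, bioclim_default, future_bios_default)
    for sp in sps:
        assert tt.category[sp.species_id] == tt.expected[sp.species_id], \
            (sp.species_id, sp.archetype)


def test_flagged_species_marked_other(bioclim_small, baseline_small,
                                      future_bios_small):
    sps = synth.make_species(6, {"stable": 1.0}, bioclim_small, seed=3,
                             n_flagged=2)
    assert sum(sp.flagged for sp in sps) == 2
    tt = synth.build_truth(sps, bioclim_small, future_bios_small)
    for sp in sps:
        if sp.flagged:
            assert tt.category[sp.species_id] == "other"
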