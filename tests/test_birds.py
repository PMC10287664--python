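"""Bird-richness modelling: filtering, collinearity pruning, the forward
stepwise quasi-Poisson fit, validation and spatial projection."""

import numpy as np
import pandas as pd
import pytest

from forestcondition.birds import (
    BirdDataset,
    BirdRichnessModel,
    BirdRichnessResults,
    filter_observed_species,
    prepare_bird_data,
    prune_collinear,
    train_test_split,
)
from forestcondition.synthetic import (
    generate_bird_table,
    generate_bird_truth,
)


@pytest.fixture(scope="module")
def bird_table():
    return generate_bird_table(4000, np.random.default_rng(21))


class TestPrepare:
    def test_total_richness_threshold(self):
        raw = pd.DataFrame({"cell_id": [1, 2, 3],
                            "total_richness": [3, 2, 10],
                            "threatened_richness": [1, 1, 4],
                            "x": [0.0, 0.1, 0.2]})
        data = prepare_bird_data(raw)
        assert list(data.df["cell_id"]) == [1, 3]

    def test_identity_when_nothing_to_drop(self, bird_table):
        high = bird_table[bird_table["total_richness"] >= 3]
        data = prepare_bird_data(high)
        assert len(data) == len(high)
        assert data.dropped_fraction == 0.0

    def test_known_subthreshold_fraction_reported(self, bird_table):
        tab = bird_table.copy()
        n = len(tab)
        tab.loc[: n // 20 - 1, "total_richness"] = 1  # plant 5% bad rows
        tab.loc[n // 20:, "total_richness"] = 10
        data = prepare_bird_data(tab)
        assert data.dropped_fraction == pytest.approx(0.05, abs=1e-9)

    def test_stratum_exclusion(self, bird_table):
        tab = bird_table.copy()
        tab["country"] = np.where(tab.index < 100, "PL", "DE")
        tab["total_richness"] = 10
        data = prepare_bird_data(tab, excluded_strata=["PL"],
                                 stratum_col="country",
                                 predictors=["forest_share"])
        assert len(data) == len(tab) - 100

    def test_empty_result_raises(self):
        raw = pd.DataFrame({"cell_id": [1], "total_richness": [0],
                            "threatened_richness": [0], "x": [1.0]})
        with pytest.raises(ValueError):
            prepare_bird_data(raw)


class TestPruneCollinear:
    def test_duplicate_predictor_removed(self, bird_table):
        tab = bird_table.copy()
        tab["forest_share_copy"] = tab["forest_share"]
        data = prepare_bird_data(tab)
        pruned = prune_collinear(data)
        assert (("forest_share" in pruned.predictors)
                ^ ("forest_share_copy" in pruned.predictors))

    def test_identity_below_threshold(self, bird_table):
        data = prepare_bird_data(bird_table)
        assert prune_collinear(data).predictors == data.predictors

    def test_planted_collinear_pairs_removed(self):
        """17 predictors with two planted collinear pairs -> 2 removals,
        keeping the member more correlated with richness."""
        tab = generate_bird_table(4000, np.random.default_rng(22),
                                  include_lonlat=True)
        data = prepare_bird_data(tab)
        assert len(data.predictors) == 17
        pruned = prune_collinear(data)
        assert len(pruned.predictors) == 15
        # mean_temperature is an active predictor; its collinear twin
        # (latitude) must be the one dropped
        assert "mean_temperature" in pruned.predictors
        assert "latitude" not in pruned.predictors


class TestStepwiseFit:
    def test_null_response_selects_nothing(self):
        rng = np.random.default_rng(3)
        tab = generate_bird_table(3000, rng,
                                  {"(Intercept)": np.log(5.0)}, 2.0)
        res = BirdRichnessModel(prepare_bird_data(tab)).fit()
        assert res.selected_terms == []
        assert res.pseudo_r2 == pytest.approx(0.0, abs=0.01)

    def test_recovers_generating_terms(self):
        coef, disp = generate_bird_truth()
        tab = generate_bird_table(5000, np.random.default_rng(4), coef, disp)
        res = BirdRichnessModel(prepare_bird_data(tab)).fit()
        assert sorted(res.selected_terms) == sorted(
            t for t in coef if t != "(Intercept)")
        for t in res.selected_terms:
            assert abs(res.params[t] - coef[t]) <= 3 * res.bse[t]
        assert res.dispersion == pytest.approx(disp, rel=0.15)

    def test_pseudo_r2_nondecreasing_along_path(self):
        tab = generate_bird_table(4000, np.random.default_rng(5))
        res = BirdRichnessModel(prepare_bird_data(tab)).fit(scan_all=True)
        r2 = res.step_trace["pseudo_r2"].to_numpy()
        assert (np.diff(r2) >= -1e-12).all()

    def test_near_perfect_predictor_saturates(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=4000)
        y = np.round(np.exp(1.2 + 0.5 * x)).astype(int)
        df = pd.DataFrame({"cell_id": range(4000), "total_richness": y + 3,
                           "threatened_richness": y, "x": x,
                           "noise": rng.normal(size=4000)})
        res = BirdRichnessModel(prepare_bird_data(df)).fit()
        assert res.pseudo_r2 > 0.97


@pytest.fixture(scope="module")
def fitted():
    coef, disp = generate_bird_truth()
    tab = generate_bird_table(5000, np.random.default_rng(7), coef, disp)
    data = prepare_bird_data(tab)
    train, test = train_test_split(data, seed=1)
    res = BirdRichnessModel(train).fit()
    return coef, disp, train, test, res


class TestValidation:
    def test_rmse_on_training_data_equals_train_rmse(self, fitted):
        _, _, train, _, res = fitted
        pred = res.predict_frame(train.df)
        rmse = np.sqrt(np.mean((train.y - pred) ** 2))
        assert rmse == pytest.approx(res.rmse_train, rel=1e-12)

    def test_test_rmse_matches_theoretical_noise(self, fitted):
        """Hold-out RMSE approximates sqrt(mean(phi * mu)) of the truth."""
        coef, disp, _, test, res = fitted
        metrics = res.validate(test)
        lp = np.full(len(test.df), coef["(Intercept)"])
        for t, b in coef.items():
            if t == "(Intercept)":
                continue
            base = t[:-2] if t.endswith("^2") else t
            v = test.df[base].to_numpy()
            lp += b * (v ** 2 if t.endswith("^2") else v)
        expected = np.sqrt(np.mean(disp * np.exp(lp)))
        assert metrics["rmse_test"] == pytest.approx(expected, rel=0.10)
        assert metrics["cor_test"] > 0.5

    def test_split_and_cv_reproducible(self, fitted):
        _, _, train, test, res = fitted
        m1 = res.validate(test, cv_data=train, cv_folds=5, cv_repeats=2, seed=3)
        m2 = res.validate(test, cv_data=train, cv_folds=5, cv_repeats=2, seed=3)
        assert m1 == m2
        tr1, te1 = train_test_split(BirdDataset(train.df, train.predictors),
                                    seed=9)
        tr2, te2 = train_test_split(BirdDataset(train.df, train.predictors),
                                    seed=9)
        pd.testing.assert_frame_equal(tr1.df, tr2.df)


class TestProjection:
    def test_intercept_only_constant_grid(self):
        res = BirdRichnessResults(
            selected_terms=[], params=pd.Series([1.0], index=["(Intercept)"]),
            bse=pd.Series([0.1]), dispersion=1.0, pseudo_r2=0.0,
            rmse_train=0.0, centers={}, train_size=10)
        grid = res.project({"forest_share": np.zeros((4, 4))})
        np.testing.assert_allclose(grid, np.exp(1.0))

    def _linear_results(self):
        return BirdRichnessResults(
            selected_terms=["forest_share"],
            params=pd.Series([0.5, 0.3], index=["(Intercept)", "forest_share"]),
            bse=pd.Series([0.1, 0.1]), dispersion=1.0, pseudo_r2=0.5,
            rmse_train=1.0, centers={"forest_share": 0.0}, train_size=10)

    def test_closed_form_and_positivity(self):
        res = self._linear_results()
        x = np.linspace(-2, 2, 16).reshape(4, 4)
        grid = res.project({"forest_share": x})
        np.testing.assert_allclose(grid, np.exp(0.5 + 0.3 * x))
        assert (grid > 0).all()

    def test_identical_dynamic_grids_identical_projection(self):
        res = self._linear_results()
        x = np.random.default_rng(0).normal(size=(5, 5))
        np.testing.assert_array_equal(res.project({"forest_share": x}),
                                      res.project({"forest_share": x.copy()}))

    def test_missing_grid_error_names_it(self):
        res = self._linear_results()
        with pytest.raises(KeyError, match="forest_share"):
            res.project({"ndvi_summer_mean": np.zeros((2, 2))})


def test_species_list_filter():
    assert len(filter_observed_species()) == 24
    assert "Loxia scotica" not in filter_observed_species()
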