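"""Presence/background SDM: features, fitting, projection, evaluation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleorange import niche_model as nm
from paleorange.io_formats import EnvSlice, OccurrenceTable, RasterGrid
from paleorange.synthetic_data import logistic_niche_fixture


def _table(coords):
    return OccurrenceTable(
        pd.DataFrame(
            {"species": "sp1", "lon": [c[0] for c in coords], "lat": [c[1] for c in coords]}
        )
    )


class TestExtractEnv:
    def test_known_cell_value(self, two_var_slice):
        grid = two_var_slice.grid()
        lon, lat = grid.cell_center(3, 4)
        X, rep = nm.extract_env(_table([(lon, lat)]), two_var_slice)
        assert X[0, 0] == two_var_slice.variables["env1"].values[3, 4]
        assert X[0, 1] == two_var_slice.variables["env2"].values[3, 4]
        assert rep["n_outside"] == 0

    def test_outside_point_flagged_not_dropped_silently(self, two_var_slice):
        grid = two_var_slice.grid()
        lon, lat = grid.cell_center(0, 0)
        X, rep = nm.extract_env(_table([(lon, lat), (999.0 % 180, 89.0)]), two_var_slice)
        assert len(X) == 1 and rep["n_outside"] == 1

    def test_vectors_match_generator_truth(self, two_var_slice):
        rng = np.random.default_rng(8)
        grid = two_var_slice.grid()
        cells = [(int(i), int(j)) for i, j in rng.integers(0, 8, size=(50, 2))]
        coords = [grid.cell_center(i, j) for i, j in cells]
        X, _ = nm.extract_env(_table(coords), two_var_slice)
        truth = np.array(
            [
                [two_var_slice.variables["env1"].values[c],
                 two_var_slice.variables["env2"].values[c]]
                for c in cells
            ]
        )
        assert np.array_equal(X, truth)

    def test_all_nodata_is_error(self):
        g = RasterGrid(np.full((3, 3), np.nan), 0, 0, 1.0)
        sl = EnvSlice(0.0, {"env1": g})
        lon, lat = g.cell_center(1, 1)
        with pytest.raises(ValueError, match="no usable"):
            nm.extract_env(_table([(lon, lat)]), sl)


class TestSampleBackground:
    def test_exhaustive_sample_hits_every_valid_cell(self, two_var_slice):
        X, cells = nm.sample_background(two_var_slice, 64, rng=1)
        assert len(np.unique(cells)) == 64

    def test_deterministic_given_seed(self, two_var_slice):
        X1, c1 = nm.sample_background(two_var_slice, 10, rng=5)
        X2, c2 = nm.sample_background(two_var_slice, 10, rng=5)
        assert np.array_equal(c1, c2) and np.array_equal(X1, X2)

    def test_oversized_request_rejected(self, two_var_slice):
        with pytest.raises(ValueError, match="valid"):
            nm.sample_background(two_var_slice, 65, rng=0)

    def test_sampling_is_uniform_over_cells(self, two_var_slice):
        rng = np.random.default_rng(99)
        counts = np.zeros(64)
        for _ in range(2500):
            _, cells = nm.sample_background(two_var_slice, 4, rng=rng)
            for c in cells:
                counts[c] += 1
        p = stats.chisquare(counts).pvalue
        assert p > 0.01


class TestFitModel:
    def test_sign_forced_by_separated_means(self):
        rng = np.random.default_rng(0)
        pres = rng.normal(3, 0.5, (50, 1))
        bg = rng.normal(-3, 0.5, (200, 1))
        model = nm.fit_model(pres, bg, ["v"], classes=("linear",), beta=0.5)
        assert model.weights[0] > 0

    def test_heavy_penalty_shrinks_to_constant(self):
        pres, bg, _ = logistic_niche_fixture(seed=3, n_presence=100, n_background=100)
        model = nm.fit_model(pres, bg, ["a", "b"], classes=("linear",), beta=1e6)
        assert np.allclose(model.weights, 0.0)
        preds = model.predict(np.vstack([pres, bg]))
        assert np.ptp(preds) < 1e-8

    def test_matches_independent_penalized_logistic_solver(self):
        from sklearn.linear_model import LogisticRegression

        pres, bg, _ = logistic_niche_fixture(seed=42)
        model = nm.fit_model(pres, bg, ["a", "b"], classes=("linear",), beta=1.0)
        A = model.expansion.transform(np.vstack([pres, bg]))
        y = np.r_[np.ones(len(pres)), np.zeros(len(bg))]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sk = LogisticRegression(
                penalty="l1", C=1.0, solver="saga", tol=1e-10, max_iter=200_000
            ).fit(A, y)
        ours = np.r_[model.weights, model.intercept]
        ref = np.r_[sk.coef_[0], sk.intercept_[0]]
        assert np.max(np.abs(ours - ref)) < 1e-4

    def test_recovers_true_suitability_ranking(self):
        pres, bg, niche = logistic_niche_fixture(seed=42)
        model = nm.fit_model(pres, bg, ["a", "b"], beta=1.0)
        gx = np.linspace(-2.5, 2.5, 25)
        G = np.array(np.meshgrid(gx, gx)).reshape(2, -1).T
        rho = stats.spearmanr(model.predict(G), niche.suitability(G)).statistic
        assert rho >= 0.9

    def test_affine_invariance_of_predictions(self):
        pres, bg, _ = logistic_niche_fixture(seed=9, n_presence=200, n_background=200)
        scale, shift = np.array([3.0, 0.2]), np.array([-7.0, 40.0])
        m1 = nm.fit_model(pres, bg, ["a", "b"], beta=1.0)
        m2 = nm.fit_model(pres * scale + shift, bg * scale + shift, ["a", "b"], beta=1.0)
        G = np.random.default_rng(1).normal(size=(100, 2))
        assert np.allclose(m1.predict(G), m2.predict(G * scale + shift), atol=1e-6)

    def test_too_few_presences_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            nm.fit_model(np.zeros((3, 1)), np.zeros((10, 1)), ["v"])


class TestPredictSuitability:
    def test_zero_weight_model_gives_half_everywhere(self, two_var_slice):
        pres, bg, _ = logistic_niche_fixture(seed=3, n_presence=10, n_background=10)
        model = nm.fit_model(pres, bg, ["env1", "env2"], classes=("linear",), beta=1e9)
        model.intercept = 0.0
        grid = nm.predict_suitability(model, two_var_slice)
        assert np.allclose(grid.values, 0.5)

    def test_grid_equals_per_cell_scalar_prediction(self, two_var_slice):
        pres, bg, _ = logistic_niche_fixture(seed=5, n_presence=50, n_background=50)
        # fixture variables stand in for the slice's env1/env2
        model = nm.fit_model(pres, bg, ["env1", "env2"], beta=1.0)
        grid = nm.predict_suitability(model, two_var_slice)
        for i, j in [(0, 0), (3, 5), (7, 7)]:
            v = np.array(
                [two_var_slice.variables["env1"].values[i, j],
                 two_var_slice.variables["env2"].values[i, j]]
            )
            assert grid.values[i, j] == pytest.approx(float(model.predict(v)[0]))

    def test_missing_variable_named_in_error(self, two_var_slice):
        pres, bg, _ = logistic_niche_fixture(seed=5, n_presence=10, n_background=10, n_variables=3)
        model = nm.fit_model(pres, bg, ["env1", "env2", "env3"], beta=1.0)
        with pytest.raises(ValueError, match="env3"):
            nm.predict_suitability(model, two_var_slice)

    def test_nodata_propagates(self):
        vals = np.ones((3, 3))
        vals[1, 1] = np.nan
        sl = EnvSlice(0.0, {"env1": RasterGrid(vals, 0, 0, 1.0)})
        pres = np.random.default_rng(0).normal(1, 1, (10, 1))
        bg = np.random.default_rng(1).normal(0, 1, (10, 1))
        model = nm.fit_model(pres, bg, ["env1"], classes=("linear",), beta=1.0)
        grid = nm.predict_suitability(model, sl)
        assert np.isnan(grid.values[1, 1])
        assert np.isfinite(grid.values).sum() == 8


class TestEvaluation:
    def test_auc_perfect_separation(self):
        assert nm.compute_auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_auc_all_tied_is_half(self):
        assert nm.compute_auc([0.5] * 5, [0.5] * 7) == 0.5

    def test_auc_equals_pairwise_oracle(self):
        rng = np.random.default_rng(17)
        p, b = rng.uniform(size=12), rng.uniform(size=8)
        wins = sum(
            1.0 if pi > bi else 0.5 if pi == bi else 0.0 for pi in p for bi in b
        )
        assert nm.compute_auc(p, b) == pytest.approx(wins / (12 * 8))

    def test_threshold_min_presence(self):
        assert nm.select_threshold([0.3, 0.5], [0.1], "min_presence") == 0.3

    def test_threshold_presence_percentile_order_statistic(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(size=10)
        tau = nm.select_threshold(scores, [0.0], "presence_percentile:10")
        assert tau == pytest.approx(np.percentile(scores, 10))

    def test_threshold_separable_midpoint(self):
        tau = nm.select_threshold([0.6, 0.8], [0.2, 0.4], "max_sens_plus_spec")
        assert tau == pytest.approx(0.5)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown threshold rule"):
            nm.select_threshold([0.5], [0.1], "bogus")

    def test_training_auc_beats_permuted_labels(self):
        pres, bg, _ = logistic_niche_fixture(seed=21)
        model = nm.fit_model(pres, bg, ["a", "b"], beta=1.0)
        auc = nm.compute_auc(model.predict(pres), model.predict(bg))
        rng = np.random.default_rng(22)
        pool = np.vstack([pres, bg])
        rng.shuffle(pool)
        auc_perm = nm.compute_auc(
            model.predict(pool[: len(pres)]), model.predict(pool[len(pres):])
        )
        assert auc > auc_perm
        assert abs(auc_perm - 0.5) < 0.1


class TestSerialization:
    def test_round_trip_exact(self, tmp_path):
        pres, bg, _ = logistic_niche_fixture(seed=31, n_presence=60, n_background=60)
        model = nm.fit_model(pres, bg, ["a", "b"], beta=0.7)
        model.save(tmp_path / "m.txt")
        back = nm.NicheModel.load(tmp_path / "m.txt")
        G = np.random.default_rng(3).normal(size=(50, 2))
        assert np.array_equal(model.weights, back.weights)
        assert model.intercept == back.intercept
        assert np.array_equal(model.predict(G), back.predict(G))
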