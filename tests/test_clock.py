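"""Clock training, prediction and cross-validation contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methclock.clock import (
    ClockModel,
    kfold_cv,
    loocv,
    performance,
    predict_age,
    train_clock,
)
from methclock.errors import ComputationError, ValidationError
from methclock.simdata import SimConfig, SpeciesSpec, simulate_dataset
from methclock.transforms import AgeTransform

IDENT = AgeTransform("identity")


def _toy_matrix(n_cpgs, n_samples, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(n_cpgs, n_samples)),
        index=[f"cpg{i:04d}" for i in range(n_cpgs)],
        columns=[f"s{j:03d}" for j in range(n_samples)],
    )


class TestPerformance:
    def test_perfect_prediction(self):
        r, mae, n = performance([1, 2, 3, 4], [1, 2, 3, 4])
        assert (r, mae, n) == (pytest.approx(1.0), 0.0, 4)

    def test_anticorrelated_hand_example(self):
        r, mae, _ = performance([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)
        assert mae == 2.0  # median of {2, 0, 2}

    def test_median_absolute_error_is_a_median(self):
        _, mae, _ = performance([1, 2, 4], [1, 2, 3])
        assert mae == 0.0  # median of {0, 0, 1}

    def test_constant_truth_rejected(self):
        with pytest.raises(ComputationError):
            performance([2, 2, 2], [1, 2, 3])


class TestTrainClock:
    def test_informative_probe_selected_across_seeds(self):
        # one CpG is an exact linear readout of age; it must get weight
        for seed in range(10):
            betas = _toy_matrix(50, 24, seed=seed)
            ages = np.linspace(1, 15, 24)
            betas.iloc[0] = 0.1 + 0.05 * ages  # in (0.1, 0.85)
            model = train_clock(betas, ages, IDENT, seed=seed)
            assert "cpg0000" in model.weights

    def test_constant_matrix_gives_intercept_only_model(self):
        betas = pd.DataFrame(0.5, index=[f"c{i}" for i in range(20)],
                             columns=[f"s{j}" for j in range(24)])
        ages = np.linspace(1, 10, 24)
        model = train_clock(betas, ages, IDENT, seed=0)
        assert model.weights == {}
        pred = predict_age(model, betas)
        assert np.allclose(pred, ages.mean())

    def test_training_predictions_reproduce_stored_fitted_values(self, small_dataset):
        betas, sheet, _ = small_dataset
        model = train_clock(betas, sheet["age_years"], IDENT, seed=0)
        again = predict_age(model, betas)
        assert np.max(np.abs(again - model.fitted_years.to_numpy())) < 1e-8

    def test_simdata_defaults_fit_well(self, default_dataset):
        betas, sheet, truth = default_dataset
        marm = (sheet["species"] == "marmoset").to_numpy()
        model = train_clock(betas.loc[:, marm], sheet.loc[marm, "age_years"],
                            IDENT, seed=1)
        assert 1 <= len(model.weights) <= 200
        r, _, _ = performance(
            sheet.loc[marm, "age_years"], model.fitted_years.to_numpy()
        )
        assert r >= 0.95

    def test_degenerate_inputs_rejected(self):
        betas = _toy_matrix(30, 24)
        with pytest.raises(ComputationError):
            train_clock(betas, np.full(24, 5.0), IDENT)
        with pytest.raises(ValidationError):
            train_clock(betas.iloc[:, :8], np.linspace(1, 10, 8), IDENT,
                        n_internal_folds=10)


class TestPredictAge:
    def test_intercept_only_model_predicts_inverse_intercept(self):
        model = ClockModel(intercept=0.5, weights={}, transform=AgeTransform("relative"),
                           training_means={})
        betas = _toy_matrix(5, 4)
        pred = predict_age(model, betas, species=["marmoset"] * 4)
        assert np.allclose(pred, 0.5 * 22.8)

    def test_relative_inverse_scales_by_lifespan(self, small_dataset):
        betas, sheet, _ = small_dataset
        rel = AgeTransform("relative")
        model = train_clock(betas, sheet["age_years"], rel,
                            species=["marmoset"] * len(sheet), seed=0)
        two = betas.iloc[:, [0, 0]]
        two.columns = ["a", "b"]
        pred = predict_age(model, two, species=["marmoset", "human"])
        assert pred[1] / pred[0] == pytest.approx(122.5 / 22.8)

    def test_missing_probes_mean_imputed_below_threshold(self, small_dataset):
        betas, sheet, _ = small_dataset
        model = train_clock(betas, sheet["age_years"], IDENT, seed=0)
        cpgs = model.cpg_ids
        n_drop = max(1, int(0.1 * len(cpgs)))
        reduced = betas.drop(index=cpgs[:n_drop])
        pred = predict_age(model, reduced)
        assert np.all(np.isfinite(pred))

    def test_too_many_missing_probes_hard_error(self, small_dataset):
        betas, sheet, _ = small_dataset
        model = train_clock(betas, sheet["age_years"], IDENT, seed=0)
        cpgs = model.cpg_ids
        n_drop = int(0.5 * len(cpgs)) + 1
        reduced = betas.drop(index=cpgs[:n_drop])
        with pytest.raises(ValidationError):
            predict_age(model, reduced)


class TestCrossValidation:
    def test_loocv_scheme_definition(self, small_dataset):
        betas, sheet, _ = small_dataset
        res = loocv(betas, sheet, IDENT, seed=0)
        assert len(res.predictions) == 30
        assert sorted(res.predictions["fold"]) == list(range(30))
        assert set(res.predictions["sample_id"]) == set(sheet["sample_id"])

    def test_no_target_leakage_for_heldout_sample(self, small_dataset):
        # the fold that predicts a sample never sees its age: corrupting the
        # held-out age must leave that sample's own prediction bit-identical
        betas, sheet, _ = small_dataset
        res = loocv(betas, sheet, IDENT, seed=0)
        corrupted = sheet.copy()
        corrupted.loc[corrupted.index[0], "age_years"] = 500.0
        res2 = loocv(betas, corrupted, IDENT, seed=0)
        sid = sheet["sample_id"].iloc[0]
        p1 = res.predictions.set_index("sample_id").loc[sid, "predicted_age_years"]
        p2 = res2.predictions.set_index("sample_id").loc[sid, "predicted_age_years"]
        assert p1 == p2

    def test_pure_noise_loocv_shows_no_spurious_skill(self):
        # on null data LOOCV must not manufacture a positive age correlation;
        # R is in fact biased negative (held-out predictions revert to the
        # training mean excluding the sample), so only the upper side is bounded
        for seed in range(5):
            cfg = SimConfig(
                n_cpgs=200,
                species_specs=(SpeciesSpec("marmoset", 22.8, (0.5, 15.5), 30),),
                n_age_cpgs=0, n_sex_cpgs=0, n_treatment_cpgs=0, seed=seed,
            )
            betas, sheet, _ = simulate_dataset(cfg)
            res = loocv(betas, sheet, IDENT, seed=seed)
            assert res.r < 0.35

    def test_kfold_deterministic_given_seed(self, small_dataset):
        betas, sheet, _ = small_dataset
        r1 = kfold_cv(betas, sheet, IDENT, k=5, seed=3)
        r2 = kfold_cv(betas, sheet, IDENT, k=5, seed=3)
        pd.testing.assert_frame_equal(r1.predictions, r2.predictions)

    def test_kfold_small_stratum_falls_back_with_warning(self, small_dataset):
        betas, sheet, _ = small_dataset
        sheet = sheet.copy()
        sheet.loc[sheet.index[:2], "species"] = "human"  # stratum of 2 < k
        with pytest.warns(UserWarning, match="unstratified"):
            kfold_cv(betas, sheet, IDENT, k=5, seed=0)

    def test_kfold_errors(self, small_dataset):
        betas, sheet, _ = small_dataset
        with pytest.raises(ValidationError):
            kfold_cv(betas, sheet, IDENT, k=1)
        with pytest.raises(ValidationError):
            kfold_cv(betas, sheet, IDENT, k=31)

    def test_nonzero_weights_enriched_for_truth_age_cpgs(self, default_dataset):
        betas, sheet, truth = default_dataset
        marm = (sheet["species"] == "marmoset").to_numpy()
        model = train_clock(betas.loc[:, marm], sheet.loc[marm, "age_years"],
                            IDENT, seed=1)
        selected = set(model.weights)
        age_cpgs = set(truth.loc[truth["role"] == "age", "cpg_id"])
        table = [
            [len(selected & age_cpgs), len(selected - age_cpgs)],
            [len(age_cpgs - selected),
             len(set(truth["cpg_id"]) - selected - age_cpgs)],
        ]
        assert stats.fisher_exact(table, alternative="greater").pvalue < 0.01
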