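"""Inverse scaling-factor models: factors, forests, correction, CV."""

import numpy as np
import pandas as pd
import pytest

import mockbias as mb
from mockbias.errors import ConfigError, ModelError
from mockbias.inverse import (
    ScalingObservations,
    correct_proportions,
    cross_validate,
    fit_inverse,
)

N_TREES = 100  # smaller forests for unit tests; defaults stay at 500


@pytest.fixture(scope="module")
def scaling(three_proportions, design80):
    return mb.scaling_factors(three_proportions["cells"], design80)


@pytest.fixture(scope="module")
def models(scaling):
    return fit_inverse(scaling, n_trees=N_TREES, seed=4)


class TestScalingFactors:
    def test_identity_observation_gives_unit_factors(self, design80):
        obs = design80.proportions.copy()
        scaling = mb.scaling_factors(obs, design80)
        assert np.allclose(scaling.factors["factor"], 1.0)

    def test_worked_example_185(self, design80, panel_names):
        obs = design80.proportions.copy()
        row = obs.index[0]
        prescribed = design80.proportions.loc[row]
        # craft a sample observed at 92.5% for a taxon prescribed at 50%
        obs2 = pd.DataFrame(
            [[0.925, 0.075]], index=[1], columns=["a", "b"]
        )
        design = mb.MixtureDesign(
            proportions=pd.DataFrame([[0.5, 0.5]], index=[1], columns=["a", "b"]),
            role=pd.Series(["support"], index=[1]),
            replicate_of=pd.Series([pd.NA], index=[1], dtype="Int64"),
        )
        scaling = mb.scaling_factors(obs2, design)
        factors = scaling.factors.set_index("taxon")["factor"]
        assert factors["a"] == pytest.approx(1.85)

    def test_zero_actual_emits_no_observation(self, scaling, design80):
        merged = scaling.factors.merge(
            design80.proportions.stack().rename("actual").reset_index(),
            left_on=["sample_id", "taxon"],
            right_on=["run_id", "level_1"],
        )
        assert (merged["actual"] > 0).all()
        n_expected = int((design80.proportions.to_numpy() > 0).sum())
        assert len(scaling.factors) == n_expected


class TestFitInverse:
    def test_constant_factors_predicted_back(self, design80):
        obs = design80.proportions.copy()
        scaling = mb.scaling_factors(obs, design80)  # all factors exactly 1
        models = fit_inverse(scaling, n_trees=N_TREES, seed=0, oob=False)
        probe = np.full((3, 7), 1 / 7)
        for taxon in models.taxa:
            assert np.allclose(models.predict_factor(taxon, probe), 1.0, atol=1e-9)

    def test_oob_error_below_response_variance(self, models):
        """Positive OOB R2 means OOB MSE < variance of the scaling factors."""
        scores = models.oob_scores()
        assert scores and all(v > 0 for v in scores.values())

    def test_same_seed_identical_predictions(self, scaling):
        probe = np.full((5, 7), 1 / 7)
        a = fit_inverse(scaling, n_trees=50, seed=9, oob=False)
        b = fit_inverse(scaling, n_trees=50, seed=9, oob=False)
        taxon = scaling.taxa[0]
        assert np.array_equal(
            a.predict_factor(taxon, probe), b.predict_factor(taxon, probe)
        )

    def test_sparse_taxon_skipped_with_warning(self, scaling):
        thin = ScalingObservations(
            factors=scaling.factors.groupby("taxon").head(3).reset_index(drop=True),
            predictors=scaling.predictors,
            actual=scaling.actual,
        )
        with pytest.warns(UserWarning, match="skipping"):
            models = fit_inverse(thin, n_trees=10, seed=0, oob=False)
        assert set(models.skipped) == set(scaling.taxa)


class TestCorrection:
    def test_unit_factor_models_return_adjusted_observed(self, design80, panel):
        obs = design80.proportions.copy()
        unit = fit_inverse(mb.scaling_factors(obs, design80), n_trees=N_TREES,
                           seed=0, oob=False)
        counts = pd.DataFrame(
            [[100, 200, 0, 0, 0, 0, 0]], index=["s1"],
            columns=[t.name for t in panel],
        )
        corrected = mb.correct_sample(counts, panel, unit)
        expected = mb.adjust_counts(counts, panel, "cells")
        pd.testing.assert_frame_equal(corrected, expected, atol=1e-9, rtol=0)

    def test_output_sums_to_one_and_zero_counts_stay_zero(self, models, panel):
        counts = pd.DataFrame(
            [[500, 0, 1200, 0, 300, 0, 0]], index=["s1"],
            columns=[t.name for t in panel],
        )
        corrected = mb.correct_sample(counts, panel, models)
        assert corrected.sum(axis=1).iloc[0] == pytest.approx(1.0)
        assert (corrected.loc["s1", corrected.columns[counts.iloc[0] == 0]] == 0).all()

    def test_scale_invariance_in_counts(self, models, panel):
        counts = pd.DataFrame(
            [[50, 30, 0, 20, 0, 0, 10]], index=["s1"],
            columns=[t.name for t in panel],
        )
        a = mb.correct_sample(counts, panel, models)
        b = mb.correct_sample(counts * 100, panel, models)
        pd.testing.assert_frame_equal(a, b)

    def test_unmodeled_taxon_rejected(self, models, panel):
        partial = mb.InverseModelSet(
            models={k: v for k, v in models.models.items() if k != "S. amnii"},
            taxa=models.taxa,
        )
        counts = pd.DataFrame(
            [[0, 0, 0, 0, 0, 100, 900]], index=["s1"],
            columns=[t.name for t in panel],
        )
        with pytest.raises(ModelError, match="S. amnii"):
            mb.correct_sample(counts, panel, partial)

    def test_correction_reduces_error_on_clinical_samples(
        self, models, panel, default_truth
    ):
        profiles = mb.random_profiles(50, panel, seed=9)
        clin = mb.simulate_clinical(default_truth, panel, profiles, seed=10)
        observed = mb.adjust_counts(clin, panel, "cells")
        corrected = mb.correct_sample(clin, panel, models)
        mae_unc = float((observed - profiles).abs().mean().mean())
        mae_cor = float((corrected - profiles).abs().mean().mean())
        assert mae_cor < mae_unc

    def test_extraction_only_recovery_below_two_percent(self, design80, panel):
        truth = mb.make_truth(7, "extraction_only", seed=2, depth=100_000)
        props = mb.adjust_counts(
            mb.simulate_experiment(design80, truth, panel, "cells"), panel, "cells"
        )
        scaling = mb.scaling_factors(props, design80)
        m = fit_inverse(scaling, n_trees=N_TREES, seed=4, oob=False)
        corrected = correct_proportions(props, m)
        err = (corrected - design80.proportions.loc[corrected.index]).abs()
        assert float(np.median(err.to_numpy())) < 0.02


class TestCrossValidation:
    def test_folds_partition_samples(self, scaling):
        cv = cross_validate(scaling, k=5, seed=0, n_trees=20)
        per_fold = cv.groupby("fold")["n"].first()
        assert per_fold.sum() == len(scaling.sample_ids)
        assert len(per_fold) == 5

    def test_leave_one_out_allowed(self):
        # 12 all-positive samples so every taxon has observations in each fold
        rng = np.random.default_rng(0)
        props = pd.DataFrame(
            rng.dirichlet(np.ones(3), size=12),
            index=range(1, 13),
            columns=["a", "b", "c"],
        )
        design = mb.MixtureDesign(
            props.copy(),
            pd.Series("support", index=props.index),
            pd.Series([pd.NA] * 12, index=props.index, dtype="Int64"),
        )
        scaling = mb.scaling_factors(props, design)
        cv = cross_validate(scaling, k=12, seed=0, n_trees=10)
        assert cv["fold"].nunique() == 12
        assert (cv.groupby("fold")["n"].first() == 1).all()

    def test_k_exceeding_samples_rejected(self, scaling):
        with pytest.raises(ConfigError, match="exceeds"):
            cross_validate(scaling, k=10_000, seed=0, n_trees=10)

    def test_cv_error_near_noise_floor_when_unbiased(self, panel):
        """With an identity pipeline, CV error is on the technical-noise scale."""
        names = [t.name for t in panel]
        design = mb.build_design(7, seed=3, taxa=names)
        truth = mb.make_truth(7, "neutral", seed=3)
        props = mb.adjust_counts(
            mb.simulate_experiment(design, truth, panel, "cells"), panel, "cells"
        )
        scaling = mb.scaling_factors(props, design)
        cv = cross_validate(scaling, k=4, seed=0, n_trees=N_TREES)
        mae_cv = cv.groupby("taxon")["mae"].mean()
        noise = mb.technical_variation(props, design)
        assert mae_cv.max() < max(5 * noise.max(), 0.03)
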