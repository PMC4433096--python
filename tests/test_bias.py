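"""Count adjustment, bias decomposition, technical variation, significance."""

import numpy as np
import pandas as pd
import pytest

import mockbias as mb
from mockbias.bias import collapse_replicates, stage_summary
from mockbias.errors import MatchingError, SchemaError
from mockbias.taxa import TaxonMeta


def two_taxa(cn=(1, 4), gs=(1.0, 1.0)):
    return [TaxonMeta("a", cn[0], gs[0], "+"), TaxonMeta("b", cn[1], gs[1], "-")]


class TestAdjustCounts:
    def test_cells_divides_by_copy_number(self):
        counts = pd.DataFrame([[100, 100]], columns=["a", "b"], index=[1])
        props = mb.adjust_counts(counts, two_taxa(), "cells")
        assert np.allclose(props.to_numpy(), [[0.8, 0.2]])

    def test_identical_metadata_cancels(self):
        counts = pd.DataFrame([[30, 70]], columns=["a", "b"], index=[1])
        props = mb.adjust_counts(counts, two_taxa(cn=(2, 2), gs=(1.5, 1.5)), "dna")
        assert np.allclose(props.to_numpy(), [[0.3, 0.7]])

    def test_dna_scales_by_genome_size_over_copy_number(self):
        counts = pd.DataFrame([[50, 50]], columns=["a", "b"], index=[1])
        props = mb.adjust_counts(counts, two_taxa(cn=(1, 1), gs=(2.0, 1.0)), "dna")
        assert np.allclose(props.to_numpy(), [[2 / 3, 1 / 3]])

    def test_scale_invariance(self):
        counts = pd.DataFrame([[12, 34], [5, 9]], columns=["a", "b"], index=[1, 2])
        a = mb.adjust_counts(counts, two_taxa(), "cells")
        b = mb.adjust_counts(counts * 17, two_taxa(), "cells")
        pd.testing.assert_frame_equal(a, b)

    def test_zero_sample_rejected(self):
        counts = pd.DataFrame([[0, 0]], columns=["a", "b"], index=[1])
        with pytest.raises(SchemaError, match="all-zero"):
            mb.adjust_counts(counts, two_taxa(), "cells")

    def test_missing_metadata_rejected(self):
        counts = pd.DataFrame([[1, 1]], columns=["a", "zzz"], index=[1])
        with pytest.raises(SchemaError, match="zzz"):
            mb.adjust_counts(counts, two_taxa(), "cells")


class TestComputeBias:
    def test_identity_gives_zero(self, design80, panel_names):
        obs = design80.proportions.copy()
        bias = mb.compute_bias(obs, design80)
        assert np.allclose(bias.to_numpy(), 0.0)

    def test_biases_sum_to_zero_per_sample(self, three_proportions, design80):
        bias = mb.compute_bias(three_proportions["cells"], design80)
        assert np.allclose(bias.sum(axis=1).to_numpy(), 0.0, atol=1e-9)

    def test_equal_blend_worked_example(self, design80, panel_names):
        """Observed 92.5% against a prescribed 50% is a +0.425 bias."""
        obs = design80.proportions.copy()
        row = obs.index[0]
        obs.loc[row] = 0.0
        obs.loc[row, panel_names[0]] = 0.925
        obs.loc[row, panel_names[1]] = 0.075
        design = design80
        prescribed = design.proportions.copy()
        prescribed.loc[row] = 0.0
        prescribed.loc[row, panel_names[0]] = 0.5
        prescribed.loc[row, panel_names[1]] = 0.5
        d = mb.MixtureDesign(prescribed, design.role.copy(), design.replicate_of.copy())
        # replicate links may now disagree with the edited row; bias only needs rows
        bias = obs.loc[[row]] - d.proportions.loc[[row]]
        assert bias.loc[row, panel_names[0]] == pytest.approx(0.425)

    def test_unmatched_sample_rejected(self, design80, panel_names):
        obs = pd.DataFrame(
            [np.full(7, 1 / 7)], index=[9999], columns=panel_names
        )
        with pytest.raises(MatchingError):
            mb.compute_bias(obs, design80)


class TestStageDecomposition:
    def test_all_identical_gives_zero_everywhere(self, design80):
        obs = design80.proportions.copy()
        decomp = mb.stage_decomposition(obs, obs.copy(), obs.copy(), design80)
        assert np.allclose(decomp["bias"].to_numpy(), 0.0)

    def test_stage_biases_telescope_to_total(self, three_proportions, design80):
        decomp = mb.stage_decomposition(
            three_proportions["cells"],
            three_proportions["dna"],
            three_proportions["pcr"],
            design80,
        )
        piv = decomp.pivot_table(
            index=["treatment_id", "taxon"], columns="stage", values="bias"
        )
        resid = piv["extraction"] + piv["pcr"] + piv["seq_class"] - piv["total"]
        assert resid.abs().max() < 1e-9

    def test_extraction_only_truth_isolated_to_extraction_stage(self, design80, panel):
        truth = mb.make_truth(7, "extraction_only", seed=2, depth=100_000)
        props = {
            exp: mb.adjust_counts(
                mb.simulate_experiment(design80, truth, panel, exp), panel, exp
            )
            for exp in ("cells", "dna", "pcr")
        }
        decomp = mb.stage_decomposition(
            props["cells"], props["dna"], props["pcr"], design80
        )
        summary = stage_summary(decomp, design80)
        med = summary.groupby("stage")["median_abs"].median()
        assert med["pcr"] < 0.01 and med["seq_class"] < 0.01
        assert med["extraction"] == pytest.approx(med["total"], rel=0.25)

    def test_missing_treatment_rejected(self, three_proportions, design80):
        partial = three_proportions["dna"].iloc[:-5]
        collapsed_full = collapse_replicates(three_proportions["cells"], design80)
        collapsed_part = collapse_replicates(partial, design80)
        if len(collapsed_part.index) == len(collapsed_full.index):
            pytest.skip("dropped rows were all replicates")
        with pytest.raises(MatchingError):
            mb.stage_decomposition(
                three_proportions["cells"], partial, three_proportions["pcr"], design80
            )


class TestTechnicalVariation:
    def test_identical_replicates_have_zero_mae(self, design80):
        obs = design80.proportions.copy()
        mae = mb.technical_variation(obs, design80)
        assert np.allclose(mae.to_numpy(), 0.0)

    def test_forced_pair_deviation(self):
        design = mb.MixtureDesign(
            proportions=pd.DataFrame(
                [[0.5, 0.5], [0.5, 0.5]], index=[1, 2], columns=["a", "b"]
            ),
            role=pd.Series(["support", "replicate"], index=[1, 2]),
            replicate_of=pd.Series([pd.NA, 1], index=[1, 2], dtype="Int64"),
        )
        obs = pd.DataFrame(
            [[0.48, 0.52], [0.52, 0.48]], index=[1, 2], columns=["a", "b"]
        )
        mae = mb.technical_variation(obs, design)
        assert mae["a"] == pytest.approx(0.02)
        assert mae["b"] == pytest.approx(0.02)

    def test_no_replicates_warns_and_returns_nan(self):
        design = mb.build_design(3, n_lack_of_fit=0, n_replicates=0, seed=0)
        obs = design.proportions.copy()
        with pytest.warns(UserWarning, match="no replicated"):
            mae = mb.technical_variation(obs, design)
        assert mae.isna().all()


class TestMahalanobisBootstrap:
    def test_zero_differences_not_significant(self):
        res = mb.mahalanobis_bootstrap(np.zeros((40, 5)), n_boot=200, seed=0)
        assert res.distance == 0.0
        assert not res.significant

    def test_constant_shift_is_significant(self):
        rng = np.random.default_rng(1)
        diffs = rng.normal(0, 0.01, size=(60, 5))
        diffs[:, 0] += 0.3
        res = mb.mahalanobis_bootstrap(diffs, n_boot=500, seed=0)
        assert res.significant
        assert res.ci_low > 0

    def test_seed_fixes_interval_endpoints(self):
        rng = np.random.default_rng(2)
        diffs = rng.normal(0, 0.05, size=(30, 4))
        a = mb.mahalanobis_bootstrap(diffs, n_boot=300, seed=7)
        b = mb.mahalanobis_bootstrap(diffs, n_boot=300, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_too_few_samples_rejected(self):
        with pytest.raises(MatchingError):
            mb.mahalanobis_bootstrap(np.zeros((1, 3)), n_boot=10, seed=0)


def test_present_taxa_summary_uses_prescribed_presence(design80, three_proportions):
    bias = mb.compute_bias(three_proportions["cells"], design80)
    summary = mb.summarize_bias(bias, design80)
    # every taxon appears in some but not all runs of the design
    assert (summary["n_present"] < design80.n_runs).all()
    assert (summary["n_present"] > 0).all()
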