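"""Pairwise t-tests, signed fold changes and the joint DE rule."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import metmem as mm
from metmem.diffexpr import NONE, DOWN, UP, POOLED, WELCH


class TestProbeTtest:
    def test_pooled_closed_form_example(self):
        # t = -3.674 on 4 df for these samples; two-tailed p ~ 0.0213
        p = mm.probe_ttest([1, 2, 3], [4, 5, 6], POOLED)
        assert p == pytest.approx(0.021312, abs=1e-5)

    def test_identical_samples_give_p_one(self):
        assert mm.probe_ttest([5, 7, 9], [5, 7, 9]) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_conventions(self):
        assert mm.probe_ttest([5, 5, 5], [5, 5]) == 1.0
        assert mm.probe_ttest([5, 5, 5], [6, 6]) == 0.0

    def test_type_i_error_near_nominal(self):
        # 10,000 null probes: the empirical false-positive fraction of the
        # bare t-test must sit at its nominal 5%
        rng = np.random.default_rng(21)
        a = rng.normal(0, 1, (10_000, 8))
        b = rng.normal(0, 1, (10_000, 5))
        from metmem.diffexpr import _ttest_matrix
        p = _ttest_matrix(a, b, POOLED)
        frac = float((p < 0.05).mean())
        assert 0.045 <= frac <= 0.055

    def test_too_small_groups_rejected(self):
        with pytest.raises(mm.ContractError):
            mm.probe_ttest([1.0], [2.0, 3.0])

    def test_pooled_equals_welch_for_balanced_equal_variance(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 8)
        b = a + 1.0  # identical variances, balanced sizes -> same t and df
        p_pooled = mm.probe_ttest(a, b, POOLED)
        p_welch = mm.probe_ttest(a, b, WELCH)
        assert abs(p_pooled - p_welch) < 1e-9


class TestFoldChange:
    @pytest.mark.parametrize("mean_a, mean_b, fc, direction", [
        (10.0, 5.0, -2.0, DOWN),
        (10.0, 12.0, 1.2, UP),
        (7.0, 7.0, 1.0, NONE),
        (5.0, 10.0, 2.0, UP),
    ])
    def test_signed_convention(self, mean_a, mean_b, fc, direction):
        got_fc, got_dir = mm.fold_change(mean_a, mean_b)
        assert got_fc == pytest.approx(fc)
        assert got_dir == direction

    def test_non_positive_mean_rejected(self):
        with pytest.raises(mm.ContractError):
            mm.fold_change(0.0, 5.0)

    @given(a=st.floats(0.1, 1e4), b=st.floats(0.1, 1e4))
    def test_antisymmetry_and_magnitude(self, a, b):
        fc_ab, dir_ab = mm.fold_change(a, b)
        fc_ba, dir_ba = mm.fold_change(b, a)
        assert abs(fc_ab) >= 1.0
        assert abs(fc_ab) == pytest.approx(abs(fc_ba))
        if a != b:
            assert np.sign(fc_ab) == -np.sign(fc_ba)
            assert {dir_ab, dir_ba} == {UP, DOWN}


class TestCallDe:
    @pytest.mark.parametrize("p, fc, expected", [
        (0.049, 1.25, True),
        (0.049, 1.2, False),   # boundary |FC| = cutoff excluded (strict >)
        (0.05, 3.0, False),    # boundary p = alpha excluded (strict <)
        (0.0499, -1.21, True),
    ])
    def test_joint_strict_rule(self, p, fc, expected):
        stats = mm.ProbeComparisonStats("p1", p, fc, UP if fc > 0 else DOWN,
                                        10.0, 12.0)
        spec = mm.ComparisonSpec(mm.Group.ND, mm.Group.D)
        assert mm.call_de(stats, spec) is expected


class TestRunAllComparisons:
    def test_every_probe_gets_all_three_comparisons(self, filtered_study):
        filtered, design, _, table = filtered_study
        assert len(table.frame) == filtered.n_probes
        for key in ("ND_D", "ND_DI", "D_DI"):
            assert f"p_{key}" in table.frame
            assert f"fc_{key}" in table.frame
            assert table.frame[f"p_{key}"].between(0, 1).all()
            assert (table.frame[f"fc_{key}"].abs() >= 1).all()

    def test_invariant_to_sample_permutation(self, filtered_study):
        filtered, design, _, table = filtered_study
        shuffled = filtered.subset_samples(filtered.sample_ids[::-1])
        table2 = mm.run_all_comparisons(shuffled, design)
        pd.testing.assert_frame_equal(table.frame, table2.frame)

    def test_noise_free_normalized_archetype_recovers_fold_changes(self):
        config = mm.SimulationConfig(
            n_probes=60, seed=3, cv=0.0, sample_scale_log2_sd=0.0,
            effect_size_fc=2.0,
            category_proportions={"Normalized": 1.0})
        matrix, design, truth = mm.simulate_expression(config)
        table = mm.run_all_comparisons(matrix, design)
        signs = np.sign(truth["true_fc"].to_numpy())
        np.testing.assert_allclose(
            table.frame["fc_ND_D"].to_numpy() * signs, 2.0, rtol=1e-6)
        np.testing.assert_allclose(
            np.abs(table.frame["fc_ND_DI"].to_numpy()), 1.0, rtol=1e-6)

    def test_swapping_groups_negates_fold_change_keeps_p(self, filtered_study):
        filtered, design, _, table = filtered_study
        swapped = mm.run_all_comparisons(
            filtered, design,
            comparisons=((mm.Group.D, mm.Group.ND),))
        np.testing.assert_allclose(swapped.frame["p_D_ND"],
                                   table.frame["p_ND_D"], rtol=1e-12)
        fc_fwd = table.frame["fc_ND_D"].to_numpy()
        fc_rev = swapped.frame["fc_D_ND"].to_numpy()
        nontrivial = np.abs(fc_fwd) > 1
        np.testing.assert_allclose(fc_rev[nontrivial], -fc_fwd[nontrivial],
                                   rtol=1e-12)

    def test_null_probes_called_at_most_alpha(self, filtered_study, sim_study):
        # the fold-change cutoff can only lower the DE rate below alpha
        filtered, design, truth, table = filtered_study
        null_probes = truth.index[truth["true_category"] == mm.UNCHANGED]
        null_probes = [p for p in null_probes if p in table.frame.index]
        de = mm.de_mask(table).loc[null_probes]
        assert de.mean() <= 0.05

    def test_missing_group_is_config_error(self, sim_study):
        matrix, design, _ = sim_study
        two_groups = mm.SampleDesign(
            design.frame[design.frame["group"] != "DI"])
        with pytest.raises(mm.ConfigError, match="DI"):
            mm.run_all_comparisons(matrix, two_groups)
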