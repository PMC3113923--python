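"""The synthetic study generator: determinism, noise-free limits, label
frequencies and the encoded archetypes."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metmem as mm


class TestDeterminism:
    def test_same_seed_identical_output(self, small_config):
        m1, d1, t1 = mm.simulate_expression(small_config)
        m2, d2, t2 = mm.simulate_expression(small_config)
        pd.testing.assert_frame_equal(m1.signal, m2.signal)
        pd.testing.assert_frame_equal(m1.detection, m2.detection)
        pd.testing.assert_frame_equal(t1, t2)

    def test_distinct_seeds_differ(self, small_config):
        import dataclasses
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        m1, _, _ = mm.simulate_expression(small_config)
        m2, _, _ = mm.simulate_expression(other)
        assert not m1.signal.equals(m2.signal)


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(mm.ConfigError, match="sum"):
            mm.SimulationConfig(category_proportions={"Normalized": 0.5})

    def test_unknown_label_rejected(self):
        with pytest.raises(mm.ConfigError, match="unknown"):
            mm.SimulationConfig(category_proportions={"Mystery": 1.0})

    def test_group_sizes_must_be_at_least_two(self):
        with pytest.raises(mm.ConfigError):
            mm.SimulationConfig(group_sizes_m3={"ND": 1, "D": 5, "DI": 7})


class TestExpressionArchetypes:
    def test_noise_free_normalized_probe_ratio_exact(self):
        config = mm.SimulationConfig(
            n_probes=20, seed=1, cv=0.0, sample_scale_log2_sd=0.0,
            effect_size_fc=2.0, category_proportions={"Normalized": 1.0})
        matrix, design, truth = mm.simulate_expression(config)
        nd = matrix.signal[design.samples(group="ND")].mean(axis=1)
        d = matrix.signal[design.samples(group="D")].mean(axis=1)
        di = matrix.signal[design.samples(group="DI")].mean(axis=1)
        ratio = (d / nd).to_numpy() ** np.sign(truth["true_fc"].to_numpy())
        np.testing.assert_allclose(ratio, 2.0, rtol=1e-6)
        np.testing.assert_allclose((di / nd).to_numpy(), 1.0, rtol=1e-6)

    def test_noise_free_archetype_mean_structure(self):
        config = mm.SimulationConfig(
            n_probes=400, seed=2, cv=0.0, sample_scale_log2_sd=0.0,
            effect_size_fc=2.0,
            category_proportions={"Normalized": 0.25,
                                  "PartiallyNormalized": 0.25,
                                  "NotNormalized": 0.25, "Inverted": 0.25})
        matrix, design, truth = mm.simulate_expression(config)
        log2 = np.log2(matrix.signal)
        nd = log2[design.samples(group="ND")].mean(axis=1)
        d = log2[design.samples(group="D")].mean(axis=1)
        di = log2[design.samples(group="DI")].mean(axis=1)
        shift_d = (d - nd).to_numpy()
        shift_di = (di - nd).to_numpy()
        cats = truth["true_category"].to_numpy()
        np.testing.assert_allclose(np.abs(shift_d), 1.0, atol=1e-9)
        np.testing.assert_allclose(shift_di[cats == "Normalized"], 0.0,
                                   atol=1e-9)
        np.testing.assert_allclose(
            shift_di[cats == "PartiallyNormalized"],
            shift_d[cats == "PartiallyNormalized"] / 2, atol=1e-9)
        np.testing.assert_allclose(
            shift_di[cats == "NotNormalized"],
            shift_d[cats == "NotNormalized"], atol=1e-9)
        np.testing.assert_allclose(
            shift_di[cats == "Inverted"],
            -shift_d[cats == "Inverted"], atol=1e-9)

    def test_category_counts_match_configured_proportions(self):
        """Realized label counts are binomial draws at the configured
        proportions: exact binomial test per category, family-wise 99%
        confidence (Bonferroni over the six labels)."""
        config = mm.SimulationConfig(n_probes=2000, seed=9)
        _, _, truth = mm.simulate_expression(config)
        realized = truth["true_category"].value_counts()
        n_labels = len(config.category_proportions)
        for label, p in config.category_proportions.items():
            result = stats.binomtest(int(realized.get(label, 0)), 2000, p)
            assert result.pvalue > 0.01 / n_labels, label

    def test_every_probe_has_exactly_one_truth_label(self, sim_study):
        _, _, truth = sim_study
        assert truth.index.is_unique
        assert (truth["true_category"] != "").all()

    def test_undetected_probes_fail_filter_detected_pass(self, sim_study):
        matrix, design, truth = sim_study
        _, kept, dropped = mm.detection_filter(matrix, design)
        undetected = set(truth.index[truth["true_category"] == mm.UNDETECTED])
        assert undetected <= set(dropped)
        detected = set(truth.index) - undetected
        # detection p-values of detected probes clear the marginal threshold
        # in essentially every sample
        assert len(set(kept) & detected) / len(detected) > 0.99


class TestQpcrPanel:
    def test_noise_free_rescued_encoding(self):
        config = mm.SimulationConfig(seed=4, sigma_ct=0.0, target_ct_sd=0.0,
                                     qpcr_effect_fc=2.0)
        records, design = mm.simulate_qpcr(config, {"g1": "Rescued"})
        quantities = mm.ddct(records, design)
        frame = mm.rq_frame(quantities)
        frame["group"] = [design.group_of(s).value for s in frame.sample_id]
        frame["tp"] = [design.timepoint_of(s).value for s in frame.sample_id]
        m1_d = frame[(frame.tp == "M1") & (frame.group == "D")]
        m3_di = frame[(frame.tp == "M3") & (frame.group == "DI")]
        np.testing.assert_allclose(m1_d["ddct"], -1.0, atol=1e-12)
        np.testing.assert_allclose(m1_d["rq"], 2.0, atol=1e-12)
        np.testing.assert_allclose(m3_di["ddct"], 0.0, atol=1e-12)

    def test_control_gene_is_group_stable(self, small_config):
        records, design = mm.simulate_qpcr(small_config, {"g1": "Prevented"})
        ct = pd.DataFrame([(r.sample_id, r.ct) for r in records
                           if r.is_endogenous_control],
                          columns=["sample_id", "ct"])
        ct["group"] = [design.group_of(s).value for s in ct.sample_id]
        means = ct.groupby("group")["ct"].mean()
        # group means differ by at most a few SEM of the Ct noise
        assert means.max() - means.min() < 4 * small_config.sigma_ct

    def test_unknown_archetype_rejected(self, small_config):
        with pytest.raises(mm.ConfigError, match="archetype"):
            mm.simulate_qpcr(small_config, {"g1": "Vanished"})


class TestPhenotypes:
    def test_one_month_glucose_matches_reported_means(self, small_config):
        rng = np.random.default_rng(31)
        design = mm.SampleDesign.from_records(
            [(f"nd{i}", "ND", "M1") for i in range(8)]
            + [(f"d{i}", "D", "M1") for i in range(8)])
        records = mm.simulate_phenotype(design, small_config, rng=rng)
        d_glucose = np.mean([r.blood_glucose for r in records
                             if r.sample_id.startswith("d")])
        nd_glucose = np.mean([r.blood_glucose for r in records
                              if r.sample_id.startswith("nd")])
        # reported dispersion is SEM, so the group mean sits within ~3 SEM
        assert abs(d_glucose - 321) < 3 * 16
        assert abs(nd_glucose - 114) < 3 * 12
        assert all(r.hba1c_pct is None for r in records)  # not measured at M1

    def test_uncoupled_expression_r_centered_on_zero(self):
        rng = np.random.default_rng(41)
        y = rng.normal(5.5, 0.5, 7)
        rs = []
        for _ in range(200):
            frame = mm.simulate_coupled_expression(
                y, [f"s{i}" for i in range(7)], ["g"], true_r=0.0, rng=rng)
            r, _ = mm.pearson(frame.iloc[0].to_numpy(), y)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05
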