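"""2^-ddCt quantification, one-way ANOVA, the SNK stepwise procedure and
gene-level confirmation."""
import numpy as np
import pytest
from scipy import stats

import metmem as mm


def _design():
    return mm.SampleDesign.from_records(
        [("nd1", "ND", "M3"), ("nd2", "ND", "M3"),
         ("d1", "D", "M3"), ("d2", "D", "M3")])


class TestDdct:
    def test_worked_example_rq_four(self):
        # target Ct 24, control Ct 18 -> dCt 6; calibrator mean dCt 8
        # -> ddCt = -2 -> rq = 4.0 exactly
        records = [
            mm.QpcrRecord("nd1", "Actb", 16.0, True),
            mm.QpcrRecord("nd1", "g", 24.0),
            mm.QpcrRecord("nd2", "Actb", 16.0, True),
            mm.QpcrRecord("nd2", "g", 24.0),
            mm.QpcrRecord("d1", "Actb", 18.0, True),
            mm.QpcrRecord("d1", "g", 24.0),
            mm.QpcrRecord("d2", "Actb", 18.0, True),
            mm.QpcrRecord("d2", "g", 24.0),
        ]
        quantities = {q.sample_id: q for q in mm.ddct(records, _design())}
        assert quantities["d1"].delta_ct == 6.0
        assert quantities["d1"].ddct == -2.0
        assert quantities["d1"].rq == 4.0

    def test_calibrator_geometric_mean_is_one(self, small_config):
        records, design = mm.simulate_qpcr(small_config, {"g1": "NotRescued"})
        frame = mm.rq_frame(mm.ddct(records, design))
        frame["group"] = [design.group_of(s).value for s in frame.sample_id]
        frame["tp"] = [design.timepoint_of(s).value for s in frame.sample_id]
        for tp in ("M1", "M3"):
            nd = frame[(frame.group == "ND") & (frame.tp == tp)]
            geo = np.exp(np.log(nd["rq"]).mean())
            assert geo == pytest.approx(1.0, abs=1e-12)

    def test_per_sample_ct_shift_leaves_rq_unchanged(self):
        base = [
            mm.QpcrRecord("nd1", "Actb", 16.0, True), mm.QpcrRecord("nd1", "g", 23.0),
            mm.QpcrRecord("nd2", "Actb", 17.0, True), mm.QpcrRecord("nd2", "g", 24.5),
            mm.QpcrRecord("d1", "Actb", 18.0, True), mm.QpcrRecord("d1", "g", 23.2),
            mm.QpcrRecord("d2", "Actb", 16.5, True), mm.QpcrRecord("d2", "g", 22.0),
        ]
        shifted = [mm.QpcrRecord(r.sample_id, r.gene,
                                 r.ct + (0.7 if r.sample_id == "d1" else 0.0),
                                 r.is_endogenous_control) for r in base]
        rq0 = {q.sample_id: q.rq for q in mm.ddct(base, _design())}
        rq1 = {q.sample_id: q.rq for q in mm.ddct(shifted, _design())}
        for sample in rq0:
            assert rq1[sample] == pytest.approx(rq0[sample], rel=1e-12)

    def test_missing_control_names_sample(self):
        records = [
            mm.QpcrRecord("nd1", "Actb", 16.0, True), mm.QpcrRecord("nd1", "g", 23.0),
            mm.QpcrRecord("nd2", "Actb", 16.0, True), mm.QpcrRecord("nd2", "g", 23.0),
            mm.QpcrRecord("d1", "g", 23.2),
            mm.QpcrRecord("d2", "Actb", 16.5, True), mm.QpcrRecord("d2", "g", 22.0),
        ]
        with pytest.raises(mm.IntegrityError, match="d1"):
            mm.ddct(records, _design())


class TestAnova:
    def test_identical_groups(self):
        assert mm.anova_oneway([[1, 2, 3], [1, 2, 3], [1, 2, 3]]) == \
            pytest.approx((0.0, 1.0))

    def test_hand_computed_sums_of_squares(self):
        f, p = mm.anova_oneway([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert f == pytest.approx(3.0, abs=1e-9)
        assert p == pytest.approx(0.125, abs=1e-9)  # (1 + 2F/6)^-3

    def test_all_values_identical(self):
        assert mm.anova_oneway([[5, 5], [5, 5]]) == (0.0, 1.0)

    def test_f_equals_squared_t_for_two_groups(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
        f, p_f = mm.anova_oneway([a, b])
        t = stats.ttest_ind(a, b)
        assert f == pytest.approx(float(t.statistic) ** 2, rel=1e-9)
        assert p_f == pytest.approx(float(t.pvalue), rel=1e-9)

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(17)
        groups = [rng.normal(0, 1, (10_000, 8)) for _ in range(3)]
        p = stats.f_oneway(*groups, axis=1).pvalue
        assert 0.045 <= float((p < 0.05).mean()) <= 0.055


class TestSnk:
    def test_identical_means_empty(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 8)
        result = mm.snk_posthoc([base, base + 1e-15, base], labels="abc")
        assert result.significant_pairs == frozenset()

    def test_single_extreme_group(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.2, 8)
        b = rng.normal(0, 0.2, 8)
        c = rng.normal(5, 0.2, 8)  # separation >> within-group SD
        result = mm.snk_posthoc([a, b, c], labels=["a", "b", "c"])
        assert result.significant_pairs == frozenset(
            {frozenset({"a", "c"}), frozenset({"b", "c"})})

    def test_critical_values_match_published_tables(self):
        # studentized-range quantiles q(0.05, span, df) spot-checked against
        # the standard tabulated values
        assert stats.studentized_range.ppf(0.95, 2, 10) == pytest.approx(
            3.151, abs=2e-3)
        assert stats.studentized_range.ppf(0.95, 3, 10) == pytest.approx(
            3.877, abs=2e-3)

    def test_blocking_forbids_subspan_rejections(self):
        """If the full span is not significant, nothing inside it may be."""
        rng = np.random.default_rng(6)
        for _ in range(40):
            k = int(rng.integers(3, 6))
            groups = [rng.normal(rng.uniform(0, 0.8), 1, 8) for _ in range(k)]
            result = mm.snk_posthoc(groups, labels=list(range(k)))
            means = np.array([np.mean(g) for g in groups])
            order = np.argsort(means)
            mse = np.mean([np.var(g, ddof=1) for g in groups])
            full_q = (means[order[-1]] - means[order[0]]) / np.sqrt(mse / 8)
            crit = stats.studentized_range.ppf(0.95, k, k * 8 - k)
            if full_q <= crit:
                assert result.significant_pairs == frozenset()

    def test_unbalanced_uses_harmonic_n_and_flags_it(self):
        rng = np.random.default_rng(7)
        result = mm.snk_posthoc(
            [rng.normal(0, 1, 8), rng.normal(0, 1, 5), rng.normal(4, 1, 7)],
            labels=["ND", "D", "DI"])
        assert result.harmonic_n_used

    def test_familywise_error_under_complete_null(self):
        rng = np.random.default_rng(19)
        hits = 0
        reps = 600
        for _ in range(reps):
            groups = [rng.normal(0, 1, 8) for _ in range(3)]
            if mm.snk_posthoc(groups).significant_pairs:
                hits += 1
        # complete-null familywise error tracks the per-span alpha
        assert hits / reps <= 0.07


class TestConfirmGene:
    def _groups(self, rng, mean_nd, mean_d, mean_di, n=8, sd=0.1):
        return {"ND": rng.normal(mean_nd, sd, n),
                "D": rng.normal(mean_d, sd, n),
                "DI": rng.normal(mean_di, sd, n)}

    def test_rescued_gene_recovered_end_to_end(self):
        rng = np.random.default_rng(23)
        result = mm.confirm_gene(
            "g", self._groups(rng, 1.0, 2.0, 1.0),
            m1_values={"ND": rng.normal(1.0, 0.1, 8),
                       "D": rng.normal(2.0, 0.1, 8)})
        assert result.confirmed
        assert result.m1_de
        assert result.m3_category is mm.ResponseCategory.NORMALIZED
        assert result.temporal is mm.TemporalCategory.RESCUED

    def test_prevented_pattern(self):
        rng = np.random.default_rng(24)
        result = mm.confirm_gene(
            "g", self._groups(rng, 1.0, 2.0, 1.0),
            m1_values={"ND": rng.normal(1.0, 0.1, 8),
                       "D": rng.normal(1.0, 0.1, 8)})
        assert result.confirmed and not result.m1_de
        assert result.temporal is mm.TemporalCategory.PREVENTED

    def test_null_gene_rarely_confirmed(self):
        rng = np.random.default_rng(25)
        confirmed = sum(
            mm.confirm_gene("g", self._groups(rng, 1.0, 1.0, 1.0, sd=0.3))
            .confirmed
            for _ in range(200))
        assert confirmed / 200 <= 0.05

    def test_full_panel_confirmation_rate(self, small_config):
        records, design = mm.simulate_qpcr(small_config, mm.DEFAULT_QPCR_PANEL)
        results = mm.analyze_qpcr(records, design)
        confirmed, examined, pct = mm.confirmation_rate(results)
        assert examined == 26
        assert confirmed == 26  # clear 2-fold effects at low Ct noise
        # Rescued-family genes must show a 1-month change, Prevented not
        for r in results:
            assert r.temporal is not None or \
                r.m3_category is mm.ResponseCategory.INVERTED
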