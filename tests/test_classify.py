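"""The four-way insulin-response partition and the temporal refinement."""
import itertools

import numpy as np
import pandas as pd
import pytest

import metmem as mm
from metmem.diffexpr import ProbeComparisonStats, UP, DOWN, NONE


def _stats(probe, p, fc, mean_a=100.0):
    direction = UP if fc > 1 else DOWN if fc < -1 else NONE
    mean_b = mean_a * fc if fc > 0 else mean_a / abs(fc)
    return ProbeComparisonStats(probe, p, fc, direction, mean_a, mean_b)


SIG, NS = 0.001, 0.5


class TestClassifyResponse:
    @pytest.mark.parametrize("p_nd_di, fc_nd_di, p_d_di, expected", [
        (SIG, 1.8, NS, mm.ResponseCategory.NOT_NORMALIZED),   # same direction
        (SIG, -1.8, NS, mm.ResponseCategory.INVERTED),        # flipped
        (NS, 1.1, SIG, mm.ResponseCategory.NORMALIZED),
        (NS, 1.1, NS, mm.ResponseCategory.PARTIALLY_NORMALIZED),
    ])
    def test_category_defining_patterns_up_regulated_probe(self, p_nd_di,
                                                           fc_nd_di,
                                                           p_d_di, expected):
        category, evidence = mm.classify_response(
            _stats("p", SIG, 2.0),
            _stats("p", p_nd_di, fc_nd_di),
            _stats("p", p_d_di, -1.5),
        )
        assert category is expected
        assert evidence.rule_path[0] == "de_ND_D"
        assert len(evidence.rule_path) >= 2

    def test_non_de_probe_is_contract_error(self):
        with pytest.raises(mm.ContractError):
            mm.classify_response(_stats("p", 0.2, 2.0),
                                 _stats("p", NS, 1.1), _stats("p", NS, 1.1))
        with pytest.raises(mm.ContractError):
            # significant but below the fold-change cutoff
            mm.classify_response(_stats("p", SIG, 1.15),
                                 _stats("p", NS, 1.1), _stats("p", NS, 1.1))

    def test_partition_exhaustive_and_exclusive(self):
        """Every significance/direction pattern yields exactly one category."""
        seen = set()
        for primary_dir, nd_di_sig, nd_di_dir, d_di_sig in itertools.product(
                (1, -1), (True, False), (1, -1), (True, False)):
            category, evidence = mm.classify_response(
                _stats("p", SIG, primary_dir * 2.0),
                _stats("p", SIG if nd_di_sig else NS, nd_di_dir * 1.6),
                _stats("p", SIG if d_di_sig else NS, 1.5),
            )
            assert isinstance(category, mm.ResponseCategory)
            assert evidence.rule_path  # auditability
            seen.add(category)
        assert seen == set(mm.ResponseCategory)

    def test_direction_flip_symmetry(self):
        """Mirroring every fold change (up <-> down) leaves labels fixed."""
        for nd_di_sig, nd_di_dir, d_di_sig in itertools.product(
                (True, False), (1, -1), (True, False)):
            args = lambda s: (
                _stats("p", SIG, s * 2.0),
                _stats("p", SIG if nd_di_sig else NS, s * nd_di_dir * 1.6),
                _stats("p", SIG if d_di_sig else NS, s * 1.5))
            up_cat, _ = mm.classify_response(*args(+1))
            down_cat, _ = mm.classify_response(*args(-1))
            assert up_cat is down_cat

    def test_all_three_significant_same_direction_is_not_normalized(self):
        # the overlapping pattern the precedence order resolves
        category, _ = mm.classify_response(
            _stats("p", SIG, 2.0), _stats("p", SIG, 1.5),
            _stats("p", SIG, -1.4))
        assert category is mm.ResponseCategory.NOT_NORMALIZED

    def test_secondary_fc_option_requires_fold_change(self):
        # significant ND-vs-DI p with tiny FC: NotNormalized by default,
        # but with the secondary FC cutoff the probe falls through
        rule = mm.SecondaryRule(alpha=0.05, use_fc=True, fc_cutoff=1.2)
        category, _ = mm.classify_response(
            _stats("p", SIG, 2.0), _stats("p", SIG, 1.1),
            _stats("p", NS, 1.1), secondary=rule)
        assert category is mm.ResponseCategory.PARTIALLY_NORMALIZED


class TestClassifyTable:
    def test_agrees_with_scalar_classifier(self, filtered_study):
        filtered, design, _, table = filtered_study
        categories = mm.classify_table(table)
        for probe in list(categories.index)[:50]:
            scalar, _ = mm.classify_response(
                table.stats(probe, mm.Group.ND, mm.Group.D),
                table.stats(probe, mm.Group.ND, mm.Group.DI),
                table.stats(probe, mm.Group.D, mm.Group.DI))
            assert categories.loc[probe] is scalar

    def test_covers_exactly_the_de_probes(self, filtered_study):
        _, _, _, table = filtered_study
        categories = mm.classify_table(table)
        de = mm.de_mask(table)
        assert set(categories.index) == set(table.frame.index[de])


class TestPartitionCounts:
    def test_published_scale_arithmetic(self):
        counts = mm.partition_counts({
            mm.ResponseCategory.NORMALIZED: 789,
            mm.ResponseCategory.PARTIALLY_NORMALIZED: 514,
            mm.ResponseCategory.NOT_NORMALIZED: 65,
            mm.ResponseCategory.INVERTED: 8,
        })
        assert counts.total == 1376
        assert counts.percentages[mm.ResponseCategory.NORMALIZED] == 57
        assert counts.percentages[mm.ResponseCategory.PARTIALLY_NORMALIZED] == 37
        assert counts.percentages[mm.ResponseCategory.NOT_NORMALIZED] == 5
        assert counts.percentages[mm.ResponseCategory.INVERTED] == 1

    def test_empty_input_all_zero(self):
        counts = mm.partition_counts({})
        assert counts.total == 0
        assert all(v == 0 for v in counts.counts.values())
        assert all(v == 0 for v in counts.percentages.values())

    def test_counts_conserve_de_total(self, filtered_study):
        _, _, _, table = filtered_study
        categories = mm.classify_table(table)
        counts = mm.partition_counts(categories)
        assert sum(counts.counts.values()) == len(categories)

    def test_half_up_rounding(self):
        counts = mm.partition_counts({
            mm.ResponseCategory.NORMALIZED: 1,
            mm.ResponseCategory.PARTIALLY_NORMALIZED: 199,
        })
        # 1/200 = 0.5% rounds up, not to even
        assert counts.percentages[mm.ResponseCategory.NORMALIZED] == 1


class TestClassifyTemporal:
    @pytest.mark.parametrize("de_m1, category, expected", [
        (True, mm.ResponseCategory.NORMALIZED, mm.TemporalCategory.RESCUED),
        (True, mm.ResponseCategory.PARTIALLY_NORMALIZED,
         mm.TemporalCategory.PARTIALLY_RESCUED),
        (True, mm.ResponseCategory.NOT_NORMALIZED,
         mm.TemporalCategory.NOT_RESCUED),
        (False, mm.ResponseCategory.NORMALIZED, mm.TemporalCategory.PREVENTED),
        (False, mm.ResponseCategory.PARTIALLY_NORMALIZED,
         mm.TemporalCategory.PARTIALLY_PREVENTED),
        (False, mm.ResponseCategory.NOT_NORMALIZED,
         mm.TemporalCategory.NOT_PREVENTED),
    ])
    def test_exhaustive_lookup(self, de_m1, category, expected):
        assert mm.classify_temporal(de_m1, category) is expected

    def test_inverted_is_unmapped_not_an_error(self):
        assert mm.classify_temporal(True, mm.ResponseCategory.INVERTED) is None
        assert mm.classify_temporal(False, mm.ResponseCategory.INVERTED) is None
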