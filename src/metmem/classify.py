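"""The four-way insulin-response partition and the two-timepoint
Rescued/Prevented refinement.

Four-way partition (one label per diabetes-altered probe)
---------------------------------------------------------
A probe differentially expressed between non-diabetic (ND) and diabetic (D)
animals is categorized by what the insulin-treated diabetic (DI) arm looks
like, via an ordered decision tree on the two secondary comparisons:

1. ND-vs-DI significant, direction *opposite* to ND-vs-D  ->  Inverted
2. ND-vs-DI significant, *same* direction                 ->  NotNormalized
3. otherwise, D-vs-DI significant                         ->  Normalized
4. otherwise                                              ->  PartiallyNormalized

The ND-vs-DI status is tested first because every category is defined by
whether treated animals still differ from controls; this precedence makes
the partition exhaustive and exclusive even for patterns where all three
comparisons are significant. Secondary comparisons use the p-value alone by
default (the fold-change cutoff belongs to the primary ND-vs-D call);
``secondary_fc`` applies the cutoff everywhere.

Note that PartiallyNormalized is an operational gray zone: it is the label
for treated animals that can be distinguished from *neither* arm, so its
reach depends on the power of the secondary tests, not only on where the
treated-group mean truly lies.

Temporal refinement (genes measured at both timepoints)
-------------------------------------------------------
Combining the 1-month (pre-insulin) DE status with the 3-month category:
changes already present at one month are Rescued / PartiallyRescued /
NotRescued according to the 3-month label; changes absent at one month are
Prevented / PartiallyPrevented / NotPrevented. A gene Inverted at three
months has no defined temporal label and maps to ``None``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import Group, ResponseCategory, TemporalCategory
from .diffexpr import (
    ComparisonSpec,
    ComparisonTable,
    ProbeComparisonStats,
    comparison_key,
    de_mask,
)
from .errors import ConfigError, ContractError


@dataclass(frozen=True)
class SecondaryRule:
    """Significance rule for the ND-vs-DI and D-vs-DI comparisons."""

    alpha: float = 0.05
    use_fc: bool = False
    fc_cutoff: float = 1.2

    def significant(self, p_value: float, signed_fc: float) -> bool:
        sig = p_value < self.alpha
        if self.use_fc:
            sig = sig and abs(signed_fc) > self.fc_cutoff
        return sig


@dataclass(frozen=True)
class ClassificationEvidence:
    """Audit trail for one probe's category: the significance pattern seen
    and the ordered rule identifiers that fired."""

    probe_id: str
    de_nd_d: bool
    dir_nd_d: int            # sign of the ND-vs-D fold change
    sig_nd_di: bool
    dir_nd_di: int
    sig_d_di: bool
    rule_path: tuple[str, ...]


def classify_response(
    stats_nd_d: ProbeComparisonStats,
    stats_nd_di: ProbeComparisonStats,
    stats_d_di: ProbeComparisonStats,
    primary: ComparisonSpec | None = None,
    secondary: SecondaryRule | None = None,
) -> tuple[ResponseCategory, ClassificationEvidence]:
    """Assign the insulin-response category of one DE probe.

    Raises ContractError if the probe is not differentially expressed
    between ND and D under the primary rule — non-DE probes carry no label.
    """
    primary = primary or ComparisonSpec(Group.ND, Group.D)
    secondary = secondary or SecondaryRule(alpha=primary.alpha)

    de = (stats_nd_d.p_value < primary.alpha
          and abs(stats_nd_d.signed_fc) > primary.fc_cutoff)
    if not de:
        raise ContractError(
            f"probe {stats_nd_d.probe_id} is not DE between ND and D; "
            "classification is defined only for DE probes"
        )
    dir_primary = int(np.sign(stats_nd_d.signed_fc)) if abs(stats_nd_d.signed_fc) > 1 else 0
    dir_nd_di = int(np.sign(stats_nd_di.signed_fc)) if abs(stats_nd_di.signed_fc) > 1 else 0
    sig_nd_di = secondary.significant(stats_nd_di.p_value, stats_nd_di.signed_fc) and dir_nd_di != 0
    sig_d_di = secondary.significant(stats_d_di.p_value, stats_d_di.signed_fc)

    path = ["de_ND_D"]
    if sig_nd_di and dir_nd_di == -dir_primary:
        path.append("ND_DI_sig_opposite")
        category = ResponseCategory.INVERTED
    elif sig_nd_di:
        path.append("ND_DI_sig_same")
        category = ResponseCategory.NOT_NORMALIZED
    elif sig_d_di:
        path.extend(["ND_DI_ns", "D_DI_sig"])
        category = ResponseCategory.NORMALIZED
    else:
        path.extend(["ND_DI_ns", "D_DI_ns"])
        category = ResponseCategory.PARTIALLY_NORMALIZED

    evidence = ClassificationEvidence(
        probe_id=stats_nd_d.probe_id,
        de_nd_d=True,
        dir_nd_d=dir_primary,
        sig_nd_di=sig_nd_di,
        dir_nd_di=dir_nd_di,
        sig_d_di=sig_d_di,
        rule_path=tuple(path),
    )
    return category, evidence


def classify_table(
    table: ComparisonTable,
    alpha: float = 0.05,
    fc_cutoff: float = 1.2,
    secondary: SecondaryRule | None = None,
) -> pd.Series:
    """Vectorized four-way classification of every DE probe in a comparison
    table.

    Returns a Series (probe id -> ResponseCategory) covering exactly the
    probes DE between ND and D under the primary rule.
    """
    secondary = secondary or SecondaryRule(alpha=alpha)
    frame = table.frame
    de = de_mask(table, alpha=alpha, fc_cutoff=fc_cutoff)
    sub = frame.loc[de]

    k_nd_di = comparison_key(Group.ND, Group.DI)
    k_d_di = comparison_key(Group.D, Group.DI)
    dir_primary = np.sign(sub[f"fc_{comparison_key(Group.ND, Group.D)}"].to_numpy())
    fc_nd_di = sub[f"fc_{k_nd_di}"].to_numpy()
    dir_nd_di = np.where(np.abs(fc_nd_di) > 1, np.sign(fc_nd_di), 0.0)

    sig_nd_di = sub[f"p_{k_nd_di}"].to_numpy() < secondary.alpha
    sig_d_di = sub[f"p_{k_d_di}"].to_numpy() < secondary.alpha
    if secondary.use_fc:
        sig_nd_di &= np.abs(fc_nd_di) > secondary.fc_cutoff
        sig_d_di &= np.abs(sub[f"fc_{k_d_di}"].to_numpy()) > secondary.fc_cutoff
    sig_nd_di &= dir_nd_di != 0

    categories = np.where(
        sig_nd_di & (dir_nd_di == -dir_primary),
        ResponseCategory.INVERTED.value,
        np.where(
            sig_nd_di,
            ResponseCategory.NOT_NORMALIZED.value,
            np.where(
                sig_d_di,
                ResponseCategory.NORMALIZED.value,
                ResponseCategory.PARTIALLY_NORMALIZED.value,
            ),
        ),
    )
    return pd.Series(
        [ResponseCategory(c) for c in categories], index=sub.index, name="category"
    )


@dataclass(frozen=True)
class PartitionCounts:
    """Category counts with integer percentages of the DE total."""

    counts: dict[ResponseCategory, int]
    total: int
    percentages: dict[ResponseCategory, int]


def _percent_half_up(count: int, total: int) -> int:
    if total == 0:
        return 0
    ratio = Decimal(count) * 100 / Decimal(total)
    return int(ratio.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def partition_counts(
    categories: Mapping[str, ResponseCategory] | pd.Series | Mapping[ResponseCategory, int],
) -> PartitionCounts:
    """Count probes per response category.

    Accepts either a probe -> category mapping/Series or a pre-tallied
    category -> count mapping. Percentages are computed on the DE total and
    rounded half-up to integers.
    """
    counts = {c: 0 for c in ResponseCategory}
    if isinstance(categories, pd.Series):
        items = categories.value_counts().items()
        for cat, n in items:
            counts[ResponseCategory(cat)] = int(n)
    elif categories and all(isinstance(k, ResponseCategory) or k in
                            {c.value for c in ResponseCategory}
                            for k in categories) and all(
                                isinstance(v, (int, np.integer))
                                for v in categories.values()):
        for cat, n in categories.items():
            counts[ResponseCategory(cat)] = int(n)
    else:
        for cat in categories.values():
            counts[ResponseCategory(cat)] += 1
    total = sum(counts.values())
    percentages = {c: _percent_half_up(n, total) for c, n in counts.items()}
    return PartitionCounts(counts=counts, total=total, percentages=percentages)


#: classify_temporal is a pure 2x3 lookup (plus the unmapped Inverted case).
_TEMPORAL_LOOKUP: dict[tuple[bool, ResponseCategory], TemporalCategory] = {
    (True, ResponseCategory.NORMALIZED): TemporalCategory.RESCUED,
    (True, ResponseCategory.PARTIALLY_NORMALIZED): TemporalCategory.PARTIALLY_RESCUED,
    (True, ResponseCategory.NOT_NORMALIZED): TemporalCategory.NOT_RESCUED,
    (False, ResponseCategory.NORMALIZED): TemporalCategory.PREVENTED,
    (False, ResponseCategory.PARTIALLY_NORMALIZED): TemporalCategory.PARTIALLY_PREVENTED,
    (False, ResponseCategory.NOT_NORMALIZED): TemporalCategory.NOT_PREVENTED,
}


def classify_temporal(
    de_at_m1: bool,
    category_m3: ResponseCategory,
) -> TemporalCategory | None:
    """Combine 1-month DE status with the 3-month category.

    A change already present at one month (before insulin) is in the
    Rescued family; one absent at a month is in the Prevented family. Genes
    Inverted at three months have no defined temporal label and return
    ``None`` (explicitly unmapped, not an error).
    """
    category_m3 = ResponseCategory(category_m3)
    if category_m3 is ResponseCategory.INVERTED:
        return None
    return _TEMPORAL_LOOKUP[(bool(de_at_m1), category_m3)]
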