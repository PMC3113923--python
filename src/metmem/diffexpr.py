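"""Per-probe pairwise differential expression: two-sample t-tests and signed
fold changes, combined by the joint rule p < alpha AND |FC| > cutoff (both
strict, defaults 0.05 and 1.2).

Fold changes are ratios of linear-scale group means written in the
negative-reciprocal convention (halving is -2.0), so |FC| >= 1 always and
the sign is the direction of regulation of group B relative to group A.
The pooled-variance t-test is the default (the classic expression-suite
behavior); Welch is available per comparison.

No multiple-testing correction is applied by default — the joint p/FC rule
is used as-is; :func:`bh_adjust` provides optional Benjamini-Hochberg
adjusted p-values for the rigor-minded.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, Group, SampleDesign, Timepoint
from .errors import ConfigError, ContractError

POOLED = "pooled"
WELCH = "welch"

UP = "up"
DOWN = "down"
NONE = "none"

#: The three pairwise comparisons of the three-arm design, in reporting order.
COMPARISONS: tuple[tuple[Group, Group], ...] = (
    (Group.ND, Group.D),
    (Group.ND, Group.DI),
    (Group.D, Group.DI),
)


def comparison_key(group_a: Group, group_b: Group) -> str:
    return f"{group_a.value}_{group_b.value}"


@dataclass(frozen=True)
class ComparisonSpec:
    """Thresholds and test variant for one pairwise comparison."""

    group_a: Group
    group_b: Group
    alpha: float = 0.05
    fc_cutoff: float = 1.2
    test_variant: str = POOLED

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha={self.alpha} outside (0, 1)")
        if self.fc_cutoff < 1:
            raise ConfigError(f"fc_cutoff={self.fc_cutoff} must be >= 1")
        if self.test_variant not in (POOLED, WELCH):
            raise ConfigError(f"unknown test variant {self.test_variant!r}")


@dataclass(frozen=True)
class ProbeComparisonStats:
    """One probe's statistics for one pairwise comparison."""

    probe_id: str
    p_value: float
    signed_fc: float
    direction: str
    mean_a: float
    mean_b: float


def probe_ttest(values_a, values_b, variant: str = POOLED) -> float:
    """Two-tailed two-sample t-test p-value.

    ``pooled`` uses the pooled-variance statistic with df = n_a + n_b - 2;
    ``welch`` uses the Welch-Satterthwaite approximation. Degenerate inputs
    follow the convention: zero variance in both groups gives p = 1 for
    equal means and p = 0 for unequal means.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ContractError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ContractError("non-finite values in t-test input")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    result = stats.ttest_ind(a, b, equal_var=(variant == POOLED))
    return float(result.pvalue)


def fold_change(mean_a: float, mean_b: float) -> tuple[float, str]:
    """Signed fold change of ``mean_b`` relative to ``mean_a``.

    Returns ``(signed_fc, direction)`` with |signed_fc| = max(b/a, a/b) and
    the sign giving the direction (positive = up in B). Equal means give
    (+1.0, "none").
    """
    if mean_a <= 0 or mean_b <= 0:
        raise ContractError("fold change requires positive means")
    if mean_b > mean_a:
        return mean_b / mean_a, UP
    if mean_b < mean_a:
        return -(mean_a / mean_b), DOWN
    return 1.0, NONE


def call_de(stats_row: ProbeComparisonStats, spec: ComparisonSpec) -> bool:
    """Joint differential-expression call: p < alpha AND |FC| > cutoff,
    both strictly — a probe exactly at either boundary is not called."""
    return (stats_row.p_value < spec.alpha
            and abs(stats_row.signed_fc) > spec.fc_cutoff)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional rigor mode)."""
    return stats.false_discovery_control(np.asarray(p_values, float), method="bh")


# ---------------------------------------------------------------------------
# vectorized machinery over whole matrices
# ---------------------------------------------------------------------------

def _ttest_matrix(a: np.ndarray, b: np.ndarray, variant: str) -> np.ndarray:
    """Row-wise two-tailed t-test p-values for probes x samples blocks,
    with the zero-variance conventions applied."""
    res = stats.ttest_ind(a, b, axis=1, equal_var=(variant == POOLED))
    p = np.asarray(res.pvalue, dtype=float)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        equal = a.mean(axis=1) == b.mean(axis=1)
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def _fold_change_vector(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        fc = np.where(mean_b >= mean_a, mean_b / mean_a, -(mean_a / mean_b))
    fc[mean_a == mean_b] = 1.0
    return fc


@dataclass
class ComparisonTable:
    """All three pairwise comparisons for every probe.

    ``frame`` holds, per probe: ``mean_<G>`` for each group and
    ``p_<A>_<B>`` / ``fc_<A>_<B>`` per comparison. Accessors return the
    per-probe dataclass for single-probe work.
    """

    frame: pd.DataFrame
    timepoint: Timepoint = Timepoint.M3

    def stats(self, probe_id: str, group_a: Group, group_b: Group) -> ProbeComparisonStats:
        key = comparison_key(group_a, group_b)
        row = self.frame.loc[probe_id]
        return ProbeComparisonStats(
            probe_id=probe_id,
            p_value=float(row[f"p_{key}"]),
            signed_fc=float(row[f"fc_{key}"]),
            direction=_direction_of(float(row[f"fc_{key}"])),
            mean_a=float(row[f"mean_{group_a.value}"]),
            mean_b=float(row[f"mean_{group_b.value}"]),
        )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.frame.index)


def _direction_of(signed_fc: float) -> str:
    if signed_fc > 1.0:
        return UP
    if signed_fc < -1.0:
        return DOWN
    return NONE


def run_all_comparisons(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    timepoint: Timepoint | str = Timepoint.M3,
    variant: str = POOLED,
    comparisons: tuple[tuple[Group, Group], ...] = COMPARISONS,
) -> ComparisonTable:
    """Compute p-value and signed fold change for every probe and every
    requested pairwise comparison at one timepoint.

    Deterministic and invariant to sample order; every probe of the input
    matrix appears in the output.
    """
    tp = Timepoint(timepoint)
    group_values: dict[Group, np.ndarray] = {}
    needed = sorted({g for pair in comparisons for g in pair}, key=lambda g: g.value)
    for group in needed:
        samples = design.samples(group=group, timepoint=tp)
        samples = [s for s in samples if s in matrix.signal.columns]
        if len(samples) < 2:
            raise ConfigError(
                f"group {group.value} at {tp.value} has fewer than 2 samples "
                "in the matrix"
            )
        group_values[group] = matrix.signal[samples].to_numpy(dtype=float)

    out = pd.DataFrame(index=matrix.signal.index.copy())
    for group, values in group_values.items():
        out[f"mean_{group.value}"] = values.mean(axis=1)
    for group_a, group_b in comparisons:
        key = comparison_key(group_a, group_b)
        a, b = group_values[group_a], group_values[group_b]
        out[f"p_{key}"] = _ttest_matrix(a, b, variant)
        out[f"fc_{key}"] = _fold_change_vector(a.mean(axis=1), b.mean(axis=1))
    return ComparisonTable(frame=out, timepoint=tp)


def de_mask(
    table: ComparisonTable,
    group_a: Group = Group.ND,
    group_b: Group = Group.D,
    alpha: float = 0.05,
    fc_cutoff: float = 1.2,
) -> pd.Series:
    """Boolean mask of probes differentially expressed between two groups
    under the joint strict rule."""
    key = comparison_key(group_a, group_b)
    frame = table.frame
    return (frame[f"p_{key}"] < alpha) & (frame[f"fc_{key}"].abs() > fc_cutoff)
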