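"""Relative quantification by the 2^-ddCt method and the confirmation
statistics used on it.

2^-ddCt
-------
For each sample, dCt = Ct(target) - Ct(endogenous control); referencing to
the calibrator group's mean dCt gives ddCt, and relative expression
rq = 2^-ddCt under the assumption of perfect doubling per cycle
(amplification efficiency 2.0). The calibrator is the non-diabetic group at
the same timepoint, so treated and untreated diabetic expression is read as
fold-of-control; by construction the calibrator group's geometric-mean rq
is exactly 1. Lower Ct means higher expression.

Confirmation statistics
-----------------------
Three-month data (ND / D / DI) are tested by one-way ANOVA followed by the
Student-Newman-Keuls (SNK) stepwise multiple-comparison procedure; the SNK
step is gated on ANOVA significance. One-month data (ND / D only) use a
two-tailed two-sample t-test. A gene is *confirmed* when the ANOVA is
significant and SNK separates ND from D at three months. Statistics run on
rq values by default (matching how such results are usually plotted);
``on_dct=True`` tests on the dCt scale instead, which is the statistically
better-behaved choice.

SNK critical values come from the studentized-range distribution evaluated
numerically (``scipy.stats.studentized_range``); unbalanced designs use the
harmonic mean of the two group sizes in each comparison (flagged in the
result).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import classify_temporal
from .containers import (
    Group,
    QpcrRecord,
    RelativeQuantity,
    ResponseCategory,
    SampleDesign,
    TemporalCategory,
    Timepoint,
)
from .diffexpr import probe_ttest
from .errors import ConfigError, ContractError, IntegrityError

EFFICIENCY = 2.0  # assumed perfect doubling per PCR cycle


@lru_cache(maxsize=4096)
def _q_crit(alpha: float, span: int, df_error: int) -> float:
    """Upper-alpha studentized-range quantile (cached: the numerical
    inversion is expensive and (span, df) pairs repeat heavily)."""
    return float(stats.studentized_range.ppf(1 - alpha, span, df_error))


# ---------------------------------------------------------------------------
# relative quantification
# ---------------------------------------------------------------------------

def ddct(
    records: Sequence[QpcrRecord],
    design: SampleDesign,
    calibrator_group: Group | str = Group.ND,
) -> list[RelativeQuantity]:
    """Compute per-sample relative expression for every target gene.

    The calibrator is ``calibrator_group`` *at the sample's own timepoint*,
    so one-month and three-month panels are each normalized to their own
    controls. Raises IntegrityError (naming the sample) if any sample with
    target wells lacks a control well.
    """
    calibrator = Group(calibrator_group)
    controls: dict[str, list[float]] = {}
    control_genes = {r.gene for r in records if r.is_endogenous_control}
    if not control_genes:
        raise IntegrityError("no endogenous-control wells in qPCR records")
    if len(control_genes) > 1:
        raise IntegrityError(
            f"multiple endogenous-control genes: {sorted(control_genes)}"
        )
    for r in records:
        if r.is_endogenous_control:
            controls.setdefault(r.sample_id, []).append(r.ct)

    targets = [r for r in records if not r.is_endogenous_control]
    lacking = sorted({r.sample_id for r in targets} - set(controls))
    if lacking:
        raise IntegrityError(f"samples missing control-gene Ct: {lacking}")

    control_ct = {s: float(np.mean(v)) for s, v in controls.items()}
    delta = pd.DataFrame(
        [(r.sample_id, r.gene, r.ct - control_ct[r.sample_id]) for r in targets],
        columns=["sample_id", "gene", "delta_ct"],
    )
    delta["timepoint"] = [design.timepoint_of(s).value for s in delta["sample_id"]]

    out: list[RelativeQuantity] = []
    for (gene, tp), block in delta.groupby(["gene", "timepoint"], sort=False):
        cal_samples = set(design.samples(group=calibrator, timepoint=tp))
        cal_dct = block.loc[block["sample_id"].isin(cal_samples), "delta_ct"]
        if cal_dct.empty:
            raise IntegrityError(
                f"gene {gene}: no calibrator ({calibrator.value}) samples at {tp}"
            )
        reference = float(cal_dct.mean())
        for _, row in block.iterrows():
            ddct_value = float(row["delta_ct"]) - reference
            out.append(RelativeQuantity(
                sample_id=row["sample_id"],
                gene=gene,
                delta_ct=float(row["delta_ct"]),
                ddct=ddct_value,
                rq=float(EFFICIENCY ** (-ddct_value)),
            ))
    return out


def rq_frame(quantities: Sequence[RelativeQuantity]) -> pd.DataFrame:
    """Tidy DataFrame of relative quantities (sample_id, gene, delta_ct,
    ddct, rq)."""
    return pd.DataFrame(
        [(q.sample_id, q.gene, q.delta_ct, q.ddct, q.rq) for q in quantities],
        columns=["sample_id", "gene", "delta_ct", "ddct", "rq"],
    )


# ---------------------------------------------------------------------------
# one-way ANOVA and the SNK stepwise procedure
# ---------------------------------------------------------------------------

def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Fixed-effects one-way ANOVA; returns (F, p).

    All values identical across every group gives (0.0, 1.0) by convention;
    zero within-group variance with distinct means gives (inf, 0.0).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ContractError("ANOVA needs >=2 groups with >=2 values each")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    if all(a.var(ddof=1) == 0.0 for a in arrays):
        return float("inf"), 0.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


@dataclass(frozen=True)
class SnkResult:
    """Outcome of the SNK stepwise procedure.

    ``significant_pairs`` holds frozensets of group labels whose means the
    procedure separates at the requested alpha. ``harmonic_n_used`` flags
    unbalanced designs, where each comparison used the harmonic mean of the
    two group sizes.
    """

    significant_pairs: frozenset[frozenset]
    alpha: float
    df_error: int
    harmonic_n_used: bool
    means: dict


def snk_posthoc(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence | None = None,
) -> SnkResult:
    """Student-Newman-Keuls stepwise comparisons on a one-way layout.

    Group means are ranked; the range of each span of r adjacent ordered
    means is tested against q(alpha, r, df_error) from the studentized-range
    distribution, largest spans first, and a non-significant span blocks all
    comparisons nested inside it (the defining step-down logic of the
    procedure).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2 or any(a.size < 2 for a in arrays):
        raise ContractError("SNK needs >=2 groups with >=2 values each")
    if labels is None:
        labels = list(range(k))
    if len(labels) != k:
        raise ConfigError("labels length must match number of groups")

    sizes = np.array([a.size for a in arrays])
    n_total = int(sizes.sum())
    df_error = n_total - k
    mse = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays) / df_error
    means = np.array([a.mean() for a in arrays])
    order = np.argsort(means, kind="stable")
    unbalanced = len(set(sizes.tolist())) > 1

    significant: set[frozenset] = set()
    blocked: list[tuple[int, int]] = []  # ordered-position intervals found ns
    if mse == 0.0:
        # Degenerate layout with no within-group spread: any difference in
        # means is a perfect separation.
        for i, j in itertools.combinations(range(k), 2):
            if means[i] != means[j]:
                significant.add(frozenset({labels[i], labels[j]}))
        return SnkResult(frozenset(significant), alpha, df_error, unbalanced,
                         dict(zip(labels, means)))

    for span in range(k, 1, -1):
        for lo in range(0, k - span + 1):
            hi = lo + span - 1
            if any(b_lo <= lo and hi <= b_hi for b_lo, b_hi in blocked):
                continue
            idx_lo, idx_hi = order[lo], order[hi]
            n_h = 2.0 / (1.0 / sizes[idx_lo] + 1.0 / sizes[idx_hi])
            q_obs = (means[idx_hi] - means[idx_lo]) / np.sqrt(mse / n_h)
            q_crit = _q_crit(alpha, span, df_error)
            if q_obs > q_crit:
                significant.add(frozenset({labels[idx_lo], labels[idx_hi]}))
            else:
                blocked.append((lo, hi))
    return SnkResult(frozenset(significant), alpha, df_error, unbalanced,
                     dict(zip(labels, means)))


# ---------------------------------------------------------------------------
# gene-level confirmation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparisonResult:
    """Per-gene confirmation summary.

    ``snk`` is reported only when the gating ANOVA is significant (otherwise
    the pair set is empty). ``t_p`` is the one-month ND-vs-D t-test p-value
    when one-month data exist.
    """

    gene: str
    group_means: dict[str, float]
    group_sems: dict[str, float]
    anova_p: float
    snk: SnkResult | None
    confirmed: bool
    m3_category: ResponseCategory | None
    t_p: float | None = None
    m1_de: bool | None = None
    temporal: TemporalCategory | None = None


def confirm_gene(
    gene: str,
    m3_values: Mapping[Group | str, Sequence[float]],
    m1_values: Mapping[Group | str, Sequence[float]] | None = None,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Confirmation analysis of one gene.

    ``m3_values`` maps the three groups to per-animal expression values
    (rq or dCt — the caller chooses the scale); ``m1_values`` maps ND and D
    at the one-month timepoint. Confirmation requires the three-month ANOVA
    to be significant *and* SNK to separate ND from D; the three-month
    response category is then read off the SNK separation pattern with the
    same precedence as the microarray classifier, and combined with the
    one-month t-test into a temporal label where one-month data exist.
    """
    m3 = {Group(g).value: np.asarray(v, dtype=float) for g, v in m3_values.items()}
    required = {Group.ND.value, Group.D.value, Group.DI.value}
    if set(m3) != required:
        raise ContractError(f"m3_values must cover exactly {sorted(required)}")
    order = [Group.ND.value, Group.D.value, Group.DI.value]
    arrays = [m3[g] for g in order]

    group_means = {g: float(m3[g].mean()) for g in order}
    group_sems = {g: float(m3[g].std(ddof=1) / np.sqrt(m3[g].size)) for g in order}
    _, anova_p = anova_oneway(arrays)

    snk = None
    pairs: frozenset[frozenset] = frozenset()
    if anova_p < alpha:  # SNK gated on the omnibus test
        snk = snk_posthoc(arrays, alpha=alpha, labels=order)
        pairs = snk.significant_pairs

    def separated(a: str, b: str) -> bool:
        return frozenset({a, b}) in pairs

    confirmed = anova_p < alpha and separated("ND", "D")
    category: ResponseCategory | None = None
    if confirmed:
        d_dir = np.sign(group_means["D"] - group_means["ND"])
        di_dir = np.sign(group_means["DI"] - group_means["ND"])
        if separated("ND", "DI") and di_dir == -d_dir and di_dir != 0:
            category = ResponseCategory.INVERTED
        elif separated("ND", "DI"):
            category = ResponseCategory.NOT_NORMALIZED
        elif separated("D", "DI"):
            category = ResponseCategory.NORMALIZED
        else:
            category = ResponseCategory.PARTIALLY_NORMALIZED

    t_p = None
    m1_de = None
    temporal = None
    if m1_values is not None:
        m1 = {Group(g).value: np.asarray(v, dtype=float)
              for g, v in m1_values.items()}
        if not {"ND", "D"} <= set(m1):
            raise ContractError("m1_values must cover ND and D")
        t_p = probe_ttest(m1["ND"], m1["D"])
        m1_de = t_p < alpha
        if category is not None:
            temporal = classify_temporal(m1_de, category)

    return GroupComparisonResult(
        gene=gene,
        group_means=group_means,
        group_sems=group_sems,
        anova_p=float(anova_p),
        snk=snk,
        confirmed=bool(confirmed),
        m3_category=category,
        t_p=t_p,
        m1_de=m1_de,
        temporal=temporal,
    )


def analyze_qpcr(
    records: Sequence[QpcrRecord],
    design: SampleDesign,
    alpha: float = 0.05,
    on_dct: bool = False,
    calibrator_group: Group | str = Group.ND,
) -> list[GroupComparisonResult]:
    """Full qPCR confirmation workflow: 2^-ddCt, then per-gene statistics.

    Genes present at both timepoints get the temporal (Rescued/Prevented)
    label; genes with three-month data only get the response category alone.
    ``on_dct=True`` runs the tests on the dCt scale instead of rq.
    """
    quantities = ddct(records, design, calibrator_group=calibrator_group)
    frame = rq_frame(quantities)
    value_col = "delta_ct" if on_dct else "rq"
    frame["group"] = [design.group_of(s).value for s in frame["sample_id"]]
    frame["timepoint"] = [design.timepoint_of(s).value for s in frame["sample_id"]]

    results: list[GroupComparisonResult] = []
    for gene, block in frame.groupby("gene", sort=True):
        m3_block = block[block["timepoint"] == Timepoint.M3.value]
        if m3_block.empty:
            continue
        m3_values = {
            g: m3_block.loc[m3_block["group"] == g, value_col].to_numpy()
            for g in ("ND", "D", "DI")
            if (m3_block["group"] == g).any()
        }
        m1_block = block[block["timepoint"] == Timepoint.M1.value]
        m1_values = None
        if not m1_block.empty:
            m1_values = {
                g: m1_block.loc[m1_block["group"] == g, value_col].to_numpy()
                for g in ("ND", "D")
                if (m1_block["group"] == g).any()
            }
        results.append(confirm_gene(gene, m3_values, m1_values, alpha=alpha))
    return results


def confirmation_rate(results: Sequence[GroupComparisonResult]) -> tuple[int, int, int]:
    """(confirmed, examined, percent) across a panel, percent rounded
    half-up."""
    confirmed = sum(r.confirmed for r in results)
    examined = len(results)
    if examined == 0:
        return 0, 0, 0
    from .classify import _percent_half_up
    return confirmed, examined, _percent_half_up(confirmed, examined)
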