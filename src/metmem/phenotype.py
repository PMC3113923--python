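"""Biometric group comparisons and the gene-to-phenotype correlation screen.

The biometric summary reproduces the study-design conventions: two-group
(1-month) cohorts are compared by two-tailed t-test, three-group (3-month)
cohorts by one-way ANOVA with the SNK post-hoc. The correlation screen asks
whether residual dysregulation of insulin-nonresponsive genes tracks the
animal's glycemic exposure: Pearson correlation of expression against blood
glucose or %HbA1c *within the insulin-treated group*, flagged at p < 0.05
with no multiplicity correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ExpressionMatrix,
    Group,
    PhenotypeRecord,
    SampleDesign,
    Timepoint,
)
from .diffexpr import probe_ttest
from .errors import ContractError, IntegrityError, UndefinedCorrelationError
from .qpcr import SnkResult, anova_oneway, snk_posthoc

PHENOTYPES = ("glucose", "hba1c", "weight")

_FIELD_OF = {"glucose": "blood_glucose", "hba1c": "hba1c_pct",
             "weight": "body_weight"}


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one gene against one phenotype."""

    gene: str
    phenotype: str
    r: float
    p: float
    n: int
    significant: bool


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with the two-tailed t-distribution
    p-value (n-2 df). Zero variance in either vector is an error, not NaN.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ContractError("pearson needs equal-length vectors of size >= 3")
    if xa.var() == 0.0 or ya.var() == 0.0:
        raise UndefinedCorrelationError(
            "correlation undefined for a zero-variance vector"
        )
    result = stats.pearsonr(xa, ya)
    return float(result.statistic), float(result.pvalue)


def correlate_genes(
    expression: ExpressionMatrix | pd.DataFrame,
    phenotypes: Sequence[PhenotypeRecord],
    genes: Sequence[str],
    design: SampleDesign | None = None,
    group: Group | str | None = Group.DI,
    which: Sequence[str] = ("hba1c",),
    alpha: float = 0.05,
    log_scale: bool = False,
) -> list[CorrelationResult]:
    """Correlate expression of selected genes/probes to phenotype values.

    By default restricted to the insulin-treated group (the question being
    whether residual dysregulation reflects residual glycemic exposure);
    pass ``group=None`` to use every phenotyped sample. Expression is the
    normalized linear-scale intensity unless ``log_scale`` (log2) is set.
    Raises IntegrityError when the expression and phenotype samples do not
    match.
    """
    signal = expression.signal if isinstance(expression, ExpressionMatrix) else expression
    pheno = {p.sample_id: p for p in phenotypes}
    samples = list(signal.columns)
    if group is not None:
        if design is None:
            raise ContractError("a design is required to restrict by group")
        members = set(design.samples(group=Group(group)))
        samples = [s for s in samples if s in members]
    missing = [s for s in samples if s not in pheno]
    if missing:
        raise IntegrityError(f"samples without phenotype records: {missing}")
    bad_genes = [g for g in genes if g not in signal.index]
    if bad_genes:
        raise IntegrityError(f"genes not in expression matrix: {bad_genes}")

    results: list[CorrelationResult] = []
    for phenotype in which:
        if phenotype not in PHENOTYPES:
            raise ContractError(f"unknown phenotype {phenotype!r}")
        values = []
        for s in samples:
            v = getattr(pheno[s], _FIELD_OF[phenotype])
            if v is None:
                raise IntegrityError(
                    f"sample {s} has no {phenotype} measurement"
                )
            values.append(float(v))
        y = np.asarray(values)
        for gene in genes:
            x = signal.loc[gene, samples].to_numpy(dtype=float)
            if log_scale:
                x = np.log2(x)
            r, p = pearson(x, y)
            results.append(CorrelationResult(
                gene=gene, phenotype=phenotype, r=r, p=p, n=len(samples),
                significant=bool(p < alpha),
            ))
    return results


# Backwards-friendly alias for the screen over insulin-nonresponsive gene
# sets (NotRescued / NotPrevented / PartiallyPrevented members).
correlate_noncompliant_genes = correlate_genes


@dataclass(frozen=True)
class BiometricGroupStats:
    group: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class BiometricSummary:
    """Group summaries and tests for one phenotype at one timepoint."""

    phenotype: str
    timepoint: Timepoint
    groups: list[BiometricGroupStats]
    t_p: float | None            # two-group mode
    anova_p: float | None        # three-group mode
    snk: SnkResult | None


def biometric_summary(
    phenotypes: Sequence[PhenotypeRecord],
    design: SampleDesign,
    timepoint: Timepoint | str,
    which: Sequence[str] = ("glucose", "weight"),
    alpha: float = 0.05,
) -> list[BiometricSummary]:
    """Per-group mean +/- SEM with the design-appropriate test.

    Two groups present at the timepoint -> two-tailed t-test (ND vs D);
    three groups -> one-way ANOVA with SNK (gated on ANOVA significance).
    """
    tp = Timepoint(timepoint)
    pheno = {p.sample_id: p for p in phenotypes}
    groups_present = design.groups_at(tp)
    summaries: list[BiometricSummary] = []
    for phenotype in which:
        field_name = _FIELD_OF[phenotype]
        per_group: dict[str, np.ndarray] = {}
        for g in groups_present:
            vals = [getattr(pheno[s], field_name)
                    for s in design.samples(group=g, timepoint=tp)
                    if s in pheno and getattr(pheno[s], field_name) is not None]
            if len(vals) >= 2:
                per_group[g.value] = np.asarray(vals, dtype=float)
        if len(per_group) < 2:
            continue
        stats_rows = [
            BiometricGroupStats(
                group=g, n=v.size, mean=float(v.mean()),
                sem=float(v.std(ddof=1) / np.sqrt(v.size)),
            )
            for g, v in per_group.items()
        ]
        t_p = anova_p = None
        snk = None
        if len(per_group) == 2:
            a, b = per_group.values()
            t_p = probe_ttest(a, b)
        else:
            arrays = list(per_group.values())
            _, anova_p = anova_oneway(arrays)
            if anova_p < alpha:
                snk = snk_posthoc(arrays, alpha=alpha,
                                  labels=list(per_group.keys()))
        summaries.append(BiometricSummary(
            phenotype=phenotype, timepoint=tp, groups=stats_rows,
            t_p=t_p, anova_p=anova_p, snk=snk,
        ))
    return summaries
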