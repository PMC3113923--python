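"""Synthetic three-arm, two-timepoint study generator with known ground
truth.

The generator emulates the structure of an STZ diabetic-rat retina
experiment read on a ~22.5k-probe BeadArray: log-normal intensity noise
(microarray noise is multiplicative), per-probe per-sample detection
p-values, the four insulin-response effect archetypes plus unchanged and
undetected probes, two-timepoint qPCR Ct panels with a stable endogenous
control, and biometric phenotype tables. Every probe and gene carries a
ground-truth label so downstream stages can be tested by parameter
recovery rather than against deposited animal data.

Effect archetypes (log2 group means; b = baseline, d = signed log2 fold)::

    Unchanged       ND = D = DI = b
    Normalized      D = b + d,  DI = b
    Partially       D = b + d,  DI = b + d/2      (geometric midpoint)
    NotNormalized   D = b + d,  DI = b + d
    Inverted        D = b + d,  DI = b - d
    Undetected      means at background; detection p above threshold
                    in every sample

Default category proportions mirror a genome-scale study in which roughly
half the array is reliably detected and ~12% of detected probes respond to
the disease, most of which the therapy normalizes fully or partially.

Everything is deterministic under a fixed seed (numpy Generator,
PCG64); distinct seeds give distinct data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    UNCHANGED,
    UNDETECTED,
    ExpressionMatrix,
    Group,
    PhenotypeRecord,
    QpcrRecord,
    ResponseCategory,
    SampleDesign,
    TemporalCategory,
    Timepoint,
)
from .errors import ConfigError

#: Default per-category probe proportions: the affected-category mix
#: 789 : 514 : 65 : 8 over 1,376 responders, 11,040 of 22,523 probes
#: detected, the remainder unchanged.
DEFAULT_PROPORTIONS: dict[str, float] = {
    ResponseCategory.NORMALIZED.value: 789 / 22523,
    ResponseCategory.PARTIALLY_NORMALIZED.value: 514 / 22523,
    ResponseCategory.NOT_NORMALIZED.value: 65 / 22523,
    ResponseCategory.INVERTED.value: 8 / 22523,
    UNCHANGED: 9664 / 22523,
    UNDETECTED: 11483 / 22523,
}

_AFFECTED = tuple(c.value for c in ResponseCategory)

#: Fraction of affected probes whose change is already manifest at one
#: month (the Rescued family); the confirmation panel found 8 of 26
#: confirmed genes already changed pre-insulin.
DEFAULT_MANIFEST_AT_M1 = 8 / 26

_RESCUED_OF = {
    ResponseCategory.NORMALIZED.value: TemporalCategory.RESCUED.value,
    ResponseCategory.PARTIALLY_NORMALIZED.value: TemporalCategory.PARTIALLY_RESCUED.value,
    ResponseCategory.NOT_NORMALIZED.value: TemporalCategory.NOT_RESCUED.value,
}
_PREVENTED_OF = {
    ResponseCategory.NORMALIZED.value: TemporalCategory.PREVENTED.value,
    ResponseCategory.PARTIALLY_NORMALIZED.value: TemporalCategory.PARTIALLY_PREVENTED.value,
    ResponseCategory.NOT_NORMALIZED.value: TemporalCategory.NOT_PREVENTED.value,
}

#: Biometric generator defaults, written as (mean, SEM) per (phenotype,
#: timepoint, group). Glucose and one-month weights are the reported animal
#: values; three-month weights and HbA1c follow the reported ordering
#: (D underweight and hyperglycemic; DI near-normal glucose with slightly
#: elevated HbA1c and slightly reduced weight).
DEFAULT_PHENOTYPE_PARAMS: dict[tuple[str, str, str], tuple[float, float]] = {
    ("glucose", "M1", "ND"): (114.0, 12.0),
    ("glucose", "M1", "D"): (321.0, 16.0),
    ("glucose", "M3", "ND"): (114.0, 12.0),
    ("glucose", "M3", "D"): (321.0, 16.0),
    ("glucose", "M3", "DI"): (130.0, 10.0),
    ("weight", "M1", "ND"): (391.0, 9.0),
    ("weight", "M1", "D"): (264.0, 16.0),
    ("weight", "M3", "ND"): (480.0, 10.0),
    ("weight", "M3", "D"): (300.0, 15.0),
    ("weight", "M3", "DI"): (430.0, 12.0),
    ("hba1c", "M3", "ND"): (4.5, 0.2),
    ("hba1c", "M3", "D"): (11.0, 0.5),
    ("hba1c", "M3", "DI"): (5.5, 0.3),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Parameters
    ----------
    n_probes
        Array size (default 22,523 features).
    group_sizes_m3, group_sizes_m1
        Animals per arm after array QC: 8/5/7 at three months; the one-month
        cohort sizes are only loosely pinned by the study (7-11/group), so
        8/8 is the default.
    category_proportions
        Probe fractions per ground-truth label; must sum to 1.
    effect_size_fc
        True fold change (linear scale) of affected probes, default 1.8.
    cv
        Within-group intensity coefficient of variation on the natural
        scale, default 0.15; intensities are log-normal.
    baseline_log2_mean, baseline_log2_sd
        Distribution of probe baseline log2 intensities; undetected probes
        sit ``undetected_log2_offset`` below baseline, at background level.
    sample_scale_log2_sd
        Per-array brightness jitter (multiplicative), removed by average
        normalization.
    detected_beta, undetected_uniform
        Detection p-value models: Beta(a, b) for detected probes
        (essentially always below the 0.05 marginal threshold) and
        Uniform(0.05, 1) for undetected ones (never below it).
    manifest_at_m1
        Fraction of affected probes whose change predates insulin
        (Rescued-family ground truth).
    sigma_ct, qpcr_effect_fc, control_ct_mean, target_ct_mean, target_ct_sd
        qPCR panel: additive Gaussian Ct noise, true fold change of altered
        genes, and Ct baselines for the control and target genes.
    seed
        Base seed for every random draw.
    """

    n_probes: int = 22523
    group_sizes_m3: Mapping[str, int] = field(
        default_factory=lambda: {"ND": 8, "D": 5, "DI": 7})
    group_sizes_m1: Mapping[str, int] = field(
        default_factory=lambda: {"ND": 8, "D": 8})
    category_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    effect_size_fc: float = 1.8
    cv: float = 0.15
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    undetected_log2_offset: float = 3.0
    sample_scale_log2_sd: float = 0.2
    detected_beta: tuple[float, float] = (0.5, 100.0)
    undetected_uniform: tuple[float, float] = (0.05, 1.0)
    manifest_at_m1: float = DEFAULT_MANIFEST_AT_M1
    sigma_ct: float = 0.15
    qpcr_effect_fc: float = 2.0
    control_ct_mean: float = 18.0
    target_ct_mean: float = 24.0
    target_ct_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.category_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"category proportions sum to {total}, expected 1"
            )
        known = set(_AFFECTED) | {UNCHANGED, UNDETECTED}
        unknown = set(self.category_proportions) - known
        if unknown:
            raise ConfigError(f"unknown category labels: {sorted(unknown)}")
        if any(v < 0 for v in self.category_proportions.values()):
            raise ConfigError("category proportions must be non-negative")
        for sizes in (self.group_sizes_m3, self.group_sizes_m1):
            if any(n < 2 for n in sizes.values()):
                raise ConfigError("all group sizes must be >= 2")
        if self.effect_size_fc <= 1:
            raise ConfigError("effect_size_fc must be > 1")
        if self.cv < 0:
            raise ConfigError("cv must be >= 0")
        if not (0 <= self.manifest_at_m1 <= 1):
            raise ConfigError("manifest_at_m1 must be in [0, 1]")


def _sigma_log2(cv: float) -> float:
    """Log2-scale SD equivalent to a natural-scale coefficient of
    variation for a log-normal variable."""
    if cv == 0.0:
        return 0.0
    return math.sqrt(math.log1p(cv * cv)) / math.log(2.0)


def _design_for(config: SimulationConfig, timepoint: Timepoint) -> SampleDesign:
    sizes = (config.group_sizes_m3 if timepoint is Timepoint.M3
             else config.group_sizes_m1)
    records = []
    for group, n in sizes.items():
        for i in range(1, n + 1):
            records.append((f"{timepoint.value}_{group}_{i:02d}", group,
                            timepoint.value))
    return SampleDesign.from_records(records)


def draw_ground_truth(config: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Assign each probe a true category, temporal label and signed fold
    change."""
    labels = list(config.category_proportions.keys())
    probs = np.array([config.category_proportions[l] for l in labels])
    categories = rng.choice(labels, size=config.n_probes, p=probs / probs.sum())
    signs = rng.choice([-1.0, 1.0], size=config.n_probes)
    affected = np.isin(categories, _AFFECTED)
    true_fc = np.where(affected, signs * config.effect_size_fc, 1.0)

    manifest = rng.random(config.n_probes) < config.manifest_at_m1
    temporal = np.full(config.n_probes, "", dtype=object)
    for i, cat in enumerate(categories):
        if cat in _RESCUED_OF:
            temporal[i] = (_RESCUED_OF[cat] if manifest[i]
                           else _PREVENTED_OF[cat])
        # Inverted probes have no defined temporal label.
    probe_ids = [f"PROBE_{i + 1:06d}" for i in range(config.n_probes)]
    return pd.DataFrame(
        {"true_category": categories, "true_temporal": temporal,
         "true_fc": true_fc},
        index=pd.Index(probe_ids, name="probe_id"),
    )


_RESCUED_FAMILY = frozenset({
    TemporalCategory.RESCUED.value,
    TemporalCategory.PARTIALLY_RESCUED.value,
    TemporalCategory.NOT_RESCUED.value,
})


def _group_shifts_log2(
    categories: np.ndarray,
    temporals: np.ndarray,
    d: np.ndarray,
    timepoint: Timepoint,
) -> dict[Group, np.ndarray]:
    """Per-group log2 offsets of the group mean from the probe baseline."""
    zeros = np.zeros_like(d)
    shifts: dict[Group, np.ndarray] = {Group.ND: zeros}
    if timepoint is Timepoint.M1:
        # Pre-insulin: D differs only where the change is already manifest.
        manifest = np.isin(temporals, list(_RESCUED_FAMILY))
        shifts[Group.D] = np.where(manifest, d, 0.0)
        return shifts
    shifts[Group.D] = d
    shifts[Group.DI] = np.select(
        [categories == ResponseCategory.PARTIALLY_NORMALIZED.value,
         categories == ResponseCategory.NOT_NORMALIZED.value,
         categories == ResponseCategory.INVERTED.value],
        [d / 2.0, d, -d],
        default=0.0,
    )
    return shifts


def simulate_expression(
    config: SimulationConfig,
    timepoint: Timepoint | str = Timepoint.M3,
    truth: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, SampleDesign, pd.DataFrame]:
    """Generate one timepoint's expression matrix with detection layer.

    Returns ``(matrix, design, ground_truth)``. Passing the ``truth`` frame
    from a previous call keeps probe labels consistent across timepoints
    (the two-timepoint workflow); otherwise truth is drawn fresh from the
    configured proportions.
    """
    tp = Timepoint(timepoint)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if truth is None:
        truth = draw_ground_truth(config, rng)
    design = _design_for(config, tp)
    samples = design.frame.index.tolist()
    n_probes, n_samples = len(truth), len(samples)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          n_probes)
    undetected = (truth["true_category"] == UNDETECTED).to_numpy()
    baseline = baseline - config.undetected_log2_offset * undetected

    d = np.where(truth["true_fc"].to_numpy() == 1.0, 0.0,
                 np.sign(truth["true_fc"].to_numpy())
                 * np.log2(np.abs(truth["true_fc"].to_numpy())))
    categories = truth["true_category"].to_numpy()
    temporals = truth["true_temporal"].to_numpy()

    shifts = _group_shifts_log2(categories, temporals, d, tp)
    mean_log2 = np.empty((n_probes, n_samples))
    for j, sample in enumerate(samples):
        mean_log2[:, j] = baseline + shifts[design.group_of(sample)]

    sigma = _sigma_log2(config.cv)
    log2_values = (mean_log2 if sigma == 0.0
                   else rng.normal(mean_log2, sigma))
    if config.sample_scale_log2_sd > 0:
        log2_values = log2_values + rng.normal(
            0.0, config.sample_scale_log2_sd, n_samples)[None, :]
    signal = pd.DataFrame(np.exp2(log2_values), index=truth.index.copy(),
                          columns=samples)

    a, b = config.detected_beta
    lo, hi = config.undetected_uniform
    detection = np.where(
        undetected[:, None],
        rng.uniform(lo, hi, (n_probes, n_samples)),
        rng.beta(a, b, (n_probes, n_samples)),
    )
    detection_df = pd.DataFrame(detection, index=truth.index.copy(),
                                columns=samples)
    matrix = ExpressionMatrix(signal=signal, detection=detection_df,
                              normalized=False)
    return matrix, design, truth


# ---------------------------------------------------------------------------
# qPCR panels
# ---------------------------------------------------------------------------

_M1_FOLD = {
    TemporalCategory.RESCUED.value: "full",
    TemporalCategory.PARTIALLY_RESCUED.value: "full",
    TemporalCategory.NOT_RESCUED.value: "full",
    TemporalCategory.PREVENTED.value: "none",
    TemporalCategory.PARTIALLY_PREVENTED.value: "none",
    TemporalCategory.NOT_PREVENTED.value: "none",
}
_M3_DI_FOLD = {
    TemporalCategory.RESCUED.value: "none",
    TemporalCategory.PREVENTED.value: "none",
    TemporalCategory.PARTIALLY_RESCUED.value: "half",
    TemporalCategory.PARTIALLY_PREVENTED.value: "half",
    TemporalCategory.NOT_RESCUED.value: "full",
    TemporalCategory.NOT_PREVENTED.value: "full",
}

CONTROL_GENE = "Actb"


def simulate_qpcr(
    config: SimulationConfig,
    genes: Mapping[str, TemporalCategory | str],
    signs: Mapping[str, int] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[QpcrRecord], SampleDesign]:
    """Generate a two-timepoint qPCR Ct panel for genes with known temporal
    archetypes.

    The endogenous control gene's Ct is drawn with a group-independent mean
    (a stable reference); each target gene's Ct encodes its archetype's
    fold-change trajectory across (M1: ND, D) and (M3: ND, D, DI) — an
    x-fold induction lowers Ct by log2(x). ``signs`` optionally flips
    individual genes to repression (-1); the default is induction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    valid = {t.value for t in TemporalCategory}
    archetypes = {}
    for gene, arch in genes.items():
        value = arch.value if isinstance(arch, TemporalCategory) else str(arch)
        if value not in valid:
            raise ConfigError(f"unknown temporal archetype {arch!r} for {gene}")
        archetypes[gene] = value
    signs = dict(signs or {})

    design_m1 = _design_for(config, Timepoint.M1)
    design_m3 = _design_for(config, Timepoint.M3)
    design = SampleDesign(pd.concat([design_m1.frame, design_m3.frame]))

    log2_f = math.log2(config.qpcr_effect_fc)
    records: list[QpcrRecord] = []
    for sample in design.frame.index:
        records.append(QpcrRecord(
            sample_id=sample, gene=CONTROL_GENE,
            ct=float(config.control_ct_mean
                     + rng.normal(0.0, config.sigma_ct))
            if config.sigma_ct > 0 else float(config.control_ct_mean),
            is_endogenous_control=True,
        ))
    for gene, arch in archetypes.items():
        sign = signs.get(gene, 1)
        base_ct = float(config.target_ct_mean
                        + (rng.normal(0.0, config.target_ct_sd)
                           if config.target_ct_sd > 0 else 0.0))
        for sample in design.frame.index:
            group = design.group_of(sample)
            tp = design.timepoint_of(sample)
            if group is Group.ND:
                fold_log2 = 0.0
            elif tp is Timepoint.M1:
                fold_log2 = log2_f if _M1_FOLD[arch] == "full" else 0.0
            elif group is Group.D:
                fold_log2 = log2_f
            else:  # DI at M3
                fold_log2 = {"none": 0.0, "half": log2_f / 2.0,
                             "full": log2_f}[_M3_DI_FOLD[arch]]
            ct = base_ct - sign * fold_log2
            if config.sigma_ct > 0:
                ct += rng.normal(0.0, config.sigma_ct)
            records.append(QpcrRecord(sample_id=sample, gene=gene,
                                      ct=float(ct)))
    return records, design


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotype(
    design: SampleDesign,
    config: SimulationConfig,
    params: Mapping[tuple[str, str, str], tuple[float, float]] | None = None,
    rng: np.random.Generator | None = None,
) -> list[PhenotypeRecord]:
    """Generate biometric records for every sample of a design.

    ``params`` maps (phenotype, timepoint, group) to (mean, SEM); the
    published convention reports dispersion as SEM, so the per-animal SD is
    SEM * sqrt(n) with n the design's group size. HbA1c is generated only
    for three-month samples (it was not measured at one month). Values are
    clamped to stay positive.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params = dict(DEFAULT_PHENOTYPE_PARAMS if params is None else params)

    sizes = design.frame.groupby(["group", "timepoint"], observed=True).size()

    def draw(phenotype: str, tp: str, group: str) -> float | None:
        key = (phenotype, tp, group)
        if key not in params:
            return None
        mean, sem = params[key]
        n = int(sizes.loc[(group, tp)])
        sd = sem * math.sqrt(n)
        return float(max(rng.normal(mean, sd), 1.0))

    records = []
    for sample in design.frame.index:
        group = design.group_of(sample).value
        tp = design.timepoint_of(sample).value
        glucose = draw("glucose", tp, group)
        weight = draw("weight", tp, group)
        if glucose is None or weight is None:
            raise ConfigError(
                f"no phenotype parameters for group {group} at {tp}"
            )
        hba1c = draw("hba1c", tp, group) if tp == Timepoint.M3.value else None
        records.append(PhenotypeRecord(
            sample_id=sample, blood_glucose=glucose, body_weight=weight,
            hba1c_pct=hba1c,
        ))
    return records


def simulate_coupled_expression(
    phenotype_values: Sequence[float],
    sample_ids: Sequence[str],
    gene_ids: Sequence[str],
    true_r: float,
    rng: np.random.Generator,
    base_mean: float = 200.0,
    base_sd: float = 30.0,
) -> pd.DataFrame:
    """Expression for genes linearly coupled to a phenotype at population
    correlation ``true_r`` (0 gives independent genes) — the oracle input
    for correlation-recovery tests."""
    if not (-1.0 <= true_r <= 1.0):
        raise ConfigError("true_r must be in [-1, 1]")
    y = np.asarray(phenotype_values, dtype=float)
    if y.var() == 0:
        raise ConfigError("phenotype values must vary to couple against")
    z = (y - y.mean()) / y.std()
    rows = []
    for _ in gene_ids:
        eps = rng.normal(0.0, 1.0, y.size)
        latent = true_r * z + math.sqrt(1.0 - true_r ** 2) * eps
        rows.append(base_mean + base_sd * latent)
    values = np.clip(np.asarray(rows), 1.0, None)
    return pd.DataFrame(values, index=pd.Index(gene_ids, name="probe_id"),
                        columns=list(sample_ids))
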