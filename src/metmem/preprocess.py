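"""Average normalization with background subtraction, and the
present/marginal detection filter that defines the analyzable probe set.

Normalization model
-------------------
Per sample: estimate a background level, subtract it, clamp at a small
positive floor (so downstream ratios stay defined), then rescale every
sample so its mean equals the grand mean of the per-sample means. This is
the "average normalization with background subtraction" scheme of BeadArray
scanner software: it equalizes overall array brightness without touching
the shape of each sample's intensity distribution.

The background estimate is the mean of designated negative-control probes
when a list is supplied, else the 5th percentile of the sample's own
signals — a robust stand-in for the negative-bead summary when control
probes are not in the export.

Detection filter
----------------
A probe is kept iff there is at least one experimental group in which every
sample has a present-or-marginal detection call (detection p <= the marginal
threshold, conventionally 0.05; "present" alone is p <= 0.01). Requiring
100% of samples within some group keeps genes expressed in only one arm
while dropping probes never reliably detected.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SampleDesign
from .errors import ConfigError, IntegrityError

BACKGROUND_PERCENTILE = 5.0
DEFAULT_FLOOR = 1.0


@dataclass(frozen=True)
class NormalizationParams:
    """Per-sample background estimates and scale factors actually applied."""

    background: dict[str, float]
    scale_factor: dict[str, float]
    floor: float

    def __post_init__(self) -> None:
        if self.floor <= 0:
            raise ConfigError("floor must be positive")
        if any(s <= 0 for s in self.scale_factor.values()):
            raise ConfigError("scale factors must be positive")


@dataclass(frozen=True)
class DetectionRule:
    """Present/marginal call thresholds on the detection p-value.

    ``required_fraction`` is fixed at 1.0: the filter demands calls in 100%
    of the samples of at least one group.
    """

    present_p: float = 0.01
    marginal_p: float = 0.05
    required_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.present_p <= self.marginal_p <= 1):
            raise ConfigError("need 0 < present_p <= marginal_p <= 1")
        if self.required_fraction != 1.0:
            raise ConfigError("required_fraction is fixed at 1.0")


def normalize(
    matrix: ExpressionMatrix,
    negative_control_probes: list[str] | None = None,
    floor: float = DEFAULT_FLOOR,
    force: bool = False,
) -> tuple[ExpressionMatrix, NormalizationParams]:
    """Background-subtract and average-normalize an expression matrix.

    Refuses matrices already flagged as normalized unless ``force`` is set
    (re-normalizing a normalized matrix with a zero background is a no-op,
    but double background subtraction is not). Detection p-values pass
    through untouched — they are a property of the raw scan.

    Returns the normalized matrix (flagged) and the parameters applied.
    """
    if matrix.n_samples < 2:
        raise ConfigError("normalization needs at least 2 samples")
    if matrix.normalized and not force:
        raise ConfigError(
            "matrix is flagged as already normalized; pass force=True to "
            "re-normalize"
        )
    signal = matrix.signal
    if negative_control_probes is not None:
        missing = set(negative_control_probes) - set(matrix.probe_ids)
        if missing:
            raise IntegrityError(
                f"negative-control probes not in matrix: {sorted(missing)[:5]}"
            )
        background = signal.loc[list(negative_control_probes)].mean(axis=0)
    else:
        background = signal.quantile(BACKGROUND_PERCENTILE / 100.0, axis=0)
    if matrix.normalized and force:
        # Idempotent re-run: a normalized matrix has no residual background
        # and its values were already floored, so neither step is reapplied.
        background = pd.Series(0.0, index=signal.columns)
        backgrounded = signal.copy()
    else:
        backgrounded = (signal - background).clip(lower=floor)
    sample_means = backgrounded.mean(axis=0)
    grand_mean = float(sample_means.mean())
    scale = grand_mean / sample_means
    normalized_signal = backgrounded * scale

    params = NormalizationParams(
        background={s: float(background[s]) for s in signal.columns},
        scale_factor={s: float(scale[s]) for s in signal.columns},
        floor=floor,
    )
    out = ExpressionMatrix(
        signal=normalized_signal,
        detection=None if matrix.detection is None else matrix.detection.copy(),
        annotations=matrix.annotations.copy(),
        normalized=True,
    )
    return out, params


def detection_filter(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    rule: DetectionRule | None = None,
) -> tuple[ExpressionMatrix, list[str], list[str]]:
    """Keep probes with present-or-marginal calls in 100% of the samples of
    at least one experimental group.

    Returns ``(filtered_matrix, kept_ids, dropped_ids)``; kept and dropped
    partition the input probes with order preserved.
    """
    if matrix.detection is None:
        raise IntegrityError("matrix has no detection layer; cannot filter")
    rule = rule or DetectionRule()
    design_samples = [s for s in matrix.sample_ids if s in design.frame.index]
    if not design_samples:
        raise IntegrityError("no matrix samples present in the design")

    detected = matrix.detection[design_samples] <= rule.marginal_p
    groups = design.frame.loc[design_samples, "group"]
    keep = pd.Series(False, index=matrix.signal.index)
    for _, members in groups.groupby(groups).groups.items():
        keep |= detected[list(members)].all(axis=1)

    kept_ids = list(matrix.signal.index[keep])
    dropped_ids = list(matrix.signal.index[~keep])
    return matrix.subset_probes(kept_ids), kept_ids, dropped_ids
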