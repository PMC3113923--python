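"""Core in-memory containers for the three-arm expression study.

The study design is a streptozotocin (STZ) diabetic-rat experiment with three
arms — non-diabetic control (``ND``), untreated diabetic (``D``) and
insulin-treated diabetic (``DI``) — sampled at one month (``M1``, before any
insulin) and three months (``M3``, after 1.5 months of insulin in the DI arm).

Everything tabular is a :class:`pandas.DataFrame` underneath; the thin
dataclass wrappers exist to enforce the invariants the pipeline relies on
(aligned signal/detection layers, unique probe ids, minimum group sizes).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError


class Group(str, Enum):
    """Experimental arm."""

    ND = "ND"   # non-diabetic control
    D = "D"     # untreated diabetic
    DI = "DI"   # insulin-treated diabetic

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Timepoint(str, Enum):
    """Duration of diabetes at sacrifice."""

    M1 = "M1"   # one month (pre-insulin)
    M3 = "M3"   # three months

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ResponseCategory(str, Enum):
    """Four-way partition of diabetes-altered probes by their expression in
    the insulin-treated arm."""

    NOT_NORMALIZED = "NotNormalized"
    PARTIALLY_NORMALIZED = "PartiallyNormalized"
    NORMALIZED = "Normalized"
    INVERTED = "Inverted"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class TemporalCategory(str, Enum):
    """Six-way refinement using the pre-treatment (1-month) timepoint.

    Rescued-family labels apply to changes already present at one month;
    Prevented-family labels to changes that only develop later.
    """

    RESCUED = "Rescued"
    PARTIALLY_RESCUED = "PartiallyRescued"
    NOT_RESCUED = "NotRescued"
    PREVENTED = "Prevented"
    PARTIALLY_PREVENTED = "PartiallyPrevented"
    NOT_PREVENTED = "NotPrevented"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Ground-truth labels a simulated probe may carry beyond the four response
#: categories: no true effect, or signal below the detection threshold.
UNCHANGED = "Unchanged"
UNDETECTED = "Undetected"

ANNOTATION_COLUMNS = ("gene_symbol", "entrez_id", "gene_name")


@dataclass
class ExpressionMatrix:
    """Probe x sample intensity matrix with a parallel detection-p layer.

    Parameters
    ----------
    signal
        Non-negative intensities (arbitrary fluorescence units), probes as
        rows, samples as columns.
    detection
        Per-probe, per-sample detection p-values in [0, 1] with the same
        index/columns as ``signal``, or ``None`` when the source file did not
        carry them (GEO series-matrix deposits often do not).
    annotations
        Optional per-probe annotation (``gene_symbol``, ``entrez_id``,
        ``gene_name``); missing entries are empty strings.
    normalized
        Provenance flag: True once average normalization has run, or when the
        source is known to be post-normalization (GEO dialect default).
    """

    signal: pd.DataFrame
    detection: pd.DataFrame | None = None
    annotations: pd.DataFrame | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        sig = self.signal
        if sig.index.has_duplicates:
            dupes = sig.index[sig.index.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate probe ids: {dupes[:5]}")
        if sig.columns.has_duplicates:
            raise IntegrityError("duplicate sample ids in expression matrix")
        if (sig.to_numpy() < 0).any():
            raise IntegrityError("negative intensities in signal layer")
        if self.detection is not None:
            det = self.detection
            if not det.index.equals(sig.index) or not det.columns.equals(sig.columns):
                raise IntegrityError(
                    "detection layer index/columns do not match signal layer"
                )
            vals = det.to_numpy()
            if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
                raise IntegrityError("detection p-values outside [0, 1]")
        if self.annotations is None:
            self.annotations = pd.DataFrame(
                "", index=sig.index, columns=list(ANNOTATION_COLUMNS)
            )
        else:
            self.annotations = self.annotations.reindex(
                index=sig.index, columns=list(ANNOTATION_COLUMNS), fill_value=""
            ).fillna("")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.signal.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.signal.columns)

    @property
    def n_probes(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a matrix restricted to ``probe_ids`` (order preserved)."""
        ids = list(probe_ids)
        return ExpressionMatrix(
            signal=self.signal.loc[ids].copy(),
            detection=None if self.detection is None else self.detection.loc[ids].copy(),
            annotations=self.annotations.loc[ids].copy(),
            normalized=self.normalized,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(
            signal=self.signal[ids].copy(),
            detection=None if self.detection is None else self.detection[ids].copy(),
            annotations=self.annotations.copy(),
            normalized=self.normalized,
        )


@dataclass
class SampleDesign:
    """Assignment of samples to (group, timepoint).

    ``frame`` is indexed by sample id with columns ``group`` and
    ``timepoint``. Any (group, timepoint) cell that is present must hold at
    least two samples — one animal cannot anchor a group statistic.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if f.index.has_duplicates:
            raise IntegrityError("duplicate sample ids in design")
        missing = {"group", "timepoint"} - set(f.columns)
        if missing:
            raise IntegrityError(f"design missing columns: {sorted(missing)}")
        f = f.copy()
        f["group"] = f["group"].map(lambda g: Group(g).value)
        f["timepoint"] = f["timepoint"].map(lambda t: Timepoint(t).value)
        sizes = f.groupby(["group", "timepoint"], observed=True).size()
        small = sizes[sizes < 2]
        if len(small):
            raise IntegrityError(
                f"(group, timepoint) cells with fewer than 2 samples: "
                f"{list(small.index)}"
            )
        self.frame = f

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str | Group, str | Timepoint]]
    ) -> "SampleDesign":
        rows = [(s, Group(g).value, Timepoint(t).value) for s, g, t in records]
        frame = pd.DataFrame(rows, columns=["sample_id", "group", "timepoint"])
        return cls(frame.set_index("sample_id"))

    def samples(
        self,
        group: Group | str | None = None,
        timepoint: Timepoint | str | None = None,
    ) -> list[str]:
        """Sample ids matching the given group and/or timepoint."""
        mask = pd.Series(True, index=self.frame.index)
        if group is not None:
            mask &= self.frame["group"] == Group(group).value
        if timepoint is not None:
            mask &= self.frame["timepoint"] == Timepoint(timepoint).value
        return list(self.frame.index[mask])

    def groups_at(self, timepoint: Timepoint | str) -> list[Group]:
        tp = Timepoint(timepoint).value
        present = self.frame.loc[self.frame["timepoint"] == tp, "group"].unique()
        return [Group(g) for g in ("ND", "D", "DI") if g in set(present)]

    def group_of(self, sample_id: str) -> Group:
        return Group(self.frame.loc[sample_id, "group"])

    def timepoint_of(self, sample_id: str) -> Timepoint:
        return Timepoint(self.frame.loc[sample_id, "timepoint"])

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class ResultRow:
    """One probe's entry in a differential-expression result table: the
    p-value and signed fold change of each pairwise comparison plus
    annotation and (optionally) the assigned response category.

    Signed fold changes follow the negative-reciprocal convention:
    -2.0 means halved, +2.0 means doubled, so |fc| >= 1 always.
    """

    probe_id: str
    p_nd_d: float
    p_nd_di: float
    p_d_di: float
    fc_nd_d: float
    fc_nd_di: float
    fc_d_di: float
    gene_symbol: str = ""
    entrez_id: str = ""
    gene_name: str = ""
    category: ResponseCategory | None = None

    def __post_init__(self) -> None:
        for name in ("p_nd_d", "p_nd_di", "p_d_di"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise IntegrityError(f"{name}={p} outside [0, 1]")
        for name in ("fc_nd_d", "fc_nd_di", "fc_d_di"):
            fc = getattr(self, name)
            if abs(fc) < 1.0:
                raise IntegrityError(f"{name}={fc} has |fc| < 1")


@dataclass(frozen=True)
class QpcrRecord:
    """A single real-time PCR well: threshold cycle for one gene in one
    sample. ``is_endogenous_control`` marks the reference gene (beta-actin
    in the retina experiments)."""

    sample_id: str
    gene: str
    ct: float
    is_endogenous_control: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct):
            raise IntegrityError(f"non-finite Ct for {self.gene}/{self.sample_id}")


@dataclass(frozen=True)
class RelativeQuantity:
    """Per-sample relative expression from the 2^-ddCt method.

    ``delta_ct`` is Ct(target) - Ct(control gene) for the sample;
    ``ddct`` subtracts the calibrator group's mean delta-Ct;
    ``rq = 2**(-ddct)`` is fold expression relative to the calibrator.
    """

    sample_id: str
    gene: str
    delta_ct: float
    ddct: float
    rq: float


@dataclass(frozen=True)
class PhenotypeRecord:
    """Biometric measurements for one animal at sacrifice."""

    sample_id: str
    blood_glucose: float        # mg/dL
    body_weight: float          # g
    hba1c_pct: float | None = None  # % glycosylated hemoglobin; M3 only

    def __post_init__(self) -> None:
        if self.blood_glucose <= 0 or self.body_weight <= 0:
            raise IntegrityError("phenotype values must be positive")
        if self.hba1c_pct is not None and self.hba1c_pct <= 0:
            raise IntegrityError("phenotype values must be positive")
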