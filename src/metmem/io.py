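"""Readers and writers for every external representation the pipeline touches.

Supported dialects
------------------
* GenomeStudio-style Sample Probe Profile: tab-delimited, one row per probe,
  with paired ``AVG_Signal.<sample>`` / ``Detection Pval.<sample>`` columns.
  This is the flat-file export of Illumina BeadArray scanner software and the
  raw-ish carrier of both intensities and detection p-values.
* GEO series matrix: the ``!``-prefixed header format with the expression
  block between ``!series_matrix_table_begin`` and ``!series_matrix_table_end``.
  Deposits in this dialect are typically post-normalization and usually lack
  detection p-values, so the reader flags the matrix as normalized and leaves
  the detection layer absent (never zero-filled).
* Result tables: tab-delimited, one probe per row, columns ordered as
  ProbeID, the three pairwise p-values, the three signed fold changes,
  gene symbol, Entrez id, gene name (+ a Category column in combined mode).
* qPCR tables, sample designs, phenotype tables and simulation ground truth:
  plain CSV/TSV as documented on each function.

Encoding is UTF-8 throughout; tabs for array/result files, commas for qPCR,
design and phenotype files; decimal point ``.``.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    ANNOTATION_COLUMNS,
    ExpressionMatrix,
    Group,
    PhenotypeRecord,
    QpcrRecord,
    ResponseCategory,
    ResultRow,
    SampleDesign,
    Timepoint,
)
from .errors import FormatError, IntegrityError

GENOMESTUDIO_FLAT = "genomestudio_flat"
GEO_SERIES_MATRIX = "geo_series_matrix"

_SIGNAL_PREFIX = "AVG_Signal."
_DETECTION_PREFIX = "Detection Pval."

RESULT_COLUMNS = [
    "ProbeID",
    "Pval.ND_D",
    "Pval.ND_DI",
    "Pval.D_DI",
    "FC.ND_D",
    "FC.ND_DI",
    "FC.D_DI",
    "GeneSymbol",
    "EntrezGeneID",
    "GeneName",
]
_CATEGORY_COLUMN = "Category"

_ANNOT_HEADER = {"GeneSymbol": "gene_symbol", "EntrezGeneID": "entrez_id",
                 "GeneName": "gene_name"}


# ---------------------------------------------------------------------------
# probe profiles
# ---------------------------------------------------------------------------

def read_probe_profile(path: str | Path, dialect: str = GENOMESTUDIO_FLAT) -> ExpressionMatrix:
    """Read a probe x sample expression file.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"genomestudio_flat"`` (intensities + detection p-values, raw
        provenance) or ``"geo_series_matrix"`` (intensities only, flagged as
        already normalized).

    Raises
    ------
    FormatError
        Malformed header — e.g. a sample with an ``AVG_Signal`` column but no
        ``Detection Pval`` column (the offending column is named).
    IntegrityError
        Duplicate probe ids.
    """
    path = Path(path)
    if dialect == GENOMESTUDIO_FLAT:
        return _read_genomestudio_flat(path)
    if dialect == GEO_SERIES_MATRIX:
        return _read_geo_series_matrix(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_genomestudio_flat(path: Path) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", dtype={"ProbeID": str},
                        float_precision="round_trip")
    if "ProbeID" not in frame.columns:
        raise FormatError(f"{path}: missing 'ProbeID' column")
    samples = [c[len(_SIGNAL_PREFIX):] for c in frame.columns
               if c.startswith(_SIGNAL_PREFIX)]
    if not samples:
        raise FormatError(f"{path}: no '{_SIGNAL_PREFIX}<sample>' columns")
    for sid in samples:
        det_col = _DETECTION_PREFIX + sid
        if det_col not in frame.columns:
            raise FormatError(f"{path}: missing column '{det_col}'")
    if frame["ProbeID"].duplicated().any():
        dupes = frame.loc[frame["ProbeID"].duplicated(), "ProbeID"].unique()
        raise IntegrityError(f"{path}: duplicate probe ids: {list(dupes[:5])}")
    index = pd.Index(frame["ProbeID"], name="probe_id")
    signal = pd.DataFrame(
        {sid: frame[_SIGNAL_PREFIX + sid].to_numpy(float) for sid in samples},
        index=index,
    )
    detection = pd.DataFrame(
        {sid: frame[_DETECTION_PREFIX + sid].to_numpy(float) for sid in samples},
        index=index,
    )
    annotations = pd.DataFrame(index=index)
    for header, field in _ANNOT_HEADER.items():
        annotations[field] = (
            frame[header].fillna("").astype(str).to_numpy()
            if header in frame.columns else ""
        )
    return ExpressionMatrix(signal=signal, detection=detection,
                            annotations=annotations, normalized=False)


def _read_geo_series_matrix(path: Path) -> ExpressionMatrix:
    header: list[str] | None = None
    rows: list[list[str]] = []
    in_table = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if not in_table or not line:
                continue
            fields = [f.strip('"') for f in line.split("\t")]
            if header is None:
                header = fields
            else:
                rows.append(fields)
    if header is None:
        raise FormatError(f"{path}: no series_matrix_table_begin block found")
    if header[0] != "ID_REF":
        raise FormatError(f"{path}: matrix block must start with 'ID_REF', "
                          f"found {header[0]!r}")
    samples = header[1:]
    if not samples:
        raise FormatError(f"{path}: matrix block declares no sample columns")
    probe_ids = [r[0] for r in rows]
    if len(set(probe_ids)) != len(probe_ids):
        raise IntegrityError(f"{path}: duplicate probe ids in matrix block")
    values = np.array([[float(v) for v in r[1:]] for r in rows], dtype=float)
    signal = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                          columns=samples)
    # GEO deposits of scanner output are typically post-normalization and
    # carry no detection layer; record that rather than inventing zeros.
    return ExpressionMatrix(signal=signal, detection=None, normalized=True)


def write_probe_profile(matrix: ExpressionMatrix, path: str | Path) -> Path:
    """Write a GenomeStudio-style flat probe profile (requires a detection
    layer)."""
    if matrix.detection is None:
        raise IntegrityError("cannot write genomestudio_flat without a "
                             "detection layer")
    path = Path(path)
    out = pd.DataFrame({"ProbeID": matrix.probe_ids})
    ann = matrix.annotations
    for header, field in _ANNOT_HEADER.items():
        out[header] = ann[field].to_numpy()
    for sid in matrix.sample_ids:
        out[_SIGNAL_PREFIX + sid] = matrix.signal[sid].to_numpy()
        out[_DETECTION_PREFIX + sid] = matrix.detection[sid].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def write_geo_series_matrix(matrix: ExpressionMatrix, path: str | Path,
                            series_id: str = "GSE-synthetic") -> Path:
    """Write the expression layer in GEO series-matrix form (no detection
    layer; the dialect does not carry one)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f'!Series_geo_accession\t"{series_id}"\n')
        fh.write(f'!Series_sample_id\t"{" ".join(matrix.sample_ids)}"\n')
        fh.write("!series_matrix_table_begin\n")
        fh.write("\t".join(['"ID_REF"'] + [f'"{s}"' for s in matrix.sample_ids]))
        fh.write("\n")
        for pid, row in matrix.signal.iterrows():
            fh.write("\t".join([f'"{pid}"'] + [repr(float(v)) for v in row]))
            fh.write("\n")
        fh.write("!series_matrix_table_end\n")
    return path


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def _result_frame(rows: Sequence[ResultRow], with_category: bool) -> pd.DataFrame:
    data = {
        "ProbeID": [r.probe_id for r in rows],
        "Pval.ND_D": [r.p_nd_d for r in rows],
        "Pval.ND_DI": [r.p_nd_di for r in rows],
        "Pval.D_DI": [r.p_d_di for r in rows],
        "FC.ND_D": [r.fc_nd_d for r in rows],
        "FC.ND_DI": [r.fc_nd_di for r in rows],
        "FC.D_DI": [r.fc_d_di for r in rows],
        "GeneSymbol": [r.gene_symbol for r in rows],
        "EntrezGeneID": [r.entrez_id for r in rows],
        "GeneName": [r.gene_name for r in rows],
    }
    frame = pd.DataFrame(data, columns=RESULT_COLUMNS)
    if with_category:
        frame[_CATEGORY_COLUMN] = [
            "" if r.category is None else r.category.value for r in rows
        ]
    return frame


def write_result_rows(rows: Sequence[ResultRow], path: str | Path,
                      split_by_category: bool = True) -> list[Path]:
    """Write differential-expression result rows.

    In the default per-category mode ``path`` is a directory and one file per
    response category is produced (``NotNormalized.tsv``, ...), mirroring how
    such results are conventionally shipped as separate supplementary tables;
    rows without a category go to ``Uncategorized.tsv``. With
    ``split_by_category=False`` a single file with a Category column is
    written. Returns the paths written.
    """
    if not rows:
        raise ValueError("rows must be non-empty")
    path = Path(path)
    if not split_by_category:
        _result_frame(rows, with_category=True).to_csv(
            path, sep="\t", index=False, float_format="%.17g")
        return [path]
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    order = [c.value for c in ResponseCategory] + ["Uncategorized"]
    by_cat: dict[str, list[ResultRow]] = {}
    for r in rows:
        key = r.category.value if r.category is not None else "Uncategorized"
        by_cat.setdefault(key, []).append(r)
    for key in order:
        if key not in by_cat:
            continue
        target = path / f"{key}.tsv"
        _result_frame(by_cat[key], with_category=False).to_csv(
            target, sep="\t", index=False, float_format="%.17g"
        )
        written.append(target)
    return written


def read_result_rows(path: str | Path,
                     category: ResponseCategory | str | None = None) -> list[ResultRow]:
    """Read one result table. ``category`` supplies the label for
    per-category files (which omit the Category column); a Category column,
    if present, wins."""
    path = Path(path)
    frame = pd.read_csv(
        path, sep="\t",
        dtype={"ProbeID": str, "GeneSymbol": str, "EntrezGeneID": str,
               "GeneName": str},
        keep_default_na=False, float_precision="round_trip",
    )
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing result columns {missing}")
    default_cat = None if category is None else ResponseCategory(category)
    rows: list[ResultRow] = []
    for _, rec in frame.iterrows():
        if _CATEGORY_COLUMN in frame.columns and rec[_CATEGORY_COLUMN]:
            cat = ResponseCategory(rec[_CATEGORY_COLUMN])
        else:
            cat = default_cat
        rows.append(ResultRow(
            probe_id=rec["ProbeID"],
            p_nd_d=float(rec["Pval.ND_D"]),
            p_nd_di=float(rec["Pval.ND_DI"]),
            p_d_di=float(rec["Pval.D_DI"]),
            fc_nd_d=float(rec["FC.ND_D"]),
            fc_nd_di=float(rec["FC.ND_DI"]),
            fc_d_di=float(rec["FC.D_DI"]),
            gene_symbol=rec["GeneSymbol"],
            entrez_id=rec["EntrezGeneID"],
            gene_name=rec["GeneName"],
            category=cat,
        ))
    return rows


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

_QPCR_COLUMNS = ["sample_id", "gene", "ct", "is_endogenous_control"]


def read_qpcr_table(path: str | Path) -> list[QpcrRecord]:
    """Read a qPCR Ct table (CSV: sample_id, gene, ct, is_endogenous_control).

    Every sample must carry at least one endogenous-control well; a sample
    without one cannot be delta-Ct normalized and raises IntegrityError.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"sample_id": str, "gene": str},
                        float_precision="round_trip")
    missing = [c for c in _QPCR_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing qPCR columns {missing}")
    records = [
        QpcrRecord(
            sample_id=rec["sample_id"],
            gene=rec["gene"],
            ct=float(rec["ct"]),
            is_endogenous_control=_parse_bool(rec["is_endogenous_control"]),
        )
        for _, rec in frame.iterrows()
    ]
    with_control = {r.sample_id for r in records if r.is_endogenous_control}
    lacking = sorted({r.sample_id for r in records} - with_control)
    if lacking:
        raise IntegrityError(
            f"{path}: samples without an endogenous-control well: {lacking}"
        )
    return records


def write_qpcr_table(records: Sequence[QpcrRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_QPCR_COLUMNS)
        for r in records:
            writer.writerow([r.sample_id, r.gene, repr(float(r.ct)),
                             str(r.is_endogenous_control).lower()])
    return path


def _parse_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise FormatError(f"cannot parse boolean value {value!r}")


# ---------------------------------------------------------------------------
# sample designs & phenotypes
# ---------------------------------------------------------------------------

def read_sample_design(path: str | Path) -> SampleDesign:
    """Read a design CSV (sample_id, group, timepoint)."""
    frame = pd.read_csv(path, dtype=str)
    missing = {"sample_id", "group", "timepoint"} - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing design columns {sorted(missing)}")
    return SampleDesign(frame.set_index("sample_id"))


def write_sample_design(design: SampleDesign, path: str | Path) -> Path:
    path = Path(path)
    design.frame.reset_index(names="sample_id").to_csv(path, index=False)
    return path


def read_phenotype_table(path: str | Path) -> list[PhenotypeRecord]:
    """Read a phenotype CSV (sample_id, blood_glucose, body_weight
    [, hba1c_pct]); an empty hba1c field means not measured."""
    frame = pd.read_csv(path, dtype={"sample_id": str},
                        float_precision="round_trip")
    missing = {"sample_id", "blood_glucose", "body_weight"} - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing phenotype columns {sorted(missing)}")
    records = []
    for _, rec in frame.iterrows():
        hba1c = None
        if "hba1c_pct" in frame.columns and pd.notna(rec["hba1c_pct"]):
            hba1c = float(rec["hba1c_pct"])
        records.append(PhenotypeRecord(
            sample_id=rec["sample_id"],
            blood_glucose=float(rec["blood_glucose"]),
            body_weight=float(rec["body_weight"]),
            hba1c_pct=hba1c,
        ))
    return records


def write_phenotype_table(records: Sequence[PhenotypeRecord],
                          path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "blood_glucose", "body_weight", "hba1c_pct"])
        for r in records:
            writer.writerow([
                r.sample_id, repr(float(r.blood_glucose)),
                repr(float(r.body_weight)),
                "" if r.hba1c_pct is None else repr(float(r.hba1c_pct)),
            ])
    return path


# ---------------------------------------------------------------------------
# simulation ground truth
# ---------------------------------------------------------------------------

def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    """Write a ground-truth TSV (probe_id, true_category, true_temporal,
    true_fc)."""
    path = Path(path)
    truth.reset_index(names="probe_id").to_csv(
        path, sep="\t", index=False, float_format="%.17g")
    return path


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t",
                        dtype={"probe_id": str, "true_category": str,
                               "true_temporal": str},
                        keep_default_na=False,
                        float_precision="round_trip")
    frame["true_fc"] = frame["true_fc"].astype(float)
    return frame.set_index("probe_id")
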