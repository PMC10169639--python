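"""Readers and writers for the package's plain-text formats.

Matrices are TSV with a leading ``id`` column; the sample sheet is CSV;
the CpG annotation is TSV with semicolon-separated region categories and
``true``/``false`` booleans.  Result tables carry a single leading ``#``
comment line recording tool version, seed and parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import (
    ANNOTATION_COLUMNS,
    SHEET_COLUMNS,
    BetaMatrix,
    CpGAnnotation,
    ExpressionMatrix,
    SampleSheet,
    ValidationError,
)

_BOOL = {"true": True, "false": False}


def _read_matrix_frame(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str}, comment="#")
    if df.columns[0] != "id":
        raise ValidationError(f"{kind} {path}: first column must be 'id', got {df.columns[0]!r}")
    df = df.set_index("id")
    df.index.name = None
    if df.isna().to_numpy().any():
        rows = df.index[df.isna().any(axis=1)][:3].tolist()
        raise ValidationError(f"{kind} {path}: missing values (e.g. rows {rows})")
    return df


def read_beta_matrix(path) -> BetaMatrix:
    return BetaMatrix(_read_matrix_frame(path, "beta matrix"))


def read_expression_matrix(path) -> ExpressionMatrix:
    return ExpressionMatrix(_read_matrix_frame(path, "expression matrix"))


def write_matrix(matrix, path, float_format: str = "%.6g") -> None:
    df = matrix.data.copy()
    df.index.name = "id"
    df.to_csv(path, sep="\t", float_format=float_format)


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sample sheet {path}: missing column(s) {missing}")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, index=False)


def read_annotation(path) -> CpGAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["cpg_id"] + ANNOTATION_COLUMNS
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation {path}: missing column(s) {missing}")
    df = df.set_index("cpg_id")
    df["position"] = df["position"].astype(int)
    df["tss_distance"] = df["tss_distance"].astype(int)
    df["region_categories"] = df["region_categories"].map(
        lambda s: frozenset(s.split(";")) if isinstance(s, str) and s else frozenset()
    )
    for col in ("repeat_overlap", "snp_overlap"):
        vals = df[col].str.lower()
        bad = sorted(set(vals) - set(_BOOL))
        if bad:
            raise ValidationError(f"annotation {path}: bad boolean(s) in {col}: {bad}")
        df[col] = vals.map(_BOOL)
    return CpGAnnotation(df)


def write_annotation(annot: CpGAnnotation, path) -> None:
    df = annot.table.copy()
    df["region_categories"] = df["region_categories"].map(lambda s: ";".join(sorted(s)))
    for col in ("repeat_overlap", "snp_overlap"):
        df[col] = np.where(df[col], "true", "false")
    df.index.name = "cpg_id"
    df.to_csv(path, sep="\t")


def load_dataset(beta_path, sheet_path, annot_path):
    """Load and cross-validate a (beta, sheet, annotation) triple.

    Every sheet sample must be a matrix column and every matrix CpG must
    be annotated; violations raise naming the offending id.
    """
    beta = read_beta_matrix(beta_path)
    sheet = read_sample_sheet(sheet_path)
    annot = read_annotation(annot_path)
    cols = set(beta.sample_ids)
    missing = [s for s in sheet.sample_ids if s not in cols]
    if missing:
        raise ValidationError(f"sheet sample(s) absent from beta matrix: {missing}")
    annot.for_cpgs(beta.cpg_ids)  # raises on unannotated CpGs
    return beta, sheet, annot


# ---------------------------------------------------------------------------
# result tables (TSV with one leading comment line)
# ---------------------------------------------------------------------------


def _format_params(params: dict) -> str:
    parts = []
    for key in sorted(params):
        val = params[key]
        if isinstance(val, float):
            val = f"{val:g}"
        parts.append(f"{key}={val}")
    return " ".join(parts)


def write_result_table(df: pd.DataFrame, path, params: dict | None = None, index: bool = True) -> None:
    params = dict(params or {})
    header = f"# demkin={__version__}"
    if params:
        header += " " + _format_params(params)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_result_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
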