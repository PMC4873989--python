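"""Readers and writers for the tabular interchange formats.

One dialect everywhere: comma-separated UTF-8 with a mandatory header row
and "." decimals.  Absent optional values are empty fields on disk and
``None`` in memory.  Matrices carry compound ids in the first column and
assay ids in the header.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (ActivityMatrix, AnnotationTable, AssayDescriptor,
                   CompoundRecord, ValidationError)
from .prediction import (NeighborRow, SimilarityReport, TargetPrediction)
from .profiling import ClusterResult
from .screen import DoseResponseFit, ScreenResult


def read_activity_matrix(path, panel: list[AssayDescriptor] | None = None
                         ) -> ActivityMatrix:
    """Read a compounds x assays CSV into a validated raw ActivityMatrix."""
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path.name}: malformed CSV ({exc})") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path.name}: duplicate compound_id(s) {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{path.name}: duplicate assay_id(s) {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | (df == "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path.name}: non-numeric or missing value at compound "
            f"{df.index[r]!r}, assay {df.columns[c]!r}"
        )
    df.index = df.index.astype(str)
    return ActivityMatrix(numeric.astype(float), assays=panel)


def write_activity_matrix(matrix: ActivityMatrix, path) -> None:
    matrix.values.to_csv(path, index_label="compound_id",
                         float_format="%.12g")


_COMPOUND_COLUMNS = ("compound_id", "name", "library", "test_concentration",
                     "concentration_unit", "smiles", "annotation")


def read_compound_table(path, validate_smiles: bool = True
                        ) -> list[CompoundRecord]:
    """Read a compound table CSV; invalid SMILES are dropped with a warning.

    Only ``compound_id`` is required; any of name, library,
    test_concentration (+ concentration_unit), smiles, annotation may be
    present.  A record whose SMILES fails to parse is retained with
    ``smiles=None`` (per-record warning), so one bad structure cannot sink a
    whole library import.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "compound_id" not in df.columns:
        raise ValidationError(f"{path.name}: missing 'compound_id' column")
    seen: set[str] = set()
    records: list[CompoundRecord] = []

    def opt(row, col: str) -> str | None:
        val = row.get(col, "")
        return val if col in df.columns and val != "" else None

    for _, row in df.iterrows():
        cid = row["compound_id"]
        if cid in seen:
            raise ValidationError(f"{path.name}: duplicate compound_id {cid!r}")
        seen.add(cid)
        conc = opt(row, "test_concentration")
        smiles = opt(row, "smiles")
        if smiles is not None and validate_smiles:
            from rdkit import Chem
            from rdkit import RDLogger
            RDLogger.DisableLog("rdApp.error")
            if Chem.MolFromSmiles(smiles) is None:
                warnings.warn(
                    f"compound {cid!r}: invalid SMILES {smiles!r} dropped",
                    stacklevel=2)
                smiles = None
        records.append(CompoundRecord(
            compound_id=cid,
            name=opt(row, "name"),
            library=opt(row, "library"),
            test_concentration=float(conc) if conc is not None else None,
            concentration_unit=opt(row, "concentration_unit"),
            smiles=smiles,
            annotation=opt(row, "annotation"),
        ))
    return records


def write_compound_table(records: list[CompoundRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "compound_id": r.compound_id,
            "name": r.name or "",
            "library": r.library or "",
            "test_concentration": ("" if r.test_concentration is None
                                   else f"{r.test_concentration:.12g}"),
            "concentration_unit": r.concentration_unit or "",
            "smiles": r.smiles or "",
            "annotation": r.annotation or "",
        })
    pd.DataFrame(rows, columns=list(_COMPOUND_COLUMNS)).to_csv(path, index=False)


def read_annotation_table(path) -> AnnotationTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("compound_id", "target"):
        if col not in df.columns:
            raise ValidationError(f"annotation table missing {col!r} column")
    notes = {}
    if "note" in df.columns:
        notes = {r.compound_id: r.note for r in df.itertuples()
                 if r.note != ""}
    return AnnotationTable(
        dict(zip(df["compound_id"], df["target"])), notes)


def write_annotation_table(table: AnnotationTable, path) -> None:
    rows = [{"compound_id": cid, "target": table[cid],
             "note": table.note(cid) or ""} for cid in table]
    pd.DataFrame(rows, columns=["compound_id", "target", "note"]
                 ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(report, path) -> None:
    """Write a SimilarityReport, TargetPrediction or ScreenResult.

    Similarity reports and screen results go to CSV with a stable column
    order; target predictions go to JSON (single record).
    """
    if isinstance(report, SimilarityReport):
        df = report.to_frame()
        df["query_id"] = report.query_id
        df["threshold"] = report.threshold
        df.to_csv(path, index=False, float_format="%.6f")
    elif isinstance(report, TargetPrediction):
        payload = {
            "query_id": report.query_id,
            "predicted_target": report.predicted_target,
            "vote_fraction": report.vote_fraction,
            "n_neighbors": report.n_neighbors,
            "n_annotated": report.n_annotated,
            "coverage": report.coverage,
            "supporting_compound_ids": report.supporting_compound_ids,
            "tied_labels": report.tied_labels,
        }
        Path(path).write_text(json.dumps(payload, indent=1))
    elif isinstance(report, ScreenResult):
        df = report.rows.copy()
        df["threshold"] = report.threshold
        df.to_csv(path, index=False, float_format="%.6f")
    else:
        raise ValidationError(f"unsupported report type {type(report).__name__}")


def read_similarity_report(path) -> SimilarityReport:
    df = pd.read_csv(path, dtype={"compound_id": str, "annotation": str,
                                  "query_id": str})
    if df.empty:
        raise ValidationError(
            "empty similarity report: query id and threshold are stored "
            "per-row and cannot be recovered from a header-only file"
        )
    rows = [NeighborRow(
        compound_id=str(r.compound_id),
        rp=float(r.rp),
        tanimoto=None if pd.isna(r.tanimoto) else float(r.tanimoto),
        annotation=None if pd.isna(r.annotation) else str(r.annotation),
    ) for r in df.itertuples()]
    return SimilarityReport(query_id=str(df["query_id"].iloc[0]),
                            rows=rows,
                            threshold=float(df["threshold"].iloc[0]))


def write_cluster_result(result: ClusterResult, path) -> None:
    payload = {
        "method": result.method,
        "distance": result.distance,
        "compound_ids": result.compound_ids,
        "merges": [[int(a), int(b), float(h), int(s)]
                   for a, b, h, s in result.merges],
        "flat_labels": result.flat_labels,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_cluster_result(path) -> ClusterResult:
    payload = json.loads(Path(path).read_text())
    return ClusterResult(
        merges=[(int(a), int(b), float(h), int(s))
                for a, b, h, s in payload["merges"]],
        compound_ids=list(payload["compound_ids"]),
        flat_labels=payload.get("flat_labels"),
        method=payload.get("method", "ward"),
        distance=payload.get("distance", "euclidean"),
    )


def write_fit_result(fit: DoseResponseFit, path) -> None:
    payload = {
        "bottom": fit.bottom, "top": fit.top, "ic50": fit.ic50,
        "hill": fit.hill, "rss": fit.rss, "converged": fit.converged,
        "n_points": fit.n_points,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
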