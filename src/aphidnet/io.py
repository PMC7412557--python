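"""Readers and writers for the tab-delimited tables the pipeline exchanges.

All tables are TSV with a header row; identifiers are opaque strings.
Readers validate as they parse and raise :class:`ParseError` naming the
offending file and column.
"""

from __future__ import annotations

import os
from pathlib import Path


import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneAnnotation,
    MetaboliteTable,
    ParseError,
    SampleDesign,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_annotations",
    "write_annotations",
    "read_metabolites",
    "write_metabolites",
    "write_table",
]

#: Fixed float format used by every writer so that identical inputs produce
#: byte-identical files.
FLOAT_FORMAT = "%.10g"


def _read_tsv(path: str | os.PathLike, index_col: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    try:
        frame = pd.read_csv(path, sep="\t", dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: could not parse TSV ({exc})") from exc
    if frame.columns[0] != index_col:
        raise ParseError(
            f"{path}: first column must be {index_col!r}, got {frame.columns[0]!r}"
        )
    return frame.set_index(index_col)


def _numeric_matrix(frame: pd.DataFrame, path: Path, kind: str) -> pd.DataFrame:
    for column in frame.columns:
        converted = pd.to_numeric(frame[column], errors="coerce")
        bad = converted.isna() & frame[column].notna()
        if bad.any():
            row = frame.index[bad][0]
            raise ParseError(
                f"{path}: non-numeric {kind} value at row {row!r}, column {column!r}"
            )
        if converted.isna().any():
            row = frame.index[converted.isna()][0]
            raise ParseError(
                f"{path}: missing {kind} value at row {row!r}, column {column!r}"
            )
        frame[column] = converted
    return frame


def read_counts(path: str | os.PathLike, scale: str = "counts") -> ExpressionMatrix:
    path = Path(path)
    frame = _numeric_matrix(_read_tsv(path, "gene"), path, "expression")
    try:
        return ExpressionMatrix(data=frame, scale=scale)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_counts(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    write_table(matrix.data.reset_index(names="gene"), path)


def read_design(path: str | os.PathLike, control: str = "control") -> SampleDesign:
    path = Path(path)
    frame = _read_tsv(path, "sample")
    for column in ("timepoint", "replicate"):
        if column not in frame.columns:
            raise ParseError(f"{path}: design table missing column {column!r}")
        frame[column] = pd.to_numeric(frame[column], errors="coerce")
        if frame[column].isna().any():
            raise ParseError(f"{path}: non-numeric value in column {column!r}")
        frame[column] = frame[column].astype(int)
    try:
        return SampleDesign(table=frame, control=control)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_design(design: SampleDesign, path: str | os.PathLike) -> None:
    write_table(design.table.reset_index(names="sample"), path)


def read_annotations(path: str | os.PathLike) -> GeneAnnotation:
    path = Path(path)
    frame = _read_tsv(path, "gene")
    for column in ("is_tf", "tf_family", "pathways"):
        if column not in frame.columns:
            raise ParseError(f"{path}: annotation table missing column {column!r}")
    is_tf = frame["is_tf"].astype(str).str.lower()
    if not is_tf.isin({"true", "false"}).all():
        raise ParseError(f"{path}: column 'is_tf' must be True/False")
    pathways: dict[str, set[str]] = {}
    for gene, cell in frame["pathways"].items():
        if pd.isna(cell) or str(cell) == "":
            continue
        for pid in str(cell).split(";"):
            pathways.setdefault(pid, set()).add(gene)
    table = pd.DataFrame(
        {
            "is_tf": is_tf == "true",
            "tf_family": frame["tf_family"].fillna("").astype(str),
        },
        index=frame.index,
    )
    try:
        return GeneAnnotation(
            table=table, pathways={k: frozenset(v) for k, v in pathways.items()}
        )
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_annotations(annotation: GeneAnnotation, path: str | os.PathLike) -> None:
    by_gene: dict[str, list[str]] = {g: [] for g in annotation.genes}
    for pid in sorted(annotation.pathways):
        for gene in annotation.pathways[pid]:
            by_gene[gene].append(pid)
    frame = annotation.table.copy()
    frame["pathways"] = [";".join(sorted(by_gene[g])) for g in frame.index]
    write_table(frame.reset_index(names="gene"), path)


def read_metabolites(
    abundance_path: str | os.PathLike, pathway_path: str | os.PathLike
) -> MetaboliteTable:
    abundance_path = Path(abundance_path)
    frame = _numeric_matrix(
        _read_tsv(abundance_path, "metabolite"), abundance_path, "abundance"
    )
    pathway_path = Path(pathway_path)
    pmap = _read_tsv(pathway_path, "metabolite")
    if "pathways" not in pmap.columns:
        raise ParseError(f"{pathway_path}: missing column 'pathways'")
    pathways: dict[str, set[str]] = {}
    for mid, cell in pmap["pathways"].items():
        if pd.isna(cell) or str(cell) == "":
            continue
        for pid in str(cell).split(";"):
            pathways.setdefault(pid, set()).add(mid)
    try:
        return MetaboliteTable(
            data=frame, pathways={k: frozenset(v) for k, v in pathways.items()}
        )
    except ParseError as exc:
        raise ParseError(f"{abundance_path}: {exc}") from exc


def write_metabolites(
    table: MetaboliteTable,
    abundance_path: str | os.PathLike,
    pathway_path: str | os.PathLike,
) -> None:
    write_table(table.data.reset_index(names="metabolite"), abundance_path)
    by_met: dict[str, list[str]] = {m: [] for m in table.metabolites}
    for pid in sorted(table.pathways):
        for mid in table.pathways[pid]:
            if mid in by_met:
                by_met[mid].append(pid)
    frame = pd.DataFrame(
        {
            "metabolite": list(table.metabolites),
            "pathways": [";".join(sorted(by_met[m])) for m in table.metabolites],
        }
    )
    write_table(frame, pathway_path)


def write_table(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a TSV with a stable float format (no index column)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
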