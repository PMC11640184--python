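"""Readers and writers for sample sheets, matrices, panels and reports.

All formats are plain delimited text (tab by default, comma accepted),
matching public methylation-array exports; panel definitions are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .types import (
    BetaMatrix,
    CallMatrix,
    GroupCounts,
    PanelDefinition,
    SampleRecord,
    sheet_to_frame,
    validate_sheet,
)

if TYPE_CHECKING:  # pragma: no cover
    from .diagnostics import DiagnosticReport

SHEET_COLUMNS = ("sample_id", "diagnosis", "tissue", "cohort")


def read_sample_sheet(
    path: str | Path, delimiter: str = "\t", missing: str = "NA"
) -> list[SampleRecord]:
    """Read a delimited sample sheet into validated records.

    Required columns: sample_id, diagnosis, tissue, cohort; pair_id is
    optional.  Row order is preserved.  Errors carry the offending row
    number (1-based, excluding the header) or sample id.
    """
    df = pd.read_csv(
        path, sep=delimiter, dtype=str, na_values=[missing], keep_default_na=False
    )
    missing_cols = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"sample sheet missing columns {missing_cols}")
    records: list[SampleRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        pair = getattr(row, "pair_id", None)
        if isinstance(pair, float) and np.isnan(pair):
            pair = None
        try:
            records.append(
                SampleRecord(
                    sample_id=row.sample_id,
                    diagnosis=row.diagnosis,
                    tissue=row.tissue,
                    cohort=row.cohort,
                    pair_id=pair if pair else None,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"sample sheet row {row_no}: {exc}") from exc
    validate_sheet(records)
    return records


def write_sample_sheet(
    records: list[SampleRecord], path: str | Path, delimiter: str = "\t"
) -> None:
    df = sheet_to_frame(records).fillna("")
    df.to_csv(path, sep=delimiter, index=False, lineterminator="\n")


def _read_matrix_frame(
    path: str | Path, orientation: str, delimiter: str, missing: str
) -> pd.DataFrame:
    if orientation not in ("samples-as-rows", "probes-as-rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(
        path,
        sep=delimiter,
        index_col=0,
        na_values=[missing],
        keep_default_na=False,
    )
    if orientation == "probes-as-rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_beta_matrix(
    path: str | Path,
    orientation: str = "samples-as-rows",
    delimiter: str = "\t",
    missing: str = "NA",
) -> BetaMatrix:
    """Read a delimited beta matrix, normalized to samples x probes."""
    df = _read_matrix_frame(path, orientation, delimiter, missing)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric beta value in {path}: {exc}") from exc
    return BetaMatrix(df)


def write_beta_matrix(
    matrix: BetaMatrix, path: str | Path, delimiter: str = "\t", missing: str = "NA"
) -> None:
    matrix.values.to_csv(
        path, sep=delimiter, na_rep=missing, index_label="sample_id",
        lineterminator="\n",
    )


def read_call_matrix(
    path: str | Path,
    orientation: str = "samples-as-rows",
    delimiter: str = "\t",
    missing: str = "NA",
) -> CallMatrix:
    """Read a per-probe call matrix (methylated/unmethylated/undetermined)."""
    df = _read_matrix_frame(path, orientation, delimiter, missing)
    df = df.where(df.notna(), "undetermined").astype(str)
    return CallMatrix(df)


def write_call_matrix(
    matrix: CallMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    matrix.values.to_csv(
        path, sep=delimiter, index_label="sample_id", lineterminator="\n"
    )


def read_panel(path: str | Path) -> PanelDefinition:
    """Read a YAML panel definition.

    Keys: ``name``, ``target`` (diagnosis code), ``probes`` (list of probe
    ids, or mapping probe -> gene symbol), optional ``cutoff``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValidationError(f"panel file {path} is not a key-value document")
    for key in ("name", "target", "probes"):
        if key not in doc:
            raise ValidationError(f"panel file {path} missing key {key!r}")
    probes = doc["probes"]
    gene_map = None
    if isinstance(probes, dict):
        gene_map = {str(k): str(v) for k, v in probes.items()}
        probes = list(gene_map)
    return PanelDefinition(
        name=str(doc["name"]),
        target_diagnosis=str(doc["target"]),
        probes=tuple(str(p) for p in probes),
        cutoff=float(doc.get("cutoff", 0.30)),
        probe_gene_map=gene_map,
    )


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    doc: dict = {
        "name": panel.name,
        "target": panel.target_diagnosis,
        "probes": (
            dict(panel.probe_gene_map) if panel.probe_gene_map else list(panel.probes)
        ),
        "cutoff": panel.cutoff,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# --------------------------------------------------------------------------
# Reports


def write_report(report, path: str | Path, format: str = "tsv") -> None:
    """Write a GroupCounts table or a DiagnosticReport to TSV or JSON.

    Output is deterministic: fixed column order, canonical row order,
    percentages rendered with the one-decimal round-half-up rule.
    """
    from .diagnostics import DiagnosticReport  # local import avoids a cycle

    if format not in ("tsv", "json"):
        raise ValidationError(f"unknown report format {format!r}")
    if isinstance(report, GroupCounts):
        _write_group_counts(report, Path(path), format)
    elif isinstance(report, DiagnosticReport):
        _write_diagnostic_report(report, Path(path), format)
    else:
        raise ValidationError(
            f"cannot write object of type {type(report).__name__} as a report"
        )


def _write_group_counts(counts: GroupCounts, path: Path, format: str) -> None:
    from .types import canonical_sort_key

    df = counts.table.copy()
    order = sorted(
        range(len(df)),
        key=lambda i: canonical_sort_key(
            df.iloc[i]["cohort"], df.iloc[i]["diagnosis"], df.iloc[i]["tissue"]
        ),
    )
    df = df.iloc[order].reset_index(drop=True)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    else:
        payload = [
            {k: (int(v) if isinstance(v, (int, np.integer)) else v) for k, v in row.items()}
            for row in df.to_dict(orient="records")
        ]
        path.write_text(json.dumps(payload, indent=2) + "\n")


def _write_diagnostic_report(report: "DiagnosticReport", path: Path, format: str) -> None:
    if format == "tsv":
        frame = report.percent_table()
        frame.to_csv(path, sep="\t", index=True, index_label="metric",
                     lineterminator="\n")
    else:
        path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
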