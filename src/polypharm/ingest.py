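"""Readers and validators for heterogeneous drug-target evidence tables.

Two table shapes are supported:

* **quantitative** tables carry a numeric potency per row (IC50, Ki, Kd,
  pChEMBL, ...) in nM, uM, or M -- the shape of a ChEMBL-style activity
  export or a published kinase-affinity (Kd) table;
* **qualitative** tables carry curated drug-target links with no number --
  the shape of DrugBank / DGIdb / ChemicalProbes exports.

Everything is normalized into :class:`SourceRecord` streams.  Concentration
units are converted to nM on ingest; pChEMBL rows stay unitless.  Validation
never raises on bad rows: failures are tallied in a report and the rows
dropped, so one malformed line cannot abort a database build.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SourceRecord",
    "IngestReport",
    "ValidationReport",
    "SchemaError",
    "QUANT_VALUE_TYPES",
    "RELATIONS",
    "read_quantitative_table",
    "read_qualitative_table",
    "write_quantitative_table",
    "write_qualitative_table",
    "validate_records",
]

#: potency value types accepted on quantitative rows
QUANT_VALUE_TYPES = frozenset(
    {"IC50", "XC50", "EC50", "AC50", "C50", "Ki", "Kd", "potency", "pChEMBL"}
)

#: comparison relations; anything but "=" marks a censored measurement
RELATIONS = frozenset({"=", ">", "<", ">=", "<=", "~"})

_UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "M": 1e9}

#: unit label used for pChEMBL rows, which are already on a log scale
PCHEMBL_UNIT = "pchembl_unitless"


class SchemaError(ValueError):
    """A table is missing a required column or is otherwise malformed."""


@dataclass(frozen=True)
class SourceRecord:
    """One raw drug-target evidence row from one source database.

    Quantitative records carry ``value_type``/``value``/``unit``; the value
    is stored nM-normalized (or unitless for pChEMBL).  Qualitative records
    carry none of the numeric fields.
    """

    molecule_alias: str
    smiles: str | None
    gene_symbol: str
    kind: str  # "quantitative" | "qualitative"
    value_type: str | None = None
    value: float | None = None
    unit: str | None = None
    relation: str = "="
    source: str = ""

    @property
    def is_censored(self) -> bool:
        return self.kind == "quantitative" and self.relation != "="


@dataclass
class IngestReport:
    """Row-level problems encountered while reading one table."""

    path: str
    source: str
    n_read: int = 0
    n_emitted: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)  # (row no, reason)

    def skip(self, row_number: int, reason: str) -> None:
        self.skipped.append((row_number, reason))

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


@dataclass
class ValidationReport:
    """Counts of records removed per invariant-failure class.

    ``censored_relation`` is informational: censored records (relation other
    than "=") stay in the clean stream but are excluded from potency means
    downstream, so their count is surfaced here.
    """

    failures: Counter = field(default_factory=Counter)
    n_in: int = 0
    n_clean: int = 0

    def __getitem__(self, key: str) -> int:
        return self.failures[key]

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_clean


# default header names; remappable per source dialect
_QUANT_COLUMNS = ("molecule_alias", "smiles", "gene_symbol", "value_type", "value", "unit")
_QUAL_COLUMNS = ("molecule_alias", "smiles", "gene_symbol")


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _open_reader(path: Path, delimiter: str | None) -> tuple[csv.DictReader, str]:
    sep = _delimiter_for(path, delimiter)
    handle = path.open(newline="")
    return csv.DictReader(handle, delimiter=sep), sep


def _resolve_columns(
    fieldnames: Sequence[str] | None,
    required: Sequence[str],
    column_map: dict[str, str] | None,
    path: Path,
) -> dict[str, str]:
    """Map logical column names to file header names, erroring on gaps."""
    header = list(fieldnames or [])
    mapping = {}
    for logical in required:
        actual = (column_map or {}).get(logical, logical)
        if actual not in header:
            raise SchemaError(f"{path}: missing required column {actual!r}")
        mapping[logical] = actual
    # optional columns
    for logical in ("relation",):
        actual = (column_map or {}).get(logical, logical)
        if actual in header:
            mapping[logical] = actual
    return mapping


def _clean_gene(symbol: str) -> str:
    return symbol.strip().upper()


def _clean_smiles(raw: str | None) -> str | None:
    raw = (raw or "").strip()
    return raw or None


def read_quantitative_table(
    path: str | Path,
    source: str,
    *,
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
) -> tuple[list[SourceRecord], IngestReport]:
    """Read a potency table into nM-normalized quantitative records.

    Concentration values are converted to nM (uM x 1000, M x 1e9); rows whose
    value_type is pChEMBL pass through unitless.  Rows with an unparseable
    number, unknown value type, or unknown unit are skipped and tallied in
    the returned :class:`IngestReport`; row order is preserved.
    """
    path = Path(path)
    reader, _ = _open_reader(path, delimiter)
    cols = _resolve_columns(reader.fieldnames, _QUANT_COLUMNS, column_map, path)
    report = IngestReport(path=str(path), source=source)
    records: list[SourceRecord] = []
    for i, row in enumerate(reader, start=2):  # header is line 1
        report.n_read += 1
        value_type = (row[cols["value_type"]] or "").strip()
        if value_type not in QUANT_VALUE_TYPES:
            report.skip(i, f"unknown value_type {value_type!r}")
            continue
        try:
            value = float(row[cols["value"]])
        except (TypeError, ValueError):
            report.skip(i, f"unparseable value {row[cols['value']]!r}")
            continue
        unit = (row[cols["unit"]] or "").strip()
        if value_type == "pChEMBL":
            if unit not in ("", PCHEMBL_UNIT):
                report.skip(i, f"pChEMBL row with unit {unit!r}")
                continue
            unit_out, value_out = PCHEMBL_UNIT, value
        else:
            if unit not in _UNIT_TO_NM:
                report.skip(i, f"unknown unit {unit!r}")
                continue
            unit_out, value_out = "nM", value * _UNIT_TO_NM[unit]
        relation = (row.get(cols.get("relation", ""), "") or "=").strip() or "="
        records.append(
            SourceRecord(
                molecule_alias=(row[cols["molecule_alias"]] or "").strip(),
                smiles=_clean_smiles(row[cols["smiles"]]),
                gene_symbol=_clean_gene(row[cols["gene_symbol"]] or ""),
                kind="quantitative",
                value_type=value_type,
                value=value_out,
                unit=unit_out,
                relation=relation if relation in RELATIONS else "=",
                source=source,
            )
        )
    report.n_emitted = len(records)
    return records, report


def read_qualitative_table(
    path: str | Path,
    source: str,
    *,
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
) -> tuple[list[SourceRecord], IngestReport]:
    """Read a curated association table into qualitative records.

    Rows with an empty gene symbol are skipped with a report entry.
    Duplicate (alias, gene) rows are all emitted; de-duplication (or rather,
    evidence counting) happens at summarization.
    """
    path = Path(path)
    reader, _ = _open_reader(path, delimiter)
    cols = _resolve_columns(reader.fieldnames, _QUAL_COLUMNS, column_map, path)
    report = IngestReport(path=str(path), source=source)
    records: list[SourceRecord] = []
    for i, row in enumerate(reader, start=2):
        report.n_read += 1
        gene = _clean_gene(row[cols["gene_symbol"]] or "")
        if not gene:
            report.skip(i, "empty gene symbol")
            continue
        records.append(
            SourceRecord(
                molecule_alias=(row[cols["molecule_alias"]] or "").strip(),
                smiles=_clean_smiles(row[cols["smiles"]]),
                gene_symbol=gene,
                kind="qualitative",
                source=source,
            )
        )
    report.n_emitted = len(records)
    return records, report


def write_quantitative_table(
    records: Iterable[SourceRecord], path: str | Path, *, delimiter: str | None = None
) -> None:
    """Write quantitative records back to disk (nM-normalized, round-trippable)."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=sep)
        writer.writerow(list(_QUANT_COLUMNS) + ["relation"])
        for r in records:
            writer.writerow(
                [r.molecule_alias, r.smiles or "", r.gene_symbol, r.value_type,
                 repr(r.value), r.unit, r.relation]
            )


def write_qualitative_table(
    records: Iterable[SourceRecord], path: str | Path, *, delimiter: str | None = None
) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=sep)
        writer.writerow(list(_QUAL_COLUMNS))
        for r in records:
            writer.writerow([r.molecule_alias, r.smiles or "", r.gene_symbol])


def validate_records(
    records: Iterable[SourceRecord],
) -> tuple[list[SourceRecord], ValidationReport]:
    """Drop records that violate the evidence-record invariants.

    Order-stable and idempotent: validating an already-clean stream removes
    nothing.  All failures are captured in the report; nothing raises.
    """
    report = ValidationReport()
    clean: list[SourceRecord] = []
    for r in records:
        report.n_in += 1
        if not r.gene_symbol:
            report.failures["empty_gene"] += 1
            continue
        if r.kind == "quantitative":
            if r.value_type is None:
                report.failures["missing_value_type"] += 1
                continue
            if r.value is None:
                report.failures["missing_value"] += 1
                continue
            if r.unit is None:
                report.failures["missing_unit"] += 1
                continue
            if r.value < 0:
                report.failures["negative_value"] += 1
                continue
            if r.is_censored:
                # kept in the stream; excluded from potency means downstream
                report.failures["censored_relation"] += 1
        elif r.kind == "qualitative":
            if r.value is not None or r.value_type is not None:
                report.failures["qualitative_with_value"] += 1
                continue
        else:
            report.failures["unknown_kind"] += 1
            continue
        clean.append(r)
    report.n_clean = len(clean)
    return clean, report
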