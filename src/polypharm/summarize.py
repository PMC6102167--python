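"""Per-pair evidence aggregation: mean pChEMBL, KSI, confidence z-scores.

pChEMBL is the negative log10 of a molar potency (IC50, XC50, EC50, AC50,
Ki, Kd, or potency), so 100 nM corresponds to a pChEMBL of 7.  Because these
value types are only semi-comparable, per-record pChEMBL values are pooled
into one arithmetic mean per molecule-target pair; raw per-type means in nM
are kept alongside.

Two database-level scores are attached to every pair:

* the **known selectivity index** (KSI) of drug *d* against target *t* is
  the pair's mean pChEMBL divided by the sum of mean pChEMBLs over all
  targets of *d*; a KSI near 1 marks a known-single-target drug, and per
  drug the KSIs sum to 1;
* the **confidence score** is the z-score of the pair's total evidence
  count (quantitative + qualitative records) over all pairs in the
  database -- more independent observations, more confidence.

Group means and the z-score moments are accumulated with plain ordered
scalar arithmetic (sum / len over records in input order, population SD) so
results are reproducible bit-for-bit against a naive reference pass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .ingest import SourceRecord
from .structures import MoleculeRegistry

__all__ = [
    "ConfidenceParams",
    "to_pchembl",
    "record_pchembl",
    "summarize_associations",
    "known_selectivity_index",
    "confidence_scores",
    "write_summary_table",
    "SUMMARY_COLUMNS",
]

_UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "M": 1e9}

SUMMARY_COLUMNS = [
    "internal_id",
    "molecule_name",
    "gene_symbol",
    "mean_pchembl",
    "n_quantitative",
    "n_qualitative",
    "ksi",
    "confidence",
]


@dataclass(frozen=True)
class ConfidenceParams:
    """Moments of the total evidence count over all association rows."""

    mu_all: float
    sigma_all: float


def to_pchembl(value: float, unit: str = "nM") -> float:
    """Convert a potency to pChEMBL = -log10(value in molar).

    Computed as ``9 - log10(value in nM)`` so that the canonical anchors are
    exact: 100 nM -> 7, 1 nM -> 9, 1 uM -> 6.
    """
    if unit not in _UNIT_TO_NM:
        raise ValueError(f"unknown unit {unit!r}; expected one of {sorted(_UNIT_TO_NM)}")
    if value <= 0:
        raise ValueError(f"potency must be positive, got {value}")
    return 9.0 - math.log10(value * _UNIT_TO_NM[unit])


def record_pchembl(record: SourceRecord) -> float:
    """Per-record pChEMBL: pass-through for pChEMBL rows, converted otherwise."""
    if record.value_type == "pChEMBL":
        return float(record.value)
    return to_pchembl(record.value, record.unit)


def summarize_associations(
    records: Iterable[SourceRecord], registry: MoleculeRegistry
) -> pd.DataFrame:
    """Aggregate evidence into one row per (internal_id, gene_symbol).

    ``mean_pchembl`` pools per-record pChEMBL values across value types over
    uncensored ("=") quantitative records; censored records count toward
    ``n_quantitative`` but not toward any mean.  ``mean_by_type`` holds per
    value-type means in nM (pChEMBL-type rows under their own unitless key).
    Records that resolve to no registry entry are ignored (they were routed
    to the registry's skip report).
    """
    rows: dict[tuple[str, str], dict] = {}
    pch_values: dict[tuple[str, str], list[float]] = {}
    type_values: dict[tuple[str, str], dict[str, list[float]]] = {}
    for rec in records:
        internal_id = registry.internal_id_for_record(rec)
        if internal_id is None or not rec.gene_symbol:
            continue
        key = (internal_id, rec.gene_symbol)
        row = rows.setdefault(
            key,
            {
                "internal_id": internal_id,
                "molecule_name": _primary_alias(registry, internal_id),
                "gene_symbol": rec.gene_symbol,
                "n_quantitative": 0,
                "n_qualitative": 0,
            },
        )
        if rec.kind == "quantitative":
            row["n_quantitative"] += 1
            if not rec.is_censored:
                pch_values.setdefault(key, []).append(record_pchembl(rec))
                type_values.setdefault(key, {}).setdefault(rec.value_type, []).append(
                    float(rec.value)
                )
        else:
            row["n_qualitative"] += 1

    out = []
    for key in sorted(rows):
        row = rows[key]
        vals = pch_values.get(key)
        row["mean_pchembl"] = sum(vals) / len(vals) if vals else None
        row["mean_by_type"] = {
            vt: sum(vs) / len(vs) for vt, vs in sorted(type_values.get(key, {}).items())
        } or None
        out.append(row)
    frame = pd.DataFrame(
        out,
        columns=[
            "internal_id",
            "molecule_name",
            "gene_symbol",
            "mean_pchembl",
            "mean_by_type",
            "n_quantitative",
            "n_qualitative",
        ],
    )
    frame["mean_pchembl"] = pd.to_numeric(frame["mean_pchembl"])  # None -> NaN, float64
    return frame


def _primary_alias(registry: MoleculeRegistry, internal_id: str) -> str:
    aliases = registry.entries[internal_id].aliases
    return min(aliases) if aliases else internal_id


def known_selectivity_index(summaries: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``ksi`` column: mean pChEMBL over the drug's summed mean pChEMBLs.

    Pairs without a mean pChEMBL (qualitative-only or censored-only) get no
    KSI.  For each molecule, the defined KSI values sum to 1.
    """
    summaries = summaries.copy()
    ksi = [None] * len(summaries)
    position = {idx: i for i, idx in enumerate(summaries.index)}
    for _, group in summaries.groupby("internal_id", sort=False):
        defined = group["mean_pchembl"].notna()
        total = sum(group.loc[defined, "mean_pchembl"])  # ordered scalar sum
        if total <= 0:
            continue
        for idx in group.index[defined]:
            ksi[position[idx]] = group.at[idx, "mean_pchembl"] / total
    summaries["ksi"] = pd.array(ksi, dtype="float64")
    return summaries


def confidence_scores(summaries: pd.DataFrame) -> tuple[pd.DataFrame, ConfidenceParams]:
    """Fill the ``confidence`` column with evidence-count z-scores.

    The score for a pair is ``(n_quantitative + n_qualitative - mu_all) /
    sigma_all`` where the moments are taken over *all* association rows
    (population standard deviation).  If every pair has the same count the
    z-score is undefined; all confidences are set to 0 with a warning.
    """
    summaries = summaries.copy()
    counts = [
        int(q) + int(l)
        for q, l in zip(summaries["n_quantitative"], summaries["n_qualitative"])
    ]
    n = len(counts)
    if n == 0:
        return summaries.assign(confidence=pd.array([], dtype="float64")), ConfidenceParams(0.0, 0.0)
    mu = sum(counts) / n
    sigma = math.sqrt(sum((c - mu) ** 2 for c in counts) / n)
    if sigma == 0.0:
        warnings.warn(
            "all association rows have identical evidence counts; confidence set to 0",
            stacklevel=2,
        )
        summaries["confidence"] = 0.0
    else:
        summaries["confidence"] = [(c - mu) / sigma for c in counts]
    return summaries, ConfidenceParams(mu_all=mu, sigma_all=sigma)


def write_summary_table(summaries: pd.DataFrame, path: str | Path) -> None:
    """Write the association table as TSV, rounded to reporting precision.

    mean_pchembl and KSI are rounded to 3 decimals and confidence to 3
    decimals in the file; full precision stays in memory.
    """
    out = summaries.reindex(columns=SUMMARY_COLUMNS).copy()
    for col in ("mean_pchembl", "ksi", "confidence"):
        out[col] = out[col].round(3)
    out.to_csv(path, sep="\t", index=False)
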