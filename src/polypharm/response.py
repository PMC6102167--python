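"""Structure-similarity vs drug-response correlation against screening sets.

Mirrors the analysis a practitioner runs against CTRP/GDSC-style panels: for
a query structure (which need not be in the screening set), find the most
structurally similar screened drug, use it as the *reference*, Spearman-
correlate its AUC profile across cell lines against every other drug, and
pair each correlation with that drug's Tanimoto similarity to the *original
query*.  Drugs landing in the high-similarity / high-correlation corner are
structural analogs with matching biological activity.

AUC matrices may have missing cells; correlations use pairwise-complete
observations and are left undefined below a minimum overlap of
``MIN_SHARED`` cell lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import spearmanr

from .structures import (
    DEFAULT_FINGERPRINT,
    StructureError,
    compute_fingerprint,
    standardize_structure,
    tanimoto,
)

__all__ = [
    "ResponseMatrix",
    "read_response_matrix",
    "select_reference",
    "correlate_responses",
    "annotate_similarity",
    "MIN_SHARED",
]

#: minimum pairwise-complete cell lines for a defined correlation
MIN_SHARED = 3

CORRELATION_COLUMNS = ["drug", "tanimoto_to_query", "spearman_rho", "p_value", "n_shared"]


@dataclass
class ResponseMatrix:
    """A drug x cell-line AUC matrix with a companion structure table."""

    auc: pd.DataFrame  # index: drugs, columns: cell lines, NaN = missing
    structures: dict[str, str] = field(default_factory=dict)
    missing_structure: list[str] = field(default_factory=list)

    @property
    def drugs(self) -> list[str]:
        return list(self.auc.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.auc.columns)


def read_response_matrix(
    path_auc: str | Path, path_structures: str | Path
) -> ResponseMatrix:
    """Load an AUC CSV (drug rows, cell-line columns) and a drug->SMILES TSV.

    Empty cells parse as missing, not zero.  Drugs in the structure table
    that are absent from the matrix are a schema error; matrix drugs without
    a structure are retained and flagged in ``missing_structure``.
    """
    auc = pd.read_csv(path_auc, index_col=0)
    auc.index = auc.index.astype(str)
    if auc.index.duplicated().any():
        raise ValueError(f"{path_auc}: duplicated drug labels")
    struct = pd.read_csv(path_structures, sep="\t", dtype=str).fillna("")
    if not {"drug", "smiles"}.issubset(struct.columns):
        raise ValueError(f"{path_structures}: expected columns 'drug' and 'smiles'")
    unknown = sorted(set(struct["drug"]) - set(auc.index))
    if unknown:
        raise ValueError(
            f"{path_structures}: drugs not present in the AUC matrix: {unknown}"
        )
    structures = {
        row.drug: row.smiles for row in struct.itertuples(index=False) if row.smiles
    }
    missing = [d for d in auc.index if d not in structures]
    return ResponseMatrix(auc=auc, structures=structures, missing_structure=missing)


def select_reference(
    matrix: ResponseMatrix, query_smiles: str, method: str = DEFAULT_FINGERPRINT
) -> tuple[str, float]:
    """The screened drug most structurally similar to the query.

    Argmax of Tanimoto similarity over all drugs with a parseable structure;
    ties broken by drug label.  Works when the query itself was never
    screened.  No structured drugs is a usage error.
    """
    query_fp = compute_fingerprint(standardize_structure(query_smiles), method)
    best: tuple[float, str] | None = None
    for drug in sorted(matrix.structures):
        try:
            fp = compute_fingerprint(standardize_structure(matrix.structures[drug]), method)
        except StructureError:
            continue
        sim = tanimoto(query_fp, fp)
        if best is None or sim > best[0]:
            best = (sim, drug)
    if best is None:
        raise ValueError("no drug in the screening set has a parseable structure")
    return best[1], best[0]


def correlate_responses(matrix: ResponseMatrix, reference: str) -> pd.DataFrame:
    """Spearman correlation of every other drug's AUC profile to the reference.

    Pairwise-complete over cell lines; rows with fewer than ``MIN_SHARED``
    shared observations get undefined (NaN) rho and p.  Two-sided p-values
    (t-approximation; exact only in trivial cases).  The reference's own row
    is excluded.
    """
    if reference not in matrix.auc.index:
        raise KeyError(f"reference drug {reference!r} not in the response matrix")
    ref = matrix.auc.loc[reference]
    rows = []
    for drug in matrix.drugs:
        if drug == reference:
            continue
        other = matrix.auc.loc[drug]
        mask = ref.notna() & other.notna()
        n_shared = int(mask.sum())
        if n_shared < MIN_SHARED:
            rho, p = float("nan"), float("nan")
        else:
            result = spearmanr(ref[mask], other[mask])
            rho, p = float(result.statistic), float(result.pvalue)
        rows.append(
            {"drug": drug, "spearman_rho": rho, "p_value": p, "n_shared": n_shared}
        )
    return pd.DataFrame(rows, columns=["drug", "spearman_rho", "p_value", "n_shared"])


def annotate_similarity(
    rows: pd.DataFrame,
    matrix: ResponseMatrix,
    query_smiles: str,
    method: str = DEFAULT_FINGERPRINT,
) -> pd.DataFrame:
    """Attach each drug's Tanimoto similarity to the original query.

    Similarity is computed against the query, not the reference.  Drugs
    without a (parseable) structure get an undefined similarity but keep
    their correlation.  Output sorted by similarity descending, NaN last.
    """
    query_fp = compute_fingerprint(standardize_structure(query_smiles), method)
    sims = []
    for drug in rows["drug"]:
        smiles = matrix.structures.get(drug)
        if not smiles:
            sims.append(float("nan"))
            continue
        try:
            fp = compute_fingerprint(standardize_structure(smiles), method)
        except StructureError:
            sims.append(float("nan"))
            continue
        sims.append(tanimoto(query_fp, fp))
    out = rows.copy()
    out["tanimoto_to_query"] = sims
    out = out.reindex(columns=CORRELATION_COLUMNS)
    return out.sort_values(
        ["tanimoto_to_query", "drug"],
        ascending=[False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
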