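"""Deterministic synthetic source tables with independently computed truth.

Every pipeline stage is testable offline: this module writes small
quantitative/qualitative evidence tables, GMT collections, and AUC response
matrices in exactly the dialects the readers expect, together with ground
truth produced by a *separate, naive* pass over the written files (csv
module + plain arithmetic + ``Chem.CanonSmiles`` grouping) so the pipeline
can be checked against an implementation it shares no code with.

Molecules are drawn from an embedded list of valid, drug-like SMILES (plus
simple alcohol homologs); alias duplicates are emitted as alternate
random-atom-order SMILES spellings of the same structure, which the
registry must merge.  Identical spec + seed reproduces byte-identical
files; the RNG algorithm and seed are recorded in a sidecar metadata file.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

__all__ = [
    "FixtureSpec",
    "SourceTables",
    "ResponseFixture",
    "SMILES_POOL",
    "GENE_POOL",
    "make_source_tables",
    "make_response_matrix",
    "make_gmt",
]

# valid, neutral, pre-canonical structures (spot-checked standardizable);
# enough diversity that path fingerprints separate scaffolds
SMILES_POOL = [
    "CC(=O)Oc1ccccc1C(=O)O",                        # aspirin
    "Cn1c(=O)c2c(ncn2C)n(C)c1=O",                   # caffeine
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",                   # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",                           # paracetamol
    "CCOC(=O)c1ccc(N)cc1",                          # benzocaine
    "CCN(CC)CCOC(=O)c1ccc(N)cc1",                   # procaine
    "CN1CCC[C@H]1c1cccnc1",                         # nicotine
    "CC(C)NCC(O)COc1cccc2ccccc12",                  # propranolol
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",               # atenolol
    "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",        # warfarin
    "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21",          # diazepam
    "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1",           # fluoxetine
    "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21",             # chlorpromazine
    "Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1",  # imatinib
    "COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1",               # gefitinib
    "Nc1ccn([C@@H]2O[C@H](CO)[C@@H](O)[C@H]2O)c(=O)n1",             # cytidine
    "CCO", "CCCO", "CCCCO", "CCCCCO", "CCCCCCO", "CCCCCCCO",        # homologs
    "CCOCC", "CCOCCC",
]

GENE_POOL = [
    "PAK1", "PAK2", "PAK3", "LCK", "MAP4K5", "SIK2", "STK24", "STK25",
    "STK26", "LIMK1", "LIMK2", "AURKA", "PTK2", "PTK2B", "PLK1", "PLK2",
    "BRD4", "CAMKK2",
]

_VALUE_TYPES = ["IC50", "EC50", "AC50", "Ki", "Kd", "potency"]
_UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "M": 1e9}


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic evidence-table build."""

    n_molecules: int = 12
    n_targets: int = 8
    n_quant_records: int = 40
    n_qual_records: int = 15
    potency_range: tuple[float, float] = (1.0, 10_000.0)  # nM, log-uniform
    duplicate_rate: float = 0.25
    n_censored: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_molecules, self.n_targets, self.n_quant_records, self.n_qual_records) <= 0:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ValueError("duplicate_rate must be in [0, 1]")
        if self.n_molecules > len(SMILES_POOL):
            raise ValueError(f"at most {len(SMILES_POOL)} molecules available")


@dataclass
class SourceTables:
    quantitative_path: Path
    qualitative_path: Path
    metadata_path: Path
    ground_truth: pd.DataFrame
    mu_all: float
    sigma_all: float
    n_distinct_structures: int


@dataclass
class ResponseFixture:
    auc_path: Path
    structures_path: Path
    query_smiles: str
    expected_reference: str
    analog_drug: str | None
    expected: pd.DataFrame  # drug, spearman_rho, n_shared from the naive oracle


def make_source_tables(spec: FixtureSpec, outdir: str | Path) -> SourceTables:
    """Write quantitative + qualitative TSVs and compute their ground truth.

    The tables include alias/spelling duplicates (per ``duplicate_rate``), a
    few censored rows (relation ">"), pChEMBL-type rows, and one alias-only
    molecule without any structure, so registration, unit handling, and
    summary semantics are all exercised.  Ground truth is recomputed from
    the written files by :func:`_naive_ground_truth`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    pool = list(SMILES_POOL)
    rng.shuffle(pool)
    molecules = []
    n_dup = round(spec.duplicate_rate * spec.n_molecules)
    for i in range(spec.n_molecules):
        smiles = pool[i]
        alias = f"drug-{i + 1:02d}"
        spellings = [smiles]
        aliases = [alias]
        sources = ["chembl-like"]
        if i < n_dup:
            mol = Chem.MolFromSmiles(smiles)
            alt = Chem.MolToRandomSmilesVect(mol, 1, randomSeed=int(rng.integers(1, 2**31)))[0]
            spellings.append(alt)
            aliases.append(f"{alias}-alt")
            sources.append("vendor-like")
        molecules.append({"aliases": aliases, "spellings": spellings, "sources": sources})
    genes = list(rng.choice(GENE_POOL, size=spec.n_targets, replace=False))

    def pick_form(m) -> tuple[str, str, str]:
        j = int(rng.integers(len(m["aliases"])))
        return m["aliases"][j], m["spellings"][j], m["sources"][j]

    quant_path = outdir / "quantitative.tsv"
    with quant_path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(
            ["molecule_alias", "smiles", "gene_symbol", "value_type", "value", "unit", "relation"]
        )
        lo, hi = spec.potency_range
        for _ in range(spec.n_quant_records):
            m = molecules[int(rng.integers(spec.n_molecules))]
            alias, smiles, source_ = pick_form(m)
            gene = genes[int(rng.integers(spec.n_targets))]
            if rng.random() < 0.15:  # direct pChEMBL rows
                writer.writerow(
                    [alias, smiles, gene, "pChEMBL",
                     repr(round(float(rng.uniform(5.0, 9.0)), 3)), "pchembl_unitless", "="]
                )
                continue
            value_type = _VALUE_TYPES[int(rng.integers(len(_VALUE_TYPES)))]
            nm = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            unit = ["nM", "uM", "M"][int(rng.integers(3))]
            writer.writerow(
                [alias, smiles, gene, value_type, repr(nm / _UNIT_TO_NM[unit]), unit, "="]
            )
        for _ in range(spec.n_censored):
            m = molecules[int(rng.integers(spec.n_molecules))]
            alias, smiles, _src = pick_form(m)
            gene = genes[int(rng.integers(spec.n_targets))]
            writer.writerow([alias, smiles, gene, "IC50", repr(float(hi)), "nM", ">"])

    qual_path = outdir / "qualitative.tsv"
    with qual_path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["molecule_alias", "smiles", "gene_symbol"])
        for k in range(spec.n_qual_records):
            if k == 0:  # a molecule known only by name, never by structure
                writer.writerow(["orphan-probe", "", genes[0]])
                continue
            m = molecules[int(rng.integers(spec.n_molecules))]
            alias, smiles, _src = pick_form(m)
            if rng.random() < 0.2:
                smiles = ""  # alias-only row for a structured molecule
            writer.writerow([alias, smiles, genes[int(rng.integers(spec.n_targets))]])

    metadata_path = outdir / "fixture_metadata.json"
    with metadata_path.open("w") as handle:
        json.dump({"rng": "numpy.random.default_rng(PCG64)", "spec": asdict(spec)}, handle, indent=1)

    truth, mu, sigma, n_struct = _naive_ground_truth(quant_path, qual_path)
    return SourceTables(
        quantitative_path=quant_path,
        qualitative_path=qual_path,
        metadata_path=metadata_path,
        ground_truth=truth,
        mu_all=mu,
        sigma_all=sigma,
        n_distinct_structures=n_struct,
    )


def _naive_ground_truth(
    quant_path: Path, qual_path: Path
) -> tuple[pd.DataFrame, float, float, int]:
    """Straightforward re-derivation of the association table from the files.

    Shares no code with the pipeline modules: csv parsing, a dict-of-lists
    per pair, ``Chem.CanonSmiles`` for structure grouping, ordered sum/len
    means, and textbook population-SD z-scores.
    """
    alias_to_canon: dict[str, str] = {}
    rows: list[dict] = []
    with quant_path.open(newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            row = dict(row)
            row["kind"] = "quant"
            rows.append(row)
    with qual_path.open(newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            row = dict(row)
            row["kind"] = "qual"
            rows.append(row)
    for row in rows:
        if row["smiles"]:
            canon = Chem.CanonSmiles(row["smiles"])
            row["canon"] = canon
            alias_to_canon.setdefault(row["molecule_alias"].lower(), canon)
    structureless: dict[str, str] = {}
    for row in rows:
        if not row["smiles"]:
            key = row["molecule_alias"].lower()
            if key in alias_to_canon:
                row["canon"] = alias_to_canon[key]
            else:
                row["canon"] = None
                structureless.setdefault(key, row["molecule_alias"])

    canons = sorted({r["canon"] for r in rows if r["canon"]})
    ids = {c: f"MOL{i + 1:06d}" for i, c in enumerate(canons)}
    for j, key in enumerate(sorted(structureless)):
        ids[("alias", key)] = f"MOL{len(canons) + j + 1:06d}"

    names: dict[str, str] = {}
    groups: dict[tuple[str, str], dict] = {}
    for row in rows:
        mid = ids[row["canon"]] if row["canon"] else ids[("alias", row["molecule_alias"].lower())]
        names.setdefault(mid, row["molecule_alias"])
        names[mid] = min(names[mid], row["molecule_alias"])
        g = groups.setdefault(
            (mid, row["gene_symbol"]),
            {"pchembls": [], "n_quant": 0, "n_qual": 0},
        )
        if row["kind"] == "qual":
            g["n_qual"] += 1
            continue
        g["n_quant"] += 1
        if row.get("relation", "=") != "=":
            continue
        if row["value_type"] == "pChEMBL":
            g["pchembls"].append(float(row["value"]))
        else:
            nm = float(row["value"]) * _UNIT_TO_NM[row["unit"]]
            g["pchembls"].append(9.0 - math.log10(nm))

    records = []
    for (mid, gene) in sorted(groups):
        g = groups[(mid, gene)]
        mean = sum(g["pchembls"]) / len(g["pchembls"]) if g["pchembls"] else None
        records.append(
            {
                "internal_id": mid,
                "molecule_name": names[mid],
                "gene_symbol": gene,
                "mean_pchembl": mean,
                "n_quantitative": g["n_quant"],
                "n_qualitative": g["n_qual"],
            }
        )
    # KSI per molecule
    totals: dict[str, float] = {}
    for r in records:
        if r["mean_pchembl"] is not None:
            totals[r["internal_id"]] = totals.get(r["internal_id"], 0.0) + r["mean_pchembl"]
    for r in records:
        r["ksi"] = (
            r["mean_pchembl"] / totals[r["internal_id"]]
            if r["mean_pchembl"] is not None
            else None
        )
    counts = [r["n_quantitative"] + r["n_qualitative"] for r in records]
    mu = sum(counts) / len(counts)
    sigma = math.sqrt(sum((c - mu) ** 2 for c in counts) / len(counts))
    for r, c in zip(records, counts):
        r["confidence"] = (c - mu) / sigma if sigma > 0 else 0.0
    truth = pd.DataFrame(records)
    truth["mean_pchembl"] = pd.to_numeric(truth["mean_pchembl"])
    truth["ksi"] = pd.to_numeric(truth["ksi"])
    return truth, mu, sigma, len(canons)


# ---------------------------------------------------------------------------
# response-matrix fixture

_QUERY_SMILES = "CCOC(=O)c1ccc(N)cc1"          # the designated query (benzocaine)
_ANALOG_SMILES = "CCCOC(=O)c1ccc(N)cc1"        # propyl homolog of the query
_DECOY_SMILES = [
    "Cn1c(=O)c2c(ncn2C)n(C)c1=O",
    "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",
    "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21",
    "CC(C)NCC(O)COc1cccc2ccccc12",
    "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21",
    "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1",
    "Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1",
]


def make_response_matrix(
    spec: FixtureSpec,
    outdir: str | Path,
    n_cell_lines: int = 12,
    embedded_analog: bool = True,
    noise_sd: float = 0.1,
    missing_rate: float = 0.05,
) -> ResponseFixture:
    """Write an AUC matrix + structure table with a known best analog.

    One drug ("ref-drug") carries the query structure itself, so reference
    selection must pick it at similarity 1.0.  With ``embedded_analog``, a
    second drug is a close homolog of the query whose AUC vector is the
    reference signal plus Gaussian noise of ``noise_sd`` (rank-correlated by
    construction; exactly rank-identical at zero noise).  Decoys get
    independent response vectors.  Missing AUC cells are injected at
    ``missing_rate`` into non-reference drugs.  Expected Spearman rhos come
    from an independent average-rank + Pearson computation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)

    drugs = {"ref-drug": _QUERY_SMILES}
    if embedded_analog:
        drugs["analog-drug"] = _ANALOG_SMILES
    for i, smiles in enumerate(_DECOY_SMILES, start=1):
        drugs[f"decoy-{i:02d}"] = smiles

    cell_lines = [f"CL{j + 1:02d}" for j in range(n_cell_lines)]
    base = rng.uniform(0.2, 1.0, size=n_cell_lines)
    auc = {}
    for drug in drugs:
        if drug == "ref-drug":
            auc[drug] = base.copy()
        elif drug == "analog-drug":
            auc[drug] = base + rng.normal(0.0, noise_sd, size=n_cell_lines)
        else:
            auc[drug] = rng.uniform(0.2, 1.0, size=n_cell_lines)
    frame = pd.DataFrame(auc, index=cell_lines).T
    frame.index.name = "drug"
    if missing_rate > 0:
        for drug in frame.index:
            if drug == "ref-drug":
                continue
            mask = rng.random(n_cell_lines) < missing_rate
            # never drop below the defined-correlation floor
            if (~mask).sum() < 4:
                mask[:] = False
            frame.loc[drug, mask] = np.nan

    auc_path = outdir / "auc.csv"
    frame.to_csv(auc_path)
    structures_path = outdir / "structures.tsv"
    with structures_path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["drug", "smiles"])
        for drug in frame.index:
            writer.writerow([drug, drugs[drug]])

    expected = _naive_spearman_table(frame, "ref-drug")
    return ResponseFixture(
        auc_path=auc_path,
        structures_path=structures_path,
        query_smiles=_QUERY_SMILES,
        expected_reference="ref-drug",
        analog_drug="analog-drug" if embedded_analog else None,
        expected=expected,
    )


def _avg_ranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) computed from first principles."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _naive_spearman_table(frame: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Rank-then-Pearson Spearman rhos, independent of scipy.stats.spearmanr."""
    ref = frame.loc[reference].to_numpy()
    rows = []
    for drug in frame.index:
        if drug == reference:
            continue
        other = frame.loc[drug].to_numpy()
        mask = ~(np.isnan(ref) | np.isnan(other))
        n = int(mask.sum())
        if n < 3:
            rho = float("nan")
        else:
            r1, r2 = _avg_ranks(ref[mask]), _avg_ranks(other[mask])
            rho = float(np.corrcoef(r1, r2)[0, 1])
        rows.append({"drug": drug, "spearman_rho": rho, "n_shared": n})
    return pd.DataFrame(rows)


def make_gmt(
    outdir: str | Path,
    n_sets: int = 5,
    universe_size: int = 60,
    seed: int = 0,
) -> tuple[Path, dict[str, set[str]]]:
    """Write a small GMT collection over a synthetic gene universe."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    universe = [f"GENE{i + 1:03d}" for i in range(universe_size)]
    sets: dict[str, set[str]] = {}
    for s in range(n_sets):
        size = int(rng.integers(5, max(6, universe_size // 3)))
        members = sorted(rng.choice(universe, size=size, replace=False))
        sets[f"SET_{s + 1}"] = set(members)
    path = outdir / "collection.gmt"
    with path.open("w") as handle:
        for name in sorted(sets):
            handle.write("\t".join([name, "synthetic gene set"] + sorted(sets[name])) + "\n")
    return path, sets
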