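"""The drug-target database and its query surface.

A :class:`DrugTargetDatabase` bundles the molecule registry, the scored
association table, the confidence moments, cached fingerprints, and a
gene -> molecules index.  On top of it sit the user-facing queries:

* resolve a free-text alias to internal IDs;
* thresholded Tanimoto similarity search (the query molecule need not be in
  the database -- it is standardized and fingerprinted on the fly);
* targets of a set of molecules, most potent first;
* molecules hitting *all* (or any) of a list of targets -- the
  polypharmacology question "which single compound covers this target set";
* bipartite drug-target networks, exportable to GraphML or JSON node-link.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .ingest import SourceRecord, validate_records
from .structures import (
    DEFAULT_FINGERPRINT,
    Fingerprint,
    MoleculeRegistry,
    compute_fingerprint,
    register_molecules,
    standardize_structure,
    tanimoto,
)
from .summarize import (
    SUMMARY_COLUMNS,
    ConfidenceParams,
    confidence_scores,
    known_selectivity_index,
    summarize_associations,
    write_summary_table,
)

__all__ = [
    "SimilarityHit",
    "DrugTargetDatabase",
    "build_database",
    "resolve_alias",
    "similarity_search",
    "targets_of",
    "molecules_for_targets",
    "build_network",
    "export_network",
    "load_network",
    "save_database",
    "load_database",
]


@dataclass(frozen=True)
class SimilarityHit:
    internal_id: str
    similarity: float
    canonical_smiles: str


@dataclass
class DrugTargetDatabase:
    registry: MoleculeRegistry
    summaries: pd.DataFrame
    params: ConfidenceParams
    fingerprints: dict[tuple[str, str], Fingerprint] = field(default_factory=dict)
    gene_index: dict[str, set[str]] = field(default_factory=dict)

    def fingerprint(self, internal_id: str, method: str) -> Fingerprint | None:
        """Cached fingerprint for a registered molecule; None if structureless."""
        entry = self.registry.entries[internal_id]
        if entry.canonical_smiles is None:
            return None
        key = (internal_id, method)
        if key not in self.fingerprints:
            self.fingerprints[key] = compute_fingerprint(entry.canonical_smiles, method)
        return self.fingerprints[key]


def build_database(
    records: Iterable[SourceRecord],
    *,
    fingerprint_methods: Sequence[str] = (DEFAULT_FINGERPRINT,),
    validate: bool = True,
) -> DrugTargetDatabase:
    """Run the full harmonization pipeline over an evidence stream.

    Validates (optional), registers structures, aggregates per-pair
    summaries, fills KSI and confidence, precomputes fingerprints, and
    builds the gene index.
    """
    records = list(records)
    if validate:
        records, _ = validate_records(records)
    registry = register_molecules(records)
    summaries = summarize_associations(records, registry)
    summaries = known_selectivity_index(summaries)
    summaries, params = confidence_scores(summaries)
    db = DrugTargetDatabase(registry=registry, summaries=summaries, params=params)
    for internal_id, entry in registry.entries.items():
        if entry.canonical_smiles is not None:
            for method in fingerprint_methods:
                db.fingerprint(internal_id, method)
    for row in summaries.itertuples(index=False):
        db.gene_index.setdefault(row.gene_symbol, set()).add(row.internal_id)
    return db


def resolve_alias(db: DrugTargetDatabase, name: str) -> set[str]:
    """Case-insensitive exact alias lookup; empty set for unknown names."""
    return db.registry.lookup_alias(name)


def similarity_search(
    db: DrugTargetDatabase,
    query_smiles: str,
    threshold: float = 0.8,
    method: str = DEFAULT_FINGERPRINT,
) -> list[SimilarityHit]:
    """All database molecules with Tanimoto >= threshold to the query.

    The query is standardized first, so a query identical to a registered
    structure scores exactly 1.0.  Sorted by similarity descending, ties
    broken by internal ID.  Structureless molecules never appear.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    canonical = standardize_structure(query_smiles)
    query_fp = compute_fingerprint(canonical, method)
    hits = []
    for internal_id, entry in db.registry.entries.items():
        fp = db.fingerprint(internal_id, method)
        if fp is None:
            continue
        sim = tanimoto(query_fp, fp)
        if sim >= threshold:
            hits.append(SimilarityHit(internal_id, sim, entry.canonical_smiles))
    hits.sort(key=lambda h: (-h.similarity, h.internal_id))
    return hits


def targets_of(db: DrugTargetDatabase, internal_ids: Iterable[str]) -> pd.DataFrame:
    """Association rows for the given molecules, most potent first.

    Sorted by mean pChEMBL descending with qualitative-only rows (no mean)
    last; ties broken by gene symbol.  Unknown IDs raise ``KeyError``.
    """
    ids = list(internal_ids)
    for i in ids:
        if i not in db.registry.entries:
            raise KeyError(f"unknown internal id {i!r}")
    rows = db.summaries[db.summaries["internal_id"].isin(ids)]
    return rows.sort_values(
        by=["mean_pchembl", "gene_symbol"],
        ascending=[False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)


def molecules_for_targets(
    db: DrugTargetDatabase, genes: Sequence[str], mode: str = "all"
) -> set[str]:
    """Molecules associated with all (intersection) or any (union) query genes."""
    if not genes:
        raise ValueError("gene list must be non-empty")
    if mode not in ("all", "any"):
        raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")
    per_gene = []
    for gene in genes:
        symbol = gene.strip().upper()
        ids = db.gene_index.get(symbol, set())
        if not ids:
            warnings.warn(f"unknown gene symbol {symbol!r}", stacklevel=2)
        per_gene.append(set(ids))
    if mode == "all":
        result = per_gene[0]
        for s in per_gene[1:]:
            result = result & s
        return result
    return set().union(*per_gene)


def build_network(db: DrugTargetDatabase, internal_ids: Iterable[str]) -> nx.Graph:
    """Bipartite molecule-target graph for the given molecules.

    Molecule nodes carry ``kind='molecule'`` (bipartite side 0) and their
    primary alias; target nodes carry ``kind='target'`` (side 1).  One edge
    per association row with its evidence attributes; mean pChEMBL is set
    only when defined.
    """
    rows = targets_of(db, internal_ids)
    graph = nx.Graph()
    for internal_id in sorted(set(internal_ids)):
        entry = db.registry.entries[internal_id]
        graph.add_node(
            internal_id,
            kind="molecule",
            bipartite=0,
            label=min(entry.aliases) if entry.aliases else internal_id,
        )
    for gene in sorted(rows["gene_symbol"].unique()):
        graph.add_node(gene, kind="target", bipartite=1, label=gene)
    for row in rows.sort_values(["internal_id", "gene_symbol"]).itertuples(index=False):
        attrs = {
            "n_quantitative": int(row.n_quantitative),
            "n_qualitative": int(row.n_qualitative),
        }
        if pd.notna(row.mean_pchembl):
            attrs["mean_pchembl"] = float(row.mean_pchembl)
        graph.add_edge(row.internal_id, row.gene_symbol, **attrs)
    return graph


def export_network(network: nx.Graph, fmt: str, path: str | Path) -> None:
    """Serialize a network to ``graphml`` or ``json-node-link``."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(network, path)
    elif fmt == "json-node-link":
        with path.open("w") as handle:
            json.dump(nx.node_link_data(network, edges="edges"), handle, indent=1)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def load_network(fmt: str, path: str | Path) -> nx.Graph:
    """Read back a network written by :func:`export_network`."""
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "json-node-link":
        with path.open() as handle:
            return nx.node_link_graph(json.load(handle), edges="edges")
    raise ValueError(f"unknown network format {fmt!r}")


# ---------------------------------------------------------------------------
# on-disk form: registry TSV + alias JSON + summary TSV + params JSON


def save_database(db: DrugTargetDatabase, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "registry.tsv").open("w") as handle:
        handle.write("internal_id\tcanonical_smiles\taliases\tsources\n")
        for internal_id in sorted(db.registry.entries):
            e = db.registry.entries[internal_id]
            handle.write(
                "\t".join(
                    [
                        internal_id,
                        e.canonical_smiles or "",
                        "|".join(sorted(e.aliases)),
                        "|".join(sorted(e.sources)),
                    ]
                )
                + "\n"
            )
    with (outdir / "aliases.json").open("w") as handle:
        json.dump(
            {a: sorted(ids) for a, ids in sorted(db.registry.alias_index.items())},
            handle,
            indent=1,
        )
    # full-precision summary table for reload; rounded copy for reading
    db.summaries.reindex(columns=SUMMARY_COLUMNS).to_csv(
        outdir / "summary_full.tsv", sep="\t", index=False
    )
    write_summary_table(db.summaries, outdir / "summary.tsv")
    with (outdir / "params.json").open("w") as handle:
        json.dump(
            {"mu_all": db.params.mu_all, "sigma_all": db.params.sigma_all}, handle
        )


def load_database(outdir: str | Path) -> DrugTargetDatabase:
    """Reload a saved database; fingerprints are recomputed lazily."""
    outdir = Path(outdir)
    registry = MoleculeRegistry()
    frame = pd.read_csv(outdir / "registry.tsv", sep="\t", dtype=str).fillna("")
    from .structures import MoleculeEntry  # local import to avoid cycle noise

    for row in frame.itertuples(index=False):
        entry = MoleculeEntry(
            internal_id=row.internal_id,
            canonical_smiles=row.canonical_smiles or None,
            aliases=set(filter(None, row.aliases.split("|"))),
            sources=set(filter(None, row.sources.split("|"))),
        )
        registry.entries[entry.internal_id] = entry
        if entry.canonical_smiles:
            registry.structure_index[entry.canonical_smiles] = entry.internal_id
        for alias in entry.aliases:
            registry.alias_index.setdefault(alias.lower(), set()).add(entry.internal_id)
    summaries = pd.read_csv(outdir / "summary_full.tsv", sep="\t")
    with (outdir / "params.json").open() as handle:
        params = ConfidenceParams(**json.load(handle))
    db = DrugTargetDatabase(registry=registry, summaries=summaries, params=params)
    for row in summaries.itertuples(index=False):
        db.gene_index.setdefault(row.gene_symbol, set()).add(row.internal_id)
    return db
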