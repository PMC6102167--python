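"""Local over-representation analysis of target lists against GMT gene sets.

Given the targets of a molecule (or any gene list), each gene set in a GMT
collection is scored with the one-sided hypergeometric upper-tail
probability of the observed overlap: with a background of ``N`` genes of
which ``K`` are in the set and a target list of ``n``, the p-value is
``P(X >= k)`` for ``X ~ Hypergeom(N, K, n)`` -- equivalently Fisher's exact
test for over-representation.  Benjamini-Hochberg q-values are reported
alongside the raw p-values.

The default background is the union of all genes in the collection; pass an
explicit background to control the universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "read_gmt", "enrich_targets", "ENRICHMENT_COLUMNS"]

ENRICHMENT_COLUMNS = [
    "set_name",
    "overlap_count",
    "set_size",
    "list_size",
    "background_size",
    "p_value",
    "q_value",
    "overlap_genes",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus their union universe (symbols uppercase)."""

    sets: Mapping[str, frozenset[str]]

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name <TAB> description <TAB> genes...``.

    Genes are uppercased; duplicates within a line are stored once.  A line
    with fewer than three fields is a parse error naming the line number.
    """
    sets: dict[str, frozenset[str]] = {}
    with Path(path).open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected name, description, genes..."
                )
            name = fields[0].strip()
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise ValueError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets[name] = genes
    return GeneSetCollection(sets=sets)


def enrich_targets(
    targets: Sequence[str] | Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``targets`` in each gene set.

    Returns one row per set, sorted by p-value (ties by name), with BH
    q-values computed across all sets in the collection.  Targets and sets
    are intersected with the background before testing; an empty effective
    target list is a usage error.
    """
    # a frozenset background is trusted as already-normalized symbols -- this
    # keeps repeated calls against a large fixed universe cheap
    if background is None:
        bg = collection.universe
    elif isinstance(background, frozenset):
        bg = background
    else:
        bg = frozenset(g.strip().upper() for g in background)
    target_set = frozenset(g.strip().upper() for g in targets) & bg
    if not target_set:
        raise ValueError("no query targets remain after intersecting with the background")
    n_bg = len(bg)
    n_list = len(target_set)
    rows = []
    for name in sorted(collection.sets):
        genes = collection.sets[name] & bg
        overlap = sorted(target_set & genes)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, n_bg, len(genes), n_list))
        rows.append(
            {
                "set_name": name,
                "overlap_count": k,
                "set_size": len(genes),
                "list_size": n_list,
                "background_size": n_bg,
                "p_value": min(p, 1.0),
                "overlap_genes": "|".join(overlap),
            }
        )
    frame = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "q_value"])
    frame["q_value"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    frame = frame.reindex(columns=ENRICHMENT_COLUMNS)
    return frame.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(
        drop=True
    )
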