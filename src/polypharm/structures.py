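"""Structure standardization, molecule registry, fingerprints, Tanimoto.

Molecules arriving from different source databases are spelled in many SMILES
dialects.  To consolidate evidence for one physical molecule, every structure
is standardized (sanitize + functional-group/charge normalization +
reionization, stereochemistry preserved, salt counterions kept) and
canonicalized; identical canonical structures are merged under one internal
ID with their aliases and source labels unioned.

Three fingerprint families are available for similarity work:

* ``circular``  -- radius-3 feature-class circular fingerprint (FCFP6-like),
  chirality-aware, folded to 1024 bits;
* ``maccs``     -- the 166 MACCS structural keys;
* ``extended``  -- path-based topological fingerprint with ring membership,
  folded to 1024 bits (the default for similarity search).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

from .ingest import SourceRecord

__all__ = [
    "StructureError",
    "Fingerprint",
    "MoleculeEntry",
    "MoleculeRegistry",
    "FINGERPRINT_METHODS",
    "DEFAULT_FINGERPRINT",
    "standardize_structure",
    "compute_fingerprint",
    "tanimoto",
    "register_molecules",
]

RDLogger.DisableLog("rdApp.*")  # RDKit is chatty on perfectly recoverable inputs

FINGERPRINT_METHODS = ("circular", "maccs", "extended")
DEFAULT_FINGERPRINT = "extended"

_FOLD_BITS = 1024
_MACCS_KEYS = 166

_ID_PREFIX = "MOL"
_ID_WIDTH = 6


class StructureError(ValueError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable structure: {smiles!r}")
        self.smiles = smiles


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(smiles)
    return mol


def standardize_structure(smiles: str) -> str:
    """Return the canonical standardized SMILES for ``smiles``.

    Identical structures in any atom order or Kekule spelling map to the same
    output; stereochemistry is preserved so enantiomers stay distinct; salt
    counterions are not stripped (distinct registered entities stay distinct).
    Idempotent on its own output.

    Raises :class:`StructureError` on unparseable input.
    """
    mol = _mol_from_smiles(smiles)
    mol = rdMolStandardize.Cleanup(mol)
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Fingerprint:
    """A molecular fingerprint as a set of on-bit positions."""

    method: str
    bits: frozenset[int]
    length: int

    def __post_init__(self):
        if self.bits and max(self.bits) >= self.length:
            raise ValueError("bit position exceeds fingerprint length")


_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(
    radius=3,
    fpSize=_FOLD_BITS,
    includeChirality=True,
    atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
)
_path_gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=_FOLD_BITS)


def compute_fingerprint(canonical_smiles: str, method: str = DEFAULT_FINGERPRINT) -> Fingerprint:
    """Fingerprint a (standardized) structure. Deterministic per (structure, method)."""
    if method not in FINGERPRINT_METHODS:
        raise ValueError(f"unknown fingerprint method {method!r}; choose from {FINGERPRINT_METHODS}")
    mol = _mol_from_smiles(canonical_smiles)
    if method == "circular":
        bits = frozenset(_morgan_gen.GetFingerprint(mol).GetOnBits())
        return Fingerprint("circular", bits, _FOLD_BITS)
    if method == "extended":
        bits = frozenset(_path_gen.GetFingerprint(mol).GetOnBits())
        return Fingerprint("extended", bits, _FOLD_BITS)
    # MACCS: RDKit bit 0 is unused padding; shift to the 166-key convention
    raw = MACCSkeys.GenMACCSKeys(mol)
    bits = frozenset(b - 1 for b in raw.GetOnBits())
    return Fingerprint("maccs", bits, _MACCS_KEYS)


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto similarity |A n B| / |A u B| between two same-method fingerprints.

    Symmetric, 1.0 for identical non-empty bit sets.  Two empty fingerprints
    are defined as similarity 0.0 with a warning (the ratio is 0/0).
    """
    if fp_a.method != fp_b.method:
        raise ValueError(f"fingerprint method mismatch: {fp_a.method} vs {fp_b.method}")
    union = len(fp_a.bits | fp_b.bits)
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints defined as 0.0", stacklevel=2)
        return 0.0
    return len(fp_a.bits & fp_b.bits) / union


@dataclass
class MoleculeEntry:
    internal_id: str
    canonical_smiles: str | None  # None for alias-only (structureless) molecules
    aliases: set[str] = field(default_factory=set)
    sources: set[str] = field(default_factory=set)


@dataclass
class MoleculeRegistry:
    """Standardized structures consolidated under deterministic internal IDs.

    ``structure_index`` is a bijection between canonical SMILES and the
    structured entries; molecules that arrived without a parseable structure
    are kept as alias-keyed entries (reachable by name and by target, absent
    from similarity search).
    """

    entries: dict[str, MoleculeEntry] = field(default_factory=dict)
    alias_index: dict[str, set[str]] = field(default_factory=dict)
    structure_index: dict[str, str] = field(default_factory=dict)
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (alias, bad smiles)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup_alias(self, name: str) -> set[str]:
        return set(self.alias_index.get(name.strip().lower(), set()))

    def lookup_structure(self, canonical_smiles: str) -> str | None:
        return self.structure_index.get(canonical_smiles)

    def internal_id_for_record(self, record: SourceRecord) -> str | None:
        """Resolve a record to its internal ID (structure first, then alias)."""
        if record.smiles:
            try:
                canonical = standardize_structure(record.smiles)
            except StructureError:
                return None
            return self.structure_index.get(canonical)
        ids = self.lookup_alias(record.molecule_alias)
        if len(ids) == 1:
            return next(iter(ids))
        # ambiguous alias: prefer the alias-keyed (structureless) entry it
        # would have been registered under, else the smallest ID
        for i in sorted(ids):
            if self.entries[i].canonical_smiles is None:
                return i
        return min(ids) if ids else None


def register_molecules(records: Iterable[SourceRecord]) -> MoleculeRegistry:
    """Consolidate records into a registry, one entry per distinct structure.

    A pure function of the multiset of input records: internal IDs are
    assigned by sorting structured entries by canonical SMILES, then
    structureless entries by primary alias, so permuting the input changes
    nothing.  Unparseable structures go to ``registry.skipped``.

    Structureless records whose alias unambiguously matches one structured
    molecule are merged into it; otherwise they form alias-keyed entries.
    """
    structured: dict[str, MoleculeEntry] = {}
    skipped: list[tuple[str, str]] = []
    alias_only: list[SourceRecord] = []
    for rec in records:
        if not rec.smiles:
            alias_only.append(rec)
            continue
        try:
            canonical = standardize_structure(rec.smiles)
        except StructureError:
            skipped.append((rec.molecule_alias, rec.smiles))
            continue
        entry = structured.setdefault(
            canonical, MoleculeEntry(internal_id="", canonical_smiles=canonical)
        )
        if rec.molecule_alias.strip():
            entry.aliases.add(rec.molecule_alias.strip())
        if rec.source:
            entry.sources.add(rec.source)

    # second pass: attach structureless records by alias where unambiguous
    alias_owners: dict[str, list[MoleculeEntry]] = {}
    for entry in structured.values():
        for alias in entry.aliases:
            alias_owners.setdefault(alias.lower(), []).append(entry)
    by_alias: dict[str, MoleculeEntry] = {}
    for rec in alias_only:
        key = rec.molecule_alias.strip().lower()
        if not key:
            skipped.append((rec.molecule_alias, ""))
            continue
        owners = alias_owners.get(key, [])
        if len(owners) == 1:
            entry = owners[0]
        else:
            entry = by_alias.setdefault(
                key, MoleculeEntry(internal_id="", canonical_smiles=None)
            )
        entry.aliases.add(rec.molecule_alias.strip())
        if rec.source:
            entry.sources.add(rec.source)

    registry = MoleculeRegistry(skipped=sorted(set(skipped)))
    ordered = [structured[s] for s in sorted(structured)] + [
        by_alias[a] for a in sorted(by_alias)
    ]
    for n, entry in enumerate(ordered, start=1):
        entry.internal_id = f"{_ID_PREFIX}{n:0{_ID_WIDTH}d}"
        registry.entries[entry.internal_id] = entry
        if entry.canonical_smiles is not None:
            registry.structure_index[entry.canonical_smiles] = entry.internal_id
        for alias in entry.aliases:
            registry.alias_index.setdefault(alias.lower(), set()).add(entry.internal_id)
    return registry
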