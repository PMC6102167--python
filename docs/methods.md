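# Methods

This note documents the models and procedures `polypharm` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter for
reproducibility.

## Evidence model

An evidence record is one row from one source: a molecule (alias plus,
usually, a SMILES string), a HUGO gene symbol, and either a numeric potency
(**quantitative**: IC50, XC50, EC50, AC50, C50, Ki, Kd, potency, or an
already-log-scaled pChEMBL) or nothing (**qualitative**: an expert-curated
link). Concentrations are normalized to nM on ingest (µM × 10³, M × 10⁹);
gene symbols are uppercased and stripped, with no symbol-mapping service
consulted. Validation removes rows that violate the record invariants
(missing numeric fields on quantitative rows, negative values, empty gene
symbols, numeric fields on qualitative rows) and tallies each failure class;
it never raises, so a malformed row cannot abort a database build, and it is
idempotent on its own output.

**Censored values.** Rows whose relation is not `=` (e.g. "> 10000 nM")
stay in the record stream and count toward a pair's evidence volume
`n_quantitative` (they are genuine observations of the interaction), but
they are excluded from every potency mean: including right-censored
potencies as point values would bias mean pChEMBL toward whatever
concentration ceiling each assay used.

## Structure standardization and the registry

Structures are standardized with RDKit's `rdMolStandardize.Cleanup`
(sanitization, functional-group and charge normalization, reionization) and
emitted as canonical isomeric SMILES. Stereochemistry is preserved —
enantiomers remain distinct molecules — and salt counterions are **not**
stripped, so a hydrochloride and its free base stay separate registered
entities, mirroring how the source databases register them. The function is
idempotent on its own output, which the test suite checks on every
registered structure.

Identical canonical structures are merged into one registry entry with the
union of their aliases and source labels. Internal IDs (`MOL000001`, …) are
assigned by sorting structured entries lexicographically by canonical
SMILES, then structureless entries by primary alias — registration is
therefore a pure function of the multiset of input records, invariant under
permutation. Records without a parseable structure are kept as alias-keyed
entries when their alias does not unambiguously match a structured
molecule: they are reachable by name and by target query but excluded from
similarity search. Resolving such molecules through external chemical-ID
services is deliberately out of scope; the alias table is the only
identifier source.

## Potency pooling

pChEMBL = −log₁₀(molar potency), computed as `9 − log₁₀(value_nM)` so the
canonical anchors (100 nM ↦ 7, 1 nM ↦ 9, 1 µM ↦ 6) are exact in floating
point. The per-pair `mean_pchembl` pools per-record pChEMBL values across
value types into a single arithmetic mean rather than averaging per-type
means: the value types are only semi-comparable, and pooling weights each
measurement equally instead of up-weighting rare assay types. Per-type
means in nM are kept alongside for users who want them. Repeated
measurements are not de-duplicated; each source row is one observation.

## Selectivity and confidence scores

**KSI.** For drug *d* with target set *T*,
`KSI_dt = pChEMBL_dt / Σ_{t∈T} pChEMBL_dt`, defined only for pairs with a
mean pChEMBL (qualitative-only pairs get none — there is no potency to
apportion, though they still appear in the table and the drug's network).
Per drug, defined KSIs sum to 1 within 1e−9; the suite asserts this on
every build.

**Confidence.** `c_ab = ((n_ab + l_ab) − μ_all)/σ_all` where the moments
are taken over all association rows of the database. σ_all is the
*population* standard deviation — that choice makes the score an exact
z-score (table mean 0, SD 1), which the tests assert to 1e−12. If every
pair has the same count the score is undefined and set to 0 with a warning.
Confidence is relative to the database it is computed on; scores from
databases built on different source sets are not comparable.

Group means and the moments are accumulated with plain ordered scalar
arithmetic (`sum/len` over records in input order, `math.log10`,
`math.sqrt`) rather than vectorized reductions. This is deliberate: the
fixtures module recomputes the whole table with an independent naive pass,
and ordered scalar arithmetic makes the two routes agree bit-for-bit, so
the end-to-end test can assert exact equality instead of a tolerance.

## Fingerprints and similarity

Three families, all deterministic per (structure, method):

| method   | construction                                             | length |
|----------|----------------------------------------------------------|--------|
| circular | radius-3 feature-class circular fp (FCFP6-like), chirality-aware | 1024 |
| maccs    | MACCS structural keys                                    | 166    |
| extended | path-based topological fp with ring membership           | 1024   |

Folding lengths of 1024 are common practice; they are not semantically
meaningful and are recorded with every fingerprint. The MACCS convention
here is the 166-key one (the toolkit's unused padding bit is dropped).
`extended` is the default everywhere similarity is computed, with the other
methods selectable per call.

Tanimoto similarity is |A∩B|/|A∪B| over on-bit sets; two empty
fingerprints are defined as similarity 0 with a warning. Similarity search
standardizes the query first (so a query identical to a database structure
always scores exactly 1.0), returns all molecules at or above the
threshold sorted by similarity with internal-ID tie-breaks, and accepts
query molecules absent from the database. The CLI default threshold is 0.8
— strict enough to mean "close analog", and meant to be swept downward
interactively. Correctness is established by brute-force all-pairs oracle
scans in the tests, so the choice of fingerprint backend does not silently
change semantics.

## Target queries, networks

Multi-target queries intersect (`all`, the default — "one molecule covering
this target set") or union (`any`) the per-gene molecule sets; unknown
genes warn and contribute the empty set rather than erroring, so one typo
does not void a query. Networks are bipartite molecule/target graphs with
one edge per association row, carrying the evidence counts and (when
defined) mean pChEMBL; they export to GraphML and JSON node-link and
round-trip through both.

## Enrichment

Over-representation of a target list in GMT gene sets uses the one-sided
hypergeometric upper tail: p = P(X ≥ k) with background N, set size K, list
size n — Fisher's exact test for enrichment; depletion is not tested.
Benjamini–Hochberg q-values are computed across the sets of one collection;
raw p-values are reported alongside. The default background is the
collection's own universe (the union of its sets), overridable with an
explicit gene list; a `frozenset` background is used as-is, which keeps
repeated calls against one large universe cheap. No gene-set releases are
bundled — results depend on the GMT the user supplies.

p-value correctness is checked against exhaustive combinatorial enumeration
(`math.comb` sums) to 1e−12 on small backgrounds. The null-calibration test
draws 1000 random target lists and requires the p-values to pass a
Kolmogorov–Smirnov uniformity check at α = 0.01; because discrete
hypergeometric p-values are exactly calibrated only *at their support
points* (and slightly conservative between them), that simulation uses a
large universe (50,000 symbols, sets of 20–30k, lists of 10–20k, varied per
draw) so the support is fine enough for the KS comparison to be meaningful.
A companion test proves the exact-calibration-at-support property directly
by enumeration on a small universe.

## Screening-set correlation

Given an AUC matrix (drugs × cell lines, missing cells allowed) and a query
structure, the reference is the screened drug with maximal Tanimoto
similarity to the query (label-order tie-break; the query itself need not
have been screened). Every other drug's AUC profile is Spearman-correlated
with the reference over pairwise-complete cell lines — average ranks for
ties, two-sided p via the t-approximation — and rows with fewer than 3
shared cell lines are left undefined rather than reporting a meaningless
±1. Each correlation is paired with that drug's similarity **to the
original query**, not to the reference, so the output is directly the
similarity-vs-activity scatter. The reference's self-row is excluded.
Whether to filter cell lines globally or use all pairwise-complete pairs
was an open design choice; pairwise-complete keeps the most data and is
what the missing-value invariance test pins down.

## The synthetic-data generator

`fixtures` writes evidence tables, GMT collections, and response matrices
in exactly the dialects the readers parse, with ground truth computed by a
second, naive implementation (csv module, dict-of-lists accumulation,
`Chem.CanonSmiles` grouping, textbook mean/SD) that shares no code with the
pipeline — oracle separation. Defaults: 12 molecules over 8 targets, 40
quantitative records with potencies log-uniform on 1 nM–10 µM (the range
where assay results are typically reported), 15 qualitative records, 25%
alias/spelling duplicates, 2 censored rows, one alias-only molecule.
Molecule structures come from an embedded, vetted list of drug-like SMILES
for which standardization reduces to plain canonicalization (asserted in
the tests) — that is what lets the ground-truth pass group structures
independently yet identically. The RNG (numpy PCG64) and seed are recorded
in a sidecar file; identical spec + seed reproduces byte-identical outputs.

The response fixture embeds one drug carrying the query structure itself
(so reference selection must return it at similarity 1.0) and, optionally,
a close homolog of the query whose AUC vector is the reference signal plus
Gaussian noise (σ = 0.1 by default) — rank-correlated by construction,
exactly rank-identical at zero noise — among structurally unrelated decoys
with independent responses.

**What the fixtures do not emulate:** the potency distribution, target
promiscuity structure, and alias chaos of real ChEMBL/DrugBank releases;
assay-level heterogeneity within a value type; correlated missingness in
screening data. Passing tests therefore demonstrate that the machinery is
correct on data with known structure, not that any particular biological
conclusion transfers to a given public release.

## Problem sizes and limitations

Tests and the acceptance script run on fixture-scale inputs (tens of
molecules, ≤ ~60 evidence rows, 9-drug × 12-cell-line screens), where
brute-force oracles are exact and fast; the library itself is linear in
records and in database size per similarity query. Known limitations: no
chemical-ID resolution for structureless molecules; no source reliability
weighting; confidence and KSI are descriptive summaries of *known* evidence
(a high KSI can reflect under-studied off-targets, not true selectivity);
similarity search is a full scan, adequate for fixture- to moderate-scale
databases but not indexed for very large ones.
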