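# polypharm

Harmonize multi-source drug–target evidence into a scored association
database, and query it by structure, by target, and against cell-line
drug-response screens.

## The problem

High-throughput phenotypic screens identify bioactive molecules faster than
anyone can explain them: most small molecules are polypharmacologic, hitting
several human proteins with a range of potencies, and the evidence for those
interactions is scattered across heterogeneous resources — quantitative
activity tables (IC50/XC50/EC50/AC50/C50/Ki/Kd/potency values in assorted
units, ChEMBL-style) and curated qualitative annotations with no number
attached (DrugBank/DGIdb/ChemicalProbes-style). `polypharm` is for
biologists and chemists doing target hypothesis generation and off-target
triage: it merges such tables into one scored molecule–target database and
answers the practical questions — *what does this molecule hit, what else
looks like it, which single compound covers all of these targets, and does
anything structurally similar behave the same way in a drug screen?*

## The model

**Harmonization.** SMILES structures are standardized (sanitize + normalize
+ canonicalize, stereochemistry preserved, counterions kept) and identical
structures from any source are merged under one internal ID with all their
aliases. Potencies are converted to the common log scale

> pChEMBL = −log₁₀(potency in molar), e.g. 100 nM ↦ 7,

and pooled into a mean pChEMBL per molecule–target pair, alongside exact
counts of quantitative (n) and qualitative (l) evidence records. Censored
measurements (relation `>`, `<`, …) are counted as evidence but excluded
from the means.

**Known selectivity index.** For drug *d* and target *t* with mean potency
pChEMBL_dt over the drug's target set *T*:

> KSI_dt = pChEMBL_dt / Σ_{t∈T} pChEMBL_dt

KSI values of one drug sum to 1; a KSI near 1 flags a known-single-target
compound, while many small KSIs flag known polypharmacology.

**Confidence score.** Evidence volume is standardized over the whole
database:

> c_ab = ((n_ab + l_ab) − μ_all) / σ_all

a z-score (population SD) of the pair's total record count; larger means
more independently reported support.

**Queries.** Molecules are found by alias, or by Tanimoto similarity
|A∩B|/|A∪B| over circular (FCFP6-like, chirality-aware), MACCS (166-key),
or path-based "extended" fingerprints (the default) — the query molecule
need not be in the database. Target queries return molecules hitting *all*
(or any) of a gene list; results export as bipartite drug–target networks
(GraphML / JSON node-link). Target lists feed a local hypergeometric
over-representation test against GMT gene-set collections with
Benjamini–Hochberg q-values. Finally, given a drug×cell-line AUC matrix,
the package finds the screened drug most similar to a query, Spearman-
correlates its response profile against every other drug
(pairwise-complete), and reports each drug's correlation next to its
similarity to the query.

## Worked example

The selectivity index on a published worked example — a selective PAK1 tool
compound with eight quantified targets and one qualitative-only target:

```python
from polypharm import SourceRecord, register_molecules
from polypharm.summarize import summarize_associations, known_selectivity_index

means = {"PAK1": 7.79, "PAK2": 7.69, "LCK": 7.28, "MAP4K5": 8.0,
         "SIK2": 8.05, "STK24": 7.37, "STK25": 7.47, "STK26": 7.7}
records = [SourceRecord("query-compound", "CCO", g, "quantitative",
                        value_type="pChEMBL", value=v, unit="pchembl_unitless")
           for g, v in means.items()]
records.append(SourceRecord("query-compound", "CCO", "PAK3", "qualitative"))
rows = known_selectivity_index(
    summarize_associations(records, register_molecules(records)))
print(rows[["gene_symbol", "mean_pchembl", "ksi"]].round(3).to_string(index=False))
```

```
gene_symbol  mean_pchembl   ksi
        LCK          7.28 0.119
     MAP4K5          8.00 0.130
       PAK1          7.79 0.127
       PAK2          7.69 0.125
       PAK3           NaN   NaN
       SIK2          8.05 0.131
      STK24          7.37 0.120
      STK25          7.47 0.122
      STK26          7.70 0.126
```

PAK1's KSI of 0.127 says the compound's known potency is spread nearly
evenly over eight kinases — it is *not* PAK1-selective on the current
evidence — and the qualitative-only PAK3 row correctly gets no KSI (there
is no potency to apportion).

A full pipeline run from the shell, on generated example tables:

```bash
polypharm fixtures --out fx --seed 1
polypharm build-db --quantitative fx/quantitative.tsv:chembl-like \
                   --qualitative fx/qualitative.tsv:curated-like --out fx/db
# -> database: 13 molecules, 8 targets, 49 associations -> fx/db
polypharm similar --db fx/db --smiles 'CC(=O)Nc1ccc(O)cc1' --threshold 0.5
polypharm response-corr --smiles 'CCOC(=O)c1ccc(N)cc1' \
                        --auc fx/auc.csv --structures fx/structures.tsv
```

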