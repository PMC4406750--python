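# megpipe

Multi-evidence gene prioritization for rheumatoid arthritis (RA) omics:
integrate promoter differential methylation, differential expression and
GWAS-reported genes into a per-gene evidence ledger, test the significance
of the three-way overlap with a resampling null, and run hypergeometric
pathway enrichment on the multi-evidence gene (MEG) set.

Genome-wide assays each nominate hundreds to thousands of candidate genes;
the genes most likely to matter are those flagged independently by several
assays.  This package implements that integration for the classic
three-stream design — methylation bead arrays, expression microarrays and a
GWAS catalog, profiled in RA vs osteoarthritis (OA) vs normal (NL)
fibroblast-like synoviocytes — as a tested, reusable library with a thin
CLI, plus a synthetic-data generator that emulates the full study design so
every stage runs and is validated without any download.

## The method

**Differentially methylated genes (DMGs).**  Per methylation locus and group
comparison, Welch's unequal-variance *t*-test on beta values; Benjamini–
Hochberg *q*-values across all loci of the comparison.  A locus is a DML if
*q* < 0.05 and the group mean difference |Δβ| > 0.1.  A gene is a DMG if at
least one DML lies in a promoter window, defined strand-aware as −2500 bp to
+500 bp around any of the gene's TSSs (0-based, half-open).  RA-vs-OA and
RA-vs-NL calls are combined by union.

**Differentially expressed genes (DEGs).**  Per probe, Welch's *t*-test
(on log2 intensities) with linear-scale fold change max(m₁/m₂, m₂/m₁).  A
probe passes at fold > 2 and *uncorrected* p < 0.05; probes of a gene are
never averaged, and one passing probe makes the gene a DEG (any-probe rule).
Comparisons are combined as for methylation.

**GWAS genes.**  Reported genes of catalog rows whose trait matches
"rheumatoid arthritis" (case-insensitive substring), unioned with a
supplementary meta-analysis gene list.

**Overlap significance.**  The evidence sets are overlapped into a Venn/
ledger structure.  The observed three-way intersection is tested against a
permutation null: each round redraws, independently per assay and without
replacement, |DMG|, |DEG| and |GWAS| genes from that assay's
*identifiable* background (genes with promoter loci on the array; genes
with probes; genes reported anywhere in the catalog) and records the triple
intersection size; p = (#{null ≥ observed} + 1)/(n + 1) over 10,000 rounds.

**Pathway enrichment.**  For MEGs (≥ 2 evidence streams) and each pathway:
k of the m query genes among the K pathway genes in an N-gene background;
upper-tail hypergeometric p = P(X ≥ k), X ~ Hypergeom(N, K, m); fold
enrichment (k/m)/(K/N); BH q across the collection; q < 0.05 reported.

## Worked example

```python
from megpipe import PipelineConfig, SimulationConfig, run_all

report = run_all(PipelineConfig(
    outdir="scratch/example_run", simulate=True,
    sim=SimulationConfig(seed=2014, dmg_delta_beta=0.4, deg_fold=5.0),
    n_permutations=2_000, perm_seed=1))
```

prints (via `examples/05_full_pipeline.py`):

```
DMGs 2379 | DEGs 2947 | GWAS 114 | MEGs 367
triple-evidence genes: AIRE, CASP8, CSF2, ELMO1, ETS1, HLA-DQA1, LBH
permutation p = 0.00049975 (null mean 0.584)
backgrounds: {'methylation': 17014, 'expression': 16054, 'gwas': 10000}
```

The synthetic bundle plants 2,375 DMGs, 2,947 DEGs and 114 GWAS genes with
a seven-gene triple-evidence core; the pipeline recovers the planted triple
exactly (the extra 4 DMGs / 1 MEG are false positives from the noisier
6-sample NL comparison), and the permutation null (mean overlap ≈ 0.6)
never approaches the observed 7, so p sits near the estimator floor.

The `examples/` scripts walk through each capability one at a time:
simulation, evidence calling, integration + permutation, enrichment, and
the full run.  The same stages are available from the shell via the
`megpipe` command (`simulate`, `dmg`, `deg`, `gwas`, `integrate`,
`permute`, `enrich`, `run-all`, `report`).

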