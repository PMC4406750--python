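# Methods

This note records the statistical model, the synthetic-data design, the
numerical conventions and the open design choices behind megpipe.

## Evidence calling

**Methylation.**  Input is a loci × samples matrix of beta values in [0, 1]
with group labels (RA / OA / NL), a BED-like locus coordinate manifest and a
TSS table.  Per comparison, every locus gets a two-sided Welch *t*-test
(unequal variances are expected between disease groups); q-values are BH
step-up computed *within* each comparison, since each comparison is a
separate family of tests.  DML rule: q < 0.05 and |Δβ| > 0.1, both strict.
Loci with missing values in the compared samples are skipped and counted in
the log.  DML → DMG mapping uses promoter windows of −2500/+500 bp around
each TSS *in transcription direction* (minus-strand windows are mirrored),
0-based half-open, with membership decided by the locus start coordinate.
Multi-TSS genes get one window per TSS.  The comparisons run are RA-vs-OA
and RA-vs-NL, combined by union — the minimal RA-centric reading of a
combined disease signature; OA-vs-NL can be computed but is excluded from
the combined set by default.

**Expression.**  Input is a probes × samples intensity matrix (linear scale
unless flagged log2) and a probe → gene map.  The t-test runs on log2
values (variance stabilization; configurable to raw scale); fold change is
the symmetric ratio of *linear* group means.  DEG-probe rule: fold > 2 and
uncorrected p < 0.05, both strict.  No multiple-testing correction is
applied at this stage by design: intra-sample variation in these arrays is
large and the fold filter provides the main specificity.  Probes are never
averaged within a gene (different probes can interrogate different exons /
transcript variants); one passing probe calls the gene.  This any-probe rule
deliberately trades per-gene type-I inflation (documented by the null
simulation test) for sensitivity to isoform-specific changes.

**GWAS.**  The catalog reader accepts the TSV dialect with columns
DISEASE/TRAIT, SNPS, P-VALUE, REPORTED GENE(S); gene cells split on comma or
semicolon, and placeholder tokens (NR, intergenic, "-", empty) yield no
genes.  Trait selection is case-insensitive substring matching (default
"rheumatoid arthritis"; exact mode available).  A supplementary
one-symbol-per-line list (meta-analysis hits) is unioned in.  All symbols
everywhere are trimmed and uppercased at ingest — the single harmonization
step; no alias resolution is attempted.

## Overlap permutation null

The three evidence sets are tested jointly: could a seven-gene triple
intersection arise from independent assays?  Each assay has an
*identifiable* background — what it could in principle have flagged: genes
with ≥ 1 measured locus inside ≥ 1 promoter window; genes with ≥ 1 mapped
probe; genes reported anywhere in the catalog regardless of trait (the
supplementary list is not part of this background, since identifiability is
defined by the catalog).  Each of n rounds draws, without replacement and
independently across assays, the observed evidence-set size from each
background and records the triple intersection.  The estimator
p = (b + 1)/(n + 1) is never zero; its floor at n = 10,000 is ≈ 1e-4.
Draws are independent across assays — no coupling between what one assay
"selects" and another.

A calibration note: the size of the *joint* background (genes identifiable
by all three assays) controls the null mean.  Methylation and expression
arrays cover nearly the whole gene universe, but GWAS-catalog reported
symbols are a heterogeneous mixture across platforms, diseases and symbol
dialects, and only a minority resolve to array-annotated genes.  The
synthetic catalog therefore reports 10,000 distinct symbols of which 2,000
are universe genes, putting the expected null triple overlap near 0.5 —
the regime in which an observed overlap of 7 lies beyond the null's support
at 10,000 rounds, which is what the original analysis reports.  If the
joint background were instead nearly the whole universe, the null mean
would rise to ≈ 2.6 and the observed overlap would no longer be extreme;
the catalog/array overlap is thus a real, documented assumption, not a
nuisance detail.

## Pathway enrichment

Hypergeometric upper tail P(X ≥ k) with X ~ Hypergeom(N, K, m), fold
enrichment (k/m)/(K/N), BH q over all pathways with K ≥ 1, and strict
q < 0.05 reporting.  By default pathway membership is restricted to the
background before counting (K = |pathway ∩ background|); raw pathway sizes
are selectable since published K values cannot disambiguate the two
conventions.  The background N is a configurable gene-universe list; the
default is the annotation universe (all genes in the TSS table).  The
17,450-gene default universe is the value implied by inverting the fold
formula on published pathway rows — one background size reproduces all of
them to two decimals, which is also the package's cross-consistency test.
Printed q-values are not reproduced: q depends on the full pathway
collection tested, which is not part of the inputs.

## Statistical primitives and numerics

Welch's t is computed directly (means, unbiased variances,
Welch–Satterthwaite df) with the tail from `scipy.stats.t`; the vectorized
matrix version is exactly the scalar computation row-wise.  Degenerate
zero-variance pairs follow a fixed contract instead of NaN: equal means →
t = 0, p = 1; unequal means → t = ±inf, p = 0, flagged.  BH q-values come
from `statsmodels` (method configurable) behind `bh_adjust`; the
hypergeometric tail from `scipy.stats.hypergeom.sf`.  Tests check all three
against independent routes (a reference t implementation, a hand-rolled
step-up, exact `math.comb` enumeration).  Enrichment rows are sorted by
(q, p, name) with a stable sort; ties are therefore deterministic.  All
randomness flows through `numpy.random.default_rng` with per-stage spawned
substreams, so each simulator is reproducible in isolation and the whole
bundle is byte-identical across reruns of the same seed.

## Synthetic study design

The generator's defaults are the target study's conditions: 11 RA / 11 OA /
6 NL methylation arrays; 9 RA / 11 OA / 11 NL expression arrays; a
17,450-gene universe on 22 chromosomes (200 kb gene spacing); 1–4 TSSs per
gene; 1–6 promoter loci per gene plus distal loci (and ~2.5% of genes with
no promoter locus, ~8% with no probe, so the assay backgrounds are proper
subsets of the universe); 1–3 probes per gene plus unmapped control probes.
Planted effects: 2,375 DMG genes shifted by Δβ = 0.25 in RA at their
promoter loci; 2,947 DEG genes with a 3.0-fold RA change (about half of the
multi-probe ones on a single probe only, to exercise the any-probe rule);
114 GWAS trait genes (10 of them supplement-only).  The planted pairwise
overlaps (259 DMG∩DEG, 50 DMG∩GWAS, 50 DEG∩GWAS beyond the seven
triple-evidence genes) make exactly 366 planted multi-evidence genes.  One
pathway of 89 genes contains 7 planted MEGs (≈ 3.75-fold at these sizes);
24 decoy pathways of 30–300 genes are uniform draws.

Noise models are explicit stand-ins — the platforms' true error structure
is not modeled.  Beta values are logit-normal around the per-locus baseline
with an SD of 0.05 on the beta scale, clipped to [0.01, 0.99] to avoid
boundary artifacts; intensities are log-normal with CV 0.2 around per-probe
baselines spanning 2^6–2^12.  At these settings the planted effects are
far above the calling thresholds (≈ 12σ), so the ≥ 95% recovery tests probe
the pipeline's bookkeeping, not marginal statistical power.  Passing them
says the machinery is correct under a favorable, idealized noise model; it
does not certify performance on real arrays with batch effects, cell-type
composition drift, probe cross-hybridization or symbol-annotation mismatch,
none of which are simulated.

## Problem sizes in the test suite

Structural tests run on an 800-gene bundle with strong effects (Δβ = 0.4,
5-fold); power/recovery and end-to-end checks use the full default
configuration (≈ 68k loci, ≈ 32k probes).  The permutation-vs-enumeration
check uses an 8-gene universe (exhaustive enumeration) at 50,000 rounds;
the study-scale permutation uses 10,000 rounds.  The whole suite runs in
well under a minute on one CPU.

## Known limitations

* Gene symbols are matched by normalized string equality; real
  cross-platform integration needs alias/ID mapping.
* The DML unit is a single locus; no region-level (DMR) smoothing.
* The permutation null is uniform over backgrounds — no matching on CpG
  density, gene length or expression level.
* Raw-array preprocessing (normalization, background correction, batch
  removal) is out of scope; matrices are assumed preprocessed.
* Which pairwise comparison directions the combined evidence sets should
  include is a design choice (RA-centric here); published summary counts
  alone cannot settle it.
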