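"""Synthetic multi-omics bundle generator.

Generates every input the pipeline consumes — methylation beta matrix with a
locus manifest and TSS table, expression intensity matrix with a probe map,
a GWAS-catalog-dialect table plus supplementary gene list, and a GMT pathway
collection — with the statistical structure the analysis assumes, plus a
truth ledger recording what was planted.

The default configuration mirrors the study design this pipeline targets:
11 RA / 11 OA / 6 NL methylation arrays, 9 RA / 11 OA / 11 NL expression
arrays, a 17,450-gene universe, 2,375 planted promoter-hypermethylation
genes (Δβ = 0.25 in RA vs both OA and NL), 2,947 planted expression changes
(3-fold), 114 disease GWAS genes, and a seven-gene triple-evidence core that
is a subset of all three.  The planted two/three-evidence structure yields
exactly 366 multi-evidence genes.  Beta noise is logit-normal (values
clipped to [0.01, 0.99]); intensities are log-normal with a configurable
coefficient of variation.  Everything is reproducible bit-for-bit from the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as mio

__all__ = [
    "TRIPLE_EVIDENCE_GENES",
    "SimulationConfig",
    "GenePlan",
    "SyntheticBundle",
    "plan_genes",
    "simulate_methylation",
    "simulate_expression",
    "simulate_gwas_catalog",
    "simulate_pathways",
    "simulate_bundle",
    "write_bundle",
]

#: the seven genes planted with all three lines of evidence by default
TRIPLE_EVIDENCE_GENES = ("AIRE", "CASP8", "CSF2", "ELMO1", "ETS1", "HLA-DQA1", "LBH")

_DECOY_TRAITS = (
    "Type 2 diabetes", "Height", "Crohn's disease", "Body mass index",
    "Schizophrenia", "Coronary artery disease", "Ulcerative colitis",
    "Systemic lupus erythematosus", "Multiple sclerosis", "Asthma",
    "Breast cancer", "Prostate cancer", "Bipolar disorder",
    "Blood pressure", "LDL cholesterol",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic bundle.

    Defaults are the target study's conditions; the planted evidence-set
    sizes and their pairwise overlaps are chosen so the planted
    multi-evidence count is 7 + n_dmg_deg + n_dmg_gwas + n_deg_gwas = 366.
    """

    seed: int = 2014
    n_genes: int = 17_450
    groups_meth: tuple = (("RA", 11), ("OA", 11), ("NL", 6))
    groups_expr: tuple = (("RA", 9), ("OA", 11), ("NL", 11))
    loci_per_promoter: tuple = (1, 6)
    probes_per_gene: tuple = (1, 3)
    tss_per_gene: tuple = (1, 4)
    dmg_delta_beta: float = 0.25     # planted RA-vs-rest beta shift
    deg_fold: float = 3.0            # planted RA-vs-rest linear fold change
    n_planted_dmg: int = 2_375
    n_planted_deg: int = 2_947
    gwas_trait_genes: int = 114
    n_dmg_deg: int = 259             # planted DMG∩DEG (beyond the triple)
    n_dmg_gwas: int = 50             # planted DMG∩GWAS (beyond the triple)
    n_deg_gwas: int = 50             # planted DEG∩GWAS (beyond the triple)
    n_supplement_only: int = 10      # trait genes only in the supplementary list
    planted_triple: tuple = TRIPLE_EVIDENCE_GENES
    catalog_reported_total: int = 10_000  # distinct symbols reported in the catalog
    catalog_core_genes: int = 2_000       # of which this many are array-universe genes
    promoterless_fraction: float = 0.025  # genes with no measured promoter locus
    unprobed_fraction: float = 0.08       # genes with no expression probe
    distal_locus_fraction: float = 0.5    # genes with an extra far-from-TSS locus
    beta_noise_sd: float = 0.05           # per-locus noise, beta scale
    expr_cv: float = 0.2                  # multiplicative intensity noise
    n_pathways: int = 25
    pathway_size_range: tuple = (30, 300)
    planted_pathway_size: int = 89
    planted_pathway_megs: int = 7
    single_probe_fraction: float = 0.5    # planted DEGs carrying the fold on 1 probe only
    n_unmapped_probes: int = 20

    def __post_init__(self) -> None:
        for label, groups in (("methylation", self.groups_meth),
                              ("expression", self.groups_expr)):
            for name, count in groups:
                if count < 2:
                    raise ValueError(f"{label} group {name} needs >=2 samples")
        if self.dmg_delta_beta < 0 or self.deg_fold < 1:
            raise ValueError("effect sizes must be nonnegative (Δβ >= 0, fold >= 1)")
        n_t = len(self.planted_triple)
        if self.n_planted_dmg < n_t + self.n_dmg_deg + self.n_dmg_gwas:
            raise ValueError("n_planted_dmg too small for the requested overlaps")
        if self.n_planted_deg < n_t + self.n_dmg_deg + self.n_deg_gwas:
            raise ValueError("n_planted_deg too small for the requested overlaps")
        if self.gwas_trait_genes < n_t + self.n_dmg_gwas + self.n_deg_gwas:
            raise ValueError("gwas_trait_genes too small for the requested overlaps")
        if self.n_supplement_only > self.gwas_trait_genes - n_t:
            raise ValueError("n_supplement_only exceeds non-triple trait genes")
        if self.catalog_core_genes < self.gwas_trait_genes:
            raise ValueError("catalog_core_genes must cover the trait genes")
        if self.catalog_reported_total < self.catalog_core_genes:
            raise ValueError("catalog_reported_total must cover the core genes")

    @property
    def planted_meg(self) -> int:
        return (len(self.planted_triple) + self.n_dmg_deg
                + self.n_dmg_gwas + self.n_deg_gwas)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Independent deterministic substream per simulator stage."""
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                        spawn_key=(stream,)))


def _sample_names(groups: tuple) -> list[str]:
    return [f"{name}_{i + 1:02d}" for name, count in groups for i in range(count)]


@dataclass(frozen=True)
class GenePlan:
    """Deterministic allocation of the gene universe to planted roles."""

    genes: tuple
    planted_dmg: frozenset
    planted_deg: frozenset
    gwas_genes: frozenset
    supplement_only: frozenset
    catalog_core: tuple
    decoy_symbols: tuple
    promoterless: frozenset
    unprobed: frozenset
    planted_triple: tuple


def plan_genes(config: SimulationConfig) -> GenePlan:
    """Assign every gene its planted role(s), reproducibly from the seed."""
    rng = _rng(config, 0)
    triple = tuple(mio.normalize_symbol(g) for g in config.planted_triple)
    n_named = len(triple)
    genes = list(triple) + [f"GENE{i:05d}" for i in range(1, config.n_genes - n_named + 1)]
    perm = list(rng.permutation(genes[n_named:]))
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        if cursor + n > len(perm):
            raise ValueError("gene universe too small for the requested planted sets")
        out = perm[cursor:cursor + n]
        cursor += n
        return out

    dmg_deg = take(config.n_dmg_deg)
    dmg_gwas = take(config.n_dmg_gwas)
    deg_gwas = take(config.n_deg_gwas)
    gwas_only = take(config.gwas_trait_genes - n_named
                     - config.n_dmg_gwas - config.n_deg_gwas)
    dmg_only = take(config.n_planted_dmg - n_named - config.n_dmg_deg - config.n_dmg_gwas)
    deg_only = take(config.n_planted_deg - n_named - config.n_dmg_deg - config.n_deg_gwas)

    planted_dmg = frozenset(triple) | frozenset(dmg_deg) | frozenset(dmg_gwas) | frozenset(dmg_only)
    planted_deg = frozenset(triple) | frozenset(dmg_deg) | frozenset(deg_gwas) | frozenset(deg_only)
    gwas_genes = frozenset(triple) | frozenset(dmg_gwas) | frozenset(deg_gwas) | frozenset(gwas_only)

    # supplement-only genes never appear in catalog rows (the triple always does)
    non_triple_gwas = dmg_gwas + deg_gwas + gwas_only
    supplement_only = frozenset(non_triple_gwas[-config.n_supplement_only:]
                                if config.n_supplement_only else [])

    n_promoterless = round(config.promoterless_fraction * config.n_genes)
    n_unprobed = round(config.unprobed_fraction * config.n_genes)
    promoterless = frozenset(take(n_promoterless))
    unprobed = frozenset(take(n_unprobed))

    in_catalog_gwas = [g for g in (list(triple) + non_triple_gwas) if g not in supplement_only]
    n_filler = config.catalog_core_genes - len(in_catalog_gwas)
    catalog_core = tuple(in_catalog_gwas + take(n_filler))
    n_decoys = config.catalog_reported_total - config.catalog_core_genes
    decoys = tuple(f"LOC{100000 + i}" for i in range(n_decoys))

    return GenePlan(tuple(genes), planted_dmg, planted_deg, gwas_genes,
                    supplement_only, catalog_core, decoys, promoterless,
                    unprobed, triple)


def _gene_coords(plan: GenePlan):
    """Chromosome, base coordinate per gene: 22 chromosomes, 200 kb spacing."""
    idx = np.arange(len(plan.genes))
    chroms = np.array([f"chr{1 + i % 22}" for i in idx], dtype=object)
    bases = 1_000_000 + (idx // 22) * 200_000
    return chroms, bases


def simulate_methylation(config: SimulationConfig):
    """Beta matrix, locus manifest and TSS table.

    Every gene gets 1–4 TSSs; genes outside the 'promoterless' slice get 1–6
    promoter loci placed inside one of their windows, and about half of all
    genes additionally get a distal locus 100 kb downstream of the gene start
    (outside every window).  Planted genes have all their promoter loci
    shifted by Δβ in the RA group only.
    """
    plan = plan_genes(config)
    rng = _rng(config, 1)
    genes = np.array(plan.genes, dtype=object)
    n = len(genes)
    chroms, bases = _gene_coords(plan)
    strands = rng.choice(np.array(["+", "-"], dtype=object), size=n)

    # TSS table: first TSS at the gene base, extras within 30 kb
    t_lo, t_hi = config.tss_per_gene
    n_tss = rng.integers(t_lo, t_hi + 1, size=n)
    gene_rep = np.repeat(np.arange(n), n_tss)
    offsets = rng.integers(2_000, 30_000, size=gene_rep.size)
    first = np.r_[0, np.cumsum(n_tss)[:-1]]
    is_first = np.zeros(gene_rep.size, dtype=bool)
    is_first[first] = True
    offsets[is_first] = 0
    tss_pos = bases[gene_rep] + offsets
    variant = np.concatenate([np.arange(1, k + 1) for k in n_tss])
    tss = pd.DataFrame({
        "gene": genes[gene_rep],
        "chrom": chroms[gene_rep],
        "strand": strands[gene_rep],
        "tss_position": tss_pos,
        "transcript_label": [f"v{v}" for v in variant],
    })

    # promoter loci: d is the offset in transcription direction, chosen so the
    # genomic start lands strictly inside the half-open window on both strands
    has_prom = np.array([g not in plan.promoterless for g in genes])
    l_lo, l_hi = config.loci_per_promoter
    n_loc = np.where(has_prom, rng.integers(l_lo, l_hi + 1, size=n), 0)
    loc_gene = np.repeat(np.arange(n), n_loc)
    tss_choice = first[loc_gene] + (rng.random(loc_gene.size) * n_tss[loc_gene]).astype(int)
    d = rng.integers(-2_499, 500, size=loc_gene.size)
    plus = strands[loc_gene] == "+"
    loc_pos = np.where(plus, tss_pos[tss_choice] + d, tss_pos[tss_choice] - d)

    # distal loci 100 kb from the gene base: on the array but in no window
    distal_mask = rng.random(n) < config.distal_locus_fraction
    distal_mask |= ~has_prom  # promoterless genes still appear on the array
    distal_gene = np.where(distal_mask)[0]
    distal_pos = bases[distal_gene] + 100_000

    all_gene = np.concatenate([loc_gene, distal_gene])
    all_pos = np.concatenate([loc_pos, distal_pos])
    is_promoter = np.r_[np.ones(loc_gene.size, bool), np.zeros(distal_gene.size, bool)]
    locus_ids = np.array([f"cg{i:08d}" for i in range(1, all_pos.size + 1)], dtype=object)
    manifest = pd.DataFrame({
        "chrom": chroms[all_gene],
        "start": all_pos,
        "end": all_pos + 2,
        "locus_id": locus_ids,
    })

    # beta values: logit-normal noise around a per-locus baseline; planted
    # promoter loci get +Δβ in RA only (baselines kept low enough to stay
    # inside (0, 1) after a shift of up to 0.4)
    samples = _sample_names(config.groups_meth)
    is_ra = np.array([s.startswith("RA_") for s in samples])
    planted_locus = is_promoter & np.isin(genes[all_gene], sorted(plan.planted_dmg))
    baseline = np.where(planted_locus,
                        rng.uniform(0.15, 0.55, size=all_pos.size),
                        rng.uniform(0.10, 0.90, size=all_pos.size))
    target = baseline[:, None] + config.dmg_delta_beta * (
        planted_locus[:, None] & is_ra[None, :])
    sigma = config.beta_noise_sd / (target * (1.0 - target))
    noise = rng.standard_normal((all_pos.size, len(samples)))
    beta = expit(logit(target) + sigma * noise).clip(0.01, 0.99)
    beta = pd.DataFrame(beta, index=pd.Index(locus_ids, name="locus_id"), columns=samples)
    return beta, manifest, tss


def simulate_expression(config: SimulationConfig):
    """Intensity matrix and probe map.

    Gene baselines span ~2^6–2^12 with log-normal multiplicative noise at the
    configured CV.  Planted genes carry the fold change in RA on all probes,
    except that about half of the multi-probe planted genes carry it on a
    single probe only (exercising the any-probe calling rule downstream).
    A few control probes have no gene mapping.
    """
    plan = plan_genes(config)
    rng = _rng(config, 2)
    genes = [g for g in plan.genes if g not in plan.unprobed]
    p_lo, p_hi = config.probes_per_gene
    n_probes = rng.integers(p_lo, p_hi + 1, size=len(genes))
    gene_rep = np.repeat(np.arange(len(genes)), n_probes)
    first = np.r_[0, np.cumsum(n_probes)[:-1]]

    base_log2 = rng.uniform(6.0, 12.0, size=len(genes))
    probe_log2 = base_log2[gene_rep] + rng.normal(0.0, 0.5, size=gene_rep.size)

    planted_gene = np.isin(genes, sorted(plan.planted_deg))
    single = planted_gene & (n_probes > 1) & (rng.random(len(genes)) < config.single_probe_fraction)
    carrier = planted_gene[gene_rep].copy()
    for gi in np.where(single)[0]:
        lo = first[gi]
        block = np.zeros(n_probes[gi], dtype=bool)
        block[int(rng.integers(0, n_probes[gi]))] = True
        carrier[lo:lo + n_probes[gi]] = block

    gene_arr = np.array(genes, dtype=object)
    probe_ids = [f"A_23_P{i:06d}" for i in range(1, gene_rep.size + 1)]
    probe_map = pd.DataFrame({"probe_id": probe_ids, "gene": gene_arr[gene_rep]})

    control_ids = [f"DARKCORNER{i:03d}" for i in range(1, config.n_unmapped_probes + 1)]
    control_log2 = rng.uniform(4.0, 6.0, size=len(control_ids))
    all_ids = probe_ids + control_ids
    all_log2 = np.concatenate([probe_log2, control_log2])
    all_carrier = np.concatenate([carrier, np.zeros(len(control_ids), bool)])

    samples = _sample_names(config.groups_expr)
    is_ra = np.array([s.startswith("RA_") for s in samples])
    sigma = float(np.sqrt(np.log1p(config.expr_cv ** 2)))
    mean = np.exp2(all_log2)[:, None] * np.where(
        all_carrier[:, None] & is_ra[None, :], config.deg_fold, 1.0)
    values = mean * np.exp(rng.normal(0.0, sigma, size=(len(all_ids), len(samples))))
    expr = pd.DataFrame(values, index=pd.Index(all_ids, name="probe_id"), columns=samples)
    return expr, probe_map


def simulate_gwas_catalog(config: SimulationConfig):
    """Catalog table (DataFrame) and supplementary gene list.

    Disease-trait rows carry the trait genes (minus the supplement-only
    ones), mostly one per row with some multi-gene cells, one deliberate
    duplicate, and placeholder rows with no reportable gene.  Decoy rows for
    other traits carry the remaining core genes and the off-universe decoy
    symbols, so the full catalog reports ``catalog_reported_total`` distinct
    symbols.
    """
    plan = plan_genes(config)
    rng = _rng(config, 3)
    trait_names = ("Rheumatoid arthritis", "Rheumatoid arthritis (ACPA-positive)")
    ra_genes = [g for g in (list(plan.planted_triple)
                            + sorted(plan.gwas_genes - set(plan.planted_triple)))
                if g not in plan.supplement_only]
    ra_genes = list(rng.permutation(np.array(ra_genes, dtype=object)))

    rows, rs = [], 1_000_000

    def add_row(trait: str, cell: str, pval: float) -> None:
        nonlocal rs
        rs += int(rng.integers(1, 5000))
        rows.append((trait, f"rs{rs}", f"{pval:.1E}", cell))

    i = 0
    while i < len(ra_genes):
        width = int(rng.choice([1, 1, 1, 2, 3]))
        cell = ", ".join(ra_genes[i:i + width])
        add_row(trait_names[len(rows) % 2], cell, 10.0 ** -rng.uniform(6, 30))
        i += width
    add_row(trait_names[0], ra_genes[0], 10.0 ** -rng.uniform(6, 30))  # duplicate gene
    add_row(trait_names[0], "NR", 10.0 ** -rng.uniform(6, 30))
    add_row(trait_names[1], "intergenic", 10.0 ** -rng.uniform(6, 30))

    other = [g for g in plan.catalog_core if g not in set(ra_genes)] + list(plan.decoy_symbols)
    other = list(rng.permutation(np.array(other, dtype=object)))
    i = 0
    while i < len(other):
        width = int(rng.integers(1, 5))
        cell = ", ".join(other[i:i + width])
        add_row(_DECOY_TRAITS[len(rows) % len(_DECOY_TRAITS)], cell,
                10.0 ** -rng.uniform(6, 30))
        i += width

    catalog = pd.DataFrame(rows, columns=["DISEASE/TRAIT", "SNPS", "P-VALUE",
                                          "REPORTED GENE(S)"])
    supplement = sorted(plan.supplement_only)
    return catalog, supplement


def simulate_pathways(config: SimulationConfig):
    """GMT-style pathway collection with one planted enriched pathway.

    The planted pathway holds ``planted_pathway_megs`` of the planted
    multi-evidence genes (triple-evidence first) padded to
    ``planted_pathway_size`` with unplanted genes; the remaining pathways are
    uniform draws from the universe.
    """
    plan = plan_genes(config)
    rng = _rng(config, 4)
    megs = list(plan.planted_triple) + sorted(
        (plan.planted_dmg & plan.planted_deg) - set(plan.planted_triple))
    seed_genes = megs[:config.planted_pathway_megs]
    unplanted = sorted(set(plan.genes) - plan.planted_dmg - plan.planted_deg
                       - plan.gwas_genes)
    pad = list(rng.choice(np.array(unplanted, dtype=object),
                          size=config.planted_pathway_size - len(seed_genes),
                          replace=False))
    pathways: dict[str, set[str]] = {"Rheumatoid arthritis": set(seed_genes) | set(pad)}
    descriptions = {"Rheumatoid arthritis": "planted enriched pathway"}
    sizes = rng.integers(config.pathway_size_range[0], config.pathway_size_range[1] + 1,
                         size=config.n_pathways - 1)
    universe = np.array(plan.genes, dtype=object)
    for j, size in enumerate(sizes, start=1):
        name = f"Pathway {j:02d}"
        pathways[name] = set(rng.choice(universe, size=int(size), replace=False))
        descriptions[name] = "random pathway"
    return pathways, descriptions


@dataclass
class SyntheticBundle:
    """All pipeline inputs, in memory, plus the planted truth."""

    config: SimulationConfig
    beta: pd.DataFrame
    manifest: pd.DataFrame
    tss: pd.DataFrame
    expr: pd.DataFrame
    probe_map: pd.DataFrame
    catalog: pd.DataFrame
    supplement: list
    pathways: dict
    pathway_descriptions: dict
    truth: dict


def simulate_bundle(config: SimulationConfig | None = None) -> SyntheticBundle:
    """Generate the full synthetic input bundle for one configuration."""
    config = config or SimulationConfig()
    plan = plan_genes(config)
    beta, manifest, tss = simulate_methylation(config)
    expr, probe_map = simulate_expression(config)
    catalog, supplement = simulate_gwas_catalog(config)
    pathways, descriptions = simulate_pathways(config)
    planted_meg = sorted((plan.planted_dmg & plan.planted_deg)
                         | (plan.planted_dmg & plan.gwas_genes)
                         | (plan.planted_deg & plan.gwas_genes))
    truth = {
        "seed": config.seed,
        "universe": sorted(plan.genes),
        "planted_dmg": sorted(plan.planted_dmg),
        "planted_deg": sorted(plan.planted_deg),
        "gwas_genes": sorted(plan.gwas_genes),
        "supplement_only": sorted(plan.supplement_only),
        "planted_triple": sorted(plan.planted_triple),
        "planted_meg": planted_meg,
        "planted_pathway": "Rheumatoid arthritis",
    }
    return SyntheticBundle(config, beta, manifest, tss, expr, probe_map,
                           catalog, supplement, pathways, descriptions, truth)


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Serialize a bundle to plain-text files; byte-stable for a fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "manifest": outdir / "loci.bed",
        "tss": outdir / "tss.tsv",
        "expr": outdir / "expression.tsv",
        "probe_map": outdir / "probe_map.tsv",
        "catalog": outdir / "gwas_catalog.tsv",
        "supplement": outdir / "gwas_supplement.txt",
        "gmt": outdir / "pathways.gmt",
        "truth": outdir / "truth.json",
    }
    mio.write_matrix(bundle.beta, paths["beta"], float_format="%.4f")
    mio.write_manifest(bundle.manifest, paths["manifest"])
    mio.write_tss_table(bundle.tss, paths["tss"])
    mio.write_matrix(bundle.expr, paths["expr"], float_format="%.2f")
    mio.write_probe_map(bundle.probe_map, paths["probe_map"])
    bundle.catalog.to_csv(paths["catalog"], sep="\t", index=False)
    Path(paths["supplement"]).write_text("".join(f"{g}\n" for g in bundle.supplement))
    mio.write_gmt(bundle.pathways, paths["gmt"], bundle.pathway_descriptions)
    mio.write_json(bundle.truth, paths["truth"])
    return paths
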