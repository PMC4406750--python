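"""End-to-end orchestration: bundle -> evidence sets -> overlap -> enrichment.

``run_all`` executes the whole integration in order — (optional) simulation,
DMG calling, DEG calling, GWAS gene extraction, evidence ledger and Venn
counts, overlap permutation, pathway enrichment — writing every intermediate
table plus a JSON run report.  Stage boundaries are explicit so a failure is
reported with its stage label and earlier outputs are retained.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as menrich
from . import expression as mexpr
from . import gwas as mgwas
from . import integrate as mint
from . import io as mio
from . import methylation as mmeth
from . import permutation as mperm
from .simulate import (SimulationConfig, simulate_bundle, simulate_expression,
                       simulate_gwas_catalog, simulate_methylation, write_bundle)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_all", "overlap_significance"]

DEFAULT_COMPARISONS = (("RA", "OA"), ("RA", "NL"))


def overlap_significance(seed: int = 2014, n_permutations: int = 10_000,
                         draws: tuple = (2_375, 2_947, 114),
                         observed: int = 7,
                         sim: SimulationConfig | None = None):
    """Permutation p-value for the triple overlap at the study's set sizes.

    Builds the three identifiable-gene backgrounds from a synthetic
    platform's files — promoter-locus manifest with TSS windows, expression
    probe map, GWAS catalog — then redraws the study's evidence-set sizes
    (2,375 methylation genes, 2,947 expression genes, 114 GWAS genes by
    default) for ``n_permutations`` rounds against the observed three-way
    overlap.  The permutation stream is seeded with ``seed + 1`` so it is
    independent of the platform simulation.
    """
    cfg = sim or SimulationConfig(seed=seed)
    _, manifest, tss = simulate_methylation(cfg)
    _, probe_map = simulate_expression(cfg)
    catalog, _ = simulate_gwas_catalog(cfg)
    windows = mmeth.build_promoter_windows(tss)
    backgrounds = [
        mperm.methylation_background(manifest, windows, draws[0]),
        mperm.expression_background(probe_map, draws[1]),
        mperm.gwas_background(mgwas.rows_from_frame(catalog), draws[2]),
    ]
    return mperm.permute_overlap(backgrounds, observed, n_permutations,
                                 seed=seed + 1)


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for one pipeline run.

    Threshold defaults are the calling rules the whole analysis is built
    around: locus q < 0.05 with |Δβ| > 0.1; probe fold > 2 with uncorrected
    p < 0.05; promoter window −2500/+500 bp around each TSS; pathway
    q < 0.05; 10,000 permutation rounds.
    """

    outdir: str = "megpipe_out"
    # inputs (ignored when simulate=True, which writes a bundle first)
    beta: str | None = None
    manifest: str | None = None
    tss: str | None = None
    expr: str | None = None
    probe_map: str | None = None
    catalog: str | None = None
    supplement: str | None = None
    gmt: str | None = None
    simulate: bool = False
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # thresholds
    dml_q: float = 0.05
    dml_delta: float = 0.1
    deg_fold: float = 2.0
    deg_p: float = 0.05
    enrich_q: float = 0.05
    promoter_upstream: int = 2500
    promoter_downstream: int = 500
    comparisons: tuple = DEFAULT_COMPARISONS
    expr_log2_input: bool = False
    min_evidence: int = 2
    n_permutations: int = 10_000
    perm_seed: int = 0
    trait_patterns: tuple = ("rheumatoid arthritis",)
    restrict_to_background: bool = True

    def __post_init__(self) -> None:
        if min(self.dml_q, self.dml_delta, self.deg_fold, self.deg_p,
               self.enrich_q) <= 0:
            raise ValueError("thresholds must be positive")
        if self.promoter_upstream + self.promoter_downstream <= 0:
            raise ValueError("promoter window must have positive extent")
        self.comparisons = tuple(tuple(c) for c in self.comparisons)
        self.trait_patterns = tuple(self.trait_patterns)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = data.pop("sim", None)
        cfg = cls(**data)
        if sim is not None:
            cfg.sim = SimulationConfig(**{k: tuple(v) if isinstance(v, list) else v
                                          for k, v in sim.items()})
        return cfg


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage label
                raise StageError(name, exc) from exc
        return inner
    return wrap


@_stage("dmg")
def _run_dmg(cfg: PipelineConfig, beta, manifest, tss, outdir: Path):
    groups = mio.infer_groups(beta.columns)
    windows = mmeth.build_promoter_windows(tss, cfg.promoter_upstream,
                                           cfg.promoter_downstream)
    tables, per_comp = [], []
    for comp in cfg.comparisons:
        dml = mmeth.test_all_loci(beta, groups, comp, cfg.dml_q, cfg.dml_delta)
        genes = mmeth.dml_to_dmg(dml, windows, manifest)
        logger.info("dmg %s_vs_%s: %d DMLs -> %d DMGs", comp[0], comp[1],
                    int(dml["is_dml"].sum()), len(genes))
        tables.append(dml)
        per_comp.append(genes)
    combined = mmeth.combined_dmg(per_comp)
    dml_all = pd.concat(tables, ignore_index=True)
    dml_all.to_csv(outdir / "dml.tsv", sep="\t", index=False, float_format="%.6g")
    mio.write_gene_list(combined, outdir / "dmg_genes.txt")
    return combined, windows


@_stage("deg")
def _run_deg(cfg: PipelineConfig, expr, probe_map, outdir: Path):
    groups = mio.infer_groups(expr.columns)
    tables, per_comp = [], []
    for comp in cfg.comparisons:
        rec = mexpr.test_all_probes(expr, probe_map, groups, comp,
                                    log2_input=cfg.expr_log2_input,
                                    fold_threshold=cfg.deg_fold,
                                    p_threshold=cfg.deg_p)
        genes = mexpr.probes_to_deg(rec)
        logger.info("deg %s_vs_%s: %d DEG probes -> %d DEGs", comp[0], comp[1],
                    int(rec["is_deg_probe"].sum()), len(genes))
        tables.append(rec)
        per_comp.append(genes)
    combined = mexpr.combined_deg(per_comp)
    rec_all = pd.concat(tables, ignore_index=True)
    rec_all.to_csv(outdir / "probe_diff.tsv", sep="\t", index=False, float_format="%.6g")
    mio.write_gene_list(combined, outdir / "deg_genes.txt")
    return combined


@_stage("gwas")
def _run_gwas(cfg: PipelineConfig, catalog_rows, supplement, outdir: Path):
    genes = mgwas.extract_trait_genes(catalog_rows, cfg.trait_patterns, supplement)
    logger.info("gwas: %d trait genes (incl. %d supplementary)", len(genes),
                len(set(supplement)))
    mio.write_gene_list(genes, outdir / "gwas_genes.txt")
    return genes


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage and return (and write) the run report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.simulate:
        try:
            bundle = simulate_bundle(cfg.sim)
            paths = write_bundle(bundle, outdir / "bundle")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("simulate", exc) from exc
        cfg = dataclasses.replace(
            cfg, beta=str(paths["beta"]), manifest=str(paths["manifest"]),
            tss=str(paths["tss"]), expr=str(paths["expr"]),
            probe_map=str(paths["probe_map"]), catalog=str(paths["catalog"]),
            supplement=str(paths["supplement"]), gmt=str(paths["gmt"]))

    try:
        beta = mio.read_matrix(cfg.beta)
        manifest = mio.read_manifest(cfg.manifest)
        tss = mio.read_tss_table(cfg.tss)
        expr = mio.read_matrix(cfg.expr)
        probe_map = mio.read_probe_map(cfg.probe_map)
        catalog_rows = mgwas.read_catalog(cfg.catalog)
        supplement = mio.read_gene_list(cfg.supplement) if cfg.supplement else []
        pathways = mio.read_gmt(cfg.gmt)
    except Exception as exc:
        raise StageError("read_inputs", exc) from exc

    dmg, windows = _run_dmg(cfg, beta, manifest, tss, outdir)
    deg = _run_deg(cfg, expr, probe_map, outdir)
    gwas_genes = _run_gwas(cfg, catalog_rows, supplement, outdir)

    try:
        ledger = mint.build_ledger(dmg, deg, gwas_genes)
        venn = mint.venn_counts(ledger)
        meg = mint.meg_set(ledger, cfg.min_evidence)
        triple = sorted(mint.meg_set(ledger, 3))
        ledger.to_csv(outdir / "evidence_ledger.tsv", sep="\t")
        mio.write_json(venn, outdir / "venn_counts.json")
        mio.write_gene_list(meg, outdir / "meg_genes.txt")
        logger.info("integrate: |DMG|=%d |DEG|=%d |GWAS|=%d -> %d MEGs, %d triple",
                    len(dmg), len(deg), len(gwas_genes), len(meg), len(triple))
    except Exception as exc:
        raise StageError("integrate", exc) from exc

    try:
        backgrounds = [
            mperm.methylation_background(manifest, windows, dmg),
            mperm.expression_background(probe_map, deg),
            mperm.gwas_background(catalog_rows, gwas_genes),
        ]
        perm = mperm.permute_overlap(backgrounds, observed_overlap=len(triple),
                                     n_permutations=cfg.n_permutations,
                                     seed=cfg.perm_seed)
        mio.write_json(perm.to_dict(), outdir / "permutation.json")
        logger.info("permute: observed=%d null_mean=%.3f p=%.5g", len(triple),
                    perm.null_mean, perm.p_value)
    except Exception as exc:
        raise StageError("permute", exc) from exc

    try:
        background = set(tss["gene"])
        table = menrich.enrich(meg, pathways, background,
                               restrict_to_background=cfg.restrict_to_background)
        sig = menrich.filter_significant(table, cfg.enrich_q)
        table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        sig.to_csv(outdir / "enrichment_significant.tsv", sep="\t", index=False,
                   float_format="%.6g")
        logger.info("enrich: %d pathways tested, %d significant at q<%g",
                    len(table), len(sig), cfg.enrich_q)
    except Exception as exc:
        raise StageError("enrich", exc) from exc

    report = {
        "n_dmg": len(dmg),
        "n_deg": len(deg),
        "n_gwas": len(gwas_genes),
        "n_meg": len(meg),
        "venn": venn,
        "triple_evidence_genes": triple,
        "permutation": perm.to_dict(),
        "significant_pathways": sig["pathway"].tolist(),
        "backgrounds": {b.label: len(b.genes) for b in backgrounds},
        "seeds": {"permutation": cfg.perm_seed,
                  "simulation": cfg.sim.seed if cfg.simulate else None},
    }
    mio.write_json(report, outdir / "report.json")
    return report
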