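"""Structure, planted truth and determinism of the synthetic bundle."""

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pytest

from conftest import SMALL_CONFIG
from megpipe import gwas as mgwas
from megpipe.methylation import build_promoter_windows, loci_in_windows
from megpipe.simulate import (SimulationConfig, plan_genes, simulate_bundle,
                              simulate_gwas_catalog, simulate_pathways,
                              write_bundle)


def test_bundle_files_byte_identical_across_reruns(tmp_path):
    digests = []
    for run in range(2):
        paths = write_bundle(simulate_bundle(SMALL_CONFIG), tmp_path / f"run{run}")
        digests.append({k: hashlib.sha256(Path(p).read_bytes()).hexdigest()
                        for k, p in paths.items()})
    assert digests[0] == digests[1]


def test_beta_values_bounded_and_effect_planted(small_bundle):
    beta = small_bundle.beta
    assert float(beta.min().min()) >= 0.01 and float(beta.max().max()) <= 0.99
    # planted genes: RA-vs-OA difference at promoter loci near the planted shift
    windows = build_promoter_windows(small_bundle.tss)
    planted = set(small_bundle.truth["planted_dmg"])
    window_genes = windows[windows["gene"].isin(planted)]
    ra = [c for c in beta.columns if c.startswith("RA_")]
    oa = [c for c in beta.columns if c.startswith("OA_")]
    # collect the promoter loci of planted genes via the manifest coordinates
    hits = loci_in_windows(small_bundle.manifest, window_genes)
    assert hits == planted  # every planted gene has >=1 promoter locus
    man = small_bundle.manifest
    planted_loci = []
    for w in window_genes.itertuples():
        sel = (man["chrom"] == w.chrom) & (man["start"] >= w.start) & (man["start"] < w.end)
        planted_loci.extend(man.loc[sel, "locus_id"])
    deltas = beta.loc[sorted(set(planted_loci)), ra].mean(axis=1) - \
        beta.loc[sorted(set(planted_loci)), oa].mean(axis=1)
    assert deltas.mean() == pytest.approx(SMALL_CONFIG.dmg_delta_beta, abs=0.05)


def test_some_measured_loci_fall_outside_all_windows(small_bundle):
    windows = build_promoter_windows(small_bundle.tss)
    man = small_bundle.manifest
    inside = np.zeros(len(man), dtype=bool)
    for w in windows.itertuples():
        inside |= ((man["chrom"] == w.chrom) & (man["start"] >= w.start)
                   & (man["start"] < w.end)).to_numpy()
    assert 0 < inside.sum() < len(man)


def test_multi_tss_genes_present(small_bundle):
    per_gene = small_bundle.tss.groupby("gene").size()
    assert per_gene.max() >= 2


def test_promoterless_and_unprobed_genes_exist(small_bundle):
    universe = set(small_bundle.truth["universe"])
    windows = build_promoter_windows(small_bundle.tss)
    meth_callable = loci_in_windows(small_bundle.manifest, windows)
    assert meth_callable < universe
    probed = set(small_bundle.probe_map["gene"])
    assert probed < universe


def test_default_catalog_yields_the_reported_trait_gene_count():
    cfg = SimulationConfig()
    catalog, supplement = simulate_gwas_catalog(cfg)
    rows = mgwas.rows_from_frame(catalog)
    genes = mgwas.extract_trait_genes(rows, supplement=supplement)
    assert len(genes) == 114
    assert genes == set(plan_genes(cfg).gwas_genes)
    background = mgwas.catalog_background(rows)
    assert len(background) == cfg.catalog_reported_total
    # supplement-only genes never occur in catalog rows
    assert not (set(supplement) & background) or \
        len(set(supplement) - background) == len(supplement)


def test_planted_triple_subset_of_every_evidence_set(small_bundle):
    truth = small_bundle.truth
    triple = set(truth["planted_triple"])
    assert triple <= set(truth["planted_dmg"])
    assert triple <= set(truth["planted_deg"])
    assert triple <= set(truth["gwas_genes"])
    assert len(truth["planted_meg"]) == SMALL_CONFIG.planted_meg


def test_planted_pathway_composition(small_bundle):
    name = small_bundle.truth["planted_pathway"]
    pw = small_bundle.pathways[name]
    assert len(pw) == SMALL_CONFIG.planted_pathway_size
    megs = set(small_bundle.truth["planted_meg"])
    assert len(pw & megs) == SMALL_CONFIG.planted_pathway_megs
    assert len(small_bundle.pathways) >= 20


def test_pathway_sizes_span_configured_range():
    pathways, _ = simulate_pathways(SMALL_CONFIG)
    lo, hi = SMALL_CONFIG.pathway_size_range
    others = [len(g) for n, g in pathways.items() if n != "Rheumatoid arthritis"]
    assert min(others) >= lo and max(others) <= hi


@pytest.mark.parametrize("kwargs", [
    {"groups_meth": (("RA", 1), ("OA", 11), ("NL", 6))},
    {"dmg_delta_beta": -0.1},
    {"deg_fold": 0.5},
    {"n_planted_dmg": 10},            # too small for requested overlaps
    {"catalog_core_genes": 50},       # cannot cover 114 trait genes
])
def test_invalid_configurations_rejected(kwargs):
    with pytest.raises(ValueError):
        SimulationConfig(**kwargs)


def test_expression_any_probe_structure(small_bundle):
    # at least one planted gene carries the fold on a strict subset of probes
    truth = set(small_bundle.truth["planted_deg"])
    pm = small_bundle.probe_map
    expr = small_bundle.expr
    ra = [c for c in expr.columns if c.startswith("RA_")]
    nl = [c for c in expr.columns if c.startswith("NL_")]
    partial = 0
    for gene, probes in pm.groupby("gene")["probe_id"]:
        if gene not in truth or len(probes) < 2:
            continue
        ratios = expr.loc[probes, ra].mean(axis=1) / expr.loc[probes, nl].mean(axis=1)
        carried = (ratios > 2.0).sum()
        if 0 < carried < len(probes):
            partial += 1
    assert partial > 0
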