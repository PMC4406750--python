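"""Shared fixtures: synthetic bundles at two scales plus called evidence sets.

The "small" bundle (800 genes, strong planted effects) keeps structural
tests fast; the "default" bundle uses the full study-design configuration
(17,450 genes, Δβ = 0.25, 3-fold) for the power/recovery checks.
"""

from __future__ import annotations

from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

from megpipe import expression as mexpr
from megpipe import gwas as mgwas
from megpipe import io as mio
from megpipe import methylation as mmeth
from megpipe.simulate import SimulationConfig, simulate_bundle

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

COMPARISONS = (("RA", "OA"), ("RA", "NL"))

SMALL_CONFIG = SimulationConfig(
    n_genes=800, n_planted_dmg=120, n_planted_deg=140, gwas_trait_genes=40,
    n_dmg_deg=20, n_dmg_gwas=8, n_deg_gwas=8, n_supplement_only=4,
    catalog_reported_total=400, catalog_core_genes=120,
    n_pathways=20, pathway_size_range=(10, 40), planted_pathway_size=30,
    planted_pathway_megs=7, dmg_delta_beta=0.4, deg_fold=5.0)


def call_evidence(bundle, comparisons=COMPARISONS):
    """Run the three evidence callers on a bundle; return everything downstream needs."""
    groups_m = mio.infer_groups(bundle.beta.columns)
    groups_e = mio.infer_groups(bundle.expr.columns)
    windows = mmeth.build_promoter_windows(bundle.tss)
    dml_tables, dmg_sets, deg_tables, deg_sets = [], [], [], []
    for comp in comparisons:
        dml = mmeth.test_all_loci(bundle.beta, groups_m, comp)
        dml_tables.append(dml)
        dmg_sets.append(mmeth.dml_to_dmg(dml, windows, bundle.manifest))
        rec = mexpr.test_all_probes(bundle.expr, bundle.probe_map, groups_e, comp)
        deg_tables.append(rec)
        deg_sets.append(mexpr.probes_to_deg(rec))
    catalog_rows = mgwas.rows_from_frame(bundle.catalog)
    gwas_genes = mgwas.extract_trait_genes(catalog_rows, supplement=bundle.supplement)
    return SimpleNamespace(
        bundle=bundle, windows=windows, catalog_rows=catalog_rows,
        dml_tables=dml_tables, dmg_sets=dmg_sets,
        dmg=mmeth.combined_dmg(dmg_sets),
        deg_tables=deg_tables, deg_sets=deg_sets,
        deg=mexpr.combined_deg(deg_sets),
        gwas=gwas_genes)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_bundle(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_calls(small_bundle):
    return call_evidence(small_bundle)


@pytest.fixture(scope="session")
def default_bundle():
    return simulate_bundle(SimulationConfig())


@pytest.fixture(scope="session")
def default_calls(default_bundle):
    return call_evidence(default_bundle)
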