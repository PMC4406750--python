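"""Run the entire pipeline end to end on a simulated bundle.

simulate -> DMG -> DEG -> GWAS -> integrate -> permute -> enrich, with all
intermediate tables and a JSON report written to the output directory.
"""

from megpipe import PipelineConfig, SimulationConfig, run_all

config = PipelineConfig(
    outdir="scratch/example_run",
    simulate=True,
    sim=SimulationConfig(seed=2014, dmg_delta_beta=0.4, deg_fold=5.0),
    n_permutations=2_000,
    perm_seed=1,
)
report = run_all(config)

print(f"DMGs {report['n_dmg']} | DEGs {report['n_deg']} | "
      f"GWAS {report['n_gwas']} | MEGs {report['n_meg']}")
print(f"triple-evidence genes: {', '.join(report['triple_evidence_genes'])}")
print(f"permutation p = {report['permutation']['p_value']:.6g} "
      f"(null mean {report['permutation']['null_mean']:.3f})")
print(f"backgrounds: {report['backgrounds']}")
print(f"significant pathways: {report['significant_pathways'] or 'none'}")
# At these strong planted effects the recovered triple-evidence list equals
# the planted seven exactly, and the permutation p sits at its floor.
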