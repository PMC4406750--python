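"""Hypergeometric pathway enrichment of the multi-evidence gene set.

Per pathway: k of the m query genes among the K pathway genes in an N-gene
background; fold enrichment (k/m)/(K/N); upper-tail hypergeometric p; BH
q-values across the collection; q < 0.05 reported.
"""

from megpipe import (SimulationConfig, enrich, filter_significant,
                     simulate_bundle)

bundle = simulate_bundle(SimulationConfig(seed=2014))
meg = set(bundle.truth["planted_meg"])
background = set(bundle.truth["universe"])

table = enrich(meg, bundle.pathways, background)
print(table.head(5).to_string(index=False,
                              formatters={"fold": "{:.2f}".format,
                                          "p_hyper": "{:.2e}".format,
                                          "q_value": "{:.2e}".format}))
significant = filter_significant(table, 0.05)
print(f"\n{len(significant)} pathway(s) at q < 0.05")
print(f"top-ranked pathway: {table.iloc[0]['pathway']} "
      f"({table.iloc[0]['k']}/{table.iloc[0]['K']} genes, "
      f"{table.iloc[0]['fold']:.2f}-fold)")
# The planted pathway (7 of its 89 members are planted multi-evidence genes)
# ranks first at ~3.75-fold enrichment — the regime the analysis is designed
# to flag.  Its BH q depends on the collection size: with only 25 synthetic
# pathways the q-value is ~6e-2, so rank, fold and p are the stable readouts.
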