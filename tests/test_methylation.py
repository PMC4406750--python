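"""Promoter windows, DML thresholds and DMG mapping."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from _oracles import genes_with_dml_brute
from conftest import SMALL_CONFIG, call_evidence
from megpipe.methylation import (build_promoter_windows, classify_dml,
                                 combined_dmg, dml_to_dmg, loci_in_windows)
from megpipe.methylation import test_all_loci as call_loci
from megpipe.simulate import simulate_bundle


def tss_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "strand",
                                       "tss_position", "transcript_label"])


class TestPromoterWindows:
    def test_plus_strand_window(self):
        w = build_promoter_windows(tss_frame([("G1", "chr1", "+", 10_000, "v1")]))
        assert (int(w.at[0, "start"]), int(w.at[0, "end"])) == (7_500, 10_500)

    def test_minus_strand_window_mirrored(self):
        w = build_promoter_windows(tss_frame([("G1", "chr1", "-", 10_000, "v1")]))
        assert (int(w.at[0, "start"]), int(w.at[0, "end"])) == (9_500, 12_500)

    def test_multi_tss_gene_gets_multiple_windows(self):
        w = build_promoter_windows(tss_frame([("G1", "chr1", "+", 10_000, "v1"),
                                              ("G1", "chr1", "+", 50_000, "v2")]))
        assert len(w) == 2 and set(w["gene"]) == {"G1"}
        assert np.all(w["end"] - w["start"] == 3_000)

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError):
            build_promoter_windows(tss_frame([("G1", "chr1", ".", 10_000, "v1")]))


class TestDmlRule:
    @pytest.mark.parametrize("q, delta, expected", [
        (0.04, 0.15, True),
        (0.04, 0.05, False),    # fails mean-difference filter
        (0.06, 0.30, False),    # fails q filter
        (0.05, 0.15, False),    # strict threshold on q
        (0.04, 0.10, False),    # strict threshold on |delta|
        (0.04, -0.15, True),    # direction-agnostic
    ])
    def test_threshold_rule(self, q, delta, expected):
        assert classify_dml([q], [delta])[0] == expected

    def test_called_table_consistent_with_rule(self, small_calls):
        for dml in small_calls.dml_tables:
            expected = (dml["q_value"] < 0.05) & (dml["delta"].abs() > 0.1)
            assert (dml["is_dml"] == expected).all()
            assert dml["p_value"].between(0, 1).all()

    def test_missing_values_skipped(self, small_bundle):
        beta = small_bundle.beta.copy()
        beta.iloc[0, 0] = np.nan
        groups = {c: c.split("_")[0] for c in beta.columns}
        out = call_loci(beta, groups, ("RA", "OA"))
        assert beta.index[0] not in set(out["locus_id"])
        assert len(out) == len(beta) - 1

    def test_absent_group_rejected(self, small_bundle):
        groups = {c: c.split("_")[0] for c in small_bundle.beta.columns}
        with pytest.raises(ValueError):
            call_loci(small_bundle.beta, groups, ("RA", "XX"))


class TestDmgMapping:
    def setup_method(self):
        self.windows = build_promoter_windows(
            tss_frame([("G1", "chr1", "+", 10_000, "v1")]))
        self.manifest = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [7_500, 10_500, 9_000],
            "end": [7_502, 10_502, 9_002],
            "locus_id": ["cgA", "cgB", "cgC"],
        })

    def dml(self, locus_ids):
        return pd.DataFrame({"locus_id": locus_ids, "is_dml": True})

    def test_window_start_is_inclusive(self):
        assert dml_to_dmg(self.dml(["cgA"]), self.windows, self.manifest) == {"G1"}

    def test_window_end_is_exclusive(self):
        assert dml_to_dmg(self.dml(["cgB"]), self.windows, self.manifest) == set()

    def test_unknown_locus_is_a_hard_error(self):
        with pytest.raises(ValueError):
            dml_to_dmg(self.dml(["cgZ"]), self.windows, self.manifest)

    def test_matches_bruteforce_double_loop(self, small_calls):
        bundle = small_calls.bundle
        dml = small_calls.dml_tables[0]
        hits = dml.loc[dml["is_dml"], "locus_id"]
        fast = dml_to_dmg(dml, small_calls.windows, bundle.manifest)
        brute = genes_with_dml_brute(bundle.manifest, small_calls.windows, hits)
        assert fast == brute


class TestCombined:
    def test_union_semantics(self):
        assert combined_dmg([{"A", "B"}, {"B", "C"}]) == {"A", "B", "C"}
        assert combined_dmg([{"A"}]) == {"A"}
        assert combined_dmg([]) == set()


class TestPower:
    def test_planted_recovery_at_default_effect(self, default_calls):
        """>=95% of genes planted with Δβ=0.25 are recovered as DMGs."""
        planted = set(default_calls.bundle.truth["planted_dmg"])
        recovered = default_calls.dmg
        assert len(recovered & planted) / len(planted) >= 0.95
        false_positives = recovered - planted
        assert len(false_positives) <= 20

    def test_null_simulation_false_positive_rate_controlled(self):
        """With no planted effect the DMG false-positive gene rate stays below q."""
        cfg = dataclasses.replace(SMALL_CONFIG, dmg_delta_beta=0.0, seed=99)
        calls = call_evidence(simulate_bundle(cfg))
        universe = cfg.n_genes
        assert len(calls.dmg) / universe <= 0.05

    def test_dmg_subset_of_methylation_callable_genes(self, small_calls):
        callable_genes = loci_in_windows(small_calls.bundle.manifest,
                                         small_calls.windows)
        assert small_calls.dmg <= callable_genes
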