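"""Risk-locus algorithm: greedy clumping, merging passes, naming."""

import numpy as np
import pandas as pd
import pytest

from _oracles import check_loci
from conftest import make_gws_table, panel_from_pairs, random_correlation
from migwas.ld import LDPanel
from migwas.loci import (ConsistencyError, call_risk_loci, define_loci,
                         name_and_lead, select_index_variants)


class TestIndexSelection:
    def test_single_variant_is_its_own_index(self):
        gws = make_gws_table(["rs1"], [1], [100], [1e-9])
        panel = panel_from_pairs(["rs1"], [])
        assert select_index_variants(gws, panel) == ["rs1"]

    def test_mutually_linked_variants_give_one_index(self):
        gws = make_gws_table(["rs1", "rs2", "rs3"], [1, 1, 1],
                             [100, 200, 300], [1e-9, 1e-12, 1e-10])
        panel = panel_from_pairs(gws["SNP"], [
            ("rs1", "rs2", 0.8), ("rs1", "rs3", 0.8), ("rs2", "rs3", 0.8)])
        assert select_index_variants(gws, panel) == ["rs2"]

    def test_greedy_loop_hand_example(self):
        """p = (1e-12, 1e-10, 1e-9, 1e-8); r2(1,2)=0.5, r2(1,3)=0.05,
        r2(3,4)=0.3: variant 1 absorbs 2, then variant 3 absorbs 4."""
        gws = make_gws_table(["v1", "v2", "v3", "v4"], [1] * 4,
                             [100, 200, 300, 400],
                             [1e-12, 1e-10, 1e-9, 1e-8])
        panel = panel_from_pairs(gws["SNP"], [
            ("v1", "v2", np.sqrt(0.5)), ("v1", "v3", np.sqrt(0.05)),
            ("v3", "v4", np.sqrt(0.3))])
        assert select_index_variants(gws, panel) == ["v1", "v3"]

    def test_unknown_ld_becomes_singleton_candidate(self):
        gws = make_gws_table(["v1", "v2"], [1, 1], [100, 200], [1e-12, 1e-9])
        panel = panel_from_pairs(["v1"], [])
        assert select_index_variants(gws, panel) == ["v1", "v2"]

    def test_secondary_panel_resolves_and_replaces(self):
        gws = make_gws_table(["v1", "v2", "v3"], [1, 1, 1],
                             [100, 200, 300], [1e-9, 1e-12, 1e-7 * 0.4])
        panel = panel_from_pairs(["v1", "v3"], [])
        # v2 unknown to the primary panel, in LD with index v1 and stronger
        panel2 = panel_from_pairs(["v1", "v2"], [("v1", "v2", 0.7)])
        out = select_index_variants(gws, panel, panel2=panel2)
        assert "v2" in out and "v1" not in out and "v3" in out

    def test_row_order_invariance(self, rng):
        gws = make_gws_table([f"v{i}" for i in range(8)], [1] * 8,
                             range(100, 900, 100),
                             10.0 ** -rng.uniform(8, 15, size=8))
        panel = panel_from_pairs(gws["SNP"], [
            ("v0", "v1", 0.5), ("v2", "v3", 0.5), ("v4", "v5", 0.9)])
        base = select_index_variants(gws, panel)
        shuffled = gws.sample(frac=1, random_state=3).reset_index(drop=True)
        assert select_index_variants(shuffled, panel) == base

    def test_empty_input_empty_output(self):
        gws = make_gws_table([], [], [], [])
        assert select_index_variants(gws, panel_from_pairs([], [])) == []


class TestDefineLoci:
    def test_blocks_merge_below_gap(self):
        """Blocks [100k, 200k] and [400k, 500k] (gap 200 kb) merge."""
        gws = make_gws_table(["a1", "a2", "b1", "b2"], [1] * 4,
                             [100_000, 200_000, 400_000, 500_000],
                             [1e-12, 1e-9, 1e-11, 1e-9])
        panel = panel_from_pairs(gws["SNP"], [
            ("a1", "a2", 0.9), ("b1", "b2", 0.9)])
        loci = define_loci(["a1", "b1"], gws, panel)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (100_000, 500_000)

    def test_blocks_stay_apart_at_gap_over_threshold(self):
        gws = make_gws_table(["a1", "a2", "b1", "b2"], [1] * 4,
                             [100_000, 200_000, 460_000, 500_000],
                             [1e-12, 1e-9, 1e-11, 1e-9])
        panel = panel_from_pairs(gws["SNP"], [
            ("a1", "a2", 0.9), ("b1", "b2", 0.9)])
        loci = define_loci(["a1", "b1"], gws, panel)
        assert len(loci) == 2

    def test_stray_variant_bridges_blocks_via_assignment(self):
        """Gap 260 kb, but a stray GWS variant at 330 kb extends the first
        block to 330 kb; the new 130 kb gap merges in the final pass."""
        gws = make_gws_table(["a1", "a2", "s", "b1", "b2"], [1] * 5,
                             [100_000, 200_000, 330_000, 460_000, 500_000],
                             [1e-12, 1e-9, 1e-8 * 0.5, 1e-11, 1e-9])
        panel = panel_from_pairs(gws["SNP"], [
            ("a1", "a2", 0.9), ("b1", "b2", 0.9)])
        loci = define_loci(["a1", "b1"], gws, panel)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (100_000, 500_000)
        assert set(loci[0].members) == set(gws["SNP"])

    def test_lone_index_gives_one_bp_locus(self):
        gws = make_gws_table(["v1"], [1], [12_345], [1e-9])
        loci = define_loci(["v1"], gws, panel_from_pairs(["v1"], []))
        assert loci[0].size == 1
        assert loci[0].start == loci[0].end == 12_345

    def test_merging_never_crosses_chromosomes(self):
        gws = make_gws_table(["v1", "v2"], [1, 2], [100, 200], [1e-9, 1e-9])
        loci = define_loci(["v1", "v2"], gws, panel_from_pairs(gws["SNP"], []))
        assert len(loci) == 2

    def test_unknown_index_raises(self):
        gws = make_gws_table(["v1"], [1], [100], [1e-9])
        with pytest.raises(ConsistencyError):
            define_loci(["nope"], gws, panel_from_pairs(["v1"], []))

    def test_random_instances_satisfy_invariants(self, rng):
        """Brute-force verification on 50 random small instances."""
        for _ in range(50):
            m = int(rng.integers(2, 30))
            chroms = rng.choice(["1", "2"], size=m)
            bps = rng.integers(1, 2_000_000, size=m)
            snps = [f"v{i}" for i in range(m)]
            gws = make_gws_table(snps, chroms, bps,
                                 10.0 ** -rng.uniform(8, 20, size=m))
            # per-chromosome random correlation; unknown LD for some
            r = np.eye(m)
            for c in ("1", "2"):
                idx = np.where(chroms == c)[0]
                if len(idx) > 1:
                    r[np.ix_(idx, idx)] = random_correlation(rng, len(idx))
            known = rng.random(m) > 0.2
            panel = LDPanel(variants=[s for s, k in zip(snps, known) if k],
                            r=r[np.ix_(known, known)])
            indices = select_index_variants(gws, panel)
            loci = define_loci(indices, gws, panel)
            check_loci(loci, gws, panel)
            # fixed point: a further merge pass changes nothing
            again = define_loci(indices, gws, panel)
            assert [(lo.start, lo.end, sorted(lo.members)) for lo in loci] \
                == [(lo.start, lo.end, sorted(lo.members)) for lo in again]


GENES = pd.DataFrame({
    "CHR": ["1", "1", "1"],
    "START": [1_000, 50_001, 400_001],
    "END": [2_000, 60_000, 410_000],
    "NAME": ["NC1", "PC1", "PC2"],
    "BIOTYPE": ["lincRNA", "protein_coding", "protein_coding"],
})


def one_locus(bp):
    gws = make_gws_table(["v1"], [1], [bp], [1e-9])
    loci = define_loci(["v1"], gws, panel_from_pairs(["v1"], []))
    return loci[0], gws


class TestNaming:
    def test_lead_inside_protein_coding_gene(self):
        locus, gws = one_locus(55_000)
        out = name_and_lead(locus, gws, GENES)
        assert out.name == "PC1" and out.is_near is False

    def test_near_prefix_outside_any_transcript(self):
        locus, gws = one_locus(70_000)  # 10 kb from PC1
        out = name_and_lead(locus, gws, GENES)
        assert out.name == "Near PC1" and out.is_near is True

    def test_noncoding_fallback_when_no_pc_within_window(self):
        # 300 kb+ from both protein-coding genes, 50 kb from NC1
        genes = GENES.copy()
        genes.loc[2, ["START", "END"]] = [900_001, 910_000]
        locus, gws = one_locus(52_000 + 300_000 + 250_001)
        genes2 = pd.DataFrame({
            "CHR": ["1", "1"], "START": [1_000, 551_000],
            "END": [2_000, 552_000], "NAME": ["PCX", "NCX"],
            "BIOTYPE": ["protein_coding", "lincRNA"]})
        out = name_and_lead(locus, gws, genes2)
        assert out.name == "Near NCX" and out.is_near is True

    def test_positional_fallback_without_genes(self):
        locus, gws = one_locus(100)
        out = name_and_lead(locus, gws, None)
        assert out.name == "chr1:100" and out.is_near is True

    def test_lead_is_minimum_p_member(self):
        gws = make_gws_table(["v1", "v2"], [1, 1], [100, 150], [1e-9, 1e-14])
        panel = panel_from_pairs(gws["SNP"], [("v1", "v2", 0.9)])
        loci = define_loci(select_index_variants(gws, panel), gws, panel)
        out = name_and_lead(loci[0], gws, None)
        assert out.lead == "v2"
        assert out.lead_p == pytest.approx(1e-14)


def test_call_risk_loci_end_to_end(rng):
    from migwas.meta import ivw_meta
    from migwas.synth import SimConfig, simulate_cohorts, simulate_ld_panel
    cfg = SimConfig(n_variants=400, n_blocks=20, seed=17,
                    causal_fraction=0.05, effect_sd=0.3)
    panel = simulate_ld_panel(cfg)
    _, tables = simulate_cohorts(cfg, panel)
    pooled = ivw_meta(tables)
    loci = call_risk_loci(pooled, panel)
    assert loci, "strong spike effects should yield at least one locus"
    gws = pooled[pooled["P"] < 5e-8]
    check_loci(loci, gws, panel)
    for lo in loci:
        assert lo.lead is not None and lo.name is not None
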