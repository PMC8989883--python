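"""Generator operations: WGD calibration, fusion plans, fractionation,
rearrangements, expression/contact simulation, and the replay scenarios."""

import numpy as np
import pandas as pd
import pytest

from paleoshuffle import synthetic_data as sd
from paleoshuffle import wgd_dating as wd


@pytest.fixture(scope="module")
def small_genome():
    cfg = sd.SimulationConfig(seed=5, n_anc_chrom=3, genes_per_chrom=40,
                              codons_per_gene=60)
    rng = np.random.default_rng(5)
    return sd.simulate_ancestral_genome(cfg, rng)


class TestAncestralGenome:
    def test_default_counts(self):
        cfg = sd.SimulationConfig(seed=0)
        g, seqs = sd.simulate_ancestral_genome(cfg)
        assert g.n_chromosomes == 7
        assert g.n_genes() == 7 * 120
        assert len(seqs) == 840

    def test_same_seed_identical(self):
        cfg = sd.SimulationConfig(seed=9, n_anc_chrom=2, genes_per_chrom=10)
        g1, s1 = sd.simulate_ancestral_genome(cfg)
        g2, s2 = sd.simulate_ancestral_genome(cfg)
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)

    def test_sequences_in_frame_no_stops(self, small_genome):
        _, seqs = small_genome
        for arr in list(seqs.values())[:50]:
            nt = wd.codon_idx_to_str(arr)
            assert len(nt) == 3 * 60
            for i in range(0, len(nt), 3):
                assert wd.GENETIC_CODE[nt[i:i + 3]] != "*"

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(seed=0, n_anc_chrom=0)


class TestWgd:
    def test_triplication_chromosome_count(self, small_genome):
        g, seqs = small_genome
        rng = np.random.default_rng(1)
        g2, _, _ = sd.apply_wgd(g, seqs, 3, "gamma", 0.8, rng)
        assert g2.n_chromosomes == 3 * g.n_chromosomes
        assert g2.n_genes() == 3 * g.n_genes()

    def test_duplication_doubles(self, small_genome):
        g, seqs = small_genome
        rng = np.random.default_rng(1)
        g2, _, _ = sd.apply_wgd(g, seqs, 2, "beta", 0.3, rng,
                                label_kind="beta")
        assert g2.n_chromosomes == 2 * g.n_chromosomes

    @pytest.mark.parametrize("target", [0.2, 0.6, 1.2])
    def test_ks_calibration_within_tolerance(self, target):
        cfg = sd.SimulationConfig(seed=11)
        rng = np.random.default_rng(11)
        g, seqs = sd.simulate_ancestral_genome(cfg, rng)
        _, _, measured = sd.apply_wgd(g, seqs, 2, "x", target, rng,
                                      label_kind="beta")
        assert abs(measured - target) <= 0.05

    def test_bad_parameters_rejected(self, small_genome):
        g, seqs = small_genome
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sd.apply_wgd(g, seqs, 4, "x", 0.5, rng)
        with pytest.raises(ValueError):
            sd.apply_wgd(g, seqs, 2, "x", -0.1, rng)


class TestFusionPlan:
    def test_whole_chromosome_concatenation(self, small_genome):
        g, _ = small_genome
        plan = {"N1": [("Eu1", 0, None), ("Eu2", 0, None)],
                "N2": [("Eu3", 0, None)]}
        g2 = sd.apply_fusion_plan(g, plan, "L")
        assert g2.n_chromosomes == 2
        assert len(g2.junction_registry) == 1
        assert list(g2.junction_registry.values()) == ["L"]

    def test_junctions_equal_segments_minus_chromosomes(self):
        cfg = sd.SimulationConfig(seed=2, genes_per_chrom=40)
        rng = np.random.default_rng(2)
        g, seqs = sd.simulate_ancestral_genome(cfg, rng)
        g3, _, _ = sd.apply_wgd(g, seqs, 3, "gamma", 0.5, rng)
        plan = sd._gamma_fusion_plan(40)
        g4 = sd.apply_fusion_plan(g3, plan, "post-gamma")
        n_segments = sum(len(v) for v in plan.values())
        assert n_segments == 34
        assert g4.n_chromosomes == 8
        assert len(g4.junction_registry) == 34 - 8

    def test_omitted_segment_rejected(self, small_genome):
        g, _ = small_genome
        plan = {"N1": [("Eu1", 0, 20)], "N2": [("Eu2", 0, None)],
                "N3": [("Eu3", 0, None)]}   # Eu1[20:40] missing
        with pytest.raises(ValueError, match="omits"):
            sd.apply_fusion_plan(g, plan, "L")

    def test_reused_segment_rejected(self, small_genome):
        g, _ = small_genome
        plan = {"N1": [("Eu1", 0, None), ("Eu1", 0, None)],
                "N2": [("Eu2", 0, None)], "N3": [("Eu3", 0, None)]}
        with pytest.raises(ValueError):
            sd.apply_fusion_plan(g, plan, "L")


class TestFractionation:
    def test_zero_loss_is_identity(self, small_genome):
        g, _ = small_genome
        rng = np.random.default_rng(0)
        g2, truth = sd.apply_fractionation(
            g, {"retention": {("", ""): 1.0}}, rng)
        assert g2.n_genes() == g.n_genes()

    def test_explicit_implant(self, small_genome):
        g, seqs = small_genome
        rng = np.random.default_rng(0)
        g2, _, _ = sd.apply_wgd(g, seqs, 2, "b", 0.3, rng, label_kind="beta")
        locus = next(g.all_genes()).locus
        implant = {locus: {("", "a")}}
        g3, truth = sd.apply_fractionation(g2, {"implant": implant}, rng)
        copies = [x for x in g3.all_genes() if x.locus == locus]
        assert len(copies) == 1 and copies[0].beta == "a"

    def test_conservation_of_retention_truth(self, small_genome):
        g, seqs = small_genome
        rng = np.random.default_rng(3)
        g2, _, _ = sd.apply_wgd(g, seqs, 2, "b", 0.3, rng, label_kind="beta")
        g3, truth = sd.apply_fractionation(
            g2, {"retention": {("", "a"): 0.8, ("", "b"): 0.4}}, rng)
        assert g3.n_genes() == sum(len(v) for v in truth.values())
        assert all(len(v) >= 1 for v in truth.values())

    def test_bad_probability_rejected(self, small_genome):
        g, _ = small_genome
        with pytest.raises(ValueError):
            sd.apply_fractionation(g, {"retention": {("", ""): 1.5}},
                                   np.random.default_rng(0))


class TestRearrangements:
    def test_inversion_reverses_and_flips(self, small_genome):
        g, _ = small_genome
        before = [x.locus for x in g.chromosomes["Eu1"]]
        g2, ev = sd.apply_rearrangement(g, "inversion",
                                        {"chrom": "Eu1", "lo": 10, "hi": 20})
        after = [x.locus for x in g2.chromosomes["Eu1"]]
        assert after[10] == before[19] and after[19] == before[10]
        assert g2.chromosomes["Eu1"][10].strand == "-"
        assert ev["kind"] == "inversion"

    def test_double_inversion_is_identity(self, small_genome):
        g, _ = small_genome
        g2, _ = sd.apply_rearrangement(g, "inversion",
                                       {"chrom": "Eu1", "lo": 5, "hi": 15})
        g3, _ = sd.apply_rearrangement(g2, "inversion",
                                       {"chrom": "Eu1", "lo": 5, "hi": 15})
        assert [x.locus for x in g3.chromosomes["Eu1"]] == \
            [x.locus for x in g.chromosomes["Eu1"]]
        assert [x.strand for x in g3.chromosomes["Eu1"]] == \
            [x.strand for x in g.chromosomes["Eu1"]]

    def test_translocation_conserves_length_multiset(self, small_genome):
        g, _ = small_genome
        g2, ev = sd.apply_rearrangement(
            g, "translocation",
            {"chrom_a": "Eu1", "chrom_b": "Eu2", "tail_a": 7, "tail_b": 7})
        assert sorted(len(v) for v in g2.chromosomes.values()) == \
            sorted(len(v) for v in g.chromosomes.values())
        assert ev["kind"] == "reciprocal_translocation"

    def test_fission_splits(self, small_genome):
        g, _ = small_genome
        g2, _ = sd.apply_rearrangement(g, "fission", {"chrom": "Eu1", "at": 15})
        assert g2.n_chromosomes == g.n_chromosomes + 1
        assert len(g2.chromosomes["Eu1_p"]) == 15

    def test_out_of_range_span_rejected(self, small_genome):
        g, _ = small_genome
        with pytest.raises(ValueError):
            sd.apply_rearrangement(g, "inversion",
                                   {"chrom": "Eu1", "lo": 30, "hi": 99})


class TestExpressionSimulation:
    def test_high_concentration_near_archetype(self, rng):
        df, truth = sd.simulate_expression(
            ["g1"] * 1, rng, concentration=1e6,
            implant={"g1": "Balanced"})
        wide = df.groupby("tissue").tpm.mean()
        fr = wide / wide.sum()
        assert np.allclose(fr, 1 / 3, atol=0.01)

    def test_never_all_zero(self, rng):
        df, _ = sd.simulate_expression([f"g{i}" for i in range(200)], rng)
        sums = df.groupby("gene_id").tpm.sum()
        assert (sums > 0).all()

    def test_bad_category_probs_rejected(self, rng):
        with pytest.raises(ValueError):
            sd.simulate_expression(["g1"], rng,
                                   category_probs={"Balanced": 0.5})


class TestContactSimulation:
    def test_symmetric_nonnegative(self, rng):
        cm = sd.simulate_contact_matrix({"c1": 400_000}, 20_000, rng,
                                        depth=1e5)
        assert np.allclose(cm.counts, cm.counts.T)
        assert (cm.counts >= 0).all()

    def test_pure_decay_depends_only_on_distance(self, rng):
        cm = sd.simulate_contact_matrix({"c1": 2_000_000}, 20_000, rng,
                                        depth=5e6)
        n = cm.n_bins
        d1 = np.diagonal(cm.counts, 1).mean()
        d5 = np.diagonal(cm.counts, 5).mean()
        d20 = np.diagonal(cm.counts, 20).mean()
        assert d1 > d5 > d20

    def test_tad_enrichment_at_equal_distance(self, rng):
        tads = [(0, 10), (10, 20)]
        cm = sd.simulate_contact_matrix({"c1": 400_000}, 20_000, rng,
                                        tads=tads, tad_boost=3.0, depth=2e6)
        within = [cm.counts[i, i + 4] for i in range(0, 6)]
        across = [cm.counts[i, i + 4] for i in range(7, 10)]
        assert np.mean(within) > np.mean(across)

    def test_truncated_last_bin_allowed(self, rng):
        cm = sd.simulate_contact_matrix({"c1": 50_000}, 20_000, rng, depth=1e3)
        assert cm.n_bins == 3  # ceil(50/20)


class TestReplayScenarios:
    def test_fig1_truth_counts(self, replay42):
        t = replay42.truth
        assert t.chromosome_counts == {
            "ancestor": 7, "post_gamma": 21, "pre_beta": 8, "post_beta": 16,
            "panax_ancestor": 12, "Ps": 12, "Pn": 12}
        assert t.fusion_events == {"post-gamma": 26, "post-beta": 4}
        assert t.n_region_classes == 42
        assert len(t.rearrangements) == 3

    def test_fig1_junction_adjacencies(self, replay42):
        layers = pd.Series([j["layer"] for j in replay42.truth.junctions["Ps"]])
        counts = layers.value_counts().to_dict()
        # pre-duplication junctions appear once per duplicated copy
        assert counts["post-gamma"] == 52
        assert counts["post-beta"] == 4

    def test_fig1_retention_truth_consistency(self, replay42):
        t = replay42.truth
        n_genes = sum(len(v) for v in t.retention.values())
        assert n_genes == replay42.layouts["Ps"].n_genes()
        assert all(v for v in t.retention.values())

    def test_c6b_replay_counts(self):
        rr = sd.c6b_replay(seed=0)
        assert rr.truth_counts == {"both": 69, "only_a": 98, "only_b": 112}
        assert len(rr.ancestral_loci) == 279
        cls_a, cls_b = sorted(rr.region_classes)
        assert len(rr.region_classes[cls_a]) == 69 + 98
        assert len(rr.region_classes[cls_b]) == 69 + 112

    def test_retention_replay_counts(self):
        rr = sd.retention_replay(seed=0, n_loci=2000, n_high=134)
        per_locus = {}
        for cls, genes in rr.region_classes.items():
            for gid in genes:
                per_locus[rr.locus_of[gid]] = per_locus.get(rr.locus_of[gid], 0) + 1
        n_high = sum(1 for v in per_locus.values() if v > 3)
        assert n_high == 134
        assert len(per_locus) == 2000
        assert all(1 <= v <= 6 for v in per_locus.values())
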