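"""Anchor chaining vs an exhaustive oracle, family filtering, paralog depth."""

import itertools

import numpy as np
import pytest

from paleoshuffle import collinearity as col
from paleoshuffle.io_formats import GeneModel, GenomeLayout, HomologyRecord


def make_layout(name, n_chrom, n_genes):
    genes = [GeneModel(f"{name}c{c}g{i}", f"{name}_{c}", i * 100 + 1,
                       i * 100 + 50, "+")
             for c in range(n_chrom) for i in range(n_genes)]
    return GenomeLayout(name, genes)


def anchors_from_ranks(la, lb, rank_pairs, chrom_a="A_0", chrom_b="B_0"):
    out = []
    for ra, rb in rank_pairs:
        out.append(col.AnchorPair(la.gene_at(chrom_a, ra).gene_id,
                                  lb.gene_at(chrom_b, rb).gene_id,
                                  chrom_a, ra, chrom_b, rb, 100.0))
    return out


class TestFamilyFilter:
    def test_large_clique_removed(self):
        recs = [HomologyRecord(f"g{i}", f"g{j}", 90.0, 1e-20, 100.0)
                for i in range(31) for j in range(i + 1, 31)]
        keep = [HomologyRecord("x1", "x2", 90.0, 1e-20, 100.0)]
        out = col.filter_large_families(recs + keep, max_family_size=30)
        assert out == keep

    def test_infinite_threshold_is_identity(self):
        recs = [HomologyRecord(f"g{i}", f"g{i + 1}", 90.0, 1e-20, 100.0)
                for i in range(50)]
        assert col.filter_large_families(recs, np.inf) == recs

    def test_remaining_families_within_bound(self, rng):
        # random graph; recount the surviving components independently
        genes = [f"g{i}" for i in range(120)]
        recs = [HomologyRecord(*rng.choice(genes, 2, replace=False),
                               90.0, 1e-20, 100.0) for _ in range(200)]
        out = col.filter_large_families(recs, max_family_size=10)
        # independent recount by union-find
        parent = {g: g for g in genes}
        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x
        for r in out:
            parent[find(r.query)] = find(r.subject)
        sizes = {}
        members = {r.query for r in out} | {r.subject for r in out}
        for g in members:
            sizes[find(g)] = sizes.get(find(g), 0) + 1
        assert all(s <= 10 for s in sizes.values())


def brute_force_max_chain(pairs, max_gap):
    """Exhaustive check over all subsets (independent of the DP)."""
    best = 0
    n = len(pairs)
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            ch = [pairs[i] for i in combo]
            ch.sort()
            for sign in (+1, -1):
                ok = all(a1 < a2 and sign * b1 < sign * b2
                         and a2 - a1 <= max_gap + 1
                         and abs(b2 - b1) <= max_gap + 1
                         for (a1, b1), (a2, b2) in zip(ch, ch[1:]))
                if ok:
                    best = max(best, r)
    return best


class TestChaining:
    def setup_method(self):
        self.la = make_layout("A", 1, 200)
        self.lb = make_layout("B", 1, 200)

    def test_perfect_run_single_block(self):
        anchors = anchors_from_ranks(self.la, self.lb,
                                     [(i, i) for i in range(10)])
        blocks = col.detect_collinear_blocks(self.la, self.lb, anchors)
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 10
        assert blocks[0].orientation == "+"

    def test_reversed_run_is_minus_block(self):
        anchors = anchors_from_ranks(self.la, self.lb,
                                     [(i, 20 - i) for i in range(10)])
        blocks = col.detect_collinear_blocks(self.la, self.lb, anchors)
        assert len(blocks) == 1
        assert blocks[0].orientation == "-"

    def test_large_gap_splits_blocks(self):
        runs = [(i, i) for i in range(6)] + \
               [(i + 66, i + 66) for i in range(6)]  # 60-gene gap
        anchors = anchors_from_ranks(self.la, self.lb, runs)
        blocks = col.detect_collinear_blocks(self.la, self.lb, anchors,
                                             max_gap=50)
        assert len(blocks) == 2
        assert all(b.n_anchors == 6 for b in blocks)

    def test_min_anchors_discards_short_chains(self):
        anchors = anchors_from_ranks(self.la, self.lb,
                                     [(i, i) for i in range(4)])
        assert col.detect_collinear_blocks(self.la, self.lb, anchors,
                                           min_anchors=5) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_dp_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        pairs = [(int(rng.integers(0, 60)), int(rng.integers(0, 60)))
                 for _ in range(n)]
        pairs = list(dict.fromkeys(pairs))
        max_gap = 20
        anchors = anchors_from_ranks(self.la, self.lb, pairs)
        blocks = col.detect_collinear_blocks(self.la, self.lb, anchors,
                                             max_gap=max_gap, min_anchors=1)
        got = max((b.n_anchors for b in blocks), default=0)
        assert got == brute_force_max_chain(pairs, max_gap)

    def test_block_invariants_hold_on_random_inputs(self, rng):
        for _ in range(5):
            pairs = {(int(rng.integers(0, 150)), int(rng.integers(0, 150)))
                     for _ in range(80)}
            anchors = anchors_from_ranks(self.la, self.lb, sorted(pairs))
            blocks = col.detect_collinear_blocks(self.la, self.lb, anchors,
                                                 max_gap=30, min_anchors=3)
            used = set()
            for b in blocks:
                b.validate(max_gap=30)  # raises on violation
                for a in b.anchors:
                    key = (a.gene_a, a.gene_b)
                    assert key not in used, "anchor in two blocks"
                    used.add(key)


class TestAncestralGenes:
    def test_min_subgenome_rule(self):
        la = make_layout("A", 1, 50)
        lb = make_layout("B", 1, 50)
        def block(ranks):
            return col.CollinearBlock(
                "A_0", "B_0",
                anchors_from_ranks(la, lb, [(r, r) for r in ranks]), "+")
        blocks_by_unit = {"u1": [block(range(10))],
                          "u2": [block(range(5, 15))],
                          "u3": [block(range(3))]}
        called = col.call_ancestral_genes(blocks_by_unit, min_units=2)
        # ranks 5-9 are shared by u1/u2, ranks 0-2 by u1/u3
        anchored_twice = {lb.gene_at("B_0", r).gene_id
                          for r in [0, 1, 2, 5, 6, 7, 8, 9]}
        assert called == anchored_twice

    def test_fig1_replay_recovers_multicopy_loci(self, replay42, recovery42):
        truth = replay42.truth
        multi = {l for l, copies in truth.retention.items() if len(copies) >= 2}
        lineage = truth.gene_lineage["Ps"]
        anc_layout = replay42.layouts["ancestor"]
        locus_of_anc = {g.gene_id: g.family_id for g in anc_layout.genes()}
        called_loci = {locus_of_anc[g] for g in recovery42["Ps"].ancestral_genes}
        assert len(called_loci & multi) / len(multi) >= 0.95


class TestParalogDepth:
    def test_six_homologs_two_in_four_out(self):
        homs = [(f"h{i}", 100.0 - i) for i in range(6)]
        out = col.classify_paralog_depth(homs)
        assert out["in_paralog"] == ["h0", "h1"]
        assert len(out["out_paralog"]) == 4

    def test_single_homolog(self):
        out = col.classify_paralog_depth([("h0", 50.0)])
        assert out == {"in_paralog": ["h0"], "out_paralog": []}

    def test_empty(self):
        assert col.classify_paralog_depth([]) == {"in_paralog": [],
                                                  "out_paralog": []}

    def test_tie_breaks_lexicographically(self):
        out = col.classify_paralog_depth([("b", 90.0), ("a", 90.0),
                                          ("c", 90.0)])
        assert out["in_paralog"] == ["a", "b"]

    def test_in_paralogs_have_lower_ks_than_out_paralogs(self, replay42,
                                                         recovery42):
        """Top-two-by-similarity homologs are the recent duplicates."""
        ps = recovery42["Ps"]
        lineage = replay42.truth.gene_lineage["Ps"]
        by_locus = {}
        for r in replay42.homology_self["Ps"]:
            by_locus.setdefault(lineage[r.query]["locus"], []).append(r)
        in_ks, out_ks = [], []
        for locus, recs in list(by_locus.items())[:200]:
            genes = {r.query for r in recs} | {r.subject for r in recs}
            if len(genes) < 3:
                continue
            ref = sorted(genes)[0]
            homs = [(r.subject if r.query == ref else r.query, r.bitscore)
                    for r in recs if ref in (r.query, r.subject)]
            cls = col.classify_paralog_depth(homs)
            for h in cls["in_paralog"]:
                k = ps.anchor_ks.get((ref, h), ps.anchor_ks.get((h, ref)))
                if k is not None and np.isfinite(k):
                    in_ks.append(k)
            for h in cls["out_paralog"]:
                k = ps.anchor_ks.get((ref, h), ps.anchor_ks.get((h, ref)))
                if k is not None and np.isfinite(k):
                    out_ks.append(k)
        assert np.median(in_ks) < np.median(out_ks)


class TestBlockStats:
    def _blocks(self, sizes):
        la = make_layout("A", 1, 100)
        lb = make_layout("B", 1, 100)
        return [col.CollinearBlock(
            "A_0", "B_0",
            anchors_from_ranks(la, lb, [(i, i) for i in range(s)]), "+")
            for s in sizes]

    def test_equal_sizes_zero_width(self):
        mean, (lo, hi) = col.block_anchor_stats(self._blocks([10, 10, 10]))
        assert mean == 10 and lo == hi == 10

    def test_two_sizes_arithmetic(self):
        mean, (lo, hi) = col.block_anchor_stats(self._blocks([5, 15]))
        assert mean == 10
        assert hi - mean == pytest.approx(1.96 * 5)

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            col.block_anchor_stats(self._blocks([7]))

    def test_ci_covers_truth(self, rng):
        cover = 0
        for _ in range(60):
            sizes = rng.poisson(17, size=40) + 1
            mean, (lo, hi) = col.block_anchor_stats(self._blocks(sizes.tolist()))
            if lo <= 18 <= hi:  # E[size] = 17 + 1
                cover += 1
        assert cover >= 48  # ~95% nominal; allow slack at 60 trials
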