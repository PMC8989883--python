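"""ICE balancing, compartments, insulation/TADs, topology comparison."""

import numpy as np
import pytest

from paleoshuffle import hic_topology as hic
from paleoshuffle import synthetic_data as sd
from paleoshuffle.io_formats import ContactMatrix
from paleoshuffle.karyotype import Segment, SegmentPainting


def decay_matrix(rng, n=120, res=20_000, depth=1e6, **kw):
    return sd.simulate_contact_matrix({"c1": n * res}, res, rng,
                                      depth=depth, **kw)


class TestIceBalance:
    def test_row_sums_equalized(self, rng):
        cm = decay_matrix(rng)
        bal, _ = hic.ice_balance(cm, tol=1e-5)
        s = np.nansum(bal.counts, axis=1)
        live = s > 0
        assert s[live].std() / s[live].mean() < 1e-5

    def test_reconstruction_identity(self, rng):
        cm = decay_matrix(rng)
        bal, bias = hic.ice_balance(cm)
        recon = bias[:, None] * bias[None, :] * bal.counts
        finite = np.isfinite(recon)
        denom = np.abs(cm.counts[finite]) + 1.0
        assert np.max(np.abs(recon[finite] - cm.counts[finite]) / denom) < 1e-6

    def test_balanced_matrix_is_fixed_point(self, rng):
        cm = decay_matrix(rng)
        bal, _ = hic.ice_balance(cm, min_bin_coverage_quantile=0.0)
        again, bias2 = hic.ice_balance(bal, min_bin_coverage_quantile=0.0)
        finite = np.isfinite(bal.counts) & np.isfinite(again.counts)
        sel = finite & (bal.counts > 0)
        ratio = again.counts[sel] / bal.counts[sel]
        assert np.allclose(ratio, ratio.mean(), rtol=1e-3)

    def test_all_zero_rejected(self):
        cm = ContactMatrix(np.zeros((5, 5)), 10, {"c": 50})
        with pytest.raises(ValueError):
            hic.ice_balance(cm)


class TestObservedOverExpected:
    def test_pure_decay_flattens_to_one(self, rng):
        cm = decay_matrix(rng, n=200, depth=5e6)
        bal, _ = hic.ice_balance(cm)
        oe = hic.observed_over_expected(bal, "c1")
        finite = np.isfinite(oe)
        assert abs(np.nanmedian(oe[finite]) - 1.0) < 0.05
        assert abs(np.nanmean(oe[finite]) - 1.0) < 0.15

    def test_checkerboard_preserved(self, rng):
        n = 200
        comp = {i: ("A" if (i // 20) % 2 == 0 else "B") for i in range(n)}
        cm = decay_matrix(rng, n=n, depth=5e6, compartments=comp,
                          comp_boost=2.0)
        bal, _ = hic.ice_balance(cm)
        oe = hic.observed_over_expected(bal, "c1")
        same, diff = [], []
        for i in range(0, n, 7):
            for j in range(0, n, 7):
                if abs(i - j) < 25 or not np.isfinite(oe[i, j]):
                    continue
                (same if comp[i] == comp[j] else diff).append(oe[i, j])
        assert np.mean(same) > np.mean(diff)

    def test_expected_curve_monotone_for_power_law(self, rng):
        cm = decay_matrix(rng, n=200, depth=5e6)
        bal, _ = hic.ice_balance(cm)
        m = bal.counts
        means = [np.nanmean(np.diagonal(m, d)) for d in range(1, 60)]
        # non-increasing up to sampling noise
        diffs = np.diff(means)
        assert (diffs < 0.05 * np.abs(means[:-1])).mean() > 0.9


class TestCompartments:
    def _checker(self, rng, n=300):
        comp = {i: ("A" if (i // 12) % 2 == 0 else "B") for i in range(n)}
        dens = np.array([1.5 if comp[i] == "A" else 0.7 for i in range(n)])
        cm = decay_matrix(rng, n=n, depth=4e6, compartments=comp,
                          comp_boost=1.8)
        bal, _ = hic.ice_balance(cm)
        oe = hic.observed_over_expected(bal, "c1")
        return comp, dens, oe

    def test_label_accuracy(self, rng):
        comp, dens, oe = self._checker(rng)
        track = hic.call_compartments(oe, "c1", gene_density=dens)
        ok = [track.labels[i] == comp[i] for i in range(len(dens))
              if track.labels[i] != "NA"]
        assert np.mean(ok) >= 0.95

    def test_orientation_invariance(self, rng):
        comp, dens, oe = self._checker(rng)
        t1 = hic.call_compartments(oe, "c1", gene_density=dens)
        t2 = hic.call_compartments(-1.0 * oe * -1.0, "c1", gene_density=dens)
        assert list(t1.labels) == list(t2.labels)

    def test_accuracy_degrades_with_shallower_sequencing(self):
        def acc_at(depth, seed):
            rng = np.random.default_rng(seed)
            n = 300
            comp = {i: ("A" if (i // 12) % 2 == 0 else "B") for i in range(n)}
            dens = np.array([1.5 if comp[i] == "A" else 0.7
                             for i in range(n)])
            cm = decay_matrix(rng, n=n, depth=depth, compartments=comp,
                              comp_boost=1.8)
            bal, _ = hic.ice_balance(cm)
            oe = hic.observed_over_expected(bal, "c1")
            track = hic.call_compartments(oe, "c1", gene_density=dens)
            ok = [track.labels[i] == comp[i] for i in range(n)
                  if track.labels[i] != "NA"]
            return np.mean(ok)
        deep = np.mean([acc_at(4e6, s) for s in range(3)])
        shallow = np.mean([acc_at(2e4, s) for s in range(3)])
        assert deep >= shallow
        assert deep >= 0.95

    def test_degenerate_matrix_all_na(self):
        oe = np.ones((30, 30))
        track = hic.call_compartments(oe, "c1")
        assert set(track.labels) == {"NA"}

    def test_label_sign_convention(self, rng):
        comp, dens, oe = self._checker(rng)
        track = hic.call_compartments(oe, "c1", gene_density=dens)
        for i, lab in enumerate(track.labels):
            if lab == "A":
                assert track.eigenvector[i] > 0
            elif lab == "B":
                assert track.eigenvector[i] <= 0


class TestInsulation:
    def test_uniform_matrix_scores_zero(self):
        n = 60
        cm = ContactMatrix(np.ones((n, n)), 20_000, {"c": n * 20_000})
        tr = hic.insulation_score(cm, "c", window=100_000)
        finite = np.isfinite(tr.score)
        assert finite.sum() == n - 2 * tr.window_bins
        assert np.allclose(tr.score[finite], 0.0)

    def test_two_block_matrix_minimum_at_junction(self):
        n = 60
        m = np.full((n, n), 0.2)
        m[:30, :30] = 1.0
        m[30:, 30:] = 1.0
        cm = ContactMatrix(m, 20_000, {"c": n * 20_000})
        tr = hic.insulation_score(cm, "c", window=100_000)
        assert np.nanargmin(tr.score) in (29, 30)

    def test_window_too_small_rejected(self):
        cm = ContactMatrix(np.ones((10, 10)), 20_000, {"c": 200_000})
        with pytest.raises(ValueError):
            hic.insulation_score(cm, "c", window=20_000)


class TestCallTads:
    def test_no_minima_gives_single_tad(self):
        track = hic.InsulationTrack("c", np.zeros(50), 5)
        tads = hic.call_tads(track, resolution=20_000)
        assert len(tads) == 1
        assert (tads[0].start_bin, tads[0].end_bin) == (0, 50)

    def test_tads_tile_without_overlap(self, rng):
        tads_truth = sd._random_partition(400, 25, 45, rng)
        cm = decay_matrix(rng, n=400, depth=4e6, tads=tads_truth,
                          tad_boost=3.0)
        bal, _ = hic.ice_balance(cm)
        tr = hic.insulation_score(bal, "c1")
        tads = hic.call_tads(tr, resolution=20_000)
        for t1, t2 in zip(tads, tads[1:]):
            assert t1.end_bin == t2.start_bin
        assert tads[0].start_bin == 0 and tads[-1].end_bin == 400

    def test_boundary_recovery(self, rng):
        n = 500
        truth = sd._random_partition(n, 25, 45, rng)
        cm = decay_matrix(rng, n=n, depth=5e6, tads=truth, tad_boost=3.0)
        bal, _ = hic.ice_balance(cm)
        tr = hic.insulation_score(bal, "c1")
        called = hic.call_tads(tr, resolution=20_000)
        tb = sorted({t[0] for t in truth if 0 < t[0] < n})
        cb = sorted({t.start_bin for t in called if t.start_bin > 0})
        recall = sum(any(abs(b - c) <= 1 for c in cb) for b in tb) / len(tb)
        precision = sum(any(abs(b - c) <= 1 for b in tb) for c in cb) / len(cb)
        assert recall >= 0.9
        assert precision >= 0.8


class TestRegionTopology:
    N_ANC = 6
    BINS_PER_REGION = 30
    RES = 20_000

    def _setup(self, rng, boost):
        """Twelve single-region chromosomes: six ancestors x two duplication
        copies; same-ancestor chromosome pairs optionally enriched.
        One region per chromosome keeps region-pair contrasts free of the
        intra-chromosomal distance confound."""
        q, res = self.BINS_PER_REGION, self.RES
        sizes, segs, groups = {}, [], {}
        k = 0
        for b in "ab":
            for a in range(self.N_ANC):
                chrom = f"c{a}{b}"
                sizes[chrom] = q * res
                segs.append(Segment(
                    chrom=chrom, start=0, end=q, anc_chrom=f"Eu{a + 1}",
                    anc_start=0, anc_end=q, orientation="+",
                    gene_ids=[f"g{chrom}_{i}" for i in range(q)],
                    gamma="A", beta=b, bp_start=1, bp_end=q * res))
                for i in range(q):
                    groups[k * q + i] = f"Eu{a + 1}"
                k += 1
        cm = sd.simulate_contact_matrix(sizes, res, rng, depth=8e6,
                                        bin_groups=groups, group_boost=boost)
        bal, _ = hic.ice_balance(cm)
        return bal, SegmentPainting(segs)

    def test_same_ancestor_enrichment_detected(self, rng):
        bal, painting = self._setup(rng, boost=2.0)
        out = hic.compare_region_topology(bal, painting)
        assert out["within_ancestor_mean"] > out["between_ancestor_mean"]
        assert out["p_value"] < 0.01

    def test_null_has_no_contrast(self):
        diffs, pvals = [], []
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            bal, painting = self._setup(rng, boost=1.0)
            out = hic.compare_region_topology(bal, painting)
            diffs.append(out["within_ancestor_mean"]
                         - out["between_ancestor_mean"])
            pvals.append(out["p_value"])
        assert abs(np.mean(diffs)) < 0.05
        assert min(pvals) > 0.001  # no spurious strong signal

    def test_switch_junction_overlap_reported(self, rng):
        bal, painting = self._setup(rng, boost=1.0)
        n = bal.n_bins
        comp = {i: ("A" if i < n // 2 else "B") for i in range(n)}
        out = hic.compare_region_topology(
            bal, painting, compartment_labels=comp, junction_bins=[n // 2])
        assert out["switch_junction_overlap"] == 1.0


class TestProfileOverTads:
    def test_interior_hypermethylation_recovered(self, rng):
        n, res = 200, 20_000
        tad_b = sd._random_partition(n, 20, 30, rng)
        cm = sd.simulate_contact_matrix({"c1": n * res}, res, rng, depth=1e5)
        tads = [hic.TADInterval("c1", lo, hi, 0.5, 0.5) for lo, hi in tad_b]
        gene_bins = {f"g{i}": i for i in range(n)}
        boundary = set()
        for lo, hi in tad_b:
            boundary |= {lo - 1, lo, lo + 1, hi - 2, hi - 1, hi}
        zones = {f"g{i}": ("border" if i in boundary else "interior")
                 for i in range(n)}
        mC = dict(zip(zones, sd.simulate_methylation(zones, rng).mC))
        tpm = {g: (5.0 if z == "interior" else 20.0)
               for g, z in zones.items()}
        out = hic.profile_over_tads(tads, cm, gene_bins, mC, tpm)
        assert out["interior_mC"] > out["border_mC"]
        assert out["interior_tpm"] < out["border_tpm"]

    def test_every_gene_in_exactly_one_zone(self, rng):
        n, res = 100, 20_000
        cm = sd.simulate_contact_matrix({"c1": n * res}, res, rng, depth=1e4)
        tads = [hic.TADInterval("c1", 0, 50, 0.5, 0.5),
                hic.TADInterval("c1", 50, 100, 0.5, 0.5)]
        gene_bins = {f"g{i}": i for i in range(n)}
        out = hic.profile_over_tads(tads, cm, gene_bins, {}, {})
        assert set(out["zones"]) == set(gene_bins)
        assert all(z in ("interior", "border", "outside")
                   for z in out["zones"].values())

    def test_no_genes_rejected(self, rng):
        cm = sd.simulate_contact_matrix({"c1": 100_000}, 20_000, rng,
                                        depth=1e3)
        with pytest.raises(ValueError):
            hic.profile_over_tads([], cm, {}, {}, {})
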