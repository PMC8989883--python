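"""End-to-end history recovery: collinearity -> painting -> Ks layers ->
copy labels -> junction/karyotype counts -> retention statistics.

This is the analysis side of the replay scenarios: it consumes only the
emitted data (layouts, homology tables, coding sequences) and never touches
the generator's truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from . import collinearity as col
from . import duplicate_evolution as dup
from . import karyotype as kt
from . import wgd_dating as wd
from .io_formats import GenomeLayout, HomologyRecord
from .synthetic_data import Fig1Replay

log = logging.getLogger("paleoshuffle")

__all__ = ["SpeciesAnalysis", "analyze_species", "analyze_genome",
           "recover_history"]


@dataclass
class SpeciesAnalysis:
    species: str
    painting: kt.SegmentPainting
    blocks_vs_ancestor: list
    self_blocks: list
    mixture: wd.KsMixture
    block_event: dict[int, str]
    anchor_ks: dict[tuple[str, str], float]
    junction_counts: dict[str, int]
    junction_events: list
    region_classes: dict[tuple, list[str]]
    karyotype_counts: dict[str, int]
    ancestral_genes: set[str]
    retention: Optional[dup.RetentionMatrix] = None


def _anchor_ks_values(records: list[HomologyRecord],
                      seqs: Mapping[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """NG86 Ks for every homolog pair (vectorized)."""
    pairs = [(r.query, r.subject) for r in records]
    if not pairs:
        return {}
    a = np.stack([seqs[q] for q, _ in pairs])
    b = np.stack([seqs[s] for _, s in pairs])
    ks = wd.ks_ng86_many(a, b)
    return {p: float(k) for p, k in zip(pairs, ks)}


def analyze_species(dataset: Fig1Replay, species: str, max_gap: int = 50,
                    min_anchors: int = 5, min_segment_genes: int = 5,
                    seed: int = 0) -> SpeciesAnalysis:
    """Recover the polyploidy history of one simulated species from its
    emitted layout, homology tables and coding sequences."""
    return analyze_genome(
        species=species,
        layout=dataset.layouts[species],
        ancestor=dataset.layouts["ancestor"],
        seqs=dataset.seqs[species],
        homology_vs_ancestor=dataset.homology_vs_ancestor[species],
        homology_self=dataset.homology_self[species],
        max_gap=max_gap, min_anchors=min_anchors,
        min_segment_genes=min_segment_genes, seed=seed)


def analyze_genome(species: str, layout: GenomeLayout, ancestor: GenomeLayout,
                   seqs: Mapping[str, np.ndarray],
                   homology_vs_ancestor: list[HomologyRecord],
                   homology_self: list[HomologyRecord], max_gap: int = 50,
                   min_anchors: int = 5, min_segment_genes: int = 5,
                   seed: int = 0) -> SpeciesAnalysis:
    """History recovery from explicit inputs (layouts, homology tables,
    codon-index sequences)."""
    # --- painting against the ancestor -------------------------------------
    hom_anc = col.filter_large_families(homology_vs_ancestor)
    anchors_anc = col.build_anchors(hom_anc, layout, ancestor)
    blocks_anc = col.detect_collinear_blocks(layout, ancestor, anchors_anc,
                                             max_gap=max_gap,
                                             min_anchors=min_anchors)
    painting = kt.paint_genome(layout, ancestor, blocks_anc,
                               min_segment_genes=min_segment_genes,
                               max_gap=max_gap)

    # --- Ks layers from the self-comparison --------------------------------
    hom_self = col.filter_large_families(homology_self)
    anchors_self = col.build_anchors(hom_self, layout, layout)
    self_blocks = col.detect_collinear_blocks(layout, layout, anchors_self,
                                              max_gap=max_gap,
                                              min_anchors=min_anchors)
    anchor_ks = _anchor_ks_values(hom_self, seqs)
    block_medians = []
    datable = []
    for blk in self_blocks:
        vals = [anchor_ks.get((a.gene_a, a.gene_b),
                              anchor_ks.get((a.gene_b, a.gene_a), np.nan))
                for a in blk.anchors]
        try:
            med = wd.block_median_ks(vals)
        except ValueError:
            blk.median_ks = None
            continue
        blk.median_ks = med
        block_medians.append(med)
        datable.append(blk)
    # WGD peaks are dated on block medians (the per-anchor Ks distribution
    # is heavy-tailed; the per-block median is the dating statistic)
    fit_values = block_medians if len(block_medians) >= 50 \
        else list(anchor_ks.values())
    mixture = wd.fit_ks_mixture(fit_values, seed=seed)
    assignments = wd.assign_blocks_to_events(block_medians, mixture)
    # the two dominant peaks carry the two WGD layers; the lower-mean one is
    # the recent duplication (beta), the higher the triplication (gamma).
    # Minor components (spurious micro-peaks) are folded into the nearer of
    # the two dominant means.
    dom = np.argsort(mixture.weights)[-2:] if mixture.k >= 2 else [0, 0]
    beta_comp = dom[np.argmin(mixture.means[dom])]
    gamma_comp = dom[np.argmax(mixture.means[dom])]
    block_event = {}
    for blk, (comp, _post) in zip(datable, assignments):
        if comp not in (beta_comp, gamma_comp):
            comp = beta_comp if (abs(mixture.means[comp] - mixture.means[beta_comp])
                                 <= abs(mixture.means[comp] - mixture.means[gamma_comp])) \
                else gamma_comp
        block_event[blk.block_id] = "beta" if comp == beta_comp else "gamma"

    # --- copy labels, junctions, karyotypes --------------------------------
    kt.resolve_copy_labels(painting, self_blocks, block_event)
    junction_counts, junction_events = kt.count_fusion_junctions(painting)
    region_classes = kt.enumerate_region_classes(painting)
    karyo = {}
    for layer in ("ancestor", "post-gamma", "pre-beta", "extant"):
        try:
            karyo[layer] = kt.reconstruct_karyotype(painting, layer)[0]
        except ValueError as e:
            log.warning("reconstruct_karyotype[%s] failed: %s", layer, e)
            karyo[layer] = -1

    # --- ancestral genes + retention ---------------------------------------
    seg_class_of_block = {}
    for seg in painting.all_segments():
        if seg.block_id is not None:
            seg_class_of_block[seg.block_id] = seg.full_class()
    blocks_by_unit: dict[str, list] = {}
    for blk in blocks_anc:
        cls = _class_of_block(blk, painting)
        if cls is not None:
            blocks_by_unit.setdefault(str(cls), []).append(blk)
    ancestral = col.call_ancestral_genes(blocks_by_unit, min_units=2)

    locus_of = {}
    anc_locus = {g.gene_id: g.family_id for g in ancestor.genes()}
    gene_to_anc: dict[str, str] = {}
    for blk in blocks_anc:
        for a in blk.anchors:
            gene_to_anc[a.gene_a] = a.gene_b
    for gid, anc_gid in gene_to_anc.items():
        locus_of[gid] = anc_locus[anc_gid]
    retention = dup.build_retention_matrix(region_classes, locus_of)

    return SpeciesAnalysis(species, painting, blocks_anc, self_blocks, mixture,
                           block_event, anchor_ks, junction_counts,
                           junction_events, region_classes, karyo, ancestral,
                           retention)


def _class_of_block(blk, painting: kt.SegmentPainting) -> Optional[tuple]:
    """Region class of the painting segment an extant-vs-ancestor block
    landed in (best rank-span overlap on the extant side)."""
    lo, hi = blk.span_a()
    best, best_ov = None, 0
    for seg in painting.all_segments():
        if seg.chrom != blk.chrom_a:
            continue
        ov = max(0, min(hi, seg.end) - max(lo, seg.start))
        if ov > best_ov:
            best, best_ov = seg.full_class(), ov
    return best


def recover_history(dataset: Fig1Replay, seed: int = 0) -> dict:
    """Full recovery over both species; returns the headline quantities the
    replay scenario implants (chromosome counts per layer, fusion events per
    layer, region classes, extant rearrangement events)."""
    ps = analyze_species(dataset, "Ps", seed=seed)
    pn = analyze_species(dataset, "Pn", seed=seed)
    events = kt.detect_rearrangements(ps.painting, pn.painting)
    n_inv = sum(1 for e in events if e.kind == "inversion")
    n_tra = sum(1 for e in events if e.kind == "reciprocal_translocation")
    return {
        "Ps": ps,
        "Pn": pn,
        "n_region_classes": len(ps.region_classes),
        "post_gamma_chromosomes": ps.karyotype_counts["post-gamma"],
        "pre_beta_chromosomes": ps.karyotype_counts["pre-beta"],
        "extant_chromosomes": ps.karyotype_counts["extant"],
        "ancestor_chromosomes": ps.karyotype_counts["ancestor"],
        "post_gamma_fusions": ps.junction_counts["post-gamma"],
        "post_beta_fusions": ps.junction_counts["post-beta"],
        "rearrangement_events": events,
        "n_inversions": n_inv,
        "n_reciprocal_translocations": n_tra,
        "n_rearrangements": len(events),
    }
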