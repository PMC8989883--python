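"""Chromosome painting by ancestral origin and karyotype-history recovery.

An extant chromosome is decomposed into segments, each tracing back to one
ancestral chromosome and (once Ks-layer information is available) to one
triplication copy (A/B/C) and one duplication copy (a/b). Fusion junctions
are adjacencies between segments of different ancestral origin; the layer of
a junction is resolved by multiplicity: an adjacency created before the
duplication is inherited by both duplicated copies and therefore observed
twice in the extant genome, while an adjacency created after it is observed
once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .collinearity import CollinearBlock
from .io_formats import GenomeLayout

log = logging.getLogger("paleoshuffle")

__all__ = [
    "Segment",
    "SegmentPainting",
    "KaryotypeEvent",
    "paint_genome",
    "resolve_copy_labels",
    "count_fusion_junctions",
    "reconstruct_karyotype",
    "detect_rearrangements",
    "enumerate_region_classes",
    "assign_subgenomes",
]


@dataclass
class Segment:
    chrom: str
    start: int                 # rank span, 0-based half-open
    end: int
    anc_chrom: str
    anc_start: int
    anc_end: int
    orientation: str
    gene_ids: list[str] = field(default_factory=list)   # anchored extant genes
    anc_gene_ids: list[str] = field(default_factory=list)
    anchor_ranks: list[tuple[int, int]] = field(default_factory=list)
    gamma: str = ""            # triplication copy label, resolved later
    beta: str = ""             # duplication copy label
    bp_start: int = 0          # 1-based bp of first gene (for BED emission)
    bp_end: int = 0
    block_id: Optional[int] = None

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def origin_class(self) -> tuple:
        """(ancestral chromosome, triplication copy) — the pre-duplication
        chromosome class this segment derives from."""
        return (self.anc_chrom, self.gamma)

    def full_class(self) -> tuple:
        return (self.anc_chrom, self.gamma, self.beta)

    def class_name(self) -> str:
        if self.gamma or self.beta:
            return f"{self.anc_chrom}:{self.gamma}{self.beta}"
        return self.anc_chrom

    def anc_overlap(self, other: "Segment") -> int:
        if self.anc_chrom != other.anc_chrom:
            return 0
        return max(0, min(self.anc_end, other.anc_end)
                   - max(self.anc_start, other.anc_start))


class SegmentPainting:
    def __init__(self, segments: Sequence[Segment]):
        self._by_chrom: dict[str, list[Segment]] = {}
        for s in segments:
            self._by_chrom.setdefault(s.chrom, []).append(s)
        for c in self._by_chrom:
            self._by_chrom[c].sort(key=lambda s: s.start)
            spans = [(s.start, s.end) for s in self._by_chrom[c]]
            for (a, b), (x, y) in zip(spans, spans[1:]):
                if x < b:
                    raise ValueError(f"overlapping segments on {c}: "
                                     f"[{a},{b}) and [{x},{y})")

    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def segments_of(self, chrom: str) -> list[Segment]:
        return self._by_chrom[chrom]

    def all_segments(self) -> list[Segment]:
        return [s for c in self.chromosomes() for s in self._by_chrom[c]]

    @property
    def n_chromosomes(self) -> int:
        return len(self._by_chrom)


@dataclass
class KaryotypeEvent:
    kind: str     # fusion | fission | inversion | reciprocal_translocation
    layer: str    # post-gamma | post-beta | extant | unassigned
    loci: dict


# ---------------------------------------------------------------------------
# painting
# ---------------------------------------------------------------------------

def paint_genome(extant: GenomeLayout, ancestor: GenomeLayout,
                 blocks: Sequence[CollinearBlock], min_segment_genes: int = 5,
                 max_gap: int = 50) -> SegmentPainting:
    """Project extant-vs-ancestor collinear blocks to ancestral-origin
    segments; merge adjacent same-origin same-orientation segments closer
    than ``max_gap`` genes (on both coordinate systems); drop segments with
    fewer than ``min_segment_genes`` anchored genes."""
    if not blocks:
        log.warning("paint_genome: no blocks; empty painting")
        return SegmentPainting([])
    segs: list[Segment] = []
    for blk in blocks:
        sa, ea = blk.span_a()
        sb, eb = blk.span_b()
        segs.append(Segment(
            chrom=blk.chrom_a, start=sa, end=ea, anc_chrom=blk.chrom_b,
            anc_start=sb, anc_end=eb, orientation=blk.orientation,
            gene_ids=[a.gene_a for a in blk.anchors],
            anc_gene_ids=[a.gene_b for a in blk.anchors],
            anchor_ranks=[(a.rank_a, a.rank_b) for a in blk.anchors],
            block_id=blk.block_id))
    by_chrom: dict[str, list[Segment]] = {}
    for s in segs:
        by_chrom.setdefault(s.chrom, []).append(s)
    merged: list[Segment] = []
    for chrom in sorted(by_chrom):
        cur: Optional[Segment] = None
        for s in _resolve_overlaps(by_chrom[chrom]):
            if cur is not None and _mergeable(cur, s, max_gap):
                cur.end = s.end
                cur.anc_start = min(cur.anc_start, s.anc_start)
                cur.anc_end = max(cur.anc_end, s.anc_end)
                cur.gene_ids += s.gene_ids
                cur.anc_gene_ids += s.anc_gene_ids
                cur.anchor_ranks += s.anchor_ranks
            else:
                if cur is not None:
                    merged.append(cur)
                cur = s
        if cur is not None:
            merged.append(cur)
    kept = [s for s in merged if s.n_genes >= min_segment_genes]
    for s in kept:
        first = extant.gene_at(s.chrom, s.start)
        last = extant.gene_at(s.chrom, s.end - 1)
        s.bp_start, s.bp_end = first.start, last.end
    log.info("paint_genome: %d blocks -> %d segments (%d dropped short)",
             len(blocks), len(kept), len(merged) - len(kept))
    return SegmentPainting(kept)


def _resolve_overlaps(segs: list[Segment]) -> list[Segment]:
    """Split rank-overlapping segments: an interior inversion chains as one
    long block plus a short reversed block inside its span; the long block
    is cut around the short one (stray anchors inside the cut are dropped)."""
    segs = list(segs)
    changed = True
    while changed:
        changed = False
        segs.sort(key=lambda s: (s.start, s.end))
        for i in range(len(segs) - 1):
            a, b = segs[i], segs[i + 1]
            if b.start < a.end:
                big, small = (a, b) if a.n_genes >= b.n_genes else (b, a)
                segs.remove(big)
                segs.extend(_split_segment(big, small.start, small.end))
                changed = True
                break
    return segs


def _split_segment(seg: Segment, lo: int, hi: int) -> list[Segment]:
    pieces = []
    for keep in (lambda r: r < lo, lambda r: r >= hi):
        sel = [k for k, (ra, _) in enumerate(seg.anchor_ranks) if keep(ra)]
        if not sel:
            continue
        ra = [seg.anchor_ranks[k][0] for k in sel]
        rb = [seg.anchor_ranks[k][1] for k in sel]
        pieces.append(Segment(
            chrom=seg.chrom, start=min(ra), end=max(ra) + 1,
            anc_chrom=seg.anc_chrom, anc_start=min(rb), anc_end=max(rb) + 1,
            orientation=seg.orientation,
            gene_ids=[seg.gene_ids[k] for k in sel],
            anc_gene_ids=[seg.anc_gene_ids[k] for k in sel],
            anchor_ranks=[seg.anchor_ranks[k] for k in sel],
            block_id=seg.block_id))
    return pieces


def _mergeable(a: Segment, b: Segment, max_gap: int) -> bool:
    if a.anc_chrom != b.anc_chrom or a.orientation != b.orientation:
        return False
    if b.start - a.end > max_gap:
        return False
    # ancestral spans must continue in the direction of the orientation
    if a.orientation == "+":
        gap = b.anc_start - a.anc_end
    else:
        gap = a.anc_start - b.anc_end
    return -max_gap <= gap <= max_gap


# ---------------------------------------------------------------------------
# copy-label resolution from Ks layers
# ---------------------------------------------------------------------------

def resolve_copy_labels(painting: SegmentPainting,
                        self_blocks: Sequence[CollinearBlock],
                        block_event: Mapping[int, str]) -> None:
    """Resolve triplication (A/B/C) and duplication (a/b) copy labels.

    ``block_event`` maps self-comparison block ids to "beta" (younger peak)
    or "gamma" (older peak), from the fitted Ks mixture. Duplication-layer
    blocks link the two copies of one pre-duplication chromosome; connected
    components of that link graph are the triplication copy classes, and the
    bipartition of each component gives the two duplication sides. Labels
    are deterministic: classes of one ancestral chromosome are lettered
    A/B/C by their smallest (chrom, start) member; the side holding that
    member is 'a'. Mutates the painting's segments in place.
    """
    segments = painting.all_segments()
    # interval index: (chrom, rank) -> segment, for anchor-level linking
    # (one duplication-layer block can span several fused segments, so the
    # link graph is built per anchor, not per block)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, s in enumerate(segments):
        by_chrom.setdefault(s.chrom, []).append((s.start, s.end, i))
    for c in by_chrom:
        by_chrom[c].sort()

    def locate(chrom: str, rank: int) -> Optional[int]:
        for lo, hi, i in by_chrom.get(chrom, ()):
            if lo <= rank < hi:
                return i
        return None

    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(len(segments)))
    for blk in self_blocks:
        if block_event.get(blk.block_id) != "beta":
            continue
        for a in blk.anchors:
            ia = locate(a.chrom_a, a.rank_a)
            ib = locate(a.chrom_b, a.rank_b)
            if ia is None or ib is None or ia == ib:
                continue
            if segments[ia].anc_chrom != segments[ib].anc_chrom:
                continue
            if g.has_edge(ia, ib):
                g[ia][ib]["weight"] += 1
            else:
                g.add_edge(ia, ib, weight=1)
    # prune incidental one-anchor links (misassigned homologs)
    g.remove_edges_from([(u, v) for u, v, w in g.edges(data="weight") if w < 3])

    by_anc: dict[str, list[set]] = {}
    for comp in nx.connected_components(g):
        anc = segments[min(comp)].anc_chrom
        by_anc.setdefault(anc, []).append(comp)
    for anc in by_anc:
        comps = sorted(by_anc[anc],
                       key=lambda c: (min(segments[i].anc_start for i in c),
                                      -max(segments[i].anc_end for i in c),
                                      min((segments[i].chrom, segments[i].start)
                                          for i in c)))
        # a triplication copy broken apart by later fusions appears as
        # several disjoint-span components; tile components into copies so
        # each copy covers the ancestral chromosome without overlap (the
        # head/tail pairing within one copy is not identifiable from Ks and
        # any consistent tiling yields the same class and junction counts)
        groups: list[list[set]] = []
        spans: list[list[tuple[int, int]]] = []
        for comp in comps:
            lo = min(segments[i].anc_start for i in comp)
            hi = max(segments[i].anc_end for i in comp)
            tol = max(5, (hi - lo) // 4)
            placed = False
            for gi, cover in enumerate(spans):
                if all(min(hi, h) - max(lo, l) <= tol for l, h in cover):
                    groups[gi].append(comp)
                    cover.append((lo, hi))
                    placed = True
                    break
            if not placed:
                groups.append([comp])
                spans.append([(lo, hi)])
        groups.sort(key=lambda gr: min((segments[i].chrom, segments[i].start)
                                       for c in gr for i in c))
        for letter, group in zip("ABCDEFGHIJ", groups):
            for comp in group:
                nodes = sorted(comp)
                if len(nodes) == 1:
                    segments[nodes[0]].gamma = letter
                    segments[nodes[0]].beta = "a"
                    continue
                # bipartition by BFS two-coloring over duplication links
                color: dict[int, int] = {}
                sub = g.subgraph(comp)
                start = min(comp, key=lambda i: (segments[i].chrom,
                                                 segments[i].start))
                color[start] = 0
                stack = [start]
                while stack:
                    u = stack.pop()
                    for v in sub.neighbors(u):
                        if v not in color:
                            color[v] = 1 - color[u]
                            stack.append(v)
                for i in comp:
                    segments[i].gamma = letter
                    segments[i].beta = "a" if color.get(i, 0) == 0 else "b"


# ---------------------------------------------------------------------------
# fusion junctions
# ---------------------------------------------------------------------------

def _junction_list(painting: SegmentPainting) -> list[dict]:
    out = []
    for chrom in painting.chromosomes():
        segs = painting.segments_of(chrom)
        for left, right in zip(segs, segs[1:]):
            if left.origin_class() == right.origin_class():
                continue  # homologous adjacency (e.g. inversion flank)
            out.append({"chrom": chrom, "pos": right.start,
                        "left": left, "right": right})
    return out


def count_fusion_junctions(painting: SegmentPainting
                           ) -> tuple[dict[str, int], list[KaryotypeEvent]]:
    """Count fusion events per WGD layer from heterologous adjacencies.

    Junctions sharing the same unordered pair of (ancestral chromosome,
    triplication copy) origin classes — with overlapping flank spans — are
    one fusion event. Events observed in both duplication copies are
    attributed to the older (post-triplication) layer; events observed once
    to the post-duplication layer. Unresolved copy labels yield layer
    "unassigned".
    """
    junctions = _junction_list(painting)
    groups: dict[tuple, list[dict]] = {}
    for j in junctions:
        key = frozenset((j["left"].origin_class(), j["right"].origin_class()))
        groups.setdefault(key, []).append(j)
    # sub-split class-pair groups whose flank spans do not overlap
    events: list[KaryotypeEvent] = []
    counts = {"post-gamma": 0, "post-beta": 0, "unassigned": 0}
    for key, js in groups.items():
        clusters: list[list[dict]] = []
        for j in js:
            placed = False
            for cl in clusters:
                if _same_event(cl[0], j):
                    cl.append(j)
                    placed = True
                    break
            if not placed:
                clusters.append([j])
        for cl in clusters:
            unresolved = any(not j["left"].gamma or not j["right"].gamma
                             for j in cl)
            if unresolved:
                layer = "unassigned"
            else:
                layer = "post-gamma" if len(cl) >= 2 else "post-beta"
            counts[layer] += 1
            events.append(KaryotypeEvent(
                "fusion", layer,
                {"junctions": [{"chrom": j["chrom"], "pos": j["pos"],
                                "left_class": j["left"].class_name(),
                                "right_class": j["right"].class_name()}
                               for j in cl]}))
    log.info("count_fusion_junctions: %s", counts)
    return counts, events


def _same_event(j1: dict, j2: dict) -> bool:
    """Same class pair assumed; require both flank spans to overlap."""
    def flank(j, anc_gamma):
        for side in ("left", "right"):
            if j[side].origin_class() == anc_gamma:
                return j[side]
        return None
    for cls in (j1["left"].origin_class(), j1["right"].origin_class()):
        f1, f2 = flank(j1, cls), flank(j2, cls)
        if f1 is None or f2 is None or f1.anc_overlap(f2) == 0:
            return False
    return True


# ---------------------------------------------------------------------------
# karyotype reconstruction across layers
# ---------------------------------------------------------------------------

def reconstruct_karyotype(painting: SegmentPainting, layer: str
                          ) -> tuple[int, list[str]]:
    """Infer the chromosome count (and per-chromosome origin composition) of
    an ancestral layer from a labeled painting of the extant genome.

    layers: "extant" (count as painted), "pre-beta" (cut at post-duplication
    junctions, collapse duplication-paired units of identical origin
    composition), "post-gamma" (count distinct (ancestral chromosome,
    triplication copy) classes), "ancestor" (distinct ancestral chromosomes).
    """
    if layer == "extant":
        comp = ["+".join(s.class_name() for s in painting.segments_of(c))
                for c in painting.chromosomes()]
        return painting.n_chromosomes, comp
    if layer == "post-gamma":
        classes = sorted({s.origin_class() for s in painting.all_segments()})
        return len(classes), [f"{a}:{g}" for a, g in classes]
    if layer == "ancestor":
        ancs = sorted({s.anc_chrom for s in painting.all_segments()})
        return len(ancs), ancs
    if layer != "pre-beta":
        raise ValueError(f"unknown layer {layer!r}")

    _, events = count_fusion_junctions(painting)
    beta_cuts: dict[str, set[int]] = {}
    for ev in events:
        if ev.layer == "post-beta":
            for j in ev.loci["junctions"]:
                beta_cuts.setdefault(j["chrom"], set()).add(j["pos"])
    units: list[tuple[tuple, ...]] = []
    for chrom in painting.chromosomes():
        cuts = sorted(beta_cuts.get(chrom, set()))
        cur: list[Segment] = []
        for s in painting.segments_of(chrom):
            if cuts and s.start >= cuts[0]:
                if cur:
                    units.append(tuple(x.origin_class() for x in cur))
                cur = []
                cuts = cuts[1:]
            cur.append(s)
        if cur:
            units.append(tuple(x.origin_class() for x in cur))
    # collapse duplication-paired units of identical composition (either
    # orientation); homologous-adjacency splits (inversions) make repeated
    # classes within a unit harmless because composition uses the class set
    def signature(u):
        dedup = tuple(dict.fromkeys(u))
        return min(dedup, dedup[::-1])
    groups: dict[tuple, int] = {}
    for u in units:
        groups[signature(u)] = groups.get(signature(u), 0) + 1
    bad = [sig for sig, n in groups.items() if n not in (1, 2)]
    if bad:
        raise ValueError(f"inconsistent duplication pairing for units: {bad}")
    comp = ["+".join(f"{a}:{g}" for a, g in sig) for sig in sorted(groups)]
    return len(groups), comp


# ---------------------------------------------------------------------------
# rearrangement detection between two paintings
# ---------------------------------------------------------------------------

def _coverage_similarity(segs_a: Sequence[Segment], segs_b: Sequence[Segment]
                         ) -> int:
    sim = 0
    for sa in segs_a:
        for sb in segs_b:
            sim += sa.anc_overlap(sb)
    return sim


def _match_chromosomes(pa: SegmentPainting, pb: SegmentPainting
                       ) -> dict[str, str]:
    pairs = []
    for ca in pa.chromosomes():
        for cb in pb.chromosomes():
            s = _coverage_similarity(pa.segments_of(ca), pb.segments_of(cb))
            if s > 0:
                pairs.append((-s, ca, cb))
    pairs.sort()
    used_a, used_b, match = set(), set(), {}
    for _, ca, cb in pairs:
        if ca in used_a or cb in used_b:
            continue
        match[ca] = cb
        used_a.add(ca)
        used_b.add(cb)
    return match


def detect_rearrangements(painting_a: SegmentPainting,
                          painting_b: SegmentPainting,
                          min_segment_genes: int = 5) -> list[KaryotypeEvent]:
    """Structural differences between two paintings of a common reference:
    inversions (same origin locus, flipped orientation) and reciprocal
    translocations (terminal origin-segments exchanged between two
    chromosomes). Self-comparison yields no events.

    Cross-species segment correspondence is by ancestral chromosome and
    span overlap within matched chromosomes: triplication/duplication copy
    letters are species-local and cannot be compared directly."""
    match = _match_chromosomes(painting_a, painting_b)

    inversions: list[dict] = []
    displaced: list[dict] = []   # {species_side, chrom, cls, span}
    for ca, cb in match.items():
        segs_a, segs_b = painting_a.segments_of(ca), painting_b.segments_of(cb)
        for (side, own, other, own_chrom) in (("a", segs_a, segs_b, ca),
                                              ("b", segs_b, segs_a, cb)):
            for s in own:
                same_cov: list[tuple[int, int]] = []
                opp_cov: list[tuple[int, int]] = []
                for t in other:
                    # corresponding segments share the ancestral chromosome
                    # AND the extant position: matched chromosomes are the
                    # same coordinate system, and a chromosome can carry two
                    # copies of one ancestral chromosome at different spots
                    rank_ov = min(s.end, t.end) - max(s.start, t.start)
                    if rank_ov <= 0:
                        continue
                    ov = s.anc_overlap(t)  # zero unless same ancestral chrom
                    if ov < min_segment_genes:
                        continue
                    lo = max(s.anc_start, t.anc_start)
                    hi = min(s.anc_end, t.anc_end)
                    (same_cov if t.orientation == s.orientation
                     else opp_cov).append((lo, hi))
                # flipped only where no same-orientation partner covers;
                # detected from whichever painting carries the flipped
                # segment, then deduplicated by class + span
                for lo, hi in opp_cov:
                    for ilo, ihi in _subtract_span((lo, hi), same_cov):
                        if ihi - ilo >= min_segment_genes:
                            inversions.append({"cls": s.full_class(),
                                               "anc": s.anc_chrom,
                                               "span": (ilo, ihi),
                                               "chrom": ca})
                # residual = own span minus all coverage
                for lo, hi in _subtract_span((s.anc_start, s.anc_end),
                                             same_cov + opp_cov):
                    if hi - lo >= min_segment_genes:
                        displaced.append({"side": side, "chrom": own_chrom,
                                          "pair": (ca, cb),
                                          "cls": s.full_class(),
                                          "anc": s.anc_chrom,
                                          "span": (lo, hi)})

    events: list[KaryotypeEvent] = []
    for inv in _merge_intervals(inversions):
        events.append(KaryotypeEvent("inversion", "extant", inv))

    # pair displaced pieces: piece present on a-side chrom pair (ca,cb) and
    # the matching extra on the b side of a different pair = a move
    moves = []
    a_pieces = [d for d in displaced if d["side"] == "a"]
    b_pieces = [d for d in displaced if d["side"] == "b"]
    for ap in a_pieces:
        for bp_ in b_pieces:
            if ap["anc"] != bp_["anc"] or ap["pair"] == bp_["pair"]:
                continue
            lo = max(ap["span"][0], bp_["span"][0])
            hi = min(ap["span"][1], bp_["span"][1])
            if hi - lo >= min_segment_genes:
                moves.append({"cls": ap["cls"], "from": ap["pair"][0],
                              "to": bp_["pair"][0], "span": (lo, hi)})
    used = set()
    for i, m1 in enumerate(moves):
        for j in range(i + 1, len(moves)):
            m2 = moves[j]
            if i in used or j in used:
                continue
            if m1["from"] == m2["to"] and m1["to"] == m2["from"]:
                used |= {i, j}
                events.append(KaryotypeEvent(
                    "reciprocal_translocation", "extant",
                    {"chrom_a": m1["from"], "chrom_b": m1["to"],
                     "moved": [m1["cls"], m2["cls"]]}))
    for i, m in enumerate(moves):
        if i not in used:
            events.append(KaryotypeEvent("translocation", "extant", m))
    return events


def _subtract_span(span: tuple[int, int], covered: list[tuple[int, int]]
                   ) -> list[tuple[int, int]]:
    out = []
    pos, end = span
    for lo, hi in sorted(covered):
        if lo > pos:
            out.append((pos, min(lo, end)))
        pos = max(pos, hi)
    if pos < end:
        out.append((pos, end))
    return [(lo, hi) for lo, hi in out if hi > lo]


def _merge_intervals(invs: list[dict]) -> list[dict]:
    """One event per (ancestral chromosome, overlapping span) cluster; the
    same inversion may be seen from both paintings."""
    merged: list[dict] = []
    for inv in sorted(invs, key=lambda d: (d["anc"], d["span"])):
        for m in merged:
            if m["anc"] == inv["anc"] and not (
                    inv["span"][1] <= m["span"][0] or
                    inv["span"][0] >= m["span"][1]):
                m["span"] = (min(m["span"][0], inv["span"][0]),
                             max(m["span"][1], inv["span"][1]))
                break
        else:
            merged.append(dict(inv))
    return merged


# ---------------------------------------------------------------------------
# region classes and subgenome assignment
# ---------------------------------------------------------------------------

def enumerate_region_classes(painting: SegmentPainting
                             ) -> dict[tuple, list[str]]:
    """Distinct (ancestral chromosome, triplication copy, duplication copy)
    region classes with their anchored extant gene lists."""
    out: dict[tuple, list[str]] = {}
    for s in painting.all_segments():
        out.setdefault(s.full_class(), []).extend(s.gene_ids)
    return out


def assign_subgenomes(tetraploid: GenomeLayout, diploid: GenomeLayout,
                      blocks: Sequence[CollinearBlock],
                      block_ks: Mapping[int, float]) -> dict[str, str]:
    """Partition tetraploid chromosomes into subgenomes A/B against a
    diploid relative: homoeologous pairs share the same best-covered diploid
    chromosome; within a pair the chromosome with the lower median Ks to the
    diploid clusters with it (subgenome B). Ties break to the chromosome
    with more anchors to the diploid (logged)."""
    cover: dict[str, dict[str, int]] = {}
    ks_of: dict[str, list[float]] = {}
    anchors_of: dict[str, int] = {}
    for blk in blocks:
        cover.setdefault(blk.chrom_a, {})
        cover[blk.chrom_a][blk.chrom_b] = (cover[blk.chrom_a].get(blk.chrom_b, 0)
                                           + blk.n_anchors)
        if blk.block_id in block_ks and np.isfinite(block_ks[blk.block_id]):
            ks_of.setdefault(blk.chrom_a, []).append(block_ks[blk.block_id])
        anchors_of[blk.chrom_a] = anchors_of.get(blk.chrom_a, 0) + blk.n_anchors

    best_dip: dict[str, str] = {}
    for tc in tetraploid.chromosomes:
        if tc not in cover:
            raise ValueError(f"no homoeologous pair for chromosome {tc!r}")
        best_dip[tc] = max(cover[tc].items(), key=lambda kv: kv[1])[0]
    pairs: dict[str, list[str]] = {}
    for tc, dc in best_dip.items():
        pairs.setdefault(dc, []).append(tc)
    bad = {dc: tcs for dc, tcs in pairs.items() if len(tcs) != 2}
    if bad:
        raise ValueError(f"no homoeologous pairs: unpaired chromosomes {bad}")

    out: dict[str, str] = {}
    for dc, (t1, t2) in sorted(pairs.items()):
        k1 = float(np.median(ks_of.get(t1, [np.inf])))
        k2 = float(np.median(ks_of.get(t2, [np.inf])))
        if k1 == k2:
            log.info("assign_subgenomes: Ks tie on (%s, %s); breaking by "
                     "anchor count", t1, t2)
            closer = t1 if anchors_of.get(t1, 0) >= anchors_of.get(t2, 0) else t2
        else:
            closer = t1 if k1 < k2 else t2
        other = t2 if closer == t1 else t1
        out[closer] = "B"
        out[other] = "A"
    return out
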