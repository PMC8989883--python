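"""Collinear-block detection by anchor chaining on gene ranks.

Anchors are homologous gene pairs placed at (chrom, rank) in two layouts.
Blocks are maximum-weight monotone chains (weight = anchor count) under a
rank-gap constraint enforced on BOTH genomes; anchors are consumed greedily
so every anchor belongs to at most one block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .io_formats import GenomeLayout, HomologyRecord

log = logging.getLogger("paleoshuffle")

__all__ = [
    "AnchorPair",
    "CollinearBlock",
    "build_anchors",
    "filter_large_families",
    "detect_collinear_blocks",
    "call_ancestral_genes",
    "classify_paralog_depth",
    "block_anchor_stats",
]


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    chrom_a: str
    rank_a: int
    chrom_b: str
    rank_b: int
    similarity: float


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[AnchorPair]
    orientation: str  # '+' or '-'
    median_ks: Optional[float] = None
    block_id: Optional[int] = None

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def span_a(self) -> tuple[int, int]:
        """Half-open rank span on genome a."""
        r = [a.rank_a for a in self.anchors]
        return min(r), max(r) + 1

    def span_b(self) -> tuple[int, int]:
        r = [a.rank_b for a in self.anchors]
        return min(r), max(r) + 1

    def validate(self, max_gap: int) -> None:
        """Assert monotonicity and the two-sided gap invariant."""
        ra = [a.rank_a for a in self.anchors]
        rb = [a.rank_b for a in self.anchors]
        assert all(x < y for x, y in zip(ra, ra[1:])), "rank_a not increasing"
        if self.orientation == "+":
            assert all(x < y for x, y in zip(rb, rb[1:])), "rank_b not increasing"
        else:
            assert all(x > y for x, y in zip(rb, rb[1:])), "rank_b not decreasing"
        for (x1, y1), (x2, y2) in zip(zip(ra, rb), zip(ra[1:], rb[1:])):
            assert x2 - x1 <= max_gap + 1, "gap on genome a exceeded"
            assert abs(y2 - y1) <= max_gap + 1, "gap on genome b exceeded"


def build_anchors(records: Iterable[HomologyRecord], layout_a: GenomeLayout,
                  layout_b: GenomeLayout) -> list[AnchorPair]:
    """Place homology records on both layouts; records with a missing gene
    are dropped (count logged)."""
    anchors, missing = [], 0
    for r in records:
        if r.query not in layout_a or r.subject not in layout_b:
            missing += 1
            continue
        ca, ra = layout_a.rank_of(r.query)
        cb, rb = layout_b.rank_of(r.subject)
        anchors.append(AnchorPair(r.query, r.subject, ca, ra, cb, rb, r.bitscore))
    if missing:
        log.info("build_anchors: %d records dropped (gene not in layout)", missing)
    return anchors


# ---------------------------------------------------------------------------
# family-size filter
# ---------------------------------------------------------------------------

def filter_large_families(records: Sequence[HomologyRecord],
                          max_family_size: int = 30) -> list[HomologyRecord]:
    """Drop all pairs touching a gene family with more than ``max_family_size``
    members; families are connected components of the homology graph."""
    if max_family_size == np.inf:
        return list(records)
    g = nx.Graph()
    for r in records:
        g.add_edge(r.query, r.subject)
    big: set[str] = set()
    for comp in nx.connected_components(g):
        if len(comp) > max_family_size:
            big |= comp
    kept = [r for r in records if r.query not in big and r.subject not in big]
    log.info("filter_large_families: %d/%d pairs kept (families > %d members removed)",
             len(kept), len(records), max_family_size)
    return kept


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def _best_chain(anchors: list[AnchorPair], max_gap: int, sign: int) -> list[int]:
    """Longest chain (by anchor count) with strictly increasing rank_a and
    strictly increasing (sign=+1) / decreasing (sign=-1) rank_b, consecutive
    gaps <= max_gap genes on both axes. O(n^2) DP; ties prefer leftmost start."""
    order = sorted(range(len(anchors)),
                   key=lambda i: (anchors[i].rank_a, sign * anchors[i].rank_b))
    ra = np.array([anchors[i].rank_a for i in order])
    rb = np.array([sign * anchors[i].rank_b for i in order])
    n = len(order)
    best = np.ones(n, dtype=int)
    prev = np.full(n, -1, dtype=int)
    for j in range(1, n):
        ok = ((ra[:j] < ra[j]) & (rb[:j] < rb[j])
              & (ra[j] - ra[:j] <= max_gap + 1)
              & (rb[j] - rb[:j] <= max_gap + 1))
        if ok.any():
            cand = np.where(ok, best[:j], 0)
            i = int(np.argmax(cand))
            if cand[i] + 1 > best[j]:
                best[j] = cand[i] + 1
                prev[j] = i
    end = int(np.argmax(best))
    chain = []
    while end != -1:
        chain.append(order[end])
        end = prev[end]
    return chain[::-1]


def detect_collinear_blocks(layout_a: GenomeLayout, layout_b: GenomeLayout,
                            anchors: Sequence[AnchorPair], max_gap: int = 50,
                            min_anchors: int = 5) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks per chromosome pair.

    Per pair, maximum chains are extracted greedily (best chain first, its
    anchors removed, repeat) for both orientations until no chain reaches
    ``min_anchors``. Every returned block satisfies the monotonicity and
    two-sided gap invariants (asserted).
    """
    by_pair: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        by_pair.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks: list[CollinearBlock] = []
    for (ca, cb) in sorted(by_pair):
        pool = list(by_pair[(ca, cb)])
        while len(pool) >= min_anchors:
            chain_p = _best_chain(pool, max_gap, +1)
            chain_m = _best_chain(pool, max_gap, -1)
            if len(chain_p) >= len(chain_m):
                chain, orient = chain_p, "+"
            else:
                chain, orient = chain_m, "-"
            if len(chain) < min_anchors:
                break
            chosen = [pool[i] for i in chain]
            blk = CollinearBlock(ca, cb, chosen, orient)
            blk.validate(max_gap)
            blocks.append(blk)
            used = set(chain)
            pool = [a for i, a in enumerate(pool) if i not in used]
    # stable ids: by score desc, leftmost start on a
    blocks.sort(key=lambda b: (-b.n_anchors, b.chrom_a, b.span_a()[0], b.chrom_b))
    for i, b in enumerate(blocks):
        b.block_id = i
    log.info("detect_collinear_blocks: %d anchors -> %d blocks", len(anchors), len(blocks))
    return blocks


# ---------------------------------------------------------------------------
# ancestral genes and paralog depth
# ---------------------------------------------------------------------------

def call_ancestral_genes(blocks_by_unit: Mapping[str, Sequence[CollinearBlock]],
                         min_units: int = 2) -> set[str]:
    """Reference genes anchored in collinear blocks from >= ``min_units``
    distinct units (subgenomes or duplicated region classes).

    Blocks must have the common reference on the *b* side.
    """
    seen: dict[str, set[str]] = {}
    for unit, blocks in blocks_by_unit.items():
        for blk in blocks:
            for a in blk.anchors:
                seen.setdefault(a.gene_b, set()).add(unit)
    return {g for g, units in seen.items() if len(units) >= min_units}


def classify_paralog_depth(homologs: Sequence[tuple[str, float]]
                           ) -> dict[str, list[str]]:
    """Split one reference gene's homologs into in-paralogs (top two by
    similarity; the most recent duplication) and out-paralogs (the rest).

    Ties break by gene_id lexicographic order (logged).
    """
    if not homologs:
        return {"in_paralog": [], "out_paralog": []}
    ranked = sorted(homologs, key=lambda h: (-h[1], h[0]))
    if len(ranked) > 2 and ranked[1][1] == ranked[2][1]:
        log.info("classify_paralog_depth: similarity tie at rank 2 (%s vs %s), "
                 "broken lexicographically", ranked[1][0], ranked[2][0])
    return {"in_paralog": [g for g, _ in ranked[:2]],
            "out_paralog": [g for g, _ in ranked[2:]]}


def block_anchor_stats(blocks: Sequence[CollinearBlock]
                       ) -> tuple[float, tuple[float, float]]:
    """Mean anchors per block with a normal-approximation 95% CI."""
    if len(blocks) < 2:
        raise ValueError("need >= 2 blocks for a confidence interval")
    sizes = np.array([b.n_anchors for b in blocks], dtype=float)
    mean = float(sizes.mean())
    se = float(sizes.std(ddof=1) / np.sqrt(len(sizes)))
    return mean, (mean - 1.96 * se, mean + 1.96 * se)
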