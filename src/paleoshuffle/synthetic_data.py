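"""Synthetic multi-species genomes with implanted polyploidy truth.

The generator builds a seven-chromosome ancestral genome, replays a scripted
history of whole-genome duplications (a triplication followed by a
duplication), chromosome fusions, per-copy biased fractionation, and extant
rearrangements, and emits every file the analysis stages consume together
with a :class:`TruthSet` recording the implanted answers.

Sequence evolution is a continuous-time Markov chain over the 61 sense
codons: single-nucleotide neighbour substitutions at rate 5 (synonymous) or
1 (nonsynonymous), no stop codons ever. Branch lengths are calibrated by
bisection so the Nei-Gojobori Ks between sister copies matches a requested
target.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .io_formats import (ContactMatrix, GeneModel, GenomeLayout,
                         HomologyRecord)
from . import wgd_dating as wd

log = logging.getLogger("paleoshuffle")

__all__ = [
    "SimulationConfig",
    "EventSpec",
    "TruthSet",
    "SimGenome",
    "simulate_ancestral_genome",
    "apply_wgd",
    "apply_fusion_plan",
    "apply_fractionation",
    "apply_rearrangement",
    "simulate_expression",
    "simulate_methylation",
    "simulate_contact_matrix",
    "fig1_replay",
    "c6b_replay",
    "retention_replay",
    "make_tetraploid_scenario",
    "GENE_SPACING_BP",
    "GENE_LENGTH_BP",
]

GENE_SPACING_BP = 10_000
GENE_LENGTH_BP = 4_000

TISSUES = ("leaf", "root", "stem")

# archetype tissue-fraction profiles of the seven triad categories
ARCHETYPES: dict[str, tuple[float, float, float]] = {
    "Balanced": (1 / 3, 1 / 3, 1 / 3),
    "Leaf-dominant": (1.0, 0.0, 0.0),
    "Root-dominant": (0.0, 1.0, 0.0),
    "Stem-dominant": (0.0, 0.0, 1.0),
    "Leaf-suppressed": (0.0, 0.5, 0.5),
    "Root-suppressed": (0.5, 0.0, 0.5),
    "Stem-suppressed": (0.5, 0.5, 0.0),
}


# ---------------------------------------------------------------------------
# configuration / truth containers
# ---------------------------------------------------------------------------

@dataclass
class EventSpec:
    kind: str          # wgd | fusion_plan | fission | inversion | translocation | fractionation
    layer_label: str   # e.g. "gamma", "beta", "extant"
    params: dict = field(default_factory=dict)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_anc_chrom: int = 7
    genes_per_chrom: int = 120
    codons_per_gene: int = 100
    event_plan: list[EventSpec] = field(default_factory=list)
    expression_spec: dict = field(default_factory=dict)
    methylation_spec: dict = field(default_factory=dict)
    hic_spec: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_anc_chrom < 1:
            raise ValueError("n_anc_chrom must be >= 1")


@dataclass
class TruthSet:
    """Generator-side ground truth against which every stage is scored."""

    # gene_id -> dict(locus, eu, gamma, beta) per species
    gene_lineage: dict[str, dict[str, dict]] = field(default_factory=dict)
    # per species: list of dicts(chrom, pos, layer, left_class, right_class)
    junctions: dict[str, list[dict]] = field(default_factory=dict)
    # event-level fusion counts per layer
    fusion_events: dict[str, int] = field(default_factory=dict)
    # locus -> set of retained (gamma, beta) copy classes
    retention: dict[str, set] = field(default_factory=dict)
    ks_targets: dict[str, float] = field(default_factory=dict)
    triad_category: dict[str, str] = field(default_factory=dict)
    compartments: dict[int, str] = field(default_factory=dict)   # bin -> A/B
    tads: list[tuple[int, int]] = field(default_factory=list)    # bin intervals
    methylation_zone: dict[str, str] = field(default_factory=dict)
    rearrangements: list[dict] = field(default_factory=list)
    n_region_classes: Optional[int] = None
    chromosome_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        def conv(o):
            if isinstance(o, set):
                return sorted(list(x) if isinstance(x, tuple) else x for x in o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))
        payload = {
            "gene_lineage": self.gene_lineage,
            "junctions": self.junctions,
            "fusion_events": self.fusion_events,
            "retention": {k: sorted(map(list, v)) for k, v in self.retention.items()},
            "ks_targets": self.ks_targets,
            "triad_category": self.triad_category,
            "compartments": self.compartments,
            "tads": self.tads,
            "methylation_zone": self.methylation_zone,
            "rearrangements": self.rearrangements,
            "n_region_classes": self.n_region_classes,
            "chromosome_counts": self.chromosome_counts,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, default=conv, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# internal mutable genome representation
# ---------------------------------------------------------------------------

@dataclass
class SimGene:
    uid: int
    locus: str
    eu: int
    gamma: str = ""
    beta: str = ""
    strand: str = "+"
    seg: str = ""     # provenance segment id, set by fusion plans

    def copy_class(self) -> tuple[str, str]:
        return (self.gamma, self.beta)


class SimGenome:
    """Mutable simulation-side genome: ordered SimGenes per chromosome."""

    def __init__(self, chromosomes: Optional[dict[str, list[SimGene]]] = None):
        self.chromosomes: dict[str, list[SimGene]] = chromosomes or {}
        # registry of fusion junctions: frozenset({segL, segR}) -> layer
        self.junction_registry: dict[frozenset, str] = {}

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def n_genes(self) -> int:
        return sum(len(g) for g in self.chromosomes.values())

    def all_genes(self):
        for c in self.chromosomes:
            yield from self.chromosomes[c]

    def deepcopy(self) -> "SimGenome":
        g = SimGenome({c: [copy.copy(x) for x in gs]
                       for c, gs in self.chromosomes.items()})
        g.junction_registry = dict(self.junction_registry)
        return g

    def to_layout(self, species_id: str, id_prefix: str) -> tuple[GenomeLayout, dict]:
        """Emit a GenomeLayout plus gene_id -> SimGene mapping.

        Gene bp coordinates are synthetic: rank r occupies
        [r*GENE_SPACING_BP + 1, r*GENE_SPACING_BP + GENE_LENGTH_BP] (1-based).
        """
        genes, mapping = [], {}
        counter = 0
        for chrom in self.chromosomes:
            for r, sg in enumerate(self.chromosomes[chrom]):
                gid = f"{id_prefix}g{counter:06d}"
                counter += 1
                start = r * GENE_SPACING_BP + 1
                genes.append(GeneModel(gid, chrom, start, start + GENE_LENGTH_BP - 1,
                                       sg.strand, family_id=sg.locus))
                mapping[gid] = sg
        return GenomeLayout(species_id, genes), mapping


# ---------------------------------------------------------------------------
# codon evolution engine
# ---------------------------------------------------------------------------

def _build_rate_matrix() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric 61x61 codon rate matrix: syn neighbours 5, nonsyn 1."""
    codons = wd.SENSE_CODONS
    n = len(codons)
    q = np.zeros((n, n))
    for i, a in enumerate(codons):
        for j, b in enumerate(codons):
            if i == j:
                continue
            diffs = sum(x != y for x, y in zip(a, b))
            if diffs != 1:
                continue
            q[i, j] = 5.0 if wd.GENETIC_CODE[a] == wd.GENETIC_CODE[b] else 1.0
    np.fill_diagonal(q, -q.sum(axis=1))
    q /= -np.mean(np.diag(q))  # unit: ~1 expected event per site per unit t
    vals, vecs = eigh(q)
    return q, vals, vecs


_Q, _QVALS, _QVECS = _build_rate_matrix()


def _transition_matrix(t: float) -> np.ndarray:
    p = (_QVECS * np.exp(_QVALS * t)) @ _QVECS.T
    p = np.clip(p, 0.0, None)
    return p / p.sum(axis=1, keepdims=True)


def _evolve(seqs: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an int codon array (any shape) for branch length t."""
    p = _transition_matrix(t)
    flat = seqs.ravel()
    out = flat.copy()
    for state in np.unique(flat):
        idx = np.where(flat == state)[0]
        out[idx] = rng.choice(len(wd.SENSE_CODONS), size=idx.size, p=p[state])
    return out.reshape(seqs.shape)


def _expected_ks(two_t: float, rho: np.ndarray) -> float:
    """Expected NG86 Ks between two copies separated by total branch 2t,
    for ancestral codon composition rho."""
    m = _transition_matrix(two_t)
    joint = rho[:, None] * m
    s_pair = (wd._S_SITES[:, None] + wd._S_SITES[None, :]) / 2.0
    S = (joint * s_pair).sum()
    Sd = (joint * wd._SD_TAB).sum()
    ps = Sd / S
    if ps >= 0.75:
        return np.inf
    return float(-0.75 * np.log(1 - 4 * ps / 3))


def calibrate_branch_length(target_ks: float, rho: Optional[np.ndarray] = None
                            ) -> float:
    """Per-branch length t such that two copies diverging independently for t
    each have expected NG86 Ks = target_ks (bisection on the closed-form
    expectation under the substitution model)."""
    if target_ks <= 0:
        raise ValueError("target_ks must be positive")
    if rho is None:
        rho = np.full(len(wd.SENSE_CODONS), 1.0 / len(wd.SENSE_CODONS))
    lo, hi = 1e-6, 8.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _expected_ks(mid, rho) < target_ks:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)  # total 2t -> per-branch t = half


def _median_pairwise_ks(seq_sets: Sequence[np.ndarray]) -> float:
    """Median NG86 Ks over all copy pairs of stacked (n_genes, n_codons) sets."""
    vals = []
    for i in range(len(seq_sets)):
        for j in range(i + 1, len(seq_sets)):
            vals.append(wd.ks_ng86_many(seq_sets[i], seq_sets[j]))
    allv = np.concatenate(vals)
    return float(np.nanmedian(allv))


# ---------------------------------------------------------------------------
# simulation operations
# ---------------------------------------------------------------------------

def simulate_ancestral_genome(config: SimulationConfig,
                              rng: Optional[np.random.Generator] = None
                              ) -> tuple[SimGenome, dict[int, np.ndarray]]:
    """Ancestral genome: ``n_anc_chrom`` chromosomes x ``genes_per_chrom``
    loci, each with a random in-frame codon sequence (no stops possible:
    sequences are drawn over the 61 sense codons)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genome = SimGenome()
    seqs: dict[int, np.ndarray] = {}
    uid = 0
    for c in range(1, config.n_anc_chrom + 1):
        chrom = f"Eu{c}"
        genes = []
        for g in range(config.genes_per_chrom):
            locus = f"L{c}_{g:04d}"
            genes.append(SimGene(uid, locus, eu=c))
            seqs[uid] = rng.integers(0, len(wd.SENSE_CODONS),
                                     size=config.codons_per_gene).astype(np.int16)
            uid += 1
        genome.chromosomes[chrom] = genes
    return genome, seqs


def apply_wgd(genome: SimGenome, seqs: dict[int, np.ndarray], multiplicity: int,
              layer_label: str, target_ks: float, rng: np.random.Generator,
              copy_labels: Optional[Sequence[str]] = None,
              label_kind: str = "gamma",
              name_fn=None) -> tuple[SimGenome, dict[int, np.ndarray], float]:
    """Duplicate every chromosome ``multiplicity`` times; each copy's
    sequences evolve independently so sister-copy Ks matches ``target_ks``.

    Returns (new genome, new seqs, measured median sister Ks).
    """
    if multiplicity not in (2, 3):
        raise ValueError("multiplicity must be 2 or 3")
    if target_ks <= 0:
        raise ValueError("target_ks must be positive")
    if copy_labels is None:
        copy_labels = ["A", "B", "C"][:multiplicity] if label_kind == "gamma" \
            else ["a", "b"][:multiplicity]
    if name_fn is None:
        if label_kind == "gamma":
            def name_fn(chrom, lab):  # Eu3 -> A3
                return f"{lab}{chrom[2:]}" if chrom.startswith("Eu") else f"{chrom}{lab}"
        else:
            def name_fn(chrom, lab):  # Ar1 -> Ar1a
                return f"{chrom}{lab}"

    base_arr = np.stack([seqs[g.uid] for g in genome.all_genes()])
    rho = np.bincount(base_arr.ravel(), minlength=len(wd.SENSE_CODONS)) / base_arr.size
    t = calibrate_branch_length(target_ks, rho)

    # empirical refinement against the NG86 estimator (up to 3 rounds)
    measured = np.nan
    for _ in range(3):
        sub_rng = np.random.default_rng(rng.integers(0, 2**31))
        evolved = [_evolve(base_arr, t, sub_rng) for _ in range(multiplicity)]
        measured = _median_pairwise_ks(evolved)
        if abs(measured - target_ks) <= 0.02:
            break
        t *= target_ks / measured
    log.info("apply_wgd[%s]: multiplicity=%d target_ks=%.3f measured=%.3f",
             layer_label, multiplicity, target_ks, measured)

    new = SimGenome()
    new.junction_registry = dict(genome.junction_registry)
    new_seqs: dict[int, np.ndarray] = {}
    uid = max(seqs.keys(), default=-1) + 1
    gene_index = {g.uid: i for i, g in enumerate(genome.all_genes())}
    for ci, lab in enumerate(copy_labels):
        for chrom, genes in genome.chromosomes.items():
            new_genes = []
            for g in genes:
                ng = copy.copy(g)
                ng.uid = uid
                if label_kind == "gamma":
                    ng.gamma = lab
                elif label_kind == "beta":
                    ng.beta = lab
                if ng.seg:
                    ng.seg = f"{ng.seg}|{lab}"
                new_seqs[uid] = evolved[ci][gene_index[g.uid]]
                uid += 1
                new_genes.append(ng)
            new.chromosomes[name_fn(chrom, lab)] = new_genes
    # duplicate the junction registry through the copy labels
    if genome.junction_registry:
        reg = {}
        for key, layer in genome.junction_registry.items():
            for lab in copy_labels:
                reg[frozenset(f"{s}|{lab}" for s in key)] = layer
        new.junction_registry = reg
    return new, new_seqs, measured


def apply_fusion_plan(genome: SimGenome, plan: Mapping[str, Sequence[tuple]],
                      layer_label: str) -> SimGenome:
    """Cut current chromosomes into segments and concatenate per ``plan``.

    ``plan`` maps new chromosome name -> ordered list of segments
    ``(src_chrom, lo_rank, hi_rank)`` (half-open; ``hi_rank=None`` = end).
    The plan must use every gene of every chromosome exactly once.
    Heterologous adjacencies are recorded in the junction registry under
    ``layer_label``.
    """
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chromosomes}
    new = SimGenome()
    new.junction_registry = dict(genome.junction_registry)
    seg_counter = 0
    for new_chrom, segments in plan.items():
        assembled: list[SimGene] = []
        prev_tail_seg: Optional[str] = None
        for (src, lo, hi) in segments:
            if src not in genome.chromosomes:
                raise ValueError(f"fusion plan references unknown chromosome {src!r}")
            genes = genome.chromosomes[src]
            hi = len(genes) if hi is None else hi
            if not (0 <= lo < hi <= len(genes)):
                raise ValueError(f"bad segment span {src}[{lo}:{hi}]")
            used[src].append((lo, hi))
            piece = [copy.copy(g) for g in genes[lo:hi]]
            seg_id = f"{layer_label}:{src}:{lo}-{hi}"
            seg_counter += 1
            for g in piece:
                if not g.seg:
                    g.seg = seg_id
            if assembled:
                left = assembled[-1].seg
                right = piece[0].seg
                if left != right:
                    new.junction_registry.setdefault(
                        frozenset((left, right)), layer_label)
            assembled.extend(piece)
            prev_tail_seg = piece[-1].seg
        new.chromosomes[new_chrom] = assembled
    # validate the partition
    for src, spans in used.items():
        spans.sort()
        total = len(genome.chromosomes[src])
        pos = 0
        for lo, hi in spans:
            if lo != pos:
                raise ValueError(f"fusion plan omits or reuses {src}[{pos}:{lo}]")
            pos = hi
        if pos != total:
            raise ValueError(f"fusion plan omits {src}[{pos}:{total}]")
    log.info("apply_fusion_plan[%s]: %d -> %d chromosomes, %d junctions recorded",
             layer_label, genome.n_chromosomes, new.n_chromosomes,
             len(new.junction_registry) - len(genome.junction_registry))
    return new


def apply_fractionation(genome: SimGenome, retention_spec: Mapping,
                        rng: np.random.Generator,
                        allow_full_loss: bool = False
                        ) -> tuple[SimGenome, dict[str, set]]:
    """Delete gene copies per copy-class retention probabilities or an
    explicit per-locus implant; returns (genome, retention truth).

    Unless ``allow_full_loss``, every locus keeps at least one copy (the
    copy with the highest retention probability is restored when sampling
    would lose all of them).
    """
    probs: Optional[Mapping[tuple, float]] = retention_spec.get("retention")
    implant: Optional[Mapping[str, set]] = retention_spec.get("implant")
    if probs is not None:
        for p in probs.values():
            if not (0.0 <= p <= 1.0):
                raise ValueError("retention probabilities must be in [0, 1]")

    keep_flags: dict[int, bool] = {}
    by_locus: dict[str, list[SimGene]] = {}
    for g in genome.all_genes():
        by_locus.setdefault(g.locus, []).append(g)

    for locus, copies in by_locus.items():
        if implant is not None:
            wanted = implant.get(locus)
            for g in copies:
                keep_flags[g.uid] = (wanted is None) or (g.copy_class() in wanted)
        else:
            flags = [rng.random() < probs.get(g.copy_class(), 1.0) for g in copies]
            if not any(flags) and not allow_full_loss:
                best = int(np.argmax([probs.get(g.copy_class(), 1.0) for g in copies]))
                flags[best] = True
            for g, f in zip(copies, flags):
                keep_flags[g.uid] = f

    new = SimGenome()
    new.junction_registry = dict(genome.junction_registry)
    truth: dict[str, set] = {}
    for chrom, genes in genome.chromosomes.items():
        kept = [copy.copy(g) for g in genes if keep_flags[g.uid]]
        new.chromosomes[chrom] = kept
        for g in kept:
            truth.setdefault(g.locus, set()).add(g.copy_class())
    log.info("apply_fractionation: %d -> %d genes", genome.n_genes(), new.n_genes())
    return new, truth


def apply_rearrangement(genome: SimGenome, kind: str, params: Mapping,
                        layer_label: str = "extant") -> tuple[SimGenome, dict]:
    """In-place style rearrangement returning (new genome, event truth).

    kinds: ``inversion`` (chrom, lo, hi: reverse order + flip strands),
    ``translocation`` (chrom_a, chrom_b, tail_a, tail_b: swap terminal
    segments), ``fission`` (chrom, at: split into two).
    """
    new = genome.deepcopy()
    if kind == "inversion":
        chrom, lo, hi = params["chrom"], params["lo"], params["hi"]
        genes = new.chromosomes[chrom]
        if not (0 <= lo < hi <= len(genes)):
            raise ValueError(f"inversion span [{lo}:{hi}] out of range on {chrom}")
        seg = genes[lo:hi][::-1]
        for g in seg:
            g.strand = "-" if g.strand == "+" else "+"
        new.chromosomes[chrom] = genes[:lo] + seg + genes[hi:]
        event = {"kind": "inversion", "layer": layer_label, "chrom": chrom,
                 "lo": lo, "hi": hi}
    elif kind == "translocation":
        ca, cb = params["chrom_a"], params["chrom_b"]
        ta, tb = params["tail_a"], params["tail_b"]
        ga, gb = new.chromosomes[ca], new.chromosomes[cb]
        if ta >= len(ga) or tb >= len(gb):
            raise ValueError("translocation tail exceeds chromosome length")
        new.chromosomes[ca] = ga[:len(ga) - ta] + gb[len(gb) - tb:]
        new.chromosomes[cb] = gb[:len(gb) - tb] + ga[len(ga) - ta:]
        event = {"kind": "reciprocal_translocation", "layer": layer_label,
                 "chrom_a": ca, "chrom_b": cb, "tail_a": ta, "tail_b": tb}
    elif kind == "fission":
        chrom, at = params["chrom"], params["at"]
        genes = new.chromosomes.pop(chrom)
        if not (0 < at < len(genes)):
            raise ValueError(f"fission point {at} out of range on {chrom}")
        new.chromosomes[f"{chrom}_p"] = genes[:at]
        new.chromosomes[f"{chrom}_q"] = genes[at:]
        event = {"kind": "fission", "layer": layer_label, "chrom": chrom, "at": at}
    else:
        raise ValueError(f"unknown rearrangement kind {kind!r}")
    return new, event


# ---------------------------------------------------------------------------
# expression / methylation / Hi-C
# ---------------------------------------------------------------------------

def simulate_expression(gene_ids: Sequence[str], rng: np.random.Generator,
                        category_probs: Optional[Mapping[str, float]] = None,
                        concentration: float = 50.0,
                        n_replicates: int = 3,
                        implant: Optional[Mapping[str, str]] = None
                        ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Tissue TPM triples with an implanted triad category per gene.

    Fractions are Dirichlet draws around the category archetype at the given
    concentration; magnitudes are lognormal; replicates add small lognormal
    noise. No gene is ever emitted with an all-zero triple.
    """
    if category_probs is None:
        category_probs = {"Balanced": 0.40, "Leaf-dominant": 0.10,
                          "Root-dominant": 0.10, "Stem-dominant": 0.10,
                          "Leaf-suppressed": 0.10, "Root-suppressed": 0.10,
                          "Stem-suppressed": 0.10}
    cats = list(category_probs)
    p = np.array([category_probs[c] for c in cats])
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("category probabilities must sum to 1")
    for arch in ARCHETYPES.values():
        assert abs(sum(arch) - 1.0) < 1e-12

    rows = []
    truth: dict[str, str] = {}
    for gid in gene_ids:
        cat = implant[gid] if implant and gid in implant \
            else cats[rng.choice(len(cats), p=p)]
        truth[gid] = cat
        alpha = concentration * np.asarray(ARCHETYPES[cat]) + 0.02
        frac = rng.dirichlet(alpha)
        total = float(rng.lognormal(np.log(60.0), 0.8))
        total = max(total, 0.5)  # precondition of the triad fractions: never all-zero
        for ti, tissue in enumerate(TISSUES):
            for rep in range(1, n_replicates + 1):
                tpm = frac[ti] * total * float(rng.lognormal(0.0, 0.05))
                rows.append((gid, tissue, rep, tpm))
    df = pd.DataFrame(rows, columns=["gene_id", "tissue", "replicate", "tpm"])
    return df, truth


def simulate_methylation(gene_zone: Mapping[str, str], rng: np.random.Generator,
                         interior_beta: tuple[float, float] = (6.0, 3.0),
                         border_beta: tuple[float, float] = (2.0, 5.0)
                         ) -> pd.DataFrame:
    """Per-gene mC levels: TAD-interior genes hypermethylated relative to
    border/outside genes (beta-distributed)."""
    rows = []
    for gid, zone in gene_zone.items():
        a, b = interior_beta if zone == "interior" else border_beta
        rows.append((gid, float(rng.beta(a, b))))
    return pd.DataFrame(rows, columns=["gene_id", "mC"])


def _random_partition(n_bins: int, lo: int, hi: int,
                      rng: np.random.Generator) -> list[tuple[int, int]]:
    out, pos = [], 0
    while pos < n_bins:
        w = int(rng.integers(lo, hi + 1))
        out.append((pos, min(pos + w, n_bins)))
        pos += w
    return out


def simulate_contact_matrix(chrom_sizes: Mapping[str, int], resolution: int,
                            rng: np.random.Generator,
                            compartments: Optional[Mapping[int, str]] = None,
                            tads: Optional[Sequence[tuple[int, int]]] = None,
                            decay_exponent: float = 1.0,
                            depth: float = 1e6,
                            comp_boost: float = 1.6,
                            tad_boost: float = 2.0,
                            inter_background: float = 0.02,
                            bin_groups: Optional[Mapping[int, object]] = None,
                            group_boost: float = 1.0) -> ContactMatrix:
    """Poisson contact matrix with power-law distance decay and optional
    implanted compartment checkerboard, TADs, and same-group (same ancestral
    chromosome) enrichment."""
    template = ContactMatrix(np.zeros((sum(int(np.ceil(s / resolution))
                                           for s in chrom_sizes.values()),) * 2),
                             resolution, chrom_sizes)
    n = template.n_bins
    chrom_of = np.array([template.chrom_offsets[c] for c in template.bin_chrom])
    idx = np.arange(n)
    same_chrom = chrom_of[:, None] == chrom_of[None, :]
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    expected = np.where(same_chrom, (d + 1.0) ** (-decay_exponent),
                        inter_background)
    if compartments:
        lab = np.array([compartments.get(i, "A") for i in range(n)])
        same_comp = lab[:, None] == lab[None, :]
        expected *= np.where(same_comp & same_chrom, comp_boost,
                             np.where(same_chrom, 1.0 / comp_boost, 1.0))
    if tads:
        tad_id = np.full(n, -1)
        for k, (lo, hi) in enumerate(tads):
            tad_id[lo:hi] = k
        same_tad = (tad_id[:, None] == tad_id[None, :]) & (tad_id[:, None] >= 0)
        expected *= np.where(same_tad, tad_boost, 1.0)
    if bin_groups and group_boost != 1.0:
        grp = np.array([str(bin_groups.get(i, f"__none{i}")) for i in range(n)])
        expected *= np.where(grp[:, None] == grp[None, :], group_boost, 1.0)
    expected *= depth / expected.sum()
    upper = np.triu(rng.poisson(expected)).astype(float)
    counts = upper + np.triu(upper, 1).T
    return ContactMatrix(counts, resolution, chrom_sizes)


# ---------------------------------------------------------------------------
# the canonical replay scenario
# ---------------------------------------------------------------------------

def _gamma_fusion_plan(L: int) -> dict[str, list[tuple]]:
    """34 segments of the 21 post-triplication chromosomes -> 8 chromosomes,
    26 heterologous junctions; no two adjacent segments share an ancestral
    chromosome and all 26 junction class pairs are distinct."""
    H = L // 2
    W = lambda c: (c, 0, None)          # whole chromosome
    HD = lambda c: (c, 0, H)            # head half
    TL = lambda c: (c, H, None)         # tail half
    return {
        "Ar1": [W("A1"), W("A2"), W("A3"), W("A4"), W("A5")],
        "Ar2": [W("A6"), W("A7"), HD("B1"), HD("B2"), HD("B3")],
        "Ar3": [HD("B4"), HD("B5"), HD("B6"), HD("B7")],
        "Ar4": [TL("B1"), TL("B3"), TL("B5"), TL("B7")],
        "Ar5": [TL("B2"), TL("B4"), TL("B6"), HD("C1")],
        "Ar6": [HD("C2"), HD("C3"), HD("C4"), HD("C5")],
        "Ar7": [HD("C6"), W("C7"), TL("C1"), TL("C2")],
        "Ar8": [TL("C3"), TL("C5"), TL("C6"), TL("C4")],
    }


def _beta_fusion_plan() -> dict[str, list[tuple]]:
    """Four whole-chromosome fusions: 16 -> 12 chromosomes (4 junctions)."""
    W = lambda c: (c, 0, None)
    plan = {
        "Pa1": [W("Ar1a"), W("Ar3a")],
        "Pa2": [W("Ar4b"), W("Ar2b")],
        "Pa3": [W("Ar5a"), W("Ar7a")],
        "Pa4": [W("Ar8b"), W("Ar6b")],
    }
    for i, c in enumerate(["Ar1b", "Ar2a", "Ar3b", "Ar4a",
                           "Ar5b", "Ar6a", "Ar7b", "Ar8a"], start=5):
        plan[f"Pa{i}"] = [W(c)]
    return plan


# per-copy-class retention probabilities: biased fractionation, every class
# keeps enough genes per segment for painting
REPLAY_RETENTION = {
    ("A", "a"): 0.92, ("A", "b"): 0.85,
    ("B", "a"): 0.80, ("B", "b"): 0.72,
    ("C", "a"): 0.66, ("C", "b"): 0.58,
}

REPLAY_KS_TARGETS = {"gamma": 1.0, "beta": 0.3, "speciation": 0.1}


@dataclass
class Fig1Replay:
    """Everything fig1_replay emits: layouts per layer, sequences, homology
    tables, expression/methylation tables, a contact matrix, and truth."""

    config: SimulationConfig
    layouts: dict[str, GenomeLayout]
    seqs: dict[str, dict[str, np.ndarray]]     # species -> gene_id -> codons
    anc_seqs: dict[str, np.ndarray]            # ancestor gene_id -> codons
    homology_vs_ancestor: dict[str, list[HomologyRecord]]
    homology_self: dict[str, list[HomologyRecord]]
    expression: pd.DataFrame
    methylation: pd.DataFrame
    contact: Optional[ContactMatrix]
    truth: TruthSet


def _nt_diff_table() -> np.ndarray:
    n = len(wd.SENSE_CODONS)
    t = np.zeros((n, n), dtype=np.int8)
    for i, a in enumerate(wd.SENSE_CODONS):
        for j, b in enumerate(wd.SENSE_CODONS):
            t[i, j] = sum(x != y for x, y in zip(a, b))
    return t


_NTDIFF = _nt_diff_table()


def _homology_records(q_ids, q_seqs, s_ids, s_seqs) -> list[HomologyRecord]:
    out = []
    for qid, sid in zip(q_ids, s_ids):
        a, b = q_seqs[qid], s_seqs[sid]
        ndiff = int(_NTDIFF[a, b].sum())
        length = 3 * len(a)
        pid = 100.0 * (length - ndiff) / length
        out.append(HomologyRecord(qid, sid, round(pid, 2), 1e-50,
                                  float(2 * (length - ndiff))))
    return out


def fig1_replay(seed: int = 42, fractionation: bool = True,
                rearrangements: bool = True, with_epigenome: bool = True,
                genes_per_chrom: int = 120, codons_per_gene: int = 100
                ) -> Fig1Replay:
    """The canonical scenario: 7-chromosome ancestor -> triplication (x3) ->
    34-segment fusion plan (21 -> 8 chromosomes, 26 junctions) -> duplication
    (x2) -> 4 whole-chromosome fusions (16 -> 12) -> biased fractionation ->
    two extant species with 2 inversions + 1 reciprocal translocation."""
    config = SimulationConfig(seed=seed, genes_per_chrom=genes_per_chrom,
                              codons_per_gene=codons_per_gene)
    rng = np.random.default_rng(seed)
    truth = TruthSet(ks_targets=dict(REPLAY_KS_TARGETS))

    genome, seqs = simulate_ancestral_genome(config, rng)
    layouts: dict[str, GenomeLayout] = {}
    anc_layout, anc_map = genome.to_layout("ancestor", "anc")
    layouts["ancestor"] = anc_layout
    anc_gene_of_locus = {sg.locus: gid for gid, sg in anc_map.items()}
    anc_seqs = {gid: seqs[sg.uid] for gid, sg in anc_map.items()}

    genome, seqs, _ = apply_wgd(genome, seqs, 3, "gamma",
                                REPLAY_KS_TARGETS["gamma"], rng)
    layouts["post_gamma"] = genome.to_layout("post_gamma", "pg")[0]

    genome = apply_fusion_plan(genome, _gamma_fusion_plan(config.genes_per_chrom),
                               "post-gamma")
    layouts["pre_beta"] = genome.to_layout("pre_beta", "pb")[0]

    genome, seqs, _ = apply_wgd(genome, seqs, 2, "beta",
                                REPLAY_KS_TARGETS["beta"], rng, label_kind="beta")
    layouts["post_beta"] = genome.to_layout("post_beta", "ps_")[0]

    genome = apply_fusion_plan(genome, _beta_fusion_plan(), "post-beta")
    layouts["panax_ancestor"] = genome.to_layout("panax_ancestor", "pa")[0]
    truth.n_region_classes = len({(g.eu, g.gamma, g.beta)
                                  for g in genome.all_genes()})
    truth.chromosome_counts = {
        "ancestor": 7, "post_gamma": layouts["post_gamma"].n_chromosomes,
        "pre_beta": layouts["pre_beta"].n_chromosomes,
        "post_beta": layouts["post_beta"].n_chromosomes,
        "panax_ancestor": layouts["panax_ancestor"].n_chromosomes,
    }

    if fractionation:
        genome, retention = apply_fractionation(
            genome, {"retention": REPLAY_RETENTION}, rng)
        truth.retention = retention
    else:
        retention: dict[str, set] = {}
        for g in genome.all_genes():
            retention.setdefault(g.locus, set()).add(g.copy_class())
        truth.retention = retention

    # speciation: two extant species, small extra divergence
    t_spec = calibrate_branch_length(REPLAY_KS_TARGETS["speciation"])
    order = list(genome.all_genes())
    base_arr = np.stack([seqs[g.uid] for g in order])
    species_genomes: dict[str, SimGenome] = {}
    species_seq_arr: dict[str, np.ndarray] = {}
    for sp in ("Ps", "Pn"):
        species_genomes[sp] = genome.deepcopy()
        species_seq_arr[sp] = _evolve(base_arr, t_spec, rng)
    uid_row = {g.uid: i for i, g in enumerate(order)}

    # rename chromosomes Pa1..Pa12 -> chr1..chr12
    for sp, g in species_genomes.items():
        g.chromosomes = {f"chr{i}": genes for i, (_, genes) in
                         enumerate(sorted(g.chromosomes.items(),
                                          key=lambda kv: int(kv[0][2:])), start=1)}

    if rearrangements:
        def seg_span(g: SimGenome, chrom: str, seg_frag: str) -> tuple[int, int]:
            rs = [r for r, x in enumerate(g.chromosomes[chrom])
                  if seg_frag in x.seg]
            return min(rs), max(rs) + 1

        ps = species_genomes["Ps"]
        lo, hi = seg_span(ps, "chr1", "post-gamma:A1:")
        inv_lo = lo + 5
        inv_hi = min(inv_lo + 14, hi - 5)
        ps, ev1 = apply_rearrangement(ps, "inversion",
                                      {"chrom": "chr1", "lo": inv_lo, "hi": inv_hi})
        ev1["species"] = "Ps"
        species_genomes["Ps"] = ps

        pn = species_genomes["Pn"]
        lo, hi = seg_span(pn, "chr9", "post-gamma:B2:")  # Ar5b head segment B2t
        inv_lo = lo + 5
        inv_hi = min(inv_lo + 14, hi - 5)
        pn, ev2 = apply_rearrangement(pn, "inversion",
                                      {"chrom": "chr9", "lo": inv_lo, "hi": inv_hi})
        ev2["species"] = "Pn"
        pn, ev3 = apply_rearrangement(pn, "translocation",
                                      {"chrom_a": "chr6", "chrom_b": "chr8",
                                       "tail_a": 15, "tail_b": 15})
        ev3["species"] = "Pn"
        species_genomes["Pn"] = pn
        truth.rearrangements = [ev1, ev2, ev3]

    # event-level fusion truth
    layer_counts: dict[str, int] = {}
    for key, layer in genome.junction_registry.items():
        layer_counts[layer] = layer_counts.get(layer, 0) + 1
    # pre-beta junctions were duplicated through the beta WGD: 2 adjacencies
    # per event; post-beta junctions are single
    truth.fusion_events = {"post-gamma": layer_counts.get("post-gamma", 0) // 2,
                           "post-beta": layer_counts.get("post-beta", 0)}

    # emit species layouts, sequences, homology, truth lineage + junctions
    species_seqs: dict[str, dict[str, np.ndarray]] = {}
    hom_anc: dict[str, list[HomologyRecord]] = {}
    hom_self: dict[str, list[HomologyRecord]] = {}
    for sp, g in species_genomes.items():
        layout, mapping = g.to_layout(sp, sp)
        layouts[sp] = layout
        sseqs = {gid: species_seq_arr[sp][uid_row[sg.uid]]
                 for gid, sg in mapping.items()}
        species_seqs[sp] = sseqs
        truth.gene_lineage[sp] = {
            gid: {"locus": sg.locus, "eu": sg.eu, "gamma": sg.gamma,
                  "beta": sg.beta, "seg": sg.seg}
            for gid, sg in mapping.items()}
        # junction truth from segment provenance
        jl = []
        for chrom, genes in g.chromosomes.items():
            for r in range(len(genes) - 1):
                a, b = genes[r], genes[r + 1]
                if a.seg != b.seg:
                    layer = g.junction_registry.get(frozenset((a.seg, b.seg)),
                                                    "extant")
                    jl.append({"chrom": chrom, "pos": r + 1, "layer": layer,
                               "left_class": [a.eu, a.gamma, a.beta],
                               "right_class": [b.eu, b.gamma, b.beta]})
        truth.junctions[sp] = jl
        # homology tables
        gids = list(mapping)
        anc_ids = [anc_gene_of_locus[mapping[gid].locus] for gid in gids]
        hom_anc[sp] = _homology_records(gids, sseqs, anc_ids, anc_seqs)
        by_locus: dict[str, list[str]] = {}
        for gid in gids:
            by_locus.setdefault(mapping[gid].locus, []).append(gid)
        pairs_q, pairs_s = [], []
        for locus, members in by_locus.items():
            members.sort()
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pairs_q.append(members[i])
                    pairs_s.append(members[j])
        hom_self[sp] = _homology_records(pairs_q, sseqs, pairs_s, sseqs)

    # expression + triad truth (primary species)
    ps_layout = layouts["Ps"]
    ps_ids = sorted(g.gene_id for g in ps_layout.genes())
    if with_epigenome:
        expr, triad_truth = simulate_expression(ps_ids, rng)
        truth.triad_category = triad_truth
        # contact matrix over the first two chromosomes of Ps
        cm_chroms = ["chr1", "chr2"]
        chrom_sizes = {c: ps_layout.n_genes(c) * GENE_SPACING_BP
                       for c in cm_chroms}
        resolution = 20_000
        nb_total = sum(int(np.ceil(s / resolution)) for s in chrom_sizes.values())
        comp, tads = {}, []
        off = 0
        for c in cm_chroms:
            nb = int(np.ceil(chrom_sizes[c] / resolution))
            for k, (lo, hi) in enumerate(_random_partition(nb, 8, 12, rng)):
                for b in range(lo, hi):
                    comp[off + b] = "A" if k % 2 == 0 else "B"
            for lo, hi in _random_partition(nb, 4, 9, rng):
                tads.append((off + lo, off + hi))
            off += nb
        truth.compartments = comp
        truth.tads = tads
        # same-ancestor (Eu) group per bin, majority gene origin
        lineage = truth.gene_lineage["Ps"]
        bin_group: dict[int, object] = {}
        cm_tpl = ContactMatrix(np.zeros((nb_total, nb_total)), resolution,
                               chrom_sizes)
        from collections import Counter
        per_bin: dict[int, Counter] = {}
        for gid in ps_ids:
            chrom, rank = ps_layout.rank_of(gid)
            if chrom not in cm_chroms:
                continue
            b = cm_tpl.bin_of(chrom, rank * GENE_SPACING_BP)
            per_bin.setdefault(b, Counter())[lineage[gid]["eu"]] += 1
        for b, cnt in per_bin.items():
            bin_group[b] = cnt.most_common(1)[0][0]
        contact = simulate_contact_matrix(
            chrom_sizes, resolution, rng, compartments=comp, tads=tads,
            decay_exponent=1.0, depth=2e6, bin_groups=bin_group,
            group_boost=1.6)
        # methylation: interior vs border zones from TAD truth
        boundary_bins = set()
        for lo, hi in tads:
            boundary_bins |= {lo, hi - 1}
        gene_zone: dict[str, str] = {}
        for gid in ps_ids:
            chrom, rank = ps_layout.rank_of(gid)
            if chrom in cm_chroms:
                b = cm_tpl.bin_of(chrom, rank * GENE_SPACING_BP)
                near_boundary = bool({b - 1, b, b + 1} & boundary_bins)
                gene_zone[gid] = "border" if near_boundary else "interior"
            else:
                gene_zone[gid] = "outside"
        truth.methylation_zone = gene_zone
        meth = simulate_methylation(gene_zone, rng)
    else:
        expr = pd.DataFrame(columns=["gene_id", "tissue", "replicate", "tpm"])
        meth = pd.DataFrame(columns=["gene_id", "mC"])
        contact = None

    truth.chromosome_counts["Ps"] = layouts["Ps"].n_chromosomes
    truth.chromosome_counts["Pn"] = layouts["Pn"].n_chromosomes
    return Fig1Replay(config, layouts, species_seqs, anc_seqs, hom_anc,
                      hom_self, expr, meth, contact, truth)


# ---------------------------------------------------------------------------
# small replay scenarios for retention statistics
# ---------------------------------------------------------------------------

@dataclass
class RetentionReplay:
    region_classes: dict[tuple, list[str]]   # class -> gene ids
    locus_of: dict[str, str]
    ancestral_loci: list[str]
    truth_counts: dict


def c6b_replay(seed: int = 0, n_both: int = 69, n_only_a: int = 98,
               n_only_b: int = 112) -> RetentionReplay:
    """One duplication-derived segment pair with an explicit retention
    implant: ``n_both`` loci keep both copies, the rest fall back to
    singletons on one side or the other."""
    rng = np.random.default_rng(seed)
    n = n_both + n_only_a + n_only_b
    loci = [f"C6bL{i:04d}" for i in range(n)]
    status = np.array(["both"] * n_both + ["only_a"] * n_only_a
                      + ["only_b"] * n_only_b)
    rng.shuffle(status)
    cls_a, cls_b = (6, "C", "a"), (6, "C", "b")
    classes: dict[tuple, list[str]] = {cls_a: [], cls_b: []}
    locus_of: dict[str, str] = {}
    for locus, st in zip(loci, status):
        if st in ("both", "only_a"):
            gid = f"{locus}.a"
            classes[cls_a].append(gid)
            locus_of[gid] = locus
        if st in ("both", "only_b"):
            gid = f"{locus}.b"
            classes[cls_b].append(gid)
            locus_of[gid] = locus
    return RetentionReplay(classes, locus_of, loci,
                           {"both": n_both, "only_a": n_only_a,
                            "only_b": n_only_b})


def retention_replay(seed: int = 0, n_loci: int = 14_821, n_high: int = 993
                     ) -> RetentionReplay:
    """Diploid-scale retention implant over the six duplicated region
    classes: exactly ``n_high`` loci keep more than half (>3) of their six
    copies; every other locus keeps 1-3 copies."""
    rng = np.random.default_rng(seed)
    classes6 = [(e, g, b) for e in [1] for g in "ABC" for b in "ab"]
    high = np.zeros(n_loci, dtype=bool)
    high[rng.choice(n_loci, size=n_high, replace=False)] = True
    k = np.where(high,
                 rng.choice([4, 5, 6], size=n_loci, p=[0.6, 0.3, 0.1]),
                 rng.choice([1, 2, 3], size=n_loci, p=[0.3, 0.4, 0.3]))
    pick = np.argsort(rng.random((n_loci, 6)), axis=1)
    region_classes: dict[tuple, list[str]] = {c: [] for c in classes6}
    locus_of: dict[str, str] = {}
    loci = [f"L{i:05d}" for i in range(n_loci)]
    for i, locus in enumerate(loci):
        for c_idx in pick[i, :k[i]]:
            gid = f"{locus}.{c_idx}"
            region_classes[classes6[c_idx]].append(gid)
            locus_of[gid] = locus
    return RetentionReplay(region_classes, locus_of, loci,
                           {"n_high": int(n_high), "n_loci": int(n_loci)})


# ---------------------------------------------------------------------------
# tetraploid / diploid-relative scenario for subgenome assignment
# ---------------------------------------------------------------------------

def make_tetraploid_scenario(seed: int = 0, n_chrom: int = 3,
                             genes_per_chrom: int = 80,
                             ks_a: float = 0.6, ks_b: float = 0.25
                             ) -> dict:
    """A diploid relative plus a tetraploid whose subgenome B is closer to
    the relative (Ks ``ks_b``) than subgenome A (``ks_a``)."""
    cfg = SimulationConfig(seed=seed, n_anc_chrom=n_chrom,
                           genes_per_chrom=genes_per_chrom)
    rng = np.random.default_rng(seed)
    genome, seqs = simulate_ancestral_genome(cfg, rng)
    order = list(genome.all_genes())
    base = np.stack([seqs[g.uid] for g in order])
    t_a = calibrate_branch_length(ks_a)
    t_b = calibrate_branch_length(ks_b)
    arr_d = _evolve(base, min(t_a, t_b) / 2, rng)      # the diploid relative
    arr_sa = _evolve(base, 2 * t_a - min(t_a, t_b) / 2, rng)
    arr_sb = _evolve(base, 2 * t_b - min(t_a, t_b) / 2, rng)

    def emit(prefix, arr, chrom_suffix):
        genes, smap, idx = [], {}, 0
        for c in range(1, n_chrom + 1):
            for r in range(genes_per_chrom):
                gid = f"{prefix}g{idx:05d}"
                start = r * GENE_SPACING_BP + 1
                genes.append(GeneModel(gid, f"{prefix}_{c}{chrom_suffix}", start,
                                       start + GENE_LENGTH_BP - 1, "+",
                                       family_id=order[idx].locus))
                smap[gid] = arr[idx]
                idx += 1
        return GenomeLayout(prefix, genes), smap

    dip_layout, dip_seqs = emit("Dip", arr_d, "")
    sa_layout, sa_seqs = emit("TetA", arr_sa, "")
    sb_layout, sb_seqs = emit("TetB", arr_sb, "")
    tet_genes = list(sa_layout.genes()) + list(sb_layout.genes())
    tet_layout = GenomeLayout("Tet", tet_genes)
    tet_seqs = {**sa_seqs, **sb_seqs}
    dip_ids = sorted(dip_seqs)
    hom = []
    for prefix_seqs in (sa_seqs, sb_seqs):
        ids = sorted(prefix_seqs)
        hom += _homology_records(ids, prefix_seqs, dip_ids, dip_seqs)
    return {"diploid": dip_layout, "diploid_seqs": dip_seqs,
            "tetraploid": tet_layout, "tetraploid_seqs": tet_seqs,
            "homology": hom,
            "truth_subgenome": {**{c: "A" for c in sa_layout.chromosomes},
                                **{c: "B" for c in sb_layout.chromosomes}}}
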