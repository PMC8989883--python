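"""Retention and fractionation statistics, expression triads, methylation.

Fractionation is summarized over a presence matrix of ancestral loci by
duplicated region class (up to six classes: three triplication copies times
two duplication copies). Expression triads normalize a gene's leaf/root/stem
TPM to fractions summing to one and classify it against the seven
wheat-style archetypes (balanced, three tissue-dominant, three
tissue-suppressed) by nearest Euclidean distance in the fraction simplex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

log = logging.getLogger("paleoshuffle")

__all__ = [
    "RetentionMatrix",
    "TriadRecord",
    "build_retention_matrix",
    "retention_summary",
    "pair_retention_classes",
    "triad_normalize",
    "classify_triad",
    "classify_triads_frame",
    "classify_methylation",
    "expression_diversity_specificity",
    "average_replicates",
    "TRIAD_ARCHETYPES",
]

TRIAD_ARCHETYPES: dict[str, np.ndarray] = {
    "Balanced": np.array([1 / 3, 1 / 3, 1 / 3]),
    "Leaf-dominant": np.array([1.0, 0.0, 0.0]),
    "Root-dominant": np.array([0.0, 1.0, 0.0]),
    "Stem-dominant": np.array([0.0, 0.0, 1.0]),
    "Leaf-suppressed": np.array([0.0, 0.5, 0.5]),
    "Root-suppressed": np.array([0.5, 0.0, 0.5]),
    "Stem-suppressed": np.array([0.5, 0.5, 0.0]),
}

TISSUES = ("leaf", "root", "stem")


# ---------------------------------------------------------------------------
# retention / fractionation
# ---------------------------------------------------------------------------

@dataclass
class RetentionMatrix:
    """Presence of ancestral loci (rows) across region classes (columns);
    every present cell maps to exactly one extant gene id."""

    presence: pd.DataFrame              # bool, index=locus, columns=class
    gene_of: dict[tuple[str, tuple], str]   # (locus, class) -> gene_id

    @property
    def loci(self) -> list[str]:
        return list(self.presence.index)

    @property
    def classes(self) -> list[tuple]:
        return list(self.presence.columns)


def build_retention_matrix(region_classes: Mapping[tuple, Sequence[str]],
                           locus_of: Mapping[str, str],
                           ancestral_loci: Optional[Sequence[str]] = None
                           ) -> RetentionMatrix:
    """Presence matrix from region-class gene lists.

    A gene mapped to two classes is an upstream painting bug and raises.
    Loci absent from every class are dropped (count logged).
    """
    seen_gene: dict[str, tuple] = {}
    cells: dict[tuple[str, tuple], str] = {}
    for cls, genes in region_classes.items():
        for gid in genes:
            if gid in seen_gene and seen_gene[gid] != cls:
                raise ValueError(f"gene {gid!r} mapped to two region classes "
                                 f"{seen_gene[gid]} and {cls}")
            seen_gene[gid] = cls
            locus = locus_of.get(gid)
            if locus is None:
                continue
            cells[(locus, cls)] = gid
    classes = sorted(region_classes)
    loci = sorted({loc for loc, _ in cells})
    if ancestral_loci is not None:
        wanted = [l for l in ancestral_loci if l in set(loci)]
        dropped = len(set(ancestral_loci)) - len(wanted)
        if dropped:
            log.info("build_retention_matrix: %d loci absent everywhere, dropped",
                     dropped)
        loci = sorted(wanted)
    row_of = {l: i for i, l in enumerate(loci)}
    col_of = {c: j for j, c in enumerate(classes)}
    arr = np.zeros((len(loci), len(classes)), dtype=bool)
    for (locus, cls) in cells:
        i = row_of.get(locus)
        if i is not None:
            arr[i, col_of[cls]] = True
    mat = pd.DataFrame(arr, index=loci,
                       columns=pd.Index(classes, tupleize_cols=False))
    return RetentionMatrix(mat, cells)


def retention_summary(matrix: RetentionMatrix, threshold_more_than: int = 3
                      ) -> dict:
    """Counts/percentages of high-retention loci (row sum > threshold) plus
    per-class retention rates."""
    rowsum = matrix.presence.sum(axis=1)
    n = len(rowsum)
    n_high = int((rowsum > threshold_more_than).sum())
    per_class = {cls: float(matrix.presence[cls].mean())
                 for cls in matrix.presence.columns}
    return {
        "n_loci": n,
        "n_high_retention": n_high,
        "pct_high_retention": 100.0 * n_high / n if n else float("nan"),
        "threshold_more_than": threshold_more_than,
        "per_class_retention_rate": per_class,
        "mean_copies_per_locus": float(rowsum.mean()) if n else float("nan"),
    }


def pair_retention_classes(matrix: RetentionMatrix, class_1: tuple,
                           class_2: tuple) -> dict:
    """Both/singleton/absent status of each locus over one duplication-
    derived segment pair; percentages over loci present in >= 1 copy.

    The two classes must be the two duplication sides of one
    (ancestral chromosome, triplication copy) class.
    """
    for cls in (class_1, class_2):
        if cls not in matrix.presence.columns:
            raise ValueError(f"{cls} not a region class of this matrix")
    if class_1[:-1] != class_2[:-1] or class_1[-1] == class_2[-1]:
        raise ValueError(f"{class_1} and {class_2} are not a duplication pair")
    in1 = matrix.presence[class_1]
    in2 = matrix.presence[class_2]
    both = int((in1 & in2).sum())
    only1 = int((in1 & ~in2).sum())
    only2 = int((~in1 & in2).sum())
    absent = int((~in1 & ~in2).sum())
    present = both + only1 + only2
    pct = (lambda x: 100.0 * x / present if present else float("nan"))
    status = pd.Series(
        np.select([in1 & in2, in1 & ~in2, ~in1 & in2],
                  ["both", "singleton_copy1", "singleton_copy2"], "absent"),
        index=matrix.presence.index)
    return {"both": both, "singleton_copy1": only1, "singleton_copy2": only2,
            "absent": absent,
            "pct_both": pct(both), "pct_singleton_copy1": pct(only1),
            "pct_singleton_copy2": pct(only2), "status": status}


# ---------------------------------------------------------------------------
# expression triads
# ---------------------------------------------------------------------------

@dataclass
class TriadRecord:
    gene_id: str
    tpm: tuple[float, float, float]
    fractions: Optional[tuple[float, float, float]]
    category: Optional[str]     # None when not expressed

    @property
    def expressed(self) -> bool:
        return self.fractions is not None


def average_replicates(expression: pd.DataFrame) -> pd.DataFrame:
    """Mean TPM per gene x tissue (replicates averaged); wide frame with one
    column per tissue."""
    wide = (expression.groupby(["gene_id", "tissue"])["tpm"].mean()
            .unstack("tissue"))
    missing = [t for t in TISSUES if t not in wide.columns]
    if missing:
        raise ValueError(f"expression table lacks tissues {missing}")
    return wide[list(TISSUES)].fillna(0.0)


def triad_normalize(tpm_leaf: float, tpm_root: float, tpm_stem: float
                    ) -> Optional[tuple[float, float, float]]:
    """Tissue fractions: each TPM over the triad sum; None when the triad is
    all zero (flagged not expressed by the caller)."""
    total = tpm_leaf + tpm_root + tpm_stem
    if total <= 0:
        return None
    return (tpm_leaf / total, tpm_root / total, tpm_stem / total)


def classify_triad(fractions: Sequence[float]) -> str:
    """Nearest-archetype category in the fraction simplex; exact distance
    ties resolve to Balanced (logged)."""
    f = np.asarray(fractions, dtype=float)
    if not np.isclose(f.sum(), 1.0, atol=1e-6):
        raise ValueError("fractions must sum to 1")
    names = list(TRIAD_ARCHETYPES)
    d = np.array([np.linalg.norm(f - TRIAD_ARCHETYPES[n]) for n in names])
    best = float(d.min())
    winners = [n for n, x in zip(names, d) if np.isclose(x, best, atol=1e-12)]
    if len(winners) > 1:
        log.info("classify_triad: distance tie among %s -> Balanced", winners)
        return "Balanced" if "Balanced" in winners else sorted(winners)[0]
    return winners[0]


def classify_triads_frame(expression: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged triads for every gene: fractions + category.

    Returns a frame indexed by gene_id with columns tpm_leaf/root/stem,
    frac_leaf/root/stem, category (NaN fractions and category
    "not_expressed" for all-zero triads).
    """
    wide = average_replicates(expression)
    rows = []
    for gid, (tl, tr, ts) in wide.iterrows():
        fr = triad_normalize(tl, tr, ts)
        if fr is None:
            rows.append((gid, tl, tr, ts, np.nan, np.nan, np.nan, "not_expressed"))
        else:
            assert abs(sum(fr) - 1.0) < 1e-9
            rows.append((gid, tl, tr, ts, *fr, classify_triad(fr)))
    return pd.DataFrame(rows, columns=["gene_id", "tpm_leaf", "tpm_root",
                                       "tpm_stem", "frac_leaf", "frac_root",
                                       "frac_stem", "category"]).set_index("gene_id")


# ---------------------------------------------------------------------------
# methylation classes
# ---------------------------------------------------------------------------

def classify_methylation(mC: float, hypo_max: float = 0.3,
                         hyper_min: float = 0.7) -> str:
    """hypo (mC <= hypo_max), hyper (mC >= hyper_min), else intermediate;
    boundaries inclusive."""
    if not (0.0 <= mC <= 1.0):
        raise ValueError(f"mC {mC} outside [0, 1]")
    if mC <= hypo_max:
        return "hypo"
    if mC >= hyper_min:
        return "hyper"
    return "intermediate"


# ---------------------------------------------------------------------------
# expression diversity / specificity per region class
# ---------------------------------------------------------------------------

def _tau(profile: np.ndarray) -> float:
    """Tissue-specificity tau: sum(1 - x/x_max) / (n - 1)."""
    m = profile.max()
    if m <= 0:
        return float("nan")
    return float((1.0 - profile / m).sum() / (len(profile) - 1))


def expression_diversity_specificity(
        triads: pd.DataFrame, class_of_gene: Mapping[str, tuple]
) -> pd.DataFrame:
    """Per region class: Dj = mean pairwise Jensen-Shannon distance (base 2)
    of tissue-fraction profiles; Sj = mean tau specificity. Both in [0, 1].
    Classes with a single expressed gene get Dj = NaN (flagged).
    """
    frac_cols = ["frac_leaf", "frac_root", "frac_stem"]
    rows = []
    by_class: dict[tuple, list[np.ndarray]] = {}
    for gid, rec in triads.iterrows():
        cls = class_of_gene.get(gid)
        if cls is None or rec["category"] == "not_expressed":
            continue
        by_class.setdefault(cls, []).append(rec[frac_cols].to_numpy(dtype=float))
    for cls in sorted(by_class):
        profs = by_class[cls]
        sj = float(np.mean([_tau(p) for p in profs]))
        if len(profs) < 2:
            dj = float("nan")
        else:
            # subsample pair set for very large classes
            d = []
            for i in range(len(profs)):
                for j in range(i + 1, min(i + 51, len(profs))):
                    v = jensenshannon(profs[i], profs[j], base=2)
                    # identical profiles can come back as sqrt of a tiny
                    # negative -> NaN; that distance is zero
                    d.append(0.0 if not np.isfinite(v) else float(v))
            dj = float(np.mean(d))
        rows.append((cls, len(profs), dj, sj))
    out = pd.DataFrame(rows, columns=["region_class", "n_genes", "Dj", "Sj"])
    out.attrs["definitions"] = (
        "Dj: mean pairwise Jensen-Shannon distance (base 2) of tissue-fraction "
        "profiles within the region class; Sj: mean tau specificity "
        "sum(1 - x_i/x_max)/(n_tissues - 1)")
    return out
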