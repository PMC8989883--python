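"""Hi-C matrix balancing, A/B compartments, insulation-score TADs, and
topology comparison across duplicated region classes.

Masked (low-coverage) bins are NA-propagated, never zero-filled; zero-fill
would bias the compartment eigenvectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .io_formats import ContactMatrix
from .karyotype import SegmentPainting

log = logging.getLogger("paleoshuffle")

__all__ = [
    "CompartmentTrack",
    "InsulationTrack",
    "TADInterval",
    "ice_balance",
    "observed_over_expected",
    "call_compartments",
    "insulation_score",
    "call_tads",
    "compare_region_topology",
    "profile_over_tads",
]


@dataclass
class CompartmentTrack:
    chrom: str
    eigenvector: np.ndarray    # NaN for masked bins
    labels: np.ndarray         # 'A' | 'B' | 'NA'


@dataclass
class InsulationTrack:
    chrom: str
    score: np.ndarray          # log2 vs chromosome mean; NaN near ends
    window_bins: int


@dataclass
class TADInterval:
    chrom: str
    start_bin: int             # chromosome-local, half-open
    end_bin: int
    boundary_strength_left: float
    boundary_strength_right: float


# ---------------------------------------------------------------------------
# ICE balancing
# ---------------------------------------------------------------------------

def ice_balance(cm: ContactMatrix, max_iter: int = 200, tol: float = 1e-5,
                min_bin_coverage_quantile: float = 0.02
                ) -> tuple[ContactMatrix, np.ndarray]:
    """Iterative correction: equalize bin coverage until the coefficient of
    variation of nonzero-row sums drops below ``tol``.

    Bins whose raw coverage falls below the given quantile are masked (NaN
    rows/columns). Returns (balanced matrix, bias vector b) with
    raw ≈ b_i · b_j · balanced on unmasked bins.
    """
    raw = cm.counts.copy()
    if not np.nansum(raw):
        raise ValueError("all-zero contact matrix cannot be balanced")
    n = raw.shape[0]
    coverage = np.nansum(raw, axis=1)
    cutoff = np.quantile(coverage[coverage > 0], min_bin_coverage_quantile)
    mask = coverage < cutoff
    work = raw.astype(float)
    work[mask, :] = np.nan
    work[:, mask] = np.nan
    bias = np.ones(n)
    for it in range(max_iter):
        s = np.nansum(work, axis=1)
        live = ~mask & (s > 0)
        if not live.any():
            break
        cv = s[live].std() / s[live].mean()
        if cv < tol:
            break
        corr = np.where(live, s / s[live].mean(), 1.0)
        bias *= corr
        work /= corr[:, None]
        work /= corr[None, :]
    # rescale so the balanced matrix keeps the raw total
    total_raw = np.nansum(raw[~mask][:, ~mask])
    total_bal = np.nansum(work)
    if total_bal > 0:
        scale = np.sqrt(total_raw / total_bal)
        work *= total_raw / total_bal
        bias /= scale
    out = ContactMatrix(work, cm.resolution, cm.chrom_sizes, balanced=True)
    log.info("ice_balance: %d/%d bins masked, %d iterations", mask.sum(), n, it + 1)
    return out, bias


# ---------------------------------------------------------------------------
# observed / expected
# ---------------------------------------------------------------------------

def observed_over_expected(cm: ContactMatrix, chrom: str,
                           lowess_frac: float = 0.3) -> np.ndarray:
    """Per-chromosome O/E: expected(d) is a lowess-smoothed (falling back to
    plain means for short chromosomes) average of counts at bin-distance d;
    NaN propagates through masked bins."""
    sl = cm.chrom_slice(chrom)
    m = cm.counts[sl, sl]
    n = m.shape[0]
    exp_d = np.empty(n)
    for d in range(n):
        diag = np.diagonal(m, offset=d)
        exp_d[d] = np.nanmean(diag) if np.isfinite(diag).any() else np.nan
    finite = np.isfinite(exp_d) & (exp_d > 0)
    if finite.sum() >= 10:
        from statsmodels.nonparametric.smoothers_lowess import lowess
        dist = np.arange(n)[finite]
        sm = lowess(np.log(exp_d[finite]), dist, frac=lowess_frac,
                    return_sorted=False)
        exp_d[finite] = np.exp(sm)
    expected = np.empty_like(m)
    idx = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    expected = exp_d[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = m / expected
    return oe


# ---------------------------------------------------------------------------
# A/B compartments
# ---------------------------------------------------------------------------

def call_compartments(oe: np.ndarray, chrom: str,
                      gene_density: Optional[np.ndarray] = None
                      ) -> CompartmentTrack:
    """Leading eigenvector of the Pearson-correlation matrix of O/E.

    Positive entries are compartment A; the sign is oriented so the positive
    (A) set has the higher mean gene density when a density track is given.
    Masked bins stay NA. A near-constant matrix yields all-NA with a warning.
    """
    n = oe.shape[0]
    valid = np.isfinite(oe).sum(axis=1) > max(2, n // 10)
    ev = np.full(n, np.nan)
    labels = np.array(["NA"] * n, dtype=object)
    sub = oe[np.ix_(valid, valid)]
    if sub.shape[0] < 3 or np.nanstd(sub) < 1e-12:
        log.warning("call_compartments[%s]: degenerate matrix, all NA", chrom)
        return CompartmentTrack(chrom, ev, labels)
    x = np.where(np.isfinite(sub), sub, np.nanmean(sub))
    corr = np.corrcoef(x)
    corr = np.nan_to_num(corr)
    vals, vecs = np.linalg.eigh(corr)
    lead = vecs[:, -1]
    if gene_density is not None:
        dens = np.asarray(gene_density, dtype=float)[valid]
        pos_mean = dens[lead > 0].mean() if (lead > 0).any() else -np.inf
        neg_mean = dens[lead < 0].mean() if (lead < 0).any() else -np.inf
        if neg_mean > pos_mean:
            lead = -lead
    elif lead.sum() < 0:
        lead = -lead  # deterministic orientation without a density track
    ev[valid] = lead
    labels[valid] = np.where(lead > 0, "A", "B")
    return CompartmentTrack(chrom, ev, labels)


# ---------------------------------------------------------------------------
# insulation score and TAD calling
# ---------------------------------------------------------------------------

def insulation_score(cm: ContactMatrix, chrom: str,
                     window: int = 500_000) -> InsulationTrack:
    """Mean counts in a square window sliding along the diagonal
    (bins i-w..i-1 x i+1..i+w), log2-normalized by the chromosome mean;
    NaN within w bins of the chromosome ends."""
    w = window // cm.resolution
    if w < 2:
        raise ValueError("insulation window must span >= 2 bins")
    sl = cm.chrom_slice(chrom)
    m = cm.counts[sl, sl]
    n = m.shape[0]
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        sq = m[i - w:i, i + 1:i + 1 + w]
        raw[i] = np.nanmean(sq)
    finite = np.isfinite(raw) & (raw > 0)
    if not finite.any():
        return InsulationTrack(chrom, raw, w)
    mean = raw[finite].mean()
    score = np.full(n, np.nan)
    score[finite] = np.log2(raw[finite] / mean)
    return InsulationTrack(chrom, score, w)


def _viterbi_two_state(obs: np.ndarray, stay: float = 0.95) -> np.ndarray:
    """2-state (interior/boundary) Gaussian Viterbi smoothing of insulation
    scores; optional refinement, default OFF in call_tads."""
    x = obs[np.isfinite(obs)]
    mu = np.array([np.quantile(x, 0.7), np.quantile(x, 0.05)])
    sd = max(x.std(), 1e-3)
    logp = np.log(np.array([[stay, 1 - stay], [1 - stay, stay]]))
    ll = np.full((len(obs), 2), -np.inf)
    ptr = np.zeros((len(obs), 2), dtype=int)
    def emit(o):
        if not np.isfinite(o):
            return np.zeros(2)
        return -0.5 * ((o - mu) / sd) ** 2
    ll[0] = np.log([0.5, 0.5]) + emit(obs[0])
    for t in range(1, len(obs)):
        for s in range(2):
            cand = ll[t - 1] + logp[:, s]
            ptr[t, s] = int(np.argmax(cand))
            ll[t, s] = cand[ptr[t, s]] + emit(obs[t])[s]
    path = np.zeros(len(obs), dtype=int)
    path[-1] = int(np.argmax(ll[-1]))
    for t in range(len(obs) - 2, -1, -1):
        path[t] = ptr[t + 1, path[t + 1]]
    return path


def call_tads(track: InsulationTrack, delta_span: int = 100_000,
              boundary_strength_min: float = 0.1, resolution: int = 20_000,
              hmm_refine: bool = False) -> list[TADInterval]:
    """TADs between insulation minima.

    Candidate boundaries are local minima of the insulation score whose
    depth relative to the flanking mean score (over ``delta_span``) reaches
    ``boundary_strength_min``; TADs tile the chromosome between successive
    boundaries. ``hmm_refine`` applies a 2-state Viterbi smoothing of the
    score before minima detection (OFF by default).
    """
    raw = track.score.copy()
    n = len(raw)
    d = max(1, delta_span // resolution)
    if hmm_refine:
        path = _viterbi_two_state(raw)
        raw = np.where(path == 1, raw, raw)
    # 3-bin moving average: single-bin count noise otherwise shifts the
    # minimum by a bin or two
    score = raw.copy()
    for i in range(1, n - 1):
        win = raw[i - 1:i + 2]
        if np.isfinite(win).all():
            score[i] = win.mean()
    boundaries: list[tuple[int, float]] = []
    for i in range(1, n - 1):
        if not np.isfinite(score[i]):
            continue
        left = score[max(0, i - d):i]
        right = score[i + 1:i + 1 + d]
        lf, rf = left[np.isfinite(left)], right[np.isfinite(right)]
        if lf.size == 0 or rf.size == 0:
            continue
        if score[i] > lf.min() or score[i] > rf.min():
            continue  # not a local minimum over the delta span
        strength = min(lf.mean(), rf.mean()) - score[i]
        if strength >= boundary_strength_min:
            boundaries.append((i, float(strength)))
    # deduplicate plateaus: keep the deepest bin of each run of minima
    dedup: list[tuple[int, float]] = []
    for b, s in boundaries:
        if dedup and b - dedup[-1][0] <= d:
            if score[b] < score[dedup[-1][0]]:
                dedup[-1] = (b, s)
        else:
            dedup.append((b, s))
    tads: list[TADInterval] = []
    prev, prev_s = 0, 0.0
    for b, s in dedup:
        if b > prev:
            tads.append(TADInterval(track.chrom, prev, b, prev_s, s))
        prev, prev_s = b, s
    if prev < n:
        tads.append(TADInterval(track.chrom, prev, n, prev_s, 0.0))
    for t1, t2 in zip(tads, tads[1:]):
        assert t1.end_bin <= t2.start_bin, "TADs overlap"
    return tads


# ---------------------------------------------------------------------------
# topology comparison across duplicated region classes
# ---------------------------------------------------------------------------

def _region_bins(cm: ContactMatrix, painting: SegmentPainting,
                 gene_bp_of, min_bins: int = 2) -> dict[tuple, np.ndarray]:
    """Bins covered by each region class (via its segments' gene spans)."""
    out: dict[tuple, set[int]] = {}
    for seg in painting.all_segments():
        if seg.chrom not in cm.chrom_sizes:
            continue
        b1 = cm.bin_of(seg.chrom, max(0, seg.bp_start - 1))
        b2 = cm.bin_of(seg.chrom, min(seg.bp_end - 1,
                                      cm.chrom_sizes[seg.chrom] - 1))
        out.setdefault(seg.full_class(), set()).update(range(b1, b2 + 1))
    final = {}
    for cls, bins in out.items():
        if len(bins) < min_bins:
            log.warning("compare_region_topology: class %s spans < %d bins, "
                        "skipped", cls, min_bins)
            continue
        final[cls] = np.array(sorted(bins))
    return final


def compare_region_topology(cm: ContactMatrix, painting: SegmentPainting,
                            compartment_labels: Optional[Mapping[int, str]] = None,
                            junction_bins: Optional[Sequence[int]] = None
                            ) -> dict:
    """Mean log2 normalized contact per region-class pair; within- vs
    between-ancestor contrast (two-sample t); optional fraction of A/B
    switch points overlapping fusion-junction bins (± 1 bin)."""
    regions = _region_bins(cm, painting, None)
    total = np.nansum(cm.counts)
    pair_log2: dict[tuple, float] = {}
    within, between = [], []
    classes = sorted(regions)
    for i, c1 in enumerate(classes):
        for c2 in classes[i + 1:]:
            sub = cm.counts[np.ix_(regions[c1], regions[c2])]
            if not np.isfinite(sub).any():
                continue
            mean_norm = np.nanmean(sub) / total
            val = float(np.log2(mean_norm)) if mean_norm > 0 else float("nan")
            pair_log2[(c1, c2)] = val
            if np.isfinite(val):
                (within if c1[0] == c2[0] else between).append(val)
    if len(within) >= 2 and len(between) >= 2:
        t_stat, p_val = stats.ttest_ind(within, between, equal_var=False)
    else:
        t_stat, p_val = float("nan"), float("nan")
    out = {"pair_log2": pair_log2,
           "within_ancestor_mean": float(np.mean(within)) if within else float("nan"),
           "between_ancestor_mean": float(np.mean(between)) if between else float("nan"),
           "t_stat": float(t_stat), "p_value": float(p_val)}
    if compartment_labels is not None and junction_bins is not None:
        switches = [b for b in range(1, cm.n_bins)
                    if compartment_labels.get(b) is not None
                    and compartment_labels.get(b - 1) is not None
                    and compartment_labels[b] != compartment_labels[b - 1]]
        jset = set(junction_bins)
        hits = sum(1 for b in switches
                   if jset & {b - 1, b, b + 1})
        out["switch_junction_overlap"] = (hits / len(switches)
                                          if switches else float("nan"))
    return out


def profile_over_tads(tads: Sequence[TADInterval], cm: ContactMatrix,
                      gene_bins: Mapping[str, int],
                      gene_mC: Mapping[str, float],
                      gene_tpm: Mapping[str, float],
                      flank_bins: int = 5, n_interior_bins: int = 20) -> dict:
    """Interior vs border aggregate methylation / expression.

    Border = boundary bin ± 1; every gene lands in exactly one zone. Also
    returns a rescaled meta-profile over ``n_interior_bins`` interior
    quantile bins plus flanks.
    """
    if not gene_bins:
        raise ValueError("no genes in scope")
    boundary = set()
    tad_of_bin: dict[int, tuple[int, int]] = {}
    for t in tads:
        off = cm.chrom_offsets[t.chrom]
        lo, hi = off + t.start_bin, off + t.end_bin
        boundary |= {lo - 1, lo, lo + 1, hi - 2, hi - 1, hi}
        for b in range(lo, hi):
            tad_of_bin[b] = (lo, hi)
    zones: dict[str, str] = {}
    for gid, b in gene_bins.items():
        if b in boundary:
            zones[gid] = "border"
        elif b in tad_of_bin:
            zones[gid] = "interior"
        else:
            zones[gid] = "outside"
    def zone_mean(track, zone):
        vals = [track[g] for g, z in zones.items() if z == zone and g in track]
        return float(np.mean(vals)) if vals else float("nan")
    # meta-profile over rescaled interior position
    prof_mC = np.full(n_interior_bins + 2 * flank_bins, np.nan)
    acc: dict[int, list[float]] = {}
    for gid, b in gene_bins.items():
        if gid not in gene_mC:
            continue
        if b in tad_of_bin:
            lo, hi = tad_of_bin[b]
            rel = (b - lo + 0.5) / (hi - lo)
            slot = flank_bins + min(int(rel * n_interior_bins), n_interior_bins - 1)
        else:
            continue
        acc.setdefault(slot, []).append(gene_mC[gid])
    for slot, vals in acc.items():
        prof_mC[slot] = float(np.mean(vals))
    return {"zones": zones,
            "interior_mC": zone_mean(gene_mC, "interior"),
            "border_mC": zone_mean(gene_mC, "border"),
            "interior_tpm": zone_mean(gene_tpm, "interior"),
            "border_tpm": zone_mean(gene_tpm, "border"),
            "meta_profile_mC": prof_mC}
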