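"""Ks/Ka estimation (Nei–Gojobori 1986), Ks mixture dating and LTR ages.

The NG86 estimator counts synonymous (S) and nonsynonymous (N) sites per
codon, averages multi-difference codons over all substitution pathways
(pathways through stop codons excluded; if every pathway is blocked the
average falls back to all pathways), and applies the Jukes–Cantor correction
Ks = -(3/4) ln(1 - (4/3) ps). Mutations to stop codons are excluded from
site counting (per-position denominator 3 minus the number of stop changes).

Per-event dating follows the block-median convention: the median Ks of a
collinear block places the block on the mixture of WGD peaks fitted to the
genome-wide Ks distribution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde

log = logging.getLogger("paleoshuffle")

__all__ = [
    "CodonAlignment",
    "KsEstimate",
    "KsMixture",
    "ks_ng86",
    "ks_ng86_many",
    "block_median_ks",
    "ks_density",
    "fit_ks_mixture",
    "plot_ks_mixture",
    "assign_blocks_to_events",
    "ltr_age",
    "k2p_distance",
    "SENSE_CODONS",
    "codon_str_to_idx",
    "codon_idx_to_str",
]

# ---------------------------------------------------------------------------
# genetic-code tables
# ---------------------------------------------------------------------------

_BASES = "TCAG"


def _build_code() -> dict[str, str]:
    from Bio.Data.CodonTable import unambiguous_dna_by_id
    tab = unambiguous_dna_by_id[1]  # the standard code
    code = dict(tab.forward_table)
    for stop in tab.stop_codons:
        code[stop] = "*"
    return code


GENETIC_CODE: dict[str, str] = _build_code()
ALL_CODONS: list[str] = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
SENSE_CODONS: list[str] = [c for c in ALL_CODONS if GENETIC_CODE[c] != "*"]
_SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}


def codon_str_to_idx(seq: str) -> np.ndarray:
    """Nucleotide string -> array of sense-codon indices."""
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    out = np.empty(len(seq) // 3, dtype=np.int16)
    for i in range(0, len(seq), 3):
        cod = seq[i:i + 3].upper()
        if cod not in _SENSE_INDEX:
            raise ValueError(f"internal stop or invalid codon {cod!r} at nt {i}")
        out[i // 3] = _SENSE_INDEX[cod]
    return out


def codon_idx_to_str(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)


def _syn_sites(codon: str) -> float:
    """NG86 synonymous-site count of one sense codon.

    Per position: (# synonymous changes) / (# non-stop changes).
    """
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if GENETIC_CODE[mut] == "*":
                continue
            tot += 1
            if GENETIC_CODE[mut] == aa:
                syn += 1
        if tot:
            s += syn / tot
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences of one codon pair."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(diff):
        cur, sd, nd, through_stop = c1, 0.0, 0.0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                through_stop = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur] and GENETIC_CODE[nxt] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else valid).append((sd, nd))
    pool = valid or blocked
    return (float(np.mean([p[0] for p in pool])),
            float(np.mean([p[1] for p in pool])))


def _build_pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(SENSE_CODONS)
    s_sites = np.array([_syn_sites(c) for c in SENSE_CODONS])
    sd = np.zeros((n, n))
    nd = np.zeros((n, n))
    for i, a in enumerate(SENSE_CODONS):
        for j in range(i + 1, n):
            b = SENSE_CODONS[j]
            sd[i, j], nd[i, j] = _pathway_counts(a, b)
            sd[j, i], nd[j, i] = sd[i, j], nd[i, j]
    return s_sites, sd, nd


_S_SITES, _SD_TAB, _ND_TAB = _build_pair_tables()


# ---------------------------------------------------------------------------
# NG86 estimator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free, equal-length, in-frame nucleotide pair."""

    seq_a: str
    seq_b: str

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("sequences differ in length")
        if len(self.seq_a) % 3:
            raise ValueError("alignment length not divisible by 3")


@dataclass(frozen=True)
class KsEstimate:
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float  # NaN when saturated
    Ka: float
    saturated: bool


def _jc(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0), False


def ks_ng86(aln: CodonAlignment) -> KsEstimate:
    """Nei–Gojobori Ks/Ka for one codon alignment."""
    a = codon_str_to_idx(aln.seq_a)
    b = codon_str_to_idx(aln.seq_b)
    S = float((_S_SITES[a] + _S_SITES[b]).sum() / 2.0)
    N = 3.0 * len(a) - S
    Sd = float(_SD_TAB[a, b].sum())
    Nd = float(_ND_TAB[a, b].sum())
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks, sat_s = _jc(ps)
    Ka, _ = _jc(pn)
    return KsEstimate(S, N, Sd, Nd, ps, pn, Ks, Ka, sat_s)


def ks_ng86_many(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized Ks for stacked codon-index arrays of shape (n_pairs, n_codons).

    Saturated pairs (ps >= 3/4) come back NaN.
    """
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    S = (_S_SITES[a] + _S_SITES[b]).sum(axis=1) / 2.0
    Sd = _SD_TAB[a, b].sum(axis=1)
    ps = np.divide(Sd, S, out=np.zeros_like(S), where=S > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ks = np.where(ps < 0.75, -0.75 * np.log(1.0 - 4.0 * ps / 3.0), np.nan)
        ks = np.where(np.isinf(ks), np.nan, ks)
    return ks


# ---------------------------------------------------------------------------
# block summaries and mixture dating
# ---------------------------------------------------------------------------

def block_median_ks(ks_values: Sequence[float]) -> float:
    """Median of the unsaturated anchor Ks values of one block.

    Raises ValueError when every anchor is saturated (the caller should flag
    the block instead of dating it).
    """
    vals = np.asarray([v for v in ks_values if np.isfinite(v)])
    if vals.size == 0:
        raise ValueError("all anchor Ks values saturated; block undatable")
    return float(np.median(vals))


def ks_density(values: Sequence[float], bandwidth: Optional[float] = None,
               ks_max: float = 3.0, step: float = 0.005
               ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel Ks density on the grid [0, ks_max] (Silverman default).

    Returns (grid, density); the density integrates to ~1 over the grid for
    values well inside the range.
    """
    vals = np.asarray([v for v in values if np.isfinite(v)])
    if vals.size < 2:
        raise ValueError("need >= 2 finite Ks values for a density")
    grid = np.arange(0.0, ks_max + step / 2, step)
    kde = gaussian_kde(vals, bw_method="silverman" if bandwidth is None
                       else bandwidth / vals.std(ddof=1))
    return grid, kde(grid)


@dataclass
class KsMixture:
    """Gaussian mixture over Ks: components sorted by mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    bic: float
    log_likelihood: float
    fit_range: tuple[float, float]
    n: int

    @property
    def k(self) -> int:
        return len(self.means)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        dens = self.weights * _normal_pdf(x[:, None], self.means, self.sds)
        tot = dens.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        return dens / tot


def _normal_pdf(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def _em_1d(x: np.ndarray, w0, mu0, sd0, max_iter=500, tol=1e-8):
    """1-D Gaussian-mixture EM; asserts the log-likelihood never decreases.

    Component sds are floored at 1% of the data sd to keep single-point
    spike components from collapsing the likelihood."""
    w, mu, sd = map(lambda v: np.asarray(v, dtype=float).copy(), (w0, mu0, sd0))
    n = x.size
    sd_floor = max(1e-3, 0.01 * float(x.std(ddof=1)))
    prev_ll = -np.inf
    for _ in range(max_iter):
        dens = w * _normal_pdf(x[:, None], mu, sd) + 1e-300
        tot = dens.sum(axis=1)
        ll = float(np.log(tot).sum())
        assert ll >= prev_ll - 1e-6, "EM log-likelihood decreased"
        r = dens / tot[:, None]
        nk = r.sum(axis=0)
        w = nk / n
        mu = (r * x[:, None]).sum(axis=0) / nk
        sd = np.sqrt((r * (x[:, None] - mu) ** 2).sum(axis=0) / nk)
        sd = np.maximum(sd, sd_floor)
        if ll - prev_ll < tol:
            prev_ll = ll
            break
        prev_ll = ll
    order = np.argsort(mu)
    return w[order], mu[order], sd[order], prev_ll


def fit_ks_mixture(values: Sequence[float], k_range: Sequence[int] = range(1, 6),
                   fit_range: tuple[float, float] = (0.05, 3.0),
                   n_restarts: int = 5, seed: int = 0) -> KsMixture:
    """Fit Gaussian mixtures to Ks values and select k by BIC.

    Each k is initialized from the top-k KDE modes plus ``n_restarts`` seeded
    random restarts; the best restart by log-likelihood wins, the best k by
    BIC. Deterministic given ``seed``.
    """
    x = np.asarray([v for v in values
                    if np.isfinite(v) and fit_range[0] <= v <= fit_range[1]])
    if x.size < 50:
        raise ValueError(
            f"only {x.size} Ks values in {fit_range}; need >= 50 for mixture fitting")
    rng = np.random.default_rng(seed)
    grid, dens = ks_density(x, ks_max=fit_range[1])
    # KDE modes, highest first
    mod = np.where((dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:]))[0] + 1
    modes = grid[mod[np.argsort(dens[mod])[::-1]]] if mod.size else np.array([x.mean()])

    best: Optional[KsMixture] = None
    for k in k_range:
        inits = []
        mu0 = np.sort(np.concatenate([modes[:k],
                                      np.quantile(x, np.linspace(0.2, 0.8, k - len(modes[:k])))])
                      if len(modes) < k else modes[:k])
        inits.append(mu0)
        for _ in range(n_restarts):
            inits.append(np.sort(rng.choice(x, size=k, replace=False)))
        best_ll, best_fit = -np.inf, None
        for mu_init in inits:
            w, mu, sd, ll = _em_1d(
                x, np.full(k, 1.0 / k), np.asarray(mu_init, dtype=float),
                np.full(k, max(x.std(ddof=1) / k, 1e-3)))
            if ll > best_ll:
                best_ll, best_fit = ll, (w, mu, sd)
        w, mu, sd = best_fit
        p = 3 * k - 1
        bic = -2.0 * best_ll + p * np.log(x.size)
        cand = KsMixture(w, mu, sd, bic, best_ll, fit_range, x.size)
        if best is None or cand.bic < best.bic:
            best = cand
    log.info("fit_ks_mixture: n=%d, chose k=%d (BIC=%.1f) means=%s",
             best.n, best.k, best.bic, np.round(best.means, 3))
    return best


def assign_blocks_to_events(block_medians: Sequence[float], mixture: KsMixture
                            ) -> list[tuple[int, float]]:
    """Assign each block median to the mixture component of max posterior.

    Returns (component index ascending by mean, posterior) per block; exact
    ties break to the lower-mean component (logged).
    """
    out = []
    resp = mixture.responsibilities(np.asarray(block_medians, dtype=float))
    for i, r in enumerate(resp):
        best = int(np.argmax(r))  # argmax takes the first (lower-mean) on ties
        if np.sum(r == r[best]) > 1:
            log.info("assign_blocks_to_events: tie at block %d -> component %d", i, best)
        out.append((best, float(r[best])))
    return out


def plot_ks_mixture(values: Sequence[float], mixture: KsMixture, path,
                    bandwidth: Optional[float] = None) -> None:
    """KDE of the Ks distribution with the fitted mixture components
    overlaid; written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid, dens = ks_density(values, bandwidth=bandwidth,
                            ks_max=mixture.fit_range[1])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(grid, dens, color="k", lw=1.5, label="KDE")
    for w, mu, sdv in zip(mixture.weights, mixture.means, mixture.sds):
        ax.plot(grid, w * _normal_pdf(grid, mu, sdv), lw=1,
                label=f"peak {mu:.2f} (w={w:.2f})")
    ax.set_xlabel("Ks")
    ax.set_ylabel("density")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# K2P distance and LTR insertion age
# ---------------------------------------------------------------------------

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura 2-parameter distance; NaN when the log arguments saturate."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    if not seq_a:
        raise ValueError("empty sequences")
    n = len(seq_a)
    ts = tv = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x == y:
            continue
        if (x, y) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    P, Q = ts / n, tv / n
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        return float("nan")
    return -0.5 * np.log(arg1 * np.sqrt(arg2))


def ltr_age(K: float, r: float = 1.3e-8) -> float:
    """LTR insertion age in years: age = K / (2 r)."""
    if r <= 0:
        raise ValueError("rate r must be positive")
    if K < 0:
        raise ValueError("K must be >= 0")
    return K / (2.0 * r)
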