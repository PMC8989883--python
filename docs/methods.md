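# Methods

`paleoshuffle` implements a paleo-polyploidy comparative-genomics pipeline —
collinearity-based ancestral-karyotype reconstruction, Ks-based WGD dating,
biased-fractionation statistics, homoeolog expression-triad classification,
and Hi-C compartment/TAD analysis — together with a synthetic-genome
generator that implants a known polyploidy history so that every stage can
be verified against ground truth without any external data.

## The model system

The scenario the package is built around is the history of a core-eudicot
genome: a seven-chromosome ancestor (Eu1–Eu7) undergoes an ancient
triplication (the γ event, producing 21 chromosomes A1–A7, B1–B7, C1–C7),
extensive chromosome fusion during rediploidization (to an
eight-chromosome pre-duplication karyotype, Ar1–Ar8), a lineage-specific
whole-genome duplication (β; 16 chromosomes), four further whole-chromosome
fusions (to a 12-chromosome karyotype), biased loss of duplicated genes
(fractionation), and finally species-specific inversions and a reciprocal
translocation. Every extant gene therefore carries a latent lineage label
(ancestral chromosome, γ copy ∈ {A,B,C}, β copy ∈ {a,b}); the 7 × 3 × 2 = 42
combinations are the *duplicated region classes* all downstream statistics
are organized around.

## Synthetic data generator

**Gene order and coordinates.** Chromosomes are ordered gene lists; a gene's
rank (0-based order along the chromosome) is the coordinate for all
collinearity and gap computations. Emitted GFF3 uses synthetic base-pair
coordinates (one gene per 10 kb, 4 kb footprint), 1-based inclusive; BED
output is 0-based half-open.

**Sequence evolution.** Each gene carries a random in-frame coding sequence
over the 61 sense codons (default 100 codons). Evolution is a
continuous-time Markov chain on sense codons: single-nucleotide neighbour
substitutions at rate 5 when synonymous and 1 when nonsynonymous (stop
codons excluded from the state space, so frames never break). The
5:1 ratio makes synonymous divergence accumulate faster, giving clean Ks
layering between WGD events. At each WGD every chromosome set is copied and
each copy evolved independently for a branch length *t* calibrated so that
the median Nei–Gojobori Ks between sister copies equals the requested
target: *t* is found by bisection on the closed-form expectation of Ks under
the substitution model, then refined (≤ 3 rounds) against the package's own
NG86 estimator on the simulated sequences. Measured medians land within
±0.02–0.05 of the target for ≥ 100 gene pairs.

**Replay scenario targets.** The canonical scenario uses γ target Ks = 1.0,
β = 0.3 and a speciation divergence of 0.1. Because γ-derived pairs keep
accumulating substitutions through the β and speciation eras, the observed
γ peak sits near 1.4 and the β peak near 0.4–0.5 — well separated and far
from NG86 saturation (ps = 3/4).

**Fusion plans and junction truth.** A fusion plan cuts the current
chromosomes into rank-span segments and concatenates them into new
chromosomes; the plan must use every gene exactly once. Every adjacency
between segments from different source chromosomes is recorded in a
junction registry under its era label. The packaged post-γ plan cuts the 21
chromosomes into 34 segments (the 8 A-set/whole chromosomes kept intact,
the rest halved) and assembles 8 chromosomes — 26 junctions (34 − 8). It is
constructed so that (i) adjacent segments never share an ancestral
chromosome (so the painter cannot chain across a junction) and (ii) all 30
junction class-pairs in the final genome are distinct, making layer
attribution unambiguous. The post-β plan fuses four whole-chromosome pairs
(16 → 12; 4 junctions). One consistent realization of the segment
composition is packaged; layer-wise junction and chromosome counts are the
invariants.

**Fractionation.** Gene loss is sampled per copy class — defaults
(A,a)=0.92 … (C,b)=0.58 retention, a biased pattern — or implanted
explicitly per locus. At least one copy of every locus survives. Retention
truth is the locus × copy-class presence set.

**Expression, methylation, Hi-C.** Expression triads: per gene a category
(balanced / tissue-dominant / tissue-suppressed) is drawn (balanced 0.40,
others 0.10 each), tissue fractions are Dirichlet draws around the
category archetype (concentration 50 by default; 200 in the recovery
benchmarks), magnitudes lognormal(log 60, 0.8), three replicates with 5%
lognormal noise; no all-zero triads are ever emitted. Methylation per gene
is Beta(6,3) for TAD-interior genes and Beta(2,5) otherwise. Contact
matrices are Poisson draws around an expected matrix combining power-law
distance decay (exponent 1), an A/B checkerboard factor (same-label bins
× 1.6), a within-TAD factor (× 2–3), a small inter-chromosomal background,
and optionally a same-ancestral-chromosome enrichment factor.

**What the generator does not emulate.** No indels or alignment ambiguity
(CDS pairs are gap-free by construction), no tandem duplications or
transposable elements, no gene-density or GC heterogeneity along
chromosomes, no Hi-C mapping artifacts beyond Poisson noise, and identical
fractionation in the two extant species. Passing tests therefore
demonstrate algorithmic correctness on clean signals with realistic
stochasticity — not robustness to alignment error, annotation noise, or
assembly artifacts in real genomes.

## Analysis pipeline

**Collinearity.** Homology pairs (BLAST outfmt-6 dialect, e-value cutoff
1e-5) are filtered by gene-family size: families are connected components
of the homology graph and families with > 30 members are excluded. Anchors
are chained per chromosome pair by sparse dynamic programming into
maximum-anchor-count monotone chains with a rank gap ≤ 50 genes enforced on
*both* genomes (the stricter reading); chains are extracted greedily (best
first, anchors consumed) per orientation until none reaches 5 anchors. The
DP is validated against exhaustive subset enumeration on small instances.

**Painting and copy labels.** Extant-vs-ancestor blocks project to
segments; adjacent same-origin, same-orientation segments are merged when
both coordinate gaps are below the chaining gap; segments under 5 anchored
genes are dropped. An interior inversion chains as one long block plus a
short reversed block inside its span; overlapping segments are resolved by
cutting the long block around the short one. Copy labels come from the
within-genome self-comparison: per-block median Ks values are fitted with a
1-D Gaussian mixture (EM, KDE-mode initialization plus seeded restarts, BIC
for k, component sd floored at 1% of the data sd); the two dominant
components define the β (younger) and γ (older) layers, and each block
joins the nearer dominant peak. β-layer anchors link segment pairs; the
connected components of that link graph are β pairs, whose bipartition
gives the a/b sides. A γ copy broken apart by later fusions appears as
several disjoint-span components; components are tiled into γ copies so
each copy covers the ancestral chromosome without overlap. Which head goes
with which tail within a copy is not identifiable from Ks (all γ pairs are
equidistant), but every consistent tiling yields identical class and
junction counts, which is what the pipeline reports. The mixture is fitted
on block medians, not raw anchor Ks: the per-anchor Ks distribution at high
divergence is heavy-tailed and over-fragments under a Gaussian mixture,
while the block median is the dating statistic.

**Junction layers and karyotypes.** A fusion junction is an adjacency
between segments of different (ancestral chromosome, γ copy) origin;
same-class adjacencies (inversion flanks) are not junctions. Junctions
sharing the same unordered class pair with overlapping flank spans are one
*event*. An event observed in both β copies predates the duplication
(post-γ); an event observed once postdates it (post-β). Karyotype counts
per layer follow: extant = painted chromosomes; pre-β = cut chromosomes at
post-β junctions and collapse β-paired units of identical origin
composition; post-γ = distinct (ancestral chromosome, γ copy) classes;
ancestor = distinct ancestral chromosomes.

**Rearrangements.** Two paintings against the common ancestor are
compared. Chromosomes are matched by origin-coverage similarity; segments
correspond when they share the ancestral chromosome and overlap in extant
rank (matched chromosomes share a coordinate system, and one chromosome
can carry two copies of the same ancestral chromosome at different
positions — rank overlap disambiguates). An inversion is an interval
covered by opposite-orientation partners and by no same-orientation
partner (≥ 5 genes); detections of the same interval from either side are
merged. Residual spans uncovered in the partner chromosome are displaced
pieces; two displaced pieces moving reciprocally between one chromosome
pair are one reciprocal translocation.

**Subgenome assignment.** Tetraploid chromosomes are paired through their
best-covered diploid-relative chromosome; within a pair the chromosome
with the lower median Ks to the relative is subgenome B (it clusters with
the diploid), ties breaking to the better-covered chromosome.

**Ks estimation (NG86).** Synonymous sites per codon are the per-position
fractions of non-stop single-nucleotide changes that are synonymous;
mutations to stop codons are excluded from the denominator. Multi-difference
codons are averaged over all substitution pathways, excluding pathways
through stop codons (falling back to all pathways when every one is
blocked). ps = Sd/S is Jukes–Cantor corrected, Ks = −(3/4)·ln(1 − (4/3)ps);
ps ≥ 3/4 is flagged saturated. The estimator is verified against an
independent brute-force pathway-enumeration oracle, exactly, on all sense
codon pairs and random short alignments. The K2P distance and the LTR
insertion-age formula age = K/(2r) with r = 1.3 × 10⁻⁸ per site per year
are provided alongside.

**Retention statistics.** The retention matrix is the boolean presence of
ancestral loci across region classes (each TRUE cell maps to exactly one
extant gene). Reported statistics: the count and percentage of loci
retaining more than half (> 3 of 6) of their copies; per-class retention
rates; and both/singleton/absent decomposition over one β segment pair,
with percentages over loci present in at least one copy.

**Triads.** Replicates are averaged per gene × tissue; fractions are each
tissue's TPM over the triad sum (all-zero triads flagged not-expressed);
the category is the nearest of seven archetypes by Euclidean distance in
the fraction simplex — balanced (1/3,1/3,1/3), tissue-dominant (unit
vertices), tissue-suppressed ((0,1/2,1/2) patterns) — with exact ties
resolved to Balanced. No unclassified band is introduced since no distance
threshold is defined for one. Expression diversity and specificity per
region class are this package's own definitions (no standard exists):
Dj = mean pairwise Jensen–Shannon distance (base 2) of tissue-fraction
profiles, Sj = mean tau specificity Σ(1 − xᵢ/x_max)/(n − 1); both lie in
[0, 1] and the definitions are embedded in the output metadata.
Methylation classes use inclusive thresholds: hypo ≤ 0.3, hyper ≥ 0.7
(configurable; no canonical values exist).

**Hi-C.** ICE balancing iterates row-coverage equalization to a
coefficient of variation < 1e-5 (≤ 200 iterations), masking bins below the
2nd coverage percentile as NA (never zero-filled — zero filling biases the
eigenvectors); the bias vector reconstructs the raw matrix. Expected
contact at distance d is a lowess-smoothed diagonal mean (plain means for
short chromosomes); compartments are the sign of the leading eigenvector
of the Pearson correlation of O/E, oriented so the positive (A) set has
the higher gene density where a density track exists, else by a fixed sign
convention. Insulation is the mean count in a square window (default
500 kb at 20 kb bins) sliding along the diagonal, log2-normalized by the
chromosome mean, NA near ends. TAD boundaries are local minima of a 3-bin
moving average of the insulation score (single-bin count noise otherwise
shifts boundaries) whose depth below the flanking mean (over a 100 kb
delta span) reaches 0.1; TADs tile between boundaries. An optional 2-state
Viterbi smoothing is available behind a flag and OFF by default. Region
topology comparison reports mean log2 normalized contact per region-class
pair, a Welch t contrast of within- vs between-ancestor pairs, and the
fraction of A/B switch points within ± 1 bin of fusion junctions.

## Numerical and scale choices

Default problem sizes keep every stage interactive: 7 × 120 ancestral loci
(≈ 3 800 extant genes per species after fractionation), 100 codons per
gene, contact matrices of 300–600 bins at 20 kb. The replay-and-recover
cycle runs in a few seconds per seed; the acceptance script recomputes all
headline quantities in well under a minute. Determinism: all randomness
flows from one `numpy` Generator seeded at entry; identical seeds give
byte-identical outputs, which the test suite asserts.

## Known limitations

* γ-copy head/tail pairing across fusion breakpoints is reported as one
  consistent tiling, not THE historical pairing (unidentifiable from Ks).
* β-side letters (a/b) are species-local; cross-species comparisons use
  position and origin, not letters.
* The junction-count bookkeeping defines one fusion event per heterologous
  adjacency; histories mixing fissions with fusions between the same
  partners would be undercounted.
* The rearrangement detector handles inversions and reciprocal
  translocations between two paintings; it does not attempt multi-genome
  parsimony or detect nested events.
* NG86 (not the full codon-frequency-corrected YN00 model) is the Ks
  estimator; with the synonymous-biased simulation this is exact by
  construction, but on real data NG86 underestimates high Ks.
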