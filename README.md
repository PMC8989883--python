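# paleoshuffle

Paleo-polyploidy comparative genomics on verifiable synthetic genomes.

Plant genomes are palimpsests of ancient whole-genome duplications (WGDs):
a polyploidy event copies every chromosome, rediploidization then fuses and
shuffles the copies and deletes most duplicated genes, and the cycle
repeats. Reconstructing that history — which extant chromosome segment
descends from which ancestral chromosome, through which WGD — underpins
comparative work on genome structure, homoeolog expression, and chromatin
topology in paleopolyploid lineages such as the ginseng genus. The analyses
involved (synteny chaining, Ks dating, fractionation statistics,
compartment/TAD calling) are usually scattered across tools and impossible
to validate end-to-end on real data, where the truth is unknown.

`paleoshuffle` packages the whole pipeline **together with a generator that
manufactures the truth**: it simulates a seven-chromosome ancestor through
a triplication (γ), scripted chromosome fusions, a duplication (β), biased
fractionation, and extant rearrangements — emitting gene models, coding
sequences, homology tables, expression, methylation and Hi-C matrices plus
a machine-readable `TruthSet`. Every analysis stage is then scored against
the implanted answers.

## What it computes

* **Collinearity** — gene-family filtering (components of the homology
  graph, families > 30 members excluded), anchor chaining by sparse DP with
  a two-sided gap cap of 50 genes, ancestral-gene calling (anchored in ≥ 2
  subgenomes/regions), in-/out-paralog depth (top two homologs = the most
  recent duplication).
* **Karyotype** — painting extant chromosomes by ancestral origin;
  resolving triplication (A/B/C) and duplication (a/b) copy labels from the
  Ks layers of the self-comparison; counting fusion junctions per WGD layer
  (an adjacency seen in both duplication copies predates the duplication);
  reconstructing intermediate karyotypes; detecting inversions and
  reciprocal translocations between species; assigning tetraploid
  subgenomes against a diploid relative.
* **WGD dating** — Nei–Gojobori (1986) Ks/Ka with exhaustive pathway
  averaging (estimator verified exactly against an independent
  pathway-enumeration oracle), Ks = −¾ ln(1 − 4⁄3 ps); per-block median Ks;
  Gaussian-kernel Ks densities; 1-D Gaussian-mixture peak fitting (EM,
  BIC); block-to-WGD assignment by posterior; K2P distances and LTR ages
  (age = K / 2r, r = 1.3 × 10⁻⁸).
* **Duplicate evolution** — locus × region-class retention matrices,
  high-retention (> 3 of 6 copies) summaries, both/singleton decomposition
  of duplication segment pairs; leaf/root/stem expression triads
  (fractions = TPM over the triad sum, nearest-archetype classification
  into 7 categories); methylation classes; per-region expression
  diversity/specificity (Dj/Sj).
* **Hi-C topology** — ICE balancing, lowess observed/expected, A/B
  compartments from the leading correlation eigenvector, insulation-score
  TAD calling, within- vs between-ancestor contact contrasts, and
  methylation/expression profiles over TAD interiors vs borders.

See `docs/methods.md` for models, assumptions, defaults and limitations.

## Worked example

Recover the implanted history of the packaged replay scenario:

```bash
paleoshuffle replay --seed 42
```

prints

```json
{
 "n_region_classes": 42,
 "post_gamma_chromosomes": 21,
 "pre_beta_chromosomes": 8,
 "extant_chromosomes": 12,
 "ancestor_chromosomes": 7,
 "post_gamma_fusions": 26,
 "post_beta_fusions": 4,
 "n_inversions": 2,
 "n_reciprocal_translocations": 1,
 "n_rearrangements": 3
}
```

Reading: painting the simulated extant diploid (12 chromosomes) against its
7-chromosome ancestor and resolving copy labels via the Ks mixture, the
pipeline recovers all **42** duplicated region classes (7 ancestors × 3
triplication copies × 2 duplication copies), the **21** post-triplication
chromosomes, the **8**-chromosome pre-duplication karyotype, **26** fusion
events attributed to the post-triplication era and **4** to the
post-duplication era, and — comparing the two simulated species — exactly
**2** inversions and **1** reciprocal translocation. All of these match the
generator's implanted truth.

The same run as a library:

```python
from paleoshuffle.synthetic_data import fig1_replay
from paleoshuffle.pipeline import recover_history

dataset = fig1_replay(seed=42)          # genomes, CDS, homology, truth
result = recover_history(dataset)       # analysis side only
assert result["n_region_classes"] == 42
mix = result["Ps"].mixture              # fitted Ks peaks, e.g. ~0.50 / ~1.47
```

Other entry points: `paleoshuffle simulate --scenario fig1_replay --seed 42
--out DIR` writes all files (GFF3, FASTA CDS, BLAST-style tables,
expression/methylation TSV, contact matrix, `truth.json`);
`paleoshuffle collinearity | paint | ksdate | fractionation | triads | hic`
run the individual stages on files.

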