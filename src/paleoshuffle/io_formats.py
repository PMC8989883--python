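"""Readers, writers and core domain containers.

Every other module consumes and produces only the types defined here.

Coordinate contract
-------------------
* GFF3 (and :class:`GeneModel`) carry 1-based, inclusive base-pair coordinates.
* BED output and all internal bin indices are 0-based, half-open.
* All collinearity and gap computations run on gene *rank*, the 0-based
  position of a gene along its chromosome after sorting by start coordinate;
  base pairs appear only at I/O boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("paleoshuffle")

__all__ = [
    "GeneModel",
    "GenomeLayout",
    "HomologyRecord",
    "ExpressionRecord",
    "MethylationRecord",
    "ContactMatrix",
    "read_gene_models",
    "write_gene_models",
    "read_homology_table",
    "write_homology_table",
    "read_contact_matrix",
    "write_contact_matrix",
    "write_painting_bed",
    "read_painting_bed",
    "read_expression_table",
    "write_expression_table",
    "read_methylation_table",
    "write_methylation_table",
    "load_run_config",
]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One gene model: 1-based inclusive bp coordinates on ``chrom``."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family_id: Optional[str] = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


class GenomeLayout:
    """Ordered gene models per chromosome for one (sub)genome.

    ``chromosomes`` maps chrom name -> list of :class:`GeneModel` sorted by
    start; a gene's index in that list is its rank.
    """

    def __init__(self, species_id: str, genes: Iterable[GeneModel],
                 subgenome: Optional[str] = None):
        self.species_id = species_id
        self.subgenome = subgenome
        chroms: dict[str, list[GeneModel]] = {}
        seen: set[str] = set()
        for g in genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            chroms.setdefault(g.chrom, []).append(g)
        self.chromosomes: dict[str, list[GeneModel]] = {
            c: sorted(gs, key=lambda g: (g.start, g.gene_id))
            for c, gs in chroms.items()
        }
        self._rank: dict[str, tuple[str, int]] = {}
        for c, gs in self.chromosomes.items():
            for i, g in enumerate(gs):
                self._rank[g.gene_id] = (c, i)

    # -- queries ----------------------------------------------------------
    def rank_of(self, gene_id: str) -> tuple[str, int]:
        """(chrom, 0-based rank) of a gene."""
        return self._rank[gene_id]

    def gene_at(self, chrom: str, rank: int) -> GeneModel:
        return self.chromosomes[chrom][rank]

    def n_genes(self, chrom: Optional[str] = None) -> int:
        if chrom is not None:
            return len(self.chromosomes[chrom])
        return sum(len(g) for g in self.chromosomes.values())

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def genes(self) -> Iterable[GeneModel]:
        for c in self.chromosomes:
            yield from self.chromosomes[c]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._rank

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenomeLayout)
                and self.species_id == other.species_id
                and self.subgenome == other.subgenome
                and self.chromosomes == other.chromosomes)


@dataclass(frozen=True)
class HomologyRecord:
    query: str
    subject: str
    pct_identity: float
    evalue: float
    bitscore: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError("pct_identity must be in [0, 100]")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    tissue: str
    replicate: int
    tpm: float

    def __post_init__(self):
        if not np.isfinite(self.tpm) or self.tpm < 0:
            raise ValueError(f"{self.gene_id}: TPM must be finite and >= 0")


@dataclass(frozen=True)
class MethylationRecord:
    gene_id: str
    mC: float

    def __post_init__(self):
        if not (0.0 <= self.mC <= 1.0):
            raise ValueError(f"{self.gene_id}: mC must be in [0, 1]")


class ContactMatrix:
    """Binned, symmetric Hi-C interaction matrix.

    Bins are 0-based, half-open genomic windows of ``resolution`` bp laid out
    chromosome by chromosome in the order of ``chrom_sizes``.
    """

    def __init__(self, counts: np.ndarray, resolution: int,
                 chrom_sizes: Mapping[str, int], balanced: bool = False):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        nz = counts[np.isfinite(counts)]
        if nz.size and not np.allclose(
                np.nan_to_num(counts), np.nan_to_num(counts.T), atol=1e-9):
            raise ValueError("contact matrix is not symmetric")
        self.counts = counts
        self.resolution = int(resolution)
        self.chrom_sizes = dict(chrom_sizes)
        self.balanced = balanced
        # bin layout
        self.chrom_offsets: dict[str, int] = {}
        self.bin_chrom: list[str] = []
        self.bin_start: list[int] = []
        off = 0
        for c, size in self.chrom_sizes.items():
            self.chrom_offsets[c] = off
            nb = int(np.ceil(size / self.resolution))
            for b in range(nb):
                self.bin_chrom.append(c)
                self.bin_start.append(b * self.resolution)
            off += nb
        if off != counts.shape[0]:
            raise ValueError(
                f"matrix has {counts.shape[0]} bins but chrom_sizes imply {off}")
        self.n_bins = off

    def bin_of(self, chrom: str, pos: int) -> int:
        """Bin index of a 0-based genomic position."""
        b = self.chrom_offsets[chrom] + pos // self.resolution
        if not (self.chrom_offsets[chrom] <= b < self.chrom_offsets[chrom]
                + int(np.ceil(self.chrom_sizes[chrom] / self.resolution))):
            raise IndexError(f"position {pos} outside {chrom}")
        return b

    def chrom_slice(self, chrom: str) -> slice:
        off = self.chrom_offsets[chrom]
        nb = int(np.ceil(self.chrom_sizes[chrom] / self.resolution))
        return slice(off, off + nb)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gene_models(path, feature: str = "gene",
                     species_id: Optional[str] = None) -> GenomeLayout:
    """Read gene models of one feature type from a GFF3 file.

    Coordinates stay 1-based inclusive. Ranks are assigned by (chrom, start).
    ``ID=`` is required in column 9; ``family_id=`` is picked up when present.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != feature:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            gid = attr.get("ID")
            if gid is None:
                raise ParseError(f"{path}:{lineno}: missing ID attribute")
            if gid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
            seen.add(gid)
            genes.append(GeneModel(gid, chrom, start_i, end_i, strand,
                                   attr.get("family_id")))
    if not genes:
        log.warning("read_gene_models: %s contains no %r features", path, feature)
    layout = GenomeLayout(species_id or path.stem, genes)
    log.info("read_gene_models: %s -> %d genes on %d chromosomes",
             path, layout.n_genes(), layout.n_chromosomes)
    return layout


def write_gene_models(layout: GenomeLayout, path, feature: str = "gene") -> None:
    """Write a layout back to GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in layout.chromosomes:
            for g in layout.chromosomes[chrom]:
                attrs = f"ID={g.gene_id}"
                if g.family_id is not None:
                    attrs += f";family_id={g.family_id}"
                fh.write(f"{chrom}\tpaleoshuffle\t{feature}\t{g.start}\t{g.end}"
                         f"\t.\t{g.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# homology tables (BLAST outfmt-6 dialect)
# ---------------------------------------------------------------------------

_OUTFMT6 = ["query", "subject", "pct_identity", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def read_homology_table(path, max_evalue: float = 1e-5) -> list[HomologyRecord]:
    """Read a 12-column tabular homology file, dropping weak hits.

    Column order follows BLAST outfmt 6; extra columns are ignored with a
    warning. Records with evalue > ``max_evalue`` are dropped (count logged).
    """
    records: list[HomologyRecord] = []
    dropped = 0
    warned_extra = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 12:
                raise ParseError(f"{path}:{lineno}: expected >=12 columns, got {len(parts)}")
            if len(parts) > 12 and not warned_extra:
                log.warning("read_homology_table: %s has extra columns (ignored)", path)
                warned_extra = True
            try:
                pid = float(parts[2])
                ev = float(parts[10])
                bs = float(parts[11])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric field") from None
            if ev > max_evalue:
                dropped += 1
                continue
            records.append(HomologyRecord(parts[0], parts[1], pid, ev, bs))
    log.info("read_homology_table: %s -> %d records kept, %d dropped (evalue > %g)",
             path, len(records), dropped, max_evalue)
    return records


def write_homology_table(records: Iterable[HomologyRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.query}\t{r.subject}\t{r.pct_identity:.2f}\t0\t0\t0"
                     f"\t0\t0\t0\t0\t{r.evalue:.3g}\t{r.bitscore:.1f}\n")


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------

def read_contact_matrix(path, resolution: int,
                        chrom_sizes: Mapping[str, int]) -> ContactMatrix:
    """Read a dense TSV or COO triplet text contact matrix.

    A file whose data lines have exactly three columns is treated as COO
    triplets ``bin_i bin_j count`` (symmetrized on load); anything else is
    parsed as a dense square matrix.
    """
    path = Path(path)
    n = sum(int(np.ceil(s / resolution)) for s in chrom_sizes.values())
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty contact matrix")
    ncol = len(lines[0].split())
    if ncol == 3 and n != 3:
        mat = np.zeros((n, n))
        for lineno, ln in enumerate(lines, 1):
            i_s, j_s, v_s = ln.split()
            i, j, v = int(i_s), int(j_s), float(v_s)
            if not (0 <= i < n and 0 <= j < n):
                raise ParseError(f"{path}:{lineno}: bin index ({i},{j}) out of range 0..{n - 1}")
            mat[i, j] = v
            mat[j, i] = v
    else:
        mat = np.array([[float(x) for x in ln.split()] for ln in lines])
        if mat.shape != (n, n):
            raise ParseError(f"{path}: dense matrix is {mat.shape}, expected ({n},{n})")
        if not np.allclose(mat, mat.T, atol=1e-9):
            raise ParseError(f"{path}: dense matrix asymmetric beyond 1e-9")
    return ContactMatrix(mat, resolution, chrom_sizes)


def write_contact_matrix(cm: ContactMatrix, path, fmt: str = "dense") -> None:
    if fmt == "dense":
        np.savetxt(path, cm.counts, delimiter="\t", fmt="%.10g")
    elif fmt == "coo":
        with open(path, "w") as fh:
            ii, jj = np.nonzero(np.triu(cm.counts))
            for i, j in zip(ii, jj):
                fh.write(f"{i}\t{j}\t{cm.counts[i, j]:.10g}\n")
    else:
        raise ValueError(f"unknown contact-matrix format {fmt!r}")


# ---------------------------------------------------------------------------
# painting BED
# ---------------------------------------------------------------------------

def write_painting_bed(painting, path) -> None:
    """Write a SegmentPainting as BED6 (0-based half-open bp).

    Name column is ``Eu{c}:{gamma}{beta}`` when copy labels are resolved,
    else the bare ancestral chromosome name.
    """
    with open(path, "w") as fh:
        for chrom in painting.chromosomes():
            for seg in painting.segments_of(chrom):
                name = seg.class_name()
                fh.write(f"{chrom}\t{seg.bp_start - 1}\t{seg.bp_end}\t{name}"
                         f"\t{seg.n_genes}\t{seg.orientation}\n")


def read_painting_bed(path) -> list[tuple]:
    """Read painting BED back as (chrom, start0, end, name, n_genes, strand)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            p = line.split("\t")
            if len(p) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns")
            rows.append((p[0], int(p[1]), int(p[2]), p[3], int(p[4]), p[5]))
    return rows


# ---------------------------------------------------------------------------
# expression / methylation tables
# ---------------------------------------------------------------------------

def read_expression_table(path) -> pd.DataFrame:
    """TSV with columns gene_id, tissue, replicate, tpm."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "tissue": str})
    need = {"gene_id", "tissue", "replicate", "tpm"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: expression table needs columns {sorted(need)}")
    if (df.tpm < 0).any() or not np.isfinite(df.tpm).all():
        raise ParseError(f"{path}: TPM values must be finite and non-negative")
    return df


def write_expression_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_methylation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "mC"}.issubset(df.columns):
        raise ParseError(f"{path}: methylation table needs gene_id and mC columns")
    if ((df.mC < 0) | (df.mC > 1)).any():
        raise ParseError(f"{path}: mC outside [0, 1]")
    return df


def write_methylation_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def load_run_config(path) -> dict:
    """Load a YAML run config (paths, resolutions, thresholds, seed)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: run config must be a mapping")
    if "seed" in cfg:
        log.info("run config: seed=%s", cfg["seed"])
    return cfg
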