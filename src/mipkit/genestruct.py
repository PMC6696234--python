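"""Gene-structure and chromosomal-placement tabulation.

Intron counts are derived from exon intervals (introns = exons - 1) of the
longest annotated isoform.  Chromosome placement follows the annotation
seqid; seqids that do not match the chromosome naming pattern (unanchored
scaffolds) are reported as UNPLACED, mirroring how genome papers list
genes that cannot be placed on any chromosome.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .seqio import GffFeature

logger = logging.getLogger(__name__)

UNPLACED = "UNPLACED"
#: default chromosome naming pattern ("Chr01".."Chr17" style)
CHROMOSOME_PATTERN = r"^[Cc]hr\d+$"


@dataclass
class GeneModel:
    """One gene: chromosome (or UNPLACED), strand, and ordered exons."""

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        for s, e in self.exons:
            if not (1 <= s <= e):
                raise ValueError(f"gene {self.gene_id}: invalid exon {s}..{e}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)


def intron_count(model: GeneModel) -> int:
    """Number of introns: always exons - 1."""
    return model.n_exons - 1


def gene_model_from_gff(
    features: list[GffFeature],
    gene_id: str,
    chromosome_pattern: str = CHROMOSOME_PATTERN,
) -> GeneModel:
    """Build a gene model from parsed GFF3 features.

    Exons come from the longest mRNA child (total exon length; ties by
    mRNA id).  A gene without annotated exons is treated as single-exon
    over its own interval (logged).  Seqids not matching
    ``chromosome_pattern`` map to UNPLACED.
    """
    genes = [f for f in features if f.type == "gene" and f.id == gene_id]
    if not genes:
        raise ValueError(f"gene {gene_id!r} not found")
    gene = genes[0]
    mrnas = [f for f in features if f.type == "mRNA" and f.parent == gene_id]
    exons_by_parent: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        if f.type == "exon" and f.parent is not None:
            exons_by_parent.setdefault(f.parent, []).append((f.start, f.end))

    if mrnas:
        scored = []
        for m in mrnas:
            ex = exons_by_parent.get(m.id, [])
            scored.append((sum(e - s + 1 for s, e in ex), m.id, ex))
        scored.sort(key=lambda t: (-t[0], t[1]))
        if len(scored) > 1:
            logger.info(
                "gene %s: %d isoforms, keeping longest (%s)",
                gene_id, len(scored), scored[0][1],
            )
        exons = scored[0][2]
        if not exons:  # mRNA without exon children
            exons = [(mrnas[0].start, mrnas[0].end)]
    else:
        exons = exons_by_parent.get(gene_id, [])

    if not exons:
        logger.info("gene %s: no exon features, using gene interval", gene_id)
        exons = [(gene.start, gene.end)]

    chrom = gene.seqid if re.match(chromosome_pattern, gene.seqid) else UNPLACED
    return GeneModel(
        gene_id=gene_id, chromosome=chrom, strand=gene.strand, exons=exons
    )


def gene_models_from_gff(
    features: list[GffFeature], chromosome_pattern: str = CHROMOSOME_PATTERN
) -> list[GeneModel]:
    """Models for every gene feature, in annotation order."""
    ids = [f.id for f in features if f.type == "gene"]
    return [gene_model_from_gff(features, g, chromosome_pattern) for g in ids]


@dataclass
class ChromosomeTable:
    """Per-chromosome gene lists plus the unplaced set and summary counts."""

    by_chromosome: dict[str, list[str]]
    unplaced: list[str]
    n_placed: int
    n_unplaced: int
    n_chromosomes: int


def chromosome_table(models: Iterable[GeneModel]) -> ChromosomeTable:
    """Group genes by chromosome, ordered by start; UNPLACED listed apart.

    Ordering within a chromosome is by first-exon start (ties by gene id),
    so the table is stable under permutation of the input.
    """
    models = list(models)
    if not models:
        raise ValueError("need at least one gene model")
    placed: dict[str, list[GeneModel]] = {}
    unplaced = []
    for m in models:
        if m.chromosome == UNPLACED:
            unplaced.append(m.gene_id)
        else:
            placed.setdefault(m.chromosome, []).append(m)
    by_chrom = {
        c: [m.gene_id for m in sorted(ms, key=lambda m: (m.start, m.gene_id))]
        for c, ms in sorted(placed.items())
    }
    n_placed = sum(len(v) for v in by_chrom.values())
    return ChromosomeTable(
        by_chromosome=by_chrom,
        unplaced=sorted(unplaced),
        n_placed=n_placed,
        n_unplaced=len(unplaced),
        n_chromosomes=len(by_chrom),
    )


def structure_table(models: Iterable[GeneModel]) -> pd.DataFrame:
    """Per-gene structure table (id, placement, span, exon/intron counts)."""
    rows = [
        {"gene_id": m.gene_id, "chromosome": m.chromosome, "strand": m.strand,
         "start": m.start, "end": m.end, "n_exons": m.n_exons,
         "n_introns": intron_count(m)}
        for m in models
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "strand", "start", "end",
                       "n_exons", "n_introns"]
    )
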