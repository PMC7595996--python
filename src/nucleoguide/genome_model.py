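"""Genome and gene-model services.

Loads a genome FASTA and a GFF3 gene annotation, derives transcription
start sites (TSSs) and strand-aware promoter windows, and detects
bidirectional (divergent-gene) promoters such as the compact intergenic
control regions common in gene-dense fungal genomes.

All internal coordinates are 0-based half-open; GFF3 input is converted
from its native 1-based inclusive convention on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

from .dna import VALID_BASES


class GenomeError(ValueError):
    """Malformed genome or annotation input."""


@dataclass
class Genome:
    """Chromosome name -> uppercase DNA string (A/C/G/T/N)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise GenomeError(f"chromosome {name!r} has an empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise GenomeError(
                    f"chromosome {name!r} contains non-IUPAC characters: {sorted(bad)}"
                )

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass(frozen=True)
class GeneModel:
    """A gene with its span and derived TSS.

    The TSS defaults to the annotated gene start (strand-aware); callers
    holding better (e.g. RNA-seq-derived) TSS estimates can override it
    via the `tss_override` mechanism of :func:`load_annotation`.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int   # 0-based inclusive
    end: int     # 0-based exclusive
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.start < self.end:
            raise GenomeError(f"gene {self.gene_id}: empty span")


@dataclass
class PromoterRegion:
    """A promoter interval targeting one gene, or two for a bidirectional promoter."""

    chrom: str
    start: int
    end: int
    target_genes: list[GeneModel]
    bidirectional: bool = False
    tss_positions: dict[str, int] = field(default_factory=dict)
    clipped: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.bidirectional and len(self.target_genes) != 2:
            raise GenomeError("bidirectional promoter must reference exactly two genes")


def load_genome(path) -> Genome:
    """Parse a FASTA file into a :class:`Genome` (sequences uppercased).

    Duplicate record names and non-IUPAC characters are hard errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise GenomeError(f"duplicate FASTA record name {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise GenomeError(f"no FASTA records found in {path}")
    return Genome(sequences)


def _gene_id(feature) -> str:
    for key in ("ID", "gene_id", "Name"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    raise GenomeError(f"gene feature at {feature.seqid}:{feature.start} lacks an ID")


def load_annotation(path, genome: Genome, tss_override: dict[str, int] | None = None
                    ) -> list[GeneModel]:
    """Load gene features from a GFF3 file.

    GFF3 1-based inclusive coordinates become 0-based half-open; the TSS
    is the strand-aware gene start unless overridden by `tss_override`
    (gene_id -> 0-based position).
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    tss_override = tss_override or {}
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.seqid not in genome:
            raise GenomeError(f"gene on unknown seqid {feat.seqid!r}")
        start, end = feat.start - 1, feat.end  # to 0-based half-open
        if end > genome.length(feat.seqid) or start < 0:
            raise GenomeError(
                f"gene {_gene_id(feat)} spans past the end of {feat.seqid}"
            )
        gid = _gene_id(feat)
        tss = start if feat.strand == "+" else end - 1
        tss = tss_override.get(gid, tss)
        genes.append(GeneModel(gid, feat.seqid, feat.strand, start, end, tss))
    return genes


def load_tss_table(path) -> dict[str, int]:
    """Read a 2-column TSV (gene_id, 0-based TSS position)."""
    table: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gid, pos = line.split("\t")[:2]
            table[gid] = int(pos)
    return table


def promoter_region(gene: GeneModel, genome: Genome, upstream: int,
                    downstream: int = 0) -> PromoterRegion:
    """Strand-aware promoter window around the TSS, clipped to the chromosome.

    `upstream` bases extend 5' of the TSS and `downstream` bases 3' of it
    (the TSS base itself counts as the first downstream base). Clipping
    at chromosome bounds raises a warning, not an error.
    """
    if upstream < 0 or downstream < 0:
        raise GenomeError("upstream/downstream must be non-negative")
    length = genome.length(gene.chrom)
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss + 1 - downstream, gene.tss + 1 + upstream
    clipped = start < 0 or end > length
    if clipped:
        warnings.warn(
            f"promoter window for {gene.gene_id} clipped to chromosome bounds",
            stacklevel=2,
        )
    start, end = max(start, 0), min(end, length)
    return PromoterRegion(
        chrom=gene.chrom, start=start, end=end, target_genes=[gene],
        bidirectional=False, tss_positions={gene.gene_id: gene.tss},
        clipped=clipped,
    )


def detect_bidirectional(genes: list[GeneModel], max_gap: int = 600
                         ) -> list[PromoterRegion]:
    """Find divergent gene pairs sharing a compact intergenic control region.

    Adjacent genes on the same chromosome in (-, +) orientation whose TSS
    separation is at most `max_gap` yield one bidirectional promoter
    spanning [tss_minus, tss_plus); its width equals the TSS separation.
    The default 600 bp admits compact fungal intergenic regions (the
    motivating divergent pair shares only 305 bp) while excluding
    unrelated neighbours.
    """
    regions: list[PromoterRegion] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, glist in by_chrom.items():
        glist = sorted(glist, key=lambda g: (g.start, g.end))
        for left, right in zip(glist, glist[1:]):
            if left.strand == "-" and right.strand == "+":
                sep = right.tss - left.tss
                if 0 < sep <= max_gap:
                    regions.append(PromoterRegion(
                        chrom=chrom, start=left.tss, end=right.tss,
                        target_genes=[left, right], bidirectional=True,
                        tss_positions={left.gene_id: left.tss,
                                       right.gene_id: right.tss},
                    ))
    return regions
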