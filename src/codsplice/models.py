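"""Core data model: stranded genomic intervals, exon chains and gene models.

All coordinates are 0-based, half-open ``[start, end)`` internally; GFF3/GTF
I/O converts to and from the 1-based inclusive convention of those formats.
Exon chains are stored in genomic order regardless of strand; traversal in
transcript (5'->3') orientation is computed on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

STRANDS = ("+", "-")
SITES = ("KIL", "GDA")
TREATMENTS = ("CTRL", "LS", "RS")
BIOTYPES = ("protein_coding", "pseudogene", "non_coding")


class ModelError(ValueError):
    """Raised when a structural invariant of the data model is violated."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A non-empty stranded interval on a chromosome (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ModelError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ModelError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def coords(self) -> tuple[int, int]:
        return (self.start, self.end)


def _validate_chain(exons: list[GenomicInterval], strand: str, label: str) -> None:
    if not exons:
        raise ModelError(f"{label}: transcript must have at least one exon")
    chrom = exons[0].chrom
    for e in exons:
        if e.chrom != chrom:
            raise ModelError(f"{label}: exons on multiple chromosomes")
        if e.strand != strand:
            raise ModelError(f"{label}: exon strand disagrees with transcript strand")
    for a, b in zip(exons, exons[1:]):
        if b.start < a.end:
            raise ModelError(f"{label}: overlapping exons {a.coords()} / {b.coords()}")
        if b.start == a.end:
            raise ModelError(
                f"{label}: adjacent exons {a.coords()} / {b.coords()} (gap must be >= 1)"
            )


@dataclass
class TranscriptModel:
    """An annotated isoform: an ordered, non-overlapping exon chain of a gene."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    strand: str

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        _validate_chain(self.exons, self.strand, self.transcript_id)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def chain(self) -> tuple[tuple[int, int], ...]:
        """Exon coordinates as a hashable genomic-order tuple."""
        return tuple(e.coords() for e in self.exons)


@dataclass
class ObservedTranscript:
    """An experimentally observed transcript structure with its read support
    and experimental-group labels (sampling site and salinity treatment)."""

    variant_id: str
    gene_id: str
    exons: list[GenomicInterval]
    strand: str
    coverage: int
    site: str
    treatment: str

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        _validate_chain(self.exons, self.strand, self.variant_id)
        if not isinstance(self.coverage, int) or self.coverage < 0:
            raise ModelError(f"{self.variant_id}: coverage must be a non-negative integer")
        if self.site not in SITES:
            raise ModelError(f"{self.variant_id}: unknown site {self.site!r}")
        if self.treatment not in TREATMENTS:
            raise ModelError(f"{self.variant_id}: unknown treatment {self.treatment!r}")

    chrom = TranscriptModel.chrom
    span = TranscriptModel.span
    chain = TranscriptModel.chain


@dataclass
class GeneModel:
    """A gene with one or more annotated isoforms.

    ``annotated_AS`` is definitional: true iff the gene carries at least two
    annotated isoforms (i.e. alternative splicing is annotated for it).
    """

    gene_id: str
    symbol: str
    biotype: str
    isoforms: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ModelError(f"{self.gene_id}: unknown biotype {self.biotype!r}")
        for iso in self.isoforms:
            if iso.gene_id != self.gene_id:
                raise ModelError(f"{self.gene_id}: isoform {iso.transcript_id} has foreign gene_id")
        strands = {iso.strand for iso in self.isoforms}
        if len(strands) > 1:
            raise ModelError(f"{self.gene_id}: isoforms on both strands")

    @property
    def annotated_AS(self) -> bool:
        return len(self.isoforms) >= 2

    @property
    def strand(self) -> str:
        return self.isoforms[0].strand


class GenomeAnnotation:
    """An ordered collection of GeneModel, indexed by gene_id."""

    def __init__(self, genes: Iterable[GeneModel] = ()) -> None:
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            self.add(g)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self._genes:
            raise ModelError(f"duplicate gene_id {gene.gene_id}")
        self._genes[gene.gene_id] = gene

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __len__(self) -> int:
        return len(self._genes)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def transcripts(self) -> Iterator[TranscriptModel]:
        for g in self:
            yield from g.isoforms


def introns_of(t: TranscriptModel | ObservedTranscript) -> list[GenomicInterval]:
    """Introns of a transcript: the gaps between consecutive exons, in
    genomic order. A single-exon transcript has none."""
    out = []
    for a, b in zip(t.exons, t.exons[1:]):
        out.append(GenomicInterval(a.chrom, a.end, b.start, a.strand))
    return out


def boundary(exon: GenomicInterval, which: str) -> int:
    """Strand-aware exon end position.

    On the + strand the 5' end is the genomic start and the 3' end the genomic
    end; on the - strand the roles are swapped.
    """
    if which not in ("five_prime", "three_prime"):
        raise ValueError(f"unknown boundary {which!r}")
    if exon.strand == "+":
        return exon.start if which == "five_prime" else exon.end
    return exon.end if which == "five_prime" else exon.start
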