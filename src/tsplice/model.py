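"""Gene/transcript/exon/intron model and the interval predicates the screens use.

All coordinates are 0-based half-open on the forward genomic strand.
Conversion to and from GTF's 1-based closed convention happens only in
:mod:`tsplice.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

PROTEIN_CODING = "protein_coding"
OTHER_ANNOTATED = "other_annotated"
NOVEL = "novel"

ANNOTATION_CLASSES = (PROTEIN_CODING, OTHER_ANNOTATED, NOVEL)
SOURCE_CLASSES = ("reference_annotated", "novel_assembled")


class ModelError(ValueError):
    """Raised when a domain-type invariant is violated."""


@dataclass(frozen=True, order=True)
class Exon:
    """A genomic exon interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ModelError(f"exon start {self.start} is negative")
        if self.end <= self.start:
            raise ModelError(f"exon end {self.end} <= start {self.start}")
        if self.strand not in ("+", "-"):
            raise ModelError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class Intron:
    """The genomic gap between two consecutive exons of a transcript.

    ``start`` is the end of the upstream (genomically left) exon and
    ``end`` the start of the downstream exon, regardless of strand.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ModelError(f"intron start {self.start} is negative")
        if self.end <= self.start:
            raise ModelError(f"intron end {self.end} <= start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int]:
        """Strand-less key used for junction-evidence lookup."""
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: an ordered chain of exons on a single chromosome/strand."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]
    source_class: str = "novel_assembled"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ModelError(f"transcript {self.transcript_id} has no exons")
        if self.source_class not in SOURCE_CLASSES:
            raise ModelError(f"invalid source_class {self.source_class!r}")
        object.__setattr__(self, "exons", tuple(self.exons))
        prev_end = -1
        for e in self.exons:
            if e.chrom != self.chrom or e.strand != self.strand:
                raise ModelError(
                    f"transcript {self.transcript_id}: exon on {e.chrom}/{e.strand}"
                    f" does not match transcript {self.chrom}/{self.strand}"
                )
            if e.start < prev_end:
                raise ModelError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e.end

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0].start, self.exons[-1].end)


@dataclass
class GeneModel:
    """A locus: one or more isoforms plus annotation status.

    ``annotation_class`` records whether the locus coincides with a
    reference-annotated protein-coding gene, some other annotated feature,
    or is a novel assembled prediction.  ``te_flag`` marks
    transposable-element-associated genes (supplied externally, never
    inferred here).
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]
    annotation_class: str = NOVEL
    te_flag: bool = False

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ModelError(f"gene {self.gene_id} has no transcripts")
        if self.annotation_class not in ANNOTATION_CLASSES:
            raise ModelError(f"invalid annotation_class {self.annotation_class!r}")
        for t in self.transcripts:
            if t.chrom != self.chrom or t.strand != self.strand:
                raise ModelError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} on"
                    f" {t.chrom}/{t.strand}, gene on {self.chrom}/{self.strand}"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.exons[0].start for t in self.transcripts),
            max(t.exons[-1].end for t in self.transcripts),
        )

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(f"gene {self.gene_id} has no transcript {transcript_id}")


def derive_introns(t: TranscriptModel) -> list[Intron]:
    """Return the introns of ``t``, one per adjacent exon pair, in genomic order.

    A single-exon transcript has no junctions and yields an empty list.
    """
    return [
        Intron(t.chrom, a.end, b.start, t.strand)
        for a, b in zip(t.exons, t.exons[1:])
    ]


def is_distinguishing_intron(
    candidate: Intron,
    others: Iterable[Intron],
    min_end_diff: int = 20,
) -> bool:
    """Is ``candidate`` distinguishable from every intron in ``others``?

    An intron distinguishes its isoform when, against each comparison
    intron, at least one boundary differs by strictly more than
    ``min_end_diff`` bp.  Boundary offsets are absolute genomic-coordinate
    differences, independent of strand.  An empty comparison set is
    vacuously distinguishing.
    """
    if min_end_diff < 0:
        raise ModelError("min_end_diff must be >= 0")
    for other in others:
        if (
            abs(candidate.start - other.start) <= min_end_diff
            and abs(candidate.end - other.end) <= min_end_diff
        ):
            return False
    return True


def intron_within_annotated_gene(
    intron: Intron, annotation: Iterable[GeneModel]
) -> bool:
    """True iff an annotated gene's genomic span fully contains the intron.

    Containment is required (partial overlap fails): the filter exists to
    reject intergenic intervals mis-predicted as introns by faulty
    transcript merging, and span containment is the weakest condition that
    does so.  Strand is ignored.
    """
    for gene in annotation:
        if gene.annotation_class == NOVEL:
            continue
        if gene.chrom != intron.chrom:
            continue
        g_start, g_end = gene.span
        if g_start <= intron.start and intron.end <= g_end:
            return True
    return False


def gene_passes_size_annotation_filter(
    gene: GeneModel,
    min_novel_length: int = 1000,
    length_mode: str = "spliced",
) -> bool:
    """Short-non-coding-RNA filter.

    Annotated protein-coding genes always pass.  Novel predicted genes pass
    only when longer than ``min_novel_length`` (strictly: "over 1 Kb"), by
    default measured as the longest isoform's spliced length
    (``length_mode="spliced"``); ``length_mode="span"`` uses the genomic
    span instead.  Non-coding annotated genes fail.
    """
    if gene.annotation_class == PROTEIN_CODING:
        return True
    if gene.annotation_class != NOVEL:
        return False
    if length_mode == "spliced":
        length = max(t.spliced_length for t in gene.transcripts)
    elif length_mode == "span":
        start, end = gene.span
        length = end - start
    else:
        raise ModelError(f"unknown length_mode {length_mode!r}")
    return length > min_novel_length


def classify_genes_by_reference(
    genes: Sequence[GeneModel], reference: Sequence[GeneModel]
) -> None:
    """Assign ``annotation_class`` to assembled genes from a reference annotation.

    A gene whose genomic span overlaps (same chromosome, either strand) a
    reference gene inherits that gene's annotation class; genes overlapping
    no reference locus are ``novel``.  Protein-coding takes precedence when
    several reference genes overlap.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for ref in reference:
        by_chrom.setdefault(ref.chrom, []).append(ref)
    for gene in genes:
        start, end = gene.span
        best: str | None = None
        for ref in by_chrom.get(gene.chrom, ()):
            r_start, r_end = ref.span
            if r_start < end and start < r_end:
                if ref.annotation_class == PROTEIN_CODING:
                    best = PROTEIN_CODING
                    break
                best = best or OTHER_ANNOTATED
        gene.annotation_class = best or NOVEL
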