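"""Primer-design support sequences.

Three artifacts per candidate: the exon-exon junction flank sequence with a
numbered junction position (for primers spanning the tissue-specific
junction), the spliced transcript sequence (e.g. for building BLAST
databases), and a genome-anchored alignment of all isoforms of a gene.

The alignment is a deterministic projection onto genomic coordinates —
because all isoforms of a gene share the genome, no heuristic multiple
alignment is needed: a column per exonic genomic position, a gap where an
isoform lacks that position.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .io import Genome, write_fasta
from .model import Exon, GeneModel, Intron, ModelError, TranscriptModel

_COMPLEMENT = str.maketrans(
    "ACGTUacgtuRYSWKMBDHVNryswkmbdhvn-",
    "TGCAAtgcaaYRSWMKVHDBNyrswmkvhdbn-",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement; IUPAC ambiguity codes map to their complements, N→N."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FlankReport:
    """Junction flank sequences for one intron, oriented to the transcript strand.

    ``junction_index`` is the 0-based position in ``spliced_junction_seq``
    of the first base after the junction, i.e. the length of the upstream
    flank actually extracted (human-readable reports print it 1-based).
    """

    intron: Intron
    spliced_junction_seq: str
    junction_index: int
    intron_retained_seq: str
    truncated_upstream: bool
    truncated_downstream: bool


def junction_flank_sequence(
    intron: Intron,
    genome: Genome,
    flank: int = 500,
    exonic_bounds: tuple[int, int] | None = None,
) -> FlankReport:
    """Extract ``flank`` bp on each side of an intron's junction.

    By default flanks are pure genomic sequence, ignoring exon boundaries.
    ``exonic_bounds=(upstream_exon_start, downstream_exon_end)`` restricts
    each flank to the adjacent exon of a particular isoform, for primers
    strictly within the mature transcript.  Flanks are truncated at contig
    (or exonic) bounds with the corresponding flag set.  For minus-strand
    introns the sequences are reverse-complemented and the junction index
    recomputed for the oriented sequence.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    contig_len = genome.contig_length(intron.chrom)
    if intron.start > contig_len or intron.end > contig_len:
        raise ModelError(
            f"intron {intron.chrom}:{intron.start}-{intron.end} outside contig"
        )
    left_bound, right_bound = 0, contig_len
    if exonic_bounds is not None:
        left_bound = max(left_bound, exonic_bounds[0])
        right_bound = min(right_bound, exonic_bounds[1])
    up_start = intron.start - flank
    down_end = intron.end + flank
    left_trunc = up_start < left_bound
    right_trunc = down_end > right_bound
    up = genome.fetch(intron.chrom, max(up_start, left_bound), intron.start)
    down = genome.fetch(intron.chrom, intron.end, min(down_end, right_bound))
    intron_seq = genome.fetch(intron.chrom, intron.start, intron.end)

    if intron.strand == "-":
        spliced = reverse_complement(up + down)
        retained = reverse_complement(up + intron_seq + down)
        junction_index = len(down)
        trunc_up, trunc_down = right_trunc, left_trunc
    else:
        spliced = up + down
        retained = up + intron_seq + down
        junction_index = len(up)
        trunc_up, trunc_down = left_trunc, right_trunc
    return FlankReport(
        intron=intron,
        spliced_junction_seq=spliced,
        junction_index=junction_index,
        intron_retained_seq=retained,
        truncated_upstream=trunc_up,
        truncated_downstream=trunc_down,
    )


def flank_for_transcript_intron(
    tx: TranscriptModel,
    intron: Intron,
    genome: Genome,
    flank: int = 500,
    exonic_only: bool = False,
) -> FlankReport:
    """Flank extraction for an intron of a specific isoform.

    With ``exonic_only`` the flanks stop at the far edges of the two exons
    adjacent to the intron in this isoform.
    """
    bounds = None
    if exonic_only:
        upstream = next(e for e in tx.exons if e.end == intron.start)
        downstream = next(e for e in tx.exons if e.start == intron.end)
        bounds = (upstream.start, downstream.end)
    return junction_flank_sequence(intron, genome, flank, bounds)


def spliced_transcript_sequence(tx: TranscriptModel, genome: Genome) -> str:
    """The mature transcript sequence: exon substrings joined in genomic order,
    reverse-complemented as a whole on the minus strand."""
    seq = "".join(genome.fetch(e.chrom, e.start, e.end) for e in tx.exons)
    return reverse_complement(seq) if tx.strand == "-" else seq


@dataclass(frozen=True)
class IsoformAlignment:
    """Genome-anchored alignment of a gene's isoforms.

    ``columns`` holds the genomic position of each alignment column, in row
    orientation (descending for minus-strand genes).  Removing the gaps
    from a row reproduces that isoform's spliced, strand-oriented sequence.
    """

    gene_id: str
    transcript_ids: tuple[str, ...]
    columns: tuple[int, ...]
    rows: tuple[str, ...]

    def row(self, transcript_id: str) -> str:
        return self.rows[self.transcript_ids.index(transcript_id)]

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(
            [
                (f"{self.gene_id}|{tid}", row)
                for tid, row in zip(self.transcript_ids, self.rows)
            ],
            path,
        )


def isoform_alignment(gene: GeneModel, genome: Genome) -> IsoformAlignment:
    """Project every isoform of a gene onto the union of exonic positions."""
    strands = {t.strand for t in gene.transcripts}
    chroms = {t.chrom for t in gene.transcripts}
    if len(strands) > 1 or len(chroms) > 1:
        raise ModelError(f"gene {gene.gene_id} mixes strands/chromosomes")
    positions: set[int] = set()
    for tx in gene.transcripts:
        for e in tx.exons:
            positions.update(range(e.start, e.end))
    columns = sorted(positions)
    span_start, span_end = gene.span
    span_seq = genome.fetch(gene.chrom, span_start, span_end)

    rows: list[str] = []
    for tx in gene.transcripts:
        exonic = set()
        for e in tx.exons:
            exonic.update(range(e.start, e.end))
        row = "".join(
            span_seq[p - span_start] if p in exonic else "-" for p in columns
        )
        rows.append(row)

    if gene.strand == "-":
        rows = [reverse_complement(r) for r in rows]
        columns = columns[::-1]
    return IsoformAlignment(
        gene_id=gene.gene_id,
        transcript_ids=tuple(t.transcript_id for t in gene.transcripts),
        columns=tuple(columns),
        rows=tuple(rows),
    )


def flank_record_id(
    gene_id: str, transcript_id: str, intron: Intron, junction_index: int
) -> str:
    """Stable FASTA record id for one distinguishing intron's flank sequence."""
    return (
        f"{gene_id}|{transcript_id}|intron:{intron.chrom}:{intron.start}-{intron.end}"
        f"|junction:{junction_index}"
    )


def write_flank_fasta(
    entries: Iterable[tuple[str, str, FlankReport]], path: str | Path
) -> list[dict]:
    """Write flank records (one per distinguishing intron) as FASTA.

    ``entries`` yields (gene_id, transcript_id, report).  Returns index rows
    (machine-readable, 0-based junction positions) for the TSV index.
    """
    records = []
    index_rows = []
    for gene_id, transcript_id, rep in entries:
        rec_id = flank_record_id(gene_id, transcript_id, rep.intron, rep.junction_index)
        records.append((rec_id, rep.spliced_junction_seq))
        index_rows.append(
            {
                "record_id": rec_id,
                "gene_id": gene_id,
                "transcript_id": transcript_id,
                "intron_chrom": rep.intron.chrom,
                "intron_start": rep.intron.start,
                "intron_end": rep.intron.end,
                "junction_index_0based": rep.junction_index,
                "junction_position_1based": rep.junction_index + 1,
                "truncated_upstream": rep.truncated_upstream,
                "truncated_downstream": rep.truncated_downstream,
            }
        )
    write_fasta(records, path)
    return index_rows
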