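import numpy as np
import pytest

from tsplice import Genome
from tsplice.model import Exon, GeneModel, Intron, ModelError, TranscriptModel
from tsplice.sequences import (
    flank_for_transcript_intron,
    isoform_alignment,
    junction_flank_sequence,
    reverse_complement,
    spliced_transcript_sequence,
)

# genome used by the worked examples: positions 0-3 A, 4-7 C, 8-11 G
GENOME = Genome({"chr1": "AAAACCCCGGGG"})


def I(s, e, strand="+"):
    return Intron("chr1", s, e, strand)


def tx(exons, strand="+", tid="t1", gid="g1"):
    return TranscriptModel(
        tid, gid, "chr1", strand, tuple(Exon("chr1", s, e, strand) for s, e in exons)
    )


# ---------------------------------------------------------------------------
# junction flanks


def test_flank_extraction_plus_strand():
    rep = junction_flank_sequence(I(4, 8), GENOME, flank=2)
    assert rep.spliced_junction_seq == "AAGG"
    assert rep.junction_index == 2
    assert rep.intron_retained_seq == "AACCCCGG"
    assert not rep.truncated_upstream and not rep.truncated_downstream
    assert len(rep.intron_retained_seq) == len(rep.spliced_junction_seq) + 4


def test_flank_extraction_minus_strand_is_reverse_complement():
    rep = junction_flank_sequence(I(4, 8, "-"), GENOME, flank=2)
    assert rep.spliced_junction_seq == "CCTT"
    assert rep.junction_index == 2
    assert rep.intron_retained_seq == reverse_complement("AACCCCGG")


def test_flank_truncation_at_contig_start():
    rep = junction_flank_sequence(I(1, 3), GENOME, flank=5)
    assert rep.spliced_junction_seq == "A" + "ACCCC"
    assert rep.junction_index == 1
    assert rep.truncated_upstream and not rep.truncated_downstream


def test_flank_length_bound_with_equality_iff_untruncated():
    for intron, flank in [(I(4, 8), 2), (I(4, 8), 4), (I(1, 3), 5), (I(4, 8), 6)]:
        rep = junction_flank_sequence(intron, GENOME, flank=flank)
        assert len(rep.spliced_junction_seq) <= 2 * flank
        untruncated = not (rep.truncated_upstream or rep.truncated_downstream)
        assert (len(rep.spliced_junction_seq) == 2 * flank) is untruncated


def test_exonic_only_mode_truncates_at_adjacent_exon_edges():
    t = tx([(2, 4), (8, 10)])
    rep = flank_for_transcript_intron(t, I(4, 8), GENOME, flank=5, exonic_only=True)
    assert rep.spliced_junction_seq == "AAGG"  # both flanks capped at 2 bp exons
    assert rep.junction_index == 2
    assert rep.truncated_upstream and rep.truncated_downstream


def test_flank_errors_outside_contig():
    with pytest.raises(ModelError):
        junction_flank_sequence(I(10, 20), GENOME, flank=2)


def test_strand_flip_invariance():
    """Minus-strand extraction equals plus-strand extraction on the
    reverse-complemented genome with mirrored coordinates."""
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGTN"), size=200))
    L = len(seq)
    genome = Genome({"c": seq})
    mirrored = Genome({"c": reverse_complement(seq)})
    for start, end, flank in [(50, 90, 10), (5, 30, 20), (150, 198, 30)]:
        direct = junction_flank_sequence(Intron("c", start, end, "-"), genome, flank)
        flipped = junction_flank_sequence(
            Intron("c", L - end, L - start, "+"), mirrored, flank
        )
        assert direct.spliced_junction_seq == flipped.spliced_junction_seq
        assert direct.intron_retained_seq == flipped.intron_retained_seq
        assert direct.junction_index == flipped.junction_index
        assert (direct.truncated_upstream, direct.truncated_downstream) == (
            flipped.truncated_upstream, flipped.truncated_downstream
        )


# ---------------------------------------------------------------------------
# spliced transcript sequence


@pytest.mark.parametrize(
    "exons,strand,expected",
    [
        ([(0, 4), (8, 12)], "+", "AAAAGGGG"),
        ([(0, 4), (8, 12)], "-", "CCCCTTTT"),
        ([(0, 12)], "+", "AAAACCCCGGGG"),
    ],
)
def test_spliced_transcript_sequence(exons, strand, expected):
    assert spliced_transcript_sequence(tx(exons, strand), GENOME) == expected


def test_reverse_complement_maps_ambiguity_codes():
    assert reverse_complement("ACGTN") == "NACGT"
    assert reverse_complement(reverse_complement("RYSWKMBDHVN")) == "RYSWKMBDHVN"


# ---------------------------------------------------------------------------
# isoform alignment


def test_alignment_projects_isoforms_onto_genomic_columns():
    t1 = tx([(0, 4), (8, 12)], tid="i1")
    t2 = tx([(0, 12)], tid="i2")
    g = GeneModel("g1", "chr1", "+", [t1, t2])
    aln = isoform_alignment(g, GENOME)
    assert aln.columns == tuple(range(12))
    assert aln.row("i1") == "AAAA----GGGG"
    assert aln.row("i2") == "AAAACCCCGGGG"


def test_alignment_single_and_identical_isoforms():
    t1 = tx([(0, 4), (8, 12)], tid="i1")
    g = GeneModel("g1", "chr1", "+", [t1])
    aln = isoform_alignment(g, GENOME)
    assert aln.rows == ("AAAAGGGG",)
    t2 = tx([(0, 4), (8, 12)], tid="i2")
    g2 = GeneModel("g2", "chr1", "+", [t1, t2])
    rows = isoform_alignment(g2, GENOME).rows
    assert rows[0] == rows[1]


def test_alignment_rows_degap_to_spliced_sequences_both_strands():
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), size=600))
    genome = Genome({"c": seq})
    for strand in "+-":
        exon_sets = [
            [(10, 60), (100, 180), (300, 420)],
            [(10, 60), (300, 420)],
            [(10, 200)],
        ]
        txs = [
            TranscriptModel(
                f"t{k}", "g", "c", strand,
                tuple(Exon("c", s, e, strand) for s, e in exons),
            )
            for k, exons in enumerate(exon_sets)
        ]
        g = GeneModel("g", "c", strand, txs)
        aln = isoform_alignment(g, genome)
        assert len({len(r) for r in aln.rows}) == 1
        for t in txs:
            assert aln.row(t.transcript_id).replace("-", "") == \
                spliced_transcript_sequence(t, genome)


def test_alignment_rejects_mixed_strand_gene():
    t1 = tx([(0, 4)], "+", tid="i1")
    t2 = tx([(8, 12)], "-", tid="i2")
    g = GeneModel.__new__(GeneModel)  # bypass GeneModel validation deliberately
    g.gene_id, g.chrom, g.strand = "g", "chr1", "+"
    g.transcripts, g.annotation_class, g.te_flag = [t1, t2], "novel", False
    with pytest.raises(ModelError):
        isoform_alignment(g, GENOME)
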