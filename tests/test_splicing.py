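import pandas as pd
import pytest

from tsplice import AbundanceTable, JunctionEvidence, SampleRoles
from tsplice.model import Exon, GeneModel, Intron, TranscriptModel
from tsplice.splicing import (
    SplicingCandidate,
    SplicingThresholds,
    rank_splicing_candidates,
    screen_splicing,
    screen_splicing_detailed,
    shared_primer_site_predicate,
)

from _oracles import oracle_splicing_candidates, random_cases

ROLES = SampleRoles(("testis_early", "testis_late"), ("gx_male", "ovary", "female"))


def _skip_gene(gid="g1", chrom="chr1", strand="+"):
    """Isoform B keeps exons E1..E4; isoform A skips E2 (its unique intron
    spans E1.end..E3.start)."""
    e = [Exon(chrom, s, t, strand) for s, t in
         [(1000, 1200), (1500, 1700), (2100, 2300), (2700, 2900)]]
    tx_b = TranscriptModel(f"{gid}.B", gid, chrom, strand, tuple(e))
    tx_a = TranscriptModel(f"{gid}.A", gid, chrom, strand, (e[0], e[2], e[3]))
    gene = GeneModel(gid, chrom, strand, [tx_b, tx_a])
    return gene, Intron(chrom, 1200, 2100, strand)


def _annotation(chrom="chr1", span=(0, 5000)):
    t = TranscriptModel("ann.t1", "ann", chrom, "+", (Exon(chrom, *span, "+"),))
    return [GeneModel("ann", chrom, "+", [t], "protein_coding")]


def _tx_table(values, roles=ROLES):
    df = pd.DataFrame(values, index=list(roles.all_samples)).T
    return AbundanceTable("transcript", df)


def _evidence(intron, reads, sample="testis_early"):
    ev = JunctionEvidence()
    ev.add(sample, intron.key, reads)
    return ev


def _run(a_fpkm, b_fpkm, reads=15, annotation=None, th=SplicingThresholds()):
    gene, intron = _skip_gene()
    table = _tx_table({"g1.A": a_fpkm, "g1.B": b_fpkm})
    ev = _evidence(intron, reads)
    ann = _annotation() if annotation is None else annotation
    return screen_splicing([gene], table, ev, ann, ROLES, th), intron


def test_candidate_satisfying_all_rules_is_reported_with_its_intron():
    cands, intron = _run(
        a_fpkm=[50.0, 5.0, 0.0, 0.0, 0.0],  # testis-specific isoform
        b_fpkm=[2.0, 2.0, 20.0, 1.0, 1.0],  # alternate form expressed off-target
    )
    assert len(cands) == 1
    c = cands[0]
    assert (c.gene_id, c.transcript_id) == ("g1", "g1.A")
    assert [(i.key, n) for i, n in c.distinguishing_introns] == [(intron.key, 15)]
    assert c.best_alt_isoform == ("g1.B", "gx_male", 20.0)


@pytest.mark.parametrize(
    "a_fpkm,b_fpkm,reads,expected,why",
    [
        ([50, 5, 0, 0, 0], [2, 2, 20, 1, 1], 10, False,
         "exactly 10 junction reads: strictly more than 10 required"),
        ([50, 5, 0, 0, 0], [2, 2, 20, 1, 1], 11, True,
         "11 junction reads pass the strict threshold"),
        ([50, 5, 0, 0, 0], [2, 2, 8, 1, 1], 15, False,
         "no other isoform reaches 10 FPKM off-target: the gene is "
         "tissue-specifically expressed, not spliced"),
        ([50, 5, 0, 0.5, 0], [2, 2, 20, 1, 1], 15, False,
         "candidate isoform at 0.5 FPKM in ovary breaches the 0.4 maximum"),
        ([50, 5, 0, 0.4, 0], [2, 2, 20, 1, 1], 15, False,
         "exactly 0.4 FPKM off-target: strict maximum"),
        ([9.9, 5, 0, 0, 0], [2, 2, 20, 1, 1], 15, False,
         "candidate isoform below the 10 FPKM target minimum"),
        ([10.0, 5, 0, 0, 0], [2, 2, 20, 1, 1], 15, True,
         "exactly 10 FPKM in the earliest target sample: inclusive minimum"),
        ([50, 5, 0, 0, 0], [2, 2, 10.0, 1, 1], 15, True,
         "alternate isoform at exactly 10 FPKM off-target: '10 FPKM or above'"),
    ],
)
def test_splicing_rule_boundaries(a_fpkm, b_fpkm, reads, expected, why):
    cands, _ = _run(a_fpkm, b_fpkm, reads)
    assert bool(cands) is expected, why


def test_intron_must_lie_within_an_annotated_gene():
    cands, _ = _run([50, 5, 0, 0, 0], [2, 2, 20, 1, 1],
                    annotation=_annotation(span=(0, 1500)))
    assert cands == []
    cands, _ = _run([50, 5, 0, 0, 0], [2, 2, 20, 1, 1],
                    annotation=_annotation(chrom="chr2"))
    assert cands == []


def test_end_shifted_intron_at_exactly_20bp_is_not_distinguishing():
    chrom, strand = "chr1", "+"
    e = [Exon(chrom, s, t, strand) for s, t in
         [(1000, 1200), (1500, 1700), (2100, 2300)]]
    tx_b = TranscriptModel("g1.B", "g1", chrom, strand, tuple(e))
    shifted = Exon(chrom, 1520, 1700, strand)  # acceptor moved by exactly 20
    tx_a = TranscriptModel("g1.A", "g1", chrom, strand, (e[0], shifted, e[2]))
    gene = GeneModel("g1", chrom, strand, [tx_b, tx_a])
    table = _tx_table({"g1.A": [50, 5, 0, 0, 0], "g1.B": [2, 2, 20, 1, 1]})
    ev = JunctionEvidence()
    for intron in ((1200, 1520), (1700, 2100)):
        ev.add("testis_early", (chrom, *intron), 40)
    assert screen_splicing([gene], table, ev, _annotation(), ROLES) == []


def test_junction_coverage_max_target_mode():
    gene, intron = _skip_gene()
    table = _tx_table({"g1.A": [50, 5, 0, 0, 0], "g1.B": [2, 2, 20, 1, 1]})
    ev = _evidence(intron, 30, sample="testis_late")  # no reads in earliest
    assert screen_splicing([gene], table, ev, _annotation(), ROLES) == []
    th = SplicingThresholds(junction_sample_mode="max_target")
    assert len(screen_splicing([gene], table, ev, _annotation(), ROLES, th)) == 1


def test_detailed_result_reports_filter_cascade():
    gene, intron = _skip_gene()
    table = _tx_table({"g1.A": [50, 5, 0, 0, 0], "g1.B": [2, 2, 20, 1, 1]})
    result = screen_splicing_detailed(
        [gene], table, _evidence(intron, 15), _annotation(), ROLES
    )
    counts = result.filter_counts
    order = ["input", "target_min", "off_target_max", "alt_isoform",
             "distinguishing_intron"]
    values = [counts[k] for k in order]
    assert values == sorted(values, reverse=True)
    assert counts["distinguishing_intron"] == 1


# ---------------------------------------------------------------------------
# ranking and shared-primer detection


def _cand(tid, intron_len, gid="g"):
    intron = Intron("chr1", 1000, 1000 + intron_len, "+")
    return SplicingCandidate(gid, tid, ((intron, 15),), 50.0, 0.0, ("x", "gx", 20.0))


def test_rank_ascending_min_intron_length_with_truncation():
    cands = [_cand("t1", 500), _cand("t2", 80), _cand("t3", 2000)]
    ranked = rank_splicing_candidates(cands, 2)
    assert [c.transcript_id for c in ranked] == ["t2", "t1"]
    assert rank_splicing_candidates([], 5) == []


def test_shared_primer_candidates_all_retained_ahead_of_ranked_rest():
    cands = [_cand("t1", 500), _cand("t2", 80), _cand("t3", 2000), _cand("t4", 900)]
    shared = {"t3", "t4"}
    ranked = rank_splicing_candidates(cands, 1, lambda c: c.transcript_id in shared)
    assert [c.transcript_id for c in ranked] == ["t4", "t3", "t2"]


def test_shared_primer_predicate_detects_exon_skipping_but_not_disjoint_flanks():
    gene, intron = _skip_gene()
    pred = shared_primer_site_predicate([gene])
    cand = SplicingCandidate("g1", "g1.A", ((intron, 15),), 50.0, 0.0,
                             ("g1.B", "gx_male", 20.0))
    # A's flanking exons E1 and E3 both occur in isoform B -> shared site
    assert pred(cand)

    # disjoint flanks: no other isoform contains both flanking exons
    e_a = (Exon("chr1", 0, 100, "+"), Exon("chr1", 200, 300, "+"))
    e_b = (Exon("chr1", 0, 50, "+"), Exon("chr1", 400, 500, "+"))
    tx_a = TranscriptModel("h.A", "h", "chr1", "+", e_a)
    tx_b = TranscriptModel("h.B", "h", "chr1", "+", e_b)
    gene2 = GeneModel("h", "chr1", "+", [tx_a, tx_b])
    cand2 = SplicingCandidate(
        "h", "h.A", ((Intron("chr1", 100, 200, "+"), 15),), 50.0, 0.0,
        ("h.B", "gx_male", 20.0),
    )
    assert not shared_primer_site_predicate([gene2])(cand2)


def test_shared_primer_predicate_detects_intron_retention():
    # isoform B retains A's intron inside one long exon
    e_a = (Exon("chr1", 0, 100, "+"), Exon("chr1", 200, 300, "+"))
    tx_a = TranscriptModel("g.A", "g", "chr1", "+", e_a)
    tx_b = TranscriptModel(
        "g.B", "g", "chr1", "+", (Exon("chr1", 0, 300, "+"),)
    )
    gene = GeneModel("g", "chr1", "+", [tx_a, tx_b])
    cand = SplicingCandidate(
        "g", "g.A", ((Intron("chr1", 100, 200, "+"), 15),), 50.0, 0.0,
        ("g.B", "gx_male", 20.0),
    )
    assert shared_primer_site_predicate([gene])(cand)


# ---------------------------------------------------------------------------
# properties on random inputs


def _random_inputs(seed):
    roles = SampleRoles(("early", "mid", "late"), ("gx", "ovary", "female"))
    genes, annotation, _, tx_table, junctions = random_cases(seed, 80, roles)
    return genes, annotation, tx_table, junctions, roles


@pytest.mark.parametrize("seed", [5, 6, 7])
def test_screen_agrees_with_brute_force_oracle(seed):
    genes, annotation, table, junctions, roles = _random_inputs(seed)
    th = SplicingThresholds()
    got = {
        (c.gene_id, c.transcript_id): {i.key for i, _ in c.distinguishing_introns}
        for c in screen_splicing(genes, table, junctions, annotation, roles, th)
    }
    assert got == oracle_splicing_candidates(
        genes, table, junctions, annotation, roles, th
    )


@pytest.mark.parametrize("seed", [8, 9])
def test_tightening_any_threshold_never_adds_candidates(seed):
    genes, annotation, table, junctions, roles = _random_inputs(seed)
    base = {
        (c.gene_id, c.transcript_id)
        for c in screen_splicing(genes, table, junctions, annotation, roles)
    }
    for th in (
        SplicingThresholds(min_target_isoform_fpkm=12),
        SplicingThresholds(max_off_target_isoform_fpkm=0.2),
        SplicingThresholds(min_alt_isoform_fpkm=20),
        SplicingThresholds(min_junction_reads=20),
        SplicingThresholds(min_intron_end_diff=40),
    ):
        tightened = {
            (c.gene_id, c.transcript_id)
            for c in screen_splicing(genes, table, junctions, annotation, roles, th)
        }
        assert tightened <= base


@pytest.mark.parametrize("seed", [13])
def test_purely_tissue_specifically_expressed_genes_never_fire_splicing(seed):
    """If every isoform of a gene is under the off-target maximum in every
    off-target sample, no other isoform can reach the 10 FPKM alternate-form
    requirement, so the splicing screen cannot call the gene."""
    genes, annotation, table, junctions, roles = _random_inputs(seed)
    th = SplicingThresholds()
    specific = {
        g.gene_id
        for g in genes
        if all(
            table.value(t.transcript_id, s) < th.max_off_target_isoform_fpkm
            for t in g.transcripts
            for s in roles.off_target_samples
        )
    }
    called = {
        c.gene_id
        for c in screen_splicing(genes, table, junctions, annotation, roles, th)
    }
    assert not (specific & called)
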