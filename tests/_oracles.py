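"""Independent brute-force re-evaluations of the screening rules.

These transcribe the filtering rules directly, per gene and per intron,
without sharing code with the package's screen implementations; the tests
assert agreement between the two routes on randomly generated inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from tsplice import (
    AbundanceTable,
    Exon,
    GeneModel,
    Intron,
    JunctionEvidence,
    SampleRoles,
    TranscriptModel,
)
from tsplice.expression import ExpressionThresholds
from tsplice.splicing import SplicingThresholds


def oracle_expression_candidates(genes, table: AbundanceTable, roles: SampleRoles,
                                 th: ExpressionThresholds) -> set[str]:
    """Direct four-rule evaluation per gene."""
    out = set()
    for g in genes:
        early = table.value(g.gene_id, roles.target_stage_samples[0])
        if early < th.min_target_fpkm:
            continue
        if any(
            table.value(g.gene_id, s) >= th.max_off_target_fpkm
            for s in roles.off_target_samples
        ):
            continue
        if g.annotation_class == "protein_coding":
            pass
        elif g.annotation_class == "novel":
            longest = max(sum(e.end - e.start for e in t.exons) for t in g.transcripts)
            if longest <= th.min_novel_length:
                continue
        else:
            continue
        later = roles.target_stage_samples[1:]
        if later:
            mean_later = sum(table.value(g.gene_id, s) for s in later) / len(later)
            if not early > mean_later:
                continue
        out.add(g.gene_id)
    return out


def oracle_splicing_candidates(
    genes, table: AbundanceTable, junctions: JunctionEvidence,
    annotation, roles: SampleRoles, th: SplicingThresholds,
) -> dict[tuple[str, str], set[tuple[str, int, int]]]:
    """Direct per-transcript, per-intron evaluation of the six filters.

    Returns {(gene_id, transcript_id): set of qualifying intron keys}.
    """
    out: dict[tuple[str, str], set[tuple[str, int, int]]] = {}
    early_sample = roles.target_stage_samples[0]
    for g in genes:
        for t in g.transcripts:
            if table.value(t.transcript_id, early_sample) < th.min_target_isoform_fpkm:
                continue
            if any(
                table.value(t.transcript_id, s) >= th.max_off_target_isoform_fpkm
                for s in roles.off_target_samples
            ):
                continue
            alt_ok = False
            for t2 in g.transcripts:
                if t2.transcript_id == t.transcript_id:
                    continue
                for s in roles.off_target_samples:
                    if table.value(t2.transcript_id, s) >= th.min_alt_isoform_fpkm:
                        alt_ok = True
            if not alt_ok:
                continue
            # all introns of every other isoform of the gene
            other_introns = []
            for t2 in g.transcripts:
                if t2.transcript_id == t.transcript_id:
                    continue
                for a, b in zip(t2.exons, t2.exons[1:]):
                    other_introns.append((a.end, b.start))
            qualifying: set[tuple[str, int, int]] = set()
            for a, b in zip(t.exons, t.exons[1:]):
                start, end = a.end, b.start
                shared = any(
                    abs(start - os) <= th.min_intron_end_diff
                    and abs(end - oe) <= th.min_intron_end_diff
                    for os, oe in other_introns
                )
                if shared:
                    continue
                if th.junction_sample_mode == "earliest":
                    reads = junctions.count(early_sample, (t.chrom, start, end))
                else:
                    reads = max(
                        junctions.count(s, (t.chrom, start, end))
                        for s in roles.target_stage_samples
                    )
                if not reads > th.min_junction_reads:
                    continue
                contained = any(
                    ann.annotation_class != "novel"
                    and ann.chrom == t.chrom
                    and min(tt.exons[0].start for tt in ann.transcripts) <= start
                    and end <= max(tt.exons[-1].end for tt in ann.transcripts)
                    for ann in annotation
                )
                if not contained:
                    continue
                qualifying.add((t.chrom, start, end))
            if qualifying:
                out[(g.gene_id, t.transcript_id)] = qualifying
    return out


# ---------------------------------------------------------------------------
# random-case generator (boundary-heavy, independent of tsplice.fixtures)

_FPKM_CHOICES = [0.0, 0.1, 0.2, 0.39, 0.4, 0.41, 0.9, 1.0, 1.1, 5.0, 9.9, 10.0, 10.1, 15.0, 40.0]
_READ_CHOICES = [0, 5, 9, 10, 11, 15, 50]
_SHIFT_CHOICES = [0, 10, 19, 20, 21, 50]


def random_cases(seed: int, n_genes: int, roles: SampleRoles):
    """Random gene models + abundances + junction evidence, threshold-heavy.

    Designed to exercise every filter branch: FPKM values and junction
    counts are drawn from sets straddling the default thresholds, and
    alternative isoforms shift intron boundaries by amounts around the
    20 bp end-offset rule.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    annotation: list[GeneModel] = []
    tx_rows: dict[str, dict[str, float]] = {}
    gene_rows: dict[str, dict[str, float]] = {}
    junctions = JunctionEvidence()
    pos = 1000
    for gi in range(n_genes):
        gid = f"R{gi:04d}"
        chrom = f"chr{int(rng.integers(1, 3))}"
        strand = "+" if rng.integers(0, 2) else "-"
        n_exons = int(rng.integers(2, 5))
        exons = []
        p = pos
        for _ in range(n_exons):
            length = int(rng.integers(80, 200))
            exons.append((p, p + length))
            p += length + int(rng.integers(100, 300))
        gene_end = p
        pos = gene_end + 500
        txs = []
        n_iso = int(rng.integers(1, 4))
        base = tuple(Exon(chrom, s, e, strand) for s, e in exons)
        txs.append(TranscriptModel(f"{gid}.t1", gid, chrom, strand, base))
        for k in range(2, n_iso + 1):
            mode = rng.integers(0, 3)
            if mode == 0 and n_exons >= 3:  # skip an internal exon
                drop = int(rng.integers(1, n_exons - 1))
                alt = tuple(e for i, e in enumerate(base) if i != drop)
            elif mode == 1:  # shift an internal acceptor
                i = int(rng.integers(1, n_exons))
                shift = int(rng.choice(_SHIFT_CHOICES))
                e = base[i]
                if e.start + shift < e.end:
                    alt = base[:i] + (Exon(chrom, e.start + shift, e.end, strand),) + base[i + 1:]
                else:
                    alt = base
            else:  # truncated 3' end
                alt = base[: max(1, n_exons - 1)]
            txs.append(TranscriptModel(f"{gid}.t{k}", gid, chrom, strand, alt))
        klass = ["protein_coding", "other_annotated", "novel"][int(rng.integers(0, 3))]
        gene = GeneModel(gid, chrom, strand, txs, annotation_class=klass)
        genes.append(gene)
        if rng.integers(0, 4) > 0:  # 3/4 of loci covered by an annotated span
            ref_tx = TranscriptModel(
                f"ann_{gid}.t1", f"ann_{gid}", chrom, strand, base
            )
            annotation.append(
                GeneModel(f"ann_{gid}", chrom, strand, [ref_tx],
                          annotation_class="protein_coding")
            )
        for t in txs:
            tx_rows[t.transcript_id] = {
                s: float(rng.choice(_FPKM_CHOICES)) for s in roles.all_samples
            }
            for a, b in zip(t.exons, t.exons[1:]):
                for s in roles.target_stage_samples:
                    n = int(rng.choice(_READ_CHOICES))
                    key = (t.chrom, a.end, b.start)
                    if junctions.count(s, key) == 0 and n > 0:
                        junctions.add(s, key, n)
        gene_rows[gid] = {
            s: sum(tx_rows[t.transcript_id][s] for t in txs)
            for s in roles.all_samples
        }
    tx_table = AbundanceTable("transcript", pd.DataFrame(tx_rows).T[list(roles.all_samples)])
    gene_table = AbundanceTable("gene", pd.DataFrame(gene_rows).T[list(roles.all_samples)])
    return genes, annotation, gene_table, tx_table, junctions
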