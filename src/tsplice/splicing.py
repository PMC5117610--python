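"""Screen for target-tissue-specific splice forms.

A (gene, isoform) pair survives when:

1. the isoform's FPKM in the earliest target sample is at or above
   ``min_target_isoform_fpkm`` (default 10);
2. its FPKM is strictly below ``max_off_target_isoform_fpkm`` (default 0.4)
   in every off-target sample;
3. some OTHER isoform of the gene reaches ``min_alt_isoform_fpkm``
   (default 10) in at least one off-target sample — this distinguishes
   tissue-specific *splicing* from tissue-specific *expression*;
4. the isoform carries at least one distinguishing intron: its boundaries
   differ by strictly more than ``min_intron_end_diff`` bp (default 20) at
   one end from every intron of the gene's other isoforms, strictly more
   than ``min_junction_reads`` (default 10) reads span its junction in the
   target tissue, and the intron lies within an annotated gene's span
   (rejecting intergenic merge artifacts).

Filters 1–2 guard against low-expression assembly noise; filter 4's end
offset guards against near-identical introns produced by ragged assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .io import AbundanceTable, JunctionEvidence, SampleRoles
from .model import (
    GeneModel,
    Intron,
    TranscriptModel,
    derive_introns,
    intron_within_annotated_gene,
    is_distinguishing_intron,
)

FILTER_NAMES = (
    "target_min",
    "off_target_max",
    "alt_isoform",
    "distinguishing_intron",
)
FILTER_BITS = {name: 1 << i for i, name in enumerate(FILTER_NAMES)}


@dataclass(frozen=True)
class SplicingThresholds:
    min_target_isoform_fpkm: float = 10.0
    max_off_target_isoform_fpkm: float = 0.4
    min_alt_isoform_fpkm: float = 10.0
    min_junction_reads: int = 10  # strict: more than this many spanning reads
    min_intron_end_diff: int = 20  # strict: boundaries differ by more than this
    # sample in which junction coverage is assessed: "earliest" (default)
    # or "max_target" (max over all target-stage samples)
    junction_sample_mode: str = "earliest"
    target_min_inclusive: bool = True

    def __post_init__(self) -> None:
        if (
            min(
                self.min_target_isoform_fpkm,
                self.max_off_target_isoform_fpkm,
                self.min_alt_isoform_fpkm,
                self.min_junction_reads,
                self.min_intron_end_diff,
            )
            < 0
        ):
            raise ValueError("thresholds must be non-negative")
        if self.junction_sample_mode not in ("earliest", "max_target"):
            raise ValueError(f"unknown junction_sample_mode {self.junction_sample_mode!r}")


@dataclass(frozen=True)
class SplicingCandidate:
    gene_id: str
    transcript_id: str
    # every intron that passed novelty, junction coverage and containment
    distinguishing_introns: tuple[tuple[Intron, int], ...]
    target_isoform_fpkm: float
    off_target_isoform_max_fpkm: float
    best_alt_isoform: tuple[str, str, float]  # (transcript_id, sample_id, fpkm)

    @property
    def min_intron_length(self) -> int:
        return min(len(i) for i, _ in self.distinguishing_introns)


@dataclass
class SplicingScreenResult:
    candidates: list[SplicingCandidate]
    rows: list[dict] = field(default_factory=list)
    filter_counts: dict[str, int] = field(default_factory=dict)


def _junction_count(
    junctions: JunctionEvidence, intron: Intron, roles: SampleRoles, mode: str
) -> int:
    if mode == "earliest":
        return junctions.count(roles.earliest, intron)
    return max(junctions.count(s, intron) for s in roles.target_stage_samples)


def screen_splicing(
    genes: Iterable[GeneModel],
    transcript_abundance: AbundanceTable,
    junctions: JunctionEvidence,
    annotation: Sequence[GeneModel],
    roles: SampleRoles,
    th: SplicingThresholds = SplicingThresholds(),
) -> list[SplicingCandidate]:
    """Apply the splicing filters and return the surviving isoforms."""
    return screen_splicing_detailed(
        genes, transcript_abundance, junctions, annotation, roles, th
    ).candidates


def screen_splicing_detailed(
    genes: Iterable[GeneModel],
    transcript_abundance: AbundanceTable,
    junctions: JunctionEvidence,
    annotation: Sequence[GeneModel],
    roles: SampleRoles,
    th: SplicingThresholds = SplicingThresholds(),
) -> SplicingScreenResult:
    if transcript_abundance.feature_level != "transcript":
        raise ValueError("screen_splicing requires a transcript-level abundance table")
    candidates: list[SplicingCandidate] = []
    rows: list[dict] = []
    counts = {"input": 0, **{name: 0 for name in FILTER_NAMES}}
    for gene in genes:
        gene_introns = {
            t.transcript_id: derive_introns(t) for t in gene.transcripts
        }
        for tx in gene.transcripts:
            counts["input"] += 1
            early = transcript_abundance.value(tx.transcript_id, roles.earliest)
            off = {
                s: transcript_abundance.value(tx.transcript_id, s)
                for s in roles.off_target_samples
            }
            if th.target_min_inclusive:
                pass_target = early >= th.min_target_isoform_fpkm
            else:
                pass_target = early > th.min_target_isoform_fpkm
            pass_off = all(v < th.max_off_target_isoform_fpkm for v in off.values())

            # rule 3: another isoform of the same gene expressed off-target
            best_alt: tuple[str, str, float] | None = None
            for other in gene.transcripts:
                if other.transcript_id == tx.transcript_id:
                    continue
                for s in roles.off_target_samples:
                    v = transcript_abundance.value(other.transcript_id, s)
                    if v >= th.min_alt_isoform_fpkm and (
                        best_alt is None or v > best_alt[2]
                    ):
                        best_alt = (other.transcript_id, s, v)
            pass_alt = best_alt is not None

            # rule 4: distinguishing introns with coverage and containment
            others = [
                i
                for tid, intr in gene_introns.items()
                if tid != tx.transcript_id
                for i in intr
            ]
            distinguishing: list[tuple[Intron, int]] = []
            for intron in gene_introns[tx.transcript_id]:
                if not is_distinguishing_intron(intron, others, th.min_intron_end_diff):
                    continue
                n_reads = _junction_count(
                    junctions, intron, roles, th.junction_sample_mode
                )
                if n_reads <= th.min_junction_reads:
                    continue
                if not intron_within_annotated_gene(intron, annotation):
                    continue
                distinguishing.append((intron, n_reads))
            pass_intron = bool(distinguishing)

            flags = {
                "target_min": pass_target,
                "off_target_max": pass_off,
                "alt_isoform": pass_alt,
                "distinguishing_intron": pass_intron,
            }
            surviving = True
            for name in FILTER_NAMES:
                surviving = surviving and flags[name]
                if surviving:
                    counts[name] += 1
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "transcript_id": tx.transcript_id,
                    "earliest_target_fpkm": early,
                    "off_target_max_fpkm": max(off.values()),
                    "n_distinguishing_introns": len(distinguishing),
                    "filters": sum(FILTER_BITS[n] for n in FILTER_NAMES if flags[n]),
                    "candidate": all(flags.values()),
                }
            )
            if all(flags.values()):
                assert best_alt is not None
                candidates.append(
                    SplicingCandidate(
                        gene_id=gene.gene_id,
                        transcript_id=tx.transcript_id,
                        distinguishing_introns=tuple(distinguishing),
                        target_isoform_fpkm=early,
                        off_target_isoform_max_fpkm=max(off.values()),
                        best_alt_isoform=best_alt,
                    )
                )
    return SplicingScreenResult(candidates, rows, counts)


def shared_primer_site_predicate(
    genes: Mapping[str, GeneModel] | Iterable[GeneModel],
) -> Callable[[SplicingCandidate], bool]:
    """Build the default shared-primer-site detector.

    A candidate has a shared primer site when, for one of its distinguishing
    introns, both flanking exonic segments of the candidate isoform are
    contained in the exonic intervals of a single other isoform of the gene
    — then one primer pair can amplify both the tissue-specific and another
    splice form, yielding products of different sizes.  Containment covers
    both exon skipping (the flanks are shared exons) and intron retention
    (the flanks lie inside one larger exon).
    """
    if not isinstance(genes, Mapping):
        genes = {g.gene_id: g for g in genes}
    gene_map: Mapping[str, GeneModel] = genes

    def _contained(start: int, end: int, tx: TranscriptModel) -> bool:
        return any(e.start <= start and end <= e.end for e in tx.exons)

    def predicate(c: SplicingCandidate) -> bool:
        gene = gene_map[c.gene_id]
        tx = gene.transcript(c.transcript_id)
        for intron, _ in c.distinguishing_introns:
            upstream = next(e for e in tx.exons if e.end == intron.start)
            downstream = next(e for e in tx.exons if e.start == intron.end)
            for other in gene.transcripts:
                if other.transcript_id == tx.transcript_id:
                    continue
                if _contained(upstream.start, upstream.end, other) and _contained(
                    downstream.start, downstream.end, other
                ):
                    return True
        return False

    return predicate


def rank_splicing_candidates(
    candidates: Sequence[SplicingCandidate],
    n: int,
    has_shared_primer_site: Callable[[SplicingCandidate], bool] | None = None,
) -> list[SplicingCandidate]:
    """Order candidates for experimental follow-up.

    Candidates where a primer common to the tissue-specific and another
    splice form exists are all retained and listed first (they allow a
    size-difference assay and were few in practice); the remainder are
    sorted by ascending minimum distinguishing-intron length (short introns
    give short, easy junction amplicons) and truncated to ``n``.  Ties
    break by transcript id.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    pred = has_shared_primer_site or (lambda c: False)
    key = lambda c: (c.min_intron_length, c.transcript_id)
    shared = sorted((c for c in candidates if pred(c)), key=key)
    rest = sorted((c for c in candidates if not pred(c)), key=key)
    return shared + rest[:n]


def splicing_table_columns(roles: SampleRoles) -> list[str]:
    """Fixed column order for the per-intron splicing candidate TSV."""
    return [
        "gene_id",
        "transcript_id",
        "intron_chrom",
        "intron_start",
        "intron_end",
        "intron_length",
        "junction_reads",
        "target_isoform_fpkm",
        "off_target_isoform_max_fpkm",
        "alt_isoform_id",
        "alt_isoform_sample",
        "alt_isoform_fpkm",
    ]


def candidates_to_intron_rows(candidates: Sequence[SplicingCandidate]) -> list[dict]:
    """One output row per distinguishing intron of each candidate."""
    rows = []
    for c in candidates:
        for intron, n_reads in c.distinguishing_introns:
            rows.append(
                {
                    "gene_id": c.gene_id,
                    "transcript_id": c.transcript_id,
                    "intron_chrom": intron.chrom,
                    "intron_start": intron.start,
                    "intron_end": intron.end,
                    "intron_length": len(intron),
                    "junction_reads": n_reads,
                    "target_isoform_fpkm": c.target_isoform_fpkm,
                    "off_target_isoform_max_fpkm": c.off_target_isoform_max_fpkm,
                    "alt_isoform_id": c.best_alt_isoform[0],
                    "alt_isoform_sample": c.best_alt_isoform[1],
                    "alt_isoform_fpkm": c.best_alt_isoform[2],
                }
            )
    return rows
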