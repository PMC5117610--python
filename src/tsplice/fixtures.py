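"""Seeded generator of complete toy pipeline inputs with planted ground truth.

The generator emulates the statistical structure the screens assume: staged
target-tissue samples with an early/late contrast, off-target somatic
samples, and multi-isoform genes with isoform-specific introns.  It plants
genes of known kinds at stated FPKM margins from the default thresholds,
plants boundary decoys exactly ON each threshold to pin the documented
inclusive/strict conventions, and writes a truth manifest recording the
expected screen outcome of every planted gene.

Background (non-planted) genes draw log-uniform FPKM noise but are forced
to express in at least one off-target sample above every off-target
threshold, so they can never be candidates: the truth manifest is exact by
construction.  Read-level realism (error models, coverage variability) is
deliberately absent — the screens consume only FPKM and junction-count
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .io import (
    AbundanceTable,
    Genome,
    JunctionEvidence,
    SampleRoles,
    write_abundance_tsv,
    write_fasta,
    write_gtf,
    write_junctions_bed,
)
from .model import Exon, GeneModel, Intron, TranscriptModel

PLANT_KINDS = (
    "tissue_specific_expressed_early",
    "tissue_specific_expressed_late",
    "tissue_specific_spliced",
    "off_target_expressed",
    "near_threshold_decoy",
)

DECOY_SCENARIOS = (
    "expression_target_boundary",  # earliest exactly 10 FPKM -> candidate (inclusive >=)
    "expression_off_target_boundary",  # one off-target exactly 1 FPKM -> rejected (strict <)
    "splicing_junction_boundary",  # exactly 10 spanning reads -> rejected (strict >)
    "splicing_end_diff_boundary",  # intron ends differ by exactly 20 bp -> rejected (strict >)
    "expression_timing_tie",  # earliest == mean(later) -> rejected (strict >)
    "novel_length_boundary",  # novel gene of exactly 1000 bp -> rejected (strict >)
)

DEFAULT_ROLES = SampleRoles(
    target_stage_samples=(
        "early_spermatocytes",
        "late_spermatocytes",
        "round_spermatids",
        "elongated_spermatids",
    ),
    off_target_samples=("gonadectomised_male", "ovary", "female"),
)

_READ_ANCHOR = 20  # exonic bases on each side of a junction in simulated reads
_GENE_SLOT = 3600  # genomic bp reserved per gene (max span ~3.1 kb + spacing)
_SLOT_MARGIN = 200  # offset of the first exon inside a slot (keeps read anchors on-contig)


class FixtureError(ValueError):
    """Raised before any file is written when the configuration is infeasible."""


@dataclass(frozen=True)
class PlantSpec:
    """One planted gene: its kind, threshold margin and junction coverage."""

    kind: str
    margin: float = 2.0
    junction_reads: int = 15
    decoy_scenario: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in PLANT_KINDS:
            raise FixtureError(f"unknown plant kind {self.kind!r}")
        if self.kind == "near_threshold_decoy":
            if self.decoy_scenario not in DECOY_SCENARIOS:
                raise FixtureError(
                    f"decoy requires a scenario from {DECOY_SCENARIOS}"
                )
        elif self.margin <= 0:
            raise FixtureError("margin must be > 0 for non-decoy kinds")


@dataclass(frozen=True)
class FixtureConfig:
    seed: int
    n_genes: int = 30
    n_contigs: int = 2
    contig_length: int = 120_000
    sample_roles: SampleRoles = DEFAULT_ROLES
    planted: tuple[PlantSpec, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted", tuple(self.planted))
        if self.n_genes < len(self.planted):
            raise FixtureError("n_genes must be >= number of planted genes")
        capacity = self.n_contigs * max(
            0, (self.contig_length - _SLOT_MARGIN) // _GENE_SLOT
        )
        if self.n_genes > capacity:
            raise FixtureError(
                f"cannot place {self.n_genes} genes on {self.n_contigs} contigs of"
                f" {self.contig_length} bp (capacity {capacity})"
            )


def default_fixture_config(seed: int = 42) -> FixtureConfig:
    """The standard 30-gene validation fixture: 3 early-expressed, 2
    late-expressed and 3 tissue-specifically-spliced plants plus 4 boundary
    decoys, among 18 background genes."""
    planted = (
        (PlantSpec("tissue_specific_expressed_early"),) * 3
        + (PlantSpec("tissue_specific_expressed_late"),) * 2
        + (PlantSpec("tissue_specific_spliced"),) * 3
        + tuple(
            PlantSpec("near_threshold_decoy", decoy_scenario=s)
            for s in DECOY_SCENARIOS[:4]
        )
    )
    return FixtureConfig(seed=seed, planted=planted)


@dataclass(frozen=True)
class TruthEntry:
    gene_id: str
    kind: str
    scenario: str
    transcript_ids: tuple[str, ...]
    candidate_transcript_id: str  # "." when not a splicing plant
    distinguishing_introns: tuple[tuple[str, int, int], ...]
    junction_reads: int
    expected_expression_candidate: bool
    expected_splicing_candidate: bool
    note: str


@dataclass
class FixtureTruth:
    """Manifest of planted genes and their expected screen outcomes."""

    entries: list[TruthEntry] = field(default_factory=list)

    def expected_expression_gene_ids(self) -> set[str]:
        return {e.gene_id for e in self.entries if e.expected_expression_candidate}

    def expected_splicing(self) -> dict[tuple[str, str], set[tuple[str, int, int]]]:
        """(gene_id, transcript_id) -> expected distinguishing intron keys."""
        return {
            (e.gene_id, e.candidate_transcript_id): set(e.distinguishing_introns)
            for e in self.entries
            if e.expected_splicing_candidate
        }

    def write_tsv(self, path: str | Path) -> None:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "gene_id": e.gene_id,
                    "kind": e.kind,
                    "scenario": e.scenario,
                    "transcript_ids": ",".join(e.transcript_ids),
                    "candidate_transcript_id": e.candidate_transcript_id,
                    "distinguishing_introns": ";".join(
                        f"{c}:{s}-{t}" for c, s, t in e.distinguishing_introns
                    )
                    or ".",
                    "junction_reads": e.junction_reads,
                    "expected_expression_candidate": e.expected_expression_candidate,
                    "expected_splicing_candidate": e.expected_splicing_candidate,
                    "note": e.note,
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FixtureTruth":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        entries = []
        for _, r in df.iterrows():
            introns: list[tuple[str, int, int]] = []
            if r["distinguishing_introns"] not in (".", ""):
                for token in r["distinguishing_introns"].split(";"):
                    chrom, rest = token.rsplit(":", 1)
                    s, t = rest.split("-")
                    introns.append((chrom, int(s), int(t)))
            entries.append(
                TruthEntry(
                    gene_id=r["gene_id"],
                    kind=r["kind"],
                    scenario=r["scenario"],
                    transcript_ids=tuple(r["transcript_ids"].split(",")),
                    candidate_transcript_id=r["candidate_transcript_id"],
                    distinguishing_introns=tuple(introns),
                    junction_reads=int(r["junction_reads"]),
                    expected_expression_candidate=r["expected_expression_candidate"]
                    == "True",
                    expected_splicing_candidate=r["expected_splicing_candidate"]
                    == "True",
                    note=r["note"],
                )
            )
        return cls(entries)

    def write_summary(self, path: str | Path) -> None:
        lines = [
            "Planted-gene truth summary",
            f"planted genes: {len(self.entries)}",
            f"expected expression candidates: "
            f"{sorted(self.expected_expression_gene_ids())}",
            f"expected splicing candidates: "
            f"{sorted(g for g, _ in self.expected_splicing())}",
            "",
        ]
        for e in self.entries:
            lines.append(
                f"{e.gene_id}\t{e.kind}"
                + (f"[{e.scenario}]" if e.scenario != "." else "")
                + f"\texpr={e.expected_expression_candidate}"
                f"\tsplice={e.expected_splicing_candidate}\t{e.note}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# gene construction helpers


def _exon_chain(
    rng: np.random.Generator,
    chrom: str,
    strand: str,
    offset: int,
    n_exons: int,
    exon_lens: Sequence[int] | None = None,
) -> list[Exon]:
    exons = []
    pos = offset
    for i in range(n_exons):
        length = (
            int(exon_lens[i]) if exon_lens is not None else int(rng.integers(100, 301))
        )
        exons.append(Exon(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(100, 401))
    return exons


def _single_isoform_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    offset: int,
    exon_lens: Sequence[int] | None = None,
    n_exons: int = 3,
) -> GeneModel:
    exons = _exon_chain(rng, chrom, strand, offset, n_exons, exon_lens)
    tx = TranscriptModel(f"{gene_id}.t1", gene_id, chrom, strand, tuple(exons))
    return GeneModel(gene_id, chrom, strand, [tx])


def _skip_isoform_gene(
    rng: np.random.Generator, gene_id: str, chrom: str, strand: str, offset: int
) -> tuple[GeneModel, Intron]:
    """Two isoforms: B keeps the full 4-exon chain, A skips exon 2.

    A's skip intron differs from every B intron by >100 bp at one end, so it
    is distinguishing at the default 20 bp threshold.
    """
    exons = _exon_chain(rng, chrom, strand, offset, 4)
    tx_b = TranscriptModel(f"{gene_id}.t1", gene_id, chrom, strand, tuple(exons))
    a_exons = (exons[0], exons[2], exons[3])
    tx_a = TranscriptModel(f"{gene_id}.t2", gene_id, chrom, strand, a_exons)
    gene = GeneModel(gene_id, chrom, strand, [tx_b, tx_a])
    skip_intron = Intron(chrom, exons[0].end, exons[2].start, strand)
    return gene, skip_intron


def _end_shift_isoform_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    offset: int,
    shift: int = 20,
) -> tuple[GeneModel, Intron]:
    """Two isoforms differing only in exon 2's acceptor, shifted by ``shift`` bp.

    With shift equal to the end-offset threshold the shifted intron is NOT
    distinguishing (the rule is strictly greater-than).
    """
    exons = _exon_chain(rng, chrom, strand, offset, 4)
    tx_b = TranscriptModel(f"{gene_id}.t1", gene_id, chrom, strand, tuple(exons))
    e2 = exons[1]
    shifted = Exon(chrom, e2.start + shift, e2.end, strand)
    tx_a = TranscriptModel(
        f"{gene_id}.t2", gene_id, chrom, strand, (exons[0], shifted, exons[2], exons[3])
    )
    gene = GeneModel(gene_id, chrom, strand, [tx_b, tx_a])
    shifted_intron = Intron(chrom, exons[0].end, shifted.start, strand)
    return gene, shifted_intron


# ---------------------------------------------------------------------------
# generation


def generate_fixture(cfg: FixtureConfig, out_dir: str | Path) -> FixtureTruth:
    """Write a complete toy input set under ``out_dir`` and return the truth.

    Emits: ``genome.fa``, ``merged.gtf`` (assembled transcripts, no
    annotation classes), ``reference.gtf`` (annotated loci), gene- and
    transcript-level FPKM TSVs, one TopHat-dialect junction BED per target
    sample, a SAM file of simulated spliced reads for the earliest target
    sample, and ``truth.tsv`` / ``truth_summary.txt``.  Regeneration with
    the same config is byte-identical.
    """
    rng = np.random.default_rng(cfg.seed)
    roles = cfg.sample_roles
    out = Path(out_dir)

    # --- plan gene placement (fails before anything is written) -----------
    contig_names = [f"ctg{i + 1}" for i in range(cfg.n_contigs)]
    per_contig = (cfg.contig_length - _SLOT_MARGIN) // _GENE_SLOT
    slots = [
        (contig_names[i // per_contig], _SLOT_MARGIN + (i % per_contig) * _GENE_SLOT)
        for i in range(cfg.n_genes)
    ]
    if len(slots) < cfg.n_genes:  # pragma: no cover - guarded by FixtureConfig
        raise FixtureError("infeasible placement")

    genes: list[GeneModel] = []
    annotated_flags: list[bool] = []
    truth = FixtureTruth()
    # FPKM per transcript: {tid: {sample: value}}
    tx_fpkm: dict[str, dict[str, float]] = {}
    # planted junction counts (earliest sample) for distinguishing introns
    planted_junctions: dict[tuple[str, int, int], int] = {}

    def u(lo: float, hi: float) -> float:
        return float(rng.uniform(lo, hi))

    n_later = len(roles.later_target_samples)

    def set_fpkm(
        tid: str,
        early: float,
        later: Sequence[float],
        off: Sequence[float],
    ) -> None:
        values = dict(zip(roles.later_target_samples, later))
        values[roles.earliest] = early
        values.update(zip(roles.off_target_samples, off))
        tx_fpkm[tid] = {s: round(values[s], 6) for s in roles.all_samples}

    for idx in range(cfg.n_genes):
        gene_id = f"G{idx + 1:04d}"
        chrom, offset = slots[idx]
        strand = "+" if idx % 2 == 0 else "-"
        spec = cfg.planted[idx] if idx < len(cfg.planted) else None
        kind = spec.kind if spec else "background"
        scenario = spec.decoy_scenario if spec and spec.decoy_scenario else "."
        margin = spec.margin if spec else 2.0

        if kind == "tissue_specific_expressed_early":
            gene = _single_isoform_gene(rng, gene_id, chrom, strand, offset)
            early = 10.0 + margin + u(0, 30)
            later = [u(0.2, (early - margin) / 2) for _ in range(n_later)]
            off = [u(0.0, 0.5) for _ in roles.off_target_samples]
            set_fpkm(f"{gene_id}.t1", early, later, off)
            genes.append(gene)
            annotated_flags.append(True)
            truth.entries.append(
                TruthEntry(
                    gene_id, kind, ".", (f"{gene_id}.t1",), ".", (), 0,
                    True, False,
                    "early-biased, tissue-specific; passes all four expression filters",
                )
            )
        elif kind == "tissue_specific_expressed_late":
            gene = _single_isoform_gene(rng, gene_id, chrom, strand, offset)
            early = 10.0 + margin + u(0, 10)
            later = [early + margin + u(0, 20) for _ in range(n_later)]
            off = [u(0.0, 0.5) for _ in roles.off_target_samples]
            set_fpkm(f"{gene_id}.t1", early, later, off)
            genes.append(gene)
            annotated_flags.append(True)
            truth.entries.append(
                TruthEntry(
                    gene_id, kind, ".", (f"{gene_id}.t1",), ".", (), 0,
                    False, False,
                    "tissue-specific but late-biased; fails the timing filter",
                )
            )
        elif kind == "off_target_expressed":
            gene = _single_isoform_gene(rng, gene_id, chrom, strand, offset)
            early = u(15, 50)
            later = [u(0.5, 10) for _ in range(n_later)]
            off = [10.0 + margin + u(0, 20)] + [
                u(0.5, 10) for _ in roles.off_target_samples[1:]
            ]
            set_fpkm(f"{gene_id}.t1", early, later, off)
            genes.append(gene)
            annotated_flags.append(True)
            truth.entries.append(
                TruthEntry(
                    gene_id, kind, ".", (f"{gene_id}.t1",), ".", (), 0,
                    False, False,
                    "broadly expressed; fails the off-target filter",
                )
            )
        elif kind == "tissue_specific_spliced":
            gene, intron = _skip_isoform_gene(rng, gene_id, chrom, strand, offset)
            tid_b, tid_a = gene.transcripts[0].transcript_id, gene.transcripts[1].transcript_id
            early_a = 10.0 + margin + u(0, 30)
            set_fpkm(
                tid_a,
                early_a,
                [u(0.5, 5) for _ in range(n_later)],
                [u(0.0, 0.2) for _ in roles.off_target_samples],
            )
            set_fpkm(
                tid_b,
                u(1, 20),
                [u(1, 20) for _ in range(n_later)],
                [10.0 + margin + u(0, 20)]
                + [u(0.5, 5) for _ in roles.off_target_samples[1:]],
            )
            planted_junctions[intron.key] = spec.junction_reads
            genes.append(gene)
            annotated_flags.append(True)
            truth.entries.append(
                TruthEntry(
                    gene_id, kind, ".", (tid_b, tid_a), tid_a,
                    (intron.key,), spec.junction_reads,
                    False, True,
                    "exon-skipping isoform spliced only in target tissue",
                )
            )
        elif kind == "near_threshold_decoy":
            if scenario == "expression_target_boundary":
                gene = _single_isoform_gene(rng, gene_id, chrom, strand, offset)
                later = [u(0.2, 4.0) for _ in range(n_later)]
                off = [u(0.0, 0.5) for _ in roles.off_target_samples]
                set_fpkm(f"{gene_id}.t1", 10.0, later, off)
                genes.append(gene)
                annotated_flags.append(True)
                truth.entries.append(
                    TruthEntry(
                        gene_id, kind, scenario, (f"{gene_id}.t1",), ".", (), 0,
                        True, False,
                        "earliest-sample FPKM exactly 10: accepted (inclusive minimum)",
                    )
                )
            elif scenario == "expression_off_target_boundary":
                gene = _single_isoform_gene(rng, gene_id, chrom, strand, offset)
                early = 10.0 + 2.0 + u(0, 10)
                later = [u(0.2, 4.0) for _ in range(n_later)]
                off = [1.0] + [u(0.0, 0.5) for _ in roles.off_target_samples[1:]]
                set_fpkm(f"{gene_id}.t1", early, later, off)
                genes.append(gene)
                annotated_flags.append(True)
                truth.entries.append(
                    TruthEntry(
                        gene_id, kind, scenario, (f"{gene_id}.t1",), ".", (), 0,
                        False, False,
                        "one off-target sample exactly 1 FPKM: rejected (strict maximum)",
                    )
                )
            elif scenario == "splicing_junction_boundary":
                gene, intron = _skip_isoform_gene(rng, gene_id, chrom, strand, offset)
                tid_b, tid_a = (
                    gene.transcripts[0].transcript_id,
                    gene.transcripts[1].transcript_id,
                )
                set_fpkm(
                    tid_a,
                    10.0 + 2.0 + u(0, 10),
                    [u(0.5, 5) for _ in range(n_later)],
                    [u(0.0, 0.2) for _ in roles.off_target_samples],
                )
                set_fpkm(
                    tid_b,
                    u(1, 20),
                    [u(1, 20) for _ in range(n_later)],
                    [10.0 + 2.0 + u(0, 20)]
                    + [u(0.5, 5) for _ in roles.off_target_samples[1:]],
                )
                planted_junctions[intron.key] = 10
                genes.append(gene)
                annotated_flags.append(True)
                truth.entries.append(
                    TruthEntry(
                        gene_id, kind, scenario, (tid_b, tid_a), tid_a,
                        (intron.key,), 10,
                        False, False,
                        "exactly 10 junction-spanning reads: rejected (strictly more than 10 required)",
                    )
                )
            elif scenario == "splicing_end_diff_boundary":
                gene, intron = _end_shift_isoform_gene(
                    rng, gene_id, chrom, strand, offset, shift=20
                )
                tid_b, tid_a = (
                    gene.transcripts[0].transcript_id,
                    gene.transcripts[1].transcript_id,
                )
                set_fpkm(
                    tid_a,
                    10.0 + 2.0 + u(0, 10),
                    [u(0.5, 5) for _ in range(n_later)],
                    [u(0.0, 0.2) for _ in roles.off_target_samples],
                )
                set_fpkm(
                    tid_b,
                    u(1, 20),
                    [u(1, 20) for _ in range(n_later)],
                    [10.0 + 2.0 + u(0, 20)]
                    + [u(0.5, 5) for _ in roles.off_target_samples[1:]],
                )
                planted_junctions[intron.key] = 15
                genes.append(gene)
                annotated_flags.append(True)
                truth.entries.append(
                    TruthEntry(
                        gene_id, kind, scenario, (tid_b, tid_a), tid_a,
                        (intron.key,), 15,
                        False, False,
                        "intron boundary shifted by exactly 20 bp: not distinguishing (strictly more than 20 required)",
                    )
                )
            elif scenario == "expression_timing_tie":
                gene = _single_isoform_gene(rng, gene_id, chrom, strand, offset)
                early = 10.0 + 2.0
                later = [early for _ in range(n_later)]
                off = [u(0.0, 0.5) for _ in roles.off_target_samples]
                set_fpkm(f"{gene_id}.t1", early, later, off)
                genes.append(gene)
                annotated_flags.append(True)
                truth.entries.append(
                    TruthEntry(
                        gene_id, kind, scenario, (f"{gene_id}.t1",), ".", (), 0,
                        False, False,
                        "earliest equals mean of later stages: rejected (timing is strict)",
                    )
                )
            elif scenario == "novel_length_boundary":
                gene = _single_isoform_gene(
                    rng, gene_id, chrom, strand, offset, exon_lens=(500, 500), n_exons=2
                )
                early = 10.0 + 2.0 + u(0, 10)
                later = [u(0.2, 4.0) for _ in range(n_later)]
                off = [u(0.0, 0.5) for _ in roles.off_target_samples]
                set_fpkm(f"{gene_id}.t1", early, later, off)
                genes.append(gene)
                annotated_flags.append(False)  # novel: absent from reference
                truth.entries.append(
                    TruthEntry(
                        gene_id, kind, scenario, (f"{gene_id}.t1",), ".", (), 0,
                        False, False,
                        "novel gene of exactly 1000 bp spliced length: rejected (strictly over 1 kb required)",
                    )
                )
            else:  # pragma: no cover - guarded by PlantSpec
                raise FixtureError(f"unknown decoy scenario {scenario!r}")
        else:  # background
            n_iso = int(rng.integers(1, 4))
            if n_iso == 1:
                gene = _single_isoform_gene(
                    rng, gene_id, chrom, strand, offset,
                    n_exons=int(rng.integers(1, 5)),
                )
            else:
                gene, _ = _skip_isoform_gene(rng, gene_id, chrom, strand, offset)
                if n_iso == 3:
                    base = gene.transcripts[0]
                    extra = TranscriptModel(
                        f"{gene_id}.t3", gene_id, chrom, strand, base.exons[:2]
                    )
                    gene.transcripts.append(extra)
            for tx in gene.transcripts:
                values = [10 ** u(-2, 2) for _ in roles.all_samples]
                # force broad off-target expression: never a candidate
                values[len(roles.target_stage_samples)] = u(1.5, 30)
                set_fpkm(
                    tx.transcript_id,
                    values[0],
                    values[1 : len(roles.target_stage_samples)],
                    values[len(roles.target_stage_samples) :],
                )
            genes.append(gene)
            annotated_flags.append(bool(rng.integers(0, 2)))

    # --- genome ------------------------------------------------------------
    bases = np.array(list("ACGT"))
    contigs = {
        name: "".join(rng.choice(bases, size=cfg.contig_length))
        for name in contig_names
    }
    genome = Genome(contigs)

    # --- junction evidence ---------------------------------------------------
    evidence = JunctionEvidence()
    all_introns: list[Intron] = []
    seen: set[tuple[str, int, int]] = set()
    for gene in genes:
        for tx in gene.transcripts:
            for a, b in zip(tx.exons, tx.exons[1:]):
                intron = Intron(tx.chrom, a.end, b.start, tx.strand)
                if intron.key not in seen:
                    seen.add(intron.key)
                    all_introns.append(intron)
    for intron in all_introns:
        n_early = planted_junctions.get(
            intron.key, int(rng.integers(25, 81))
        )
        evidence.add(roles.earliest, intron.key, n_early)
        for s in roles.later_target_samples:
            evidence.add(s, intron.key, int(rng.integers(5, 41)))

    # --- write everything ----------------------------------------------------
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(sorted(contigs.items()), out / "genome.fa")
    write_gtf(genes, out / "merged.gtf", source="assembled")

    reference_genes = []
    for gene, annotated in zip(genes, annotated_flags):
        if not annotated:
            continue
        base = gene.transcripts[0]
        ref_id = f"ref_{gene.gene_id}"
        ref_tx = TranscriptModel(
            f"{ref_id}.t1", ref_id, gene.chrom, gene.strand, base.exons,
            source_class="reference_annotated",
        )
        reference_genes.append(
            GeneModel(
                ref_id, gene.chrom, gene.strand, [ref_tx],
                annotation_class="protein_coding",
            )
        )
    write_gtf(reference_genes, out / "reference.gtf", source="reference")

    tx_df = pd.DataFrame(
        {s: {tid: v[s] for tid, v in tx_fpkm.items()} for s in roles.all_samples}
    ).loc[[t.transcript_id for g in genes for t in g.transcripts]]
    tx_table = AbundanceTable("transcript", tx_df)
    write_abundance_tsv(tx_table, out / "transcript_fpkm.tsv")

    gene_rows = {}
    for gene in genes:
        gene_rows[gene.gene_id] = {
            s: sum(tx_fpkm[t.transcript_id][s] for t in gene.transcripts)
            for s in roles.all_samples
        }
    gene_df = pd.DataFrame(gene_rows).T.loc[[g.gene_id for g in genes], list(roles.all_samples)]
    write_abundance_tsv(AbundanceTable("gene", gene_df), out / "gene_fpkm.tsv")

    for s in roles.target_stage_samples:
        write_junctions_bed(
            evidence, s, out / f"junctions_{s}.bed", anchor=_READ_ANCHOR
        )
    generate_sam_reads(
        evidence, roles.earliest, genome, out / f"reads_{roles.earliest}.sam"
    )

    truth.write_tsv(out / "truth.tsv")
    truth.write_summary(out / "truth_summary.txt")
    return truth


def generate_sam_reads(
    evidence: JunctionEvidence,
    sample_id: str,
    genome: Genome,
    path: str | Path,
    anchor: int = _READ_ANCHOR,
) -> None:
    """Emit spliced SAM reads whose CIGAR N operations encode the junctions.

    Each junction with count ``n`` in ``sample_id`` yields ``n`` identical
    reads anchored ``anchor`` bp into the flanking exons, so
    junction extraction over the output reproduces the counts exactly.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": genome.contig_length(name)}
            for name in genome.contig_names
        ],
    }
    records = sorted(
        (key, n) for (s, key), n in evidence.counts.items() if s == sample_id
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        read_no = 0
        for (chrom, start, end), n in records:
            seq = genome.fetch(chrom, start - anchor, start) + genome.fetch(
                chrom, end, end + anchor
            )
            cigar = f"{anchor}M{end - start}N{anchor}M"
            for _ in range(n):
                read_no += 1
                a = pysam.AlignedSegment(sam.header)
                a.query_name = f"read{read_no:07d}"
                a.query_sequence = seq
                a.flag = 0
                a.reference_id = sam.get_tid(chrom)
                a.reference_start = start - anchor
                a.mapping_quality = 50
                a.cigarstring = cigar
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                sam.write(a)
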