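"""Readers and writers for the standard formats the pipeline touches.

GTF (read/write), FASTA (read/write), TopHat-dialect BED12 junctions (read),
SAM spliced alignments (read, via pysam), and TSV abundance/candidate tables
(read/write, via pandas).  All genomic coordinates are converted to the
package-internal 0-based half-open convention at this boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from pyfaidx import Fasta

from .model import (
    NOVEL,
    ANNOTATION_CLASSES,
    Exon,
    GeneModel,
    Intron,
    ModelError,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

# reference-advancing CIGAR operation codes (pysam numeric encoding)
_REF_ADVANCE = {0, 2, 7, 8}  # M, D, =, X
_SKIP = 3  # N


class FormatError(ValueError):
    """Raised for malformed input files; the message names the location."""


class AbundanceError(KeyError):
    """Raised when an abundance value is missing for a (feature, sample)."""

    def __str__(self) -> str:  # KeyError repr-quotes its message otherwise
        return self.args[0] if self.args else ""


# ---------------------------------------------------------------------------
# abundance tables


@dataclass
class AbundanceTable:
    """FPKM per (feature, sample).

    Missing entries are an error, never an implicit zero: silently treating
    an absent measurement as 0 FPKM would manufacture false
    tissue-specificity calls.
    """

    feature_level: str  # "gene" | "transcript"
    data: pd.DataFrame  # index = feature ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.feature_level not in ("gene", "transcript"):
            raise ValueError(f"invalid feature_level {self.feature_level!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise FormatError(f"duplicate feature rows: {', '.join(map(str, dupes))}")
        if self.data.isna().any().any():
            raise FormatError("abundance table contains missing values")
        if (self.data < 0).any().any():
            raise FormatError("abundance table contains negative FPKM values")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.data.index

    def value(self, feature_id: str, sample_id: str) -> float:
        try:
            col = self.data[sample_id]
        except KeyError:
            raise AbundanceError(
                f"no sample {sample_id!r} in {self.feature_level}-level abundance table"
            ) from None
        try:
            return float(col.loc[feature_id])
        except KeyError:
            raise AbundanceError(
                f"no abundance for {self.feature_level} {feature_id!r}"
                f" in sample {sample_id!r}"
            ) from None


def read_abundance_tsv(
    path: str | Path, feature_level: str, dialect: str = "simple"
) -> AbundanceTable:
    """Read an FPKM table.

    ``dialect="simple"``: first column is the feature id, remaining column
    headers are sample ids.  ``dialect="tracking"``: Cuffdiff
    fpkm-tracking layout, where sample columns are named ``<sample>_FPKM``
    and the feature id column is ``tracking_id``.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: abundance table needs >= 2 columns")
    if dialect == "simple":
        df = df.set_index(df.columns[0])
    elif dialect == "tracking":
        if "tracking_id" not in df.columns:
            raise FormatError(f"{path}: tracking dialect requires a tracking_id column")
        fpkm_cols = [c for c in df.columns if c.endswith("_FPKM")]
        if not fpkm_cols:
            raise FormatError(f"{path}: tracking dialect has no *_FPKM columns")
        df = df.set_index("tracking_id")[fpkm_cols]
        df.columns = [c[: -len("_FPKM")] for c in fpkm_cols]
    else:
        raise ValueError(f"unknown abundance dialect {dialect!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric FPKM value ({exc})") from None
    try:
        return AbundanceTable(feature_level, df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_abundance_tsv(table: AbundanceTable, path: str | Path) -> None:
    label = "gene_id" if table.feature_level == "gene" else "transcript_id"
    table.data.to_csv(path, sep="\t", index_label=label, float_format="%.6f")


# ---------------------------------------------------------------------------
# sample roles


@dataclass(frozen=True)
class SampleRoles:
    """Which samples are staged target tissue (earliest first) and which are off-target.

    In the source study design the target samples are staged testis samples
    ordered through spermatogenesis and the off-target samples are
    gonadectomised male, ovary and whole female.
    """

    target_stage_samples: tuple[str, ...]
    off_target_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "target_stage_samples", tuple(self.target_stage_samples)
        )
        object.__setattr__(self, "off_target_samples", tuple(self.off_target_samples))
        if not self.target_stage_samples:
            raise ValueError("at least one target-stage sample is required")
        if not self.off_target_samples:
            raise ValueError("at least one off-target sample is required")
        overlap = set(self.target_stage_samples) & set(self.off_target_samples)
        if overlap:
            raise ValueError(f"samples in both roles: {sorted(overlap)}")
        if len(set(self.target_stage_samples)) != len(self.target_stage_samples):
            raise ValueError("duplicate target-stage sample")
        if len(set(self.off_target_samples)) != len(self.off_target_samples):
            raise ValueError("duplicate off-target sample")

    @property
    def earliest(self) -> str:
        return self.target_stage_samples[0]

    @property
    def later_target_samples(self) -> tuple[str, ...]:
        return self.target_stage_samples[1:]

    @property
    def all_samples(self) -> tuple[str, ...]:
        return self.target_stage_samples + self.off_target_samples


# ---------------------------------------------------------------------------
# junction evidence


@dataclass
class JunctionEvidence:
    """Spanning-read counts per (sample, intron).

    Keys are ``(sample_id, (chrom, start, end))`` with 0-based half-open
    intron coordinates.  A junction never observed in a sample has count 0.
    """

    counts: dict[tuple[str, tuple[str, int, int]], int] = field(default_factory=dict)

    def add(self, sample_id: str, key: tuple[str, int, int], n: int = 1) -> None:
        if n < 0:
            raise ValueError("junction counts must be non-negative")
        k = (sample_id, key)
        self.counts[k] = self.counts.get(k, 0) + n

    def count(self, sample_id: str, intron: Intron | tuple[str, int, int]) -> int:
        key = intron.key if isinstance(intron, Intron) else tuple(intron)
        return self.counts.get((sample_id, key), 0)

    def update(self, other: "JunctionEvidence") -> None:
        for (sample, key), n in other.counts.items():
            self.add(sample, key, n)

    @property
    def samples(self) -> set[str]:
        return {s for s, _ in self.counts}


def read_junctions_bed(
    path: str | Path, sample_id: str, rejected: list[str] | None = None
) -> JunctionEvidence:
    """Read a TopHat-style junctions BED12 file.

    Each record describes one junction as two anchor blocks flanking the
    intron; the intron is ``(chromStart + blockSize1,
    chromStart + blockStart2)`` and the score column carries the
    spanning-read count.  Records whose blockCount differs from 2 are
    rejected and logged.  Duplicate junction keys accumulate.
    """
    ev = JunctionEvidence()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED fields")
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                score = int(float(fields[4]))
                block_count = int(fields[9])
                block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if block_count != 2 or len(block_sizes) != 2 or len(block_starts) != 2:
                msg = f"{path}:{lineno}: blockCount {block_count} != 2, record rejected"
                logger.warning(msg)
                if rejected is not None:
                    rejected.append(msg)
                continue
            intron_start = chrom_start + block_starts[0] + block_sizes[0]
            intron_end = chrom_start + block_starts[1]
            if intron_end <= intron_start:
                raise FormatError(f"{path}:{lineno}: blocks imply an empty intron")
            ev.add(sample_id, (chrom, intron_start, intron_end), score)
    return ev


def extract_junctions_from_sam(path: str | Path, sample_id: str) -> JunctionEvidence:
    """Count junction-spanning reads from spliced alignments.

    Each N operation in a CIGAR string is one crossed intron: its start is
    the reference position reached after the preceding reference-advancing
    operations (M/D/=/X) and its length is the N length.  A read spanning
    several junctions contributes one count to each.  Unmapped, secondary
    and supplementary records are skipped; duplicates are counted.
    """
    ev = JunctionEvidence()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            cig = read.cigartuples
            if cig is None:
                continue
            pos = read.reference_start
            chrom = read.reference_name
            for op, length in cig:
                if op == _SKIP:
                    if length <= 0:
                        raise FormatError(
                            f"{path}: read {read.query_name}: non-positive N length"
                        )
                    ev.add(sample_id, (chrom, pos, pos + length), 1)
                    pos += length
                elif op in _REF_ADVANCE:
                    pos += length
    return ev


def write_junctions_bed(
    ev: JunctionEvidence,
    sample_id: str,
    path: str | Path,
    anchor: int = 20,
) -> None:
    """Write one sample's junction counts in the TopHat BED12 dialect."""
    records = sorted(
        (key, n) for (s, key), n in ev.counts.items() if s == sample_id
    )
    with open(path, "w") as fh:
        for i, ((chrom, start, end), n) in enumerate(records, start=1):
            chrom_start = start - anchor
            chrom_end = end + anchor
            if chrom_start < 0:
                raise ValueError(f"junction {chrom}:{start}-{end}: anchor before contig start")
            fh.write(
                "\t".join(
                    [
                        chrom,
                        str(chrom_start),
                        str(chrom_end),
                        f"JUNC{i:05d}",
                        str(n),
                        "+",
                        str(chrom_start),
                        str(chrom_end),
                        "255,0,0",
                        "2",
                        f"{anchor},{anchor}",
                        f"0,{end - chrom_start}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GTF


def read_gtf(
    path: str | Path,
    default_annotation_class: str = NOVEL,
    rejected: list[str] | None = None,
) -> list[GeneModel]:
    """Read exon features from a GTF file into gene models.

    1-based closed GTF coordinates become 0-based half-open.  Exons are
    grouped by ``transcript_id`` then ``gene_id``; out-of-order exons are
    repaired by sorting, while transcripts spanning multiple
    chromosomes/strands or with overlapping exons are rejected and logged.
    The optional ``annotation_class`` / ``gene_biotype`` and ``te_flag``
    attributes, when present, set the corresponding gene fields.
    """
    if default_annotation_class not in ANNOTATION_CLASSES:
        raise ValueError(f"invalid annotation class {default_annotation_class!r}")
    # transcript_id -> (gene_id, [(chrom, strand, start, end)])
    tx_exons: dict[str, list[tuple[str, str, int, int]]] = {}
    tx_gene: dict[str, str] = {}
    gene_attrs: dict[str, dict[str, str]] = {}
    tx_order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start1 < 1 or end1 < start1:
                raise FormatError(f"{path}:{lineno}: invalid coordinates {start1}-{end1}")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            attrs = dict(_GTF_ATTR_RE.findall(attrs_s))
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise FormatError(
                    f"{path}:{lineno}: exon lacks gene_id/transcript_id attributes"
                )
            tid, gid = attrs["transcript_id"], attrs["gene_id"]
            if tid not in tx_exons:
                tx_exons[tid] = []
                tx_gene[tid] = gid
                tx_order.append(tid)
            tx_exons[tid].append((chrom, strand, start1 - 1, end1))
            ga = gene_attrs.setdefault(gid, {})
            for key in ("annotation_class", "gene_biotype", "te_flag"):
                if key in attrs:
                    ga.setdefault(key, attrs[key])

    def _reject(msg: str) -> None:
        logger.warning(msg)
        if rejected is not None:
            rejected.append(msg)

    genes: dict[str, list[TranscriptModel]] = {}
    gene_order: list[str] = []
    for tid in tx_order:
        rows = sorted(tx_exons[tid], key=lambda r: (r[0], r[2]))
        chroms = {r[0] for r in rows}
        strands = {r[1] for r in rows}
        if len(chroms) > 1 or len(strands) > 1:
            _reject(f"{path}: transcript {tid} spans multiple chromosomes/strands, rejected")
            continue
        chrom, strand = rows[0][0], rows[0][1]
        try:
            exons = tuple(Exon(chrom, s, e, strand) for _, _, s, e in rows)
            tx = TranscriptModel(tid, tx_gene[tid], chrom, strand, exons)
        except ModelError as exc:
            _reject(f"{path}: transcript {tid} rejected: {exc}")
            continue
        gid = tx_gene[tid]
        if gid not in genes:
            genes[gid] = []
            gene_order.append(gid)
        genes[gid].append(tx)

    out: list[GeneModel] = []
    for gid in gene_order:
        txs = genes[gid]
        chroms = {t.chrom for t in txs}
        strands = {t.strand for t in txs}
        if len(chroms) > 1 or len(strands) > 1:
            _reject(f"{path}: gene {gid} mixes chromosomes/strands, rejected")
            continue
        attrs = gene_attrs.get(gid, {})
        klass = attrs.get("annotation_class") or attrs.get("gene_biotype")
        if klass is not None and klass not in ANNOTATION_CLASSES:
            klass = "other_annotated"
        te = attrs.get("te_flag", "").lower() in ("1", "true", "yes")
        out.append(
            GeneModel(
                gid,
                txs[0].chrom,
                txs[0].strand,
                txs,
                annotation_class=klass or default_annotation_class,
                te_flag=te,
            )
        )
    return out


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "tsplice") -> None:
    """Write gene models as GTF exon features (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for gene in genes:
            extra = f' annotation_class "{gene.annotation_class}";'
            if gene.te_flag:
                extra += ' te_flag "true";'
            for tx in gene.transcripts:
                for exon in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                        + extra
                    )
                    fh.write(
                        "\t".join(
                            [
                                exon.chrom,
                                source,
                                "exon",
                                str(exon.start + 1),
                                str(exon.end),
                                ".",
                                exon.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# FASTA


class Genome:
    """Random-access genome sequence, backed by a dict or an indexed FASTA."""

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = dict(contigs)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=False, rebuild=True)
        genome = cls.__new__(cls)
        genome._contigs = None  # type: ignore[assignment]
        genome._fasta = fa
        genome._lengths = {name: len(fa[name]) for name in fa.keys()}
        return genome

    @property
    def contig_names(self) -> list[str]:
        if self._contigs is not None:
            return list(self._contigs)
        return list(self._lengths)

    def contig_length(self, chrom: str) -> int:
        if self._contigs is not None:
            try:
                return len(self._contigs[chrom])
            except KeyError:
                raise FormatError(f"unknown sequence id {chrom!r}") from None
        try:
            return self._lengths[chrom]
        except KeyError:
            raise FormatError(f"unknown sequence id {chrom!r}") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Fetch [start, end) of a contig; out-of-bounds requests are errors."""
        length = self.contig_length(chrom)
        if start < 0 or end > length or end < start:
            raise FormatError(
                f"fetch {chrom}:{start}-{end} outside contig bounds [0, {length})"
            )
        if self._contigs is not None:
            return self._contigs[chrom][start:end]
        return str(self._fasta[chrom][start:end])


def read_fasta(path: str | Path) -> Genome:
    """Open a FASTA file as a random-access :class:`Genome`."""
    return Genome.from_fasta(path)


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, width: int = 60
) -> None:
    """Write (id, sequence) records as FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta_records(path: str | Path) -> list[tuple[str, str]]:
    """Read all FASTA records as (id, sequence) pairs (ids up to first space)."""
    records: list[tuple[str, str]] = []
    rec_id: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if rec_id is not None:
                    records.append((rec_id, "".join(chunks)))
                rec_id = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            elif line:
                chunks.append(line)
    if rec_id is not None:
        records.append((rec_id, "".join(chunks)))
    return records


# ---------------------------------------------------------------------------
# candidate tables


def write_candidates_tsv(
    rows: Sequence[Mapping[str, object]], columns: Sequence[str], path: str | Path
) -> None:
    """Write candidate rows as TSV with a fixed, documented column order."""
    df = pd.DataFrame(list(rows), columns=list(columns))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
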