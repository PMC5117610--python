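"""Screen for target-tissue-specifically expressed genes with early-stage timing.

Four deterministic filters, evaluated per gene on gene-level FPKM values:

1. FPKM in the earliest target-stage sample at or above ``min_target_fpkm``
   (inclusive; default 10 FPKM, the low/moderate expression boundary).
2. FPKM strictly below ``max_off_target_fpkm`` (default 1 FPKM, allowing
   measurement noise) in every off-target sample.
3. The gene either coincides with an annotated protein-coding locus or is a
   novel prediction longer than ``min_novel_length`` (default 1 kb) — a
   guard against spuriously quantified short non-coding RNAs.
4. Timing: expression in the earliest target sample strictly exceeds the
   mean over the later target-stage samples, selecting genes transcribed
   early in the developmental progression (vacuously true when there are no
   later samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import AbundanceTable, SampleRoles
from .model import GeneModel, gene_passes_size_annotation_filter

FILTER_NAMES = ("target_min", "off_target_max", "size_annotation", "timing")

# bitmask positions for the candidate-table "filters" column
FILTER_BITS = {name: 1 << i for i, name in enumerate(FILTER_NAMES)}


@dataclass(frozen=True)
class ExpressionThresholds:
    min_target_fpkm: float = 10.0
    max_off_target_fpkm: float = 1.0
    min_novel_length: int = 1000
    # "spliced" = longest isoform's spliced length; "span" = genomic span
    novel_length_mode: str = "spliced"
    # inclusive >= for the target minimum (the documented convention);
    # set False for a strict > boundary
    target_min_inclusive: bool = True

    def __post_init__(self) -> None:
        if min(self.min_target_fpkm, self.max_off_target_fpkm, self.min_novel_length) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class ExpressionCandidate:
    gene_id: str
    annotation_class: str
    te_flag: bool
    earliest_target_fpkm: float
    later_target_mean_fpkm: float  # NaN when there are no later samples
    off_target_max_fpkm: float
    passed_timing: bool


@dataclass
class ExpressionScreenResult:
    """Candidates plus the per-filter audit trail for every gene screened."""

    candidates: list[ExpressionCandidate]
    rows: list[dict] = field(default_factory=list)
    filter_counts: dict[str, int] = field(default_factory=dict)


def _passes_target_min(fpkm: float, th: ExpressionThresholds) -> bool:
    if th.target_min_inclusive:
        return fpkm >= th.min_target_fpkm
    return fpkm > th.min_target_fpkm


def screen_expression(
    genes: Iterable[GeneModel],
    gene_abundance: AbundanceTable,
    roles: SampleRoles,
    th: ExpressionThresholds = ExpressionThresholds(),
) -> list[ExpressionCandidate]:
    """Apply the four expression filters and return the surviving genes."""
    return screen_expression_detailed(genes, gene_abundance, roles, th).candidates


def screen_expression_detailed(
    genes: Iterable[GeneModel],
    gene_abundance: AbundanceTable,
    roles: SampleRoles,
    th: ExpressionThresholds = ExpressionThresholds(),
) -> ExpressionScreenResult:
    """Like :func:`screen_expression` but keeps per-gene filter flags and counts.

    The per-filter survivor counts apply the filters sequentially in the
    order of ``FILTER_NAMES``; the ``filters`` bitmask in each row records
    every filter's independent outcome.
    """
    if gene_abundance.feature_level != "gene":
        raise ValueError("screen_expression requires a gene-level abundance table")
    candidates: list[ExpressionCandidate] = []
    rows: list[dict] = []
    counts = {"input": 0, **{name: 0 for name in FILTER_NAMES}}
    for gene in genes:
        counts["input"] += 1
        early = gene_abundance.value(gene.gene_id, roles.earliest)
        later = [
            gene_abundance.value(gene.gene_id, s) for s in roles.later_target_samples
        ]
        off = {s: gene_abundance.value(gene.gene_id, s) for s in roles.off_target_samples}
        later_mean = sum(later) / len(later) if later else math.nan
        off_max = max(off.values())

        flags = {
            "target_min": _passes_target_min(early, th),
            "off_target_max": all(v < th.max_off_target_fpkm for v in off.values()),
            "size_annotation": gene_passes_size_annotation_filter(
                gene, th.min_novel_length, th.novel_length_mode
            ),
            "timing": (not later) or early > later_mean,
        }
        surviving = True
        for name in FILTER_NAMES:
            surviving = surviving and flags[name]
            if surviving:
                counts[name] += 1
        row = {
            "gene_id": gene.gene_id,
            "annotation_class": gene.annotation_class,
            "earliest_target_fpkm": early,
            "later_target_mean_fpkm": later_mean,
            **{f"fpkm_{s}": v for s, v in off.items()},
            "filters": sum(FILTER_BITS[n] for n in FILTER_NAMES if flags[n]),
            "candidate": all(flags.values()),
        }
        rows.append(row)
        if all(flags.values()):
            candidates.append(
                ExpressionCandidate(
                    gene_id=gene.gene_id,
                    annotation_class=gene.annotation_class,
                    te_flag=gene.te_flag,
                    earliest_target_fpkm=early,
                    later_target_mean_fpkm=later_mean,
                    off_target_max_fpkm=off_max,
                    passed_timing=flags["timing"],
                )
            )
    return ExpressionScreenResult(candidates, rows, counts)


def rank_expression_candidates(
    candidates: Sequence[ExpressionCandidate],
    n: int,
    exclusion_ids: Iterable[str] = (),
) -> list[ExpressionCandidate]:
    """Top-``n`` candidates by earliest-target expression, after exclusions.

    Transposable-element-associated genes (``te_flag``) and any gene in
    ``exclusion_ids`` are removed before ranking.  Ties in FPKM break by
    gene id for determinism.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    excluded = set(exclusion_ids)
    kept = [
        c for c in candidates if c.gene_id not in excluded and not c.te_flag
    ]
    kept.sort(key=lambda c: (-c.earliest_target_fpkm, c.gene_id))
    return kept[:n]


EXPRESSION_TSV_COLUMNS_BASE = (
    "gene_id",
    "annotation_class",
    "earliest_target_fpkm",
    "later_target_mean_fpkm",
)


def expression_table_columns(roles: SampleRoles) -> list[str]:
    """Fixed column order for the expression candidate TSV."""
    return (
        list(EXPRESSION_TSV_COLUMNS_BASE)
        + [f"fpkm_{s}" for s in roles.off_target_samples]
        + ["filters", "candidate"]
    )
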