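# Methods

## Problem and model

`tsplice` identifies two classes of candidate loci from bulk RNA-seq of a
staged target tissue (in the motivating application: testis samples ordered
early → late through spermatogenesis) against off-target reference samples
(gonadectomised male, ovary, whole female):

- **tissue-specifically expressed genes with early timing** — usable as
  sources of promoters/UTRs for pre-meiotic protein expression, and
- **tissue-specifically spliced isoforms** — usable to restrict expression
  via alternative splicing, detectable by RT-PCR with primers spanning the
  isoform's distinguishing exon-exon junction.

Both screens are deterministic threshold filters over assembled transcript
models (merged GTF), per-sample FPKM estimates, and junction-spanning read
counts. There is no statistical model to fit: upstream quantification has
already absorbed the read-level uncertainty, and the screen's purpose is a
reproducible, auditable shortlist. Consequently there are no p-values,
no normalisation, and no multiple-testing machinery by design.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_target_fpkm` | 10 FPKM | minimum gene expression in the earliest target sample; 10 FPKM is the conventional boundary between low and moderate expression in insect RNA-seq. **Inclusive** (≥). |
| `max_off_target_fpkm` | 1 FPKM | per-off-target-sample ceiling for gene-level expression; non-zero to tolerate noise. **Strict** (<). |
| `min_novel_length` | 1000 bp | novel genes must be *over* 1 kb (strict >), measured by the longest isoform's spliced length (`novel_length_mode="spliced"`; `"span"` uses genomic extent). Filters short non-coding RNAs whose quantification under polyA selection is unreliable. |
| timing rule | — | earliest-stage FPKM strictly greater than the **mean** over all later target stages; vacuous when only one target sample exists. |
| `min_target_isoform_fpkm` | 10 FPKM | isoform-level analogue of the target minimum (inclusive ≥). |
| `max_off_target_isoform_fpkm` | 0.4 FPKM | isoform-level off-target ceiling (strict <); tighter than the gene-level 1 FPKM because isoform-level noise calibrates lower. |
| `min_alt_isoform_fpkm` | 10 FPKM | another isoform of the gene must reach this in ≥ 1 off-target sample ("10 FPKM or above", inclusive ≥) — otherwise the gene is tissue-specifically *expressed*, not *spliced*. |
| `min_junction_reads` | 10 reads | **strictly more than** 10 reads must span the distinguishing junction. |
| `min_intron_end_diff` | 20 bp | a distinguishing intron must differ from every intron of the gene's other isoforms by **strictly more than** 20 bp at ≥ 1 end; guards against ragged assembly ends mimicking alternative splicing. Offsets are absolute genomic-coordinate differences, strand-independent. |
| `flank` | 500 bp | junction flank length emitted for primer design; chosen to exceed typical RT-PCR amplicon sizes, configurable. |

Boundary conventions, uniformly: **target minimums are inclusive (≥),
off-target maximums are strict (<), and the junction-read, end-offset,
timing and novel-length rules are strict (>)**. The generator plants decoys
exactly on each boundary so that regression tests pin these conventions.

## Design choices in genuinely open territory

- **Junction-coverage sample.** The source procedure does not name the
  sample in which the >10-read rule is evaluated. Default: the earliest
  target sample (the tissue-specific form is, by construction, only
  expressed there); `junction_sample_mode="max_target"` takes the maximum
  over all target stages instead.
- **"Within an annotated gene"** is interpreted as full containment of the
  intron interval in an annotated (non-novel) gene's genomic span, ignoring
  strand and exon structure. The filter exists to reject intergenic
  intervals mis-merged into transcripts; span containment is the weakest
  reading that achieves this. Partial overlap fails.
- **Intron comparison set** for the novelty predicate: all introns of all
  *other* isoforms of the same gene, regardless of their expression. The
  candidate isoform's own introns are excluded.
- **Novel-gene length** uses spliced transcript length by default (the
  filter targets short RNAs, a transcript property), with genomic span as an
  alternative mode.
- **Shared-primer-site detection** (for ranking): a candidate has a shared
  site when both exonic flanks of a distinguishing intron are contained in
  the exonic intervals of a single other isoform — containment rather than
  exact exon-coordinate equality, so that both exon-skipping (flanks are
  shared exons) and intron-retention (flanks lie inside one longer exon)
  layouts are detected. Candidates with a shared site are all retained and
  listed first in the ranking; the rest are ordered by ascending minimum
  distinguishing-intron length.
- **Isoform alignments** are genome-anchored projections (a column per
  exonic genomic position, gaps where an isoform lacks the position), not
  heuristic multiple alignments: all isoforms share genome coordinates, so
  the projection is exact, deterministic, and de-gaps to each isoform's
  spliced sequence. Minus-strand genes are reverse-complemented row-wise.
- **Junction counting from SAM**: each CIGAR `N` operation contributes one
  count; multi-junction reads count once per junction crossed; unmapped,
  secondary and supplementary records are skipped; duplicates are counted
  (matching upstream workflows that did not deduplicate).
- **Missing FPKM entries are errors**, never implicit zeros — an absent
  measurement read as 0 would manufacture false tissue-specificity.
- Flank extraction defaults to pure genomic flanks (introns of other
  isoforms included); `exonic_only` truncates each flank at the adjacent
  exon's far edge for primers strictly within the mature transcript.
  Junction positions are 0-based in machine-readable output and 1-based in
  the human-readable index column, both labelled.

## The synthetic data generator

`tsplice.fixtures.generate_fixture` emits a complete, parseable input set
(genome FASTA, merged and reference GTF, gene/transcript FPKM TSVs, per-
sample TopHat-dialect junction BEDs, spliced SAM reads) from a single seeded
RNG; regeneration with the same seed is byte-identical. The default
configuration (30 genes, 7 samples mirroring a staged-testis design) plants:

- 3 early-biased tissue-specific genes and 2 late-biased ones, at ≥ 2 FPKM
  margins from the 10-FPKM threshold (off-target values at most half the
  1-FPKM ceiling — a 2-FPKM margin below a 1-FPKM threshold is impossible,
  so off-target margins are proportional);
- 3 tissue-specifically spliced genes (exon-skipping isoform pairs whose
  skip intron differs from sibling introns by >100 bp, 15 junction reads);
- 4 boundary decoys, one exactly on each of: the 10-FPKM target minimum
  (accepted — pins inclusivity), the 1-FPKM off-target ceiling (rejected),
  the 10-read junction rule (rejected), and the 20-bp end-offset rule
  (rejected). Two further scenarios (timing tie, exactly-1000-bp novel gene)
  are available but not in the default set.

Background genes draw log-uniform FPKM in [0.01, 100] to exercise all filter
branches, but every background isoform is forced to ≥ 1.5 FPKM in one
off-target sample, so background genes fail both screens' off-target rules
*by construction*. The truth manifest is therefore exact: a green
planted-recovery test establishes sensitivity 1.0 and zero false positives
on this stated world. What it does **not** establish: robustness to
quantification error in real FPKM estimates, to mis-assembled transcript
models, or to junction counts from multi-mapping reads — the generator
plants summary values directly and deliberately models none of these.

## Numerical and degenerate-input behaviour

- Coordinates are 0-based half-open internally; GTF's 1-based closed
  convention is converted only at the I/O boundary.
- Single-exon transcripts yield no introns (and so can never be splicing
  candidates); single-isoform genes fail the alternate-isoform rule.
- Ranking ties break lexicographically (gene id / transcript id) for
  determinism; all outputs are byte-stable across reruns on identical
  inputs.
- FPKM values are written with six decimal places; threshold comparisons
  use the parsed values exactly (boundary decoys round-trip losslessly).
- Flanks are truncated at contig bounds with per-side flags;
  reverse complement passes IUPAC ambiguity codes through (N→N).

## Known limitations

- The screens trust upstream quantification; no isoform re-quantification,
  PSI statistics, or event classification (A3SS/A5SS/SE/RI) is attempted.
- Gene classification against the reference annotation uses span overlap on
  either strand; antisense overlaps are treated as annotated.
- BED junction input follows the TopHat two-block dialect only; BAM/CRAM
  and GFF3 are out of scope (SAM and GTF are supported).
- The published headline counts from the original studies (57/388 and
  68/667 early-expressed candidates; 27 and 33 spliced candidates) are not
  reproducible without the multi-gigabyte raw datasets and legacy upstream
  tools; validation is therefore property-based on synthetic data with
  planted truth.
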