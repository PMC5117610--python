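# tsplice

Screens an assembled transcriptome for genes **expressed** specifically in a
target tissue with early-developmental-stage timing, and for transcript
isoforms **spliced** specifically in that tissue, and emits the sequences
needed to design junction-spanning PCR primers for validating the candidates.

The motivating use case is insect male-germline genetics: synthetic genetic
control systems (e.g. GAL4/UAS or tTA/tetO constructs) need regulatory
regions that drive testis-specific, pre-meiotic expression, because
transcription shuts down at the meiotic divisions. Given staged testis
RNA-seq samples (ordered early → late through spermatogenesis) and off-target
samples (gonadectomised male, ovary, whole female), both screens are
deterministic threshold filters over per-sample FPKM values from an upstream
TopHat/Cufflinks/Cuffdiff-style workflow.

## The screens

**Expression screen** — a gene is a candidate iff

1. FPKM ≥ 10 in the earliest target-stage sample (inclusive),
2. FPKM < 1 in *every* off-target sample (strict; tolerates noise),
3. it coincides with an annotated protein-coding locus, or is a novel
   prediction whose longest isoform exceeds 1 kb (guards against spuriously
   quantified short non-coding RNAs under polyA selection), and
4. its earliest-stage FPKM strictly exceeds the **mean** FPKM of the later
   target stages (early timing).

**Splicing screen** — an isoform is a candidate iff

1. isoform FPKM ≥ 10 in the earliest target sample,
2. isoform FPKM < 0.4 in every off-target sample,
3. some *other* isoform of the gene reaches ≥ 10 FPKM in at least one
   off-target sample (distinguishing tissue-specific splicing from
   tissue-specific expression), and
4. the isoform has ≥ 1 *distinguishing intron*: boundaries differing by
   **more than 20 bp at one end** from every intron of the gene's other
   isoforms, **more than 10** junction-spanning reads in the target tissue,
   and full containment within an annotated gene's span (rejects intergenic
   merge artifacts).

For each candidate intron the tool writes flank sequences with a numbered
exon-exon junction position, plus a deterministic genome-anchored alignment
of all isoforms of the gene — the two artifacts a primer designer needs.

## Worked example

No external data is needed: the package ships a seeded generator of complete
toy inputs (genome FASTA, merged + reference GTF, FPKM TSVs, junction
BED/SAM) with planted candidates and boundary decoys.

```bash
tsplice simulate --seed 42 --out-dir fixture

tsplice expression-candidates \
  --gtf fixture/merged.gtf --reference-gtf fixture/reference.gtf \
  --gene-fpkm fixture/gene_fpkm.tsv \
  --target-samples early_spermatocytes,late_spermatocytes,round_spermatids,elongated_spermatids \
  --off-target-samples gonadectomised_male,ovary,female \
  --out-dir expr
```

The log reports the filter cascade (30 genes in; 26 pass the 10-FPKM
minimum; 6 are off-target-silent; 4 survive timing):

```
tsplice: expression screen: input -> 30 genes
tsplice: expression screen: target_min -> 26 genes
tsplice: expression screen: off_target_max -> 6 genes
tsplice: expression screen: size_annotation -> 6 genes
tsplice: expression screen: timing -> 4 genes
```

`expr/expression_candidates.tsv` then holds, e.g.:

```
gene_id  earliest_target_fpkm  later_target_mean_fpkm  fpkm_ovary  ...
G0001    32.921041             9.513696                0.064057
G0009    10.000000             1.810231                0.101182
```

`G0009` is a planted decoy sitting exactly on the 10-FPKM boundary — it is
accepted because the target minimum is inclusive. The splicing screen
(`tsplice splicing-candidates ...`, additionally taking `--transcript-fpkm`,
`--genome` and `--junctions-bed SAMPLE=PATH`) recovers the three planted
tissue-specific splice forms with their distinguishing introns:

```
gene_id  transcript_id  intron_start  intron_end  junction_reads  target_isoform_fpkm
G0006    G0006.t2       18467         18990       15              33.154961
G0007    G0007.t2       22021         22530       15              37.602092
G0008    G0008.t2       25655         26451       15              16.569363
```

and writes `flanks.fa` (one record per distinguishing intron, with the
junction position encoded in the id), `flanks_index.tsv`, per-gene aligned
FASTA under `alignments/`, and a ranked shortlist `splicing_top.tsv`
(candidates with a primer site shared across splice forms first, then
ascending intron size).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic dataset from the given seed, runs both screens and
the sequence-output stage end to end, and verifies that the screens
reproduce the planted ground truth exactly (expression candidates, splicing
candidates and their distinguishing introns) and that junction counting from
SAM and BED evidence agrees; it exits non-zero on any mismatch.

See `docs/methods.md` for the model, parameter and design details.
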