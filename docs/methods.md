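# Methods

This note records the statistical model behind each analysis, the default
parameter choices and why they were made, what the synthetic-data generator
does and does not emulate, and the numerical conventions used throughout.
All quantitative statements here are computed by the package (see
`tests/test_acceptance.py` and `scripts/acceptance.py`); none are external
empirical claims.

## 1. Annotation model

A transcript is one refFlat record: accession, gene symbol, chromosome,
strand, transcript bounds, and parallel exon start/end lists, all 0-based
half-open. Two transcripts are *mutually antisense-overlapped* when they lie
on the same chromosome, on opposite strands, and share at least one exonic
base. Span-only (intronic) overlap is deliberately not counted: the read
allocation ambiguity the pipeline cares about arises only where exons share
bases. The per-side *overlap value* of a pair is

```
O_side = 100 × shared_exonic_bases / exonic_length_side
```

and is asymmetric by construction. For binning, a transcript overlapped by
several partners is characterised by its maximum overlap value.
`filter_single_locus` drops accessions appearing more than once in the
annotation (multi-locus alignments of the same accession), because a
transcript mapping to two loci makes both its counting and its overlap value
ill-defined.

## 2. Quantification

Reads are counted per transcript with *equal-split allocation*: the k
transcripts to which a read aligns (after strand filtering and a mismatch
cap) each receive weight 1/k. Expression is reported as RPKM:

```
RPKM = count / (exonic_length / 1000) / (library_mapped_reads / 10^6)
```

Strand modes: `sense_only` (the SS convention), `antisense_only`
(diagnostics), `both` (the NSS convention). The default mismatch cap is 3
per alignment, a typical aligner-side setting for ~100-base reads; mismatch
counts are taken from the SAM `NM` tag with an `MD`-tag fallback.

Analytically, for an antisense pair with true abundances a ≥ b, equal
lengths, uniform read starts, and overlap fraction o, strand-blind counting
estimates the ratio as roughly

```
(a(1−o) + o(a+b)/2) / (b(1−o) + o(a+b)/2),
```

which lies strictly between 1 and a/b for 0 < o < 1 and collapses to exactly
1 at o = 1. The acceptance test measures this at o = 0.7, a/b = 4, 10^5
reads: the NSS estimate centres near 1.5 while sense-only SS counting
recovers 4 within sampling error, over 100 independent seeds.

## 3. Overlap-stratified correlation and the mimic control

Transcripts are partitioned by maximum overlap value into an O = 0 set plus
(lower, upper] percentage bins (default decile edges 0–100). Within each set
the Pearson correlation of log2 expression between the SS and NSS libraries
is computed after excluding transcripts whose read count is ≤ `min_count` in
either library (default 10^-4, i.e. "any nonzero weighted count passes";
the threshold exists to drop log2 of zero, not to filter real signal).

Declining correlation with overlap could in principle be an artefact of bin
size. The *mimic* control repeats each bin with size-matched random draws
(without replacement) from the O = 0 pool, `reps` times (default 100), and
reports mean and standard deviation of r per size. The standard deviation
across resampling replicates is the resampling standard error of the control
curve; a flat mimic curve (spread below twice that SE) while the real curve
declines isolates overlap — not set size — as the cause.

## 4. qPCR concordance bootstrap

Fold changes from cycle thresholds use the ΔCt model with amplification
efficiency fixed at 2:

```
FC = 2^(Ct_control − Ct_target)
```

computed per (target, control, replicate) — 9 × 3 × 3 = 81 values for the
packaged table — and from RPKM as target/control per protocol (27 values
each). The bootstrap resamples target genes with replacement (default 100
replicates, seeded), expands each draw over its (control, replicate)
combinations, and computes Pearson r of log2 Ct fold change against log2 SS
and log2 NSS RPKM fold change. Summary outputs: per-replicate r pairs, the
fraction of replicates with r_ss > r_nss, and a paired two-sided t-test
p-value across replicates.

The resampling unit is the gene because the 27 (target, control) fold-change
pairs reuse each gene three times and are not independent. On the packaged
table the gene-unit bootstrap prefers SS in ≈96% of replicates in the long
run, so individual 100-replicate runs occasionally dip just below 95%.
`unit="fold_change"` (resampling the 27 pairs directly) is available as a
lower-variance alternative and prefers SS in ≥99% of replicates, at the cost
of treating dependent values as exchangeable.

## 5. Strand-specificity QC

* **Quality profiles**: per-position Phred score histograms from FASTQ
  (offset 33), reported as count, mean, and nearest-rank quartiles.
* **Gene-body coverage**: each transcript's length is normalised to 100
  bins (`bin = 100 × pos // length`); aligned bases are accumulated and
  divided by the total aligned bases, so the profile sums to 1 and is
  comparable across libraries. End bins carry an edge effect of one read
  length and are not length-invariant; interior bins are.
* **Mappable rates**: fractions of all sequenced reads mapped under sense,
  antisense, and either orientation; the sense:antisense ratio is ≈1 for an
  NSS library and large for an SS one; `antisense_fraction` is the share of
  mapped reads on the antisense strand.
* **Strand ratios**: per-transcript log2(sense/antisense) weighted counts,
  restricted to nonoverlapped transcripts with at least `min_count` (default
  10) on both strands — small denominators otherwise produce dramatic
  ratios. Transcripts with antisense excess are listed explicitly.

## 6. Novel antisense gene (NAG) discovery

Assembled contig alignments are read from 21-column PSL. Alignment identity
is `matches / (matches + misMatches + qNumInsert)`; alignments below 0.95
are dropped (boundary inclusive), each contig keeps only its best locus, and
an exact identity tie discards the contig as unplaceable. Multi-block
alignments must satisfy the GT-AG rule on the transcribed strand (a
minus-strand alignment reads CT…AC on the genomic plus strand); GC-AG minor
introns are rejected. Surviving alignments sharing exonic bases with a known
transcript on the *same* strand are discarded as fragments of known genes;
the rest must exonically overlap a known transcript on the opposite strand,
which becomes the host (most shared bases wins). By default the host pool
excludes known genes that are themselves antisense-overlapped, so discovery
reports antisense transcription at loci previously believed single-stranded.
Transcripts are grouped into genes by transitive exon overlap on the same
chromosome and strand; transcripts without shared exonic bases stay separate
genes even when only a few hundred bases apart. For grouped genes,
`fc_same_diff` compares max/min RPKM fold changes within the same host
versus across different hosts with a one-sided Welch t-test on log2 values.

## 7. Synthetic-data generator

The generator produces every input the pipeline consumes, with ground truth:

* **Genome**: i.i.d. uniform A/C/G/T per chromosome.
* **Annotation**: singleton multi-exon genes; antisense pairs built as
  equal-length single-exon transcripts sharing exactly `round(o × L)` bases,
  so realized overlap matches the drawn target to one base; planted NAGs
  (two 150-base exons, 80-base intron, isoforms shifted by 40 bases) inside
  a long exon of a singleton host, with GT-AG (optionally GC-AG, for
  splice-filter testing) dinucleotides patched into the genome.
* **Reads**: multinomial over transcripts with weights abundance × length;
  start positions follow a Beta positional law scaled to the transcript; SS
  reads flip strand with probability `leakage_p`, NSS reads are uniform.
  Reads falling entirely inside a pair's shared region are emitted with the
  secondary antisense alignment to the partner — exactly the ambiguity
  equal-split counting halves. Alignments are emitted directly (in-memory,
  SAM in transcript or genome coordinates); no external aligner is run.
* **qPCR**: `Ct = baseline − log2(abundance) + N(0, σ²)` per replicate, so a
  noise-free table recovers fold changes exactly through the ΔCt model.
* **True abundances**: `2^N(0, log2_abundance_sd²)`.

### Default parameters

| Parameter | Default | Rationale |
| --- | --- | --- |
| `read_length` | 101 | common single-end Illumina read length |
| `n_reads` | 100,000 | large enough for stable ratios, seconds to generate |
| `leakage_p` | 0.13 | ≈13% wrong-strand reads, a realistic SS protocol imperfection |
| `positional_bias` | Beta(1, 2) | monotone 5′-biased gene-body coverage |
| `log2_abundance_sd` | 2.0 | several orders of magnitude of expression dynamic range |
| `overlap_range` | (0.1, 0.9) | spans low to high mutual overlap |
| `fraction_antisense_pairs` | 0.4 | a large minority of genes overlapped |
| `ct_noise_sd` | 0.1 cycles | replicate spread of a well-behaved qPCR assay |
| `ct_baseline` | 30 | typical mid-dynamic-range cycle threshold |
| `quality_start/slope/noise` | 40 / −0.2 / 2.0 | decaying per-position quality typical of sequencing chemistry |
| `n_replicates` | 3 | standard qPCR triplicates |

These defaults are the study conditions the analyses are demonstrated under;
tests and the acceptance script use them unless a specific mechanism needs a
controlled value (for example `leakage_p = 0` when isolating the equal-split
effect from strand leakage).

### Scope and limitations

* Reads are single-end and error-free by default; a nonzero `error_rate`
  attaches per-read Binomial mismatch counts to the alignments (exercising
  the mismatch cap) without mutating sequence, and FASTQ bases are random
  placeholders rather than genome substrings. No indels, and no
  junction-spanning ambiguity beyond the antisense-pair and planted-NAG
  constructions.
* Antisense pairs are equal-length and single-exon so the overlap value is
  exact and symmetric; real pairs are asymmetric (the package handles
  asymmetric annotations — only the generator simplifies).
* The genome is compositionally uniform: no GC bias, repeats, or
  mappability structure, so "mappable rate" differences here come solely
  from strand assignment.
* qPCR noise is homoscedastic Gaussian on the Ct scale with efficiency
  exactly 2; primer efficiency variation is not modelled.
* Planted NAG read projection assumes both planted exons sit inside one
  host exon (how they are constructed); it is not a general spliced
  projector between arbitrary transcript pairs.

## 8. Numerical conventions

* Coordinates are 0-based half-open throughout; refFlat exon lists are
  comma-terminated on output and tolerated with or without the trailing
  comma on input.
* All randomness flows through `numpy.random.Generator` seeded from
  user-supplied seeds; identical seeds give bit-identical outputs.
* Correlations are Pearson on log2 values; sets with fewer than 3 usable
  members are flagged rather than returning a spurious r.
* Quartiles in quality profiles use the nearest-rank method.
* Equal-split weights (1/k) are accumulated in double precision; total
  assigned weight per read is 1 by construction and the tests check count
  conservation against hand-computed totals.
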