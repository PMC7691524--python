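# transieve

Genome-guided polishing of de novo assembled transcriptomes.

De novo RNA-seq assemblies are inflated by artefacts: contigs that are
really genomic fragments, chimaeras, error-rich fragments, and redundant
duplicates of the same gene. When a genome draft is available — even a
preliminary one — each tentative transcript (TT) can be aligned to it
with a splice-aware aligner and judged by how it maps. `transieve`
implements that sieving step and the bookkeeping around it, for anyone
curating an assembled transcriptome before using it as a reference for
expression analysis:

* **Alignment handling** — read plain-text SAM or PAF, filter by SAM
  flags (default mask `-F 2052`: drop unmapped and supplementary
  records), convert SAM to PAF semantics with the CIGAR transferred,
  and resolve one best mapping per transcript (primary preferred, then
  most matching bases).
* **Sieving** — from each best mapping compute

  - coverage = (qend − qstart) / query length,
  - identity = matches / alignment block length (PAF columns 10/11,
    intron `N` ops excluded from the block),
  - exon count = number of `N` CIGAR ops + 1,

  and classify every transcript:

  | class | rule |
  |---|---|
  | `unmapping` | no surviving genome mapping |
  | `atypical` | single ungapped block with identity > 0.90 (a genomic fragment, not a transcript) |
  | `low_quality` | fails the retention rule identity > 0.70 **and** coverage > 0.70 |
  | `retained` | everything else → the polished transcriptome |

  All inequalities strict; precedence unmapping > atypical >
  low_quality.
* **Summary statistics** — N50/N90, aggregate length, %N
  indeterminations, structural-status tallies from an external
  annotator's table, redundancy (orthologue-bearing TTs minus distinct
  orthologue IDs), per-library mapping ratios, and the derived report
  numbers (artefact removal fraction, between-assembly deltas).
* **DE consensus** — given one `(transcript, logFC, FDR)` table per
  differential-expression caller (edgeR, DESeq2, limma, NOISeq, ...), a
  transcript is a DET in one caller when |FC| > 2 and FDR < 0.05
  (strict); it is labelled **prevalent** when every caller agrees,
  **possible** when some but not all do. Effects are aggregated as mean
  logFC and a combined FDR (maximum across callers by default).
* **Simulation** — a generator of synthetic genomes, gene models,
  transcript sets with planted artefact classes, exactly consistent PAF
  alignments, and multi-caller DE tables with a planted prevalent set,
  so the whole pipeline is testable without any external data.

## Worked example

Simulate a 100-transcript fixture with a known class mix
(50% retained, 20% atypical, 20% low-quality, 10% unmapping), then
polish it:

```sh
$ transieve simulate --seed 7 --n-genes 20 --n-transcripts 100 --outdir demo
$ transieve sieve --fasta demo/transcripts.fasta --aln demo/alignments.paf \
      --out demo/definitive.fasta --report demo/removed.tsv
retained	50
unmapping	10
atypical	20
low_quality	20
```

The tally reproduces the planted mix exactly: the 50 retained
transcripts are written to `demo/definitive.fasta`, and the other 50 to
the removal table with their metrics and the rule each one tripped:

```
qname	klass	coverage	identity	exons	reason
tt00050	atypical	1.0000	0.9799	1	ungapped mapping with identity 0.980 > 0.90
tt00051	atypical	1.0000	0.9792	1	ungapped mapping with identity 0.979 > 0.90
```

Summary statistics of the polished set:

```sh
$ transieve stats --fasta demo/definitive.fasta
n_transcripts	50
aggregate_length	39717
longest	1324
n50	850
n90	532
```

The consensus step runs the same way on the simulated caller tables
(`transieve consensus --tables demo/caller1.tsv ... --out dets.tsv`)
and recovers the planted prevalent set exactly.

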