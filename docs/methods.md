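# Methods

## The sieving model

A de novo assembled tentative transcript (TT), aligned to a genome
draft by a splice-aware aligner, leaves three kinds of evidence in its
best mapping record:

* **coverage** — the fraction of the transcript's length inside the
  aligned query interval, `(qend − qstart) / qlen`. Soft/hard-clipped
  bases do not count as aligned; chimaeras and fragments show low
  coverage because only part of the contig finds a home.
* **identity** — matching bases over the alignment block,
  `matches / block_len` with PAF column-10/11 semantics: the block is
  M/=/X + I + D, introns (`N`) excluded. Error-rich contigs and
  cross-contamination show low identity.
* **exon count** — the number of `N` operations in the CIGAR plus one.
  A real multi-exon transcript maps back across its introns; a contig
  that maps in one contiguous genomic block with near-perfect identity
  is more plausibly a fragment of genomic DNA than a processed
  transcript.

Classification applies three rules in order of precedence:

1. no mapping → `unmapping`;
2. exactly one exon **and** identity > `atypical_min_identity`
   (default 0.90) → `atypical`;
3. retention requires identity > `retain_min_identity` (0.70) **and**
   coverage > `retain_min_coverage` (0.70); a transcript failing it is
   `low_quality`, otherwise `retained`.

All inequalities are strict, so a transcript at exactly 0.70 identity
is removed and one at exactly 0.90 identity with a single exon is not
atypical. The `low_quality_rule` parameter selects between the default
`either` (failing either metric removes the transcript — retention
demands both) and `both` (removal only when both fail); the two
readings of a sub-70% rule are both defensible and the choice is
exposed rather than hidden. The atypical rule deliberately ignores
coverage: gaplessness plus high identity is the genomic-fragment
signature regardless of how much of the contig aligns.

The precedence order means the low-quality tally is counted after
unmapping and atypical transcripts are set aside, mirroring a two-pass
cleanup (first remove what is not transcript-like at all, then apply
the quality rule to the remainder).

## Alignment handling

SAM and PAF are parsed from plain text. SAM positions are 1-based;
PAF intervals are 0-based half-open; the shift happens in exactly one
place, `sam_to_paf`. The conversion

* excludes clips from the query interval and reports its ends in the
  original query orientation (for reverse-strand records the clip roles
  swap ends, the PAF convention);
* recovers matches from the `NM` tag as
  `aligned − max(0, NM − inserted − deleted)`; without `NM` the aligned
  length is used and the record tagged `approx_matches`. An `NM`
  smaller than the indel bases is clamped with a logged warning.

Flag filtering uses the mask 2052 (unmapped | supplementary) by
default. Because that mask keeps secondary records, a per-transcript
resolution step follows: primary records are preferred, then the most
matching bases, with ties broken by target name and start for
determinism. A `--keep-secondary` switch lets secondaries compete
equally for users who want the raw mask behaviour.

`trim_terminal_artefacts` (off by default, `--trim` enables) is this
package's own definition of terminal-artefact cleanup, for the spurious
micro-exons splice-aware aligners sometimes anchor across a long
intron: a terminal exon with fewer than `min_terminal_exon` (default
10) aligned bases is removed together with its adjoining intron, the
removed query bases become soft clips, and matches shrink by the
removed aligned length (clamped into the valid range). Trimming that
would consume the whole alignment leaves the record unchanged with a
warning.

## Summary statistics

N50/N90 is the smallest length L such that sequences ≥ L cover 50%
(90%) of the aggregate; the implementation is a vectorised cumulative
sum, cross-checked in the tests against a brute-force sorted scan.
Indeterminations count only N/n (assemblers emit N for gaps; other
IUPAC codes are left alone). Status tallies consume an external
annotator's table — this package never re-annotates — and the
redundancy statistic is the count of orthologue-bearing transcripts
minus the number of distinct orthologue IDs among them. Percentages
are reported to 1 decimal, except the artefact removal fraction which
is conventionally quoted to 2. Mapping ratios take the library's
useful read pairs as the reads denominator, and libraries above a
configurable 70% mapping-rate cutoff are flagged for QC review, not
dropped.

## DE consensus

A per-caller DET call requires |logFC| > log2(2) and FDR < 0.05, both
strict; the fold-change threshold is interpreted on the linear scale
and applied to |logFC|. A transcript absent from one caller's table
counts as not-called there (callers filter independently), which makes
the prevalent label anti-monotone in the caller set — adding a caller
can only shrink it. The combined FDR is the maximum across callers by
default: it is the only simple combination that guarantees the
prevalent rule's per-caller bound carries over. Fisher's method is
available as an option but is heuristic on already-adjusted values.
The mean logFC is the arithmetic mean of the available per-caller
values.

## What the simulator emulates — and what it does not

The generator plants one chromosome of uniform random sequence with
`n_genes` gene models (2–6 exons of 50–300 nt, introns 60–2000 nt, all
on the forward strand) and draws transcripts from a class mix
(defaults: 50% retained, 20% atypical, 20% low-quality, 10%
unmapping). Alignment records are synthesised directly from the known
generative edits, so CIGARs, matches and block lengths are exact by
construction and no aligner is involved.

The mutation model is substitution-only with an exact count
`round(rate × length)` rather than a binomial draw, so a planted class
sits at a deterministic margin from every threshold: retained
transcripts at 1% substitutions (identity 0.99), atypical genomic
fragments at 2% (0.98, comfortably above the 0.90 bar), heavily
mutated low-quality transcripts at 35% (identity 0.65, a 0.05 margin
below the 0.70 bar), and chimaeras built as a real spliced transcript
plus an equal-length unmappable tail (coverage exactly 0.5). DE tables
plant |logFC| ≥ 1.5 and FDR ≤ 0.01 in every caller for the signal set
and FDR > 0.05 with |logFC| < 1 for the rest.

Consequently, passing the 100%-recovery tests shows that the decision
rules and the metric arithmetic are implemented exactly — it does not
show robustness to real-data features the simulator omits: indels and
sequencing-error structure, paralogy and multi-mapping ambiguity,
reverse-strand and fragmented gene models, misassembly modes other
than the planted ones, and correlated caller behaviour. A separate
test degrades the planted margins toward the thresholds and checks
that accuracy falls monotonically, which is the failure mode real data
would exercise.

Every generator is a pure function of the config seed (sub-streams are
derived as seed+1 … seed+4 for transcripts, annotations, counts and DE
tables), and determinism is asserted byte-for-byte in the tests.

## Numerical and design choices

* Coordinates are validated against the record invariants
  (`0 ≤ qstart < qend ≤ qlen`, CIGAR consistency) after every
  constructing operation in the tests.
* Degenerate inputs raise rather than guess: zero query length or zero
  block length, empty FASTA or empty length lists, duplicate ids,
  FDR outside [0, 1].
* Missing logFC/FDR values ("NA") never satisfy a DET call.
* The acceptance script's fixture sizes (500 transcripts for the
  sieve, 400 for the consensus, 200 toy alignments and 1000 length
  multisets for the oracle checks) were chosen as the smallest sets
  that exercise every class and branch while keeping the whole run in
  seconds.

## Known limitations

* Only plain-text SAM is read (no BAM/CRAM); split/chimeric alignment
  stitching is out of scope — a supplementary-record chimaera is
  simply removed by the flag mask and its transcript judged by what
  remains.
* The sieve never rescues a transcript via its second-best mapping.
* Structural statuses are consumed verbatim from the annotation table;
  their detection (including the "misassembled"/"unmapped" artefact
  split) belongs to the upstream annotator.
* The combined-FDR default is a conservative convention, not an
  estimator with frequentist guarantees across dependent callers.
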