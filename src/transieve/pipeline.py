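"""End-to-end polishing pipeline: alignments in, polished FASTA out."""

from __future__ import annotations

from typing import Iterable, TextIO

from Bio import SeqIO

from . import alignment as aln
from .sieve import SieveThresholds, SieveVerdict
from .sieve import polish_transcriptome, sieve as classify_all


def load_alignments(
    stream: Iterable[str],
    fmt: str,
    exclude_mask: int = aln.DEFAULT_EXCLUDE_MASK,
    keep_secondary: bool = False,
    trim: bool = False,
    min_terminal_exon: int = 10,
) -> dict[str, aln.AlignmentRecord]:
    """Read SAM or PAF, apply the flag mask, resolve one best mapping each.

    SAM records are converted to PAF semantics after flag filtering.
    With ``keep_secondary`` the per-query resolution still runs but
    secondary records compete equally with primaries.
    """
    if fmt == "sam":
        records = aln.read_sam(stream)
        records = aln.filter_flags(records, exclude_mask)
        records = [aln.sam_to_paf(r) for r in records if r.is_mapped and r.cigar]
    elif fmt == "paf":
        records = aln.read_paf(stream)
    else:
        raise ValueError(f"unknown alignment format: {fmt}")
    if trim:
        records = [
            aln.trim_terminal_artefacts(r, min_terminal_exon)
            if r.is_mapped and r.cigar else r
            for r in records
        ]
    if keep_secondary:
        records = [
            aln.AlignmentRecord(**{**r.__dict__, "flags": r.flags & ~aln.FLAG_SECONDARY,
                                   "tags": {k: v for k, v in r.tags.items()
                                            if k != "tp"}})
            for r in records
        ]
    return aln.best_per_transcript(records)


def sieve_fasta(
    fasta_in,
    aln_stream: Iterable[str],
    fmt: str,
    fasta_out: TextIO,
    report_out: TextIO | None = None,
    thresholds: SieveThresholds = SieveThresholds(),
    **load_kwargs,
) -> dict[str, SieveVerdict]:
    """Classify every FASTA transcript from its alignments and polish.

    Returns the verdict per transcript id; the retained FASTA and the
    removal table are written to the supplied handles.
    """
    best = load_alignments(aln_stream, fmt, **load_kwargs)
    qnames = [rec.id for rec in SeqIO.parse(fasta_in, "fasta")]
    verdicts = classify_all(qnames, best, thresholds)
    if hasattr(fasta_in, "seek"):
        fasta_in.seek(0)
    polish_transcriptome(fasta_in, verdicts, fasta_out, report_out)
    return verdicts
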