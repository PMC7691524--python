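"""Transcriptome summary statistics and derived report numbers.

Covers the usual assembly-report quantities (N50/N90, aggregate length,
longest sequence, fraction of N indeterminations), tallies of the
structural-annotation statuses an external annotator assigns to each
tentative transcript (TT), the redundancy statistic (orthologue-bearing
TTs minus distinct orthologue ids), per-library mapping ratios, and the
small derived statistics a polishing report quotes (artefact removal
fraction, between-transcriptome deltas).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

#: structural statuses carrying an orthologue hit
ORTHOLOGUE_STATUSES = frozenset(
    {"complete", "c_terminal", "n_terminal", "internal"}
)
#: statuses counted as artefactual
ARTIFACT_STATUSES = frozenset({"artifact", "misassembled", "unmapped_artifact"})
KNOWN_STATUSES = ORTHOLOGUE_STATUSES | ARTIFACT_STATUSES | {
    "new_coding", "ncRNA", "unknown"
}

EXON_BINS = ("1", "2", "3", "4", "5", ">5")


@dataclass(frozen=True)
class AnnotationRecord:
    """External annotator's verdict for one transcript (consumed, not made)."""

    qname: str
    orthologue_id: str | None
    status: str

    def __post_init__(self) -> None:
        if self.status not in KNOWN_STATUSES:
            raise ValueError(f"{self.qname}: unknown status {self.status!r}")


@dataclass
class TranscriptomeSummary:
    n_transcripts: int = 0
    aggregate_length: int = 0
    longest: int = 0
    pct_indeterminations: float = 0.0
    n50: int = 0
    n90: int = 0
    n_with_orth: int = 0
    n_unique_orth: int = 0
    n_complete: int = 0
    n_unique_complete: int = 0
    n_ncRNA: int = 0
    n_without_orth: int = 0
    n_coding_no_orth: int = 0
    n_unknown: int = 0
    n_artifacts: int = 0
    status_counts: dict[str, int] = field(default_factory=dict)


def length_metrics(lengths: Sequence[int]) -> tuple[int, int, int, int]:
    """Return ``(n50, n90, aggregate, longest)`` for a length multiset.

    N50 (N90) is the smallest length L such that sequences of length
    >= L sum to at least 50% (90%) of the aggregate.
    """
    if len(lengths) == 0:
        raise ValueError("length_metrics needs a non-empty length list")
    arr = np.asarray(lengths, dtype=np.int64)
    if (arr <= 0).any():
        raise ValueError("all lengths must be positive")
    desc = np.sort(arr)[::-1]
    csum = np.cumsum(desc)
    total = int(csum[-1])
    n50 = int(desc[np.searchsorted(csum, 0.5 * total)])
    n90 = int(desc[np.searchsorted(csum, 0.9 * total)])
    return n50, n90, total, int(desc[0])


def composition_stats(fasta) -> tuple[int, int, float]:
    """``(aggregate, longest, %N)`` over a FASTA file or handle.

    Indeterminations count only N/n, the character assemblers emit for
    gaps; other IUPAC ambiguity codes are not counted.
    """
    aggregate = longest = n_count = 0
    for rec in SeqIO.parse(fasta, "fasta"):
        s = str(rec.seq)
        aggregate += len(s)
        longest = max(longest, len(s))
        n_count += s.count("N") + s.count("n")
    if aggregate == 0:
        raise ValueError("empty FASTA")
    return aggregate, longest, 100.0 * n_count / aggregate


def status_tally(annotations: Iterable[AnnotationRecord]) -> TranscriptomeSummary:
    """Exhaustive status counts plus orthologue-uniqueness tallies."""
    summary = TranscriptomeSummary()
    seen: set[str] = set()
    orth_ids: set[str] = set()
    complete_orth_ids: set[str] = set()
    counts: dict[str, int] = {}
    for a in annotations:
        if a.qname in seen:
            raise ValueError(f"duplicate annotation for {a.qname}")
        seen.add(a.qname)
        counts[a.status] = counts.get(a.status, 0) + 1
        summary.n_transcripts += 1
        if a.status in ARTIFACT_STATUSES:
            summary.n_artifacts += 1
        elif a.status in ORTHOLOGUE_STATUSES and a.orthologue_id:
            summary.n_with_orth += 1
            orth_ids.add(a.orthologue_id)
            if a.status == "complete":
                summary.n_complete += 1
                complete_orth_ids.add(a.orthologue_id)
        else:
            summary.n_without_orth += 1
            if a.status == "new_coding":
                summary.n_coding_no_orth += 1
            elif a.status == "ncRNA":
                summary.n_ncRNA += 1
            elif a.status == "unknown":
                summary.n_unknown += 1
    summary.n_unique_orth = len(orth_ids)
    summary.n_unique_complete = len(complete_orth_ids)
    summary.status_counts = counts
    return summary


def redundancy(summary: TranscriptomeSummary) -> int:
    """Orthologue-bearing transcripts minus distinct orthologue ids.

    Zero means every orthologue is represented once; large values flag
    duplicated isoforms/fragments hitting the same protein.
    """
    if summary.n_unique_orth > summary.n_with_orth:
        raise ValueError("unique orthologue ids exceed orthologue-bearing count")
    return summary.n_with_orth - summary.n_unique_orth


def exon_distribution(exon_counts: Sequence[int]) -> dict[str, float]:
    """Percentages of transcripts in exon-count bins {1,2,3,4,5,>5}."""
    if len(exon_counts) == 0:
        raise ValueError("exon_distribution needs at least one mapped transcript")
    total = len(exon_counts)
    out = {b: 0 for b in EXON_BINS}
    for e in exon_counts:
        if e < 1:
            raise ValueError(f"exon count must be >= 1, got {e}")
        out[str(e) if e <= 5 else ">5"] += 1
    return {b: 100.0 * c / total for b, c in out.items()}


def summary_delta(
    a: TranscriptomeSummary, b: TranscriptomeSummary
) -> dict[str, float]:
    """Compare two transcriptomes on their orthologue-less fractions.

    Returns the excess of transcripts without orthologue in ``a`` over
    ``b``, the excess of those predicted coding, and the percentage of
    ``a``'s orthologue-less transcripts predicted coding (1 decimal).
    """
    out: dict[str, float] = {
        "without_orth_excess": a.n_without_orth - b.n_without_orth,
        "coding_no_orth_excess": a.n_coding_no_orth - b.n_coding_no_orth,
    }
    if a.n_without_orth == 0:
        out["pct_coding_among_no_orth"] = float("nan")
    else:
        out["pct_coding_among_no_orth"] = round(
            100.0 * a.n_coding_no_orth / a.n_without_orth, 1
        )
    return out


def removal_fraction(
    unmapped_removed: int, atypical_removed: int, total_pool: int
) -> float:
    """Percentage of a pool removed as unmapping + atypical (2 decimals)."""
    if total_pool <= 0:
        raise ValueError("total_pool must be positive")
    if unmapped_removed + atypical_removed > total_pool:
        raise ValueError("removed counts exceed the pool")
    return round(100.0 * (unmapped_removed + atypical_removed) / total_pool, 2)


@dataclass(frozen=True)
class MappingRatioReport:
    pct_mapping_reads: float
    pct_mapped_tts: float
    pct_mapped_tts_vs_baseline: float
    reads_per_tt: float
    flagged_high_mapping: bool = False


def mapping_ratios(
    mapped_pairs: int,
    total_pairs: int,
    tts_with_reads: int,
    n_tts: int,
    baseline_n_tts: int,
    qc_cutoff_pct: float = 70.0,
) -> MappingRatioReport:
    """Per-library mapping ratios against a transcriptome.

    ``pct_mapping_reads`` uses the library's useful read pairs as
    denominator; ``pct_mapped_tts_vs_baseline`` rescales the mapped-TT
    count by a baseline transcriptome size so differently sized
    references compare fairly.  Libraries above ``qc_cutoff_pct``
    mapping reads are flagged (not dropped) for QC review.
    """
    if min(mapped_pairs, tts_with_reads) < 0:
        raise ValueError("counts must be non-negative")
    if min(total_pairs, n_tts, baseline_n_tts) <= 0:
        raise ValueError("denominators must be positive")
    pct_reads = 100.0 * mapped_pairs / total_pairs
    return MappingRatioReport(
        pct_mapping_reads=pct_reads,
        pct_mapped_tts=100.0 * tts_with_reads / n_tts,
        pct_mapped_tts_vs_baseline=100.0 * tts_with_reads / baseline_n_tts,
        reads_per_tt=mapped_pairs / n_tts,
        flagged_high_mapping=pct_reads > qc_cutoff_pct,
    )


def read_annotation_tsv(stream) -> list[AnnotationRecord]:
    """Read a (qname, orthologue_id, status) TSV; '-' or '' means no orthologue."""
    records = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#") or (
            lineno == 1 and line.lower().startswith("qname")
        ):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"annotation line {lineno}: expected 3 columns")
        qname, orth, status = parts
        records.append(
            AnnotationRecord(qname, orth if orth not in ("", "-") else None, status)
        )
    return records


def summarize_transcriptome(
    fasta, annotations: Iterable[AnnotationRecord] | None = None
) -> TranscriptomeSummary:
    """Full summary of a transcriptome FASTA, optionally with annotations."""
    lengths = []
    aggregate = n_count = 0
    for rec in SeqIO.parse(fasta, "fasta"):
        s = str(rec.seq)
        lengths.append(len(s))
        aggregate += len(s)
        n_count += s.count("N") + s.count("n")
    if not lengths:
        raise ValueError("empty FASTA")
    n50, n90, total, longest = length_metrics(lengths)
    if annotations is not None:
        summary = status_tally(annotations)
    else:
        summary = TranscriptomeSummary(n_transcripts=len(lengths))
    summary.n_transcripts = len(lengths)
    summary.aggregate_length = total
    summary.longest = longest
    summary.pct_indeterminations = 100.0 * n_count / aggregate
    summary.n50 = n50
    summary.n90 = n90
    return summary
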