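"""Per-transcript mapping metrics and low-confidence classification.

Given one resolved genome mapping per assembled transcript, three
metrics decide its fate: query coverage (fraction of the transcript
aligned), alignment identity (matching bases over the alignment block)
and exon count (intron N ops in the CIGAR plus one).  A transcript is
then classed as

* ``unmapping``   — no surviving mapping on the genome, suggesting an
  assembly artefact;
* ``atypical``    — mapped in a single ungapped block with >90%
  identity, i.e. closer to a genomic fragment than to a spliced
  transcript;
* ``low_quality`` — fails the >70% identity / >70% coverage retention
  rule (chimaeric or error-rich);
* ``retained``    — everything else; these constitute the polished
  ("definitive") transcriptome.

All inequalities are strict.  Precedence is unmapping > atypical >
low_quality, mirroring a two-pass removal: genomic-fragment candidates
are pulled out before the coverage/identity rule is applied to the rest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, TextIO

from Bio import SeqIO

from .alignment import AlignmentRecord, parse_cigar

KLASSES = ("retained", "unmapping", "atypical", "low_quality")


@dataclass(frozen=True)
class SieveThresholds:
    """Classification cut-offs, as fractions.

    ``low_quality_rule`` resolves the ambiguity between "fails identity
    OR fails coverage" (``either``, the default: retention requires both
    metrics to pass) and "fails identity AND fails coverage" (``both``).
    """

    atypical_min_identity: float = 0.90
    retain_min_identity: float = 0.70
    retain_min_coverage: float = 0.70
    low_quality_rule: str = "either"

    def __post_init__(self) -> None:
        for name in ("atypical_min_identity", "retain_min_identity",
                     "retain_min_coverage"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.retain_min_identity > self.atypical_min_identity:
            raise ValueError("retain_min_identity must not exceed "
                             "atypical_min_identity")
        if self.low_quality_rule not in ("either", "both"):
            raise ValueError("low_quality_rule must be 'either' or 'both'")


@dataclass(frozen=True)
class TranscriptMetrics:
    qname: str
    is_mapped: bool
    coverage: float = 0.0
    identity: float = 0.0
    exons: int = 0


@dataclass(frozen=True)
class SieveVerdict:
    qname: str
    klass: str
    reason: str
    metrics: TranscriptMetrics | None = None


def exon_count(cigar: str) -> int:
    """Number of exons implied by a splice-aware CIGAR: N ops + 1."""
    return sum(1 for _, op in parse_cigar(cigar) if op == "N") + 1


def query_coverage(record: AlignmentRecord) -> float:
    """Fraction of the transcript covered by the alignment."""
    if not record.is_mapped:
        raise ValueError(f"{record.qname}: coverage undefined for unmapped record")
    if record.qlen <= 0:
        raise ValueError(f"{record.qname}: query length is zero")
    return (record.qend - record.qstart) / record.qlen


def alignment_identity(record: AlignmentRecord) -> float:
    """Matching bases over the alignment block (PAF cols 10/11)."""
    if not record.is_mapped:
        raise ValueError(f"{record.qname}: identity undefined for unmapped record")
    if record.block_len <= 0:
        raise ValueError(f"{record.qname}: alignment block length is zero")
    return record.matches / record.block_len


def compute_metrics(
    qname: str, record: AlignmentRecord | None
) -> TranscriptMetrics:
    """Metrics from a transcript's single best mapping, or an unmapped stub."""
    if record is None or not record.is_mapped:
        return TranscriptMetrics(qname=qname, is_mapped=False)
    return TranscriptMetrics(
        qname=qname,
        is_mapped=True,
        coverage=query_coverage(record),
        identity=alignment_identity(record),
        exons=exon_count(record.cigar) if record.cigar else 1,
    )


def classify_transcript(
    m: TranscriptMetrics, t: SieveThresholds = SieveThresholds()
) -> SieveVerdict:
    """Assign one of the four sieve classes; see the module docstring."""
    if not m.is_mapped:
        return SieveVerdict(m.qname, "unmapping", "no mapping on the genome", m)
    if m.exons == 1 and m.identity > t.atypical_min_identity:
        return SieveVerdict(
            m.qname, "atypical",
            f"ungapped mapping with identity {m.identity:.3f} > "
            f"{t.atypical_min_identity:.2f}", m,
        )
    id_fail = m.identity <= t.retain_min_identity
    cov_fail = m.coverage <= t.retain_min_coverage
    low = (id_fail or cov_fail) if t.low_quality_rule == "either" \
        else (id_fail and cov_fail)
    if low:
        parts = []
        if id_fail:
            parts.append(f"identity {m.identity:.3f} <= {t.retain_min_identity:.2f}")
        if cov_fail:
            parts.append(f"coverage {m.coverage:.3f} <= {t.retain_min_coverage:.2f}")
        return SieveVerdict(m.qname, "low_quality", "; ".join(parts), m)
    return SieveVerdict(
        m.qname, "retained",
        f"identity {m.identity:.3f}, coverage {m.coverage:.3f}, "
        f"{m.exons} exon(s)", m,
    )


def sieve(
    qnames: Iterable[str],
    best: Mapping[str, AlignmentRecord],
    thresholds: SieveThresholds = SieveThresholds(),
) -> dict[str, SieveVerdict]:
    """Classify every transcript id against its best mapping (if any)."""
    return {
        q: classify_transcript(compute_metrics(q, best.get(q)), thresholds)
        for q in qnames
    }


def polish_transcriptome(
    fasta_in: TextIO | str,
    verdicts: Mapping[str, SieveVerdict],
    fasta_out: TextIO,
    report_out: TextIO | None = None,
) -> tuple[int, int]:
    """Split a raw transcriptome FASTA into retained sequences + removal table.

    Retained sequences preserve input order and are written unwrapped so
    the sequence text is byte-identical to the parsed input.  Ids absent
    from ``verdicts`` are treated as unmapping.  Returns
    ``(n_retained, n_removed)``.
    """
    if report_out is not None:
        report_out.write("qname\tklass\tcoverage\tidentity\texons\treason\n")
    seen: set[str] = set()
    n_kept = n_removed = 0
    for rec in SeqIO.parse(fasta_in, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        verdict = verdicts.get(rec.id)
        if verdict is None:
            verdict = SieveVerdict(rec.id, "unmapping", "no alignment record")
        if verdict.klass == "retained":
            fasta_out.write(f">{rec.description}\n{rec.seq}\n")
            n_kept += 1
        else:
            n_removed += 1
            if report_out is not None:
                m = verdict.metrics
                cov = f"{m.coverage:.4f}" if m and m.is_mapped else "NA"
                ident = f"{m.identity:.4f}" if m and m.is_mapped else "NA"
                exons = str(m.exons) if m and m.is_mapped else "NA"
                report_out.write(
                    f"{rec.id}\t{verdict.klass}\t{cov}\t{ident}\t{exons}\t"
                    f"{verdict.reason}\n"
                )
    return n_kept, n_removed
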