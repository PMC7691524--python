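"""Transcript-to-genome alignment records: SAM/PAF I/O and conversion.

Splice-aware aligners report transcript-to-genome mappings as SAM; the
sieving metrics (coverage, identity, exon count) are naturally expressed
on PAF records, whose columns 10/11 carry residue matches and alignment
block length.  This module parses both formats into a common
:class:`AlignmentRecord`, converts SAM records to PAF semantics with the
CIGAR transferred, applies SAM flag filtering, and resolves one best
mapping per transcript.

Coordinate conventions: PAF is 0-based half-open; SAM positions are
1-based.  The 1→0 shift happens in exactly one place,
:func:`sam_to_paf`.  Query coordinates of reverse-strand records are
reported in the original query orientation, as PAF prescribes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

#: SAM flags excluded by default: 0x4 (unmapped) | 0x800 (supplementary).
DEFAULT_EXCLUDE_MASK = 2052

FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_CIGAR_VALID = re.compile(r"^(\d+[MIDNSHP=X])+$")

#: ops that consume the query / the target
QUERY_OPS = frozenset("MIS=XH")
TARGET_OPS = frozenset("MDN=X")
ALIGN_OPS = frozenset("M=X")


class AlignmentParseError(ValueError):
    """Raised on malformed SAM/PAF input; carries the line number."""


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Split a CIGAR string into ``(length, op)`` tuples.

    Raises ``ValueError`` on empty strings, ``"*"`` or invalid op letters.
    """
    if not cigar or cigar == "*":
        raise ValueError(f"missing or empty CIGAR: {cigar!r}")
    if not _CIGAR_VALID.match(cigar):
        raise ValueError(f"invalid CIGAR string: {cigar!r}")
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def cigar_to_string(ops: Sequence[tuple[int, str]]) -> str:
    return "".join(f"{n}{op}" for n, op in ops)


def _oplen(ops: Iterable[tuple[int, str]], which: frozenset[str]) -> int:
    return sum(n for n, op in ops if op in which)


@dataclass
class AlignmentRecord:
    """One transcript-to-genome mapping in PAF-style coordinates.

    ``matches`` follows PAF column 10 (identical aligned bases) and
    ``block_len`` column 11 (M/=/X + I + D; intron N ops excluded).
    ``flags`` are SAM bitwise flags, 0 for PAF-origin records.
    """

    qname: str
    qlen: int = 0
    qstart: int = 0
    qend: int = 0
    strand: str = "+"
    tname: str = "*"
    tlen: int = 0
    tstart: int = 0
    tend: int = 0
    matches: int = 0
    block_len: int = 0
    mapq: int = 0
    cigar: str = ""
    flags: int = 0
    is_mapped: bool = True
    tags: dict[str, str] = field(default_factory=dict)

    @property
    def is_secondary(self) -> bool:
        if self.flags & FLAG_SECONDARY:
            return True
        return self.tags.get("tp") == "S"

    def validate(self) -> None:
        """Assert the record invariants; raises ``ValueError`` on violation."""
        if not self.is_mapped:
            return
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(
                f"{self.qname}: query interval {self.qstart}-{self.qend} "
                f"outside [0, {self.qlen})"
            )
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(
                f"{self.qname}: target interval {self.tstart}-{self.tend} "
                f"outside [0, {self.tlen})"
            )
        if self.matches > self.block_len:
            raise ValueError(
                f"{self.qname}: matches {self.matches} > block {self.block_len}"
            )
        if self.cigar:
            ops = parse_cigar(self.cigar)
            if _oplen(ops, QUERY_OPS) != self.qlen:
                raise ValueError(f"{self.qname}: CIGAR query length != qlen")
            if _oplen(ops, TARGET_OPS) != self.tend - self.tstart:
                raise ValueError(f"{self.qname}: CIGAR target span != tend-tstart")


def read_paf(stream: Iterable[str]) -> list[AlignmentRecord]:
    """Parse PAF lines into :class:`AlignmentRecord` objects.

    The CIGAR, when present, is read from the ``cg:Z:`` tag; records
    without one carry an empty ``cigar`` and support only
    coordinate-level metrics.  Malformed lines (fewer than 12 columns,
    non-integer coordinates) raise :class:`AlignmentParseError` naming
    the line number.
    """
    records = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise AlignmentParseError(
                f"PAF line {lineno}: expected >=12 columns, got {len(cols)}"
            )
        try:
            qlen, qstart, qend = int(cols[1]), int(cols[2]), int(cols[3])
            tlen, tstart, tend = int(cols[6]), int(cols[7]), int(cols[8])
            matches, block_len, mapq = int(cols[9]), int(cols[10]), int(cols[11])
        except ValueError as exc:
            raise AlignmentParseError(f"PAF line {lineno}: {exc}") from None
        tags: dict[str, str] = {}
        cigar = ""
        for tag in cols[12:]:
            name, _typ, value = tag.split(":", 2)
            if name == "cg":
                cigar = value
            else:
                tags[name] = value
        records.append(
            AlignmentRecord(
                qname=cols[0], qlen=qlen, qstart=qstart, qend=qend,
                strand=cols[4], tname=cols[5], tlen=tlen, tstart=tstart,
                tend=tend, matches=matches, block_len=block_len, mapq=mapq,
                cigar=cigar, flags=0, is_mapped=True, tags=tags,
            )
        )
    return records


def write_paf(records: Iterable[AlignmentRecord], stream) -> None:
    """Write records as PAF, CIGAR in ``cg:Z:``, mapping type in ``tp:A:``."""
    for r in records:
        cols = [
            r.qname, str(r.qlen), str(r.qstart), str(r.qend), r.strand,
            r.tname, str(r.tlen), str(r.tstart), str(r.tend),
            str(r.matches), str(r.block_len), str(r.mapq),
        ]
        cols.append(f"tp:A:{'S' if r.is_secondary else 'P'}")
        for name, value in r.tags.items():
            if name == "tp":
                continue
            typ = "i" if value.lstrip("-").isdigit() else "Z"
            cols.append(f"{name}:{typ}:{value}")
        if r.cigar:
            cols.append(f"cg:Z:{r.cigar}")
        stream.write("\t".join(cols) + "\n")


def read_sam(stream: Iterable[str]) -> list[AlignmentRecord]:
    """Parse plain-text SAM into records with SAM semantics retained.

    The 1-based POS is kept in ``tstart`` untouched until
    :func:`sam_to_paf` converts it; coverage/identity fields are left
    zero.  Target lengths come from ``@SQ`` headers when present, else 0
    with a warning.  Unmapped records (flag 0x4) yield
    ``is_mapped=False``.
    """
    tlens: dict[str, int] = {}
    records = []
    warned_missing_sq = False
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("@"):
            if line.startswith("@SQ"):
                fields = dict(
                    f.split(":", 1) for f in line.split("\t")[1:] if ":" in f
                )
                if "SN" in fields and "LN" in fields:
                    tlens[fields["SN"]] = int(fields["LN"])
            continue
        cols = line.split("\t")
        if len(cols) < 11:
            raise AlignmentParseError(
                f"SAM line {lineno}: expected 11 mandatory columns, got {len(cols)}"
            )
        try:
            flags = int(cols[1])
            pos = int(cols[3])
            mapq = int(cols[4])
        except ValueError as exc:
            raise AlignmentParseError(f"SAM line {lineno}: {exc}") from None
        tags = {}
        for tag in cols[11:]:
            name, _typ, value = tag.split(":", 2)
            tags[name] = value
        mapped = not flags & FLAG_UNMAPPED
        tname = cols[2]
        tlen = tlens.get(tname, 0)
        if mapped and tlen == 0 and not warned_missing_sq:
            logger.warning("no @SQ header for %s; target length set to 0", tname)
            warned_missing_sq = True
        cigar = cols[5] if cols[5] != "*" else ""
        seq = cols[9]
        if cigar:
            qlen = _oplen(parse_cigar(cigar), QUERY_OPS)
        elif seq != "*":
            qlen = len(seq)
        else:
            qlen = 0
        records.append(
            AlignmentRecord(
                qname=cols[0], qlen=qlen, strand="-" if flags & FLAG_REVERSE else "+",
                tname=tname, tlen=tlen, tstart=pos, tend=0, mapq=mapq,
                cigar=cigar, flags=flags, is_mapped=mapped, tags=tags,
            )
        )
    return records


def sam_to_paf(record: AlignmentRecord) -> AlignmentRecord:
    """Convert a mapped SAM-origin record to PAF semantics.

    Coordinates become 0-based half-open; soft/hard clips are excluded
    from the query interval, whose ends are reported in the original
    query orientation (clip roles swap for reverse-strand records).
    ``block_len`` counts M/=/X + I + D (introns excluded) and
    ``matches`` is recovered from the NM tag when present
    (mismatches = NM − inserted − deleted bases); without NM the
    aligned length is used and the record tagged approximate.
    """
    if not record.is_mapped:
        raise ValueError(f"{record.qname}: cannot convert an unmapped record")
    if not record.cigar:
        raise ValueError(f"{record.qname}: cannot convert without a CIGAR")
    ops = parse_cigar(record.cigar)
    aligned = _oplen(ops, ALIGN_OPS)
    ins = _oplen(ops, frozenset("I"))
    dele = _oplen(ops, frozenset("D"))
    target_span = _oplen(ops, TARGET_OPS)
    qlen = _oplen(ops, QUERY_OPS)
    lead_clip = 0
    for n, op in ops:
        if op in "SH":
            lead_clip += n
        else:
            break
    tail_clip = 0
    for n, op in reversed(ops):
        if op in "SH":
            tail_clip += n
        else:
            break
    if record.strand == "-":
        lead_clip, tail_clip = tail_clip, lead_clip
    qstart = lead_clip
    qend = qlen - tail_clip

    tags = dict(record.tags)
    if "NM" in tags:
        nm = int(tags["NM"])
        mismatches = nm - ins - dele
        if mismatches < 0:
            logger.warning(
                "%s: NM=%d smaller than indel bases %d; clamping mismatches to 0",
                record.qname, nm, ins + dele,
            )
            mismatches = 0
        matches = aligned - mismatches
    else:
        matches = aligned
        tags["approx_matches"] = "1"

    tstart = record.tstart - 1
    return replace(
        record,
        qlen=qlen, qstart=qstart, qend=qend,
        tstart=tstart, tend=tstart + target_span,
        matches=matches, block_len=aligned + ins + dele,
        tags=tags,
    )


def filter_flags(
    records: Iterable[AlignmentRecord], exclude_mask: int = DEFAULT_EXCLUDE_MASK
) -> list[AlignmentRecord]:
    """Drop records whose SAM flags intersect ``exclude_mask``.

    The default mask 2052 removes unmapped and supplementary records,
    mirroring ``samtools view -F 2052``.  PAF-origin records (flags 0)
    always pass.
    """
    return [r for r in records if not r.flags & exclude_mask]


def select_best(records: Sequence[AlignmentRecord]) -> AlignmentRecord | None:
    """Resolve one best mapping among a transcript's records.

    Primary (non-secondary) mapped records win over secondary ones; among
    candidates the most ``matches`` wins, ties broken by
    (lexicographically smaller target name, smaller target start) for
    determinism.  Returns ``None`` when nothing is mapped.
    """
    qnames = {r.qname for r in records}
    if len(qnames) > 1:
        raise ValueError(f"select_best fed multiple transcripts: {sorted(qnames)}")
    mapped = [r for r in records if r.is_mapped]
    if not mapped:
        return None
    primaries = [r for r in mapped if not r.is_secondary]
    pool = primaries or mapped
    return min(pool, key=lambda r: (-r.matches, r.tname, r.tstart))


def best_per_transcript(
    records: Iterable[AlignmentRecord],
) -> dict[str, AlignmentRecord]:
    """Group records by transcript and keep one best mapping for each."""
    groups: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        groups.setdefault(r.qname, []).append(r)
    best = {}
    for qname, group in groups.items():
        chosen = select_best(group)
        if chosen is not None:
            best[qname] = chosen
    return best


def trim_terminal_artefacts(
    record: AlignmentRecord, min_terminal_exon: int = 10
) -> AlignmentRecord:
    """Iteratively strip terminal micro-exons and their adjoining introns.

    Splice-aware aligners occasionally anchor a handful of terminal
    bases across a long intron; such a terminal exon shorter than
    ``min_terminal_exon`` aligned bases is removed from either end
    together with its N op, the removed query bases becoming soft
    clips.  ``matches`` is decremented by the removed aligned length
    (clamped at zero).  If trimming would consume the whole alignment
    the record is returned unchanged with a warning.
    """
    if not record.is_mapped or not record.cigar:
        raise ValueError(f"{record.qname}: trimming needs a mapped record with CIGAR")
    ops = parse_cigar(record.cigar)

    lead_clips = []
    while ops and ops[0][1] in "SH":
        lead_clips.append(ops.pop(0))
    tail_clips = []
    while ops and ops[-1][1] in "SH":
        tail_clips.insert(0, ops.pop())

    # exons = maximal runs of non-N ops, separated by single N ops
    def split_exons(core: list[tuple[int, str]]):
        exons: list[list[tuple[int, str]]] = [[]]
        introns: list[int] = []
        for n, op in core:
            if op == "N":
                introns.append(n)
                exons.append([])
            else:
                exons[-1].append((n, op))
        return exons, introns

    exons, introns = split_exons(ops)
    removed_q = [0, 0]  # query bases turned into clips at [left, right]
    removed_t_left = 0
    removed_aligned = 0
    changed = True
    while changed and len(exons) > 1:
        changed = False
        left_aligned = _oplen(exons[0], ALIGN_OPS)
        if left_aligned < min_terminal_exon:
            removed_q[0] += _oplen(exons[0], QUERY_OPS)
            removed_t_left += _oplen(exons[0], TARGET_OPS) + introns[0]
            removed_aligned += left_aligned
            exons.pop(0)
            introns.pop(0)
            changed = True
            continue
        right_aligned = _oplen(exons[-1], ALIGN_OPS)
        if right_aligned < min_terminal_exon:
            removed_q[1] += _oplen(exons[-1], QUERY_OPS)
            removed_aligned += right_aligned
            exons.pop()
            introns.pop()
            changed = True
    if len(exons) == 1 and _oplen(exons[0], ALIGN_OPS) < min_terminal_exon:
        logger.warning("%s: trimming would empty the alignment; left unchanged",
                       record.qname)
        return record
    if removed_q == [0, 0]:
        return record

    core: list[tuple[int, str]] = []
    for i, exon in enumerate(exons):
        if i:
            core.append((introns[i - 1], "N"))
        core.extend(exon)
    new_lead = sum(n for n, _ in lead_clips) + removed_q[0]
    new_tail = sum(n for n, _ in tail_clips) + removed_q[1]
    new_ops = []
    if new_lead:
        new_ops.append((new_lead, "S"))
    new_ops.extend(core)
    if new_tail:
        new_ops.append((new_tail, "S"))

    d_qstart, d_qend = removed_q
    if record.strand == "-":
        d_qstart, d_qend = d_qend, d_qstart
    removed_t_right = (record.tend - record.tstart) - _oplen(core, TARGET_OPS) \
        - removed_t_left
    new_block = _oplen(core, frozenset("M=XID"))
    return replace(
        record,
        qstart=record.qstart + d_qstart,
        qend=record.qend - d_qend,
        tstart=record.tstart + removed_t_left,
        tend=record.tend - removed_t_right,
        matches=max(0, min(record.matches - removed_aligned, new_block)),
        block_len=new_block,
        cigar=cigar_to_string(new_ops),
    )
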