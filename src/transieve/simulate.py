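"""Synthetic fixtures: genomes, gene models, artefact-laden transcript
sets with matching alignments, annotation tables, count tables and
multi-caller DE tables — all with recorded ground truth.

The generator emulates the failure modes genome-guided polishing is
meant to catch:

* ``retained``     — a faithful spliced transcript (exon concatenation,
  ~1% substitutions) that maps across its introns;
* ``atypical``     — a contiguous genomic fragment spanning an intron
  (~2% substitutions): it maps in one ungapped, high-identity block;
* ``low_quality``  — either a transcript mutated at 35% (identity ~0.65)
  or a chimaera whose mappable half covers ~50% of its length;
* ``unmapping``    — random sequence absent from the genome.

Alignments are synthesised directly from the known generative edits
(no aligner dependency), so CIGARs, matches and block lengths are exact
by construction and every identity/coverage is analytically predictable.
The mutation model is substitution-only for that reason.  Everything is
a pure function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AlignmentRecord
from .stats import AnnotationRecord

BASES = np.frombuffer(b"ACGT", dtype="S1")

DEFAULT_CLASS_MIX = {
    "retained": 0.5, "atypical": 0.2, "low_quality": 0.2, "unmapping": 0.1,
}


@dataclass(frozen=True)
class GeneModel:
    """A gene: ordered, non-overlapping exons on one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def validate(self, min_intron: int = 60) -> None:
        if len(self.exons) < 1:
            raise ValueError(f"{self.gene_id}: needs at least one exon")
        prev_end = None
        for start, end in self.exons:
            if not 0 <= start < end:
                raise ValueError(f"{self.gene_id}: bad exon ({start}, {end})")
            if prev_end is not None and start - prev_end < min_intron:
                raise ValueError(f"{self.gene_id}: intron shorter than "
                                 f"{min_intron}")
            prev_end = end

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the generator; the seed is mandatory."""

    seed: int
    n_genes: int = 20
    n_transcripts: int = 100
    exon_len_range: tuple[int, int] = (50, 300)
    intron_len_range: tuple[int, int] = (60, 2000)
    exons_per_gene: tuple[int, int] = (2, 6)
    min_intron: int = 60
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    mut_rate_retained: float = 0.01
    mut_rate_atypical: float = 0.02
    mut_rate_low_quality: float = 0.35
    chimera_fraction: float = 0.5  # of low_quality transcripts
    n_callers: int = 4
    de_fraction: float = 0.10
    planted_min_abs_logfc: float = 1.5
    planted_max_fdr: float = 0.01
    n_libraries: int = 6

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mix must sum to 1, got {total}")
        unknown = set(self.class_mix) - set(DEFAULT_CLASS_MIX)
        if unknown:
            raise ValueError(f"unknown classes in mix: {sorted(unknown)}")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.exon_len_range[0] > self.exon_len_range[1] or \
                self.intron_len_range[0] > self.intron_len_range[1]:
            raise ValueError("infeasible length ranges")
        if self.intron_len_range[0] < self.min_intron:
            raise ValueError("intron range below min_intron")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Substitute exactly ``round(rate * len)`` bases at random positions.

    Substitutions always change the base, so the returned count equals
    the mismatch count of the implied alignment and the identity of a
    full-length mapping is (1 − rate) to within 1/len — the planted
    class margins are deterministic, not subject to sampling noise.
    """
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n_mut = int(round(rate * len(arr)))
    hit = rng.choice(len(arr), size=n_mut, replace=False)
    for i in hit:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode(), n_mut


def make_genome(cfg: FixtureConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """One synthetic chromosome with ``n_genes`` embedded gene models."""
    rng = np.random.default_rng(cfg.seed)
    chrom = "chrS"
    parts: list[str] = []
    models: list[GeneModel] = []
    pos = 0
    for g in range(cfg.n_genes):
        gap = int(rng.integers(200, 800))
        parts.append(_random_seq(rng, gap))
        pos += gap
        n_exons = int(rng.integers(cfg.exons_per_gene[0],
                                   cfg.exons_per_gene[1] + 1))
        exons = []
        for e in range(n_exons):
            if e:
                intron = int(rng.integers(cfg.intron_len_range[0],
                                          cfg.intron_len_range[1] + 1))
                parts.append(_random_seq(rng, intron))
                pos += intron
            exon_len = int(rng.integers(cfg.exon_len_range[0],
                                        cfg.exon_len_range[1] + 1))
            parts.append(_random_seq(rng, exon_len))
            exons.append((pos, pos + exon_len))
            pos += exon_len
        models.append(GeneModel(f"gene{g:04d}", chrom, "+", tuple(exons)))
    parts.append(_random_seq(rng, 500))
    genome = {chrom: "".join(parts)}
    for m in models:
        m.validate(cfg.min_intron)
    return genome, models


def _spliced(genome: dict[str, str], model: GeneModel) -> str:
    seq = genome[model.chrom]
    return "".join(seq[s:e] for s, e in model.exons)


def _spliced_cigar(model: GeneModel) -> str:
    ops = []
    prev_end = None
    for s, e in model.exons:
        if prev_end is not None:
            ops.append(f"{s - prev_end}N")
        ops.append(f"{e - s}M")
        prev_end = e
    return "".join(ops)


def make_transcript_set(
    genome: dict[str, str], models: list[GeneModel], cfg: FixtureConfig
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Transcript sequences plus a per-transcript truth table.

    The truth table records the planted class and the parameters the
    alignment synthesis needs (source gene, substitution count, aligned
    fraction for chimaeras).
    """
    if not models:
        raise ValueError("need at least one gene model")
    rng = np.random.default_rng(cfg.seed + 1)
    classes = list(cfg.class_mix)
    n_per = {
        k: int(round(cfg.class_mix[k] * cfg.n_transcripts)) for k in classes
    }
    # fix rounding drift on the most abundant class
    drift = cfg.n_transcripts - sum(n_per.values())
    n_per[max(n_per, key=n_per.get)] += drift
    if n_per.get("low_quality", 0) and cfg.chimera_fraction > 0 and len(models) < 2:
        raise ValueError("chimaera generation needs at least two genes")

    multi = [m for m in models if len(m.exons) >= 2]
    if not multi:
        raise ValueError("need at least one multi-exon gene model")
    seqs: list[tuple[str, str]] = []
    rows = []
    idx = 0

    def add(seq, klass, gene, n_mut, aligned_len, variant):
        nonlocal idx
        qname = f"tt{idx:05d}"
        idx += 1
        seqs.append((qname, seq))
        rows.append((qname, klass, gene, n_mut, len(seq), aligned_len, variant))

    for _ in range(n_per.get("retained", 0)):
        m = multi[rng.integers(len(multi))]
        seq, n_mut = _mutate(rng, _spliced(genome, m), cfg.mut_rate_retained)
        add(seq, "retained", m.gene_id, n_mut, len(seq), "spliced")

    for _ in range(n_per.get("atypical", 0)):
        m = multi[rng.integers(len(multi))]
        i = int(rng.integers(len(m.exons) - 1))
        start = (m.exons[i][0] + m.exons[i][1]) // 2
        end = (m.exons[i + 1][0] + m.exons[i + 1][1]) // 2
        frag = genome[m.chrom][start:end]
        seq, n_mut = _mutate(rng, frag, cfg.mut_rate_atypical)
        add(seq, "atypical", m.gene_id, n_mut, len(seq),
            f"fragment:{start}-{end}")

    for j in range(n_per.get("low_quality", 0)):
        chimera = rng.random() < cfg.chimera_fraction
        m = multi[rng.integers(len(multi))]
        base = _spliced(genome, m)
        if chimera:
            half, n_mut = _mutate(rng, base, cfg.mut_rate_retained)
            tail = _random_seq(rng, len(half))
            add(half + tail, "low_quality", m.gene_id, n_mut,
                len(half), "chimera")
        else:
            seq, n_mut = _mutate(rng, base, cfg.mut_rate_low_quality)
            add(seq, "low_quality", m.gene_id, n_mut, len(seq), "mutated")

    for _ in range(n_per.get("unmapping", 0)):
        length = int(rng.integers(200, 1001))
        add(_random_seq(rng, length), "unmapping", "", 0, 0, "random")

    truth = pd.DataFrame(
        rows,
        columns=["qname", "planted_class", "source_gene", "n_mut",
                 "qlen", "aligned_len", "variant"],
    )
    return seqs, truth


def make_alignments(
    truth: pd.DataFrame, models: list[GeneModel], cfg: FixtureConfig,
    genome: dict[str, str],
) -> list[AlignmentRecord]:
    """PAF-style records consistent with each planted class.

    CIGARs are derived from the generative edits, so matches and block
    lengths are exact.  Unmapping transcripts yield no record.
    """
    by_id = {m.gene_id: m for m in models}
    tlen = {chrom: len(seq) for chrom, seq in genome.items()}
    records = []
    for row in truth.itertuples(index=False):
        if row.planted_class == "unmapping":
            continue
        m = by_id[row.source_gene]
        if row.planted_class == "atypical":
            start, end = map(int, row.variant.split(":")[1].split("-"))
            length = end - start
            rec = AlignmentRecord(
                qname=row.qname, qlen=length, qstart=0, qend=length,
                strand="+", tname=m.chrom, tlen=tlen[m.chrom],
                tstart=start, tend=end, matches=length - row.n_mut,
                block_len=length, mapq=60, cigar=f"{length}M",
            )
        elif row.variant == "chimera":
            span = m.span
            cigar = _spliced_cigar(m) + f"{row.qlen - row.aligned_len}S"
            rec = AlignmentRecord(
                qname=row.qname, qlen=row.qlen, qstart=0,
                qend=row.aligned_len, strand="+", tname=m.chrom,
                tlen=tlen[m.chrom], tstart=span[0], tend=span[1],
                matches=row.aligned_len - row.n_mut,
                block_len=row.aligned_len, mapq=60, cigar=cigar,
            )
        else:  # spliced, possibly heavily mutated
            span = m.span
            rec = AlignmentRecord(
                qname=row.qname, qlen=row.qlen, qstart=0, qend=row.qlen,
                strand="+", tname=m.chrom, tlen=tlen[m.chrom],
                tstart=span[0], tend=span[1],
                matches=row.qlen - row.n_mut, block_len=row.qlen,
                mapq=60, cigar=_spliced_cigar(m),
            )
        rec.validate()
        records.append(rec)
    return records


def make_annotations(
    cfg: FixtureConfig, qnames: list[str], redundancy_rate: float = 0.3
) -> list[AnnotationRecord]:
    """Annotation records with a planted fraction of shared orthologue ids."""
    rng = np.random.default_rng(cfg.seed + 2)
    statuses = ["complete", "c_terminal", "n_terminal", "internal",
                "new_coding", "ncRNA", "unknown", "artifact"]
    probs = [0.30, 0.10, 0.10, 0.05, 0.15, 0.05, 0.20, 0.05]
    out = []
    n_orth_pool = max(1, int(len(qnames) * (1 - redundancy_rate)))
    for q in qnames:
        status = statuses[rng.choice(len(statuses), p=probs)]
        orth = None
        if status in ("complete", "c_terminal", "n_terminal", "internal"):
            orth = f"P{rng.integers(n_orth_pool):05d}"
        out.append(AnnotationRecord(q, orth, status))
    return out


def make_counts(cfg: FixtureConfig, qnames: list[str]) -> pd.DataFrame:
    """Negative-binomial count table, one column per library."""
    rng = np.random.default_rng(cfg.seed + 3)
    data = rng.negative_binomial(
        n=2, p=0.02, size=(len(qnames), cfg.n_libraries)
    )
    return pd.DataFrame(
        data, index=pd.Index(qnames, name="qname"),
        columns=[f"lib{i:02d}" for i in range(cfg.n_libraries)],
    )


def make_de_tables(
    cfg: FixtureConfig, qnames: list[str] | None = None
) -> tuple[dict[str, pd.DataFrame], set[str]]:
    """Per-caller DE tables with a planted prevalent set.

    Planted transcripts carry |logFC| >= ``planted_min_abs_logfc`` and
    FDR <= ``planted_max_fdr`` in every caller (per-caller jitter stays
    within the margins); all others get logFC near 0 and FDR in
    (0.05, 1], so the consensus under default thresholds recovers the
    planted set exactly.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    if qnames is None:
        qnames = [f"tt{i:05d}" for i in range(cfg.n_transcripts)]
    n = len(qnames)
    n_de = int(round(cfg.de_fraction * n))
    planted_idx = rng.choice(n, size=n_de, replace=False)
    planted = {qnames[i] for i in planted_idx}
    is_de = np.zeros(n, dtype=bool)
    is_de[planted_idx] = True

    base_mag = cfg.planted_min_abs_logfc + rng.exponential(0.7, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    callers = [f"caller{i + 1}" for i in range(cfg.n_callers)]
    tables = {}
    for caller in callers:
        mag = base_mag + rng.normal(0, 0.1, size=n)
        mag = np.maximum(mag, cfg.planted_min_abs_logfc)
        logfc = np.where(
            is_de, sign * mag,
            np.clip(rng.normal(0, 0.25, size=n), -0.95, 0.95),
        )
        fdr = np.where(
            is_de,
            rng.uniform(1e-6, cfg.planted_max_fdr, size=n),
            rng.uniform(0.051, 1.0, size=n),
        )
        tables[caller] = pd.DataFrame(
            {"qname": qnames, "logFC": logfc, "FDR": fdr}
        )
    return tables, planted


def write_fasta(seqs: list[tuple[str, str]], stream) -> None:
    for name, seq in seqs:
        stream.write(f">{name}\n{seq}\n")
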