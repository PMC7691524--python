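"""Multi-algorithm differential-expression consensus.

Several DE callers (edgeR, DESeq2, limma, NOISeq, ...) disagree on de
novo assembled transcriptomes, where redundancy inflates FDR.  The
consensus vote labels a transcript

* ``prevalent`` — called differentially expressed (|FC| > 2, FDR < 0.05,
  both strict) by every caller;
* ``possible``  — called by at least one but not all callers;
* ``none``      — called by no caller.

A transcript missing from one caller's table counts as not-called by
that caller.  Effect sizes are aggregated as the mean of available
log2 fold-changes; the combined FDR is by default the maximum across
callers (so a prevalent call is guaranteed below the per-caller bound),
with Fisher's combination available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as sp_stats


@dataclass(frozen=True)
class ConsensusThresholds:
    """DET call thresholds: fold-change on the linear scale, FDR bound."""

    min_abs_fc: float = 2.0
    max_fdr: float = 0.05

    def __post_init__(self) -> None:
        if self.min_abs_fc <= 1:
            raise ValueError("min_abs_fc must exceed 1")
        if not 0 < self.max_fdr < 1:
            raise ValueError("max_fdr must be in (0, 1)")

    @property
    def min_abs_logfc(self) -> float:
        return math.log2(self.min_abs_fc)


@dataclass(frozen=True)
class ConsensusResult:
    qname: str
    label: str  # prevalent | possible | none
    n_callers_det: int
    n_callers: int
    mean_logfc: float  # nan when no caller reported values
    combined_fdr: float


def call_det(
    logfc: float | None, fdr: float | None,
    t: ConsensusThresholds = ConsensusThresholds(),
) -> bool:
    """True iff |logFC| > log2(min FC) and FDR < max FDR (both strict).

    Missing values (None/NaN) make the call False, mirroring the NA
    convention of callers that filter transcripts before testing.
    """
    if logfc is None or fdr is None:
        return False
    if isinstance(logfc, float) and math.isnan(logfc):
        return False
    if isinstance(fdr, float) and math.isnan(fdr):
        return False
    if not 0 <= fdr <= 1:
        raise ValueError(f"FDR must be in [0, 1], got {fdr}")
    return abs(logfc) > t.min_abs_logfc and fdr < t.max_fdr


def consensus_label(calls: Sequence[bool]) -> str:
    if len(calls) == 0:
        raise ValueError("need at least one caller")
    n = sum(calls)
    if n == len(calls):
        return "prevalent"
    return "possible" if n else "none"


def aggregate_effect(
    logfcs: Sequence[float], fdrs: Sequence[float], method: str = "max"
) -> tuple[float, float]:
    """Mean logFC across callers plus a combined FDR.

    ``max`` (default) is conservative: the combined value is below the
    threshold only when every caller's is.  ``fisher`` applies Fisher's
    chi-square combination to the adjusted values, capped at 1; with
    already-adjusted inputs it is heuristic, provided for exploration.
    """
    logfcs = [x for x in logfcs if x is not None and not math.isnan(x)]
    fdrs = [x for x in fdrs if x is not None and not math.isnan(x)]
    mean_logfc = sum(logfcs) / len(logfcs) if logfcs else float("nan")
    if not fdrs:
        return mean_logfc, float("nan")
    if method == "max":
        combined = max(fdrs)
    elif method == "fisher":
        clipped = [min(max(p, 1e-300), 1.0) for p in fdrs]
        _, combined = sp_stats.combine_pvalues(clipped, method="fisher")
        combined = min(combined, 1.0)
    else:
        raise ValueError(f"unknown combination method: {method}")
    return mean_logfc, combined


def consensus(
    tables: Mapping[str, pd.DataFrame],
    thresholds: ConsensusThresholds = ConsensusThresholds(),
    combine: str = "max",
) -> pd.DataFrame:
    """Vote across caller tables, one ``(qname, logFC, FDR)`` frame each.

    Returns a frame indexed by qname with columns label, n_callers_det,
    n_callers, mean_logFC, combined_FDR, sorted by qname for
    deterministic output.
    """
    if not tables:
        raise ValueError("need at least one caller table")
    per_caller: dict[str, dict[str, tuple[float, float]]] = {}
    all_ids: set[str] = set()
    for caller, df in tables.items():
        cols = {c.lower(): c for c in df.columns}
        qcol = cols.get("qname", df.columns[0])
        fc_col = cols.get("logfc", df.columns[1])
        fdr_col = cols.get("fdr", df.columns[2])
        if df[qcol].duplicated().any():
            dup = df[qcol][df[qcol].duplicated()].iloc[0]
            raise ValueError(f"caller {caller}: duplicate transcript {dup}")
        per_caller[caller] = {
            str(q): (float(fc), float(fdr))
            for q, fc, fdr in zip(df[qcol], df[fc_col], df[fdr_col])
        }
        all_ids.update(per_caller[caller])
    rows = []
    for q in sorted(all_ids):
        calls, logfcs, fdrs = [], [], []
        for caller in tables:
            entry = per_caller[caller].get(q)
            if entry is None:
                calls.append(False)
            else:
                calls.append(call_det(entry[0], entry[1], thresholds))
                logfcs.append(entry[0])
                fdrs.append(entry[1])
        mean_logfc, combined_fdr = aggregate_effect(logfcs, fdrs, combine)
        rows.append(
            (q, consensus_label(calls), sum(calls), len(calls),
             mean_logfc, combined_fdr)
        )
    return pd.DataFrame(
        rows,
        columns=["qname", "label", "n_callers_det", "n_callers",
                 "mean_logFC", "combined_FDR"],
    ).set_index("qname")


def prevalent_set(result: pd.DataFrame) -> set[str]:
    return set(result.index[result["label"] == "prevalent"])


def partition_sets(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Venn-style membership table over >=2 named id-sets.

    One row per id in the union, one boolean column per set, plus a
    ``pattern`` column ("A&B", "A", ...) naming the Venn cell.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets to partition")
    names = list(sets)
    union = sorted(set().union(*sets.values()))
    rows = []
    for q in union:
        member = [q in sets[n] for n in names]
        pattern = "&".join(n for n, m in zip(names, member) if m)
        rows.append((q, *member, pattern))
    return pd.DataFrame(
        rows, columns=["qname", *names, "pattern"]
    ).set_index("qname")


def venn_counts(sets: Mapping[str, set[str]]) -> dict[str, int]:
    """Counts per non-empty Venn cell; values sum to |union|."""
    table = partition_sets(sets)
    return table["pattern"].value_counts().to_dict()


def read_caller_tsv(stream) -> pd.DataFrame:
    """Read one caller's (qname, logFC, FDR) TSV; 'NA' becomes NaN."""
    df = pd.read_csv(stream, sep="\t", na_values=["NA", "na", ""])
    if df.shape[1] < 3:
        raise ValueError("caller table needs qname, logFC and FDR columns")
    return df
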